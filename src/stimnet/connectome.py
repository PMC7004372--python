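"""Synthetic structural connectomes and connectivity/delay initialization.

The analysis operates on per-subject structural connectomes: an n x n
streamline-count matrix ``S`` (how many tractography streamlines connect two
grey-matter regions), an n x n mean fibre-length matrix ``L`` in millimetres,
and a region table following the Desikan parcellation (34 cortical plus 7
subcortical regions per hemisphere, 82 regions in total).

No real diffusion-imaging data ships with this package.  Instead,
:func:`generate_connectome` draws synthetic connectomes with the statistical
structure the downstream model assumes: sparse symmetric adjacency whose edge
probability decays with inter-centroid distance, heavy-tailed (log-normal)
streamline counts, and fibre lengths that exceed the straight-line centroid
distance by a curvature factor.

From a connectome the model's coupling is initialized as

    M_ij = 0.1 * ln(S_ij)   if S_ij > 0, else 0

and axonal conduction delays as ``del_ij = L_ij / v`` with a propagation
speed of ``v`` = 7 m/s, so lengths in mm give delays in ms directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CORTICAL_REGIONS",
    "SUBCORTICAL_REGIONS",
    "DEFAULT_STIMULATION_TARGETS",
    "GeneratorParams",
    "RegionTable",
    "Connectome",
    "CouplingInit",
    "FormatError",
    "generate_connectome",
    "init_weight_matrix",
    "compute_delays",
    "coupling_init",
    "read_connectome",
    "write_connectome",
    "to_graphml",
]

#: The 34 Desikan cortical parcels (per hemisphere).
CORTICAL_REGIONS: tuple[str, ...] = (
    "Bankssts",
    "Caudal Anterior Cingulate",
    "Caudal Middle Frontal",
    "Cuneus",
    "Entorhinal",
    "Frontal Pole",
    "Fusiform",
    "Inferior Parietal",
    "Inferior Temporal",
    "Insula",
    "Isthmus Cingulate",
    "Lateral Occipital",
    "Lateral Orbitofrontal",
    "Lingual",
    "Medial Orbitofrontal",
    "Middle Temporal",
    "Paracentral",
    "Parahippocampal",
    "Pars Opercularis",
    "Pars Orbitalis",
    "Pars Triangularis",
    "Pericalcarine",
    "Postcentral",
    "Posterior Cingulate",
    "Precentral",
    "Precuneus",
    "Rostral Anterior Cingulate",
    "Rostral Middle Frontal",
    "Superior Frontal",
    "Superior Parietal",
    "Superior Temporal",
    "Supramarginal",
    "Temporal Pole",
    "Transverse Temporal",
)

#: The 7 subcortical regions included in the 82-region parcellation.
SUBCORTICAL_REGIONS: tuple[str, ...] = (
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
)

#: Regions receiving cathodal stimulation (left hemisphere).
DEFAULT_STIMULATION_TARGETS: tuple[str, ...] = (
    "Amygdala",
    "Hippocampus",
    "Parahippocampal",
)

#: Labels that must be present for toy parcellations so the default
#: stimulation targets remain addressable at any n.
_TOY_PRIORITY_LEFT = DEFAULT_STIMULATION_TARGETS


class FormatError(ValueError):
    """Malformed or inconsistent connectome files."""


@dataclass(frozen=True)
class GeneratorParams:
    """Settings of the synthetic connectome generator.

    edge_density
        Target fraction of region pairs connected by at least one
        streamline.  Empirical Desikan-scale streamline connectomes are
        sparse; the default aims at 25% of pairs.
    decay_scale_mm
        Length constant of the exponential distance decay of the edge
        probability.
    curvature_factor
        Fibre trajectories are longer than the straight line between the
        region centroids; lengths are Euclidean distance times this factor.
    log_count_mean, log_count_sigma
        Parameters of the log-normal distribution of streamline counts on
        present edges (heavy right tail, as in real count matrices).
    min_separation_mm
        Minimum distance between region centroids, which bounds the
        smallest conduction delay away from zero.
    """

    edge_density: float = 0.25
    decay_scale_mm: float = 30.0
    curvature_factor: float = 1.2
    log_count_mean: float = 3.0
    log_count_sigma: float = 1.0
    min_separation_mm: float = 8.0

    def validate(self) -> None:
        if not (0.0 < self.edge_density <= 1.0):
            raise ValueError(
                f"edge_density must lie in (0, 1], got {self.edge_density}"
            )
        if self.decay_scale_mm <= 0:
            raise ValueError(
                f"decay_scale_mm must be positive, got {self.decay_scale_mm}"
            )
        if self.curvature_factor < 1.0:
            raise ValueError(
                "curvature_factor must be >= 1 (fibres cannot be shorter than "
                f"the straight line), got {self.curvature_factor}"
            )
        if self.log_count_sigma < 0:
            raise ValueError("log_count_sigma must be nonnegative")
        if self.min_separation_mm <= 0:
            raise ValueError("min_separation_mm must be positive")


@dataclass
class RegionTable:
    """Region metadata: labels, hemisphere, tissue class and centroids (mm).

    ``table`` columns: region_id (1-based), label, hemisphere (left|right),
    tissue_class (cortical|subcortical), x_mm, y_mm, z_mm.  (label,
    hemisphere) pairs are unique; homologous regions share the label.
    """

    table: pd.DataFrame

    REQUIRED_COLUMNS = (
        "region_id",
        "label",
        "hemisphere",
        "tissue_class",
        "x_mm",
        "y_mm",
        "z_mm",
    )

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n(self) -> int:
        return len(self.table)

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"region table missing columns: {missing}")
        if list(self.table["region_id"]) != list(range(1, self.n + 1)):
            raise FormatError("region_id must be a contiguous 1-based index")
        pairs = list(zip(self.table["label"], self.table["hemisphere"]))
        if len(set(pairs)) != len(pairs):
            raise FormatError("(label, hemisphere) pairs must be unique")
        bad_hemi = set(self.table["hemisphere"]) - {"left", "right"}
        if bad_hemi:
            raise FormatError(f"unknown hemisphere values: {sorted(bad_hemi)}")
        bad_tissue = set(self.table["tissue_class"]) - {"cortical", "subcortical"}
        if bad_tissue:
            raise FormatError(f"unknown tissue_class values: {sorted(bad_tissue)}")

    def centroids(self) -> np.ndarray:
        """n x 3 array of centroid coordinates in mm."""
        return self.table[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    def unique_labels(self) -> list[str]:
        """Hemisphere-qualified labels, e.g. ``L.Amygdala``."""
        prefix = self.table["hemisphere"].map({"left": "L", "right": "R"})
        return (prefix + "." + self.table["label"]).tolist()

    def find(self, label: str, hemisphere: str = "left") -> int:
        """0-based row index of a region by label and hemisphere."""
        hit = self.table.index[
            (self.table["label"] == label) & (self.table["hemisphere"] == hemisphere)
        ]
        if len(hit) == 0:
            raise KeyError(
                f"region {label!r} ({hemisphere} hemisphere) not found in region table"
            )
        return int(hit[0])

    def resolve_targets(
        self, labels: tuple[str, ...] | list[str], hemisphere: str = "left"
    ) -> list[int]:
        return [self.find(lbl, hemisphere) for lbl in labels]


@dataclass
class Connectome:
    """A single subject's structural connectome.

    S : n x n symmetric nonnegative-integer streamline counts, zero diagonal.
    L : n x n symmetric fibre lengths in mm, positive wherever S > 0.
    """

    S: np.ndarray
    L: np.ndarray
    regions: RegionTable
    subject_id: str = "synthetic"
    group_label: str = "healthy"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S)
        self.L = np.asarray(self.L, dtype=float)
        self.validate()

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean structural adjacency (S > 0)."""
        return self.S > 0

    def validate(self) -> None:
        n = self.regions.n
        if self.S.shape != (n, n):
            raise FormatError(
                f"S has shape {self.S.shape}, region table has {n} rows"
            )
        if self.L.shape != (n, n):
            raise FormatError(
                f"L has shape {self.L.shape}, region table has {n} rows"
            )
        if np.any(self.S < 0):
            raise FormatError("S has negative entries")
        if not np.array_equal(self.S, self.S.T):
            i, j = np.argwhere(self.S != self.S.T)[0]
            raise FormatError(f"S is not symmetric (first mismatch at row {i}, col {j})")
        if not np.allclose(self.L, self.L.T):
            i, j = np.argwhere(~np.isclose(self.L, self.L.T))[0]
            raise FormatError(f"L is not symmetric (first mismatch at row {i}, col {j})")
        if np.any(np.diag(self.S) != 0):
            raise FormatError("S has nonzero diagonal entries")
        if np.any((self.S > 0) & (self.L <= 0)):
            i, j = np.argwhere((self.S > 0) & (self.L <= 0))[0]
            raise FormatError(
                f"edge ({i},{j}) has streamlines but non-positive fibre length"
            )
        if self.group_label not in ("healthy", "epileptic"):
            raise FormatError(f"unknown group_label {self.group_label!r}")


@dataclass
class CouplingInit:
    """Initial inter-region weights, conduction delays and structural mask."""

    W0: np.ndarray
    delays_ms: np.ndarray
    structural_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.W0[~self.structural_mask] != 0):
            raise ValueError("W0 must vanish off the structural mask")
        on = self.structural_mask
        if np.any(~np.isfinite(self.delays_ms[on])) or np.any(self.delays_ms[on] <= 0):
            raise ValueError("delays must be finite and positive on the mask")


# ---------------------------------------------------------------------------
# Region geometry
# ---------------------------------------------------------------------------

def _sample_hemisphere(
    rng: np.random.Generator,
    n_cortical: int,
    n_subcortical: int,
    side: int,
    min_sep: float,
) -> np.ndarray:
    """Sample centroids for one hemisphere.

    Cortical regions live in an outer ellipsoidal shell, subcortical regions
    medially (small |x|), mirroring gross brain geometry well enough that
    Euclidean-distance rankings are meaningful.  ``side`` is -1 (left) or +1
    (right).  Points are rejected until at least ``min_sep`` mm apart.
    """
    semi = np.array([30.0, 65.0, 50.0])  # hemisphere semi-axes, mm
    points: list[np.ndarray] = []

    def _accept(p: np.ndarray) -> bool:
        return all(np.linalg.norm(p - q) >= min_sep for q in points)

    def _draw(radial_lo: float, radial_hi: float, medial: bool) -> np.ndarray:
        for _ in range(10_000):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            r = rng.uniform(radial_lo, radial_hi)
            p = v * r * semi
            p[0] = abs(p[0])
            if medial:
                p[0] *= 0.35
            p[0] = side * (p[0] + 4.0)  # keep hemispheres separated
            if _accept(p):
                return p
        raise RuntimeError(
            "could not place region centroids with the requested separation; "
            "decrease min_separation_mm or n_regions"
        )

    for _ in range(n_cortical):
        points.append(_draw(0.7, 1.0, medial=False))
    for _ in range(n_subcortical):
        points.append(_draw(0.2, 0.5, medial=True))
    return np.array(points)


def _make_region_table(n_regions: int, rng: np.random.Generator, min_sep: float) -> RegionTable:
    if n_regions == 2 * (len(CORTICAL_REGIONS) + len(SUBCORTICAL_REGIONS)):
        per_hemi = [(lbl, "cortical") for lbl in CORTICAL_REGIONS] + [
            (lbl, "subcortical") for lbl in SUBCORTICAL_REGIONS
        ]
        left = per_hemi
        right = per_hemi
    else:
        n_left = n_regions // 2
        n_right = n_regions - n_left

        def _toy_labels(n: int, priority: tuple[str, ...]) -> list[tuple[str, str]]:
            labels: list[tuple[str, str]] = []
            for k in range(n):
                if k < len(priority):
                    lbl = priority[k]
                    tissue = "subcortical" if lbl in SUBCORTICAL_REGIONS else "cortical"
                else:
                    lbl, tissue = f"Region{k + 1}", "cortical"
                labels.append((lbl, tissue))
            return labels

        left = _toy_labels(n_left, _TOY_PRIORITY_LEFT)
        right = _toy_labels(n_right, ())

    rows = []
    for hemi, spec_list, side in (("left", left, -1), ("right", right, +1)):
        n_cort = sum(1 for _, t in spec_list if t == "cortical")
        n_sub = len(spec_list) - n_cort
        # order sampled points: cortical first, then subcortical
        pts = _sample_hemisphere(rng, n_cort, n_sub, side, min_sep)
        cort_iter = iter(pts[:n_cort])
        sub_iter = iter(pts[n_cort:])
        for lbl, tissue in spec_list:
            p = next(cort_iter) if tissue == "cortical" else next(sub_iter)
            rows.append((lbl, hemi, tissue, *p))

    df = pd.DataFrame(rows, columns=["label", "hemisphere", "tissue_class", "x_mm", "y_mm", "z_mm"])
    df.insert(0, "region_id", np.arange(1, len(df) + 1))
    return RegionTable(df)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _edge_probabilities(dist: np.ndarray, params: GeneratorParams) -> np.ndarray:
    """Distance-decayed edge probabilities hitting the target mean density.

    p_ij = min(1, c * exp(-d_ij / lambda)), with c solved by bisection so the
    mean over off-diagonal pairs equals ``edge_density`` (up to saturation).
    """
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    decay = np.exp(-dist[iu] / params.decay_scale_mm)

    def mean_p(c: float) -> float:
        return float(np.minimum(1.0, c * decay).mean())

    lo, hi = 0.0, 1.0
    while mean_p(hi) < params.edge_density and hi < 1e12:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < params.edge_density:
            lo = mid
        else:
            hi = mid
    p = np.zeros((n, n))
    p[iu] = np.minimum(1.0, hi * decay)
    return p


def generate_connectome(
    n_regions: int = 82,
    seed: int = 0,
    gen_params: GeneratorParams | None = None,
    subject_id: str | None = None,
    group_label: str = "healthy",
) -> Connectome:
    """Draw a synthetic subject connectome.

    Deterministic in ``(n_regions, seed, gen_params)``.  Edge presence decays
    with centroid distance, nonzero counts are log-normal, and fibre length is
    the centroid distance times the curvature factor (hence >= the Euclidean
    distance).
    """
    if n_regions < 4:
        raise ValueError(f"n_regions must be >= 4, got {n_regions}")
    params = gen_params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng(seed)

    regions = _make_region_table(n_regions, rng, params.min_separation_mm)
    xyz = regions.centroids()
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)

    p = _edge_probabilities(dist, params)
    iu = np.triu_indices(n_regions, k=1)
    present = rng.random(len(iu[0])) < p[iu]
    counts = np.exp(
        rng.normal(params.log_count_mean, params.log_count_sigma, size=len(iu[0]))
    )
    counts = np.maximum(1, np.round(counts)).astype(np.int64)
    counts[~present] = 0

    S = np.zeros((n_regions, n_regions), dtype=np.int64)
    S[iu] = counts
    S = S + S.T

    L = np.where(S > 0, dist * params.curvature_factor, 0.0)

    return Connectome(
        S=S,
        L=L,
        regions=regions,
        subject_id=subject_id or f"syn{seed:04d}",
        group_label=group_label,
    )


# ---------------------------------------------------------------------------
# Coupling initialization
# ---------------------------------------------------------------------------

def init_weight_matrix(S: np.ndarray, scale: float = 0.1, base: float = math.e) -> np.ndarray:
    """Map streamline counts to initial coupling weights.

    ``M_ij = scale * log(S_ij)`` where ``S_ij > 0``, else 0.  The logarithm is
    natural by default (``base`` is configurable); counts of exactly 1 map to
    exactly 0.
    """
    S = np.asarray(S)
    if np.any(S < 0):
        raise ValueError("streamline counts must be nonnegative")
    if base <= 1.0:
        raise ValueError("log base must exceed 1")
    with np.errstate(divide="ignore"):
        M = np.where(S > 0, scale * np.log(np.maximum(S, 1)) / math.log(base), 0.0)
    return M


def compute_delays(L: np.ndarray, speed_m_per_s: float = 7.0) -> np.ndarray:
    """Conduction delays in ms from fibre lengths in mm.

    A speed of v m/s equals v mm/ms, so ``del_ij = L_ij / v`` directly gives
    milliseconds (70 mm at 7 m/s -> 10 ms).
    """
    L = np.asarray(L, dtype=float)
    if speed_m_per_s <= 0:
        raise ValueError(f"propagation speed must be positive, got {speed_m_per_s}")
    if np.any(L < 0):
        raise ValueError("fibre lengths must be nonnegative")
    return L / speed_m_per_s


def coupling_init(
    connectome: Connectome,
    speed_m_per_s: float = 7.0,
    weight_scale: float = 0.1,
    log_base: float = math.e,
) -> CouplingInit:
    """Weights, delays and mask for one subject, ready for the network model."""
    W0 = init_weight_matrix(connectome.S, scale=weight_scale, base=log_base)
    delays = compute_delays(connectome.L, speed_m_per_s)
    return CouplingInit(W0=W0, delays_ms=delays, structural_mask=connectome.mask)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _write_matrix_tsv(path, M: np.ndarray, labels: list[str], fmt: str) -> None:
    df = pd.DataFrame(M, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=fmt)


def _read_matrix_tsv(path, labels: list[str], name: str) -> np.ndarray:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise FormatError(f"could not parse {name} matrix at {path}: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise FormatError(
            f"{name} matrix at {path} is {df.shape[0]}x{df.shape[1]}, expected square"
        )
    if len(df) != len(labels):
        raise FormatError(
            f"{name} matrix has {len(df)} rows but the region table has {len(labels)}"
        )
    if list(df.index) != labels or list(df.columns) != labels:
        raise FormatError(
            f"{name} matrix row/column labels do not match the region table"
        )
    return df.to_numpy()


def write_connectome(connectome: Connectome, directory) -> None:
    """Write S.tsv, L.tsv and regions.csv (plus meta.csv) into a directory."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = connectome.regions.unique_labels()
    _write_matrix_tsv(directory / "S.tsv", connectome.S, labels, fmt="%d")
    _write_matrix_tsv(directory / "L.tsv", connectome.L, labels, fmt="%.17g")
    connectome.regions.table.to_csv(directory / "regions.csv", index=False, float_format="%.17g")
    pd.DataFrame(
        [{"subject_id": connectome.subject_id, "group_label": connectome.group_label}]
    ).to_csv(directory / "meta.csv", index=False)


def read_connectome(directory) -> Connectome:
    """Read a connectome directory written by :func:`write_connectome`."""
    from pathlib import Path

    directory = Path(directory)
    try:
        table = pd.read_csv(directory / "regions.csv")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read region table: {exc}") from exc
    regions = RegionTable(table)
    labels = regions.unique_labels()
    S = _read_matrix_tsv(directory / "S.tsv", labels, "S")
    L = _read_matrix_tsv(directory / "L.tsv", labels, "L")
    meta_path = directory / "meta.csv"
    subject_id, group_label = "unknown", "healthy"
    if meta_path.exists():
        meta = pd.read_csv(meta_path).iloc[0]
        subject_id, group_label = str(meta["subject_id"]), str(meta["group_label"])
    return Connectome(
        S=S.astype(np.int64), L=L, regions=regions,
        subject_id=subject_id, group_label=group_label,
    )


def to_graphml(connectome: Connectome, path, weights: np.ndarray | None = None) -> None:
    """Export the (optionally weighted) structural graph as GraphML."""
    import networkx as nx

    W = weights if weights is not None else init_weight_matrix(connectome.S)
    g = nx.Graph()
    labels = connectome.regions.unique_labels()
    for idx, row in connectome.regions.table.iterrows():
        g.add_node(
            labels[idx],
            hemisphere=row["hemisphere"],
            tissue_class=row["tissue_class"],
            x_mm=float(row["x_mm"]),
            y_mm=float(row["y_mm"]),
            z_mm=float(row["z_mm"]),
        )
    for i, j in zip(*np.nonzero(np.triu(connectome.S, k=1))):
        g.add_edge(
            labels[i],
            labels[j],
            streamlines=int(connectome.S[i, j]),
            length_mm=float(connectome.L[i, j]),
            weight=float(W[i, j]),
        )
    nx.write_graphml(g, path)
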