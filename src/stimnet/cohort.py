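"""Multi-subject experiment orchestration and group-level reporting.

A cohort experiment mirrors the study design: synthetic subjects are drawn
per group, and three groups are simulated —

* healthy:   healthy-group connectomes, all-healthy node parameters;
* epileptic: epileptic-group connectomes, the stimulated regions
  parameterized as epileptogenic;
* control:   each epileptic subject's connectome re-simulated with the
  all-healthy model (a 1:1 matched control).

For every subject/group entry a stimulated and an unstimulated run execute
with identical clocks, the effect measures are computed, and per-subject
summaries land in an output directory keyed by a manifest.  Reporting
aggregates per-group means +/- SD of the headline quantities (global effect
at stimulation end, persistence rate, stimulated-node local effects),
pairwise two-tailed t-tests, Cohen's d values, and the matched-vs-random
correlation of the global-effect traces.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import GeneratorParams, generate_connectome, write_connectome
from .engine import (
    SECOND_MS,
    SimulationConfig,
    StimulationProtocol,
    run_paired,
)
from .metrics import effect_series, persistence_rate, stabilization_time, detect_secondary_excitation
from .plasticity import PlasticityConfig
from .stats import cohens_d, matched_vs_random_correlation, two_sample_test

__all__ = ["CohortSpec", "run_cohort", "report"]

GROUPS = ("healthy", "epileptic", "control")


@dataclass(frozen=True)
class CohortSpec:
    """Subjects, seeds and shared configuration of one cohort experiment."""

    n_healthy: int = 5
    n_epileptic: int = 5
    n_regions: int = 82
    base_seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    protocol: StimulationProtocol = field(default_factory=StimulationProtocol)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    gen_params: GeneratorParams = field(default_factory=GeneratorParams)

    def subject_seeds(self) -> dict[str, list[int]]:
        """Unique per-subject connectome seeds, derived from the base seed."""
        healthy = [self.base_seed * 1000 + k for k in range(self.n_healthy)]
        epileptic = [
            self.base_seed * 1000 + 500 + k for k in range(self.n_epileptic)
        ]
        return {"healthy": healthy, "epileptic": epileptic}

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for key, sub in (("sim", SimulationConfig), ("protocol", StimulationProtocol),
                         ("plasticity", PlasticityConfig), ("gen_params", GeneratorParams)):
            if key in raw:
                block = raw.pop(key)
                for tup_key in ("target_labels", "initial_state"):
                    if tup_key in block:
                        block[tup_key] = tuple(block[tup_key])
                kwargs[key] = sub(**block)
        return cls(**raw, **kwargs)


def _subject_entries(spec: CohortSpec):
    """(subject_id, group, connectome_seed, connectome_group) work list."""
    seeds = spec.subject_seeds()
    entries = []
    for k, seed in enumerate(seeds["healthy"]):
        entries.append((f"H{k:02d}", "healthy", seed, "healthy"))
    for k, seed in enumerate(seeds["epileptic"]):
        entries.append((f"E{k:02d}", "epileptic", seed, "epileptic"))
        entries.append((f"E{k:02d}", "control", seed, "epileptic"))
    return entries


def _run_entry(spec: CohortSpec, subject_id: str, group: str, seed: int,
               conn_group: str, entry_dir: Path) -> dict:
    connectome = generate_connectome(
        spec.n_regions, seed, spec.gen_params,
        subject_id=subject_id, group_label=conn_group,
    )
    stim, nostim = run_paired(
        connectome, group, spec.sim, spec.protocol, spec.plasticity
    )
    eff = effect_series(stim, nostim)
    onset = stim.provenance["onset_ms"]
    end = onset + stim.provenance["duration_ms"]
    t_final = eff.times_ms[-1]
    targets = stim.provenance["targets"]

    d_stim = eff.d[:, targets]
    i_end = int(np.argmin(np.abs(eff.times_ms - end)))
    try:
        r = persistence_rate(eff.times_ms, eff.D, end, t_final)
    except ZeroDivisionError:
        r = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stab = [
            stabilization_time(eff.times_ms, d_stim[:, k])
            for k in range(d_stim.shape[1])
        ]
    flags = detect_secondary_excitation(eff, targets, onset_ms=onset)

    entry_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_ms": eff.times_ms, "D": eff.D}).to_csv(
        entry_dir / "D.csv", index=False
    )
    tidy = pd.DataFrame(eff.d, columns=[f"node{j}" for j in range(eff.d.shape[1])])
    tidy.insert(0, "time_ms", eff.times_ms)
    tidy.to_csv(entry_dir / "d.csv", index=False)
    flags.to_csv(entry_dir / "secondary_flags.csv", index=False)

    summary = {
        "subject_id": subject_id,
        "group": group,
        "connectome_seed": seed,
        "D_end": float(eff.D[i_end]),
        "D_final": float(eff.D[-1]),
        "persistence_rate": r,
        "d_stim_end_mean": float(d_stim[i_end].mean()),
        "d_stim_final_mean": float(d_stim[-1].mean()),
        "stabilization_ms": [None if s is None else float(s) for s in stab],
        "n_secondary_flags": int(len(flags)),
        "onset_ms": float(onset),
        "stim_end_ms": float(end),
    }
    (entry_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_cohort(spec: CohortSpec, out_dir) -> dict:
    """Run every subject of every group; returns (and writes) the manifest.

    Re-running on a completed directory skips finished entries; a directory
    produced under a different spec is refused.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    spec_hash = spec.config_hash()
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") != spec_hash:
            raise RuntimeError(
                f"output directory {out_dir} holds a cohort with a different "
                "configuration; use a fresh directory"
            )
    else:
        manifest = {"config_hash": spec_hash, "entries": {}}

    for subject_id, group, seed, conn_group in _subject_entries(spec):
        key = f"{subject_id}/{group}"
        entry_dir = out_dir / subject_id / group
        if key in manifest["entries"] and (entry_dir / "summary.json").exists():
            continue
        summary = _run_entry(spec, subject_id, group, seed, conn_group, entry_dir)
        manifest["entries"][key] = {
            "subject_id": subject_id,
            "group": group,
            "connectome_seed": seed,
            "path": str(entry_dir.relative_to(out_dir)),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_summaries(out_dir: Path, manifest: dict) -> pd.DataFrame:
    rows, missing = [], []
    for key, entry in manifest["entries"].items():
        path = out_dir / entry["path"] / "summary.json"
        if not path.exists():
            missing.append(str(path))
            continue
        rows.append(json.loads(path.read_text()))
    if missing:
        raise FileNotFoundError(
            "missing metrics for manifest entries:\n" + "\n".join(missing)
        )
    return pd.DataFrame(rows)


def report(out_dir) -> dict:
    """Aggregate a finished cohort into a GroupResult JSON + markdown table."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    df = _load_summaries(out_dir, manifest)

    quantities = ("D_end", "persistence_rate", "d_stim_end_mean", "d_stim_final_mean")
    groups = [g for g in GROUPS if g in set(df["group"])]

    def _summ(vals: pd.Series):
        vals = vals.dropna()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else None
        return mean, sd

    group_stats = {
        g: {q: _summ(df.loc[df["group"] == g, q]) for q in quantities}
        for g in groups
    }

    tests = {}
    for q in quantities:
        for ga, gb in (("epileptic", "healthy"), ("epileptic", "control"),
                       ("healthy", "control")):
            if ga not in groups or gb not in groups:
                continue
            a = df.loc[df["group"] == ga, q].dropna().to_numpy()
            b = df.loc[df["group"] == gb, q].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = two_sample_test(a, b)
            sa = a.std(ddof=1)
            sb = b.std(ddof=1)
            d = cohens_d(a.mean(), sa, b.mean(), sb) if (sa > 0 or sb > 0) else None
            tests[f"{q}:{ga}_vs_{gb}"] = {"t": t, "p": p, "cohens_d": d}

    correlation = None
    if "control" in groups and "epileptic" in groups:
        def _traces(group: str) -> dict[str, np.ndarray]:
            out = {}
            for _, entry in manifest["entries"].items():
                if entry["group"] != group:
                    continue
                trace = pd.read_csv(out_dir / entry["path"] / "D.csv")["D"].to_numpy()
                out[entry["subject_id"]] = trace
            return out

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                correlation = matched_vs_random_correlation(
                    _traces("control"), _traces("epileptic")
                )
            except ValueError:
                correlation = None

    result = {
        "groups": group_stats,
        "tests": tests,
        "matched_vs_random_correlation": correlation,
        "n_subjects": {g: int((df["group"] == g).sum()) for g in groups},
        "note": "no multiple-testing correction applied",
    }
    (out_dir / "group_result.json").write_text(json.dumps(result, indent=2))

    lines = ["# Cohort report", ""]
    lines.append("| quantity | " + " | ".join(groups) + " |")
    lines.append("|---" * (len(groups) + 1) + "|")
    for q in quantities:
        cells = []
        for g in groups:
            mean, sd = group_stats[g][q]
            cells.append(f"{mean:.4f} ± {sd:.4f}" if sd is not None else f"{mean:.4f} ± n/a")
        lines.append(f"| {q} | " + " | ".join(cells) + " |")
    lines.append("")
    if tests:
        lines.append("| comparison | t | p | Cohen's d |")
        lines.append("|---|---|---|---|")
        for name, res in tests.items():
            dtxt = "n/a" if res["cohens_d"] is None else f"{res['cohens_d']:.3f}"
            lines.append(f"| {name} | {res['t']:.3f} | {res['p']:.4f} | {dtxt} |")
        lines.append("")
    if correlation is not None:
        m, r = correlation["matched"], correlation["random"]
        lines.append(
            f"Matched control-epileptic D-trace correlation {m[0]:.4f} ± {m[1]:.4f}; "
            f"random pairs {r[0]:.4f} ± {r[1]:.4f}."
        )
        lines.append("")
    lines.append("_No multiple-testing correction applied._")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
    return result
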