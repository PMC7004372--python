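# Methods

## Model

Each brain region is a three-population neural mass: excitatory *E*,
subtractive-inhibitory *Is* and divisive-inhibitory *Id*.  Subtractive
inhibition enters the excitatory input-output function as a rightward shift
of its threshold (θ argument); divisive (shunting) inhibition enters as a
flattening of its slope (a argument).  The sigmoid is anchored so that
F(0,0,0) = 0 and saturates at k_j = logistic(a_j θ_j/(1+a)); the sigmoid
constants are θ_e = 4, θ_i = 3.7, a_e = 1.3, a_i = 2, the external drives
P_e = 2, P_s = P_d = 1.  The saturation constants are evaluated once at
a = 0 and held fixed during integration (k_e ≈ 0.994514, k_i ≈ 0.999390):
re-evaluating them with the time-varying divisive input would make the
"constant" state-dependent, and a config switch
(`saturation_constant(..., a=...)`) exists for sensitivity checks but is
not used by the integrator.

Regions are coupled through the delayed excitatory activities only:
region i receives Σ_{j≠i} W_ji E_j(t − del_ij).  Weights are initialized
from streamline counts as M_ij = 0.1 ln S_ij (natural log; counts of 0
or 1 give weight 0) and delays as fibre length / 7 m/s, i.e. mm/7 ms.
Self-coupling is carried by the internal weight w1, and the diagonal of W
is forced to zero.

### Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| θ_e, θ_i, a_e, a_i | 4, 3.7, 1.3, 2 | — | standard divisive-inhibition parameterization |
| P_e, P_s, P_d | 2, 1, 1 | — | oscillatory operating point of the node |
| τ_e, τ_i | 20, 20 | ms | typical neural-mass relaxation times; never published for this model, so they are explicit config fields |
| w1..w7 (healthy) | calibrated, see below | — | within the oscillatory range [8, 21] |
| epileptogenic factors | ×1.1 excitatory (w1,w4,w5), ×0.9 inhibitory (w2,w3,w6,w7) | — | mild excitability increase of the stimulated regions |
| conduction speed | 7 | m/s | standard white-matter estimate |
| learning rates | c = 0.1 external, 0.05 internal | 1/update | per 10 ms update tick |
| stimulation | 50% P_e reduction, onset 200 s, 30 min | — | cathodal protocol |

### Internal-weight calibration

The seven internal weights of a healthy region are not published as
readable numbers, so the package calibrates them itself:
`calibrate_healthy_params` draws seeded uniform candidates from [8, 21]^7,
probes each with a 4 s isolated-node run (RK4, dt = 0.5 ms), and keeps the
candidate with the largest sustained peak-to-peak E amplitude over the
final quarter of the probe.  The shipped defaults
(18.798209, 11.374136, 9.979835, 10.590951, 13.619445, 14.657939,
10.529922) are the output of that search (seed 0, 96 candidates) and are
recorded as calibrated values, not published ones.  At this operating point
the isolated node oscillates for P_e = 2, P_s = P_d = 1 and loses sustained
oscillation when the inhibitory populations receive no drive
(P_s = P_d = 0).  The oscillatory window in P_e is narrower at this point
than the nominal 1.1–4 range (no sustained oscillation at P_e ≥ 3); this is
a known limitation of the single-point calibration.

## Plasticity

Both weight families follow Δw = c · Pre(t) · (Post(t) − Post(t−1)) on a
10 ms clock, where t−1 denotes the previous clock tick — the rule lives on
the update clock, not on the integration grid.  For inter-region weights
the presynaptic activity is read at the conduction delay
(Pre(t) = E_i(t − del_ij)); updates are restricted to structurally present
edges (S_ij > 0), since the rule is weight-independent and absent tracts
have no defined delay.  Internal wiring: w1 E→E, w2 Is→E, w3 Id→E,
w4 E→Is, w6 Is→Id are plastic; w5 (E→Id) and w7 (Id→Id) are frozen
(inhibitory-to-inhibitory plasticity has no accepted neural-mass rule).

After each update, incoming inter-region weights per region are rescaled
to sum to 1, and each region's seven internal weights are rescaled to sum
to 1 — the frozen w5, w7 are included in the internal sum (the rule as
literally written), so they are rescaled by the common factor but never
Hebbian-updated; a config flag restricts the rescaling to the plastic
entries for sensitivity analysis.  Negative weights are clipped to zero
before normalization (plain-sum normalization presumes nonnegativity; the
handling of negative weights is implementation policy, not an established
fact).  Note the consequence of the literal internal normalization: the
calibrated weights (scale ~10–20, sum ~90) collapse to sum 1 at the first
update, after which the network operates in a low-gain, weakly oscillatory
regime.  The effect measures are ratio-based and remain well defined, but
absolute effect magnitudes are far smaller than they would be if the
normalization preserved the initial weight mass.

## Integration

The 3n-dimensional delay system (n = 82 → 246 equations) is advanced by
the method of steps with a fixed-step classical RK4 scheme and linear
interpolation of the excitatory history at every required lag (delay lags
are interpolated, not rounded, to the step grid).  A fixed-step scheme was
chosen over an adaptive solver for bit-reproducibility and for clean
interleaving with the 10 ms plasticity clock; weights are held constant
within each plasticity interval.  Default dt = 1 ms, with the constraint
dt ≤ min positive delay enforced (the synthetic generator's minimum
centroid separation of 8 mm keeps the minimum delay above 1 ms at default
settings).  Initial state is (E, Is, Id) = (0.1, 0.1, 0.1) for every
region with constant pre-zero history equal to the initial state; both are
config fields since no published values exist.  Step-halving
self-convergence (empirical order ≥ 2) is the correctness oracle — there is
no trajectory-level reference to compare against, since the original
trajectories depend on solver tolerances and data that are not available.

Scaled-down runs multiply onset, duration, total duration and snapshot
interval by a common `time_scale` and snap them to the plasticity grid
(onset floored at 50 dt to preserve a settling period).  Desk-scale
problem sizes used by the test suite and the acceptance script: 10–20
region networks, 1–5 simulated minutes for invariant checks, a 20-fold
compressed protocol (onset 10 s, 90 s session, 120 s total) for the
qualitative stimulation-response and cohort computations, and 82-region
runs only where dimensionality itself is the question.

## Synthetic connectomes

The generator emulates the statistical shape of Desikan-scale streamline
connectomes: region centroids as two mirrored ellipsoidal clouds
(subcortical regions placed medially, ≥ 8 mm apart), edge probability
decaying exponentially with centroid distance (length constant 30 mm)
calibrated by bisection to a target density of 25%, streamline counts
log-normal (μ = 3, σ = 1 in log space, heavy right tail), and fibre length
as centroid distance × 1.2 curvature.  Healthy and epileptic subjects are
drawn from the same distribution with different seeds — the two groups'
real connectomes show no apparent structural differences — so group
identity is carried by a label and by the node parameterization only.
What the generator does **not** reproduce: true inter-subject covariance,
hemispheric asymmetries, the empirical degree sequence, and any
patient-specific structure.  Tests passing on synthetic connectomes
therefore validate the machinery and its invariants, not patient-level
numbers; the published subject-level means (e.g. D at stimulation end of
2.97% epileptic vs 1.97% healthy at full 24 h scale) are not reproducible
without the original 39 connectomes and are not targets of this package.

## Statistics

Group comparisons use Student's pooled-variance two-tailed t-test (Welch
available by flag); effect sizes use Cohen's d with equal-weight variance
pooling, d = (m_a − m_b)/√((s_a² + s_b²)/2), which reproduces the printed
worked example (3.225 ± 1.220 vs 2.011 ± 1.110 → d ≈ 1.042) from summary
statistics alone.  Trace correlations are Pearson.  No multiple-testing
correction is applied, and the report says so.

Numerical conventions: the persistence rate r = D(t0)/D(t1) uses the
snapshots nearest t0 (stimulation end) and t1 (run end) and is exactly the
printed ratio even though it is < 1 for a growing effect; stabilization of
a trace is the earliest snapshot whose trailing 5-minute coefficient of
variation (sample SD / mean) is below 0.3, with a zero-mean window counted
as not stabilized; secondary-excitation flags use a robust
median + 3·MAD threshold over post-onset peak local effects (the
affected/background boundary is not published, so the threshold is
config); ranking ties are broken by region index; the "connectivity with
stimulated regions" ratio uses the symmetrized initial weight matrix.

## Known limitations

- The literal sum-to-1 internal normalization and the hours-long
  high-amplitude oscillations described for the original model cannot both
  hold; this package follows the equations as printed (see above).
- Single-point calibration of the internal weights narrows the oscillatory
  P_e window relative to the nominal range.
- Effect magnitudes at desk scale are orders of magnitude below the
  published 24 h patient-connectome values; only orderings, invariants and
  qualitative responses are meaningful at this scale.
- One stimulation session only; no multi-session protocols.
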