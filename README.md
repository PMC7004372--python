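# stimnet

Whole-brain simulation of a cathodal transcranial-current-stimulation (TCS)
session and of the long-term structural-connectivity changes it induces, for
computational neuroscientists studying stimulation therapies in temporal-lobe
epilepsy.

## The model

Each of 82 brain regions (Desikan parcellation: 34 cortical + 7 subcortical
per hemisphere) is a modified Wilson-Cowan neural mass with three
populations — excitatory *E*, subtractive-inhibitory *Is* (dendritic
targeting, threshold shift) and divisive-inhibitory *Id* (somatic targeting,
gain reduction):

    τ_e dE_i/dt  = −E_i  + (k_e − E_i)  F_e(w1 E_i + Σ_j W_ji E_j(t − del_ij) + P_e,  w2 Is_i,  w3 Id_i)
    τ_i dIs_i/dt = −Is_i + (k_i − Is_i) F_i(w4 E_i + P_s,  0, 0)
    τ_i dId_i/dt = −Id_i + (k_i − Id_i) F_i(w5 E_i + P_d,  w6 Is_i + w7 Id_i,  0)

with the divisively modulated sigmoid

    F_j(x, θ, a) = 1 / (1 + exp[−(a_j/(1+a)) (x − (θ_j + θ))]) − 1 / (1 + exp[a_j θ_j/(1+a)])

and saturation constants k_j = logistic(a_j θ_j / (1+a)).  Inter-region
coupling W is initialized from streamline counts, M_ij = 0.1 ln S_ij, and
delays from fibre lengths at 7 m/s conduction speed.  Both the inter-region
weights and five of the seven internal weights follow a Hebbian rule every
10 ms of simulated time, Δw = c · Pre(t) · (Post(t) − Post(t−1)), each
update followed by sum normalization (incoming weights per region sum to 1;
the seven internal weights per region sum to 1) to prevent runaway
plasticity.

A stimulation session is a 50% reduction of the excitatory drive P_e of
three left-hemisphere target regions (amygdala, hippocampus,
parahippocampal gyrus) for 30 minutes, starting 200 s into the run.  Every
simulation is run twice — with and without stimulation, otherwise
identical — and the effect is measured as percentage L1 differences between
the twins: globally D(t) over the weight matrix, locally d_i(t) over each
region's internal weights.

No patient diffusion-imaging data ships with the package; a synthetic
connectome generator produces sparse symmetric streamline-count matrices
with distance-decaying connection probability, heavy-tailed counts and
curvature-inflated fibre lengths, with the full Desikan region naming.

## Worked example

A single desk-scale session (82 regions, protocol compressed 20-fold:
onset 10 s, 90 s session, 120 s total):

```
$ python analysis/02_single_subject_session.py --seed 1
Paired run: 82 regions, group=healthy, time scale 0.0500
  stimulation window: 10-100 s (targets: ['L.Amygdala', 'L.Hippocampus', 'L.Parahippocampal'])
  D at stimulation end: 0.00865%
  D at run end:         0.00144%
  persistence rate r:   6.0034
  mean stimulated-node d at stimulation end: 0.01277%
Traces written to results/session/
```

D(t) is zero until stimulation onset (the paired twins are identical by
construction) and grows during the session as the two weight matrices
diverge.  The persistence rate r = D(end of session)/D(end of run)
compares the divergence at the session's end with what remains at the end
of the resting period: r > 1 means the effect decayed after the session
(as here, where most of the divergence relaxes away), r < 1 that it kept
growing.  Absolute magnitudes at desk scale are far below the published
24 h patient-connectome values; orderings and invariants are the
meaningful output (see docs/methods.md).

The analysis sequence is:

1. `analysis/01_generate_connectomes.py` — synthetic subject connectomes,
2. `analysis/02_single_subject_session.py` — one paired session, D/d traces,
3. `analysis/03_secondary_nodes.py` — ranking of non-stimulated regions by
   candidate drivers of secondary excitation (connectivity with the
   stimulated regions, distance, shared-neighbour Jaccard index),
4. `analysis/04_cohort_stats.py` — three-group cohort (healthy / epileptic /
   matched control), group means ± SD, two-tailed t-tests, Cohen's d,
   matched-vs-random trace correlations.

A `stimnet` CLI (`generate`, `simulate`, `metrics`, `cohort run/report`)
wraps the same library calls for shell use.

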