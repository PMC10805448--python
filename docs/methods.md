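# Methods

`wmnet` implements a group-level analysis of white-matter structural brain
networks of the kind used to compare temporal lobe epilepsy (TLE) patients
with normal controls (NC), together with a synthetic cohort generator that
stands in for diffusion-MRI data so the whole pipeline is testable end to end.

## Network model

Nodes are the 90 cerebral regions of the AAL parcellation (45 per hemisphere,
cerebellum excluded); the shipped atlas fixture carries each region's lobe and
cytoarchitectonic class (primary / association / paralimbic / subcortical).
Edges summarise deterministic tractography at the region-pair level: a
streamline count and the mean fractional anisotropy (FA) along the bundle.
An edge enters a subject's network when

* `streamline_count >= min_count` (default 1), and
* `mean_fa > fa_threshold` (default 0.2, strict inequality).

The threshold is strict because the conventional rule is stated as "FA > 0.2";
bundles at exactly 0.2 are excluded, and the threshold is exposed for
sensitivity analyses.  Two matrices result per subject: FA_wei (edge weight =
mean FA) and FA_bin (edge weight = 1), sharing the same nonzero pattern.

## Graph metrics

All metrics treat the network as undirected with non-negative weights.

* **Distances.** Weighted shortest paths run over edge lengths `1/w`
  (reciprocal mapping, the common choice for FA-weighted networks, under which
  a stronger connection is a shorter link); `1 - w` is available as an option.
  Binary networks use hop counts.  Unreachable pairs are kept as an explicit
  sentinel, never fed into arithmetic.
* **Global efficiency** `Eg = mean over ordered pairs of 1/d_ij`, with
  unreachable pairs contributing zero (harmonic convention).  **Nodal
  efficiency** is the same sum restricted to one row, so the node-mean of
  Enodal equals Eg exactly; this identity is tested to 1e-12.
* **Characteristic path length** `Lp` averages `d_ij` over *reachable* ordered
  pairs only and reports the unreachable count alongside; for an empty graph
  Lp is flagged undefined rather than raising.
* **Clustering.** Binary: `C_i = 2 t_i / (k_i (k_i - 1))` with triangle count
  `t_i`, zero when `k_i < 2`.  Weighted: the Onnela geometric-mean form on
  weights normalised by the network maximum (the toolbox default for
  FA-weighted networks).
* **Local efficiency** is the mean over nodes of the efficiency of the
  subgraph induced on each node's neighbours, computed in the same mode
  (binary or weighted) as the parent network.
* **Small-worldness.** `gamma = Cp / C_rand`, `lambda = Lp / L_rand`,
  `sigma = gamma / lambda`, against an ensemble (default 100) of
  degree-preserving Maslov–Sneppen rewirings with 10 accepted double-edge
  swaps per edge; weighted graphs swap edges carrying their weights, so every
  null preserves the degree sequence and the multiset of edge weights exactly.
  A complete graph cannot be rewired and is reported as an explicit error.
* **Hubs.** A region is a hub when its group-mean binary degree exceeds the
  grand mean over regions by more than `sd_multiplier` (default 1.0) standard
  deviations taken over regions.  The cut-off is a convention, not a
  measurement, and is exposed as a parameter.

## Statistics

The group contrast "two-sample t test with age and gender controlled" is the
group term of the additive least-squares model `y ~ group + age + gender`:
its t statistic carries `n - 4` degrees of freedom and reduces exactly to the
classical pooled two-sample t when the covariates carry no information.
Adjusted group means are model predictions at grand-mean covariates.

Multiple testing uses Benjamini–Hochberg FDR at q = 0.05 within explicit
families: the 90 nodal tests of one network kind; the global metrics of one
network kind; each clinical variable's 90 correlations.  Every result row
records its family.  Normality screening is a Kolmogorov–Smirnov test with the
Lilliefors correction (the null's mean and SD are estimated from the sample);
it is advisory and gates nothing.

Partial correlation residualises both variables on the covariates (with
intercept) and correlates the residuals; `p` comes from
`t = r sqrt(df / (1 - r^2))` with `df = n - 2 - k`.  Clinical correlations are
computed for patients only and for the weighted network only (binarisation
discards information), controlling age and gender, plus age at seizure onset
for the duration analyses.

## Synthetic cohort

No public connectome data accompany this kind of study, so the generator is
the canonical input source.  It emulates, with everything configurable from
one dataclass / YAML config:

* **Demographics** (defaults): 18 patients (10 male, age 30.4 ± 8.16, verbal
  IQ 90.00 ± 11.57, performance IQ 95.06 ± 10.90) and 29 controls (17 male,
  age 27.8 ± 5.78, verbal IQ 109.45 ± 11.91, performance IQ 109.00 ± 10.51).
  Gender counts are exact; ages are resampled below 18.
* **Duration / onset copula.**  Duration of epilepsy (13.90 ± 7.15 y) and age
  at onset (16.28 ± 10.69 y) are bivariate Gaussian with correlation −0.632,
  truncated at zero by rejection (resampling, not clipping, to avoid a point
  mass at 0).  Because rejection preferentially removes the long-duration /
  early-onset corner, the *latent* means and correlation are pre-compensated
  by a short deterministic fixed-point search so the truncated sample carries
  the configured moments — the planted values are what the data show.
* **Template network.**  The population template is a kernel-based geometric
  graph: an affinity kernel combines exponential distance decay (scale 40 mm
  on the synthetic coordinates), intra-hemisphere (×1.5), same-lobe (×2) and
  homotopic (×6) factors, and is Sinkhorn-balanced so no region is globally
  over-attractive.  Each node then selects its top-k kernel neighbours under
  small Gumbel jitter, with per-node targets `density_calibration × 8` edges
  (fractional targets resolved by largest remainder) and 2.8× that for the
  eleven configured hub regions (bilateral precuneus and putamen, right
  superior parietal, left middle occipital, left calcarine, right dorsal
  superior frontal, bilateral middle temporal, right inferior temporal).  The
  union of selections is the template.  This construction yields small-world
  topology (clustering far above degree-matched chance at near-random path
  length, sigma ≈ 3 for every subject), a tight background degree
  distribution, and a stable, well-separated hub set — three properties real
  structural connectomes share.  Edge FA values are 0.2 plus a Gamma(2, 0.065)
  excess capped at 0.8, placing realistic mass just above the edge threshold.
* **Subject networks.**  Each subject reuses the cohort template; per-edge FA
  is the template weight times a planted multiplier, plus a shared per-subject
  offset (SD = 0.5 × `edge_noise_sd`) and independent per-edge jitter
  (SD = `edge_noise_sd`, default 0.02), clipped to (0, 1].  Patients' edges
  incident to the affected regions (a temporal/limbic set of eleven regions)
  are multiplied by `fa_attenuation × (1 − duration_slope × duration)`;
  this both weakens surviving edges and pushes marginal ones below the FA
  threshold, which is how the planted effect reaches binary degree and
  topology.  Edge strength in a small set of configured regions co-varies
  with the subject's generated performance/verbal IQ (slope `iq_coupling`
  per z-unit).  Streamline counts are 1 + Poisson with a weight-dependent
  mean.  Per-subject randomness is spawned from (cohort seed, subject
  ordinal), so any subject regenerates in isolation.

### Calibration

The generator's free scale parameters are anchored to the two printed
group-level degrees: grand-mean binary degree 9.782 (NC) and 9.088 (TLE).
The shipped defaults — `density_calibration = 0.797`, `fa_attenuation = 0.85`,
`duration_slope = 0.012 / year` (mean patient multiplier ≈ 0.70) — reproduce
9.79 / 9.09 averaged over ten cohort seeds.  Splitting the patient effect
between a constant and a duration-dependent part keeps the group means at the
anchors while making the planted duration–efficiency coupling recoverable at
n = 18 (partial r ≈ −0.6 on affected regions, the magnitude range such studies
report).  These anchors are realism targets for the synthetic model, not a
claim about the true generative process.

### What the generator does not emulate

Real DWI artefacts (motion, eddy currents, susceptibility), tractography
biases (gyral bias, bottleneck effects), inter-subject anatomical variability
of the template topology, streamline-count weighting, and lateralised disease
effects.  Passing tests therefore demonstrate that the *pipeline* measures and
detects what it claims under a controlled generative model — not that any
specific clinical finding would replicate.

## Numerical choices and degenerate inputs

Empty (all-zero) networks yield zero efficiencies and an undefined-flagged Lp
rather than exceptions, and the CLI logs a warning but continues.  Disconnected
pairs contribute zero to efficiencies and are excluded (and counted) for Lp.
Asymmetry beyond 1e-9 is a validation error.  Rewiring a graph with fewer than
two independent edge pairs raises a named error; a stalled rewiring (no
accepted swap within 100× the target attempts) does too, rather than looping.
The group comparison refuses rank-deficient designs (e.g. group confounded
with a covariate); partial correlation refuses non-positive residual degrees
of freedom and numerically zero residual variance.

## Problem sizes used in the shipped checks

The metric-engine oracle suite compares against brute-force enumeration on
200 random graphs of up to 12 nodes; small-world checks run all 47 synthetic
subjects with 100 nulls each; calibration checks average 10 cohort seeds;
statistical calibration uses 1000 simulated null datasets and a 100 000-sample
closed-form partial-correlation check; copula recovery uses 5000 patients.
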