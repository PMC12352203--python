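# Methods

This note documents the models, conventions and numerical choices behind
`disomap`, in the order the pipeline runs them.

## Coordinates and containers

All residue positions are 1-based and all intervals are inclusive on both
ends ("residues 1–14" contains 14 residues), matching how regions are
reported in the disorder literature. BED exports convert to 0-based
half-open coordinates. Per-residue quantities are `PerResidueTrack`
objects (NumPy arrays with `nan` as the missing marker); variant tables
are pandas DataFrames keyed by (position, alternate residue); interaction
graphs are `networkx.Graph` objects with a `weight` edge attribute on
STRING's 0–1000 integer scale.

## Consensus disorder

The mean disorder profile (MDP) is the per-residue arithmetic mean over
the non-missing predictor scores; missing scores are excluded rather than
imputed because predictors commonly fail on terminal residues. The error
band is the per-residue **sample** standard deviation (ddof = 1), set to 0
where only one predictor reports; a residue missing in every track is an
error rather than silently zero. PPDR counts non-missing residues with
score ≥ 0.5 (the threshold is inclusive). Category boundaries are
half-open: PPDR < 10% highly ordered, 10% ≤ PPDR < 30% moderately
disordered, PPDR ≥ 30% highly disordered, so the three bins partition
[0, 100] exactly.

Threshold-run region extraction returns maximal runs of consecutive
residues with value ≥ threshold; missing values break runs, and runs
shorter than `min_length` are dropped. The default `min_length` is 1 for
generic disordered regions (no minimum is established in the literature)
and 5 for droplet-promoting regions (configurable; published DPRs are
typically ≥ 7 residues).

## Pathogenicity aggregation

Variant strings are accepted in one-letter (`G61E`) and three-letter
(`p.Gly61Glu`) notation and normalised internally. Class cutoffs follow
the AlphaMissense convention; both boundary values 0.34 and 0.564 map to
the ambiguous class (closed interval), which makes the three classes a
partition of [0, 1] — verified by property test. Per-residue means use
only the entries present at a position; a residue with no entries is
missing, never 0, because released substitution tables omit synonymous
rows and may omit positions entirely. Two protein-level means are
reported — the mean over all variants (headline) and the mean of the
per-residue means — with a consistency flag, since they differ whenever
entry counts vary by position. When per-residue class calls are needed
(e.g. for structure colouring), the class cutoffs are applied to the
residue mean.

Structure repainting replaces every atom's B-factor with its residue's
track value × 100 (PDB fixed format keeps two decimals); coordinates,
atom counts and residue numbering are untouched, and residues with
missing values are painted 0.00 with a logged warning. The representative
atom for reading per-residue B-factors (pLDDT in AlphaFold models) is CA,
falling back to the first atom; a multi-chain file requires an explicit
chain selector.

## Disorder–pathogenicity correlation

The per-residue mean pathogenicity is smoothed with a centred moving mean
of window w = 10 before fitting; the MDP enters unsmoothed (a flag allows
smoothing x for sensitivity analysis). For even windows the centre is
broken toward the right: the window at position i covers offsets
−⌈w/2⌉+1 … ⌊w/2⌋ (for w = 10: −4 … +5), truncated at the track ends, with
missing values excluded per window. This keeps the global mean of a
smoothed track within O(w/L) of the original.

The model is the three-parameter decay y = a·exp(−b·x) + c with b ≥ 0.
The offset c is retained by default because smoothed pathogenicity
plateaus above zero on real proteins; a two-parameter form (c = 0) is
available. Fitting uses trust-region least squares with deterministic
initialisation a₀ = max(y) − min(y), b₀ = 1, c₀ = min(y) and tolerances
1e−14 (noiseless instances are recovered to ≈1e−14 in practice; the test
suite asserts 1e−6 over 100 random parameter draws). A numerically
constant response (relative spread ≤ 1e−12, e.g. a smoothed constant
track) short-circuits to the degenerate result a = 0, b = 0, c = mean(y),
R² = 0 with a warning. Goodness of fit is the plain coefficient of
determination R² = 1 − SS_res/SS_tot with no degrees-of-freedom
correction, computed on the fitted pairs.

## Composition profiling

Enrichment/depletion per amino acid is the fractional difference
(C_query − C_background)/C_background, undefined (`nan`, with a warning)
when the background frequency is 0. Results are ordered on the TOP-IDP
scale — C, W, I, Y, F, L, H, V, N, M (order-promoting panel), then R, T,
D, G, A, K, Q, S, E, P (disorder-promoting panel).

Significance compares the query frequency (over its L residues) with the
frequency in a background pseudo-sample (a multinomial draw of size
`background_n`, default 10 000, from the background composition) via a
two-sample Welch t statistic treating residues as Bernoulli observations.
The two-sided p-value is **calibrated by Monte Carlo**: per iteration
(default 10 000, minimum 100) both samples are redrawn from the
background — the null of identical composition — and p is the fraction of
null |t| at least as large as the observed one, with the standard +1
correction. A parametric (Wald) p from plug-in standard errors is badly
anti-conservative here because several amino acids have expected counts
below 10 in a ~500-residue protein; the simulated null restores
calibration (measured family-wise error ≈ 0.04 at α = 0.05 with
Bonferroni m = 20 over 1000 null replicates). An alternative
`bootstrap_ci` method bootstraps the observed query and calls
significance when the Bonferroni-adjusted percentile interval of the
frequency difference excludes zero. Codes absent from both samples have
zero variance; their p is reported as 1 with a warning.

The bundled background (`data/background_globular_synthetic.csv`) is a
synthetic globular-like composition for demonstrations and tests; real
analyses should supply the background appropriate to their question
(e.g. an ordered-protein reference set) as a CSV of frequencies.

## Phase-separation calls

DPRs are threshold runs of the droplet-promoting probability track at
p_DP ≥ 0.60 (inclusive). A protein is a droplet **driver** when its
overall pLLPS ≥ 0.60 regardless of DPRs, a droplet **client** when
pLLPS < 0.60 but at least one DPR exists, and unclassified otherwise —
an exhaustive, mutually exclusive rule. Region-overlap reports give, for
each pair of intersecting intervals, the intersection length and interval
Jaccard index; adjacent intervals do not overlap under inclusive
coordinates.

## Network statistics

Average degree is 2E/N. Clustering is the unweighted local coefficient
2·T_v/(deg_v·(deg_v − 1)) averaged over **all** nodes, with nodes of
degree < 2 contributing 0 rather than being excluded — the STRING and
NetworkX convention. Weights are used only for confidence thresholding
(edges with combined score ≥ min_score·1000 are kept; duplicates collapse
to the maximum weight; self-loops are dropped with a warning).

## Synthetic data

The generators define the study conditions under which the pipeline is
validated:

* **Latent disorder** is a cumulative Gaussian random walk smoothed by a
  centred moving average (window 21) and squashed to [0, 1] by a logistic
  with slope 1.5 on the standardised walk. This yields smooth profiles
  spanning roughly [0.05, 0.95] with an autocorrelation length similar to
  real consensus disorder profiles, which is what makes the decay rate
  identifiable.
* **Predictor tracks** are the latent profile plus independent Gaussian
  noise (sd 0.05), clipped to [0, 1]. The MDP of n such tracks converges
  to the latent profile at the usual 1/√n rate (tested at n = 1, 4, 16).
* **Variant scores**: each residue receives all 19 substitutions, scored
  clip₀¹(a·exp(−b·latent) + c + noise) with defaults (a, b, c) =
  (0.6, 4, 0.2) and noise sd 0.1. Clipping bias is negligible at these
  defaults (a + c = 0.8, two noise sds below 1). The latent profile is
  shared between the disorder tracks and the variant scores, so the
  planted coupling is exact at the latent level and noise enters only at
  observation level.
* **Droplet probabilities**: U(0, 0.55) outside planted segments (safely
  below the 0.60 threshold) and 0.60 + U(0, 0.35) inside, so
  plant-and-recover is exact. Default planted segments are 1–14, 295–322
  and 367–377 on a 543-residue protein, with pLLPS 0.3692 (a droplet
  client).
* **Graphs** are uniform random simple graphs with exactly the configured
  node and edge counts (default 56/268) and integer weights in
  [900, 1000]. Note that a uniform random graph reproduces the degree
  arithmetic but not the high clustering of a curated interaction
  neighbourhood, which reflects correlated biology no random-edge model
  supplies.
* **Sequences** are i.i.d. draws from a configurable composition
  (default uniform over the 20 standard residues).

One global seed fans out to named substreams (seed plus a CRC32 tag of
the generator name), so adding a generator never perturbs the draws of
existing ones, and every generator is bit-reproducible under a fixed
seed.

What passing the synthetic tests shows — and what it does not: the
pipeline recovers planted relationships under observation noise of the
configured magnitude with smooth latent structure. Real predictor errors
are correlated along the sequence and between tools, real variant-score
distributions are bimodal rather than Gaussian around a decay curve, and
real interaction networks are far more clustered than random graphs;
conclusions about real proteins rest on the consumed predictor outputs,
not on these emulations.

## Problem sizes

Defaults mirror a single-protein study: 543 residues, 6 predictors,
10 317 variants, 10-residue smoothing window. The validation suite uses
100 seeds for end-to-end recovery, 1000 replicates for the composition
null, 1000 random tracks for the region-calculus cross-check and 200
random graphs for the clustering cross-check; these sizes give binomial
or Monte-Carlo noise well inside the asserted tolerances.

## Known limitations

* Only missense substitutions are handled; indels and frameshifts are out
  of scope.
* Single-chain structures only; multi-chain files require an explicit
  selector and assemblies are not supported.
* The composition test assumes residues are exchangeable within the
  query; it does not model positional composition biases.
* The exponential-decay fit treats the disorder axis as noise-free;
  errors-in-variables attenuation is negligible at the synthetic noise
  levels but could matter for very noisy consensus profiles.
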