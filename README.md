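# disomap

Per-residue intrinsic disorder, missense pathogenicity and phase-separation
profiling for single proteins.

Intrinsically disordered protein regions (IDPRs) are functional segments
that lack a stable 3D structure. For disease proteins such as CYP1B1 (the
main gene in primary congenital glaucoma, UniProt Q16678, 543 aa), a
recurring question is how disorder relates to the predicted impact of
missense mutations: disordered segments tend to tolerate substitutions,
while mutations in ordered regions are more often damaging. `disomap`
implements the analysis pipeline for that question: it consumes the
standard predictor outputs (per-residue disorder profiles, AlphaMissense
variant score tables, FuzDrop droplet-promoting probabilities, STRING edge
lists, AlphaFold models) and computes the derived quantities, with a
synthetic-data generator providing fully specified inputs with planted
ground truth so every stage is testable offline.

## What it computes

* **Consensus disorder.** The mean disorder profile (MDP) averages K
  per-residue predictor tracks; a residue is disordered when its score is
  ≥ 0.5. The percentage of predicted disordered residues,
  PPDR = 100 · #{i : s_i ≥ 0.5} / L, bins a protein as highly ordered
  (PPDR < 10%), moderately disordered (10% ≤ PPDR < 30%) or highly
  disordered (PPDR ≥ 30%).
* **Pathogenicity aggregation.** Per-variant scores p ∈ [0, 1] classify as
  likely benign (p < 0.34), ambiguous (0.34 ≤ p ≤ 0.564) or likely
  pathogenic (p > 0.564); per-residue means average all substitutions at a
  position, and structures can be repainted with the residue means in the
  B-factor column for visualisation.
* **Disorder–pathogenicity correlation.** The per-residue mean
  pathogenicity is smoothed with a 10-residue moving mean and fitted
  against the (unsmoothed) MDP with an exponential decay
  y = a·exp(−b·x) + c, reported with R² = 1 − SS_res/SS_tot.
* **Composition profiling.** Fractional difference
  (C_x − C_background)/C_background per amino acid, ordered on the TOP-IDP
  scale (C … P), with Monte-Carlo–calibrated two-sample significance and
  Bonferroni correction (m = 20).
* **Phase separation.** Droplet-promoting regions (DPRs) are runs of
  consecutive residues with droplet-promoting probability ≥ 0.60; a
  protein with overall pLLPS ≥ 0.60 is a droplet driver, one with a lower
  pLLPS but at least one DPR is a droplet client.
* **Interaction network.** Node/edge counts, average degree 2E/N and the
  average local (Watts–Strogatz) clustering coefficient of a
  confidence-thresholded STRING-style graph.

## Worked example

The synthetic preset generates a CYP1B1-scale study: a 543-residue
protein, six pseudo-predictor disorder tracks observing one latent smooth
disorder profile, all 19 substitutions per residue with scores planted on
y = 0.6·exp(−4·disorder) + 0.2 plus noise (sd 0.1), a droplet-promoting
probability track with planted DPRs at 1–14, 295–322 and 367–377, and a
56-node / 268-edge random interaction graph.

```python
from disomap import (SimulationConfig, generate_bundle, compute_mdp,
                     per_residue_mean, correlate_disorder_pathogenicity,
                     extract_dprs, classify_llps, summarize, ppdr)

bundle = generate_bundle(SimulationConfig(seed=1))
mdp, band = compute_mdp(bundle.disorder_tracks)
path_mean = per_residue_mean(bundle.variants, bundle.sequence.length)
fit, pairs = correlate_disorder_pathogenicity(mdp, path_mean, window=10)
print(f"exponential decay fit: a={fit.a:.3f} b={fit.b:.3f} c={fit.c:.3f} "
      f"R^2={fit.r_squared:.3f} (planted a=0.6 b=4.0 c=0.2)")
print(f"PPDR of the consensus profile: {ppdr(mdp):.2f}%")
dprs = extract_dprs(bundle.p_dp)
call = classify_llps(bundle.pllps, dprs)
print(f"pLLPS={bundle.pllps} -> {call.classification}; DPRs:",
      [(r.start, r.end) for r in dprs])
s = summarize(bundle.graph)
print(f"network: {s.n_nodes} nodes, {s.n_edges} edges, "
      f"mean degree {s.avg_node_degree:.2f}, clustering {s.avg_local_clustering:.3f}")
```

prints

```
exponential decay fit: a=0.583 b=3.965 c=0.203 R^2=0.974 (planted a=0.6 b=4.0 c=0.2)
PPDR of the consensus profile: 42.17%
pLLPS=0.3692 -> client; DPRs: [(1, 14), (295, 322), (367, 377)]
network: 56 nodes, 268 edges, mean degree 9.57, clustering 0.169
```

The fit recovers the planted decay within a few percent despite variant
noise; the planted droplet-promoting regions come back exactly; with
pLLPS = 0.3692 below the 0.60 driver threshold but non-empty DPRs the
protein is called a droplet client; and the 56-node, 268-edge network has
mean degree 2·268/56 = 9.57.

The same analyses are available from the shell:

```sh
disomap simulate --seed 1 --out-dir sim/
disomap run --sequence sim/protein.fasta --am-table sim/variants.tsv \
    --disorder-csv sim/disorder.csv --fuzdrop sim/fuzdrop.csv \
    --string-edges sim/string_edges.tsv --out-dir results/
disomap classify --am-table sim/variants.tsv --protein-id SYN0001 --variant p.Gly61Glu
```

Real studies substitute their own inputs: a UniProt FASTA, the
AlphaMissense UniProt-substitution TSV restricted to the accession, a
RIDAO-style disorder CSV, a FuzDrop export and a STRING edge list.

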