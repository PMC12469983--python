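# tcrdyn

Longitudinal single-cell T-cell receptor (TCR) repertoire analysis for
paired pre/post-intervention designs, with a synthetic cohort generator
that carries exact ground truth.

## The problem

In single-cell V(D)J sequencing each T cell yields an α (TRA) and a β
(TRB) chain, each with germline V/J segment calls and a hypervariable CDR3
junction. Following patients across an intervention — the motivating
setting is children with celiac disease sampled at diagnosis and again
after months of gluten-free diet (pre_GFD / post_GFD) — raises a set of
linked questions:

- do expanded clones contract, and does clonal diversity rise?
- how much of the repertoire persists between time points?
- do specific TRAV–TRBV chain *pairings* reorganize between conditions
  even when the marginal usage of individual genes stays stable?

`tcrdyn` implements this analysis end to end for users of 10x Genomics
contig annotations or AIRR Rearrangement tables: chain filtering to one
αβ pair per cell, clonotype calling, clonal structure and diversity,
repertoire overlap, CDR3 sequence profiling, pairing-enrichment
statistics and CDR3 similarity networks.

## Methods at a glance

- **Clonotypes.** Cells sharing a key are one clone; keys by gene
  segments (`gene`), CDR3 nucleotide (`nt`), CDR3 amino acid (`aa`), or
  segments + nucleotide CDR3 (`strict`, the default).
- **Diversity.** Shannon entropy H = −Σ pᵢ ln pᵢ, inverse Simpson
  1/Σ pᵢ², Gini–Simpson 1 − Σ pᵢ², normalized entropy H/ln S, bias-corrected
  Chao1 = S + f₁(f₁−1)/(2(f₂+1)), and ACE with rare cutoff 10 — with
  bootstrap resampling at a common downsampling depth so samples of
  different size are comparable, and paired t-tests across patients.
- **Overlap.** Morisita–Horn index on clonal proportions,
  C = 2Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·XY) ∈ [0, 1].
- **Pairing enrichment.** Dense TRAV × TRBV × stratum contingency
  arrays; a generalized Cochran–Mantel–Haenszel test of the pairing ×
  condition association stratified by patient (Q = G′V⁻¹G on
  observed−expected counts under the multiple hypergeometric); per-pair
  2×2 Fisher exact tests with Haldane–Anscombe-corrected odds ratios and
  Benjamini–Hochberg adjustment.
- **Networks.** Nodes are unique CDR3 amino-acid sequences (TRA by
  default); edges join pairs with normalized Levenshtein similarity
  1 − d/max(len) ≥ 0.85; clusters are connected components classified as
  pre-only / post-only / shared.
- **Simulator.** Five patients × two conditions by default, per-sample
  cell counts in the 1500–3500 range, a truncated-geometric clone-size
  body with a uniform expanded tail (no clone above 100 cells), expanded
  clones contracting post-intervention, repertoire turnover into novel
  singletons, and condition-specific TRAV–TRBV log-odds tilts — all
  recorded exactly in a `SimTruth` object.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
from tcrdyn import (SimConfig, simulate_cohort, cohort_cells, call_clonotypes,
                    diversity_profile, morisita_overlap, unique_clone_fraction)
from tcrdyn.clonotypes import iter_patient_pairs

sim = simulate_cohort(SimConfig(seed=42, n_patients=2, cells_per_sample=1000))
cells = cohort_cells(sim)                      # filter chains + join metadata
tables = call_clonotypes(cells, mode="strict")
for pt, pre, post in iter_patient_pairs(tables):
    d_pre, d_post = diversity_profile(pre), diversity_profile(post)
    print(f"{pt}: unique fraction {unique_clone_fraction(pre):.3f} -> "
          f"{unique_clone_fraction(post):.3f}, "
          f"Shannon {d_pre.shannon:.3f} -> {d_post.shannon:.3f}, "
          f"Morisita(pre,post) {morisita_overlap(pre, post):.3f}")
```

prints

```
CEL_01: unique fraction 0.509 -> 0.940, Shannon 3.681 -> 6.302, Morisita(pre,post) 0.450
CEL_02: unique fraction 0.464 -> 0.944, Shannon 3.378 -> 6.443, Morisita(pre,post) 0.293
```

Both simulated patients show the expected post-intervention signature:
the singleton fraction of clonotypes and the Shannon entropy rise as
expanded clones contract, while a Morisita–Horn overlap well above the
between-patient baseline (≈ 0) shows partial within-patient persistence.

The same analysis runs from the shell:

```sh
tcrdyn simulate --outdir cohort --seed 42     # AIRR TSVs + metadata + truth
tcrdyn run --outdir results --seed 42         # full pipeline + manifest
tcrdyn report results                         # condition-comparison summary
```

`tcrdyn run` writes every stage table (clonotypes, size bins, diversity,
overlap matrix, positional profiles, k-mers, gene usage, pairing counts,
Fisher results, CMH summaries, network edge/node lists) plus a
`manifest.json` whose hash is reproducible for a fixed config and seed.

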