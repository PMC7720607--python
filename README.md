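# regendiv

Downstream bulk RNA-seq analysis for comparing the regeneration
transcriptomes of two lateral-line sensory organs: **ampullary organs (AO,
electroreceptive)** and **neuromasts (NM, mechanoreceptive)**, each profiled
at 12 h and 24 h after neomycin ablation of their sensory cells and in the
untreated (mature) state, against a **general epithelium (EP)** reference
tissue.  The package is aimed at researchers analysing organ-regeneration
time courses who want the complete chain from a count matrix to
expression-divergence gene calls, co-expression networks and enrichment
statistics — plus a simulator of the whole study design so every stage can be
validated against planted truth.

## What it computes

- **Normalization** — TMM (trimmed mean of M-values) scale factors, TPM,
  log2(TPM+1), pairwise Euclidean sample distances and complete-linkage
  hierarchical clustering with Newick export.
- **Differential expression** — exact conditional tests on pooled,
  library-scaled counts.  Conditional on the per-gene total
  *t = y_A + y_B*, the null is *y_A ~ Binomial(t, N_A/(N_A+N_B))* (Poisson
  limit) or a common-dispersion negative binomial with
  Var(Y) = μ + φμ²; two-sided p by tail doubling (binomial mode) or
  minimum-likelihood summation (NB mode); BH-FDR; significance by
  |log2FC| > 1 and FDR < 0.01 (both strict).
- **Expression divergence** — a gene diverges between the organs along the
  regeneration course when it is (1) significantly different between
  untreated AO and NM, (2) not different at 12 hpt, (3) closer at 24 hpt
  than untreated (|log2FC₂₄| < |log2FC_ut|), and (4) consistently higher (or
  consistently lower) in AO at both later timepoints.  Group divergence is
  the Euclidean distance between organ log2FC-to-EP profile vectors.
- **Co-expression** — Pearson correlation of log2FC-to-EP profiles, a
  network with edges where r² > 0.7 (strict), node weight = Σ|r| over
  incident edges, and per-gene correlation quartile summaries (R type-7
  quantiles).
- **Enrichment** — hypergeometric over-representation with all annotated
  genes as background, p = P(X ≥ k) for X ~ Hypergeom(N, K, n), and
  pre-ranked GSEA (weighted Kolmogorov–Smirnov running sum, gene-label
  permutation p-values).
- **Annotation triage** — peptide length gate (> 100 aa), BLAST tabular hit
  filter (query coverage > 70 %, identity > 50 %, best hit per query) and a
  two-source ortholog merge with provenance and conflict reporting.
- **Synthetic data** — negative-binomial counts for the 7-group × 2-replicate
  design with planted gene classes; divergent genes follow the minimal
  trajectory 0 → δ/2 → δ in true AO−NM log2 difference across
  12 hpt → 24 hpt → untreated, recorded in a machine-readable truth table.

## Worked example

```python
import regendiv as rd

cfg = rd.SimulationConfig(n_genes=2000, seed=42)
cm, truth = rd.simulate_counts(cfg)

phi = rd.estimate_common_dispersion(cm, [cm.samples_of(c) for c in rd.ALL_CONDITIONS])
print(f"estimated common dispersion: {phi:.3f}")

tables = {
    tp: rd.exact_test(cm, cm.samples_of(f"AO_{tp}"), cm.samples_of(f"NM_{tp}"),
                      dispersion=phi)
    for tp in ("12hpt", "24hpt", "untreated")
}
n_up, n_down, n_ns, _ = rd.classify_de(tables["untreated"])
print(f"untreated AO vs NM: {n_up} up, {n_down} down, {n_ns} ns")

calls = rd.divergence_filter(tables["12hpt"], tables["24hpt"], tables["untreated"])
ao, nm = rd.split_by_direction(calls)
print(f"divergent genes: {int(calls['passes'].sum())} ({len(ao)} AO-high, {len(nm)} NM-high)")

planted = set(truth.index[truth["gene_class"].str.startswith("divergent")])
called = set(calls.index[calls["passes"]])
print(f"planted divergent recovered: {len(called & planted)}/{len(planted)}")

profiles, _ = rd.fold_change_to_reference(cm, dispersion=phi)
print(rd.organ_distance_by_timepoint(profiles).round(2))
```

Output:

```
estimated common dispersion: 0.094
untreated AO vs NM: 56 up, 45 down, 1899 ns
divergent genes: 36 (22 AO-high, 14 NM-high)
planted divergent recovered: 29/30
12hpt        33.03
24hpt        35.32
untreated    37.97
```

The dispersion estimate recovers the simulated φ = 0.1; about a hundred
genes differ between the mature organs; 36 pass all four divergence
criteria, recovering 29 of the 30 planted divergence-trajectory genes; and
the AO–NM profile distance grows monotonically from 12 hpt (organs most
alike, freshly regenerating) to the untreated state (most divergent, mature)
— the signature the divergence filter is built to detect.

A command-line interface mirrors the library
(`regendiv simulate|normalize|de|diverge|network|enrich|gsea|annotate-filter`);
run `regendiv --help`.

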