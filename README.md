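# circage

Analysis of circular-RNA (circRNA) expression across brain regions, sexes
and ages, starting from back-splice junction (BSJ) read counts.

circRNAs are covalently closed transcripts formed by back-splicing; a read
spanning the head-to-tail junction is the unit of evidence, and the BSJ
count of circRNA *i* in sample *j*, `k_ij`, is its raw expression. `circage`
takes per-sample junction tables (CIRI2 dialect or a minimal 6-column TSV)
for a design of 8 brain regions × 2 sexes × 2 age groups (32 samples) and
runs:

1. **Filtering** — candidate calls need ≥ 2 junction reads; the analysis set
   is defined by a five-rule cascade over samples and brain areas that
   removes loci seen only sporadically at low abundance.
2. **Normalization** — median-of-ratios size factors,
   `s_j = median_i (k_ij / (∏_j k_ij)^{1/m})` over all-positive rows;
   expression is `k_ij / s_j`, tested on the `log2(x+1)` scale.
3. **Specificity screens** — Welch t-tests: one-vs-rest (or consistently
   higher pairwise) per region for spatial-specific circRNAs, two-group
   16-vs-16 for sex- and age-biased circRNAs, plus a label-permutation null
   with the add-one estimator `p = (1 + #{|T_perm| ≥ |T_obs|})/(1 + B)`.
4. **Co-expression modules** — soft-threshold adjacency `|cor|³`,
   topological overlap `TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`,
   average-linkage clustering of `1 − TOM`, module eigengenes (first PC of
   the standardized module).
5. **Host-gene correlation** — Pearson correlation of each circRNA with its
   host mRNA across samples; pairs with |PCC| ≥ 0.3 and p ≤ 0.1 are
   classified positive/negative.
6. **Enrichment** — one-sided hypergeometric tail
   `P(X ≥ k) = Σ_i C(K,i)C(N−K,n−i)/C(N,n)` computed in log space, with BH
   correction across user-supplied gene sets.

A seeded synthetic-data generator (negative-binomial counts with planted
regional/sex/age folds and controlled circRNA–host correlations) provides
ground truth for every stage, so the whole pipeline is testable end to end
without any sequencing data.

## Worked example

```python
from circage import (SimConfig, simulate_counts, expression_filter,
                     size_factors, normalize, spatial_specific, group_biased,
                     permutation_test, compare_sets, hypergeom_tail)
from circage.filtering import apply_filter

cfg = SimConfig(seed=1)                      # 2,000 circRNAs x 32 samples
matrix, samples, truth = simulate_counts(cfg)
kept = apply_filter(matrix, expression_filter(matrix, samples))
sf = size_factors(kept)
norm = normalize(kept, sf)

spatial = spatial_specific(norm, samples, alpha=0.05, mode="vs_each")
age = group_biased(norm, samples, "age")
p_perm = permutation_test(norm, samples, "age", n_perm=10000, seed=1)
overlap = compare_sets(set(age.index[age.called]),
                       set(p_perm.index[p_perm < 0.05]))

print(len(kept.circ_ids), "circRNAs kept")
print(round(sf.factors.min(), 3), "-", round(sf.factors.max(), 3), "size factors")
print(int(spatial.called.sum()), "spatial-specific circRNAs")
print(int(age.called.sum()), "age-biased circRNAs")
print(overlap.intersection, "/", overlap.size_b, "shared with permutation calls")
print(f"{hypergeom_tail(17050, 475, 41, 30):.3g}")
```

prints

```
2000 circRNAs kept
0.675 - 1.361 size factors
97 spatial-specific circRNAs
211 age-biased circRNAs
209 / 212 shared with permutation calls
2.14e-38
```

The simulated set is already well expressed, so the cascade keeps all
2,000 rows; size factors recover the planted library-size spread; the
spatial screen (fold-4 spikes planted in CB and OC) calls 97 circRNAs; the
age screen calls 211 at p < 0.05 (100 planted, the remainder the expected
raw-threshold false positives — the emitted `q_t` column gives the
FDR-controlled set), and the t-test and permutation calls agree almost
completely. The last line is the hypergeometric tail probability for an
overlap of 30 in 41 draws from a 17,050-circRNA universe with 475
successes.

The same stages are available as a CLI:

```sh
circage simulate --seed 1 --out-dir sim/
circage filter --counts sim/counts.tsv --samples sim/samples.tsv --out filtered.tsv
circage normalize --counts filtered.tsv --out norm.tsv
circage agebias --norm norm.tsv --samples sim/samples.tsv --out age.tsv
circage overlap -N 17050 -K 475 -n 41 -k 30
circage run-all --config pipeline.yaml
```

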