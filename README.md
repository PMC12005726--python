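# combiscreen

Analysis of **combinatorial (dual-sgRNA) CRISPR knockout screens** and of the
downstream validation of synthetic-lethal gene pairs, for groups running
CombiGEM-style pooled screens: from paired-end amplicon reads to pair counts,
growth-phenotype Z scores, genetic-interaction (GI) scores, permutation-based
gene-pair ranking and hit calls — plus Bliss-independence synergy scoring for
drug dose matrices, double-knockout fold changes, and xenograft tumor-volume
trajectories. A ground-truth screen simulator makes every pipeline stage
testable without downloading sequencing data.

## The method

A one-pot cloned library delivers every ordered pair of guides from a catalog
of *N* genes × *m* sgRNAs plus non-targeting controls (for 76 × 3 + 5 guides:
233² = 54,289 sgRNA pairs, 3003 unordered gene pairs counting control as one
pseudo-gene). Cells carrying the library are sampled at the start (D0) and
end (D20) of a growth screen, and the two spacers of each construct are read
directly by paired-end sequencing.

For each sgRNA pair the **growth phenotype** is the normalized log2 fold
change in abundance,

    Z = standardize( log2((RPM_D20 + p) / (RPM_D0 + p)) ),

standardized against the control–control pairs (median / 1.4826·MAD by
default). Orientations (a,b)/(b,a) are averaged within replicate, replicates
averaged, and sgRNA pairs averaged into gene-pair scores.

Under additivity a double knockout is predicted by the sum of its single
knockouts, **expected Z = Z(A+control) + Z(B+control)**. The observed-vs-
expected cloud is summarized by a quadratic least-squares trend; the **raw GI
score** of a pair is its residual from that trend, and the **normalized GI**
divides the residual by the standard deviation of residuals among the 200
nearest neighbors in expected Z. Gene-level GI averages the member sgRNA
pairs' normalized GIs; significance comes from a rank-based permutation test
(RIGER-style weighted-sum statistic over the best two member ranks, exact
enumeration on small instances). Hits must jointly satisfy gene GI < −2,
permutation p < 0.01, and observed Z < −5.

Validation effects are scored against **Bliss independence**: expected
combined inhibition f_a + f_b − f_a·f_b (equivalently, survival and
fold-change products), applied per dose-matrix cell, per knockout fold
change, and per tumor-volume timepoint.

## Worked example

```python
import warnings
import combiscreen as cs
from combiscreen.simulate import recovery_benchmark_config

cfg = recovery_benchmark_config(seed=101)   # 12 genes x 3 sgRNAs + 3 controls,
matrix, truth = cs.simulate_counts(cfg)     # 10 planted interactions (i = -2)
pheno = cs.score_phenotypes(matrix, truth.design)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")         # k clamps to 90 at gene level
    gi = cs.score_interactions(pheno, truth.design,
                               cs.InteractionConfig(seed=101, n_perm=999))

print(gi.gene.loc[[("GENE02", "GENE04"), ("GENE11", "GENE12")],
                  ["expected_z", "observed_z", "gene_gi", "riger_p"]].round(2))
print(f"hits: {list(gi.hits.index)}")
print(f"Bliss expected inhibition at f_a=f_b=0.5 -> "
      f"{cs.bliss_expected_inhibition(0.5, 0.5):.2f}")
```

prints

```text
               expected_z  observed_z  gene_gi  riger_p
gene_a gene_b
GENE02 GENE04       -1.96       -5.15    -2.65      0.0
GENE11 GENE12        0.20       -2.54    -2.10      0.0
hits: [('GENE02', 'GENE04')]
Bliss expected inhibition at f_a=f_b=0.5 -> 0.75
```

Both printed pairs carry a planted synthetic-lethal interaction: their
observed Z falls well below the additive expectation, giving strongly
negative gene-level GI with permutation p < 0.001. GENE11–GENE12 is the
redundant-paralog case (near-neutral singles, lethal double); it shows the
negative GI signature even though only GENE02–GENE04 also clears the
observed-Z < −5 hit cutoff. The Bliss line is the independence null used by
the synergy module: two agents each killing 50% are expected to kill 75%
together.

The same pipeline runs from the shell: `combiscreen simulate | count |
score | synergy` (see `combiscreen --help`); each stage writes delimited
tables and a JSON manifest with parameters, seed, and input checksums.

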