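# Methods

## Scope and model

combiscreen analyzes pooled dual-sgRNA knockout screens in which every
ordered pair of guides from one catalog is delivered lentivirally, cells are
sequenced at the screen start (D0) and end (D20), and genetic interactions
are inferred from the deviation of double-knockout growth phenotypes from an
additive expectation. The package covers six stages: library model, read
counting, phenotype scoring, GI scoring, Bliss synergy scoring, and a
ground-truth simulator. It deliberately excludes copy-number correction,
time-series (>2 timepoint) modeling, dose–response surface smoothing, and
network analysis of hits.

## Library model

A catalog of S guides induces S² ordered sgRNA pairs (self pairs (a,a) are
enumerated — they exist combinatorially in one-pot cloning — and can be
excluded from scoring via `PhenotypeConfig.include_self_pairs`). Gene pairs
are unordered with self-pairs included, treating "Control" as one pseudo-gene
label so that A+control and control+control rows are first-class — they carry
the phenotypic null and the single-knockout scores the additive expectation
needs. A 76-gene × 3-guide + 5-control catalog gives 233² = 54,289 sgRNA
pairs and C(77,2) + 77 = 3003 gene pairs.

Expected transduction coverage is cells × MOI / library size, rounded
half-up (1e8 cells at MOI 0.3 over 54,289 constructs → 553 cells per
construct).

## Read counting

Spacers are sequenced directly (no barcodes): spacer 1 on the forward read
after a fixed anchor, spacer 2 on the reverse read (reverse-complemented
first, configurable) after its own anchor. Anchors default to the 3' ends of
the custom sequencing primers and are expected to be overridden per dataset;
they tolerate ≤1 mismatch (configurable), searched leftmost-first across
offsets that leave room for a full spacer. Spacer matching is exact:
well-designed (Brunello-derived) spacers are mutually distant, so a
sequencing error in the spacer should drop the read, not miscall it; the
anchor mismatch budget absorbs most sequencing error instead. Misses are
typed (anchor-not-found vs spacer-unknown) and reported per sample;
matched + missed always equals total read pairs.

RPM normalization divides by **matched** reads, not total reads: library
representation is a property of the library, not of junk reads.
Representation QC counts, per gene pair, the ordered sgRNA pairs (the two
orientations count separately, matching the 54,289-pair universe) with
log10 RPM ≥ 0.5, and reports the fraction of gene pairs with at least six
such pairs, evaluated on the D0 sample(s).

## Phenotype scoring

Per replicate: log2((RPM_D20 + p)/(RPM_D0 + p)) with pseudocount p = 1 RPM
(configurable); pairs whose D0 abundance falls below log10 RPM 0.5 (the same
floor as the representation QC) are excluded — fold changes off a near-zero
baseline are noise-dominated. Fold changes are standardized against the
control–control pairs, the natural phenotypic null present in the design:
z = (lfc − median(null)) / (1.4826·MAD(null)). Mean/SD is available via
config, as is a unit-scale mode (center only) for noiseless data whose null
has no spread — used by the additive-null validation, where control–control
fold changes are all identical by construction. At least five null pairs are
required; this is why the default simulated fixture carries three controls
(nine control–control ordered pairs) rather than two (four).

Aggregation order: orientation average within replicate, then replicate
mean, then gene-pair mean over member sgRNA pairs. This matches the
convention of reporting orientation correlations per replicate. QC
correlations (Pearson) are computed for orientations, all replicate pairs,
and same-gene-pair guide pairs (by within-pair rank slot).

## GI scoring

The additive expectation is the sum of single-knockout phenotypes:
gene level Z(A,Con) + Z(B,Con); sgRNA level, each guide's mean phenotype
over control partners. Same-gene pairs get 2×Z(A,Con) — biologically a
second cut adds little, so redundant targets surface as positive GI, while
redundant *paralogs* (near-neutral singles, lethal double) surface as
negative GI.

The observed-vs-expected cloud is fitted with an ordinary-least-squares
quadratic; the raw GI is the residual. The fit includes controls and
same-gene pairs by default (they anchor the additive trend). Normalized GI
divides each residual by the SD (ddof = 1) of residuals among the k = 200
nearest neighbors in expected Z — a local heteroscedasticity correction,
since strongly dropping pairs scatter more. The focal unit is excluded from
its own window; distance ties break deterministically by unit id; if fewer
than k neighbors exist, k shrinks with a warning (at gene level, 91 pairs
with k = 200, this warning is expected and benign). A zero neighbor SD
(constant residuals) is an error, not a silent division.

The quadratic fit and neighbor normalization run independently at the
sgRNA-pair and gene-pair levels. The gene table reports both the direct
gene-level normalized residual (`norm_gi`) and the mean of member sgRNA-pair
normalized GIs (`gene_gi`); hit calling uses `gene_gi`, since it pools
many reagents.

**Permutation test.** sgRNA-pair normalized GIs are ranked ascending (most
negative first; ties by unit id) and each gene pair is summarized by
0.25×best + 0.75×second-best normalized member rank — a weighted-sum variant
that emphasizes the second-best reagent for robustness with ~9–18 member
pairs; a KS-type statistic is available via config. Singleton gene pairs
fall back to the single rank and are flagged. The null permutes the
gene-pair→sgRNA-pair assignment; sampled p-values use the add-one correction
(p = (1 + #null ≤ observed)/(n_perm + 1), never zero). On instances small
enough to enumerate (≤12 units by default) all C(N, m) member sets are
enumerated instead and p is the exact tail probability — this is what the
exhaustive-enumeration tests compare against. A seed is mandatory whenever
sampling is used. Note the strict p < 0.01 hit cutoff requires n_perm ≥ 999.

**Hits** require gene GI < −2, permutation p < 0.01, and observed gene
Z < −5 jointly (all configurable), sorted by GI ascending.

## Bliss synergy

One law in three coordinate systems: expected inhibition
f_a + f_b − f_a·f_b; expected survival/fold change s_a·s_b; expected relative
tumor volume (V_A/V_veh)·(V_B/V_veh). Dose matrices must include zero-dose
margins, from which single-agent inhibitions are read; viabilities outside
[0,1] are clamped with a warning (a pragmatic choice — assay noise routinely
produces viabilities slightly above 1). The summary synergy score is the
mean per-cell excess over combination cells, ×100 (percentage points),
with the per-cell map as the primary output; no surface smoothing is
applied. Knockout fold changes must be pre-normalized to the
control+control combination (validated to 1 ± 0.05). Tumor volumes use the
caliper formula width² × length × 0.5; group SDs propagate into relative
and expected volumes by first-order error propagation, and both per-timepoint
trajectories and the endpoint are reported.

## Simulator

The generator realizes exactly the model the pipeline assumes: ordered-pair
log2 effect e_a·f_g(a) + e_b·f_g(b) + e_a·e_b·i_{g(a),g(b)}, with per-gene
fitness f (controls 0), per-guide efficiency e ∈ [0,1], and a sparse
interaction matrix i. The interaction term is scaled by **both**
efficiencies — a pair only shows epistasis if both guides cut; this is a
modeling choice. Baseline abundances are lognormal (σ = 0.5, cloning skew);
end abundances are baseline × 2^(effect × timespan) with per-pair,
per-replicate Gaussian noise on the effect; counts are gamma–Poisson
(negative binomial, size 50) around the multinomial expectation at the
configured depth — screens are overdispersed relative to Poisson.
Multinomial and deterministic ("expected") count models are available; the
deterministic mode supports exactness tests. All outputs are bit-for-bit
functions of (config, seed).

Defaults: 12 genes × 3 guides + 3 controls (1,521 ordered pairs; full
pipeline tests run in seconds), 3 replicates, depth 10⁶, fitness
~Normal(0, 0.8), efficiency ~Beta(8, 2), replicate noise SD 0.7 — set so
replicate-to-replicate phenotype correlations land near the ~0.75 typical
of real combinatorial screens. A design-scale config (76×3+5, depth 2×10⁷)
is provided for the larger checks. FASTQ emission writes one read pair per
count with configurable substitution errors (whole read or filler-only);
at error rate 0 counting reproduces the source counts exactly.

What the simulator does **not** emulate: cassette-position (orientation)
effects — so simulated orientation correlations run higher than real
screens'; guide off-target activity; double-infection artifacts, cloning
biases and PCR chimeras; copy-number-driven dropout. Passing recovery tests
therefore demonstrate correctness of the scoring chain under the additive
fitness model, not robustness to those artifacts.

## Numerical choices and edge cases

- Rounding of coverage is half-up (not banker's), matching printed
  arithmetic conventions.
- Quadratic fits require ≥3 distinct expected values; rank-deficiency is an
  error.
- Orientation averaging passes a lone orientation through unchanged;
  replicate means are NaN-aware.
- A single D0 sample is broadcast against all D20 replicates; otherwise
  replicates are matched by index, and ambiguity is an error.
- p-values are never 0; exact-mode p ≥ 1/C(N, m).
- Representation QC on an all-zero matrix reports fraction 0 rather than
  erroring; RPM normalization of a zero-depth column errors.

## Acceptance surface

`scripts/acceptance.py --seed S --out results/acceptance.json` recomputes,
at run time: the pair-universe sizes and coverage arithmetic; representation
QC of a design-scale simulated baseline; the additive null (max |raw GI| and
expected-vs-observed r on a no-interaction, noise-free screen at depth 10⁷);
hit-recovery AUROC, the paralog pair's GI, and replicate/orientation QC
correlations over five seeded default-noise screens; worst-case deviation of
permutation p-values from full enumeration; Bliss null and planted-synergy
excesses with the product-rule toys; and the FASTQ counting round trip.
Problem sizes (fixture-scale screens for the stochastic checks, design-scale
for combinatorics and representation) were chosen so the whole script
completes in seconds while every quantity is computed, never assigned.
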