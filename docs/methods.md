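# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `hubrate`, and what the synthetic-data generators do
and do not emulate.

## Expression preprocessing

Input is an already-normalized genes × samples intensity matrix (e.g. RMA
output); normalization of raw array data is out of scope. When several
probes map to one gene, one probe is drawn uniformly at random — a seeded
choice recorded in the run log, since an unseeded draw would make reruns
irreproducible. The variability filter computes each gene's coefficient of
variation CV = sd/mean (sample sd, n−1 denominator, the usual convention in
expression QC; the mean must be positive, which holds on the intensity
scale) and retains genes whose CV is **at or above the 5th percentile** of
the empirical CV distribution, i.e. within the upper 95% of that
distribution. The quantile uses linear interpolation between order
statistics and the cutoff (`lower_quantile`, default 0.05) is configurable.
An alternative reading of an "upper 95% confidence interval" — a CI around
the mean CV — would be two-sided and would not act as a variability filter,
so the one-sided quantile reading is used; the knob is exposed rather than
hard-coded. Filtering with `≥` makes the rule idempotent and keeps whole
tied groups.

## Coexpression network

Pearson correlations over genes; unsigned soft-threshold adjacency
`a_ij = |r_ij|^β` with zero diagonal (a signed-network variant is out of
scope). β is scanned over integers 1–20: for each candidate, weighted
degrees `k_i = Σ_{j≠i} a_ij` are binned into 10 equal-width bins (empty
bins skipped), and log10(bin frequency) is regressed on log10(bin mean k).
The fit statistic is the *signed* R², −sign(slope)·R², so a decreasing
(scale-free-like) degree distribution scores positively. The chosen β is
the smallest with signed R² ≥ 0.85; if none qualifies the β maximizing the
statistic is used and flagged with a warning. Degenerate scans (all degrees
equal, or fewer than two usable bins) yield NaN for that β.

Connectivity is reported in two modes. `count` (the default) tallies
partners with `a_ij ≥ τ`, τ = 0.1 — a declared default, not an inference
about any particular dataset; `weighted` is the WGCNA weighted degree. The
count tally after a large β is effectively a near-hub-only cutoff
(|r| ≥ 0.1^(1/β)), which makes it a coarser rank estimator of the
underlying degree than the weighted sum; the test suite asserts rank
recovery (Spearman ≥ 0.8 against the planted degree) on the weighted
degree and a weaker hubs-on-top property on the count tally. The
correlation stage records which mode produced each k.

## Orthology

Reciprocal best hits over two BLAST tabular (outfmt 6) files. "Best" is
lowest e-value, then highest bit score, then lexicographically smallest
subject id — a deterministic rule, since ties do occur in real BLAST
output. Self-hits are ignored; only the best record per (query, subject) is
considered. A pair is emitted when each member is the other's best hit and
*both* e-values are strictly below the ceiling (default 1e−8; the strict
inequality matches a "< 1e−8" rule). The ceiling is applied to the selected
best hits, not as a pre-filter: a best hit above the ceiling disqualifies
the query rather than promoting its second-best hit.

## Codon alignment and the in-frame rule

CDS pairs are aligned through their translations: global affine-gap dynamic
programming on amino acids (BLOSUM62, gap open −10, extend −0.5, Biopython
`PairwiseAligner`), then back-mapped to codons, so gaps land on codon
boundaries and the alignment is in-frame by construction. Inputs must be
length-divisible by 3 with no internal stop codons (a trailing stop is
stripped); codons containing ambiguity characters translate to X for
alignment and are masked — treated like gap columns — during segmentation,
because counting estimators need unambiguous codons.

Segment extraction keeps maximal runs of columns gapless and unambiguous in
both sequences, drops runs shorter than 30 nt, concatenates the survivors
5′→3′, and rejects the pair (a normal, flagged outcome) when fewer than
300 nt survive. Thresholds are in nucleotides of the gap-free block, must
be whole codons, and are configurable.

## Rate estimators

**NG86.** Per sense codon, the nine single-nucleotide neighbors are
classified; stop-codon neighbors are excluded and the synonymous fraction
renormalized so s + n = 3 exactly (hence S + N = 3L over an alignment).
Differences per codon pair average the synonymous/nonsynonymous step counts
over all orderings of the differing positions whose intermediates are sense
codons; when every ordering passes through a stop, each differing position
is classified by the direct change in both directions, averaged. pS = Sd/S
and pN = Nd/N are corrected with Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3);
p ≥ 3/4 flags the estimate as saturated. ω = dN/dS is undefined (NaN, not
infinity) when dS = 0, which avoids rank distortion downstream: ω rows with
undefined values are dropped pairwise in the correlation stage, while their
dN values are kept.

**YN00-style.** Codon frequencies come from F3×4 (position-specific
nucleotide frequencies pooled over both sequences, with a 0.5 pseudocount
per nucleotide so no sense codon has zero frequency). κ is estimated from
codon positions that are fourfold-degenerate in both codons of a column
versus positions nondegenerate in both: per class, K80 transition and
transversion distances are computed, pooled across the two classes weighted
by site counts, and κ is the ratio of pooled distances — the pooled form is
more stable than averaging per-class ratios when one class has few
differences. Sites are then counted per codon with each neighbor weighted
by its target-codon frequency times κ for transitions (s + n = 3 per codon
is preserved); differences are counted with pathways weighted by the
product of their step rates (π_target · κ^ts · ω^nonsyn). dS and dN each
receive a K80-style correction from the transition/transversion split
within their own difference class; with κ = 1 this reduces exactly to
Jukes–Cantor. The pathway weighting is iterated from ω = 0.5 until the
change in ω is below 1e−6 (max 100 iterations; non-convergence flags the
estimate, and ω is clamped to [1e−4, 99] inside the weighting only). In the
unweighted limit (κ = 1, uniform codon usage) the estimator collapses to
NG86; the suite verifies agreement within 5% on long simulated pairs.
Bit-exact parity with other implementations of the same family of counting
methods is not claimed — conventions differ in stop-neighbor handling and κ
pooling — so validation is by simulation recovery and the NG86 limit. The
standard genetic code is assumed throughout (nuclear plant genes).

## Inference layer

Kendall's τ-b with tie correction is computed from O(n²) sign matrices —
connectivity tallies and rate estimates are heavily tied, which is why τ-b
rather than τ-a or Spearman is used. Randomization p-values permute the
rate vector (the "parameter of interest"; under exchangeability permuting
either vector is equivalent), rebuild τ each time, and report the
two-tailed add-one estimate (1 + #{|τ*| ≥ |τ|})/(1 + B), which is never
zero and is conservative. Permuting y only permutes rows and columns of its
sign matrix, so each permutation costs one int8 gather-and-sum rather than
a fresh O(n log n) sort; 10,000 permutations at n ≈ 230 take ~2 s.

Multiple testing across taxa uses Holm's step-down procedure at α = 0.05
(the step-down reading of "sequential Bonferroni"); evidence is combined
across taxa with Fisher's −2Σln p ~ χ²(2m); and the count of same-sign
correlations is tested with an exact two-tailed binomial sign test,
p = 2·min(P[X≤k], P[X≥k]) capped at 1. For seven of seven same-sign
correlations this gives exactly 2·(1/2)⁷ = 0.015625. Metrics whose joined
vectors are constant or have fewer than 10 usable pairs are skipped with a
warning rather than failing the run.

## Synthetic data

`simulate_expression` draws, per module, a standard-normal eigengene over
samples; gene i's profile is λ_i·eigengene + √(1−λ_i²)·σ·noise plus a
uniform(6, 10) baseline to mimic positive log-intensities. Hub genes
(10% by default, spread across 4 modules) get λ ∈ (0.88, 0.98), peripheral
genes λ ∈ (0.25, 0.7), so within-module correlations are λ_iλ_j, and the
planted expected degree λ_i·Σ_{j≠i}λ_j is known exactly. It does **not**
emulate probe-level noise models, batch structure, or between-module
correlation; passing tests show the pipeline recovers planted rank
structure under a clean factor model, not robustness to array artifacts.

`simulate_codon_pair` evolves both sequences from a common ancestor (drawn
from the target codon frequencies) for t/2 each under a 61×61 rate matrix
q_ij ∝ π_j·κ^[transition]·ω^[nonsynonymous] for single-nucleotide changes,
normalized to one expected substitution per codon per unit t; transition
probabilities via `scipy.linalg.expm`. The factorization satisfies detailed
balance, so the stationary law equals the supplied codon frequencies (a
property test checks πQ = 0 at machine tolerance). Branch lengths are split
symmetrically because a pairwise estimator only sees their sum. One
consequence of the per-codon normalization: genes with lower ω place a
larger share of their fixed divergence budget in synonymous changes, so in
study simulations dS *rises* as ω falls and the dS–connectivity correlation
comes out positive. The weak negative dS trend some real datasets show is
therefore not emulated; only the dN and ω associations carry the planted
signal.

`simulate_taxon`/`simulate_study` tie the pieces together: per-gene ω is
assigned through a Gaussian copula on the planted-degree ranks, with the
mixing weight found by bisection until the realized Kendall τ between
planted degree and ω matches `effect_size` within ±0.005 (an empirical
calibration — the rank association of a monotone-plus-noise map has no
convenient closed form). Ortholog CDS pairs are then evolved at those ω;
the outgroup expression matrix reuses the focal module structure with
perturbed loadings so ortholog connectivities correlate positively; hit
tables contain the true pairs at e-values ≪ 1e−8 plus ~30% decoy hits
above the ceiling, so reciprocal-best-hit selection recovers exactly the
planted pairing; ~20% of genes carry a duplicate probe to exercise
deduplication.

Default study conditions: 7 taxa, 240 genes × 60 samples, 300 codons per
CDS pair, ω ∈ [0.05, 0.9], total branch length t = 0.4 substitutions per
codon, κ = 2, effect size −0.3, 10,000 permutations, α = 0.05. The gene
count puts post-filter ortholog-pair yields (~230 per taxon) within the
range typical of cross-species array compendia while keeping a full study
run at a couple of minutes on one CPU.

## Pipeline

Stages run per taxon in fixed order; every stage writes plain TSV
intermediates plus a JSON run log with the seed, a hash of the full
parameter set, and per-stage record counts (monotone non-increasing through
the filters — a property the tests assert). The global seed is expanded
into per-stage substreams so the probe draw and the permutation tests are
individually reproducible. Stages are *not* silently skipped on rerun: at
these scales recomputation is cheap and stale-intermediate reuse is a
correctness hazard; the recorded parameter hash lets a user decide when
reuse is safe.

## Known limitations

- The YN00-style estimator targets the method family, not bit-exact parity
  with any particular binary (κ pooling and stop-neighbor conventions
  differ between implementations).
- Count-mode connectivity depends on the adjacency threshold jointly with
  β; comparisons across taxa with very different β values are better made
  in weighted mode.
- No module detection, topological overlap, or signed networks; no
  ML codon models (branch/site models); no synteny-aware orthology.
- The expression generator's factor model has uncorrelated modules and
  homoscedastic noise; CV-filter behavior on skewed real intensity
  distributions is not exercised by the synthetic tests.
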