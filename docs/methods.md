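# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Molecular dating (`divergence`)

The observed per-site difference between two aligned sequences is
*d* = mismatches / comparable sites, where a site is comparable only when
both sequences carry an unambiguous base; gap and N columns are excluded
pairwise rather than masked globally, so each pair uses its own maximal
set of sites. The Jukes-Cantor correction
*K* = −(3/4)·ln(1 − 4*d*/3) assumes equal substitution rates among the
three alternative bases and is defined for *d* < 0.75; beyond that the
distance is saturated and the pair is flagged rather than dated.
Divergence time is *T* = *K*/(2µ) because both lineages accumulate
substitutions independently. µ defaults to 1.3×10⁻⁸ substitutions per
site per year, a standard plant synonymous rate; it is a parameter, not a
constant, and LTR sequences likely evolve faster than synonymous coding
sites, so absolute dates should be read as rate-conditional. *T* is
stored in years; Myr (2 decimals) and kyr (nearest integer) are display
conventions only.

Ks/Ka uses the Nei-Gojobori (1986) fractional method: each codon position
contributes (synonymous single-base changes)/3 synonymous sites, with
changes to stop codons counted as nonsynonymous; site totals are averaged
over the two sequences. Codons differing at several positions average the
synonymous/nonsynonymous split over all orderings of single-step paths,
excluding paths through stop codons unless no stop-free path exists. The
Jukes-Cantor correction is applied to ps = Sd/S and pn = Nd/N. NG86 was
chosen because the method is closed-form and checkable against exhaustive
enumeration; maximum-likelihood variants would need an optimizer and an
external reference implementation.

LAI is computed raw: 100 × intact LTR-RT bp / total LTR-RT bp, genome-wide
and in sliding windows (default 3 Mb window, 300 kb step). Windows without
LTR sequence are reported as undefined (NaN), not zero. The upstream
tool's identity-based adjustment is not published as a formula; an
optional user-supplied linear correction can be applied externally, and
the package makes no claim about adjusted scores.

## Synteny, quartets and tandem arrays (`homoeology`)

All distances are gene-rank differences on a chromosome — the units of
the chaining parameters (max gap 20 genes between consecutive matches,
min 10 aligned pairs per block) and of the tandem rule (max distance 10
genes). Base-pair distances are never used.

Chaining is a weighted longest monotone subsequence per chromosome pair
and orientation, under the hard gap constraint. The best chain maximises
pair count, then minimises total rank span, then takes the smallest first
gene id, then compares the full pair sequence lexicographically — a total
order, so output is deterministic and the dynamic program provably
matches exhaustive enumeration (the DP state carries the best chain per
endpoint; the order is preserved when a common pair is appended). Best
chains are peeled greedily: extract, remove its matches, repeat; blocks
below the pair minimum are discarded, and each match ends up in at most
one block. There is no gap penalty beyond the hard constraint.

Tandem arrays are transitive closures of same-family genes on one
chromosome linked at rank distance ≤ 10; arrays have ≥ 2 members and
partition their genes. Tandem non-primary members are removed from the
match set *before* chaining so local duplications do not fragment
collinear blocks. In the synthetic path, match pairs come from shared
family labels (all-vs-all within a family across chromosomes) instead of
sequence alignment; real match tables can be supplied as TSV.

Quartet mapping unions block-matched genes into collinear positions
(union-find); a position with two candidate genes on one copy is resolved
toward the higher-scoring block. Positions with ≥ 2 copies present are
reported; the per-copy retained counts in windows of collinear regions
give the fractionation profile. A gene's "expressed" status uses strict
FPKM > threshold so that threshold 0 means detected at all.

## Expression dominance (`dominance`)

FPKM[g,l] = (count/(total/10⁶))/(length/10³), with the library total
taken as the column sum unless an explicit mapped-read vector is given.
Per quartet and library, the four chromosome copies' FPKM sums are
compared and the argmax copy called "highest"; ties at relative tolerance
10⁻⁹ (and all-zero libraries) are flagged and excluded from counts
rather than split, for determinism. Per set, the modal copy is the most
frequent winner, agreement a_s counts its wins out of L libraries, and a
chi-square goodness-of-fit (df = 3, no continuity correction) tests the
four per-copy counts against the uniform 25% expectation. A "comparison"
is one set × library argmax event, so 12 sets × 14 libraries = 168
comparisons. Fruit reversal computes the modal copy from non-fruit
libraries only (avoiding circularity), then counts fruit-library events
where that copy ranks 4th (lowest) or 3rd–4th (bottom two), tested
against null proportions 1/4 and 1/2.

Two calibration caveats. First, the chi-square null is calibrated only
when the four copies are exchangeable — equal gene content (complete
quartets, the default restriction) and comparable gene lengths. With
unequal content the statistic correctly reports *consistent copy-level
expression differences*, which exist for reasons other than regulatory
dominance. Second, the libraries are single biological replicates; the
summary carries this as a warning field, and the calls are descriptive.

## Co-expression networks (`coexpression`)

Genes with count < 5 in ≥ 30 conditions are removed (with fewer than 30
libraries the rule cannot fire and all genes are kept, with a warning).
Variance stabilisation is median-of-ratios size factors followed by
log2(count/sf + 1) — deterministic, monotone within a library, and
invariant to uniform depth changes; it is this package's own stand-in for
fitted-dispersion transforms, adequate for rank- and correlation-based
downstream steps.

Mutual rank is MR(i,j) = √(rank_i(j)·rank_j(i)) with self excluded and
ties averaged, so MR ≥ 1 and the matrix is symmetric. The decay
w = e^−(MR−1)/x is read with the (MR−1)/x grouping — the printed form is
typographically ambiguous, but this is the geometric decay of the
mutual-rank literature, reaching w = 1 exactly for reciprocal best
partners. Five networks are built at x ∈ {5, 10, 25, 50, 100}; since w is
non-decreasing in x at fixed MR, the edge sets are nested across x after
the shared PCC ≥ 0.6 filter. Edges also require w ≥ 0.01.

Modules are grown greedily by cohesiveness
f(V) = w_in/(w_in + w_bound + p·|V|) with penalty p = 2, best-improvement
add/remove moves and lexicographic tie-breaks; overlapping candidates
merge at overlap score |A∩B|²/(|A||B|) ≥ 0.8. Module significance is a
one-sided Mann-Whitney test that member vertices carry more weight inside
the module than across its boundary, computed with the exact null
distribution: the asymptotic approximation is badly anti-conservative at
the 2–4 vertex sizes that chance subgraphs produce (an isolated weight-1
edge has true p = 1/6). Filters are inclusive: keep p ≤ 0.1 and quality
≥ 0.2. This is a from-scratch implementation in the style of
greedy-cohesiveness clustering tools and is not claimed to be
call-compatible with any of them.

Metamodules: modules from all five networks are linked at gene-set
Jaccard ≥ 0.5; connected components become metamodules, and each gene is
assigned to exactly one — the component containing it most often, ties
broken by larger summed overlap weight, then smaller component index.
The thresholds are exposed in the API since no canonical values exist.
Fruit-elevated means the members' mean FPKM over fruit libraries strictly
exceeds the non-fruit mean; specialized-metabolism flags come from a
packaged, user-replaceable Pfam domain list.

## ORAC assays (`assays`)

Per well, AUC is the trapezoidal integral of relative fluorescence
f_i/f_0 over cycle index (dimensionless; a flat 70-cycle series gives
69). The f_0 normalisation makes the AUC gain-invariant. Net AUC
subtracts the mean blank AUC; negative nets are allowed and flagged. The
Trolox standard curve is ordinary least squares of net AUC on
concentration with a free intercept (robust to baseline drift; the
intercept absorbs any uniform AUC shift, so recovered TE is
affine-invariant). TE_µM = (net − intercept)/slope. The final value in
nmol TE/mg FW multiplies by the sample aliquot volume (default 25 µL, so
µM × µL × 10⁻³ = nmol in the well) and the extract dilution factor, and
divides by tissue mass — all explicit parameters, never inferred.
Technical replicates must satisfy CV = sample SD/mean < 0.20.

## Synthetic data (`synthio`)

Defaults are the study conditions: 12 quartets × 4 copies × 200 ancestral
gene slots; per-copy retention 0.9 (fractionation); tandem seeding rate
0.05 with geometric array sizes truncated to [2, 10], emitted as
consecutive ranks; 14 libraries of which 3 are fruit; negative-binomial
counts (mean 50, dispersion 0.2, var = m + αm²) with log-normal library
size factors (σ = 0.25) and per-family log-normal baselines (σ = 0.5);
dominance factor 2 on the dominant copy, which switches identity in fruit
libraries with probability 0.8; 200 LTR pairs per divergence class of
2,000 bp at per-site differences 0.025 (between subgenomes) and 0.0085
(within); 70-cycle × 90 s plates with standards spanning 12.5–100 µM.
The pair counts are chosen for statistical power (they pin the mean
measured difference to ±0.04% at n = 200 × 2,000 bp); the published
analyses do not state their pair counts.

Design choices worth knowing:

* Homoeologous copies of a gene share their length, drawn once per
  ancestral slot. Independent per-gene lengths would give each chromosome
  copy a persistent summed-FPKM offset and make copies non-exchangeable
  under the no-dominance null; shared lengths are also what near-identical
  homoeologs look like.
* LTR pairs are produced by mutating one copy site-by-site with
  substitution probability equal to the target difference, uniformly over
  the three alternative bases (a Jukes-Cantor process), so the measured
  *d* is an unbiased estimator of the target and the downstream correction
  is exact in expectation.
* Plate decay curves are convex mixtures of a fast (τ = 2 cycles) and a
  slow (τ = 30 cycles) exponential, chosen so the trapezoidal net AUC is
  *exactly* linear in TE concentration; noise is Gaussian in AUC units.
  Noiseless plates therefore invert exactly (r² = 1, TE recovered to
  10⁻⁹), which is a property of the construction, not a claim about real
  plates.
* One global seed feeds `numpy.random.SeedSequence` children with fixed
  spawn keys (0 genome, 1 LTR, 2 counts, 3 plate, 4 dominance truth), so
  each component is reproducible in isolation and the dominance truth is
  independent of layout and count noise.

What the generator does **not** emulate: read-level data (no FASTQ,
alignment or counting noise beyond NB), Hi-C or assembly artifacts,
realistic TE sequence models (substitution only, no indels or nested
insertions), biological replicates, correlated gene programs (counts are
conditionally independent given family, copy and library), or real
LC-MS/plate chemistry. Passing tests therefore demonstrate correctness of
the algorithms and calibration under the stated generative model, not
fidelity to any real dataset; quantities that depend on the real data
(e.g. observed dominance counts, metamodule totals, tandem expressed
fractions) are exercised structurally but their published values are not
reproduction targets.

## Problem sizes and tolerances

Simulation-based checks in the test suite and acceptance script use 12
quartets with 30–40 genes per chromosome (calibration and power), 100
random instances for each brute-force oracle (mutual rank ≤ 8 genes,
chain enumeration ≤ 30 pairs), 200 null simulations for the type-I check,
and 200 LTR pairs per class for dating recovery — sizes at which the
Monte-Carlo error is several times smaller than the asserted bounds.
Floating-point assertions use absolute tolerance 10⁻⁹–10⁻¹² where the
computation is exact in exact arithmetic, and the stated statistical
bands (10% for recovery experiments) elsewhere.
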