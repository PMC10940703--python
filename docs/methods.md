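# Methods

This note documents the models, rules and numerical choices behind
`aavbench`, and what the synthetic generators do and do not emulate.

## Study design being modelled

A pool of AAV capsid variants, each packaging the same self-complementary
reporter transgene tagged with a unique 44-mer barcode, is titrated
individually, combined at a 1:1 molar ratio, and injected into the portal
circulation of an ex situ normothermically perfused human liver. The barcode
region is PCR-amplified and sequenced (2×150 paired-end) from four analyte
classes: the pre-injection mix (the normalization denominator), perfusate
plasma over time (clearance), tissue DNA (cell entry / uptake), and tissue
cDNA (transgene expression / functional transduction). Total vector load is
anchored in absolute units by droplet digital PCR.

## Demultiplexing

**Merging.** Mate 2 is reverse-complemented and every suffix/prefix overlap
length L from `min_overlap` (default 12) to min(len1, len2) is scored by
match count — a seed-free full offset scan, feasible because amplicons are
short. The admissible offset (mismatch fraction ≤ `max_mismatch_frac`,
default 0.1) with the most matches wins; ties go to the longer overlap.
Within the overlap, each disagreement takes the base of the higher-quality
mate (quality tie → mate 1) and the max of the two qualities. A
longest-first scan terminates early once no shorter overlap can beat the
best match count, keeping the scan near-linear for clean data.

**Length filter.** |len(merged) − expected_merged_length| ≤
`length_tolerance` (default 0). The expected merged length is a required
configuration value of the barcode library; it is amplicon-design specific
and cannot be inferred from the barcode table alone.

**Barcode assignment.** The barcode window is located by the upstream anchor
(exact match, else the best placement with ≤ 1 mismatch), then verified
against the downstream anchor (≤ 1 mismatch). The window's Hamming distance
to every library barcode is computed (vectorized against a byte matrix);
the unique nearest variant at distance ≤ `max_hamming` (default 3) is
assigned. A tie at the minimum admissible distance counts as *ambiguous*;
everything else (missing anchors, malformed window, distance beyond the
radius) as *unmatched*. Indel-containing barcodes are not rescued:
substitution errors dominate the short-read platform used for such
amplicons, and indels are intercepted upstream by the length filter. With a
designed minimum pairwise barcode distance of 10, a radius-3 assignment can
never be claimed by two barcodes simultaneously. All sequences are
upper-cased; `N` counts as a mismatch.

**Accounting.** Every read pair lands in exactly one bucket; the counts
table raises if assigned + ambiguous + unmatched + unmerged +
length-filtered ≠ total input pairs.

## Composition

Fractions use a pseudocount of 0 by default so that genuinely undetected
variants (fully neutralized capsids) stay at exactly zero. Normalization to
the pre-injection mix computes enrichment r_i = f_i/m_i and renormalizes to
percentages p_i = 100·r_i/Σ r_j; the renormalization-to-100% convention is
the one consistent with percentage-scale heatmaps. Normalization is
scale-invariant in the counts and is the identity (up to scale) against a
uniform mix.

Expression efficiency is e_i = p_i(cDNA)/p_i(DNA) on profiles normalized to
the same mix; zero-DNA variants are flagged undefined rather than given a
number. The barcode-bias screen (used when pre-selecting barcodes with a
replicated in vitro transduction) computes, per replicate, each barcode's
fold relative to the mean across barcodes, averages folds across replicates,
and discards barcodes outside [1/T, T] with T = `fold_threshold` (default
2 — a round, conservative choice; the original screen reports only its
outcome, not its cutoff).

Clustering of percentage profiles is agglomerative with Euclidean distance
and average linkage (scipy), with rows sorted lexicographically first so
tie-breaks are deterministic. The metric/linkage choice is echoed in the
tree metadata because "unsupervised hierarchical clustering" alone
under-determines the algorithm.

## Kinetics and dosimetry

ddPCR concentration is the Poisson maximum-likelihood estimate
λ = −ln((n − n₊)/n), concentration λ/v × dilution, with v the droplet
volume (default 0.00085 µL, the vendor-standard droplet generator;
configurable). Saturated (all-positive) and empty wells are errors. Vector
copy number per haploid cell is the ratio of transgene to single-copy
reference concentrations.

Per-variant perfusate curves are C_i(t) = C_tot(t)·f_i(t) with baseline
C_i(0) = C_tot(0)·m_i from the pre-injection mix, giving percent-of-initial
q_i(t) = 100·C_i(t)/C_i(0); Σ_i C_i(t) = C_tot(t) holds exactly by
construction. Persistence classes use closed lower bounds at 10%, 0.1% and
0.01% (configurable); a value exactly on a boundary belongs to the upper
class.

The clearance fit assumes C(t) = C₀((1−π)e^(−kt) + π). The plateau level is
estimated as the mean of the last two observations (the sampling grid
should therefore extend well past the decay phase), subtracted, and
ln-residuals are fit by least squares. Points whose residual falls below 5%
of the initial residual are excluded: once the curve is within noise of the
plateau, log-residuals are dominated by measurement error and bias the
slope. k is clipped at 0; non-positive concentrations are contract errors.

Dose arithmetic divides total vector genomes by graft (or whole-liver) mass,
body mass, and variant count, and estimates the initial perfusate
concentration as total vg over the circuit volume (default 2.0 L, the value
consistent with both studied perfusions' printed dose/concentration pairs;
always echoed in output). The module reports computed values only and never
reconciles inconsistent published roundings.

## Serology

ELISA reactivity is mean(foreground)/mean(background) strictly > 2.0;
a ratio of exactly 2.0 is non-reactive. End titer is the greatest reactive
dilution; with no reactive dilution the result is the below-detection marker
`<1:{lowest}`. Non-monotone call patterns are flagged but resolved by the
greatest reactive dilution. For correlation work the end titer is
rank-encoded: <1:25 → 0, 1:25 → 1, 1:50 → 2, 1:100 → 3.

NAb titer is the greatest serum dilution whose mean reporter signal is ≤ 50%
of the no-serum positive control (exactly 50% counts as inhibited); assays
whose positive control does not exceed the untransduced background are
invalid.

Spearman correlation uses average ranks for ties and the Pearson correlation
of ranks. The two-sided p-value is an exact permutation probability for
n ≤ 8 (all n! permutations enumerated) and the t-approximation with n−2
degrees of freedom otherwise; the method used is always reported.

## Viability

The verdict is a pure function of one panel: lactate ≤ 2.5 mmol/L (primary
gate) and at least two of six secondary criteria (bile production, pH ≥
7.30, glucose metabolism, hepatic arterial flow ≥ 150 mL/min, portal flow ≥
500 mL/min, homogeneous perfusion). Boundary values satisfy their criteria.
Absent optional measurements count as not satisfied — mirroring bedside use
with partial panels — and only a missing lactate is an error. Glucose
metabolism and homogeneous perfusion are qualitative in the source criteria
and are modelled as externally supplied booleans. The verdict is monotone:
improving any measurement never flips viable → non-viable.

## Synthetic generators

All generators are fully determined by their seed.

* **Barcode library**: random 44-mers rejection-sampled to a minimum
  pairwise Hamming distance of 10 (random 44-mers are typically ~33 apart,
  so rejection is rare at the default panel size of 14), flanked by the
  standard amplification primers as anchors.
* **Reads**: the amplicon is anchor + barcode + anchor padded with a
  library-seeded constant sequence to 220 bp (a configuration value; short
  enough that 2×150 mates always overlap by ≥ 80 bp). Variants are drawn
  multinomially from the mix fractions; each base substitutes independently
  at `base_error_rate` (default 0.3%, a realistic short-read platform
  rate) to a uniformly random different base. Phred qualities are drawn
  from a clipped normal (mean 36, sd 3) — plausible but structureless,
  since qualities only matter for consensus tie-breaking. An optional
  single-base indel per read (off by default) shifts the merged length to
  exercise the length filter. Not emulated: PCR chimeras, position-dependent
  error profiles, adapter read-through, UMI structure — so passing tests
  show correctness of the counting logic under substitution noise, not
  robustness to every real-library artefact.
* **Perfusate**: C_i(t) = C_i(0)·((1−π_i)e^(−(k_i + β·rank_i)t) + π_i) with
  optional lognormal multiplicative noise; totals and fractions are derived
  consistently. β > 0 builds in the empirically observed coupling between
  antibody reactivity and clearance speed, so the reactivity-vs-remaining
  correlation is negative by construction. The default sampling grid is
  dense over the first day and extends to 168 h so the plateau is actually
  reached before it is estimated from the last two points.
* **ELISA**: foreground mean = background·(1 + A_rank/dilution_index) with
  Gaussian well noise; A_0 = 0 and A_r = r + 0.5 place a rank-r capsid's
  expected ratio above 2 at exactly its first r dilutions. Background OD
  0.2 with sd 0.01 on duplicate wells is plate-realistic; at these settings
  a tier call sits ~3σ from the threshold, so occasional borderline flips
  (as with real borderline sera) are possible and are reported, not
  suppressed.
* **ddPCR**: n₊ ~ Binomial(n, 1 − e^(−c·v)) — exact Poisson partitioning.

## Problem sizes and tolerances

The round-trip acceptance check uses 10⁵ reads and bounds each variant's
input-normalized percentage by 3 multinomial σ of the truth; oracle
equivalence uses 10⁴ reads (barcode assignment), 10³ random pairs (merging)
and 500 random vectors (Spearman); clearance recovery uses a 14-variant
panel with k ∈ [0.05, 0.5] h⁻¹, plateaus in {0, 0.1} and 1% lognormal
noise, bounded at 10% relative error. These sizes give stable statistics at
interactive runtimes; statistical bounds are derived from the sampling
distributions involved (3σ), not tuned constants.

## Known limitations

Single-exponential-plus-plateau is the only clearance model (no
compartmental PK); serology covers endpoint logic, not 4PL curve fits;
the bias-screen cutoff is a declared default, not an inferred one; and the
demultiplexer does not rescue indel-containing barcodes, trading a small
sensitivity loss for an unambiguous assignment radius.
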