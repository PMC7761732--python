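# Methods

This note documents the models, algorithms, parameter semantics and
design decisions behind rohkit, in the spirit of a methods appendix: what
is computed, under which assumptions, and what the synthetic validation
does and does not demonstrate.

## Genotype representation and quality control

Genotypes are counted-allele dosages in {0, 1, 2} with −1 as the missing
sentinel, aligned to a marker map sorted by (chromosome, bp position).
When reading PED files the counted allele at each SNP is the first
allele symbol encountered in file order — a deterministic convention; it
means a written-then-reread panel is identical only up to per-SNP allele
relabelling (dosage complement), and write∘read∘write is a byte-level
fixpoint. Every statistic in the package is invariant to which allele
is counted (verified by test).

QC runs in a fixed order: (1) drop markers on excluded chromosome labels
(default {X, Y, MT, 0}); (2) drop SNPs with call rate < 0.95 (a SNP at
exactly the threshold is kept); (3) drop animals with a missing fraction
strictly greater than 0.15. No MAF filter is applied: in a
single-population study rare alleles carry the homozygosity signal, and
removing them inflates apparent ROH. Note that QC is only guaranteed
idempotent when sample removal does not push surviving SNPs below the
call-rate threshold; at the package's default missingness levels this
never occurs.

## ROH detection (sliding window)

Parameters (base scenario, typical for a bovine 50k array): window of 50
SNPs; window hit proportion 0.05; minimum 30 SNPs and 2 Mb per run;
maximum gap 1000 kb; density ≥ 1 SNP / 100 kb (as mean over the run);
at most 1 heterozygous and 1 missing call per run.

Pipeline per animal and chromosome:

1. every window of `window_snps` consecutive SNPs is *eligible* iff it
   holds ≤ `max_het` heterozygous and ≤ `max_missing` missing calls;
2. each SNP's hit rate is (eligible windows containing it) / (windows
   containing it); at chromosome ends only existing windows count, so
   edge SNPs remain callable;
3. SNPs with hit rate ≥ `window_hit_proportion` (inclusive comparison)
   are candidates;
4. maximal candidate stretches are split wherever adjacent SNPs lie more
   than `max_gap_kb` apart;
5. within each stretch, the emitted runs are the **disjoint
   sub-segments, bounded by homozygous non-missing SNPs, each within the
   het/missing budgets and at least `min_snps`/`min_length` in size,
   that maximise the total covered length** (dynamic programming; ties
   resolved toward fewer segments, then leftmost starts). The mean
   density filter (`length_kb / n_snps ≤ density_kb_per_snp`) is applied
   to each resulting run.

Step 5 deserves explanation. The low hit proportion deliberately calls
SNPs at the edges of a true segment, so a candidate stretch almost
always absorbs the first heterozygous SNP beyond each edge, and can
bridge two autozygous segments across a short blemished interval.
Enforcing the per-run limits by simply rejecting violating stretches
discards whole long runs (and makes results non-monotone in the
allowances); one-directional trimming or greedy splitting each mishandle
one of the two situations. The maximum-coverage partition is the unique
formulation we found that is deterministic, keeps the per-run guarantee
("at most one heterozygous and one missing call inside an ROH")
literally true, preserves detector sensitivity on known-IBD data, and
keeps total detected length monotone in the allowances. The
`window_only=True` flag restores pure window-level semantics (candidate
stretches emitted as-is), matching tools that apply the limits only when
scoring windows.

A consequence of window scoring is that runs shorter than the window
cannot be called — with a 50-SNP window, a 40-SNP homozygous tract has
no eligible window covering it. This is inherent to the method, not an
implementation choice; tests that need short planted runs to be
detectable use a 20-SNP window.

## ROHet detection (consecutive method)

Parameters: ≥ 15 SNPs, ≥ 250 kb, gap ≤ 1000 kb, at most 3 homozygous and
2 missing calls per region. The scan is window-free: a segment starts at
a target-state (heterozygous) SNP and extends right; a SNP that would
exceed either blemish budget, or that jumps the gap limit, closes the
segment, which is emitted after trimming both endpoints to target-state
SNPs; scanning then restarts at the closing SNP (which, being
opposite-state or missing, in effect means the next heterozygous SNP).
The gap limit is interpreted as the distance between consecutive panel
SNPs inside the region, regardless of their state. The same scanner
with `target="hom"` is a consecutive ROH caller; with a 1-SNP window,
hit proportion 1 and zero allowances the sliding-window detector reduces
to it exactly (verified by test).

Run lengths are reported as `end_bp − start_bp` (open difference), the
convention of the common run-calling tools.

## Inbreeding coefficients

* **Pedigree F** — tabular A matrix: founders unrelated, non-inbred;
  `a(i,j) = ½[a(j,s_i) + a(j,d_i)]`, `a(i,i) = 1 + ½ a(s_i,d_i)`;
  unknown parents contribute zero (treated as founders, F = 0), which
  matters in shallow pedigrees and biases pedigree F downward relative
  to truth.
* **FIS** — method of moments on genotype counts:
  `E(hom)_i = Σ_j [1 − 2 p_j (1−p_j) · n_j/(n_j−1)]` over animal i's
  non-missing SNPs, `FIS_i = (O(hom)_i − E(hom)_i)/(N_i − E(hom)_i)`.
  Negative values mean less homozygous than the sample average. SNPs
  with fewer than two called genotypes are excluded. The per-SNP HE
  reported by `snp_stats` is the uncorrected 2p(1−p); the corrected
  variant is exposed as a column (`he_unbiased`).
* **FROH** — per animal, Σ run lengths / L_AUTO, where L_AUTO defaults
  to the genome span covered by the panel (Σ per chromosome of last −
  first SNP position) and can be overridden with a published value
  (e.g. 2541 Mb for the bovine 50k autosomes). Per-length-class FROH
  uses left-closed bins [2,4), [4,8), [8,16), [16,∞) Mb, which partition
  the detector's output so the bins sum to the total.
* **Length ↔ generations** — IBD tract length is approximately
  exponential with mean `100/(2g)` cM, so a run of length `ℓ` cM points
  to `g = 100/(2ℓ)` generations to the common ancestor: 4 Mb ≈ 12.5
  generations (ancient), 16 Mb ≈ 3 (recent), at 1 cM/Mb.

## Relationship matrices

**G (VanRaden).** `G = ZZ'/(2Σ p_j(1−p_j))`, frequencies always from the
analysed sample. Missing dosages are replaced by the SNP mean (2p)
before centring — their Z entries are exactly zero. This mean
imputation is a deliberate simplification of haplotype-based imputation;
at QC-bounded missingness (< 5 %) its effect on G is negligible.
Monomorphic SNPs contribute zero to numerator and scale. Sample-derived
frequencies make G's rows sum to zero and put its diagonal mean near 1
on Hardy–Weinberg data.

**ROH-based.** numerator(i, j) = total bp of intersection of i's and
j's runs (diagonal: the animal's total run length). The scale is the
population-level Σ over distinct overlap regions of (carrier frequency ×
region length), computed by a sweep line over run boundaries — maximal
intervals of constant carrier count. This makes the statistic
dimensionless and symmetric, and weights longer, more widely shared runs
proportionally more. Whether such a normaliser should be population-wide
or pair-specific is genuinely open; the population-wide form is the
default and a per-pair variant (restricting the sum to regions carried
by i or j, via inclusion–exclusion) is available as
`denominator="pair"`.

**Comparison.** Pedigree F, FIS and FROH (total + per class) are
inner-joined on animal id (animals missing any coefficient are listed as
excluded); Pearson and Spearman correlation matrices are reported.

## Islands

The per-SNP in-run frequency is the fraction of animals whose runs cover
the SNP. Thresholds: ROH islands use the empirical 99.9 % quantile of
that vector, defined as the inverse empirical CDF (type-1, no
interpolation — reproducible on discrete data), with membership ≥ the
threshold; ROHet islands use a fixed threshold with strict > 0.25.
Islands are maximal stretches of consecutive member SNPs on one
chromosome; a single sub-threshold SNP separates two islands (no
merging). Island bounds are the member SNPs' positions (SNP space, not
midpoints between SNPs).

## Sensitivity sweeps

One axis is varied at a time around the base parameter set (the design
of the usual published sensitivity analyses); monitored variables are
run count, runs per animal, mean run size and (for ROH) mean FROH.
`avg_n` divides by **all** panel animals, including zero-run animals.
Every grid value is validated before any detection; each row is
reproducible by a direct detector call at that point (no state leaks
between grid points; verified by test).

## The synthetic-data generator

Gene drop with explicit haplotype origins: founder haplotypes get unique
origin labels and alleles drawn per SNP from frequencies uniform on
[0.05, 0.5]; meioses place crossovers as a Poisson process (Haldane, no
interference) at 1 cM/Mb; an animal's autozygous segments are the
intervals where its two haplotypes carry the same origin label, tracked
at breakpoint resolution (exact, independent of the SNP panel).
Genotyping error flips one allele of a call (rate 0.002); missingness
masks calls (rate 0.005); a masked call cannot also carry an error.
Unknown parents receive fresh unrelated founder haplotypes.

Default scale emulates a small two-herd cattle population on a
medium-density chip: 29 autosomes × 87.6 Mb ≈ 2540 Mb, 1700 SNPs per
chromosome (≈ 49 300 loci) at sorted uniform random positions (spacing
irregular, as on real arrays — also what gives the SNP-density
sensitivity axis a graded rather than all-or-nothing response), 30
founders, 4 generations, 2 offspring per mating (~150 animals).
Mating designs: `random` (with an optional two-herd structure connected
only through shared sires), `circular`, and `full_sib_loop`, whose
pedigree inbreeding follows the textbook recursion (0.25, 0.375, …) and
provides closed-form expectations for validation.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: linkage disequilibrium among founder
haplotypes (founders are in linkage equilibrium, so IBS-only "runs" are
rarer than on a real chip and short-ROH counts are conservative); a
realistic site-frequency spectrum (uniform MAF is a stand-in; real
arrays are biased toward common variants with a spike of rare ones);
varying chromosome sizes; sex chromosomes; crossover interference; and
selection. Heterozygosity-rich islands, which in real populations may
reflect balancing selection, have no generating mechanism here, so
synthetic ROHet island counts are typically zero.

Test problem sizes are the package's own choices balancing statistical
power against run time: detector-vs-oracle equality uses 200 randomized
planted fixtures of 260 SNPs; pedigree-A validation uses 10⁵ single-locus
allele drops on an 8-animal looped pedigree (3 Monte-Carlo SE bands);
FROH parameter recovery uses 40 founders → 60 F = 0 and 60 F = 0.25
animals on a 10 × 100 Mb genome; the exponential tract-length check pools
~330 interior segments (Kolmogorov–Smirnov at α = 0.01 — a pool size at
which the test has power against real shape errors but tolerates the
known small deviations of junction theory, which ignores tract re-entry
and the merging of adjacent tracts from different ancestors).

## Numerical and degenerate-input conventions

* Coordinates are 1-based bp inclusive internally; all BED exports are
  0-based half-open (converters round-trip-tested).
* Chromosome labels are opaque strings; numeric labels sort numerically.
* A chromosome with fewer SNPs than the window yields no windows and no
  runs (logged once).
* An all-zero frequency vector in quantile island mode returns no
  islands with a warning rather than a degenerate threshold.
* Empty RunSets propagate as zero FROH for every panel animal (the
  RunSet's provenance carries the sample list precisely so zero-run
  animals are not silently dropped).
* The ROH-relationship builder refuses to combine RunSets whose panel
  hash or parameters differ.
* Pipeline outputs are a pure function of inputs and configuration;
  reruns are bit-identical.

## Known limitations

* PED parsing assumes biallelic SNPs; a third allele symbol is an error.
* The A matrix is dense O(n²) memory — fine for the few-thousand-record
  pedigrees this package targets, not for national evaluations.
* FROH's denominator uses a single global L_AUTO; per-animal covered
  genome (excluding that animal's missing segments) is not implemented.
* The sliding-window detector's maximum-coverage partition is one
  defensible reading of per-run blemish limits among several used by
  existing tools; `window_only` covers the main alternative.
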