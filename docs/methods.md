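# Methods

## Scope and data model

The pipeline consumes called diploid genotypes (VCF with GT and per-sample
DP) and a sample → population map, and operates throughout on a matrix of
*derived-allele dosages*: polarized biallelic sites × samples, with −1 for
missing calls. Polarization defaults to "reference-is-ancestral" — the
convention when reads were mapped to an outgroup-matched reference genome —
so ALT dosages are derived counts as read; an `aa-tag` mode instead trusts an
INFO/AA annotation, flipping or dropping sites accordingly. Working from
called genotypes (rather than genotype likelihoods) trades some robustness on
low-coverage data for determinism and exact, brute-force-checkable
statistics; with ≥ 20× data the two approaches agree closely in practice.

Coordinates: VCF positions are 1-based; every emitted interval (windows,
BED) is 0-based half-open. Windows tile each chromosome from coordinate 0 in
exact `window_size` steps (default 15 kb), so a position `pos` falls in
window `(pos−1) // 15000`; the terminal partial window is kept and flagged.
This anchoring reproduces published outlier-window coordinates that are
exact 15-kb multiples.

## Site filters

Filters are applied *per population* and produce retention masks, never
deletions, so one population's filtering cannot perturb another's
statistics. In precedence order (each dropped site attributed to the first
failing filter, so drop counts and retained sites add up to the total):

1. **call rate** — fraction of non-missing genotypes ≥ `min_call_rate`
   (default 1.0, i.e. complete cases, keeping the SFS sample size fixed;
   hypergeometric projection of partial sites is deliberately not
   implemented);
2. **depth** — summed population read depth within
   `[floor(1/3 · coverage · n), 2 · coverage · n]`, inclusive, with
   `coverage` the taxon's mean per-sample depth;
3. **MAF** — minor-allele frequency strictly greater than `maf_min`
   (default 0.05), computed on integer allele counts so the boundary is
   exact (19 of 20 chromosomes is MAF 0.05 → masked).

Mapping- and base-quality thresholds are upstream of genotype calling and
are not re-applied here.

## Spectra and neutrality statistics

Spectra are exact integer histograms of derived counts (no posterior
weighting). The joint 2D spectrum uses sites retained in both populations.
Windowed spectra are restrictions of the same site list, so they sum bin-wise
to the genome-wide spectrum — an invariant the tests assert exactly.

Per-window statistics are *sums* over the window's sites (the convention of
windowed theta tools; divide by span for per-site values): S, θπ, θW, θH,
Tajima's D and Fay & Wu's H as defined in the README. Windows with S = 0
carry NaN for D and H and are excluded from genome-wide means — they are
uninformative, not zero. The raw H = θπ − θH is the default; Zeng's
variance-normalized H is available behind a flag since published per-window
H values do not always state which normalization was used. Fixed-derived
sites (bin m) stay in the spectrum but contribute nothing to any estimator.

## F_ST scan

The estimator is the Bhatia/Hudson form with finite-sample correction
(ratio-of-sums aggregation per window — the weighted convention; a crafted
two-site example distinguishing it from mean-of-ratios is a frozen test).
Window F_ST may be slightly negative; it is left unclamped for the
Z-transform (clamping would bias the mean and SD) with a clamped display
column emitted alongside. Windows are *eligible* when they hold at least
`min_snps` jointly retained SNPs (default 10) and a positive denominator;
mean and SD for ZF_ST are taken over eligible windows of the pair, pooling
all chromosomes (including Z if present — a flag can exclude named
chromosomes upstream by filtering the input).

Outliers are eligible windows with ZF_ST ≥ 6. Published descriptions of
this threshold mix "above 6" and "≥ 6"; the inclusive form is adopted. A
window is *taxon-specific* when it is an outlier in **both** pairwise
comparisons involving that taxon (with three taxa each appears in exactly
two pairs); windows outlier in one comparison only are not assigned.

Low-differentiation regions formalize the qualitative notion of a
multi-window block that is jointly low in all three comparisons: flag
windows eligible in all pairs with ZF_ST < `z_low` in all of them, merge
flagged runs allowing ≤ `max_gap` unflagged windows between, and keep runs
spanning ≥ `min_region_windows` windows. Defaults `z_low = −1.0`,
`max_gap = 2`, `min_region_windows = 20` were calibrated once so that a
strongly conserved ~3.5-Mb (233-window) synthetic region is recovered with
≤ 2 windows of boundary error while ten no-signal simulations of the same
genome produce zero regions; `z_low = −1.5` proved too strict for the
sister pair, whose genome-wide mean F_ST sits close to zero so that even a
fully undifferentiated window rarely reaches −1.5 SD.

## The synthetic generator

Each site is independent (no linkage — scan-level validation therefore uses
window-aggregate signals only, and linked-selection footprints like ramped
shoulders around sweeps are out of scope). Per site:

1. ancestral derived frequency `p0` drawn from discrete classes `i/m_ref`
   with probabilities ∝ `i^(−α)`; `α = 1` is the neutral constant-size
   shape, larger α mimics the rare-variant excess of expansion;
2. Balding–Nichols drift per branch of `((willow, red), rock)`:
   `p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` — mean-preserving with variance
   `p(1−p)F`; defaults `F_node = 0.05`, `F_willow = F_red = 0.06`,
   `F_rock = 0.20`, chosen once so the sister pair is least differentiated
   and the rock comparisons most, the ordering the study system shows;
3. inside the conserved region all branch F are multiplied by δ (default
   0.02); inside a sweep window the focal taxon's frequency maps to
   `p^(1/κ)` (κ = 50 default), pushing derived alleles toward fixation in
   that lineage only;
4. genotypes ~ Binomial(2, p), per-sample depth ~ Poisson(coverage)
   (29×/28×/28×), a zero-depth sample is an uncalled genotype; sample sizes
   default to 19/9/6 diploids.

`m_ref` defaults to 1000. A coarse grid (e.g. one matching the sample size)
has no mass below `1/m_ref`, truncating the rare-variant tail; that bias is
large enough to push the *neutral* generator's windowed Tajima's D to ≈ +0.35.
At `m_ref = 1000` the neutral null is clean (|mean D| ≲ 0.03 over ~1200
windows) and D decreases strictly in α.

`expected_pairwise_fst` gives the closed-form calibration: compound each
lineage's drift from the pair's common ancestor as
`F' = 1 − Π(1−F_branch)`; the expected Hudson F_ST is `(F'_A + F'_B)/2`
(drift on the shared branch below the root cancels for the sister pair).
Simulation agrees within ±0.01 at 10⁵ sites — an acceptance check.

### What the generator does and does not emulate

It reproduces: tree-structured differentiation with closed-form
expectations; lineage-specific high-F_ST sweep windows; a jointly
drift-damped conserved region; depth structure; and, via α > 1, a
rare-derived-allele excess giving positive Fay & Wu's H.

It does not reproduce: linkage and hitchhiking shoulders; sequencing error;
and, importantly, *tip-level* expansion spectra under strong drift. The
α-skew is imposed on the ancestor; Balding–Nichols drift at compound
F ≈ 0.15–0.2 followed by conditioning on tip polymorphism flattens it (rare
ancestral alleles either die or jump to intermediate frequency), so mean
windowed Tajima's D under α = 1.6 with the default drifts is only mildly
negative (≈ −0.1), far above the strongly negative values (≈ −2) real
expansion data show. With weak drift (F → 0) the same α gives D ≈ −1 to
−1.6. Passing sign tests therefore demonstrate direction, not magnitude, of
the expansion signal; reproducing paper-scale D would need growth within
each terminal lineage, which this generator intentionally does not model.

### Validation problem sizes

The scan-recovery checks run on a 30-Mb, 2000-window genome with 600k sites
(~100 filter-passing SNPs per window per pair — the same order as ~8M
variable sites over a ~1-Gb genome), six single-window sweeps (two per
taxon) and one 233-window conserved region, with the neutral spectrum shape
so SNP density stays uniform across drift regimes; the expansion shape is
exercised separately by the sign-recovery analyses. The bundled `tiny-*`
fixtures (≤ 2000 sites, ≤ 5 Mb) are for I/O round-trips, record accounting,
determinism and null behaviour — at ~6 raw sites per window they cannot
support ZF_ST ≥ 6 recovery claims, which is why recovery oracles use the
30-Mb configuration.

## Numerical choices

* Tajima's constants computed directly from sample size; tests pin them to
  an exact-rational reference and to tskit on coalescent simulations.
* ZF_ST uses population SD (ddof 0); standardization to mean 0 / SD 1 over
  eligible windows is asserted to 1e-10.
* Degenerate scans (constant F_ST, < 2 eligible windows) are hard errors,
  not NaN propagation; "constant" is judged at relative 1e-12.
* The depth lower bound `floor(1/3·cov·n)` adds a 1e-9 epsilon before
  flooring so the textbook value (e.g. 56 for 28× and 6 diploids) is exact.
* MAF boundaries are decided on integer allele counts, never on floats.
* Merge order and all outputs are deterministic functions of
  (inputs, config, seed); reruns are byte-identical.

## Known limitations

* Complete-case handling of missing genotypes discards whole sites per
  population at `min_call_rate = 1`; no SFS projection.
* No folded-spectrum mode: the analysis is defined for polarized data.
* The generator's independence across sites understates the spatial
  autocorrelation of real windowed statistics; empirical outlier thresholds
  on real data should account for linkage.
* Genome-wide D/H magnitudes from the generator are not comparable to real
  expansion magnitudes (see above); only signs and orderings are validated.
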