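# Methods

## Scope and model

`promarch` implements the computational core of a promoter-architecture
study in *Drosophila*-style genomes: the distinction between
**developmental** promoters (TATA-box / DPE / INR motifs, focused
initiation at one dominant TSS, a loosely positioned +1 nucleosome) and
**housekeeping** promoters (TCT / DRE / Ohler1/6 motifs, dispersed
initiation across ~50–100 bp, a well-positioned +1 nucleosome ~125 bp
downstream of the dominant TSS). Five analysis layers sit on a common
coordinate model (0-based half-open intervals, single-base stranded
signals):

1. **TSS correction.** Annotated TSSs move to the strongest CAGE position
   within ±250 bp of the annotation, searching a primary track and then
   fallback tracks in order; unsupported TSSs are retried at ±500 bp and
   otherwise kept. A "hit" is any same-strand position with a positive tag
   count (a minimum-count option exists, default 1). Ties on count break
   first to the position closest to the annotation, then to the more
   upstream one (both tie rules are our choice; the procedure itself does
   not determine them). Fallback tracks are queried sequentially, not
   pooled, so every correction is attributable to a single track. One
   transcript is kept per unique corrected TSS: the longest, ties to the
   lexicographically smallest id.

2. **PWM classification.** A promoter's match to motif *m* is the maximal
   log₂-odds score over sense-strand motif-start offsets inside a
   TSS-relative search window, rescaled to percent of the achievable range:
   `percent = 100·(S* − S_min)/(S_max − S_min)` with `S_max`/`S_min` the
   sums of per-position extrema. This min–max construction is the standard
   way to make scores comparable across motifs of different length and
   information content, and it is oracle-testable by full enumeration.
   `N` bases contribute zero log-odds. Binary presence flags use strict
   thresholds (TATA > 90, INR > 95, DPE > 98, TCT > 95, Ohler1 > 95,
   Ohler6 > 97, Ohler7 > 95, DRE > 98 percent). The exclusive label takes
   precedence TCT > TATA > DPE > INR > DRE > Ohler1/6 — the more
   position-specific element names the class; promoters with no flag are
   `other`. A k-means overview (k = 9, Lloyd's algorithm via scikit-learn,
   best of 10 restarts, seeded) gives the unsupervised picture of motif
   co-occurrence. Prototype selection adds the stringent co-occurrence
   rules (e.g. TATA > 95 with all competing motifs < 80–90) plus an
   activity requirement of ≥ 5 CAGE tags per million within ±50 bp of the
   TSS (the ±50 bp window is our choice). The DRE prototype rule demands a
   perfect (=100%) match, so that one requirement is inclusive.

3. **Initiation shape.** Profiles are tag-count vectors at sense offsets
   ±120 bp around the corrected TSS. Dominant TSS = modal position (ties
   upstream); dominant fraction = modal count / total; activated TSSs =
   positions above 20% of the dominant count, in both a strict (> 20%) and
   an inclusive (≥ 20%) mode — both readings exist in practice, so the
   choice is surfaced as a parameter instead of silently unified; width =
   span of positions with count ≥ a floor (default 1), gaps included.
   −1/+1 dinucleotides are taken on the sense strand with the +1 base at
   the TSS; contig edges and Ns are skipped and tallied.

4. **Chromatin.** +1 nucleosome = position of maximal MNase
   fragment-center coverage (fragments 100–200 bp inclusive; center
   `floor((start+end)/2)`) in a +1..+200 bp window downstream of the
   dominant TSS, ties toward the TSS. The +1..+200 window follows the wider
   of the two windows in circulation (a 150-bp variant also exists; the
   window is configurable). CAGE×MNase cross-correlation z-scores each
   promoter's CAGE vector over −50..+200 and Pearson-correlates it with
   the fragment-center vector shifted by each lag in −50..+200 (the shifted
   vector is read from the untruncated track). Promoters with constant CAGE
   or < 10 fragment centers in the window are excluded; lags where a
   shifted vector is constant contribute NaN and drop out of the mean. The
   Pearson-on-z-scores estimator is our concretization of
   "cross-correlation"; a plain dot-product variant would differ only by
   per-promoter scaling, which the z-scoring removes by design.

5. **Depletion response.** Per-sample size factors are proportional to the
   spike/reference read ratio (raw spike tallies if no reference is given),
   normalized to geometric mean 1. The differential test is an **exact
   conditional binomial**: given a gene's replicate-summed counts
   n = c + t, under the null t ~ Binomial(n, π₀) with π₀ the depleted
   share of the summed size factors; the two-sided p sums all outcome
   probabilities ≤ the observed one (relative tie fuzz 1e-7). This is a
   deliberately simple, fully calibrated test sharing the thresholds and
   normalization entry point of a negative-binomial GLM workflow; any
   external test can be injected via the `test` hook of
   `call_downregulated`. Fold changes use normalized condition sums with a
   0.5 pseudocount; genes with < 10 normalized counts total are reported
   but not testable. Down = log₂FC ≤ −log₂1.5 and BH q < 0.05. Fisher
   motif enrichment uses the same sum-of-small-probabilities two-sided
   definition on the hypergeometric; odds ratios get a Haldane 0.5
   correction only when a cell is zero. ChIP z-scores divide per-promoter
   coverage by the gene's transcription rate (nascent counts / gene
   length), average within class, and z-score the class means per factor
   (population sd, ddof 0).

## Synthetic data generator

The generator is first-class, tested code; its defaults are the package's
study conditions.

* **Landscape.** Six classes, 121-bp cores centered on the true dominant
  TSS, promoters 3 kb apart on alternating strands of one contig,
  i.i.d.-uniform background. Embedded motifs are idealized consensus PWM
  instantiations at fixed offsets (TATA −31, INR 0, DPE +28, TCT 0,
  DRE −60, Ohler1 −45, Ohler6 −25); developmental classes carry the known
  co-occurrences (TATA+INR, DPE+INR). Offsets and consensus strings are
  package inventions chosen to sit inside the default search windows; all
  are configurable.
* **CAGE.** Per promoter, total tags ~ Poisson(2000). Focused classes put
  0.8 of the mass on the dominant base with a geometric (ratio 0.5)
  fall-off over ±3 bp. Dispersed classes spread mass over a 100-bp window
  with uniform-random per-position weights, the window ending 30 bp
  upstream of the +1 nucleosome center; the dominant position always
  carries a fixed 0.15 weight so it remains the modal TSS without focusing
  initiation. Anchoring the dispersed window to the nucleosome (rather
  than a motif) encodes the empirical alignment of housekeeping initiation
  to the +1 nucleosome and gives the cross-correlation analysis real
  structure to recover; 0.15 keeps the dominant fraction well under the
  0.2 that separates the regimes while making the dominant TSS reliably
  detectable at the default tag depth.
* **MNase.** Fragment centers ~ round(Normal(true center, sd)) with sd
  10 bp (housekeeping) or 40 bp (developmental); the center sits 125 bp
  downstream of the dominant TSS in sense orientation. Lengths ~
  round(Normal(147, 10)), redrawn outside [80, 220] so a tail of
  fragments deliberately fails the [100, 200] analysis filter.
* **Counts.** Baselines ~ LogNormal(log 200, 1) over 2000 genes; the
  depleted mean of gene g is baseline·fold_g·G with G a global output
  factor. Counts are Gamma-Poisson (negative binomial, dispersion φ)
  around depth-scaled means, 3 replicates per condition, 1e6 reads per
  sample. Spike reads ~ Binomial(depth, κ/(κ+O_s)) with κ = 0.01 and O_s
  the sample's relative total output, so a global collapse inflates the
  spike share (~4-fold at G = 0.25). **Default φ = 0 (Poisson).** The
  default models UMI-collapsed counting noise, under which the exact
  conditional test is exactly calibrated; with biological overdispersion
  (φ > 0, fully supported and exercised in tests) the pooled-count
  binomial p-values become anti-conservative, which is the known cost of
  this test relative to a dispersion-modeling GLM. The fold-change
  threshold provides the practical guard in that regime.
* **Determinism.** One integer seed; every promoter and the count
  simulation draw from counter-derived `numpy` substreams
  (`default_rng([seed, stream, counter])`), so outputs are byte-stable and
  robust to subsetting.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume — motif
positioning, the focused/dispersed dichotomy, nucleosome-anchored
dispersed initiation, spike-in arithmetic — but not realistic sequence
composition (GC bias, repeats, motif degeneracy beyond IUPAC), CAGE
protocol artifacts, MNase sequence bias, or correlated gene programs.
Passing recovery tests therefore demonstrates that the estimators measure
what they claim under their own assumptions, not that those assumptions
hold in any particular real dataset.

## Numerical and edge-case conventions

* Percent scores clip to [0, 100]; an uninformative (all-uniform) matrix
  scores 100 by convention. Threshold comparisons are strict (a score
  exactly at threshold does not flag).
* Dominant-TSS and +1-center ties break upstream / toward the TSS;
  TSS-correction ties break closest-to-annotation, then upstream.
* Exact-test and Fisher tie comparisons use a 1e-7 relative fuzz; both
  match exact rational enumeration to < 1e-12 in the acceptance battery.
* All-zero profiles, empty down-sets, zero spike reads, unstranded reads
  where strand matters, and k > n clusterings raise errors rather than
  returning degenerate values.
* Where a numeric value of magnitude ≤ 1 is asserted, tolerances are
  absolute; percent-scale assertions use the tolerances stated with each
  acceptance test.

## Problem sizes

Recovery analyses run at 100–200 promoters per class (600 for
classification recovery), 150 promoters per group for cross-correlation,
and 2000 genes × 6 samples for the count battery — sizes at which every
tested property is stable across seeds while the whole battery completes
in well under a minute per analysis.

## Known limitations

* The exact conditional test ignores between-replicate overdispersion (see
  above); it is a contract-compatible default, not a DESeq2 reimplementation.
* Sense-strand-only PWM scanning by default (DRE is quasi-palindromic; a
  reverse-strand scan is available but off).
* TSS-correction band boundaries blur by the width of the initiation
  spread: a promoter whose tags extend w bp around the dominant TSS can be
  captured by a window up to w bp before its annotation error would
  suggest. Band-recovery checks therefore sample jitters a few bp away
  from the ±250/±500 edges.
* `collapse_by_tss` keys on exact TSS equality; near-duplicate TSSs (±1 bp)
  remain separate promoters.
* The activity tpm uses the whole track as denominator, i.e. assumes the
  track covers the mappable transcriptome.
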