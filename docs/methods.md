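# Methods

This note documents the statistical model, the scoring conventions, the
synthetic-cohort generator and the numerical choices behind `mirtfnet`, in
the order the pipeline runs them.

## Study design and quantification

The unit of analysis is a paired tumor/adjacent-normal design with a small
number of patients (default 4 pairs), each contributing one mRNA-seq and
one small-RNA-seq library. Counts live in a `CountMatrix` whose per-sample
metadata carries the pair id, condition, total clean reads and uniquely
mapped reads; every pair must have exactly one tumor and one normal
column.

Three within-sample normalizations are provided, each with the denominator
its convention prescribes, and these deliberately differ:

* **RPKM** = count / (exonic length in kb × uniquely mapped reads / 10⁶).
  Only unambiguously aligned reads enter the per-million term.
* **small-RNA TPM** = count / *total clean reads* × 10⁶. The denominator
  is the sequencing depth, not the miRNA-mapped total, so column sums are
  ≤ 10⁶ with equality only if every clean read was a counted miRNA read.
* **CPM** = count / column sum × 10⁶; column sums are exactly 10⁶.

Expression filters support both boundary conventions: `≥ t` (the
"RPKM ≥ 1" rule) and `> t` (the "above 1 CPM/TPM" rule), over at least
`min_samples` samples. Feature length means summed exonic length supplied
as input; no gene-model parsing is done.

## Per-pair exact negative-binomial test

With one library per condition per patient, no dispersion is estimable
from the data; the test takes a fixed dispersion φ (default 0.1, a common
fallback for no-replicate human tissue; the synthetic studies in this
repository analyze their cohorts at the generating value 0.05). The value
used is recorded in every result row.

Given counts (y_a, y_b) with library sizes (L_a, L_b):

1. Libraries are equalized to L* = √(L_a·L_b); counts are rescaled and
   rounded half-to-even.
2. Conditional on s = y′_a + y′_b, each split i ∈ [0, s] receives weight
   w(i) = NB(i; μ = s/2, φ) · NB(s−i; μ = s/2, φ) where the NB has
   variance μ + φμ².
3. The two-sided p-value is Σ{w(i) ≤ w(obs)·(1+10⁻⁹)} w(i) / Σ w(i). The
   relative tie tolerance avoids float-equality artifacts; s = 0 gives
   p = 1 (no evidence). As φ → 0 the conditional law is Binomial(s, ½)
   and the test reduces to the exact binomial two-tail.

**Numerics.** For totals s ≤ 4096 the sum is enumerated directly in log
space. For larger totals the implementation uses the exact symmetry
w(i) = w(s−i) and the unimodality of w (guaranteed for φ < 1): the
rejection region is the two tails [0, k] ∪ [s−k, s] with
k = min(y′_a, s−y′_a), and each sum is truncated once terms fall ~22
decades below the peak (truncation error < 10⁻¹²; the observed split is
always counted, so p > 0). The window width is 10 conditional standard
deviations plus a constant.

Fold changes are computed on CPM with pseudocount 0.5 (the source study
does not state its formula); BH adjustment is applied within each pair
across all features passing the CPM filter. A feature is **up** in a pair
iff log₂FC > log₂(1.5) and FDR < 0.05, **down** symmetrically, else
**ns** — so the direction is recomputable from (log₂FC, FDR) alone.

Cross-pair recurrence is summarized per feature by the sets of pairs where
it was called up/down; a feature is *coordinated* when called in the same
direction in every pair, and Venn cell counts are emitted for each pair
subset.

## Target prediction

Sequences are normalized to uppercase RNA (T→U); mature miRNAs shorter
than 16 nt are rejected. The seed is positions 2–8.

**Site grammar.** Sites are anchored on exact Watson–Crick matches of the
UTR to the reverse complement of seed positions 2–7 (no G:U in the seed).
A match to position 8 immediately 5′ on the UTR and/or an A immediately 3′
(opposite position 1) upgrade the anchor to 7mer-m8 / 7mer-A1 / 8mer; each
anchor is reported once with its maximal type. Coordinates are 0-based
half-open on the 5′→3′ UTR strand.

**Hybridization score.** A seed-weighted local alignment (Gotoh affine
gaps) of the reversed miRNA against a UTR window ending at the site:
Watson–Crick +5, G:U +2, mismatch −4, gap open −8 (first gapped base),
gap extend −2, with pair/mismatch terms doubled at miRNA positions 2–8.
The score is on this package's own scale; the historical absolute cutoff
of external tools is re-expressed *per miRNA* as a fraction (default 0.9)
of its perfect-duplex score, with an absolute override available.

**Context-like score.** Per site:
`base(type) − w_AU·AU30 − w_pos·prox`, base = {8mer −0.31, 7mer-m8 −0.16,
7mer-A1 −0.10, 6mer −0.03}, AU30 = A/U fraction of ≤30 nt flanking each
side, and `prox = max(0, 1 − min(d5, d3)/((L − ℓ)/2))` where d5/d3 are the
gaps between the site and the UTR ends, L the UTR length and ℓ the site
length. This normalization makes the feature exactly 0 for a centered
site and exactly 1 for a terminal site regardless of UTR length, which is
the behavior the two anchor cases require; weights default to 0.1 each.
The weights are a transparent additive surrogate keeping the canonical
feature ordering (site type ≫ AU context ≫ position); they are not fitted.

**Gene-level call.** Overlapping sites are resolved greedily by descending
alignment score (ties: leftmost). A (gene, miRNA) passes iff the summed
alignment score over retained sites reaches the threshold **or** the
minimum (best) context score is negative and its site is 7mer-or-better.
Aggregation is per gene total for alignment and per best site for context
— the conservative reading of per-gene vs per-site reporting.

## Network assembly

For every passing (miRNA, gene) call and every pair in which the miRNA and
the gene were called in opposite directions, that pair supports an edge of
the corresponding pattern (`miR_up_gene_down` or `miR_down_gene_up`).
Patterns are never merged: mixed-direction evidence does not sum. The
recurrence filter keeps edges with ≥ `min_pairs` supporting pairs
(default 2). "Inverse correlation" is operationalized as sign-opposite
significant DE within the same pair rather than a correlation coefficient,
which would be meaningless at n = 4 pairs.

The TF subnetwork restricts to `miR_up_gene_down` edges whose gene is in a
user-supplied TF list; hub statistics are exact degrees sorted by count
descending then id ascending. TF status is an input list — no GO-based
inference is attempted.

## Enrichment

The default test is the central hypergeometric upper tail (P(X ≥ k)), BH
across tested terms; terms with no universe genes or no study hits are
excluded before correction. The rich factor is k/K. The Wallenius
noncentral variant (via `scipy.stats.nchypergeom_wallenius`) is opt-in
with explicit per-gene weights — the odds is the mean weight of the term's
genes over the mean weight of the rest; uniform weights reproduce the
central test. We refuse to guess a weighting scheme silently.

## Synthetic cohort generator

The generator emulates the *structure* of a small paired oncology cohort,
not any particular dataset:

* **Transcriptome/mirnome** — `n_genes` random UTRs (default 2000,
  lengths 250–700 nt) with a TF subset (150) and random GO terms (TFs
  share a transcription-factor-activity term), and `n_mirnas` mature
  miRNAs (300) of length 19–23 nt. The planted co-upregulated set (40)
  has pairwise-distinct seeds.
* **Planted structure** — the hub is the TF with the longest UTR; the
  first 25 up-miRNAs get one non-overlapping 8mer site each in it. Every
  up-miRNA additionally receives 12 sites spread over a shared co-target
  pool of 40 genes: co-upregulated miRNAs convergently hit an overlapping
  gene set, so each pool gene carries sites for several miRNAs. Planted
  sites are 8mers (the strongest canonical class) so their recovery is
  threshold-robust, and never overlap.
* **Counts** — gamma-Poisson (NB) with dispersion φ = 0.05 around
  library-scaled baselines. Bulk baselines are log-normal — heavy-tailed
  for miRNAs (log-mean log 3000, log-sd 1.2), as in real small-RNA
  libraries where a few species dominate — while planted features sit at
  moderate abundance (uniform 250–800 at the per-million scale, i.e.
  means ≥ ~200 at the default 1–2M library sizes). Because the planted
  features hold a small share of the library mass, their fold changes
  survive column-sum normalization nearly undistorted. Tumor effects:
  planted miRNAs ×4 (up) or ×¼ (down); targeted genes ×0.5 per targeting
  miRNA, floored at 0.1 (multiplicative compounding is the simplest model
  of cooperative suppression; the floor keeps deeply co-targeted genes
  measurable). A random 10% of unplanted features receive per-pair
  log-normal background fold changes (log₂ sd 1.0) — the biological
  pair-to-pair heterogeneity the recurrence filter exists to remove.
  Library sizes are uniform in 1–2M reads (scaled down from tens of
  millions to keep desk-scale runtimes); total clean reads are the column
  sum divided by a mapped-fraction draw (60–75% mRNA, 20–50% small RNA).
* **Determinism** — every stage draws from `default_rng([rng_seed,
  stage_index])`, so identical configs give byte-identical artifacts and
  stages are reproducible in isolation.

**What the generator does not emulate:** real sequence composition (UTRs
are uniform random, so chance seed matches are Bernoulli-like rather than
motif-structured), stromal/macrophage admixture, isoform structure,
adapter/alignment artifacts, and correlated dispersion across features.
Passing recovery tests therefore demonstrates that the chain detects the
planted signal class under NB noise — not performance on real tissue.

## Verification strategy

The test suite checks each stage against an independent oracle: the exact
test against brute-force enumeration of the conditional distribution (all
totals ≤ 60) and the exact binomial two-tail at φ = 10⁻⁸; the windowed
large-total path against full enumeration; the site grammar against a
regex scan; the aligner against a second, memoized DP; the context score
against direct recomputation; hypergeometric p against exhaustive draw
enumeration (N ≤ 12) and Wallenius against a sequential weighted-draw DP;
BH against a hand step-up. Null calibration uses global-null cohorts
(planted effects off, background off) at matched analysis dispersion: the
pooled p-value CDF must not exceed uniform by more than 0.02.

End-to-end recovery runs the default cohort on seeds 1–5 and requires
≥ 90% of planted up-miRNAs recovered as recurrently up (up in ≥ 2 pairs —
the recurrence convention used for every "identified" feature in the
integration; the stricter all-4-pairs coordinated fraction is ~0.9⁴ by
construction at the planted effect size and is reported separately by the
acceptance script), the hub top-ranked among TFs with in-degree ≥ 20 in
every seed, and ≥ 80% precision of `miR_up_gene_down` edges against the
planted target map.

## Problem sizes and defaults

Default analysis knobs: dispersion 0.1; |FC| > 1.5, FDR < 0.05; CPM > 1
in ≥ 1 sample; pseudocount 0.5; align threshold 0.9 × perfect duplex;
context weights 0.1/0.1; min_pairs 2; top 15 enrichment terms. The
acceptance script runs 3 recovery cohorts at the full default scale
(2000 × 300 × 4 pairs), 3 null cohorts of 4000 features, and the
861-point Poisson-limit grid; the test suite uses 20 null cohorts of 10⁴
features and 5 recovery seeds.

## Known limitations

* The dispersion is a fixed input; with n = 1 per group per pair no
  tagwise/trended estimation is possible, and misspecifying φ shifts both
  power and the null calibration (testing at φ below the true value is
  anti-conservative).
* The context-like score is a fixed-weight surrogate, not a fitted
  regression; its absolute values are not comparable to external tools.
* The alignment threshold is relative to a per-miRNA perfect duplex;
  users calibrated to an absolute tool scale should set `align_min`.
* BH is applied within each pair; no cross-pair adjustment is made.
* Pairs are treated as independent; no information is shared across them.
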