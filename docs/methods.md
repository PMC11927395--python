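# Methods

## The problem and the signal-level model

Nanopore basecallers convert raw pore current (the squiggle) into bases, and
short deletions — mostly inside homopolymer runs — are their dominant
systematic error.  A candidate deletion call therefore has two possible
origins, distinguishable only below the basecall level:

* **genuine deletion**: the molecules carrying it really lack the deleted
  base, so the deletion-supporting (DEL) reads' current around the site
  differs from the reference-supporting (NODEL) reads' current;
* **basecall artifact**: the molecule is intact, the current matches the
  non-deleted template, and only the basecalls (and, empirically, the local
  base qualities) are wrong.

`delsieve` scores each candidate by the *group contrast* between DEL and
NODEL reads, either on length-normalized flanking squiggles (R9, where
per-base signal segmentation is available) or on flanking Phred qualities
(R10, or R9 at low depth), and removes candidates whose contrast falls
strictly below a per-configuration threshold.

## Procedure

**Parsing and classification.**  Canonical VCF deletions (ALT a strict
prefix of REF) with MuAF ≥ 0.05 are kept; SNVs/insertions/MNVs are counted
and skipped.  Multi-allelic records are split per allele.  A deletion is a
*homo-del* iff **every** deleted base lies inside a maximal reference
homopolymer run ≥ 3 (containment, not adjacency: a deletion next to a run
but outside it is an other-del).  Coordinates are 1-based only at the VCF
boundary; internally everything is 0-based half-open.

**Read grouping.**  A read is DEL when its alignment has a deletion spanning
exactly the variant interval, NODEL when it has aligned bases across the
whole interval; reads that only partially overlap the window, carry any
other indel inside it, or are secondary/supplementary/duplicate are excluded
and counted.  Reads with mismatches (not indels) in the window are kept —
group purity concerns alignment structure, not base identity.  Subsampling
draws min(N, available) reads uniformly without replacement from each of the
four (strand × allele) strata; the per-variant RNG substream is derived from
(seed, contig, pos) so variant order never changes draws.  A stratum below
20 reads (the smallest depth the selector covers) makes the variant
NOT_EVALUATED.

**Signal windows and binning.**  Flanks only, in reference space: k = 5
bases per side by default (k = 10 supported), excluding the deleted
interval, so DEL and NODEL rows describe homologous sequence.  Translocation
speed varies per read, so each read's concatenated flank signal (length L)
is normalized to B bins, bin *i* covering samples `[⌊iL/B⌋, ⌊(i+1)L/B⌋)`
with the slice mean as value.  B defaults to 10 × (window bases) — about
native resolution at ~400 bases/s and the 4 kHz sampling rate, from which
`sequencing_speed` also derives measurements/base and bases/s.  Degenerate
case L < B: empty bins carry the preceding bin value forward, and leading
empties are back-filled from the first occupied bin.  When B divides L the
transform preserves the mean exactly and is invariant under k-fold sample
repetition; these are tested properties.

**Group statistics.**  On the reads × bins matrix with Euclidean pairwise
distances d:

* MRPP A = 1 − δ_obs/δ_exp with δ = Σ_g (n_g/N)·(mean within-group
  distance).  With these weights, the expectation of δ under uniform random
  relabeling is exactly the mean of all pairwise distances; the analytic
  mode uses this closed form (default), and permutation / full-enumeration
  modes exist as cross-checks (they agree to < 1e-12 on enumerable
  instances).  δ_exp = 0 (all rows identical) returns A = 0 by convention.
* ANOSIM R = (mean between-group rank − mean within-group rank)/(M/2) on
  the ranked distances, average ranks on ties; bounded in [−1, 1].
* ADONIS pseudo-F from SS_total = (1/N)Σd², SS_within = Σ_g (1/n_g)Σ_g d²;
  SS_within = 0 with separated groups gives +∞, all-identical rows give 0.
* Accumulative difference = Σ_bins |mean DEL profile − mean NODEL profile|,
  in current units; absolute values keep the index sign-agnostic.
* Q-score index: per DEL read, the mean Phred quality at the window bases
  (bases falling in deleted/clipped read regions skipped); the index is the
  mean over reads, in Phred space — thresholds are published in Phred
  units, so no error-probability averaging.  DEL reads only: they are the
  entity being judged.

All four matrix statistics are invariant under label swap, and their
medians are non-decreasing in the group mean shift (tested).  P-values are
deliberately absent: the filter thresholds the statistics themselves.

**Selection and thresholding.**  The selector maps (flowcell, protocol,
strand-depth band, deletion class) to an index/threshold pair (table in the
README); depth bands are closed on the left, open on the right.  Amplicon
protocols use the amplified (WTA-calibrated) row.  R10 + fast basecalls are
refused outright (their qualities do not separate the classes); R10 + HAC
reuses the SUP thresholds with an explicit warning.  The verdict rule is a
strict inequality — index < threshold ⇒ ARTIFACT, index = threshold ⇒ KEEP
— and anything unscorable is NOT_EVALUATED, never silently dropped.  Output
is a VCF with `artifact_del` FILTER plus DSV_* INFO keys (mark mode) or with
artifacts removed (drop mode), and a per-variant decisions TSV.

**Calibration.**  ROC AUC uses the rank (Mann–Whitney) formulation with tie
correction, equal to both pair-counting and trapezoidal oracles to 1e-12 on
tested instances.  Candidate thresholds are midpoints between adjacent
distinct scores plus ±∞; the default threshold maximizes
sensitivity + specificity (sensitivity = artifacts flagged, specificity =
genuine deletions kept), ties broken toward higher specificity — the filter
exists to remove FPs, and the strict-< rule already protects TPs at the
boundary.  `depth_sweep` repeats the measurement across strand depths and
replicates with per-cell seed substreams.

## The synthetic generator

`simulate` builds complete datasets (reference FASTA, coordinate-sorted SAM
with correct CIGARs, VCF with AF, per-base signal TSV, truth table) and
statistics-level cohorts, byte-identical per seed.  It emulates exactly the
mechanism the filter exploits:

* TP loci: DEL reads lack the deleted base's segment and their covered
  bases' current levels shift by Δ (`tp_signal_shift`, default 6 ≈ 3 ×
  `noise_sd`);
* FP loci: DEL reads' basecalls contain the deletion but their flank current
  is drawn from the same per-base level template as NODEL reads (zero
  designed contrast), and their window qualities are depressed by
  `q_depression` (default 6 Phred below the 25-Phred baseline, putting FP
  reads near 19 — below every Q threshold — and TP reads near 25, above).

Defaults are the study conditions the filter targets: strand depth
100× (where the signal index is stable), MuAF 0.2 (within the 0.1–0.5
mutant-mix range; end-to-end experiments use 0.5, the 1:1 mix), deletion
lengths 1–3 nt (60/25/15%), half homopolymeric loci, ~10 samples/base with
Poisson dwell jitter, per-base current levels {A 80, C 95, G 110, T 125}
with Gaussian noise sd 2.  A per-base level table (not a k-mer pore model)
is sufficient to create the contrast structure the statistics consume; a
6-mer table is the documented extension point.

What the generator does **not** model — and therefore what passing tests do
not establish about real data: k-mer-dependent levels and real pore models,
dwell-time dynamics and stalls, basecaller-specific quality biases,
alignment artifacts around tandem repeats, sample contamination.  Because
per-base dwell varies across reads, bin b of one read does not cover exactly
the same bases as bin b of another; this misalignment inflates within-group
distances and keeps MRPP A numerically small even under strong contrast
(genuine loci score ≈ 0.03–0.1 versus ≈ ±0.002 at artifact loci at depth
100×) — consistent with thresholds of 0.01/0.001 rather than with A near 1.

## Problem sizes and numerical choices

Desk-scale sizes, chosen so the whole suite runs in about a minute: shared
integration bundle 8 variants at depth 40×; recovery experiments 10
independent datasets × 12 variants at depth 100×, MuAF 0.5; null cohort 200
variants at depth 100×; depth sweeps 24 variants, pools of 100 per stratum,
10 replicates.  All randomness flows through explicit seeds
(`numpy.random.SeedSequence` substreams); hypothesis-based property tests
are derandomized.

Open design points resolved here: flanks are extracted in reference space
(not read space) for DEL reads; both 10- and 20-base squiggle windows are
supported with 10 the default; Q scores are computed on DEL-group reads
(flag-switchable); sweeps pool variants rather than averaging per sample;
an off-table `--force-qscore`-style override is available via threshold
overrides rather than a dedicated flag.

## Limitations

Insertions and SNVs are out of scope.  The R9 signal route requires an
external resquiggle step (the fast5 adapter consumes its output; the
segmentation itself is not reimplemented).  Thresholds shipped are the
published defaults; recalibration on user data requires truth labels and
the `calibration` module.  NOT_EVALUATED variants (low depth, truncated
windows, missing signals) are reported but not adjudicated.
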