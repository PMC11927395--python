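# delsieve

Filter **low-frequency artificial short deletions** out of nanopore
sequencing variant calls, in single samples, using the raw current signal
(squiggle) or flanking base qualities.

Nanopore basecallers systematically emit short spurious deletions —
overwhelmingly in homopolymer runs of ≥3 identical bases — that survive into
low-frequency variant calls (mutated allele frequency, MuAF, as low as 0.05).
These artifacts are hard to remove because genuine low-frequency deletions
(viral quasispecies, mixed bacterial strains, tumor heterogeneity) look
identical at the basecall level.  They are *not* identical at the signal
level: when a deletion is real, the reads carrying it genuinely lack the
deleted base's current segment and their flanking squiggle differs from
reads without the deletion; when it is a basecall artifact, the deletion
reads' current matches the non-deleted template.

`delsieve` quantifies that contrast per candidate deletion and removes
variants whose contrast is too small to be real.

## Method

For each candidate deletion (from a LoFreq-style VCF):

1. classify it as **homo-del** (every deleted base inside a reference
   homopolymer run ≥ 3) or **other-del**;
2. assign overlapping reads to DEL / NODEL groups by walking their CIGARs
   across the deleted interval, and subsample **N** reads per
   (strand × allele) stratum (strand-specific depth);
3. extract the flanking squiggle (5 bases per side by default) of every
   read, length-normalize to *B* bins (bin *i* covers samples
   `[⌊iL/B⌋, ⌊(i+1)L/B⌋)`, bin value = slice mean), and compute the
   group-difference index on the reads × bins matrix with Euclidean
   distances:

   * **MRPP A** = 1 − δ_obs/δ_exp, where δ = Σ_g (n_g/N)·(mean within-group
     pairwise distance) and δ_exp is its expectation under random
     relabeling (closed form: the overall mean pairwise distance);
   * companions: **ANOSIM R** (rank-based), **ADONIS pseudo-F**
     (distance-based ANOVA), and the **accumulative difference**
     Σ_bins |mean DEL profile − mean NODEL profile|;

   or, on the quality route, the **10-mer mean Q score**: the mean flanking
   Phred quality of the deletion-supporting reads;
4. pick index and threshold from the run metadata:

   | flowcell | protocol  | strand depth | index   | threshold |
   |----------|-----------|--------------|---------|-----------|
   | R9       | amplified | ≥ 20×        | MRPP A  | 0.01 |
   | R9       | direct    | ≥ 400×       | MRPP A  | 0.001 |
   | R9       | direct    | [20×, 400×)  | Q score | 23 (homo-del) / 20.6 (other-del) |
   | R10      | direct    | ≥ 20× (SUP)  | Q score | 21.8 (homo-del) / 20.0 (other-del) |

   R10 never needs signal parsing; R10 fast-model basecalls are refused.
5. a variant whose index is **strictly below** the threshold is an
   **ARTIFACT** (FILTER `artifact_del`, or dropped); unscorable variants are
   **NOT_EVALUATED**, never silently removed.

## Worked example

`python examples/03_filter_variants.py` simulates a dataset with known
ground truth and runs the full R9-amplified filter:

```
 pos  ref alt del_class    value  threshold  verdict truth
  40   CG   C OTHER_DEL 0.000085       0.01 ARTIFACT    FP
  82   GA   G OTHER_DEL 0.001922       0.01 ARTIFACT    FP
 125 AAAA   A  HOMO_DEL 0.001753       0.01 ARTIFACT    FP
 171   TT   T  HOMO_DEL 0.052706       0.01     KEEP    TP
 215  CCC   C  HOMO_DEL 0.041407       0.01     KEEP    TP
 259  CAC   C OTHER_DEL 0.052465       0.01     KEEP    TP
 302 CATA   C OTHER_DEL 0.103675       0.01     KEEP    TP
 347   AA   A  HOMO_DEL 0.001065       0.01 ARTIFACT    FP

summary: {'KEEP': 4, 'ARTIFACT': 4, 'NOT_EVALUATED': 0}
```

`value` is MRPP A on the flanking-squiggle matrix: artifact loci sit near 0
(deletion reads' signals match the template), genuine deletions sit well
above the 0.01 threshold.  The other examples show fixture generation
(`01`), the per-locus statistics (`02`) and depth-sweep calibration (`04`).

The same run is available as a shell command:

```sh
delsieve fixtures --out-dir fx --seed 42 --n-variants 8 --depth 40 --muaf 0.5
delsieve filter --vcf fx/variants.vcf --bam fx/reads.sam --ref fx/ref.fa \
    --signal-store fx/signals.tsv --flowcell R9 --protocol amplified \
    --depth 40 --out-dir out
```

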