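# Methods

## Junction-read IRI and DI calling

Every intron of every annotated transcript is a candidate. For one intron
with boundaries `(start, end)` (0-based half-open) we classify each aligned
read once:

* **exon–exon (EE)** — the read has a splice gap equal to `(start, end)`
  exactly. An EE read is the same spliced molecule seen at both
  boundaries, so the single count enters both per-site denominators.
* **exon–intron (EI)** — otherwise, a contiguous aligned block covers a
  boundary with at least `min_overhang` nt on each side (default 6 nt; the
  value suppresses spurious 1-nt overlaps while retaining sensitivity).
  A read spanning the whole intron plus both boundaries increments both
  EI5 and EI3 — it evidences retention at both sites and keeps the two
  per-site ratios independent estimates. A read never counts as both EI
  and EE for the same intron.

Per-site ratios `EI/(EI+EE)` are averaged into the IRI. A site with zero
total junction reads leaves that side undefined; the record is flagged and
excluded from DI calling rather than imputed (the flanking-exon-coverage
requirement makes this rare in practice). Site labels (5'/3') are assigned
from the intron's strand, so unstranded libraries are supported; boundary
matching itself is purely genomic.

Intron coverage is breadth — intronic bases under at least one aligned
block divided by intron length — matching the "region coverage" reading
rather than mean depth.

DI thresholds are strict inequalities: IRI > 0.1, coverage > 0.9 (RNA-seq
preset) or > 0.8 (RIP preset), flanking exon reads > 20 for the
expressed-gene filter. Introns shorter than 150 nt form the "small" class
tracked throughout the outputs.

## Differential retention

Replicates are pooled per condition; each intron is tested with a
two-sided pooled two-proportion z-test on intronic junction reads
`EI5+EI3` versus total `EI5+EI3+2·EE` (both sites combined), with BH
adjustment across the tested set. This is a deliberate, documented
substitute for a per-bin GLM with dispersion estimation: replicate
overdispersion is not modelled, so p-values are anti-conservative when
biological replicates disagree, and adjusted p-values are not numerically
comparable to a dispersion-aware analysis. Under the binomial generative
model the test is exact in distribution, which is what the simulation
suite verifies (type-I control and ≥80% recovery at the stated effect and
depth).

The IRI > 0.1 inclusion floor is applied to the larger of the two
condition IRIs by default (`floor_mode="max"`); requiring both is a flag,
since the source convention is ambiguous. Fold change is pooled-IRI ratio
B/A; a zero baseline with non-zero signal yields +inf and a kept, flagged
record. Row z-scores use the population (n-denominator) standard
deviation; constant rows map to zero and are flagged.

## Long-read classification

Quality/length filters are strict (> 7, > 500 nt). Full length requires
≥1 nt overlap with each annotated UTR (configurable); genes without UTR
annotation are excluded with a reason code. Per-read intron status uses an
exact splice-gap match for "spliced" (a ±3 nt tolerance flag exists
because ONT alignments wobble) and ≥90% intronic coverage by the read's
blocks for "retained"; everything else is ambiguous and excluded from the
denominator. The long-read IRI is therefore a direct per-molecule retained
fraction, not the junction formula — a deliberate interpretation for
full-length data, stated here because aggregate thresholds (IRI > 0.05,
coverage > 0.9) are the only part fixed by convention.

## CLIP metagene

Offsets are transcript-oriented: at the 5'SS, offset 0 is the first
intronic base and negative offsets are exonic; at the 3'SS, offset 0 is
the first downstream-exon base and negative offsets are intronic. The
window is ±100 nt (covers the −40..+30 features of interest). Density at
each offset is the coverage sum across group introns, divided by library
size in millions (RPM) and by the number of introns long enough to
contribute at that offset — the per-offset normalizer removes edge
depletion for short introns/exons. Replicates are merged by summing counts
before normalization. Full read footprints are the default; a
crosslink-site mode (5'-most aligned base) is a flag, since density
conventions differ between iCLIP and eCLIP analyses. Peak ties break
toward the anchor, preferring the negative offset on an exact |offset|
tie.

## Peptide database

The reading frame at the upstream window is derived from annotated CDS
phase: the 60 nt window is trimmed at its 5' end to the next codon
boundary (0–2 nt, recorded as `frame_offset`). When the retained intron is
stop-free, translation continues through downstream exonic CDS until a
stop or transcript end; DIs in UTRs or non-coding genes are skipped with
reason codes rather than six-frame translated. Trypsin cleaves C-terminal
to K/R except before P; fragments with up to two missed cleavages in
[6, 50] residues are emitted by default. FASTA output is byte-stable:
`>gene|intron|source|frame` headers in input order.

## Conservation

Base-level remap fraction is adopted as the "remap ratio" (interval-level
mapping is not distinguished by the inputs we accept); conserved means
ratio strictly > 0.9. The two-proportion z-test uses pooled variance and
no continuity correction by default (so z² equals the 1-df chi-square
exactly); a correction flag exists.

## Synthetic data

The generator emulates the data-generating structure the estimators
assume, with defaults chosen once as realistic desk-scale study
conditions: 4-exon genes with 120 nt UTRs and 260 nt exons, intron lengths
300–800 nt with a 30% small-intron stratum of 60–149 nt, junction depth
200 reads per splice site, 50 nt short reads, long reads at quality 12
with an 80% full-length fraction. Short-read junction evidence draws
EI ~ Binomial(d, θ) per site and a *shared* EE pool ~ Binomial(d, 1−θ),
reflecting that one spliced junction read covers both boundaries; retained
introns get tiling body reads so breadth saturates when θ > 0, giving the
exact limits IRI = 0 at θ = 0 and IRI = 1 at θ = 1. Long reads retain each
intron independently with probability θ; truncated reads lose one
transcript end. CLIP libraries are uniform background plus stacked 1-nt
footprints at configured splice-site offsets. One RNG stream per simulator
stage is spawned from the master seed, so adding a stage never perturbs
earlier ones.

What the generator does **not** emulate — sequencing error, PCR
duplicates, multimapping, expression heterogeneity, overdispersed
replicates, co-transcriptional coverage gradients — bounds what passing
tests show: estimator correctness under the assumed model, not robustness
to real-library artefacts.

## Problem sizes and numerics

The test and acceptance workloads are sized for a single CPU at desk
scale: IRI recovery over 500–1000 introns × 6 retention fractions at depth
200/site; differential analysis over 500 introns × 3 replicates with
20–100 simulation replicates; 10,000 full-length long reads over a
5-intron gene; CLIP libraries of ~30k reads over 10 genes. Threshold
comparisons are strict everywhere a cutoff is stated; p-values below
1e-300 are clamped before log-transforming for reports; BH adjustment
enforces step-up monotonicity and a cap at 1.

## Known limitations

Deletions (CIGAR D) in real alignments are treated like reference gaps
when blocks are re-joined, which is immaterial for the simulated inputs
but could misclassify indel-rich reads near boundaries; multimapper
resolution and duplicate marking are out of scope; the differential test
ignores replicate dispersion as stated above; overlapping genes sharing an
intron are de-duplicated by coordinates, keeping one record per intron.
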