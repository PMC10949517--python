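# Methods

This note documents the models and procedures implemented in
`plasenrich`, the assumptions behind them, and the choices made where
the design was genuinely open.

## Setting

A MinION-style flow cell with 512 channels is split: channels 1–256 run
adaptive sampling (AS) against the known chromosome references of the
barcoded isolates, channels 257–512 sequence normally and serve as the
within-run control. Reads are basecalled and demultiplexed upstream;
the analysis consumes the per-read sequencing-summary table, PAF
mappings of all reads against the pooled chromosome+plasmid references,
and the AS tool's decision log.

## Read-to-replicon assignment

Each read is assigned whole to the sample and replicon class of its
*primary* alignment. The primary alignment is the one with the most
matching bases (PAF column 10); ties go to the higher mapping quality,
then to the lexicographically smallest contig name, then to the smaller
target start. This rule is a package choice — common practice provides
no single convention for secondary/multi-mapping reads — and it is
deliberately deterministic: assignment is invariant under permutation of
the alignment file. Reads without alignments stay `UNMAPPED` and are
excluded from compositions (they have no replicon denominator) but are
counted in the per-run totals. Chimeric reads are not split; a read is
one molecule. Coordinates are 0-based half-open throughout.

Rejected reads keep their (prefix) bases in all yield and composition
statistics: the prefix is present in the basecalled output, and treating
it otherwise would misstate what the sequencer actually delivered.

## Cumulative metrics

All time-resolved statistics are cumulative from the run start. A read
belongs to the snapshot at time *t* iff its start time is ≤ *t*; this
edge rule is monotone and makes every cumulative column non-decreasing.
The default grid is 30-minute bins over 24 h (48 points); any positive
bin that divides the horizon is accepted.

Three enrichment factors compare plasmid output between the halves at
each grid point: by yield (bases), by read count, and by mean
fold-coverage of the plasmid reference. Mean depth is computed as the
sum of primary-alignment reference-span lengths divided by the summed
plasmid reference length of the sample (all plasmid contigs for
multi-plasmid isolates). Spans are taken from PAF target coordinates
without CIGAR refinement; relative to a CIGAR-aware coverage tool this
overcounts deletions inside alignments, identically in numerator and
denominator regions, so the enrichment ratio is insensitive to it.
Compositional enrichment divides the plasmid base fraction of the AS
output by that of the control output.

Any ratio with a zero (or undefined) denominator propagates as an
explicit not-available marker (`nan` in memory, `null` in JSON) instead
of raising, so early, sparsely covered time points never abort a run.
A channel counts as active at *t* if it sequenced at least one molecule
and its last read starts at or after *t*. The capture-time budget is
the plain product `extra_reads x capture_time x speed` — the sequencing
capacity consumed by the additional capture dead times on the AS half
(52.5 Mbp for 250,000 extra reads at 0.5 s and 420 bp/s).

## Analytic enrichment model

Each pore is modelled as a renewal process. A cycle is: capture dead
time `c` (default 0.5 s); a molecule drawn as plasmid with read-level
probability ρ; then either full sequencing (length `L`, time `L/s` at
speed `s` = 420 bp/s) or rejection after decision latency `d` (default
1 s), which emits the `d·s`-base prefix. The read-level fraction ρ is
derived from the base-level abundance `p` by
`ρ = p·L_c / (p·L_c + (1−p)·L_p)`, where `L_p`, `L_c` are the class mean
read lengths. Classification errors enter as a false-rejection
probability for plasmid reads and a false-acceptance probability for
chromosome reads. Expected bases and expected time per cycle give base
production rates per class and half; predicted factors are rate ratios.
The control composition equals `p` by construction, so predicted
compositional enrichment is `composition_AS / p`.

Two accounting conventions exist for rejected prefixes; the
`credit_rejected_prefix` switch covers both, defaulting to crediting
them (they are in the output). Channel idle time beyond the capture
dead time is not modelled. Closed-form consequences, verified in tests:
with perfect classification and `d·s` below the mean read lengths,
`enrichment_composition ≥ enrichment_yield ≥ 1`; compositional
enrichment is strictly decreasing in abundance; and as the
false-rejection rate approaches 1 the model predicts yield depletion
(factor < 1).

## Flow-cell simulator

The simulator is the discrete-event counterpart of the same process and
the package's synthetic-data generator. Per channel it repeats
capture → draw sample (by library share, converted to read-level
weights) → draw class (via ρ) → draw length → sequence or reject, until
the run horizon or the channel's death. Defaults are the standard
operating point: 420 bp/s, 0.5 s capture, constant 1 s decision
latency, 24 h run, 256+256 channels.

Design choices:

- **Read lengths** are lognormal by default (mean 4 kb, sd 3 kb, both
  classes) — the standard heavy-tailed shape of rapid-kit nanopore
  libraries; a gamma family is available. The default sample has a 5%
  plasmid base abundance, a 3 Mb chromosome and an 80 kb plasmid,
  mid-range values for resistant enterobacterial isolates.
- **Decision latency is a distribution, not a constant.** Observed
  rejected-read lengths differ by rejection tool; two lognormal presets
  target mean rejected reads of 520 bp (`minknow`, fast mapper-based
  decisions) and 848 bp (`readbouncer`, slower k-mer classification),
  i.e. latency means of 1.24 s and 2.02 s at 420 bp/s, sd = mean/3.
- **Rejected reads** appear with length `round(d·s)` and duration `d`.
  A read still in the pore at the run end (or at channel death) is
  emitted truncated at the boundary and never flagged rejected — its
  decision had not fired.
- **False rejection** is a per-read Bernoulli with probability
  `shared_region_fraction` — the chance that the prefix falls in a
  chromosome-identical stretch of the plasmid. No sequence content is
  simulated; for forensics, synthetic alignments place those prefixes
  inside the sample's designated shared chromosome locus.
- **Pore death** is exponential per channel (default mean 24 h, so
  roughly 63% of channels die within a day — a plausible figure for the
  pore decline seen on real and especially expired flow cells, chosen
  here as a default rather than calibrated, since no quantitative decay
  rates are established). A multiplicative hazard factor (default 1)
  can accelerate death on the AS half.
- **Determinism**: each channel gets a child of a single seed sequence,
  so runs are bit-reproducible and independent of channel iteration
  order.

A schedule audit verifies conservation per channel: reads are
non-overlapping and total busy time (capture + duration) never exceeds
the run length.

What the simulator does **not** emulate: basecalling/demultiplexing
errors, barcode misassignment, actual sequences (no FASTQ), signal-level
behaviour, pore blocking dynamics, or library depletion over the run.
Passing tests therefore show that the analysis code is correct under the
stated stochastic model, not that real flow cells obey that model; in
particular, real runs show lower yield enrichment than the idealised
model predicts, because pore loss and pore quality, not cycle
accounting, dominate late-run behaviour.

## Model–simulator cross-validation

Because the closed form and the simulator formalise the same process,
their statistics must agree up to Monte-Carlo error. The comparison
(`plasenrich.compare`) simulates the flow cell implied by a parameter
set with pore death off (32+32 channels, run length auto-sized to
~120,000 reads), groups channels into 16 batches, and computes per-batch
AS composition, compositional enrichment and yield enrichment; batch
means and standard errors give z-scores against the prediction. The
test suite requires every statistic within 3 SE across 20 random
parameter draws (abundance 2–30%, lengths 2–8 kb, latency 0.5–2 s,
error rates up to 20%/10%). Note the worst-of-60 z-score is a max
statistic: values approaching 3 occur as ordinary fluctuation even
under exact agreement, which is why the acceptance report also carries
the mean |z| (≈0.8–1.0 when unbiased).

## False-rejection forensics

Falsely rejected plasmid reads (assigned `PLASMID`, flagged rejected)
are re-mapped to the chromosome; a difference-array prefix sum gives the
per-base depth vector, and maximal runs of depth ≥ 10 (inclusive, after
optional gap merging, off by default) are reported as BED intervals with
mean/max depth. The threshold is inclusive and there is no default
length filter — reported interval lengths are outcomes, not filters.
On synthetic runs with a planted shared locus the detected interval
recovers the locus essentially exactly (overlap ≈ 1).

## Problem sizes and numerics

Test and acceptance runs use scaled-down flow cells (8–32 channels per
half, 1–24 h horizons), which the package treats as its standard
experimental sizes; per-channel statistics are unaffected by channel
count, and ~1e5–5e5 reads give sub-percent standard errors on the
compared statistics. Brute-force oracles (naive recounting, per-base
depth counters, linear interval scans) back the vectorised
implementations on ≥100 random small fixtures. Floating-point
comparisons in ratio metrics are exact where the arithmetic is exact
(integer sums); statistical comparisons use 3-SE bands as above.

## Known limitations

- PAF only (no BAM) and no CIGAR-level depth refinement.
- The analytic model reduces read-length distributions to their means;
  this is exact for the statistics compared (all linear in length per
  class) but would not be for, e.g., N50-style summaries.
- The renewal model's relation to other published enrichment models is
  structural, not verified formula-by-formula; the
  `credit_rejected_prefix` and idle-time questions are left as explicit
  switches and assumptions.
- Pore-death defaults are plausible placeholders; users with real runs
  should calibrate `ChannelLifetime` against their active-channel
  curves.
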