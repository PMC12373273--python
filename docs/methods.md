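# Methods

## Scoring model

The per-base score encodes guanine clustering, the dominant sequence
determinant of G-quadruplex formation. Every base in a maximal run of
*k* consecutive Gs scores min(*k*, 4); runs longer than four score 4 at
every position (additional stacking beyond a four-quartet core adds
little propensity, and the cap keeps the score bounded). Cytosine runs
score symmetrically negative, so the sign of a window mean says which
strand is G-rich: a negative score is a G4 on the complementary strand,
and all magnitude-based decisions (detection, filtering) use |score|.
A and T are neutral. Ambiguity codes (N, R, Y, …) score 0 **and break
runs** — treating an unknown base as a possible G would require an
ambiguity-weighted scheme the model does not define. U is accepted and
treated as T. Soft-masked (lowercase) bases are scored normally, since
repeat masking is a property of annotation pipelines, not of the
physical sequence.

The window score is the arithmetic mean over `window_size` consecutive
bases, stride 1. `window_size` defaults to 25 nt, matching the typical
25–30 nt span of genomic G4s; it is the single most influential
parameter, since shorter windows raise resolution but inflate scores of
isolated G-tracts. Window sums are integers, so the means (computed by
cumulative-sum differences in float64) are exact integer-over-window
ratios and reproducible bit for bit; the optimized path is verified
against naive per-window re-summation in the tests.

## Region calling

Windows with |mean| ≥ `threshold` (inclusive) are positive windows.
Overlapping positive windows (shared ≥ 1 bp; book-ended windows do not
merge) of the same sign merge into one region; opposite signs never
merge even when overlapping, because they imply G4s on opposite
strands. The region score is the most extreme window mean among the
merged windows, sign preserved. The default threshold is 1.5, above
which nearly all tested sequences form stable G4s in vitro; 1.2 is the
permissive floor for DNA (documented, not default). Region boundaries
are the union of the merged windows; no trimming of boundaries to
G-runs is applied. Regions are identified as `seqname:start-end:strand`
with 0-based half-open coordinates.

Alternating (CG)ₙ / (CCGG)ₙ repeats score exactly 0 over any window
spanning whole repeat units (equal G and C counts); a window cut
mid-unit retains a parity residue bounded by ±(unit imbalance)/window,
e.g. ±0.04 for a 25-nt window over (CG)ₙ. Tests and the acceptance
script therefore state the exact-zero property on full-period windows.

## Variants

VCF (via cyvcf2) and MAF (TSV) are both accepted. Records are
normalized to one canonical allele form so the two encodings of the
same mutation compare equal: shared trailing, then leading bases are
trimmed, never letting the reference allele become empty. SNVs pass
through; deletions become anchorless (ref = deleted bases, alt = "");
insertions keep one anchoring reference base. No left-alignment across
repeats is attempted — homopolymer placement is taken as given, since
re-alignment would change region overlap and belongs upstream of this
tool. MAF insertions need the anchor base from the reference, so
loading a MAF containing insertions requires the sequence store.
Positions stay 1-based until interval arithmetic. Multi-allelic VCF
sites split per ALT; when genotype columns are present, each sample
carrying the ALT yields its own record (a site nobody carries yields
one sample-less record); symbolic/structural ALTs are skipped with a
logged count.

## Impact assessment

A variant is assigned to every region whose span its ref allele's
1-based inclusive interval intersects. Edits are applied to the region
sequence in descending position order (so indels do not shift pending
coordinates); a ref-allele mismatch or two intersecting ref spans in
one application are errors — skipped with a logged count at the batch
level. Variants straddling a region edge are clipped to their in-region
portion (positionally for length-preserving changes; by matching
prefix/suffix for indels), keeping wild-type scores untouched.

Re-scoring scans **only the mutated region sequence**, without flanking
genomic context. Consequence: a variant cannot reveal a new G4 outside
wild-type regions; gain-of-G4 discovery is out of scope. When a
deletion shortens a region below the window, the mutant score falls
back to the mean over the whole remaining sequence (a single truncated
window), so every mutant remains scoreable.

Single (variant-centric) mode evaluates each variant independently and
ignores sample identity (a variant shared by several samples is scored
once per region). Multi (sample-centric) mode groups variants by
(region, sample) and applies each group jointly; every variant must
carry a sample identifier. When no sample holds two variants in one
region the two modes coincide exactly. Output ordering is fully
deterministic: regions by (sequence, start, strand), then sample, then
first variant position, ties by variant id. There is no randomness
anywhere in the pipeline.

## Filtering and reporting

The disruption filter keeps records with |wild-type max| ≥ 1.5 and
|mutant max| ≤ 1.2 (inclusive comparisons on absolute values, so
minus-strand G4s are symmetric), optionally requiring a minimum
|delta| (default 0, disabled). TSV scores are printed at two decimals
with round-half-even; filtering itself compares unrounded values.
Plots show wild-type and mutant window-score profiles with variant
positions marked; they are a convenience, and tests assert the numbers
annotated on them, not pixels.

## Synthetic data

The fixture generator emulates the minimal structure needed to
exercise the pipeline: i.i.d. background sequence with configurable GC
content (default 0.5, i.e. uniform ACGT — background window scores then
concentrate near 0 with occasional regions at stringent thresholds),
and planted 25-nt four-tract motifs — four runs of 3–4 G (or C), at
least one run of four, separated by 1–7 A/T loop bases. By construction
a full motif window sums to ≥ 43, so |score| ≥ 1.72 > 1.5 regardless of
flanks, guaranteeing 100 % detection recall on plants. Plants are
spaced at least two window widths apart so each maps to its own region.
Variants are placed preferentially on run bases inside plants (ref base
mutated away, the strongest destabilization), with configurable indel
fraction (1–3 nt deletions and insertions, half each) and round-robin
sample assignment; matching VCF and MAF files encode the identical set.

Expected wild-type/mutant scores in the emitted truth table come from a
naive oracle (per-base run scan, per-window re-summation, exhaustive
window-union detection, direct string surgery) that shares no code with
the optimized implementation. What the generator does **not** emulate:
realistic variant spectra, linkage, chromatin context, or non-canonical
G4 motifs (long loops, bulges) — so passing tests demonstrate
correctness of the scoring/claiming machinery, not biological recall on
real genomes.

Default test problem sizes — two 5 kb sequences, 6–10 planted motifs,
40–200 variants, brute-force cross-checks on 1000 random sequences —
were chosen so the full suite exercises every code path, including both
strands and indel edge cases, while staying small enough to iterate on
comfortably.

## Known limitations

- The score is sequence propensity only: no thermodynamics, no
  duplex-opening penalty, no loop-length modelling.
- RNA support is limited to accepting U as T-neutral input; RNA-specific
  thresholds (≈ 1.0) are the caller's choice.
- Gain-of-G4 events outside wild-type regions are invisible by design.
- Sequences are held in memory; genomes far beyond the hundreds of
  megabases would need an indexed backend.
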