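# Methods

## Simulation model

Simulation is a two-stage process: a *model* (the configured distributions)
and a *generation* pass that draws symbols from it. `fqsim` treats a FASTQ
file as three independent information sources — headers, DNA bases, quality
scores — and simulates each with its own model, honouring only the
cross-channel constraints a valid file requires: lines 2 and 4 of a record
are equal in length, the optional `length=` header appendix equals the actual
line-2 length, and an N base always carries the lowest quality score.

All stochastic header fields use uniform distributions over their domains.
Uniform draws are the cheapest choice and minimise field collisions between
reads; nothing downstream of a header depends on its field values, so a
richer model would add cost without adding structure.

### Headers

* **Roche-454**: 14-character accessions, `<timestamp:6><hash:1><region:2><well:5>`.
  The timestamp is a uniformly drawn 6-char base-36 string held constant
  within a run (a real timestamp would break seed reproducibility); the hash
  character is uniform over `0-9A-Z` per read; the region is uniform on
  [1, 16]; the well code is the base-36 rendering of `x·4096 + y` with
  y uniform on [0, 4096) and x uniform on [0, 36^5/4096), the largest range
  for which every total fits in five digits. y < 4096 is enforced as a
  precondition — it is what makes the encoding invertible.
* **Ion Torrent**: `@<run id>:<x:05d>:<y:05d>`. Only the P1 chip's bounds
  (15456 × 10656) are fixed; the 314/316/318 entries in `CHIP_SPECS` are
  documented configurable defaults, not platform constants. No cap is placed
  on read length in any mode — Ion Torrent reads can be very long.
* **Illumina / ABI-SOLiD**: one architecture per platform matching the
  classic colon-separated (Illumina) and underscore-joined (SOLiD) shapes,
  with two selectable suffixes: a `length=NN` appendix or alternating
  `/1` `/2` mate suffixes. The two are mutually exclusive per record. Mate
  parity is derived from the read index, so paired streams are stateless
  and reproducible. Read indices count from 1.

Faithful emulation of any specific instrument-software header grammar
(e.g. CASAVA ≥ 1.8) is a non-goal; dialects vary too much for that to be
stable, and consumers of simulated data key on structure, not vendor
strings.

### DNA bases

Composition-only mode draws i.i.d. symbols over {A, C, G, T, N}. Repeat mode
generates one global stream left-to-right: `n_repeats` trigger points are
drawn uniformly over the stream interior; at each, a window of the
already-generated prefix (start uniform, size uniform in
`[min_size, max_size]`) is appended to the stream, reverse-complemented with
probability `p_reverse_complement`, then passed through per-base
substitution at `mutation_rate`. Design points that were genuinely open:

* **Placement** — copy events extend the *end* of the stream from a window
  of the past, LZ-style; novel i.i.d. segments between triggers spread the
  events uniformly. Sources may themselves lie inside earlier repeats
  (copy-of-copy is allowed: any already-generated position is a legal
  source).
* **Truncation, never discard** — a sampled size exceeding the remaining
  space or the available prefix is clipped, and the generator reserves one
  symbol of space per outstanding event, so exactly `n_repeats` events occur
  with length ≥ 1.
* **Substitution model** — a mutated position receives a uniformly chosen
  *different* base from {A, C, G, T}. This makes the expected mismatch
  fraction between a copy and its (possibly reverse-complemented) source
  exactly the configured rate, so the rate is recoverable from the stream
  and testable against a binomial interval with no resampling correction.
* **Annotations** — every event records (source start, dest start, length,
  RC flag), giving tests and downstream analyses ground truth.
* The global stream is partitioned into reads afterwards, so repeats span
  read boundaries — matching the long-range structure of real libraries.
  This is the `repeat_buffered` run mode (the stream is held in memory);
  `low_memory` streams i.i.d. reads at constant memory but cannot plant
  repeats. These are the two concrete points offered on the time/memory
  trade-off.

**Colour space.** The di-base call is the XOR of the 2-bit base codes
(A=0, C=1, G=2, T=3), which reproduces the standard SOLiD equivalence
matrix. By default the read's own first base serves as the anchor, giving
`len−1` digits: this keeps the colour-space line exactly the length of the
base read, so the quality string needs no adjustment. An explicit anchor
(conventionally `T`, the primer terminus) can be passed to prepend it and
emit all `len` transitions. Transitions involving N emit `.`, the SOLiD
missing-call convention.

### Quality scores

The alphabet is any sorted subset of ASCII 33..126, parsed from sparse range
specs (`33,34,40-45,…`; en-dashes are normalized). Two distributions:

* **uniform** — i.i.d. over the codes;
* **gaussian** — one normal draw per position, in *raw ASCII-code units*
  (not Phred units after offset subtraction — stated prominently in the CLI
  help), rounded to the nearest integer and mapped to the nearest allowed
  code. Ties break toward the lower code — arbitrary, but fixed, so streams
  are reproducible. Out-of-range draws clamp to the nearest code rather than
  being rejected and resampled: termination is guaranteed and the output
  length is exact; the cost is a small probability spike on the boundary
  codes when the mean sits far outside the alphabet.

Quantization selects `n_levels` codes evenly spaced *by rank* from the
configured alphabet (rank-even, not value-even, so it composes with sparse
alphabets); endpoints are always retained for `n_levels ≥ 2`, and one level
degenerates to a constant stream. Fewer levels mean lower symbol entropy
and a monotonically smaller deflate size of the quality channel.
Position-dependent quality decay along the read is deliberately out of
scope: draws are position-independent.

### Assembly

Records are emitted as LF-terminated lines with no trailing blank line —
bit-exact output is what makes the seed-reproducibility contract meaningful.
Any of lines 1, 3, 4 can be excluded (line 2 never: a record must have
bases); excluding 1, 3 and 4 yields a plain DNA sequence stream. Line 3 may
optionally repeat the header, but not when line 1 is excluded — there is
then no header to repeat. A validator checks the four-line rules, the
printable-window closure of qualities, and `length=` consistency, reporting
violations rather than raising.

## The information profiler

The profiler assigns each symbol the code length
`−log2 P(s_i | s_{i−k}..s_{i−1})` under a *single* adaptive order-k model
with additive-α smoothing over the 4-symbol alphabet (counts updated after
each symbol; defaults k=8, α=1/16). A mixture of models of multiple orders —
as full-strength DNA compressors use — is intentionally not reproduced: one
high-order model suffices to make planted repeats visible as low-information
zones, which is all this module is for. The sum of the profile equals the
bit cost an adaptive arithmetic coder driven by the same model would spend,
a property the tests verify against an independent dict-based
re-implementation.

Numerical details: the rolling context is initialised to zero (the all-A
context) — immaterial in practice because unseen contexts cost exactly
2 bits under the uniform prior regardless of their identity; N symbols are
assigned a flat 2 bits and skipped in context/count updates; smoothing is a
centred moving average with an odd window (default 5), truncated at the
boundaries so length is preserved.

With α = 1/16, sparse high-order contexts make the adaptive cost of pure
i.i.d. sequence sit noticeably *above* the 2-bit source entropy (≈ 2.6
bits/symbol at k=8 over 10^6 symbols) — the small-α model is sharp for
repeat detection but pays heavily on first mismatches. With Laplace
smoothing (α=1) the mean stays within 0.1 of 2 bits at the same order. Tests
that assert entropy recovery therefore use α=1; tests that assert repeat
contrast use the default.

## Synthetic-data conditions and what the tests show

The generator's defaults are the reference conditions used throughout the
tests: uniform base composition, repeat parameters (min 1, max 3000,
mutation rate 0.1, 350 events per 10^6 symbols) for the complexity
comparisons, deflate (zlib level 6) as the generic compressor, and 5 seeds
for trend checks. Streams of 10^6 symbols are used for the statistical
comparisons and 10^5 for the fidelity oracles — large enough for the
binomial/CLT intervals asserted, small enough to keep the whole suite fast.

Deflate's 32 KiB match window sees only the minority of copy events whose
source happens to lie nearby, and cannot match reverse-complement copies at
all, so the measured size reductions are a few per mille — directionally
consistent (non-increasing in repeat count in ≥ 4 of 5 seeds) but far
smaller than what a long-range context-model compressor achieves on the
same streams; the information profiler, whose order-8 model has no window
limit, shows the same comparison at ~4% of mean bits. This is a property of
the compressor, not of the planted structure.

What passing tests do *not* show: that simulated reads reproduce the error
models, positional quality decay, GC biases or header dialect details of any
real instrument. The simulator is a complexity-controlled source for
infrastructure and compressor testing, not an error-model emulator —
reference-guided sampling and SNP/indel diploid simulation are explicitly
out of scope.

## Known limitations

* Repeat sources are uniform over the whole prefix; real genomes cluster
  repeats (tandem arrays, transposon bursts), which the model does not
  attempt.
* Paired reads share one output stream with `/1` `/2` suffixes; splitting
  into `_1`/`_2` files is left to external tools, as is gzip output.
* The Gaussian quality model is stationary along the read.
* Colour-space reads use a single anchor convention per run; double-encoded
  (CSFASTA-style) output is not produced.
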