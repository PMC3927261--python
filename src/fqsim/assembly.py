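"""Assembly of the three channels into FASTQ records, and output validation.

A FASTQ record is four lines: ``@header``, bases, ``+`` (optionally repeating
the header), and quality scores, with lines 2 and 4 equal in length.  The
simulator draws each read's length once, generates the three channels
independently, and assembles them under the four-line rules.  Any of lines
1, 3 and 4 can be excluded — dropping all three turns the tool into a plain
DNA sequence simulator.

Two run modes trade memory for structure:

* ``low_memory`` — every read is sampled i.i.d. from the base composition;
  memory is constant in the number of reads, but no repeats are possible.
* ``repeat_buffered`` — one global DNA stream (held in memory) is generated
  with the repeat model and then partitioned into reads, so repeats can span
  read boundaries, reproducing the long-range structure seen in real data.

Output is deterministic: a seed plus a configuration fixes the file
byte-for-byte (LF newlines, no trailing blank line).
"""

from __future__ import annotations

import io
import time
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, TextIO, Union

import numpy as np

from . import dna, quality
from .errors import ConfigError, ContractError
from .headers import HeaderConfig, HeaderGenerator

__all__ = [
    "RunMode",
    "ReadRecord",
    "SimulationConfig",
    "SimulationSummary",
    "build_record",
    "simulate",
    "simulate_to_string",
    "ValidationIssue",
    "ValidationReport",
    "validate_fastq",
]


class RunMode(str, Enum):
    LOW_MEMORY = "low_memory"
    REPEAT_BUFFERED = "repeat_buffered"


@dataclass(frozen=True)
class ReadRecord:
    """One read: header (without '@'), bases, qualities."""

    header: str
    bases: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ContractError(
                f"lines 2 and 4 must be equal in size: "
                f"{len(self.bases)} bases vs {len(self.qualities)} quality scores"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameter set for one simulation run; the seed fixes the output."""

    n_reads: int = 100
    read_length_min: int = 100
    read_length_max: int = 100
    header: HeaderConfig = field(default_factory=HeaderConfig)
    composition: dna.CompositionProfile = field(default_factory=dna.CompositionProfile)
    repeats: dna.RepeatModel = field(default_factory=dna.RepeatModel)
    quality_alphabet: quality.QualityAlphabet = field(default_factory=quality.QualityAlphabet)
    plus3_repeats_header: bool = False
    lines_excluded: frozenset[int] = frozenset()
    color_space: bool = False
    seed: int = 0
    run_mode: RunMode = RunMode.REPEAT_BUFFERED

    def __post_init__(self) -> None:
        object.__setattr__(self, "run_mode", RunMode(self.run_mode))
        object.__setattr__(self, "lines_excluded", frozenset(self.lines_excluded))
        if self.n_reads < 1:
            raise ConfigError("n_reads must be >= 1")
        if not 1 <= self.read_length_min <= self.read_length_max:
            raise ConfigError(
                f"need 1 <= read_length_min <= read_length_max, got "
                f"[{self.read_length_min}, {self.read_length_max}]"
            )
        bad = self.lines_excluded - {1, 3, 4}
        if bad:
            raise ConfigError(
                f"only lines 1, 3 and 4 can be excluded (a record must have "
                f"bases); got {sorted(bad)}"
            )
        if self.plus3_repeats_header and 1 in self.lines_excluded:
            raise ConfigError(
                "line 3 cannot repeat the header when line 1 is excluded"
            )
        if self.run_mode is RunMode.LOW_MEMORY and self.repeats.n_repeats > 0:
            raise ConfigError(
                "repeats need the repeat_buffered run mode (the low_memory "
                "mode samples each read independently)"
            )


def build_record(rec: ReadRecord, cfg: SimulationConfig) -> str:
    """Render one record as up to four LF-terminated lines."""
    excl = cfg.lines_excluded
    lines = []
    if 1 not in excl:
        lines.append("@" + rec.header)
    lines.append(rec.bases)
    if 3 not in excl:
        lines.append("+" + (rec.header if cfg.plus3_repeats_header else ""))
    if 4 not in excl:
        lines.append(rec.qualities)
    return "\n".join(lines) + "\n"


@dataclass
class SimulationSummary:
    n_reads: int
    n_bases: int
    elapsed_s: float


def _iter_records(cfg: SimulationConfig, rng: np.random.Generator) -> Iterator[ReadRecord]:
    lengths = rng.integers(
        cfg.read_length_min, cfg.read_length_max + 1, size=cfg.n_reads
    )
    headers = HeaderGenerator(cfg.header, rng)
    alphabet = cfg.quality_alphabet

    if cfg.run_mode is RunMode.REPEAT_BUFFERED:
        total = int(lengths.sum())
        stream = dna.plant_repeats(total, cfg.composition, cfg.repeats, rng)
        offsets = np.concatenate(([0], np.cumsum(lengths)))
        base_source = lambda i: stream.symbols[offsets[i] : offsets[i + 1]]
    else:
        base_source = lambda i: dna.sample_sequence(
            int(lengths[i]), cfg.composition, rng
        ).symbols

    for i in range(cfg.n_reads):
        bases = base_source(i)
        if cfg.color_space:
            line2 = dna.to_color_space(bases)
        else:
            line2 = bases
        quals = quality.sample_qualities(len(line2), alphabet, rng)
        # N bases get the lowest score; in colour space the missing-call
        # positions ('.') are masked instead.
        mask_against = bases if not cfg.color_space else line2.replace(".", "N")
        quals = quality.mask_n_positions(quals, mask_against, alphabet)
        header = headers.make(i + 1, len(line2))
        # make_*_header renders the full line 1 including '@'; the record
        # stores the header text proper.
        yield ReadRecord(header=header.removeprefix("@"), bases=line2, qualities=quals)


def simulate(cfg: SimulationConfig, out: TextIO) -> SimulationSummary:
    """Run one simulation, streaming FASTQ text to ``out``.

    The same config and seed always produce byte-identical output.
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    n_bases = 0
    try:
        for rec in _iter_records(cfg, rng):
            out.write(build_record(rec, cfg))
            n_bases += len(rec.bases)
    except OSError as exc:
        raise OSError(f"failed writing FASTQ output: {exc}") from exc
    return SimulationSummary(
        n_reads=cfg.n_reads, n_bases=n_bases, elapsed_s=time.perf_counter() - t0
    )


def simulate_to_string(cfg: SimulationConfig) -> str:
    """Convenience wrapper returning the FASTQ text as one string."""
    buf = io.StringIO()
    simulate(cfg, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationIssue:
    record_index: int
    message: str


@dataclass
class ValidationReport:
    n_records: int = 0
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, idx: int, message: str) -> None:
        self.issues.append(ValidationIssue(idx, message))


def validate_fastq(stream: Union[str, TextIO]) -> ValidationReport:
    """Check four-line FASTQ text against the record rules.

    Per record: line 1 starts with '@', line 3 starts with '+', lines 2 and 4
    are equal in length, quality codes lie in the printable window [33, 126],
    and a ``length=NN`` appendix in the header (if present) matches the actual
    line-2 length.  Malformed records are reported, not raised.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    report = ValidationReport()
    while True:
        block = [stream.readline() for _ in range(4)]
        if not block[0]:
            break
        idx = report.n_records
        report.n_records += 1
        if any(not line for line in block[1:]):
            report.add(idx, "truncated record (fewer than 4 lines)")
            break
        head, bases, plus, quals = (line.rstrip("\n") for line in block)
        if not head.startswith("@"):
            report.add(idx, f"line 1 does not begin with '@': {head[:30]!r}")
        if not plus.startswith("+"):
            report.add(idx, f"line 3 does not begin with '+': {plus[:30]!r}")
        elif len(plus) > 1 and plus[1:] != head[1:]:
            report.add(idx, "line 3 text differs from the line-1 header")
        if len(bases) != len(quals):
            report.add(
                idx,
                f"lines 2 and 4 differ in size: {len(bases)} vs {len(quals)}",
            )
        bad = [q for q in quals if not 33 <= ord(q) <= 126]
        if bad:
            report.add(idx, f"quality code outside [33, 126]: {ord(bad[0])}")
        if " length=" in head:
            declared = head.rsplit(" length=", 1)[1]
            if not declared.isdigit() or int(declared) != len(bases):
                report.add(
                    idx,
                    f"declared length={declared} but line 2 has {len(bases)} symbols",
                )
    return report
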