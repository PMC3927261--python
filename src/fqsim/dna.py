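"""DNA base stream simulation with tunable repeat structure.

The base channel is generated over the 5-symbol alphabet {A, C, G, T, N} in
one of two modes:

* **composition-only** — i.i.d. symbols with configurable per-base
  probabilities (fast, constant memory);
* **composition + repeats** — the stream is extended left-to-right and, at
  points spread uniformly across it, a window of the already-generated prefix
  is copied to the current end.  Copies may be reverse-complemented (with a
  configurable probability) and are then passed through a per-base
  substitution process (the mutation rate), giving exact, approximate and
  reverse-complement repeats.  Each copy event is annotated so tests can
  verify it against its source.

Repeats raise the stream's self-similarity and therefore lower both its
compressed size under a generic compressor and its per-symbol information
under a high-order context model — the two properties the repeat machinery
exists to control.

SOLiD colour-space conversion is also provided: base transitions are encoded
as digits 0-3 via the standard di-base equivalence matrix (identical pair → 0;
A<->C / G<->T → 1; A<->G / C<->T → 2; A<->T / C<->G → 3), anchored by a known
leading base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .errors import ConfigError

__all__ = [
    "DNA_ALPHABET",
    "CompositionProfile",
    "RepeatModel",
    "RepeatAnnotation",
    "DnaStream",
    "sample_sequence",
    "reverse_complement",
    "mutate",
    "plant_repeats",
    "to_color_space",
]

DNA_ALPHABET = "ACGTN"
_SYM = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> 2-bit code; the colour call for a di-base pair is the XOR of the two
# codes, which reproduces the standard SOLiD equivalence matrix.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class CompositionProfile:
    """Per-symbol probabilities for {A, C, G, T, N}; must sum to 1."""

    p_A: float = 0.25
    p_C: float = 0.25
    p_G: float = 0.25
    p_T: float = 0.25
    p_N: float = 0.0

    def __post_init__(self) -> None:
        probs = self.as_array()
        if np.any(probs < 0) or np.any(probs > 1):
            raise ConfigError(f"composition probabilities must be in [0,1]: {probs}")
        if abs(float(probs.sum()) - 1.0) > 1e-9:
            raise ConfigError(f"composition must sum to 1, got {float(probs.sum())!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_A, self.p_C, self.p_G, self.p_T, self.p_N], dtype=float)

    @classmethod
    def uniform(cls) -> "CompositionProfile":
        return cls()

    @classmethod
    def from_list(cls, freqs) -> "CompositionProfile":
        freqs = list(freqs)
        if len(freqs) == 4:
            freqs.append(0.0)
        if len(freqs) != 5:
            raise ConfigError("composition needs 4 or 5 frequencies (A,C,G,T[,N])")
        return cls(*map(float, freqs))


@dataclass(frozen=True)
class RepeatModel:
    """Parameters of the copy-event process.

    ``n_repeats = 0`` recovers the composition-only mode exactly.
    """

    n_repeats: int = 0
    min_size: int = 1
    max_size: int = 3000
    mutation_rate: float = 0.0
    p_reverse_complement: float = 0.0

    def __post_init__(self) -> None:
        if self.n_repeats < 0:
            raise ConfigError("n_repeats must be non-negative")
        if self.min_size < 1:
            raise ConfigError("min_size must be positive")
        if self.min_size > self.max_size:
            raise ConfigError(
                f"min_size {self.min_size} exceeds max_size {self.max_size}"
            )
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.p_reverse_complement <= 1.0:
            raise ConfigError("p_reverse_complement must be in [0, 1]")


class RepeatAnnotation(NamedTuple):
    """One copy event: dest window copied from source window (possibly RC'd)."""

    source_start: int
    dest_start: int
    length: int
    is_reverse_complement: bool


@dataclass
class DnaStream:
    """A simulated base stream plus the copy events that produced it."""

    symbols: str
    repeat_annotations: list[RepeatAnnotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.symbols)


def _sample_symbols(length: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(5, size=length, p=probs)
    return _SYM[idx].tobytes().decode("ascii")


def sample_sequence(
    length: int, comp: CompositionProfile, rng: np.random.Generator
) -> DnaStream:
    """Draw an i.i.d. base stream of the given length (no repeats)."""
    if length < 1:
        raise ConfigError("length must be >= 1")
    return DnaStream(symbols=_sample_symbols(length, comp.as_array(), rng))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N.  An involution."""
    for ch in set(seq) - set(DNA_ALPHABET):
        raise ConfigError(f"invalid DNA symbol {ch!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``.

    A substituted position receives a uniformly chosen base from {A,C,G,T}
    *different* from the original, so the expected mismatch fraction equals
    ``rate`` exactly.  A substituted N receives a uniform base (never N).
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError("mutation rate must be in [0, 1]")
    if not seq or rate == 0.0:
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(codes)) < rate
    n_hit = int(hit.sum())
    if n_hit == 0:
        return seq
    acgt = _SYM[:4]
    old = codes[hit]
    # index of the original base in ACGT; 4 marks N
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(acgt):
        lut[b] = i
    old_idx = lut[old]
    offset = rng.integers(1, 4, size=n_hit)
    new_idx = (old_idx + offset) % 4
    is_n = old_idx == 4
    if is_n.any():
        new_idx[is_n] = rng.integers(0, 4, size=int(is_n.sum()))
    codes[hit] = acgt[new_idx]
    return codes.tobytes().decode("ascii")


def plant_repeats(
    length: int,
    comp: CompositionProfile,
    model: RepeatModel,
    rng: np.random.Generator,
) -> DnaStream:
    """Generate a base stream of exactly ``length`` symbols with copy events.

    Generation is left-to-right.  ``n_repeats`` copy events extend the stream
    from a uniformly chosen window of the already-generated prefix; novel
    i.i.d. segments between events spread the events uniformly across the
    stream.  Each event's size is uniform in [min_size, max_size], truncated
    (never discarded) to the space remaining and to the prefix available.
    """
    if length < 1:
        raise ConfigError("length must be >= 1")
    n = model.n_repeats
    if n == 0:
        return sample_sequence(length, comp, rng)
    if length < model.min_size + 1:
        raise ConfigError(
            f"length {length} too small to host a repeat of min_size "
            f"{model.min_size} after a novel prefix"
        )
    probs = comp.as_array()
    # Intended event positions, spread uniformly over the stream interior.
    triggers = np.sort(rng.integers(1, length, size=n))
    parts: list[str] = []
    annotations: list[RepeatAnnotation] = []
    pos = 0
    prefix = ""  # concatenation of parts so far, maintained incrementally
    for i, t in enumerate(triggers):
        events_left = n - i
        # Novel segment up to the trigger, capped so every remaining event can
        # still place at least one symbol.
        novel_len = min(max(int(t) - pos, 0), length - pos - events_left)
        if pos == 0 and novel_len == 0:
            novel_len = 1  # a copy needs a non-empty prefix to copy from
        if novel_len > 0:
            seg = _sample_symbols(novel_len, probs, rng)
            parts.append(seg)
            prefix += seg
            pos += novel_len
        size = int(rng.integers(model.min_size, model.max_size + 1))
        size = min(size, length - pos - (events_left - 1), pos)
        src = int(rng.integers(0, pos - size + 1))
        window = prefix[src : src + size]
        is_rc = bool(rng.random() < model.p_reverse_complement)
        if is_rc:
            window = reverse_complement(window)
        window = mutate(window, model.mutation_rate, rng)
        annotations.append(RepeatAnnotation(src, pos, size, is_rc))
        parts.append(window)
        prefix += window
        pos += size
    if pos < length:
        parts.append(_sample_symbols(length - pos, probs, rng))
    return DnaStream(symbols="".join(parts), repeat_annotations=annotations)


def to_color_space(seq: str, anchor: Optional[str] = None) -> str:
    """Encode a base string in SOLiD colour space.

    Each di-base transition becomes a digit 0-3 via the equivalence matrix
    (implemented as XOR of the 2-bit base codes).  With ``anchor=None`` the
    read's own first base is the anchor, yielding ``len(seq) - 1`` digits, so
    the encoded read keeps the length of the base read.  Passing an explicit
    anchor base (e.g. ``"T"``, the usual sequencing primer terminus) prepends
    it and yields ``len(seq)`` digits.  Transitions involving N emit ``"."``,
    the missing-call convention.
    """
    if not seq:
        return ""
    if anchor is not None:
        if anchor not in _BASE_CODE:
            raise ConfigError(f"anchor must be one of A,C,G,T, got {anchor!r}")
        seq = anchor + seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c
    lut[ord("N")] = 4
    idx = lut[codes]
    if (idx == 255).any():
        bad = chr(int(codes[idx == 255][0]))
        raise ConfigError(f"invalid DNA symbol {bad!r}")
    if len(seq) == 1:
        return seq
    a, b = idx[:-1], idx[1:]
    digits = ((a ^ b) & 3) + ord("0")
    digits = np.where((a == 4) | (b == 4), ord("."), digits).astype(np.uint8)
    return seq[0] + digits.tobytes().decode("ascii")
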