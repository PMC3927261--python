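"""Quality-score channel: sampling over sparse ASCII alphabets.

Quality scores are stored as printable ASCII characters (codes 33..126, a
simple offset mapping of the numeric score).  Real files use many different
sub-ranges of that window, so the alphabet here is an arbitrary, possibly
sparse, ordered set of codes — e.g. ``33,34,35,40-45,100,102,110-120`` — and
two sampling distributions are offered:

* **uniform** — every code equiprobable (fastest);
* **Gaussian** — a normal variate per position (mean and standard deviation
  given in raw ASCII-code units), rounded and mapped to the nearest allowed
  code, ties toward the lower code.  Out-of-range draws clamp to the nearest
  code rather than being resampled, so output length is always exact.

Two transformations complete the channel: positions whose base is N are
forced to the alphabet's lowest score, and the alphabet can be *quantized* to
fewer levels (rank-even subsetting), which lowers the symbol entropy and thus
the post-compression size of the quality stream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .errors import ConfigError, ContractError

__all__ = [
    "ASCII_MIN",
    "ASCII_MAX",
    "QualityDistribution",
    "QualityAlphabet",
    "parse_ascii_ranges",
    "sample_qualities_uniform",
    "sample_qualities_gaussian",
    "sample_qualities",
    "mask_n_positions",
    "quantize_alphabet",
]

ASCII_MIN = 33
ASCII_MAX = 126

_RANGE_TOKEN = re.compile(r"^(\d+)(?:-(\d+))?$")


class QualityDistribution(str, Enum):
    UNIFORM = "uniform"
    GAUSSIAN = "gaussian"


@dataclass(frozen=True)
class QualityAlphabet:
    """An ordered set of allowed ASCII codes plus its sampling distribution."""

    codes: tuple[int, ...] = tuple(range(ASCII_MIN, ASCII_MAX + 1))
    distribution: QualityDistribution = QualityDistribution.UNIFORM
    mean: float = 60.0   # ASCII-code units (gaussian only)
    sd: float = 10.0     # ASCII-code units (gaussian only)

    def __post_init__(self) -> None:
        codes = tuple(int(c) for c in self.codes)
        if not codes:
            raise ConfigError("quality alphabet must be non-empty")
        if any(c < ASCII_MIN or c > ASCII_MAX for c in codes):
            raise ConfigError(
                f"quality codes must lie in [{ASCII_MIN}, {ASCII_MAX}]"
            )
        if list(codes) != sorted(set(codes)):
            raise ConfigError("quality codes must be sorted ascending, no duplicates")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "distribution", QualityDistribution(self.distribution))
        if self.sd <= 0:
            raise ConfigError("gaussian sd must be positive")

    @property
    def lowest_code(self) -> int:
        return self.codes[0]

    @property
    def lowest_char(self) -> str:
        return chr(self.codes[0])

    def __len__(self) -> int:
        return len(self.codes)


def parse_ascii_ranges(spec: str) -> tuple[int, ...]:
    """Expand a sparse range spec like ``"33,34,40-45,110-120"`` into codes.

    Accepts comma-separated integers and hyphen ranges (en/em dashes are
    normalized to hyphens); the result is deduplicated, sorted and validated
    against the printable window [33, 126].
    """
    spec = spec.replace("–", "-").replace("—", "-").replace(" ", "")
    if not spec:
        raise ConfigError("empty ASCII range spec")
    codes: set[int] = set()
    for token in spec.split(","):
        m = _RANGE_TOKEN.match(token)
        if not m:
            raise ConfigError(f"malformed ASCII range token {token!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if lo > hi:
            raise ConfigError(f"descending range {token!r}")
        codes.update(range(lo, hi + 1))
    out = tuple(sorted(codes))
    if out[0] < ASCII_MIN or out[-1] > ASCII_MAX:
        raise ConfigError(
            f"ASCII codes must lie in [{ASCII_MIN}, {ASCII_MAX}], got {out[0]}..{out[-1]}"
        )
    return out


def sample_qualities_uniform(
    length: int, alphabet: QualityAlphabet, rng: np.random.Generator
) -> str:
    """Draw ``length`` quality characters i.i.d. uniform over the alphabet."""
    if length < 0:
        raise ConfigError("length must be non-negative")
    codes = np.asarray(alphabet.codes, dtype=np.uint8)
    return codes[rng.integers(0, len(codes), size=length)].tobytes().decode("ascii")


def _nearest_codes(values: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Map rounded integer values to the nearest code; ties break low."""
    pos = np.searchsorted(codes, values)
    pos = np.clip(pos, 0, len(codes) - 1)
    left = np.clip(pos - 1, 0, len(codes) - 1)
    d_left = np.abs(values - codes[left])
    d_right = np.abs(codes[pos] - values)
    take_left = (d_left <= d_right) & (pos > 0)
    return np.where(take_left, codes[left], codes[pos])


def sample_qualities_gaussian(
    length: int,
    alphabet: QualityAlphabet,
    mean: float,
    sd: float,
    rng: np.random.Generator,
) -> str:
    """Draw ``length`` quality characters from a discretized Gaussian.

    One normal variate per position, rounded to the nearest integer, then
    mapped to the nearest allowed code (ties toward the lower code).
    """
    if sd <= 0:
        raise ConfigError("sd must be positive")
    if length < 0:
        raise ConfigError("length must be non-negative")
    codes = np.asarray(alphabet.codes, dtype=np.int64)
    raw = np.rint(rng.normal(mean, sd, size=length)).astype(np.int64)
    return _nearest_codes(raw, codes).astype(np.uint8).tobytes().decode("ascii")


def sample_qualities(
    length: int, alphabet: QualityAlphabet, rng: np.random.Generator
) -> str:
    """Sample per the alphabet's configured distribution."""
    if alphabet.distribution is QualityDistribution.GAUSSIAN:
        return sample_qualities_gaussian(length, alphabet, alphabet.mean, alphabet.sd, rng)
    return sample_qualities_uniform(length, alphabet, rng)


def mask_n_positions(quals: str, seq: str, alphabet: QualityAlphabet) -> str:
    """Force the lowest quality score wherever the base is N."""
    if len(quals) != len(seq):
        raise ContractError(
            f"quality/base length mismatch: {len(quals)} vs {len(seq)}"
        )
    if "N" not in seq:
        return quals
    low = alphabet.lowest_char
    return "".join(low if b == "N" else q for b, q in zip(seq, quals))


def quantize_alphabet(alphabet: QualityAlphabet, n_levels: int) -> QualityAlphabet:
    """Restrict the alphabet to ``n_levels`` codes, evenly spaced by rank.

    ``n_levels == len(alphabet)`` is the identity; ``n_levels == 1`` keeps only
    the lowest code (a constant quality stream).  Fewer levels mean lower
    entropy and a smaller compressed quality channel.
    """
    m = len(alphabet.codes)
    if not 1 <= n_levels <= m:
        raise ConfigError(f"n_levels must be in [1, {m}], got {n_levels}")
    if n_levels == 1:
        idx = np.array([0])
    else:
        idx = np.rint(np.linspace(0, m - 1, n_levels)).astype(int)
    picked = tuple(alphabet.codes[i] for i in idx)
    return replace(alphabet, codes=picked)
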