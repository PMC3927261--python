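"""Per-read header generation for four sequencing platforms.

Headers are the first of the three FASTQ channels and are simulated
independently of bases and qualities.  Four platform dialects are supported:

* **Illumina** — ``@<tag>.<n> <instrument>:<lane>:<tile>:<x>:<y>`` with either
  a ``length=`` appendix or a ``/1`` / ``/2`` mate suffix.
* **ABI-SOLiD** — an underscore-joined architecture of run tokens, a date-like
  token and panel/x/y numeric tokens, with the same two suffix options.
* **Roche-454** — a 14-character accession: a 6-char base-36 run timestamp, a
  randomizing hash character, a 2-digit PTP region in 01..16, and a 5-char
  base-36 well code encoding ``x * 4096 + y``.
* **Ion Torrent** — ``@<run id>:<X>:<Y>`` with chip-bounded, zero-padded
  coordinates (the P1 chip spans 0..15456 by 0..10656).

Every stochastic field is drawn from a uniform distribution over its domain:
uniform draws are cheap and minimise the chance of two reads colliding on the
same field values.  Run-scoped identifiers (the 454 timestamp, the Ion Torrent
run ID, the SOLiD run tokens) are sampled once per run and held constant
across reads, like a real instrument run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

import numpy as np

from .errors import ConfigError

__all__ = [
    "BASE36_ALPHABET",
    "WELL_Y_MODULUS",
    "Platform",
    "PairedMode",
    "Roche454Accession",
    "IonTorrentChipSpec",
    "CHIP_SPECS",
    "HeaderConfig",
    "RunIdentity",
    "HeaderGenerator",
    "encode_base36",
    "decode_base36",
    "encode_well_location",
    "decode_well_location",
    "sample_run_identity",
    "make_roche454_header",
    "make_iontorrent_header",
    "make_illumina_header",
    "make_solid_header",
]

BASE36_ALPHABET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_B36_INDEX = {c: i for i, c in enumerate(BASE36_ALPHABET)}

#: Multiplier in the well-location formula ``total = x * 4096 + y``; y must be
#: below this for the encoding to be invertible.
WELL_Y_MODULUS = 4096

#: Largest x for which every (x, y) with y < 4096 fits in 5 base-36 digits.
ROCHE454_X_MAX = 36**5 // WELL_Y_MODULUS - 1


def encode_base36(value: int, width: int) -> str:
    """Render ``value`` as a fixed-width base-36 string, most-significant first.

    The digit alphabet is ``0-9A-Z``.

    Raises
    ------
    ConfigError
        If ``value`` is negative, ``width`` is not positive, or ``value`` does
        not fit in ``width`` digits.
    """
    value = int(value)
    width = int(width)
    if width < 1:
        raise ConfigError(f"width must be positive, got {width}")
    if value < 0:
        raise ConfigError(f"cannot base-36 encode negative value {value}")
    if value >= 36**width:
        raise ConfigError(f"value {value} overflows {width} base-36 digits")
    digits = []
    for _ in range(width):
        value, r = divmod(value, 36)
        digits.append(BASE36_ALPHABET[r])
    return "".join(reversed(digits))


def decode_base36(code: str) -> int:
    """Inverse of :func:`encode_base36` (width inferred from ``len(code)``)."""
    if not code:
        raise ConfigError("empty base-36 string")
    total = 0
    for ch in code:
        try:
            total = total * 36 + _B36_INDEX[ch]
        except KeyError:
            raise ConfigError(f"invalid base-36 character {ch!r} in {code!r}") from None
    return total


def encode_well_location(x: int, y: int) -> str:
    """Encode a (x, y) well location as a 5-character base-36 string.

    The total value ``x * 4096 + y`` is base-36 encoded; ``y`` must lie in
    ``[0, 4096)`` so that the encoding can be decoded unambiguously.
    """
    x, y = int(x), int(y)
    if not 0 <= y < WELL_Y_MODULUS:
        raise ConfigError(f"well y must be in [0, {WELL_Y_MODULUS}), got {y}")
    if x < 0:
        raise ConfigError(f"well x must be non-negative, got {x}")
    total = x * WELL_Y_MODULUS + y
    if total >= 36**5:
        raise ConfigError(f"well location ({x}, {y}) overflows 5 base-36 digits")
    return encode_base36(total, 5)


def decode_well_location(code: str) -> tuple[int, int]:
    """Inverse of :func:`encode_well_location`."""
    if len(code) != 5:
        raise ConfigError(f"well code must have 5 characters, got {code!r}")
    total = decode_base36(code)
    return divmod(total, WELL_Y_MODULUS)


class Platform(str, Enum):
    ILLUMINA = "illumina"
    SOLID = "solid"
    ROCHE454 = "roche454"
    IONTORRENT = "iontorrent"


class PairedMode(str, Enum):
    NONE = "none"
    PAIR_SUFFIX = "pair_suffix"


@dataclass(frozen=True)
class Roche454Accession:
    """The four components of a 14-character Roche-454 read accession."""

    timestamp_code: str  # 6-char base-36 run timestamp
    hash_char: str       # 1 randomizing alphanumeric character
    region: int          # PTP region, 1..16, rendered zero-padded
    well_code: str       # 5-char base-36 encoding of x*4096+y

    def __post_init__(self) -> None:
        if len(self.timestamp_code) != 6:
            raise ConfigError("timestamp code must have 6 characters")
        if len(self.hash_char) != 1 or self.hash_char not in BASE36_ALPHABET:
            raise ConfigError("hash character must be one alphanumeric character")
        if not 1 <= self.region <= 16:
            raise ConfigError(f"region must be in [1, 16], got {self.region}")
        if len(self.well_code) != 5:
            raise ConfigError("well code must have 5 characters")

    def render(self) -> str:
        return f"{self.timestamp_code}{self.hash_char}{self.region:02d}{self.well_code}"

    @property
    def well_location(self) -> tuple[int, int]:
        return decode_well_location(self.well_code)

    @classmethod
    def parse(cls, accession: str) -> "Roche454Accession":
        if len(accession) != 14:
            raise ConfigError(f"accession must have 14 characters, got {accession!r}")
        return cls(
            timestamp_code=accession[:6],
            hash_char=accession[6],
            region=int(accession[7:9]),
            well_code=accession[9:],
        )


@dataclass(frozen=True)
class IonTorrentChipSpec:
    """Coordinate bounds for one Ion Torrent chip.

    Only the P1 chip's bounds (15456 x 10656) are fixed by the platform
    documentation this simulator follows; the 314/316/318 entries are
    configurable defaults sized like their well grids.
    """

    chip_name: str
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_max < 0 or self.y_max < 0:
            raise ConfigError("chip bounds must be non-negative")


CHIP_SPECS: dict[str, IonTorrentChipSpec] = {
    "314": IonTorrentChipSpec("314", x_max=1280, y_max=1152),
    "316": IonTorrentChipSpec("316", x_max=2736, y_max=2640),
    "318": IonTorrentChipSpec("318", x_max=3392, y_max=3792),
    "P1": IonTorrentChipSpec("P1", x_max=15456, y_max=10656),
}

_SOLID_CENTERS = ("Broad", "Baylor", "WUGSC", "Sanger")


@dataclass(frozen=True)
class HeaderConfig:
    """Configuration of the header channel for one simulation run."""

    platform: Platform = Platform.ILLUMINA
    instrument_tag: str = "FILEOUT"
    paired_mode: PairedMode = PairedMode.NONE
    append_length: bool = True
    chip: IonTorrentChipSpec = CHIP_SPECS["P1"]
    # Illumina field domains (inclusive), matching the classic
    # <instrument>:<lane>:<tile>:<x>:<y> architecture.
    instrument_name: str = "HWUSI-EAS100R"
    lane_range: tuple[int, int] = (1, 8)
    tile_range: tuple[int, int] = (1, 120)
    x_range: tuple[int, int] = (0, 2047)
    y_range: tuple[int, int] = (0, 2047)
    # SOLiD numeric token domains.
    solid_panel_range: tuple[int, int] = (1, 2000)
    solid_x_range: tuple[int, int] = (0, 4095)
    solid_y_range: tuple[int, int] = (0, 4095)

    def __post_init__(self) -> None:
        platform = Platform(self.platform)
        paired = PairedMode(self.paired_mode)
        object.__setattr__(self, "platform", platform)
        object.__setattr__(self, "paired_mode", paired)
        if paired is PairedMode.PAIR_SUFFIX and self.append_length:
            raise ConfigError(
                "append_length and pair_suffix are mutually exclusive; "
                "a header carries either a length= appendix or a mate suffix"
            )
        for name in ("lane_range", "tile_range", "x_range", "y_range",
                     "solid_panel_range", "solid_x_range", "solid_y_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} has lo > hi: ({lo}, {hi})")

    def with_platform(self, platform: Platform | str) -> "HeaderConfig":
        return replace(self, platform=Platform(platform))


@dataclass(frozen=True)
class RunIdentity:
    """Identifiers sampled once per simulation run and shared by all reads."""

    roche454_timestamp: str          # 6-char base-36
    iontorrent_run_id: str           # 5-char alphanumeric, e.g. "QWRK0"
    solid_run_name: str              # e.g. "BARB"
    solid_date: str                  # YYYYMMDD-like token
    solid_run_no: int
    solid_center: str
    solid_slide: str                 # e.g. "3b"
    solid_frag: int


def _uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Uniform integer on the inclusive range [lo, hi]."""
    return int(rng.integers(lo, hi + 1))


def sample_run_identity(rng: np.random.Generator) -> RunIdentity:
    """Draw the run-constant header identifiers for one simulation run."""
    timestamp = encode_base36(int(rng.integers(36**6)), 6)
    run_id = "".join(BASE36_ALPHABET[i] for i in rng.integers(0, 36, size=5))
    run_name = "".join(
        BASE36_ALPHABET[10 + i] for i in rng.integers(0, 26, size=4)
    )
    date = f"{_uniform_int(rng, 2006, 2013):04d}{_uniform_int(rng, 1, 12):02d}{_uniform_int(rng, 1, 28):02d}"
    run_no = _uniform_int(rng, 1, 9)
    center = _SOLID_CENTERS[_uniform_int(rng, 0, len(_SOLID_CENTERS) - 1)]
    slide = f"{_uniform_int(rng, 1, 9)}{BASE36_ALPHABET[10 + _uniform_int(rng, 0, 25)].lower()}"
    frag = _uniform_int(rng, 25, 500)
    return RunIdentity(
        roche454_timestamp=timestamp,
        iontorrent_run_id=run_id,
        solid_run_name=run_name,
        solid_date=date,
        solid_run_no=run_no,
        solid_center=center,
        solid_slide=slide,
        solid_frag=frag,
    )


def _suffix(cfg: HeaderConfig, read_index: int, read_length: int) -> str:
    """The header tail: a length= appendix, a mate suffix, or nothing.

    Mates alternate /1, /2 with consecutive read indices (index 1 -> /1).
    """
    if cfg.paired_mode is PairedMode.PAIR_SUFFIX:
        mate = 2 - (read_index % 2)
        return f"/{mate}"
    if cfg.append_length:
        return f" length={read_length}"
    return ""


def make_roche454_header(
    rng: np.random.Generator,
    read_index: int,
    read_length: int,
    cfg: HeaderConfig,
    run: Optional[RunIdentity] = None,
) -> str:
    """Generate one Roche-454 header, e.g. ``@FILEOUT.2286 C3U5GWL01CBXT2 length=216``."""
    if read_length < 1:
        raise ConfigError("read_length must be >= 1")
    if run is None:
        run = sample_run_identity(rng)
    accession = Roche454Accession(
        timestamp_code=run.roche454_timestamp,
        hash_char=BASE36_ALPHABET[_uniform_int(rng, 0, 35)],
        region=_uniform_int(rng, 1, 16),
        well_code=encode_well_location(
            _uniform_int(rng, 0, ROCHE454_X_MAX),
            _uniform_int(rng, 0, WELL_Y_MODULUS - 1),
        ),
    )
    return f"@{cfg.instrument_tag}.{read_index} {accession.render()}{_suffix(cfg, read_index, read_length)}"


def make_iontorrent_header(
    rng: np.random.Generator,
    cfg: HeaderConfig,
    run: Optional[RunIdentity] = None,
) -> str:
    """Generate one Ion Torrent header, e.g. ``@QWRK0:01344:01216``.

    X and Y are uniform within the configured chip's bounds (inclusive) and
    rendered zero-padded to five digits.
    """
    if run is None:
        run = sample_run_identity(rng)
    x = _uniform_int(rng, 0, cfg.chip.x_max)
    y = _uniform_int(rng, 0, cfg.chip.y_max)
    return f"@{run.iontorrent_run_id}:{x:05d}:{y:05d}"


def make_illumina_header(
    rng: np.random.Generator,
    read_index: int,
    read_length: int,
    cfg: HeaderConfig,
    run: Optional[RunIdentity] = None,
) -> str:
    """Generate one Illumina header, e.g. ``@FILEOUT.2286 HWUSI-EAS100R:1:1:210:308 length=30``."""
    lane = _uniform_int(rng, *cfg.lane_range)
    tile = _uniform_int(rng, *cfg.tile_range)
    x = _uniform_int(rng, *cfg.x_range)
    y = _uniform_int(rng, *cfg.y_range)
    return (
        f"@{cfg.instrument_tag}.{read_index} "
        f"{cfg.instrument_name}:{lane}:{tile}:{x}:{y}"
        f"{_suffix(cfg, read_index, read_length)}"
    )


def make_solid_header(
    rng: np.random.Generator,
    read_index: int,
    read_length: int,
    cfg: HeaderConfig,
    run: Optional[RunIdentity] = None,
) -> str:
    """Generate one ABI-SOLiD header.

    The architecture is underscore-joined run tokens followed by
    panel/x/y numeric tokens, directly after the ``<tag>.<index>`` prefix
    (no space), e.g.
    ``@FILEOUT.2286VAB_BARB_20080515_2_Broad_3b_150_1176_133_2030 length=35``.
    """
    if run is None:
        run = sample_run_identity(rng)
    panel = _uniform_int(rng, *cfg.solid_panel_range)
    x = _uniform_int(rng, *cfg.solid_x_range)
    y = _uniform_int(rng, *cfg.solid_y_range)
    body = "_".join(
        [
            f"VAB",
            run.solid_run_name,
            run.solid_date,
            str(run.solid_run_no),
            run.solid_center,
            run.solid_slide,
            str(run.solid_frag),
            str(panel),
            str(x),
            str(y),
        ]
    )
    return f"@{cfg.instrument_tag}.{read_index}{body}{_suffix(cfg, read_index, read_length)}"


class HeaderGenerator:
    """Stateful per-run header source dispatching on the configured platform."""

    def __init__(self, cfg: HeaderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.run = sample_run_identity(rng)

    def make(self, read_index: int, read_length: int) -> str:
        cfg, rng, run = self.cfg, self.rng, self.run
        if cfg.platform is Platform.ROCHE454:
            return make_roche454_header(rng, read_index, read_length, cfg, run)
        if cfg.platform is Platform.IONTORRENT:
            return make_iontorrent_header(rng, cfg, run)
        if cfg.platform is Platform.ILLUMINA:
            return make_illumina_header(rng, read_index, read_length, cfg, run)
        return make_solid_header(rng, read_index, read_length, cfg, run)


#: Regexes for structural checks of each dialect (used by the validator/tests).
HEADER_PATTERNS = {
    Platform.ROCHE454: re.compile(
        r"^@\w+\.\d+ [0-9A-Z]{6}[0-9A-Z](?:0[1-9]|1[0-6])[0-9A-Z]{5}( length=\d+|/[12])?$"
    ),
    Platform.IONTORRENT: re.compile(r"^@[0-9A-Z]{5}:\d{5}:\d{5}$"),
    Platform.ILLUMINA: re.compile(
        r"^@\w+\.\d+ [\w-]+:\d+:\d+:\d+:\d+( length=\d+|/[12])?$"
    ),
    Platform.SOLID: re.compile(
        r"^@\w+\.\d+VAB(_[\w]+){6}_\d+_\d+_\d+( length=\d+|/[12])?$"
    ),
}
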