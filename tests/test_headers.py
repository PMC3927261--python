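"""Header channel: base-36 plumbing, accession structure, platform dialects."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fqsim import ConfigError
from fqsim.headers import (
    CHIP_SPECS,
    HEADER_PATTERNS,
    ROCHE454_X_MAX,
    HeaderConfig,
    HeaderGenerator,
    PairedMode,
    Platform,
    Roche454Accession,
    decode_base36,
    decode_well_location,
    encode_base36,
    encode_well_location,
    make_illumina_header,
    make_iontorrent_header,
    make_roche454_header,
    make_solid_header,
    sample_run_identity,
)


class TestBase36:
    @pytest.mark.parametrize(
        "value,width,expected",
        [(0, 5, "00000"), (35, 1, "Z"), (20712422, 5, "CBXT2"), (4096, 5, "0035S")],
    )
    def test_encode_examples(self, value, width, expected):
        assert encode_base36(value, width) == expected

    @pytest.mark.parametrize("code,expected", [("00000", 0), ("CBXT2", 20712422), ("Z", 35)])
    def test_decode_examples(self, code, expected):
        assert decode_base36(code) == expected

    @pytest.mark.parametrize("value,width", [(36, 1), (36**5, 5), (-1, 3)])
    def test_out_of_domain_values_rejected(self, value, width):
        with pytest.raises(ConfigError):
            encode_base36(value, width)

    def test_invalid_character_rejected(self):
        with pytest.raises(ConfigError):
            decode_base36("AB!")

    @given(value=st.integers(0, 36**6 - 1), width=st.integers(6, 8))
    @settings(deadline=None)
    def test_round_trip(self, value, width):
        code = encode_base36(value, width)
        assert len(code) == width
        assert decode_base36(code) == value


class TestWellLocation:
    @pytest.mark.parametrize(
        "x,y,code", [(0, 0, "00000"), (5056, 3046, "CBXT2"), (1, 0, "0035S")]
    )
    def test_examples_both_directions(self, x, y, code):
        assert encode_well_location(x, y) == code
        assert decode_well_location(code) == (x, y)

    def test_encoding_is_x_times_4096_plus_y(self):
        # the well total is x*4096+y rendered base-36
        assert encode_well_location(5056, 3046) == encode_base36(5056 * 4096 + 3046, 5)

    @pytest.mark.parametrize("x,y", [(0, 4096), (0, -1), (-1, 0), (36**5 // 4096 + 1, 0)])
    def test_bounds_rejected(self, x, y):
        with pytest.raises(ConfigError):
            encode_well_location(x, y)

    def test_exhaustive_round_trip_small_grid(self):
        for x in range(64):
            for y in range(64):
                assert decode_well_location(encode_well_location(x, y)) == (x, y)

    def test_random_round_trip(self, rng):
        xs = rng.integers(0, ROCHE454_X_MAX + 1, size=10_000)
        ys = rng.integers(0, 4096, size=10_000)
        for x, y in zip(xs, ys):
            assert decode_well_location(encode_well_location(x, y)) == (int(x), int(y))


class TestRoche454:
    def test_printed_accession_parses_into_four_components(self):
        acc = Roche454Accession.parse("C3U5GWL01CBXT2")
        assert acc.timestamp_code == "C3U5GW"
        assert acc.hash_char == "L"
        assert acc.region == 1
        assert acc.well_code == "CBXT2"
        assert acc.well_location == (5056, 3046)
        assert acc.render() == "C3U5GWL01CBXT2"

    def test_header_shape_and_accession_structure(self, rng):
        cfg = HeaderConfig(platform=Platform.ROCHE454)
        run = sample_run_identity(rng)
        pat = re.compile(r"^@FILEOUT\.2286 ([0-9A-Z]{14}) length=216$")
        for _ in range(500):
            h = make_roche454_header(rng, 2286, 216, cfg, run)
            m = pat.match(h)
            assert m, h
            acc = Roche454Accession.parse(m.group(1))
            assert acc.timestamp_code == run.roche454_timestamp
            assert 1 <= acc.region <= 16

    def test_region_uniform_chi_square(self, rng):
        cfg = HeaderConfig(platform=Platform.ROCHE454)
        run = sample_run_identity(rng)
        regions = [
            Roche454Accession.parse(
                make_roche454_header(rng, i, 100, cfg, run).split()[1]
            ).region
            for i in range(20_000)
        ]
        counts = np.bincount(regions, minlength=17)[1:]
        assert stats.chisquare(counts).pvalue > 0.001

    def test_length_appendix_tracks_read_length(self, rng):
        cfg = HeaderConfig(platform=Platform.ROCHE454)
        h = make_roche454_header(rng, 7, 321, cfg)
        assert h.endswith(" length=321")


class TestIonTorrent:
    def test_printed_example_shape(self):
        m = re.match(r"^@([0-9A-Z]{5}):(\d{5}):(\d{5})$", "@QWRK0:01344:01216")
        assert m
        assert (m.group(1), int(m.group(2)), int(m.group(3))) == ("QWRK0", 1344, 1216)

    def test_generated_headers_match_dialect(self, rng):
        cfg = HeaderConfig(platform=Platform.IONTORRENT)
        run = sample_run_identity(rng)
        for _ in range(200):
            h = make_iontorrent_header(rng, cfg, run)
            assert HEADER_PATTERNS[Platform.IONTORRENT].match(h), h
            assert h.split(":")[0] == "@" + run.iontorrent_run_id

    def test_p1_coordinate_bounds(self, rng):
        cfg = HeaderConfig(platform=Platform.IONTORRENT, chip=CHIP_SPECS["P1"])
        run = sample_run_identity(rng)
        xs, ys = [], []
        for _ in range(5000):
            _, x, y = make_iontorrent_header(rng, cfg, run)[1:].split(":")
            xs.append(int(x))
            ys.append(int(y))
        assert 0 <= min(xs) and max(xs) <= 15456
        assert 0 <= min(ys) and max(ys) <= 10656

    def test_zero_coordinates_zero_padded(self, rng):
        from fqsim.headers import IonTorrentChipSpec

        cfg = HeaderConfig(platform=Platform.IONTORRENT,
                           chip=IonTorrentChipSpec("tiny", 0, 0))
        h = make_iontorrent_header(rng, cfg)
        assert h.endswith(":00000:00000")


class TestIlluminaAndSolid:
    def test_both_printed_illumina_shapes_producible(self, rng):
        with_len = make_illumina_header(
            rng, 2286, 30, HeaderConfig(platform=Platform.ILLUMINA)
        )
        assert re.match(r"^@FILEOUT\.2286 HWUSI-EAS100R:\d+:\d+:\d+:\d+ length=30$", with_len)
        paired = make_illumina_header(
            rng, 1, 30,
            HeaderConfig(platform=Platform.ILLUMINA,
                         paired_mode=PairedMode.PAIR_SUFFIX, append_length=False),
        )
        assert re.match(r"^@FILEOUT\.1 HWUSI-EAS100R:\d+:\d+:\d+:\d+/1$", paired)

    def test_mate_suffix_alternates(self, rng):
        cfg = HeaderConfig(paired_mode=PairedMode.PAIR_SUFFIX, append_length=False)
        suffixes = [
            make_illumina_header(rng, i, 30, cfg)[-2:] for i in range(1, 7)
        ]
        assert suffixes == ["/1", "/2", "/1", "/2", "/1", "/2"]

    def test_both_solid_suffix_shapes_producible(self, rng):
        run = sample_run_identity(rng)
        with_len = make_solid_header(rng, 2286, 35, HeaderConfig(platform=Platform.SOLID), run)
        assert HEADER_PATTERNS[Platform.SOLID].match(with_len), with_len
        assert with_len.endswith(" length=35")
        paired = make_solid_header(
            rng, 2, 35,
            HeaderConfig(platform=Platform.SOLID,
                         paired_mode=PairedMode.PAIR_SUFFIX, append_length=False),
            run,
        )
        assert HEADER_PATTERNS[Platform.SOLID].match(paired), paired
        assert paired.endswith("/2")
        # no space between the read index and the underscore architecture
        assert " " not in paired[1:].split(" length=")[0].replace(" ", "")

    def test_headers_begin_with_at(self, rng):
        for platform in Platform:
            cfg = HeaderConfig(platform=platform)
            gen = HeaderGenerator(cfg, rng)
            assert gen.make(1, 50).startswith("@")

    def test_field_values_within_configured_ranges(self, rng):
        cfg = HeaderConfig(lane_range=(3, 3), tile_range=(7, 9), x_range=(0, 1), y_range=(5, 5))
        for i in range(100):
            fields = make_illumina_header(rng, i, 10, cfg).split(" ")[1].split(":")
            assert int(fields[1]) == 3
            assert 7 <= int(fields[2]) <= 9
            assert int(fields[3]) in (0, 1)
            assert int(fields[4]) == 5


class TestHeaderConfig:
    def test_pair_suffix_and_length_appendix_are_exclusive(self):
        with pytest.raises(ConfigError):
            HeaderConfig(paired_mode=PairedMode.PAIR_SUFFIX, append_length=True)

    def test_same_seed_gives_identical_header_stream(self, make_rng):
        for platform in Platform:
            cfg = HeaderConfig(platform=platform)
            streams = []
            for _ in range(2):
                gen = HeaderGenerator(cfg, make_rng(99))
                streams.append([gen.make(i, 80) for i in range(1, 200)])
            assert streams[0] == streams[1]
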