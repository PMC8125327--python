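"""The 17 statistical time features against an independent literal oracle.

The oracle below transcribes each defining formula with plain Python loops
and its own histogram logic; it shares no code with the implementation.
"""

import math

import numpy as np
import pytest

from emgstress import features
from emgstress.features import FEATURE_NAMES, FeatureError, ModeBinning

from conftest import make_segment


# ---------------------------------------------------------------------------
# independent oracle: plain-Python literal transcription
# ---------------------------------------------------------------------------

def oracle_mode(xs, nbins):
    lo, hi = min(xs), max(xs)
    if lo == hi:
        return lo
    width = (hi - lo) / nbins
    counts = [0] * nbins
    for v in xs:
        k = int((v - lo) / width)
        if k == nbins:  # the maximum lands in the last class
            k -= 1
        counts[k] += 1
    best = counts.index(max(counts))
    left = counts[best - 1] if best > 0 else 0
    right = counts[best + 1] if best < nbins - 1 else 0
    d_minus = abs(counts[best] - left)
    d_plus = abs(counts[best] - right)
    L = lo + best * width
    if d_minus + d_plus == 0:
        return L + width / 2
    return L + width * d_minus / (d_minus + d_plus)


def oracle_features(xs):
    xs = [float(v) for v in xs]
    n = len(xs)
    mean = sum(xs) / n
    variance = sum((v - mean) ** 2 for v in xs) / n
    std = math.sqrt(variance)
    rms = math.sqrt(sum(v * v for v in xs) / n)
    abs_mean = sum(abs(v) for v in xs) / n
    smr = (sum(math.sqrt(abs(v)) for v in xs) / n) ** 2
    peak = max(abs(v) for v in xs)
    ordered = sorted(xs)
    if n % 2 == 1:
        median = ordered[n // 2]
    else:
        median = (ordered[n // 2 - 1] + ordered[n // 2]) / 2
    nbins = max(math.ceil(1 + math.log2(n)), 1)
    return {
        "mode": oracle_mode(xs, nbins),
        "mean": mean,
        "range": max(xs) - min(xs),
        "variance": variance,
        "std": std,
        "impulse_factor": peak / abs_mean,
        "smr": smr,
        "sf_smr": smr / abs_mean,
        "rms": rms,
        "sf_rms": rms / abs_mean,
        "crest_factor": peak / rms,
        "latitude_factor": peak / smr,
        "skewness": sum((v - mean) ** 3 for v in xs) / n / rms**3,
        "kurtosis": sum((v - mean) ** 4 for v in xs) / n / rms**4,
        "moment5": sum((v - mean) ** 5 for v in xs) / n / rms**5,
        "moment6": sum((v - mean) ** 6 for v in xs) / n / rms**6,
        "median": median,
    }


# ---------------------------------------------------------------------------
# hand-computed values for x = [1, 2, 3, 4]
# ---------------------------------------------------------------------------

HAND_COMPUTED_1234 = {
    "mean": 2.5,
    "range": 3.0,
    "variance": 1.25,
    "std": 1.1180339887498949,
    "rms": 2.7386127875258306,
    "impulse_factor": 1.6,
    "crest_factor": 1.460593486680443,
    "smr": 2.3610353565761373,  # ((1 + sqrt2 + sqrt3 + 2) / 4)^2
    "sf_rms": 1.0954451150103321,
    "sf_smr": 0.9444141426304549,
    "latitude_factor": 1.694172003336965,
    "skewness": 0.0,
    "kurtosis": 0.04555555555555556,  # 10.25 / (4 * 56.25)
    "moment5": 0.0,
    "moment6": 0.013518518518518519,
    "median": 2.5,
}


class TestExtractStf:
    def test_hand_computed_small_sample(self):
        values = features.extract_stf(np.array([1.0, 2.0, 3.0, 4.0]))
        for name, expected in HAND_COMPUTED_1234.items():
            assert values[name] == pytest.approx(expected, rel=1e-12), name

    def test_matches_oracle_on_100_random_vectors(self):
        rng = np.random.default_rng(2024)
        for trial in range(100):
            n = int(rng.integers(20, 400))
            loc = rng.normal(0, 2)
            scale = rng.uniform(0.1, 5)
            x = rng.normal(loc, scale, n)
            got = features.extract_stf(x)
            expected = oracle_features(x)
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(expected[name], rel=1e-10), (
                    f"trial {trial}, feature {name}"
                )

    @pytest.mark.parametrize(
        "name",
        [
            "sf_rms", "sf_smr", "crest_factor", "impulse_factor",
            "latitude_factor", "skewness", "kurtosis", "moment5", "moment6",
        ],
    )
    def test_shape_ratios_are_scale_invariant(self, name):
        rng = np.random.default_rng(77)
        x = rng.normal(1.0, 2.0, 500)
        base = features.extract_stf(x)
        for a in (0.01, 3.0, 250.0):
            scaled = features.extract_stf(a * x)
            assert scaled[name] == pytest.approx(base[name], rel=1e-9)

    def test_rms_normalized_moment_cross_identity(self):
        # these skewness/kurtosis variants equal the conventional moment
        # ratios times (std/rms)^3 and (std/rms)^4
        rng = np.random.default_rng(13)
        x = rng.gamma(2.0, 1.5, 1000)  # asymmetric so skewness is non-trivial
        got = features.extract_stf(x)
        std, rms = got["std"], got["rms"]
        centered = x - x.mean()
        skew_conv = float(np.mean(centered**3)) / std**3
        kurt_conv = float(np.mean(centered**4)) / std**4
        assert got["skewness"] == pytest.approx(skew_conv * (std / rms) ** 3, rel=1e-10)
        assert got["kurtosis"] == pytest.approx(kurt_conv * (std / rms) ** 4, rel=1e-10)

    def test_std_is_square_root_of_variance(self):
        got = features.extract_stf(np.random.default_rng(1).normal(0, 3, 256))
        assert got["std"] ** 2 == pytest.approx(got["variance"], rel=1e-12)

    def test_all_zero_window_rejected(self):
        with pytest.raises(FeatureError):
            features.extract_stf(np.zeros(100))

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            features.extract_stf(np.array([1.0]))


class TestGroupedMode:
    def test_interpolation_within_modal_class(self):
        # three unit-width classes over [-1, 2] with counts (2, 10, 6):
        # mode = 0 + 1 * (10-2) / ((10-2) + (10-6)) = 2/3
        x = np.concatenate([
            np.linspace(-1.0, -0.1, 2),
            np.linspace(0.0, 0.9, 10),
            np.linspace(1.0, 2.0, 6),
        ])
        assert features.grouped_mode(x, ModeBinning(bin_count=3)) == pytest.approx(2 / 3)

    def test_count_ties_break_to_leftmost_class(self):
        # classes with counts (10, 10, 1): the leftmost maximal class wins;
        # its missing left neighbour counts 0, so d- = 10 and d+ = 0
        x = np.concatenate([
            np.linspace(0.0, 0.9, 10),
            np.linspace(1.0, 1.9, 10),
            [3.0],
        ])
        assert features.grouped_mode(x, ModeBinning(bin_count=3)) == pytest.approx(1.0)

    def test_single_occupied_bin_gives_its_midpoint(self):
        # occupied class flanked by near-empty ones, symmetric differences
        x = np.concatenate([[0.0], np.full(10, 1.5), [3.0]])
        assert features.grouped_mode(x, ModeBinning(bin_count=3)) == pytest.approx(1.5)

    def test_constant_sample_degenerates_to_the_value(self):
        assert features.grouped_mode(np.full(10, 4.2)) == pytest.approx(4.2)

    def test_sturges_binning_default(self):
        assert ModeBinning().bins_for(4650) == 14  # ceil(1 + log2 4650)
        assert ModeBinning().bins_for(930) == 11


class TestFeatureTable:
    def test_table_shape_and_columns(self, feature_table_5min):
        assert len(feature_table_5min) == 50
        assert list(feature_table_5min.columns[:4]) == [
            "subject_id", "segment_index", "scenario", "label",
        ]
        assert tuple(feature_table_5min.columns[4:]) == FEATURE_NAMES
        assert feature_table_5min[list(FEATURE_NAMES)].size == 850

    def test_single_segment_yields_17_values(self):
        table = features.build_feature_table(
            [make_segment(np.random.default_rng(0).normal(0, 1, 100))]
        )
        assert table[list(FEATURE_NAMES)].size == 17

    def test_five_segments_yield_85_values(self):
        rng = np.random.default_rng(1)
        scenarios = ["rest", "city", "highway", "city", "highway"]
        table = features.build_feature_table(
            [make_segment(rng.normal(0, 1, 100), s) for s in scenarios]
        )
        assert table[list(FEATURE_NAMES)].size == 85
        assert list(table["segment_index"]) == [0, 1, 2, 3, 4]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            features.build_feature_table([])

    def test_round_trip(self, feature_table_5min, tmp_path):
        path = tmp_path / "features.csv"
        features.write_feature_table(feature_table_5min, path)
        back = features.read_feature_table(path)
        assert back.shape == feature_table_5min.shape
        np.testing.assert_allclose(
            back[list(FEATURE_NAMES)].to_numpy(),
            feature_table_5min[list(FEATURE_NAMES)].to_numpy(),
            rtol=1e-12,
        )
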