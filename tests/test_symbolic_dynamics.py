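import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvrisk.errors import ContractError, InsufficientDataError
from hrvrisk.symbolic_dynamics import (
    STSD_FAMILIES,
    SymbolSequence,
    WordHistogram,
    binary_variability_patterns,
    classical_sd_indices,
    encode_classical,
    sdsd,
    ssd_24h,
    stsd,
    word_histogram,
)
from tests.conftest import make_nn


class TestEncodeClassical:
    def test_worked_example(self):
        sym = encode_classical(make_nn([900, 1050, 800, 1000, 700]))
        # mu = 890: 900 in (mu, 1.1mu] -> 0; 1050 > 1.1mu -> 1;
        # 800 <= 0.9mu -> 3; 1000 -> 1; 700 -> 3
        assert sym.symbols.tolist() == [0, 1, 3, 1, 3]

    def test_constant_maps_to_two(self, constant_series):
        sym = encode_classical(constant_series)
        assert set(sym.symbols.tolist()) == {2}

    def test_boundaries(self):
        sym = encode_classical(make_nn([1200, 800, 1000]))  # mu = 1000
        # 1200 > 1.1mu -> 1; 800 <= 0.9mu -> 3; 1000 = mu -> 2
        assert sym.symbols.tolist() == [1, 3, 2]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.5, 4.0))
    def test_scale_invariance(self, seed, k):
        rng = np.random.default_rng(seed)
        x = 700 + 200 * rng.random(60)
        a = encode_classical(make_nn(x)).symbols
        b = encode_classical(make_nn(k * x)).symbols
        assert a.tolist() == b.tolist()


class TestWordHistogram:
    def test_all_64_word_types_present(self):
        h = word_histogram(encode_classical(make_nn([900, 1050, 800, 1000, 700])))
        assert len(h.probabilities) == 4**3 == 64
        assert h.counts["013"] == 1
        assert h.counts["131"] == 1
        assert h.counts["313"] == 1
        assert h.probabilities["013"] == pytest.approx(1 / 3)

    def test_probabilities_sum_to_one(self, rng):
        x = 800 + 100 * rng.standard_normal(500)
        h = word_histogram(encode_classical(make_nn(x)))
        assert sum(h.probabilities.values()) == pytest.approx(1.0)
        assert sum(h.counts.values()) == 500 - 2

    def test_too_few_symbols(self):
        with pytest.raises(InsufficientDataError):
            word_histogram(SymbolSequence([1, 2], alphabet_size=4))

    def test_symbol_outside_alphabet_rejected(self):
        with pytest.raises(ContractError):
            SymbolSequence([0, 4, 1], alphabet_size=4)


def _uniform_histogram() -> WordHistogram:
    names = [f"{a}{b}{c}" for a in "0123" for b in "0123" for c in "0123"]
    return WordHistogram(
        word_length=3,
        alphabet_size=4,
        counts={w: 1 for w in names},
        probabilities={w: 1 / 64 for w in names},
    )


class TestClassicalIndices:
    def test_constant_series(self, constant_series):
        out = classical_sd_indices(word_histogram(encode_classical(constant_series)))
        assert out["pW222"] == pytest.approx(1.0)
        assert out["wpsum02"] == pytest.approx(1.0)
        assert out["wpsum13"] == pytest.approx(0.0)
        assert out["pTH20"] == 1  # only one word above every threshold

    def test_uniform_distribution_thresholds(self):
        out = classical_sd_indices(_uniform_histogram())
        # each word at 1.5625%: above 1% for all 64, above 2% for none
        assert out["pTH1"] == 64
        assert out["pTH2"] == 0
        assert out["wpsum02"] == pytest.approx(8 / 64)
        assert out["wpsum13"] == pytest.approx(8 / 64)

    def test_pth_nonincreasing(self, rng):
        x = 800 + 80 * rng.standard_normal(1000)
        out = classical_sd_indices(word_histogram(encode_classical(make_nn(x))))
        pth = [out[f"pTH{k}"] for k in range(1, 21)]
        assert all(a >= b for a, b in zip(pth, pth[1:]))

    def test_wpsum_example(self):
        out = classical_sd_indices(word_histogram(encode_classical(
            make_nn([900, 1050, 800, 1000, 700]))))
        # words 013, 131, 313: two of three use only symbols {1,3}
        assert out["wpsum13"] == pytest.approx(2 / 3)
        assert out["wpsum02"] == pytest.approx(0.0)

    def test_wrong_alphabet_rejected(self):
        h = word_histogram(SymbolSequence([0, 1, 0, 1, 1], alphabet_size=2))
        with pytest.raises(ContractError):
            classical_sd_indices(h)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_wpsum_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = 800 + 60 * rng.standard_normal(120)
        out = classical_sd_indices(word_histogram(encode_classical(make_nn(x))))
        assert 0.0 <= out["wpsum02"] <= 1.0
        assert 0.0 <= out["wpsum13"] <= 1.0
        assert out["wpsum02"] + out["wpsum13"] <= 1.0 + 1e-12


class TestBinaryPatterns:
    def test_constant_all_quiet(self, constant_series):
        out = binary_variability_patterns(constant_series)
        assert out["plvar5"] == pytest.approx(1.0)
        assert out["phvar5"] == pytest.approx(0.0)

    def test_alternating_all_active(self):
        x = np.where(np.arange(200) % 2 == 0, 800.0, 820.0)
        out = binary_variability_patterns(make_nn(x))
        assert out["phvar5"] == pytest.approx(1.0)
        assert out["plvar5"] == pytest.approx(0.0)

    def test_single_quiet_run_counted_once(self):
        # 101 intervals -> 100 diffs -> 95 overlapping 6-words; one run of
        # exactly 6 quiet diffs (7 equal intervals) gives one all-zero word
        x = np.where(np.arange(101) % 2 == 0, 800.0, 820.0)
        x[40:47] = 800.0
        out = binary_variability_patterns(make_nn(x))
        assert out["plvar5"] == pytest.approx(1 / 95)

    def test_threshold_is_inclusive(self):
        # |dNN| = 5 ms exactly counts as active
        x = np.cumsum(np.full(50, 5.0)) + 800.0
        out = binary_variability_patterns(make_nn(x))
        assert out["phvar5"] == pytest.approx(1.0)

    def test_custom_limit_in_names(self, constant_series):
        out = binary_variability_patterns(constant_series, limit_ms=10)
        assert set(out) == {"plvar10", "phvar10"}

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            binary_variability_patterns(make_nn([800] * 6))


class TestSSD:
    def test_window_count_on_full_day(self):
        nn = make_nn(np.full(108_002, 800.0))  # spans just over 24 h
        out = ssd_24h(nn)
        assert out["S_windows"] == 24 * 60 - 30 + 1 == 1411

    def test_stationary_series_has_zero_spread_and_entropy(self):
        nn = make_nn(np.full(108_002, 800.0))
        out = ssd_24h(nn)
        assert out["m_pW222"] == pytest.approx(1.0)
        assert out["s_pW222"] == pytest.approx(0.0)
        assert out["Shannon_pW222"] == 0.0
        assert out["m_pTH20"] == pytest.approx(1.0)

    def test_entropy_bounded_by_bin_count(self, rng):
        x = 800 + 60 * rng.standard_normal(8000)  # ~107 min -> ~78 windows
        out = ssd_24h(make_nn(x))
        nob = round(1 + 3.32 * np.log10(out["S_windows"]))
        for w in ("000", "222", "111"):
            assert 0.0 <= out[f"Shannon_pW{w}"] <= np.log2(nob) + 1e-9

    def test_per_window_mean_consistent_with_manual_windows(self, rng):
        x = 800 + 40 * rng.standard_normal(4000)
        nn = make_nn(x)
        out = ssd_24h(nn)
        manual = []
        s0 = 0.0
        while s0 + 1800 <= nn.duration_s + 1e-9:
            i0, i1 = np.searchsorted(nn.t, [s0, s0 + 1800])
            seg = make_nn(x[i0:i1])
            h = word_histogram(encode_classical(seg))
            manual.append(h.probabilities["000"])
            s0 += 60
        assert out["m_pW000"] == pytest.approx(np.mean(manual))
        assert out["S_windows"] == len(manual)

    def test_too_short_record(self):
        with pytest.raises(InsufficientDataError):
            ssd_24h(make_nn([800] * 1000))  # 800 s < 2 windows


class TestSTSD:
    def test_ramp_families_exact(self):
        # 6-level sawtooth, 300 beats = 50 periods, 298 triples:
        # ascending for phases 0-3 (200), peak at 4 (49), valley at 5 (49)
        sym = np.tile(np.arange(6), 50)
        prof = stsd(make_nn(600 + 40.0 * sym))
        ag = prof.aggregates
        assert ag["m_ST_2V"] == pytest.approx(1.0)
        assert ag["m_ST_ASC"] == pytest.approx(200 / 298)
        assert ag["m_ST_PEAK"] == pytest.approx(49 / 298)
        assert ag["m_ST_VAL"] == pytest.approx(49 / 298)
        assert ag["m_ST_DESC"] == pytest.approx(0.0)
        assert ag["m_ST_0V"] == pytest.approx(0.0)

    def test_constant_window_all_0v(self):
        prof = stsd(make_nn([800.0] * 300))
        assert prof.aggregates["m_ST_0V"] == pytest.approx(1.0)
        assert prof.n_windows == 1

    def test_plateau_equals_1v(self, rng):
        x = 800 + 60 * rng.standard_normal(1200)
        ag = stsd(make_nn(x)).aggregates
        assert ag["m_ST_1V"] == pytest.approx(ag["m_ST_PLATEAU"])

    def test_family_partitions(self, rng):
        x = 800 + 60 * rng.standard_normal(900)
        prof = stsd(make_nn(x))
        per = prof.per_window
        np.testing.assert_allclose(
            per["ST_0V"] + per["ST_1V"] + per["ST_2V"], 1.0, atol=1e-12
        )
        np.testing.assert_allclose(
            per["ST_ASC"] + per["ST_DESC"] + per["ST_PEAK"] + per["ST_VAL"],
            per["ST_2V"],
            atol=1e-12,
        )

    def test_window_count(self, rng):
        x = 800 + 20 * rng.standard_normal(950)
        prof = stsd(make_nn(x))
        assert prof.n_windows == 3  # 950 // 300

    def test_quantization_uses_window_local_range(self):
        # second window shifted by +500 ms: identical shape -> same fractions
        base = 700 + 50.0 * (np.arange(300) % 6)
        prof = stsd(make_nn(np.concatenate([base, base + 500.0])))
        for f in STSD_FAMILIES:
            assert prof.per_window[f][0] == pytest.approx(prof.per_window[f][1])

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            stsd(make_nn([800] * 299))


class TestSDSD:
    def test_constant_series(self, constant_series):
        out = sdsd(constant_series)
        assert out["tau1_p001"] == 1  # only symbol 0 occurs
        assert out["symbol_probabilities"][0] == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self, rng):
        x = 800 + 50 * rng.standard_normal(400)
        out = sdsd(make_nn(x))
        assert out["symbol_probabilities"].sum() == pytest.approx(1.0)
        assert 1 <= out["tau1_p001"] <= 5

    def test_brute_force_oracle(self, rng):
        x = 800 + 50 * rng.standard_normal(300)
        out = sdsd(make_nn(x))
        symbols = []
        for j in range(300 - 5 + 1):
            w = x[j : j + 5]
            sd_j = np.std(w, ddof=1)
            symbols.append(int(np.sum(np.diff(w) < -sd_j)))
        probs = np.bincount(symbols, minlength=5) / len(symbols)
        np.testing.assert_allclose(out["symbol_probabilities"], probs)
        assert out["tau1_p001"] == int((probs > 0.01).sum())

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            sdsd(make_nn([800] * 5))
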