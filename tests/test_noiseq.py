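"""Noise-distribution DE statistic against brute-force oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from dgetag.noiseq import (
    Contrast,
    call_degs,
    de_probability,
    noise_distribution,
    overlap_counts,
    run_contrast,
    signal_statistics,
    threshold_odds,
)

CONTRAST = Contrast("c1_vs_c2", ["a1", "a2"], ["b1", "b2"])


def tpm_frame(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["a1", "a2", "b1", "b2"]
    )


def brute_force_p1(signal: pd.DataFrame, noise_m, noise_d) -> pd.Series:
    """Independent double-loop exceedance count."""
    out = {}
    for gene, row in signal.iterrows():
        n = 0
        for m_star, d_star in zip(noise_m, noise_d):
            if m_star < abs(row["M"]) and d_star < abs(row["D"]):
                n += 1
        out[gene] = n / len(noise_m)
    return pd.Series(out)


def brute_force_noise(tpm: pd.DataFrame, contrast: Contrast, pseudo: float):
    """Exhaustive within-condition replicate-pair enumeration."""
    pairs = []
    for cond in (contrast.condition_1, contrast.condition_2):
        for a, b in combinations(cond, 2):
            for gene in tpm.index:
                x, y = tpm.loc[gene, a], tpm.loc[gene, b]
                xs, ys = (x or pseudo), (y or pseudo)
                pairs.append((abs(np.log2(xs / ys)), abs(x - y)))
    return pairs


class TestSignalStatistics:
    def test_identity(self):
        sig = signal_statistics(tpm_frame({"g": [10, 10, 10, 10]}), CONTRAST)
        assert sig.loc["g", "M"] == 0 and sig.loc["g", "D"] == 0

    def test_arithmetic(self):
        sig = signal_statistics(tpm_frame({"g": [40, 40, 10, 10]}), CONTRAST)
        assert sig.loc["g", "M"] == pytest.approx(2.0)
        assert sig.loc["g", "D"] == pytest.approx(30.0)

    def test_zero_mean_smoothed_only_in_ratio(self):
        sig = signal_statistics(tpm_frame({"g": [4, 4, 0, 0]}), CONTRAST, pseudo=0.5)
        assert sig.loc["g", "M"] == pytest.approx(np.log2(4 / 0.5))
        assert sig.loc["g", "D"] == pytest.approx(4.0)  # D on raw means

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        tpm = pd.DataFrame(rng.gamma(2, 50, size=(30, 4)), columns=["a1", "a2", "b1", "b2"])
        sig = signal_statistics(tpm, CONTRAST)
        x1 = tpm[["a1", "a2"]].mean(axis=1)
        x2 = tpm[["b1", "b2"]].mean(axis=1)
        np.testing.assert_allclose(sig["M"], np.log2(x1 / x2))
        np.testing.assert_allclose(sig["D"], (x1 - x2).abs())

    def test_absent_library_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            signal_statistics(tpm_frame({"g": [1, 2, 3, 4]}),
                              Contrast("bad", ["a1", "zz"], ["b1", "b2"]))


class TestNoiseDistribution:
    def test_identical_replicates_all_zero(self):
        tpm = tpm_frame({"g1": [5, 5, 9, 9], "g2": [1, 1, 2, 2]})
        m, d = noise_distribution(tpm, CONTRAST)
        assert (m == 0).all() and (d == 0).all()

    def test_pool_size_two_pairs_per_gene(self):
        tpm = tpm_frame({f"g{i}": [1, 2, 3, 4] for i in range(3)})
        m, d = noise_distribution(tpm, CONTRAST)
        assert len(m) == len(d) == 6

    def test_single_replicate_condition_named_in_error(self):
        tpm = tpm_frame({"g": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="condition_2"):
            noise_distribution(tpm, Contrast("x", ["a1", "a2"], ["b1"]))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        tpm = pd.DataFrame(rng.integers(0, 40, size=(5, 4)).astype(float),
                           columns=["a1", "a2", "b1", "b2"])
        m, d = noise_distribution(tpm, CONTRAST, pseudo=0.5)
        expected = brute_force_noise(tpm, CONTRAST, 0.5)
        got = sorted(zip(m, d))
        assert np.allclose(got, sorted(expected))


class TestDEProbability:
    def test_dominating_gene(self):
        signal = pd.DataFrame({"M": [10.0], "D": [1e6]}, index=["g"])
        p1 = de_probability(signal, (np.array([1.0, 2.0]), np.array([3.0, 4.0])))
        assert p1["g"] == 1.0

    def test_zero_signal_strict_inequality(self):
        signal = pd.DataFrame({"M": [0.0], "D": [0.0]}, index=["g"])
        p1 = de_probability(signal, (np.zeros(4), np.zeros(4)))
        assert p1["g"] == 0.0

    def test_empty_noise_rejected(self):
        signal = pd.DataFrame({"M": [1.0], "D": [1.0]})
        with pytest.raises(ValueError, match="noise"):
            de_probability(signal, (np.array([]), np.array([])))

    def test_twenty_gene_instance_matches_double_loop(self):
        rng = np.random.default_rng(11)
        tpm = pd.DataFrame(rng.gamma(1.5, 60, size=(20, 4)),
                           columns=["a1", "a2", "b1", "b2"])
        tpm.iloc[rng.integers(0, 20, 5), rng.integers(0, 4, 5)] = 0.0
        signal = signal_statistics(tpm, CONTRAST)
        noise = noise_distribution(tpm, CONTRAST)
        got = de_probability(signal, noise)
        expected = brute_force_p1(signal, *noise)
        np.testing.assert_array_equal(got.to_numpy(), expected.to_numpy())

    def test_monotone_in_m_and_d(self):
        rng = np.random.default_rng(13)
        noise = (rng.exponential(1, 100), rng.exponential(50, 100))
        base = pd.DataFrame({"M": [1.0], "D": [40.0]})
        p_base = de_probability(base, noise).iloc[0]
        for dm, dd in [(0.5, 0), (0, 20), (2, 100)]:
            grown = pd.DataFrame({"M": [1.0 + dm], "D": [40.0 + dd]})
            assert de_probability(grown, noise).iloc[0] >= p_base

    def test_gene_order_permutation(self):
        rng = np.random.default_rng(17)
        tpm = pd.DataFrame(rng.gamma(2, 30, size=(12, 4)),
                           columns=["a1", "a2", "b1", "b2"],
                           index=[f"g{i}" for i in range(12)])
        res = run_contrast(tpm, CONTRAST)
        perm = rng.permutation(12)
        res_perm = run_contrast(tpm.iloc[perm], CONTRAST)
        pd.testing.assert_frame_equal(
            res.table.sort_index(), res_perm.table.sort_index()
        )

    def test_condition_swap_negates_m_preserves_d_p1(self):
        rng = np.random.default_rng(19)
        tpm = pd.DataFrame(rng.gamma(2, 30, size=(15, 4)),
                           columns=["a1", "a2", "b1", "b2"])
        fwd = run_contrast(tpm, CONTRAST)
        rev = run_contrast(tpm, Contrast("swap", ["b1", "b2"], ["a1", "a2"]))
        np.testing.assert_allclose(fwd.table["M"], -rev.table["M"])
        np.testing.assert_allclose(fwd.table["D"], rev.table["D"])
        np.testing.assert_array_equal(fwd.table["P1"], rev.table["P1"])


class TestCalling:
    def make_result(self, p1, m):
        signal = pd.DataFrame({"mean_1": [1], "mean_2": [1], "M": [m], "D": [1.0]},
                              index=["g"])
        return call_degs(signal, pd.Series([p1], index=["g"]), CONTRAST)

    def test_fold_change_gate(self):
        assert not self.make_result(0.85, 0.5).table["significant"].iloc[0]

    def test_threshold_inclusive_and_direction(self):
        res = self.make_result(0.8, -1.2)
        row = res.table.iloc[0]
        assert row["significant"]
        assert row["direction"] == "up_in_condition_2"

    def test_flagged_genes_have_odds_at_least_four(self):
        rng = np.random.default_rng(23)
        tpm = pd.DataFrame(rng.gamma(1, 100, size=(200, 4)),
                           columns=["a1", "a2", "b1", "b2"])
        res = run_contrast(tpm, CONTRAST)
        sig = res.table[res.table["significant"]]
        if len(sig):
            odds = sig["P1"] / sig["P0"]
            assert (odds >= threshold_odds(0.8) - 1e-9).all()

    def test_threshold_odds_value(self):
        assert threshold_odds(0.8) == pytest.approx(4.0)


class TestOverlapCounts:
    def test_inclusion_exclusion(self):
        sets = {"A": {1, 2, 3, 4}, "B": {3, 4, 5}, "C": {4, 6}}
        table = overlap_counts(sets)
        assert table["n_genes"].sum() == len({1, 2, 3, 4, 5, 6})
        assert table.attrs["union_size"] == 6
        # region (A and B and C) = {4}
        triple = table[(table["A"] == 1) & (table["B"] == 1) & (table["C"] == 1)]
        assert triple["n_genes"].iloc[0] == 1
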