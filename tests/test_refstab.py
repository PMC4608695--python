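import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circaqpcr.refstab import (genorm, genorm_m_values,
                               genorm_pairwise_variation, genorm_rank,
                               normfinder_stability, recommended_gene_count)


def frame(arrays: dict) -> pd.DataFrame:
    return pd.DataFrame(arrays, index=[f"s{i}" for i in
                                       range(len(next(iter(arrays.values()))))])


def m_values_oracle(df: pd.DataFrame) -> dict:
    """Direct recomputation of geNorm M: mean sd of pairwise log2 ratios."""
    out = {}
    for g in df.columns:
        sds = [np.std(np.log2(df[g] / df[k]), ddof=1)
               for k in df.columns if k != g]
        out[g] = float(np.mean(sds))
    return out


class TestGenormM:
    def test_constant_ratio_pair_has_zero_m(self):
        q = frame({"a": [1.0, 2.0, 4.0], "b": [2.0, 4.0, 8.0]})
        m = genorm_m_values(q)
        assert m["a"] == pytest.approx(0.0, abs=1e-12)
        assert m["b"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        q = frame({g: rng.lognormal(0, 0.3, 4) for g in "abc"})
        m = genorm_m_values(q)
        for g, expect in m_values_oracle(q).items():
            assert m[g] == pytest.approx(expect, abs=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_per_sample_scaling_invariance(self, scale):
        rng = np.random.default_rng(4)
        q = frame({g: rng.lognormal(0, 0.3, 5) for g in "abcd"})
        scaled = q.copy()
        scaled.iloc[2] *= scale
        assert np.allclose(genorm_m_values(q), genorm_m_values(scaled))

    def test_nonpositive_quantity_rejected(self):
        with pytest.raises(ValueError):
            genorm_m_values(frame({"a": [1.0, -1.0], "b": [1.0, 2.0]}))


class TestGenormRank:
    def test_proportional_pair_survives_to_the_end(self):
        rng = np.random.default_rng(5)
        q = frame({"noisy": rng.lognormal(0, 1.0, 6),
                   "p1": rng.lognormal(0, 0.05, 6)})
        q["p2"] = q["p1"] * 3.0
        ranking = genorm_rank(q)
        assert set(ranking[:2]) == {"p1", "p2"}

    def test_tie_broken_by_removing_lexicographically_last(self):
        # b and c tie for the highest M by symmetric construction
        q = frame({"a": [1.0, 1.0], "b": [1.0, 2.0], "c": [2.0, 1.0]})
        m = genorm_m_values(q)
        assert m["b"] == pytest.approx(m["c"])
        assert genorm_rank(q) == ["a", "b", "c"]

    def test_final_pair_shares_m_equal_to_sd_of_log_ratio(self):
        rng = np.random.default_rng(6)
        q = frame({g: rng.lognormal(0, 0.4, 8) for g in "abcd"})
        best = genorm_rank(q)[:2]
        m = genorm_m_values(q[best])
        sd = np.std(np.log2(q[best[0]] / q[best[1]]), ddof=1)
        assert m[best[0]] == pytest.approx(m[best[1]]) == pytest.approx(sd)


class TestPairwiseVariation:
    def test_redundant_gene_gives_zero_v(self):
        rng = np.random.default_rng(7)
        q = frame({"a": rng.lognormal(0, 0.2, 5),
                   "b": rng.lognormal(0, 0.2, 5)})
        q["c"] = np.sqrt(q["a"] * q["b"])      # proportional to NF_2
        series, _ = genorm_pairwise_variation(q, ["a", "b", "c"])
        assert series[0][0] == 2
        assert series[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_computation(self):
        rng = np.random.default_rng(9)
        q = frame({g: rng.lognormal(0, 0.3, 5) for g in "abcd"})
        ranking = genorm_rank(q)
        series, _ = genorm_pairwise_variation(q, ranking)
        for n, v in series:                    # direct NF-ratio oracle
            nf_n = q[ranking[:n]].prod(axis=1) ** (1.0 / n)
            nf_n1 = q[ranking[:n + 1]].prod(axis=1) ** (1.0 / (n + 1))
            expect = np.std(np.log2(nf_n / nf_n1), ddof=1)
            assert v == pytest.approx(float(expect), abs=1e-10)

    def test_two_reference_genes_suffice_below_cutoff(self):
        # decision rule: V2/3 = 0.069 < 0.15 -> two genes are enough
        series = [(2, 0.069), (3, 0.08), (4, 0.1), (5, 0.12), (6, 0.13), (7, 0.14)]
        assert recommended_gene_count(series, 0.15, 8) == 2

    def test_no_v_below_cutoff_recommends_k_minus_one(self):
        series = [(2, 0.3), (3, 0.25)]
        assert recommended_gene_count(series, 0.15, 4) == 3

    def test_noiseless_proportional_panel_all_zero(self):
        base = np.array([1.0, 2.0, 0.5, 4.0])
        q = frame({"a": base, "b": 2 * base, "c": 0.5 * base, "d": base})
        res = genorm(q)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for _, v in res.pairwise_variation)
        assert all(m == pytest.approx(0.0, abs=1e-12)
                   for m in res.m_values.values())


class TestNormfinder:
    def _panel(self, rng, n=12, extra=None):
        cols = {g: rng.lognormal(0, s, n)
                for g, s in (("u", 0.3), ("v", 0.4), ("w", 0.5))}
        if extra is not None:
            cols["perfect"] = extra
        return frame(cols)

    def test_perfect_gene_attains_minimum_stability(self):
        rng = np.random.default_rng(10)
        q = self._panel(rng, extra=np.ones(12))
        groups = pd.Series(["g1"] * 6 + ["g2"] * 6, index=q.index)
        res = normfinder_stability(q, groups=groups)
        assert res.best_gene == "perfect"
        assert res.stability["perfect"] == min(res.stability.values())

    def test_global_per_sample_shift_invariance(self):
        rng = np.random.default_rng(11)
        q = self._panel(rng)
        groups = pd.Series(["g1"] * 6 + ["g2"] * 6, index=q.index)
        base = normfinder_stability(q, groups=groups)
        shifted = q.mul(np.exp(rng.normal(0, 1, len(q))), axis=0)
        res = normfinder_stability(shifted, groups=groups)
        for g in q.columns:
            assert res.stability[g] == pytest.approx(base.stability[g])

    def test_groupless_mode_scores_residual_sd(self):
        rng = np.random.default_rng(13)
        q = self._panel(rng, n=60)
        res = normfinder_stability(q, groups=None)
        assert res.groups_used == []
        # ordering follows the generating noise sds
        assert sorted(res.stability, key=res.stability.get) == ["u", "v", "w"]

    def test_small_group_is_named_in_error(self):
        rng = np.random.default_rng(14)
        q = self._panel(rng, n=5)
        groups = pd.Series(["g1"] * 4 + ["g2"], index=q.index)
        with pytest.raises(ValueError, match="g2"):
            normfinder_stability(q, groups=groups)

    def test_opposing_group_bias_pair_beats_singles(self):
        # two genes with opposite group deviations average out: their pair
        # should be preferred over any pair containing the biased singles
        rng = np.random.default_rng(15)
        n = 20
        groups = pd.Series(["g1"] * (n // 2) + ["g2"] * (n // 2))
        bias = np.where(groups == "g1", 1.25, 0.8)
        q = frame({
            "up": rng.lognormal(0, 0.05, n) * bias,
            "down": rng.lognormal(0, 0.05, n) / bias,
            "noisy": rng.lognormal(0, 0.6, n),
        })
        groups.index = q.index
        res = normfinder_stability(q, groups=groups)
        assert res.best_pair == ("down", "up")
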