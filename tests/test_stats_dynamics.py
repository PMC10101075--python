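"""Statistical engine: exactness, FDR control, and the filter rules."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stravir import stats_dynamics as stats


# ---------------------------------------------------------------- oracles
def mw_u(x, y):
    """U statistic of x over y (mid-rank convention, brute force)."""
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def mw_exact_p_enumeration(x, y):
    """Two-sided exact p by enumerating every C(n, nx) group labeling."""
    pooled = list(x) + list(y)
    nx = len(x)
    obs = mw_u(x, y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), nx):
        cset = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in cset]
        us.append(mw_u(xs, ys))
    us = np.array(us)
    lo = np.mean(us <= obs + 1e-12)
    hi = np.mean(us >= obs - 1e-12)
    return min(1.0, 2 * min(lo, hi))


def bh_step_up(pvalues):
    """Literal step-up rule, written independently of the implementation."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [None] * m
    best = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, m * pvalues[i] / rank)
        q[i] = min(best, 1.0)
    return q


# ---------------------------------------------------------------- MW tests
class TestMannWhitney:
    def test_worked_example_u_zero_p_point_one(self):
        res = stats.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_multisets_p_one(self):
        res = stats.mann_whitney_u([1, 2, 3], [3, 1, 2])
        assert res.p == pytest.approx(1.0)

    def test_degenerate_constant_groups_flagged(self):
        res = stats.mann_whitney_u([5, 5, 5], [5, 5])
        assert res.p == 1.0 and res.method == "degenerate"

    def test_exact_matches_enumeration_all_small_splits(self):
        """Exact p equals full enumeration for tie-free inputs, every split
        with n_x + n_y <= 12."""
        rng = np.random.default_rng(0)
        for n in range(2, 13):
            for nx in range(1, n):
                vals = rng.permutation(rng.normal(size=n) * 10)
                if len(np.unique(vals)) < n:  # pragma: no cover
                    continue
                x, y = vals[:nx].tolist(), vals[nx:].tolist()
                res = stats.mann_whitney_u(x, y)
                assert res.method == "exact"
                assert res.p == pytest.approx(mw_exact_p_enumeration(x, y),
                                              abs=1e-12), (n, nx)

    def test_large_sample_null_rejection_rate(self):
        """11 vs 13 lognormal null: asymptotic rejection rate near alpha."""
        rng = np.random.default_rng(1)
        rejected = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.lognormal(0, 0.4, 11)
            y = rng.lognormal(0, 0.4, 13)
            if stats.mann_whitney_u(x, y).p < 0.05:
                rejected += 1
        assert 0.02 * n_rep <= rejected <= 0.09 * n_rep

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_u([], [1, 2])


# ---------------------------------------------------------------- BH tests
class TestBhFdr:
    def test_worked_example_all_q_004(self):
        q = stats.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert stats.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_matches_independent_step_up_rule(self, pvals):
        assert np.allclose(stats.bh_fdr(pvals), bh_step_up(pvals), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=25), st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariance_and_monotonicity(self, pvals, rnd):
        q = stats.bh_fdr(pvals)
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q_perm = stats.bh_fdr([pvals[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm, atol=1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(stats.bh_fdr(p), q_sm, atol=1e-12)


# ---------------------------------------------------------------- Spearman
class TestSpearman:
    def test_monotone_vectors(self):
        assert stats.spearman_rho([1, 2, 3], [10, 20, 30]).rho == \
            pytest.approx(1.0)
        assert stats.spearman_rho([1, 2, 3, 4], [9, 7, 5, 3]).rho == \
            pytest.approx(-1.0)

    def test_worked_example_rho_08(self):
        res = stats.spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8, abs=1e-12)
        assert res.method == "exact"

    def test_exact_p_matches_permutation_oracle(self):
        """Exact p equals brute-force enumeration via rank correlation."""
        x = [1, 2, 3, 4, 5, 6]
        y = [3, 1, 2, 6, 4, 5]
        res = stats.spearman_rho(x, y)
        rx = np.argsort(np.argsort(x)) + 1.0
        obs = abs(np.corrcoef(rx, np.argsort(np.argsort(y)) + 1.0)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            r = abs(np.corrcoef(rx, np.array(perm) + 1.0)[0, 1])
            count += r >= obs - 1e-12
            total += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_constant_vector_not_available(self):
        res = stats.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.rho) and res.method == "not-available"

    @given(st.lists(st.integers(min_value=-50, max_value=50), min_size=4,
                    max_size=12, unique=True))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_strictly_monotone_transform(self, xs):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        ys = rng.normal(size=len(xs))
        r1 = stats.spearman_rho(xs, ys)
        r2 = stats.spearman_rho([math.exp(0.1 * v) for v in xs], ys)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-9)
        assert r1.p == pytest.approx(r2.p, abs=1e-9)


# ---------------------------------------------------------- phase compare
def _meta(n_ap=4, n_rp=4, easi_ap=20.0):
    phases = ["AP"] * n_ap + ["RP"] * n_rp
    return pd.DataFrame(
        dict(day=range(1, n_ap + n_rp + 1), phase=phases,
             easi=[easi_ap if p == "AP" else 0.5 for p in phases]),
        index=[f"S{i}" for i in range(n_ap + n_rp)])


class TestComparePhaseGroups:
    def test_planted_effect_detected_with_direction(self):
        rng = np.random.default_rng(3)
        meta = _meta(11, 13)
        base = rng.lognormal(0, 0.4, size=(24, 10))
        base[meta["phase"] == "RP", 0] *= 5  # feature 0 up in RP
        table = pd.DataFrame(base, index=meta.index,
                             columns=[f"f{i}" for i in range(10)])
        res = stats.compare_phase_groups(table, meta)
        top = res.set_index("feature").loc["f0"]
        assert top["significant"]
        assert top["direction"] == "up_RP"

    def test_all_zero_features_excluded_and_counted(self):
        meta = _meta(3, 3)
        table = pd.DataFrame({"live": [1, 2, 3, 4, 5, 6],
                              "dead": [0] * 6}, index=meta.index)
        res = stats.compare_phase_groups(table, meta)
        assert res["feature"].tolist() == ["live"]
        assert res.attrs["n_excluded"] == 1

    def test_single_sample_phase_rejected(self):
        meta = _meta(1, 5)
        table = pd.DataFrame({"f": range(6)}, index=meta.index)
        with pytest.raises(ValueError, match="phase"):
            stats.compare_phase_groups(table, meta)


class TestEasiCorrelation:
    def test_feature_equal_to_easi_passes(self):
        meta = _meta(4, 4)
        table = pd.DataFrame({"same": meta["easi"].to_numpy(),
                              "anti": -meta["easi"].to_numpy()},
                             index=meta.index)
        res = stats.easi_correlation(table, meta).set_index("feature")
        assert res.loc["same", "rho"] == pytest.approx(1.0)
        assert bool(res.loc["same", "passes_threshold"])
        assert res.loc["anti", "rho"] == pytest.approx(-1.0)
        assert bool(res.loc["anti", "passes_threshold"])

    def test_null_feature_rarely_passes_joint_threshold(self):
        """Independent feature, n=24: the |rho|>0.5 & p<0.01 rule passes
        at most ~2% of the time."""
        rng = np.random.default_rng(4)
        meta = _meta(11, 13)
        passes = 0
        n_rep = 200
        for _ in range(n_rep):
            table = pd.DataFrame({"f": rng.normal(size=24)}, index=meta.index)
            res = stats.easi_correlation(table, meta)
            passes += int(res["passes_threshold"].iloc[0])
        assert passes <= 0.02 * n_rep + 2

    def test_constant_easi_all_not_available(self):
        meta = _meta(4, 4, easi_ap=0.5)
        table = pd.DataFrame({"f": range(8)}, index=meta.index)
        res = stats.easi_correlation(table, meta)
        assert (res["method"] == "not-available").all()


class TestFldAdjacency:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "contig", "gene_index",
                                           "family"])

    def test_adjacent_pair_retained(self):
        genes = self._genes([("g7", "c1", 7, "fldB"), ("g8", "c1", 8, "fldC")])
        res = stats.fld_adjacency_filter(genes)
        assert len(res) == 1
        assert res.iloc[0]["fldB_gene"] == "g7"

    def test_different_contigs_dropped(self):
        genes = self._genes([("g1", "c1", 3, "fldB"), ("g2", "c2", 4, "fldC")])
        assert len(stats.fld_adjacency_filter(genes)) == 0

    def test_distant_pair_dropped(self):
        genes = self._genes([("g1", "c1", 3, "fldB"), ("g2", "c1", 6, "fldC")])
        assert len(stats.fld_adjacency_filter(genes)) == 0


class TestIncrementAnalysis:
    def _tables(self, inc_hc, inc_ad, n_hc=24, n_ad=14, seed=5):
        rng = np.random.default_rng(seed)
        subjects = [f"hc{i}" for i in range(n_hc)] + \
            [f"ad{i}" for i in range(n_ad)]
        groups = {s: ("HC" if s.startswith("hc") else "AD") for s in subjects}
        t1 = pd.DataFrame({"lytic": rng.lognormal(0, 0.3, len(subjects))},
                          index=subjects)
        t2 = t1.copy()
        t2.loc[[s for s in subjects if s.startswith("hc")], "lytic"] += inc_hc
        t2.loc[[s for s in subjects if s.startswith("ad")], "lytic"] += inc_ad
        return t1, t2, groups

    def test_positive_hc_increments_detected(self):
        t1, t2, groups = self._tables(inc_hc=1.0, inc_ad=0.0)
        res = stats.increment_analysis(t1, t2, groups)
        row = res.iloc[0]
        assert row["between_p"] < 0.05
        assert row["direction"] == "higher_HC"

    def test_identical_timepoints_degenerate(self):
        t1, t2, groups = self._tables(inc_hc=0.0, inc_ad=0.0)
        res = stats.increment_analysis(t1, t2, groups)
        assert res.iloc[0]["between_p"] == 1.0
        assert res.iloc[0]["within_HC_paired_p"] == 1.0

    def test_unmatched_subject_named(self):
        t1, t2, groups = self._tables(inc_hc=1.0, inc_ad=0.0)
        with pytest.raises(ValueError, match="hc0"):
            stats.increment_analysis(t1.drop(index="hc0"), t2, groups)

    def test_within_group_power_hc_only_effect(self):
        """A 2-fold HC-only rise is significant within HC but not within AD
        in >= 90% of replicates."""
        hits_hc = hits_ad = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            subjects = [f"hc{i}" for i in range(14)] + \
                [f"ad{i}" for i in range(14)]
            groups = {s: ("HC" if s.startswith("hc") else "AD")
                      for s in subjects}
            t1 = pd.DataFrame({"f": rng.lognormal(0, 0.3, 28)}, index=subjects)
            t2 = pd.DataFrame({"f": rng.lognormal(0, 0.3, 28)}, index=subjects)
            hc = [s for s in subjects if s.startswith("hc")]
            t2.loc[hc, "f"] *= 2.0
            res = stats.increment_analysis(t1, t2, groups).iloc[0]
            hits_hc += res["within_HC_unpaired_p"] < 0.05
            hits_ad += res["within_AD_unpaired_p"] < 0.05
        assert hits_hc >= 90
        assert hits_ad <= 20
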