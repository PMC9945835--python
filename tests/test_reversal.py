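"""Concordant-reversal detection, outlier-sum, K-S significance and BH adjustment."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_reference
from screpurpose.reference import ReferenceInstance
from screpurpose.reversal import (
    bh_adjust,
    detect_cegs,
    instance_score,
    ks_two_sample,
    outlier_sum,
    rank_product_p,
    score_cluster,
    read_cluster_results,
    write_cluster_results,
)
from screpurpose.signatures import ClusterSignature, filter_significant, to_rank_list
from screpurpose.synthetic import SyntheticConfig, generate_case_study, generate_reference


class TestRankProductP:
    def test_boundary_is_one(self):
        assert rank_product_p(100, 100, 100) == 1.0

    def test_extreme_corner_closed_form(self):
        # r = 1e-4; closed form r(1 - ln r) = 1e-4 (1 + ln 1e4)
        expected = 1e-4 * (1 + math.log(1e4))
        assert rank_product_p(1, 1, 100) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.0210e-3, abs=1e-6)

    def test_monotone_in_each_rank(self):
        G = 50
        vals = [rank_product_p(u, 7, G) for u in range(1, G + 1)]
        assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))
        vals = [rank_product_p(13, v, G) for v in range(1, G + 1)]
        assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="rank out of range"):
            rank_product_p(0, 1, 10)


def make_instance(ranks: dict) -> ReferenceInstance:
    return ReferenceInstance("i1", "DA", "CL", "t", ranks)


def uniform_signature(n, sig_up=(), sig_down=()):
    """Signature over G1..Gn with logFC descending in index order."""
    genes = [f"G{i + 1:03d}" for i in range(n)]
    lfc = np.linspace(3, -3, n)
    adj = np.array(
        [0.01 if g in set(sig_up) | set(sig_down) else 0.5 for g in genes]
    )
    for i, g in enumerate(genes):
        if g in sig_down:
            lfc[i] = -abs(lfc[i]) - 0.1
    return ClusterSignature(
        "C1", 10,
        pd.DataFrame({"gene": genes, "logFC": lfc, "p": adj / 2, "adj_p": adj}),
    )


class TestDetectCegs:
    def test_fully_reversed_top_gene_called(self):
        n = 100
        sig = uniform_signature(n, sig_up=["G001"])
        rl = to_rank_list(sig, [f"G{i + 1:03d}" for i in range(n)])
        # drug puts G001 at the very bottom (rank G) -> opposite-tail rank v=1
        ranks = {f"G{i + 1:03d}": i + 1 for i in range(n)}
        ranks["G001"], ranks[f"G{n:03d}"] = n, 1
        calls = detect_cegs(rl, filter_significant(sig), make_instance(ranks))
        assert [c.gene for c in calls] == ["G001"]
        assert calls[0].direction == "disease-up-drug-down"
        assert calls[0].rank_product_p == pytest.approx(1e-4 * (1 + math.log(1e4)))

    def test_mid_rank_same_direction_not_called(self):
        # disease-up gene that the drug also up-regulates: v = G, u = 50 of 100
        p = rank_product_p(50, 100, 100)
        assert p == pytest.approx(0.5 * (1 - math.log(0.5)), rel=1e-12)
        assert p > 0.05  # 0.847: never a reversal call

    def test_empty_significant_sets(self):
        sig = uniform_signature(10)
        rl = to_rank_list(sig, [f"G{i + 1:03d}" for i in range(10)])
        inst = make_instance({f"G{i + 1:03d}": i + 1 for i in range(10)})
        assert detect_cegs(rl, (set(), set()), inst) == []


class TestInstanceScore:
    def test_empty_is_zero(self):
        assert instance_score([]) == 0.0

    def test_exact_logs(self):
        from screpurpose.reversal import CegCall

        cegs = [CegCall("G1", "disease-up-drug-down", 0.01),
                CegCall("G2", "disease-down-drug-up", 0.001)]
        assert instance_score(cegs) == pytest.approx(5.0)

    def test_strictly_increasing(self):
        from screpurpose.reversal import CegCall

        cegs = [CegCall("G1", "disease-up-drug-down", 0.01)]
        more = cegs + [CegCall("G2", "disease-up-drug-down", 0.04)]
        assert instance_score(more) > instance_score(cegs)


class TestOutlierSum:
    def test_degenerate_equal_scores(self):
        scores = {f"i{k}": 2.0 for k in range(6)}
        idx = {"DA": ["i0", "i1"], "DB": ["i2", "i3"], "DC": ["i4", "i5"]}
        assert outlier_sum(scores, idx) == {"DA": 0.0, "DB": 0.0, "DC": 0.0}

    def test_hand_worked_example(self):
        # scores 1,2,3,4,100: median 3, MAD 1, standardized (-2,-1,0,1,97),
        # q75 = 1, IQR = 2, threshold 3 -> only the 97 exceeds it
        scores = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 100.0}
        idx = {"DA": ["a", "b", "c", "d"], "DD": ["e"]}
        os = outlier_sum(scores, idx)
        assert os["DD"] == pytest.approx(97.0)
        assert os["DA"] == 0.0

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.exponential(2.0, size=12)
        scores = {f"i{k}": float(v) for k, v in enumerate(vals)}
        shifted = {k: v + 17.3 for k, v in scores.items()}
        idx = {"DA": [f"i{k}" for k in range(6)], "DB": [f"i{k}" for k in range(6, 12)]}
        a, b = outlier_sum(scores, idx), outlier_sum(shifted, idx)
        for d in idx:
            assert a[d] == pytest.approx(b[d], abs=1e-9)

    def test_mad_zero_fallback_to_mean_absolute_deviation(self):
        # majority at one value -> MAD 0, mean abs deviation > 0
        scores = {"a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0, "e": 10.0}
        idx = {"DA": ["a", "b", "c", "d"], "DB": ["e"]}
        os = outlier_sum(scores, idx)
        assert os["DB"] > 0.0


def ks_enumeration_oracle(x, y, alternative):
    """Brute force: D over every assignment of labels to the pooled values."""
    def stat(a, b):
        grid = np.unique(np.concatenate([a, b]))
        fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        return max(0.0, (fb - fa).max()) if alternative == "greater" else np.abs(fa - fb).max()

    pooled = np.concatenate([x, y])
    d_obs = stat(np.asarray(x, float), np.asarray(y, float))
    hits = total = 0
    for idx in combinations(range(len(pooled)), len(x)):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        if stat(pooled[sel], pooled[~sel]) >= d_obs - 1e-12:
            hits += 1
        total += 1
    return d_obs, hits / total


class TestKSTwoSample:
    def test_identical_samples_null(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_complete_separation_exact(self):
        d, p = ks_two_sample([3.0, 4.0], [1.0, 2.0])
        assert d == 1.0
        assert p == pytest.approx(1 / 6)  # one of C(4,2)=6 assignments

    def test_order_invariance(self):
        a = ks_two_sample([4.0, 3.0, 7.0], [1.0, 2.0, 2.5])
        b = ks_two_sample([7.0, 4.0, 3.0], [1.0, 2.0, 2.5])
        assert a == b

    @pytest.mark.parametrize("alternative", ["greater", "two-sided"])
    def test_matches_enumeration_for_all_small_sizes(self, alternative):
        rng = np.random.default_rng(9)
        for n in range(1, 10):
            for m in range(1, 11 - n):
                x = rng.normal(0.5, 1, n)
                y = rng.normal(0.0, 1, m)
                d, p = ks_two_sample(x, y, alternative=alternative)
                d0, p0 = ks_enumeration_oracle(x, y, alternative)
                assert d == pytest.approx(d0, abs=1e-12)
                assert p == pytest.approx(p0, abs=1e-12)

    def test_tied_data_matches_enumeration(self):
        x = [0.0, 0.0, 2.0]
        y = [0.0, 1.0, 2.0, 2.0]
        for alt in ["greater", "two-sided"]:
            d, p = ks_two_sample(x, y, alternative=alt)
            d0, p0 = ks_enumeration_oracle(x, y, alt)
            assert (d, p) == pytest.approx((d0, p0), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty sample"):
            ks_two_sample([], [1.0])


def bh_oracle(p):
    """Step-up definition applied literally."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj


class TestBHAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(bh_oracle(pvals), abs=1e-12)


@pytest.fixture(scope="module")
def planted_run():
    cfg = SyntheticConfig(seed=2, n_drugs=20, n_genes=500,
                          planted={"D001": ("C1", "C2", "C3")})
    _, sigs = generate_case_study(cfg)
    ref = generate_reference(cfg)
    return cfg, sigs, ref


class TestScoreCluster:
    def test_single_drug_reference_fdr_equals_ks_p(self, small_reference):
        # restrict to one drug: BH with m=1 leaves the p untouched
        sub_meta = small_reference.meta[small_reference.meta["drug"] == "D1"]
        from screpurpose.reference import DrugReference

        cols = [list(small_reference.meta["instance_id"]).index(i)
                for i in sub_meta["instance_id"]]
        ref1 = DrugReference(small_reference.universe,
                             small_reference.rank_matrix[:, cols], sub_meta)
        sig = uniform_signature(20, sig_up=["G001"], sig_down=["G020"])
        sig = ClusterSignature("C1", 10, sig.table.assign(
            gene=[f"G{i + 1}" for i in range(20)]))
        res = score_cluster(sig, ref1)
        assert len(res) == 1
        assert res[0].fdr == res[0].ks_p

    def test_planted_drug_attains_minimum_ks_p(self, planted_run):
        cfg, sigs, ref = planted_run
        res = score_cluster(sigs[0], ref)
        best = min(res, key=lambda r: r.ks_p)
        assert best.drug == "D001"

    def test_empty_signature_rejected(self, small_reference):
        sig = uniform_signature(20)
        sig = ClusterSignature("C1", 10, sig.table.assign(
            gene=[f"G{i + 1}" for i in range(20)]))
        with pytest.raises(ValueError, match="empty signature"):
            score_cluster(sig, small_reference)

    def test_disjoint_universe_rejected(self, small_reference):
        sig = uniform_signature(5, sig_up=["G001"])
        sig = ClusterSignature("C1", 10, sig.table.assign(
            gene=[f"X{i}" for i in range(5)]))
        with pytest.raises(ValueError, match="disjoint"):
            score_cluster(sig, small_reference)

    def test_counts_invariants(self, planted_run):
        cfg, sigs, ref = planted_run
        for res in score_cluster(sigs[1], ref):
            assert 0 <= res.n_reversed <= res.n_diseased
            assert res.fdr >= res.ks_p - 1e-15
            assert res.os_stat >= 0.0

    def test_matches_per_instance_detect_cegs(self, planted_run):
        """The vectorized path must agree with the per-instance CEG API."""
        cfg, sigs, ref = planted_run
        sig = sigs[0]
        up, down = filter_significant(sig)
        rl = to_rank_list(sig, ref.universe)
        res = {r.drug: r for r in score_cluster(sig, ref)}
        # recompute one drug's reversed-gene count by hand
        for drug in ["D001", "D007"]:
            cols = ref.drug_columns(drug)
            gene_hits = {}
            for j in cols:
                inst = ref.instance(j)
                for c in detect_cegs(rl, (up, down), inst):
                    gene_hits[c.gene] = gene_hits.get(c.gene, 0) + 1
            n_rev = sum(1 for g, h in gene_hits.items() if h / len(cols) >= 0.5)
            assert res[drug].n_reversed == n_rev

    def test_strengthening_reversal_never_decreases_os(self):
        """Moving significant genes deeper into the drug's opposite tail."""
        aucs = []
        for strength in [0.3, 0.6, 0.9]:
            cfg = SyntheticConfig(seed=4, n_drugs=20, n_genes=500,
                                  reversal_strength=strength,
                                  planted={"D001": ("C1",)})
            _, sigs = generate_case_study(cfg)
            ref = generate_reference(cfg)
            res = {r.drug: r for r in score_cluster(sigs[0], ref)}
            aucs.append(res["D001"].os_stat)
        assert aucs[0] <= aucs[1] <= aucs[2]


def test_cluster_results_roundtrip(tmp_path, planted_run):
    cfg, sigs, ref = planted_run
    res = score_cluster(sigs[0], ref)
    path = tmp_path / "results.tsv"
    write_cluster_results(res, path)
    again = read_cluster_results(path)
    assert len(again) == len(res)
    for a, b in zip(again, res):
        assert a.drug == b.drug and a.cluster_id == b.cluster_id
        assert a.os_stat == pytest.approx(b.os_stat, rel=1e-12)
        assert a.ks_p == pytest.approx(b.ks_p, rel=1e-12)
        assert (a.n_reversed, a.n_diseased, a.n_instances) == (
            b.n_reversed, b.n_diseased, b.n_instances
        )
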