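"""Fisher/overlap enrichment, regulatory-domain linking, GAM de-bias, GSEA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import spearmanr

from sexewas import enrichment as enr


def _hypergeom_two_sided(a, b, c, d):
    """Exact two-sided Fisher P by enumerating all tables with fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {x: stats.hypergeom.pmf(x, n, col1, row1) for x in range(lo, hi + 1)}
    pa = probs[a]
    return sum(p for p in probs.values() if p <= pa * (1 + 1e-9))


class TestFisherEnrichment:
    def test_proportional_foreground_is_null(self):
        ann = pd.Series(["island"] * 50 + ["opensea"] * 50,
                        index=[f"p{i}" for i in range(100)])
        fg = [f"p{i}" for i in range(5)] + [f"p{i}" for i in range(50, 55)]
        out = enr.fisher_enrichment(fg, ann.index, ann)
        assert out.loc["island", "OR"] == pytest.approx(1.0)
        assert out.loc["island", "p"] == pytest.approx(1.0)

    def test_worked_table_or_14(self):
        ann = pd.Series(["x"] * 28 + ["y"] * 72, index=range(100))
        fg = list(range(8)) + list(range(28, 30))
        out = enr.fisher_enrichment(fg, list(range(100)), ann)
        assert out.loc["x", "OR"] == pytest.approx(14.0)
        assert out.loc["x", "p"] == pytest.approx(_hypergeom_two_sided(8, 2, 20, 70), rel=1e-9)

    def test_matches_enumeration_small_margins(self, rng):
        """Two-sided P equals exact hypergeometric enumeration, margins <= 30."""
        for _ in range(30):
            a, b, c, d = rng.integers(0, 15, 4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            ids = list(range(a + b + c + d))
            cat = pd.Series(["in"] * (a) + ["out"] * b + ["in"] * c + ["out"] * d,
                            index=ids)
            fg = ids[:a + b]
            out = enr.fisher_enrichment(fg, ids, cat)
            assert out.loc["in", "p"] == pytest.approx(
                _hypergeom_two_sided(a, b, c, d), rel=1e-7)

    def test_foreground_not_subset_rejected(self):
        ann = pd.Series({"a": "x"})
        with pytest.raises(ValueError):
            enr.fisher_enrichment(["z"], ["a"], ann)


class TestRegionOverlap:
    def _universe(self, n=20):
        return pd.DataFrame({"chr": "chr1",
                             "start": np.arange(n) * 1000,
                             "end": np.arange(n) * 1000 + 100},
                            index=[f"r{i}" for i in range(n)])

    def test_db_matching_exactly_fg(self):
        uni = self._universe()
        fg = [f"r{i}" for i in range(5)]
        db = {"set1": pd.DataFrame({"chr": "chr1",
                                    "start": np.arange(5) * 1000,
                                    "end": np.arange(5) * 1000 + 50})}
        out = enr.region_overlap_enrichment(fg, uni, db)
        # P equals the hypergeometric point mass 1/C(20,5)
        from math import comb
        assert out.loc["set1", "p"] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_covering_db_gives_na(self):
        uni = self._universe(6)
        db = {"all": pd.DataFrame({"chr": ["chr1"], "start": [0], "end": [10**7]})}
        out = enr.region_overlap_enrichment(["r0"], uni, db)
        assert np.isnan(out.loc["all", "OR"])

    def test_touching_boundary_is_not_overlap(self):
        uni = pd.DataFrame({"chr": ["chr1"], "start": [100], "end": [200]},
                           index=["r0"])
        db = {"s": pd.DataFrame({"chr": ["chr1"], "start": [200], "end": [300]})}
        assert not enr._any_overlap(uni, db["s"])[0]
        db2 = {"s": pd.DataFrame({"chr": ["chr1"], "start": [199], "end": [300]})}
        assert enr._any_overlap(uni, db2["s"])[0]


class TestGreatAssign:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["chr", "tss", "strand"],
                            index=pd.Index([f"G{i}" for i in range(len(rows))],
                                           name="gene"))

    def test_basal_domain_link_and_signed_distance(self):
        gm = self._genes([("chr1", 10_000, "+")])
        feats = pd.DataFrame({"chr": ["chr1"], "pos": [8_000]}, index=["c1"])
        out = enr.great_assign(feats, gm)
        assert len(out) == 1 and out.iloc[0]["distance"] == -2_000

    def test_minus_strand_distance_sign(self):
        gm = self._genes([("chr1", 10_000, "-")])
        feats = pd.DataFrame({"chr": ["chr1"], "pos": [12_000]}, index=["c1"])
        out = enr.great_assign(feats, gm)
        assert out.iloc[0]["distance"] == -2_000  # upstream of a minus-strand TSS

    def test_feature_beyond_cap_unlinked(self):
        gm = self._genes([("chr1", 10_000, "+")])
        feats = pd.DataFrame({"chr": ["chr1"], "pos": [2_010_001]}, index=["c1"])
        assert len(enr.great_assign(feats, gm)) == 0

    def test_extension_stops_at_neighbor_basal_domain(self):
        gm = self._genes([("chr1", 100_000, "+"), ("chr1", 200_000, "+")])
        # feature between the two genes but inside only the upstream extension
        feats = pd.DataFrame({"chr": ["chr1"], "pos": [150_000]}, index=["c1"])
        out = enr.great_assign(feats, gm)
        assert sorted(out["gene"]) == ["G0", "G1"]
        # a feature inside G1's basal domain links to G1 and not G0
        feats2 = pd.DataFrame({"chr": ["chr1"], "pos": [196_000]}, index=["c2"])
        out2 = enr.great_assign(feats2, gm)
        assert sorted(out2["gene"]) == ["G1"]

    def test_matches_brute_force_interval_scan(self, rng):
        genes = []
        for i in range(12):
            genes.append((f"chr{rng.integers(1, 3)}", int(rng.integers(0, 3_000_000)),
                          rng.choice(["+", "-"])))
        gm = self._genes(genes)
        feats = pd.DataFrame({
            "chr": [f"chr{rng.integers(1, 3)}" for _ in range(60)],
            "pos": rng.integers(0, 3_000_000, 60),
        }, index=[f"c{i}" for i in range(60)])
        out = enr.great_assign(feats, gm)
        got = {(r.feature_id, r.gene) for r in out.itertuples()}
        dom = enr.regulatory_domains(gm)
        brute = set()
        for fid, f in feats.iterrows():
            for g, row in dom.iterrows():
                if row["chr"] == f["chr"] and row["left"] <= f["pos"] <= row["right"]:
                    brute.add((fid, g))
        assert got == brute

    def test_missing_strand_rejected(self):
        gm = self._genes([("chr1", 1000, "+")])
        gm.loc["G0", "strand"] = None
        feats = pd.DataFrame({"chr": ["chr1"], "pos": [1000]}, index=["c1"])
        with pytest.raises(ValueError):
            enr.great_assign(feats, gm)


class TestGamDebias:
    def _scores(self, rng, n=2000, biased=True):
        nl = rng.integers(1, 30, n)
        scale = 0.5 + (0.25 * np.log(nl + 1) if biased else 0.0)
        y = rng.gamma(1.2, 1.0, n) * scale + 1e-3
        return pd.DataFrame({"min_p": 10.0 ** (-y), "n_links": nl, "Y": y},
                            index=[f"g{i}" for i in range(n)])

    def test_bias_removed(self, rng):
        sc = self._scores(rng)
        out = enr.gam_debias(sc)
        rho = spearmanr(out["residual"], out["n_links"]).statistic
        assert abs(rho) < 0.05

    def test_equal_links_preserve_y_order(self, rng):
        sc = self._scores(rng)
        sc["n_links"] = 7
        out = enr.gam_debias(sc)
        sub = out
        assert (sub.sort_values("residual", ascending=False).index
                == sub.sort_values("Y", ascending=False).index).all()

    def test_ranking_stable_under_jitter(self, rng):
        sc = self._scores(rng)
        out1 = enr.gam_debias(sc)
        sc2 = sc.copy()
        sc2["n_links"] = sc2["n_links"] + rng.integers(0, 2, len(sc2))
        out2 = enr.gam_debias(sc2)
        rho = spearmanr(out1.loc[sc.index, "residual"],
                        out2.loc[sc.index, "residual"]).statistic
        assert rho > 0.95

    def test_too_few_genes_rejected(self, rng):
        sc = self._scores(rng, n=10)
        with pytest.raises(ValueError):
            enr.gam_debias(sc)


def _brute_es(metric, hit_set, weight=1.0):
    order = np.argsort(metric)[::-1]
    best = 0.0
    run = 0.0
    hits = np.isin(order, list(hit_set))
    denom_hit = np.abs(metric[order][hits]) ** weight
    total = denom_hit.sum()
    n_miss = len(metric) - hits.sum()
    h = 0
    for i, idx in enumerate(order):
        if hits[i]:
            run += abs(metric[idx]) ** weight / total
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestGsea:
    def test_top_gene_singleton_es_one(self):
        ranked = pd.Series({f"g{i}": 10.0 - i for i in range(10)})
        out = enr.gsea_preranked(ranked, {"s": ["g0"]}, n_perm=20, min_size=1, seed=0)
        assert out["ES"].iloc[0] == pytest.approx(1.0)

    def test_matches_brute_force_running_sum(self):
        metric = np.array([3.0, 2.0, 1.5, -1.0, -2.5])
        ranked = pd.Series(metric, index=[f"g{i}" for i in range(5)])
        out = enr.gsea_preranked(ranked, {"s": ["g1", "g3"]}, n_perm=20,
                                 min_size=1, seed=0)
        assert out["ES"].iloc[0] == pytest.approx(_brute_es(metric, {1, 3}), abs=1e-12)

    def test_es_bounds_and_p_resolution(self, rng):
        ranked = pd.Series(rng.normal(size=200),
                           index=[f"g{i}" for i in range(200)])
        sets = {f"s{k}": [f"g{i}" for i in rng.choice(200, 15, replace=False)]
                for k in range(8)}
        out = enr.gsea_preranked(ranked, sets, n_perm=100, seed=1)
        assert ((out["ES"] >= -1) & (out["ES"] <= 1)).all()
        assert (out["p"] >= 1 / 101).all()

    def test_null_metric_false_positive_rate(self, rng):
        ranked = pd.Series(rng.normal(size=300),
                           index=[f"g{i}" for i in range(300)])
        sets = {f"s{k}": [f"g{i}" for i in rng.choice(300, 20, replace=False)]
                for k in range(30)}
        out = enr.gsea_preranked(ranked, sets, n_perm=200, seed=2)
        assert (out["fdr"] < 0.25).mean() <= 0.35  # null rate within MC slack

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            enr.gsea_preranked(pd.Series(dtype=float), {"s": ["a"]})


def test_read_gmt(tmp_path):
    p = tmp_path / "x.gmt"
    p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg9\n")
    sets = enr.read_gmt(p)
    assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g9"]}
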