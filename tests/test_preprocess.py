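"""QC, normalization, conversion and residualization contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sexewas import preprocess as pp


def _toy_probe_set():
    probes = list("ABCDEF")
    beta = pd.DataFrame(0.5, index=probes, columns=["s1", "s2", "s3"])
    detp = pd.DataFrame(1e-6, index=probes, columns=beta.columns)
    detp.loc["A", "s2"] = 0.5
    annot = pd.DataFrame({
        "snp_dist_3p": [np.nan, np.nan, 3.0, 10.0, np.nan, np.nan],
        "snp_maf": [np.nan, np.nan, 0.02, 0.2, np.nan, np.nan],
    }, index=probes)
    return beta, detp, annot


class TestFilterProbes:
    def test_three_rules_applied_in_order(self):
        beta, detp, annot = _toy_probe_set()
        out, rep = pp.filter_probes(beta, detp, annot, smoking_ids=["B"])
        assert list(out.index) == ["D", "E", "F"]
        assert (rep.probes_detection, rep.probes_smoking, rep.probes_snp) == (1, 1, 1)
        assert rep.probes_in - (rep.probes_detection + rep.probes_smoking
                                + rep.probes_snp) == rep.probes_out

    def test_clean_input_is_identity(self):
        beta, detp, annot = _toy_probe_set()
        detp.loc[:] = 1e-6
        annot.loc[:, ["snp_dist_3p", "snp_maf"]] = np.nan
        out, _ = pp.filter_probes(beta, detp, annot)
        assert list(out.index) == list(beta.index)

    def test_snp_boundary_inclusive(self):
        beta, detp, annot = _toy_probe_set()
        detp.loc[:] = 1e-6
        annot.loc[:, ["snp_dist_3p", "snp_maf"]] = np.nan
        annot.loc["E", ["snp_dist_3p", "snp_maf"]] = [5.0, 0.01]
        out, rep = pp.filter_probes(beta, detp, annot)
        assert "E" not in out.index and rep.probes_snp == 1

    def test_inverted_detection_rule(self):
        beta, detp, annot = _toy_probe_set()
        annot.loc[:, ["snp_dist_3p", "snp_maf"]] = np.nan
        out, _ = pp.filter_probes(beta, detp, annot, invert_detection=True)
        assert "A" in out.index  # fails in one sample only, not all


class TestFilterSamples:
    def test_low_conversion_removed_before_pca(self, rng):
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, (50, 6)),
                            index=[f"p{i}" for i in range(50)],
                            columns=[f"s{i}" for i in range(6)])
        sheet = pd.DataFrame({"bisulfite_conversion": [97, 85, 96, 98, 95, 99]},
                             index=beta.columns)
        out, sh, rep = pp.filter_samples(beta, sheet)
        assert "s1" not in out.columns and rep.samples_conversion == 1

    def test_displaced_sample_flagged_by_pca(self, rng):
        n_p, n_s = 200, 30
        beta = pd.DataFrame(rng.uniform(0.4, 0.6, (n_p, n_s)),
                            index=[f"p{i}" for i in range(n_p)],
                            columns=[f"s{i}" for i in range(n_s)])
        beta.iloc[:, 0] += 0.3  # large coherent displacement
        sheet = pd.DataFrame({"bisulfite_conversion": 97.0}, index=beta.columns)
        out, _, rep = pp.filter_samples(beta, sheet)
        assert "s0" not in out.columns
        assert rep.samples_pca >= 1
        coords = rep.pca_coordinates
        assert not coords.loc["s0", "retained"]

    def test_identical_samples_all_retained(self):
        beta = pd.DataFrame(0.5, index=[f"p{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(5)])
        sheet = pd.DataFrame({"bisulfite_conversion": 97.0}, index=beta.columns)
        out, _, rep = pp.filter_samples(beta, sheet)
        assert out.shape[1] == 5 and rep.samples_pca == 0


class TestQuantileNormalize:
    def test_worked_example(self):
        beta = pd.DataFrame({"a": [0.1, 0.2, 0.3], "b": [0.4, 0.5, 0.6]})
        out = pp.quantile_normalize(beta)
        expected = np.array([0.25, 0.35, 0.45])
        assert np.allclose(np.sort(out["a"]), expected)
        assert np.allclose(np.sort(out["b"]), expected)

    def test_identical_distributions_unchanged(self, rng):
        v = np.sort(rng.uniform(0, 1, 40))
        beta = pd.DataFrame({"a": v, "b": rng.permutation(v)})
        out = pp.quantile_normalize(beta)
        assert np.allclose(np.sort(out["a"]), v) and np.allclose(np.sort(out["b"]), v)

    def test_rank_order_preserved(self, rng):
        beta = pd.DataFrame(rng.uniform(0, 1, (100, 4)))
        out = pp.quantile_normalize(beta)
        for j in range(4):
            assert (np.argsort(beta.values[:, j], kind="stable")
                    == np.argsort(out.values[:, j], kind="stable")).all()

    def test_ties_get_mean_of_spanned_quantiles(self):
        beta = pd.DataFrame({"a": [0.2, 0.2, 0.8], "b": [0.1, 0.5, 0.9]})
        out = pp.quantile_normalize(beta)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pp.quantile_normalize(pd.DataFrame({"a": [0.1, 0.2]}))


def _mixture_draw(rng, n):
    comp = rng.choice(3, n, p=(0.35, 0.15, 0.5))
    ab = np.array([[2.0, 18.0], [5.0, 5.0], [18.0, 2.0]])
    return np.array([rng.beta(*ab[c]) for c in comp])


class TestBmiq:
    def test_all_type_one_is_identity(self, rng):
        beta = pd.DataFrame(rng.uniform(0.05, 0.95, (50, 2)),
                            index=[f"p{i}" for i in range(50)])
        types = pd.Series("I", index=beta.index)
        out = pp.bmiq(beta, types)
        assert np.allclose(out.values, beta.values)

    def test_design_bias_reduced_and_ks_small(self, rng):
        n = 5000
        t1 = _mixture_draw(rng, n)
        t2 = 0.5 + (_mixture_draw(rng, n) - 0.5) * 0.8  # compressed type II
        beta = pd.DataFrame({"s": np.concatenate([t1, t2])})
        types = pd.Series(["I"] * n + ["II"] * n, index=beta.index)
        before = stats.ks_2samp(t1, t2).statistic
        out = pp.bmiq(beta, types)
        after = stats.ks_2samp(t1, out.values[n:, 0]).statistic
        assert after < before
        assert after < 0.05

    def test_transform_monotone_within_sample(self, rng):
        n = 800
        t1 = _mixture_draw(rng, n)
        t2 = _mixture_draw(rng, n)
        beta = pd.DataFrame({"s": np.concatenate([t1, t2])})
        types = pd.Series(["I"] * n + ["II"] * n, index=beta.index)
        out = pp.bmiq(beta, types)
        order = np.argsort(t2)
        assert (np.diff(out.values[n:, 0][order]) >= -1e-12).all()


@pytest.mark.parametrize("beta,expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
def test_beta_to_m_anchor_values(beta, expected):
    assert pp.beta_to_m(beta) == pytest.approx(expected, abs=1e-12)


class TestResidualize:
    def test_intercept_only_centers(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], columns=list("abcd"))
        cov = pd.DataFrame({"const": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
        out = pp.residualize(m, cov)
        assert np.allclose(out.values, [[-1.5, -0.5, 0.5, 1.5]])

    def test_group_mean_centering(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], columns=list("abcd"))
        cov = pd.DataFrame({"slide": ["A", "A", "B", "B"]}, index=list("abcd"))
        out = pp.residualize(m, cov)
        assert np.allclose(out.values, [[-0.5, 0.5, -0.5, 0.5]])

    def test_orthogonality_and_idempotence(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 30)),
                         columns=[f"s{i}" for i in range(30)])
        cov = pd.DataFrame({"slide": rng.choice(["A", "B", "C"], 30),
                            "age": rng.uniform(50, 90, 30)},
                           index=m.columns)
        out = pp.residualize(m, cov)
        x = pp.design_matrix(cov)
        assert np.abs(out.values @ x).max() < 1e-8
        again = pp.residualize(out, cov)
        assert np.abs(again.values - out.values).max() < 1e-10

    def test_singular_design_rejected(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc"))
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0]},
                           index=list("abc"))
        with pytest.raises(ValueError):
            pp.residualize(m, cov)


class TestNeuronProportion:
    @pytest.mark.parametrize("mix,expected", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5)])
    def test_linear_mixtures_recovered(self, rng, mix, expected):
        ref = pd.DataFrame({"neuron": rng.uniform(0.1, 0.9, 30),
                            "glia": rng.uniform(0.1, 0.9, 30)},
                           index=[f"p{i}" for i in range(30)])
        sample = mix * ref["neuron"] + (1 - mix) * ref["glia"]
        beta = pd.DataFrame({"s": sample})
        est = pp.estimate_neuron_proportion(beta, ref)
        assert est["s"] == pytest.approx(expected, abs=1e-10)

    def test_no_overlap_rejected(self):
        ref = pd.DataFrame({"neuron": [0.9], "glia": [0.1]}, index=["px"])
        beta = pd.DataFrame({"s": [0.5]}, index=["py"])
        with pytest.raises(ValueError):
            pp.estimate_neuron_proportion(beta, ref)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(0.02, 0.98), min_size=5, max_size=40, unique=True))
def test_quantile_then_logit_preserves_order(values):
    """QN followed by the logit keeps within-column rank order."""
    beta = pd.DataFrame({"a": values, "b": sorted(values)})
    out = pp.beta_to_m(pp.quantile_normalize(beta).values)
    assert (np.argsort(out[:, 0], kind="stable")
            == np.argsort(np.asarray(values), kind="stable")).all()
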