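"""OLS, Spearman, faceting, Bray-Curtis and dbRDA behaviour."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from oceanpack import (
    CommunityMatrix,
    bray_curtis,
    dbrda,
    facet_summary,
    generate_community_depth_data,
    generate_redfield_data,
    ols_fit,
    relative_abundance,
    spearman,
    top_coefficients,
)
from oceanpack.errors import DegenerateInputError, ParameterError


class TestOls:
    def test_exact_line_slope_one_sixteenth(self):
        fit = ols_fit([16, 32, 48], [1, 2, 3])
        assert fit.slope == pytest.approx(0.0625)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_identity_fit(self):
        fit = ols_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noiseless_generator_recovers_exact_slope(self):
        df, man = generate_redfield_data(n=50, noise_sd=0.0, seed=9)
        fit = ols_fit(df["nitrate"], df["phosphate"])
        assert fit.slope == pytest.approx(man.true_slope, abs=1e-12)

    def test_bias_shrinks_with_sample_size(self):
        err = {}
        for n in (100, 10_000):
            df, man = generate_redfield_data(n=n, noise_sd=0.2, seed=13)
            fit = ols_fit(df["nitrate"], df["phosphate"])
            err[n] = abs(fit.slope - man.true_slope)
        assert err[10_000] < err[100]

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateInputError):
            ols_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DegenerateInputError):
            ols_fit([1, 2, 3], [1, 2])


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman([1, 2, 3], [1, 4, 9]) == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_ranks_average(self):
        # ranks of x: (1, 2.5, 2.5, 4); Pearson of ranks = 3/sqrt(10)
        rho = spearman([1, 2, 2, 3], [1, 2, 3, 4])
        assert rho == pytest.approx(3 / np.sqrt(10))

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=30,
                    unique=True).map(lambda v: [i / 10 for i in v]))
    def test_invariant_under_monotone_transform(self, xs):
        rng = np.random.default_rng(0)
        ys = rng.normal(size=len(xs))
        if np.ptp(ys) == 0:
            return
        base = spearman(xs, ys)
        assert spearman(np.exp(np.asarray(xs) / 100), ys) == pytest.approx(base)
        assert spearman(xs, 3 * ys + 7) == pytest.approx(base)


class TestFacets:
    def test_known_group_means(self, graph, registry, tmp_path):
        from oceanpack import HarmonizedTable, OntologyTermRef
        vals = pd.DataFrame({
            "attr": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0, 5.0, 7.0, 9.0, 2.0, 4.0, 6.0],
            "lat": [10.0] * 3 + [45.0] * 3 + [10.0] * 3 + [45.0] * 3,
        }, index=[f"s{i}" for i in range(12)])
        feats = ([OntologyTermRef("ENVO:01001581")] * 6
                 + [OntologyTermRef("ENVO:00000213")] * 6)
        table = HarmonizedTable(values=vals)
        table.context = pd.DataFrame({"feature": feats,
                                      "biome": [None] * 12,
                                      "material": [None] * 12},
                                     index=vals.index)
        out = facet_summary(table, "attr", "lat")
        assert len(out) == 4
        cell = out[(out.feature == "ENVO:01001581") & (out.zone == "tropical")]
        assert cell["mean"].iloc[0] == pytest.approx(2.0)
        cell = out[(out.feature == "ENVO:00000213") & (out.zone == "temperate")]
        assert cell["mean"].iloc[0] == pytest.approx(4.0)
        assert (out["n"] == 3).all()

    def test_singleton_cell_has_no_sd(self):
        from oceanpack import HarmonizedTable, OntologyTermRef
        vals = pd.DataFrame({"attr": [1.0], "lat": [0.0]}, index=["s0"])
        table = HarmonizedTable(values=vals)
        table.context = pd.DataFrame(
            {"feature": [OntologyTermRef("ENVO:00000032")],
             "biome": [None], "material": [None]}, index=["s0"])
        out = facet_summary(table, "attr", "lat")
        assert len(out) == 1 and np.isnan(out["sd"].iloc[0])

    def test_no_context_warns_empty(self):
        from oceanpack import HarmonizedTable
        vals = pd.DataFrame({"attr": [1.0], "lat": [0.0]}, index=["s0"])
        table = HarmonizedTable(values=vals)
        with pytest.warns(UserWarning):
            out = facet_summary(table, "attr", "lat")
        assert out.empty


class TestRelativeAbundance:
    def test_row_normalization(self):
        cm = CommunityMatrix(pd.DataFrame([[2, 2]], index=["s"],
                                          columns=["a", "b"]))
        rel = relative_abundance(cm, min_reads=1)
        assert rel.data.loc["s"].tolist() == [0.5, 0.5]
        assert rel.mode == "relative"

    def test_shallow_sample_dropped(self):
        cm = CommunityMatrix(pd.DataFrame(
            [[30_000, 20_000], [80_000, 70_000]], index=["shallow", "deep"],
            columns=["a", "b"]))
        rel = relative_abundance(cm, min_reads=100_000)
        assert rel.samples == ["deep"]

    def test_contaminants_removed_before_threshold(self):
        cm = CommunityMatrix(pd.DataFrame(
            [[90_000, 60_000]], index=["s"], columns=["good", "contam"]))
        # after dropping the contaminant the sample falls below threshold
        with pytest.raises(DegenerateInputError):
            relative_abundance(cm, min_reads=100_000, contaminants=["contam"])
        rel = relative_abundance(cm, min_reads=50_000, contaminants=["contam"])
        assert rel.taxa == ["good"]
        assert rel.data.loc["s", "good"] == pytest.approx(1.0)

    def test_rows_sum_to_one(self):
        cm, _, _ = generate_community_depth_data(n_samples=15, seed=3)
        rel = relative_abundance(cm, min_reads=1)
        assert np.allclose(rel.data.sum(axis=1), 1.0, atol=1e-9)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        cm = CommunityMatrix(pd.DataFrame([[1, 2], [1, 2]],
                                          index=["a", "b"], columns=["x", "y"]))
        assert bray_curtis(cm)["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        cm = CommunityMatrix(pd.DataFrame([[1, 1, 0], [0, 0, 1]],
                                          index=["a", "b"],
                                          columns=list("xyz")))
        assert bray_curtis(cm)["a", "b"] == 1.0

    def test_formula_value(self):
        cm = CommunityMatrix(pd.DataFrame([[6, 2], [2, 2]],
                                          index=["a", "b"], columns=["x", "y"]))
        assert bray_curtis(cm)["a", "b"] == pytest.approx(4 / 12)

    def test_metric_properties(self):
        cm, _, _ = generate_community_depth_data(n_samples=10, seed=4)
        d = bray_curtis(relative_abundance(cm, min_reads=1)).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_two_all_zero_rows_rejected(self):
        cm = CommunityMatrix(pd.DataFrame([[0, 0], [0, 0], [1, 1]],
                                          columns=["x", "y"]))
        with pytest.raises(DegenerateInputError):
            bray_curtis(cm)


class TestDbrda:
    def test_euclidean_matches_ols_r_squared(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        y = 0.5 * x + rng.normal(0, 0.3, 6)
        d = squareform(pdist(y[:, None]))
        res = dbrda(d, x, n_perm=99, seed=1)
        fit = ols_fit(x, y)
        assert abs(res.r_squared - fit.r_squared) <= 1e-9

    def test_coefficient_signs_follow_construction(self):
        cm, depths, man = generate_community_depth_data(n_samples=40, seed=7)
        rel = relative_abundance(cm, min_reads=1)
        res = dbrda(bray_curtis(rel), depths.to_numpy(), species=rel,
                    n_perm=99, seed=2)
        for taxon, sign in man.effect_signs.items():
            if sign:
                assert np.sign(res.coefficients[taxon]) == sign

    def test_reproducible_for_fixed_seed(self):
        cm, depths, _ = generate_community_depth_data(n_samples=15, seed=5)
        rel = relative_abundance(cm, min_reads=1)
        d = bray_curtis(rel)
        r1 = dbrda(d, depths.to_numpy(), species=rel, n_perm=199, seed=11)
        r2 = dbrda(d, depths.to_numpy(), species=rel, n_perm=199, seed=11)
        assert r1.p_value == r2.p_value
        assert r1.r_squared == r2.r_squared

    def test_p_value_never_zero_or_above_one(self):
        cm, depths, _ = generate_community_depth_data(n_samples=15, seed=6)
        rel = relative_abundance(cm, min_reads=1)
        r = dbrda(bray_curtis(rel), depths.to_numpy(), n_perm=99, seed=0)
        assert 0 < r.p_value <= 1

    def test_constant_covariate_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(DegenerateInputError):
            dbrda(d, np.ones(4), n_perm=99, seed=0)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(DegenerateInputError):
            dbrda(d, np.array([0.0, 1.0]), n_perm=99, seed=0)

    def test_matches_vegan_adonis(self, tmp_path):
        """Independent oracle: R vegan's adonis2 on the same Bray-Curtis
        instance must report the same model R^2."""
        cm, depths, _ = generate_community_depth_data(n_samples=10, seed=11)
        rel = relative_abundance(cm, min_reads=1)
        res = dbrda(bray_curtis(rel), depths.to_numpy(), species=rel,
                    n_perm=99, seed=3)
        comm = tmp_path / "comm.tsv"
        env = tmp_path / "env.tsv"
        rel.data.to_csv(comm, sep="\t")
        pd.DataFrame({"depth": depths}).to_csv(env, sep="\t")
        script = (
            'suppressMessages(library(vegan));'
            f'comm <- read.delim("{comm}", row.names=1);'
            f'env <- read.delim("{env}", row.names=1);'
            'a <- adonis2(comm ~ depth, data=env, method="bray",'
            ' permutations=99);'
            'cat(sprintf("%.10f", a$R2[1]))'
        )
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
        assert res.r_squared == pytest.approx(float(out.stdout), abs=1e-8)


class TestTopCoefficients:
    def _result(self, coefs):
        from oceanpack import DbRdaResult
        return DbRdaResult(
            coefficients=pd.Series(coefs), r_squared=0.5, pseudo_f=1.0,
            p_value=0.05, n_permutations=99, seed=0, n=10)

    def test_ordered_by_absolute_value(self):
        r = self._result({"t1": 0.5, "t2": -0.9, "t3": 0.1})
        assert top_coefficients(r, 2) == ["t2", "t1"]

    def test_k_larger_than_count(self):
        r = self._result({"t1": 0.5, "t2": -0.9})
        assert top_coefficients(r, 10) == ["t2", "t1"]

    def test_tie_broken_lexically(self):
        r = self._result({"b": -0.5, "a": 0.5, "c": 0.1})
        assert top_coefficients(r, 2) == ["a", "b"]

    def test_k_zero_rejected(self):
        with pytest.raises(ParameterError):
            top_coefficients(self._result({"a": 1.0}), 0)
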