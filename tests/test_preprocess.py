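import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from microfms.io_types import OTUTable
from microfms.preprocess import (
    NM_VARIANTS,
    PreprocessSpec,
    ZeroReplacementConfig,
    alpha_diversity,
    apply_nm,
    binarize_disease,
    binarize_yield,
    make_preprocess_grid,
    normalize,
    scale_environment,
    split_train_test,
    zero_replace,
)


def table_of(rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return OTUTable(
        pd.DataFrame(
            rows,
            index=ids or [f"s{i}" for i in range(rows.shape[0])],
            columns=[f"t{j}" for j in range(rows.shape[1])],
        )
    )


count_matrices = arrays(
    np.float64,
    st.tuples(st.integers(2, 6), st.integers(2, 8)),
    elements=st.integers(0, 200).map(float),
).filter(lambda a: (a.sum(axis=1) > 0).all() and ((a > 0).sum(axis=1) >= 1).all())


class TestZeroReplacement:
    def test_pseudo_replaces_zero_cells_only(self):
        out = zero_replace(table_of([[0, 3, 5]]), "pseudo")
        assert out.data.iloc[0].tolist() == [1.0, 3.0, 5.0]

    def test_multrepl_hand_example(self):
        # proportions [0.5, 0.5, 0] with delta = 0.0005 = 0.001 * 0.5
        cfg = ZeroReplacementConfig(mult_delta_fraction=0.001)
        out = zero_replace(table_of([[5, 5, 0]]), "multRepl", cfg)
        props = out.data.iloc[0] / out.data.iloc[0].sum()
        assert props.tolist() == pytest.approx([0.49975, 0.49975, 0.0005])

    def test_bayesmult_closed_form(self):
        # p=2, s=1, m=10: zero gets (1/2)/(10+1); nonzero the complement
        out = zero_replace(table_of([[0, 10]]), "bayesMult")
        props = (out.data.iloc[0] / out.data.iloc[0].sum()).tolist()
        assert props == pytest.approx([0.5 / 11, 1 - 0.5 / 11])

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="all zeros"):
            zero_replace(table_of([[0, 0], [1, 2]]), "multRepl")

    def test_unknown_method_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            zero_replace(table_of([[1, 2]]), "zap")

    @pytest.mark.parametrize("method", ["pseudo", "multRepl", "bayesMult"])
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(counts=count_matrices)
    def test_strict_positivity_and_nonzero_ratio_preservation(self, method, counts):
        table = OTUTable(
            pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(counts.shape[0])],
                columns=[f"t{j}" for j in range(counts.shape[1])],
            )
        )
        out = zero_replace(table, method)
        assert (out.data.to_numpy() > 0).all()
        # ratios between originally-nonzero taxa are untouched
        for k in range(table.n_samples):
            row0 = table.data.iloc[k].to_numpy()
            row1 = out.data.iloc[k].to_numpy()
            nz = np.flatnonzero(row0)
            if len(nz) >= 2:
                ratio0 = row0[nz] / row0[nz[0]]
                ratio1 = row1[nz] / row1[nz[0]]
                np.testing.assert_allclose(ratio1, ratio0, rtol=1e-9)

    @pytest.mark.parametrize("method", ["multRepl", "bayesMult"])
    def test_depth_preserved(self, method):
        table = table_of([[0, 3, 7], [2, 0, 8]])
        out = zero_replace(table, method)
        np.testing.assert_allclose(out.depths, table.depths)


class TestNormalize:
    def test_tss_closure(self):
        out = normalize(table_of([[2, 2, 4, 2]]), "TSS")
        assert out.iloc[0].tolist() == [0.2, 0.2, 0.4, 0.2]

    def test_clr_log_ratio(self):
        out = normalize(table_of([[1, 2, 4]]), "clr")
        np.testing.assert_allclose(
            out.iloc[0], [-math.log(2), 0.0, math.log(2)], atol=1e-12
        )

    def test_com_min_depth_scaling(self):
        out = normalize(table_of([[5, 5], [10, 10]]), "COM")
        assert out.iloc[1].tolist() == [5.0, 5.0]

    def test_clr_rejects_zeros(self):
        with pytest.raises(ValueError, match="zero-replacement"):
            normalize(table_of([[0, 1]]), "clr")

    def test_rarefy_equalizes_depths(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 60, size=(5, 10)).astype(float)
        out = normalize(OTUTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(5)],
            columns=[f"t{j}" for j in range(10)],
        )), "rarefy", rarefy_seed=1)
        depths = out.sum(axis=1)
        assert depths.nunique() == 1
        assert depths.iloc[0] == counts.sum(axis=1).min()

    def test_rarefy_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            normalize(table_of([[1, 2], [3, 4]]), "rarefy")

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(counts=count_matrices)
    def test_closure_properties_fuzzed(self, counts):
        table = OTUTable(
            pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(counts.shape[0])],
                columns=[f"t{j}" for j in range(counts.shape[1])],
            )
        )
        tss = normalize(table, "TSS")
        np.testing.assert_allclose(tss.sum(axis=1), 1.0, atol=1e-12)
        positive = zero_replace(table, "pseudo")
        clr = normalize(positive, "clr")
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-9)
        com = normalize(table, "COM")
        np.testing.assert_allclose(
            com.sum(axis=1), table.depths.min(), atol=1e-9
        )


class TestGrid:
    def test_twenty_nm_variants(self):
        assert len(NM_VARIANTS) == 20
        assert len(make_preprocess_grid(levels=("Genus",), augment_options=(False,))) == 20

    def test_full_design_is_200(self):
        assert len(make_preprocess_grid()) == 200

    def test_nm6_is_css_pseudo(self):
        spec = PreprocessSpec.from_nm_index(6)
        assert (spec.norm_method, spec.zero_method) == ("CSS", "pseudo")
        assert spec.nm_index == 6

    def test_enumeration_round_trips(self):
        for i in range(1, 21):
            assert PreprocessSpec.from_nm_index(i).nm_index == i

    def test_clr_none_fallback_is_defined(self):
        table = table_of([[0, 1, 3], [2, 0, 4]])
        out = apply_nm(table, PreprocessSpec("clr", "none"))
        assert np.isfinite(out.to_numpy()).all()
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-9)


class TestEnvironmentalScaling:
    def test_standard_hand_example(self):
        out = scale_environment(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), "standard")
        assert out["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_minmax_and_unitnorm(self):
        assert scale_environment(
            pd.DataFrame({"a": [5.0, 10.0]}), "minmax"
        )["a"].tolist() == [0.0, 1.0]
        row = scale_environment(pd.DataFrame([[3.0, 4.0]]), "unitnorm")
        assert row.iloc[0].tolist() == pytest.approx([0.6, 0.8])

    def test_fit_on_train_rows_only(self):
        env = pd.DataFrame({"a": [0.0, 1.0, 100.0]}, index=["r1", "r2", "r3"])
        out = scale_environment(env, "minmax", train_index=pd.Index(["r1", "r2"]))
        # r3 extrapolates beyond [0, 1] because the scaler never saw it
        assert out.loc["r3", "a"] == pytest.approx(100.0)

    def test_zero_variance_column_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = scale_environment(pd.DataFrame({"a": [2.0, 2.0]}), "standard")
        assert out["a"].tolist() == [0.0, 0.0]


class TestBinarization:
    def test_disease_threshold_at_zero(self):
        values = pd.Series([0.0, 0.2, 5.0, np.nan], index=list("abcd"))
        labels = binarize_disease(values)
        assert labels.tolist()[:3] == [0, 1, 1]
        assert pd.isna(labels["d"])

    def test_disease_negative_errors(self):
        with pytest.raises(ValueError, match="negative"):
            binarize_disease(pd.Series([-1.0]))

    def test_disease_matches_brute_force(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.random(50).round(1))
        labels = binarize_disease(values)
        assert labels.tolist() == [int(v > 0) for v in values]

    def test_yield_variety_median_rule(self):
        values = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        varieties = pd.Series(["A"] * 5, index=list("abcde"))
        labels = binarize_yield(values, varieties)
        assert labels.tolist() == [0, 0, 0, 1, 1]  # exact median joins class 0

    def test_yield_per_variety_not_pooled(self):
        # disjoint ranges: each variety is classified against its own median
        values = pd.Series([1.0, 2, 3, 100, 200, 300], index=list("abcdef"))
        varieties = pd.Series(["A"] * 3 + ["B"] * 3, index=list("abcdef"))
        labels = binarize_yield(values, varieties)
        assert labels.tolist() == [0, 0, 1, 0, 0, 1]

    def test_yield_constant_variety_all_zero(self):
        values = pd.Series([5.0, 5, 5])
        labels = binarize_yield(values, pd.Series(["A"] * 3))
        assert labels.tolist() == [0, 0, 0]

    def test_yield_order_invariance(self):
        rng = np.random.default_rng(1)
        values = pd.Series(rng.random(30), index=range(30))
        varieties = pd.Series(rng.choice(["A", "B"], 30), index=range(30))
        base = binarize_yield(values, varieties)
        perm = rng.permutation(30)
        shuffled = binarize_yield(values.iloc[perm], varieties.iloc[perm])
        pd.testing.assert_series_equal(shuffled.sort_index(), base.sort_index())

    def test_yield_missing_variety_errors(self):
        with pytest.raises(ValueError, match="variety"):
            binarize_yield(pd.Series([1.0, 2.0]), pd.Series(["A", None]))


class TestAlphaDiversity:
    def test_single_taxon_degenerate(self):
        table = table_of([[10]])
        assert alpha_diversity(table, "Shannon", rarefy_first=False).iloc[0] == 0.0
        assert alpha_diversity(table, "Simpson", rarefy_first=False).iloc[0] == 0.0
        assert alpha_diversity(table, "InvSimpson", rarefy_first=False).iloc[0] == 1.0

    def test_equal_abundances_maximize_shannon(self):
        table = table_of([[7] * 12])
        assert alpha_diversity(table, "Shannon", rarefy_first=False).iloc[
            0
        ] == pytest.approx(math.log(12))

    def test_chao1_bias_corrected_formula(self):
        # S_obs=4, f1=2, f2=0: 4 + 2*1/(2*1) = 5
        table = table_of([[5, 3, 1, 1]])
        assert alpha_diversity(table, "Chao1", rarefy_first=False).iloc[0] == 5.0

    def test_chao1_ace_match_reference_implementation(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 30, size=(6, 20))
        counts[:, 0] = 1  # ensure singletons exist
        table = OTUTable(pd.DataFrame(
            counts.astype(float),
            index=[f"s{i}" for i in range(6)],
            columns=[f"t{j}" for j in range(20)],
        ))
        ours_chao = alpha_diversity(table, "Chao1", rarefy_first=False)
        ours_ace = alpha_diversity(table, "ACE", rarefy_first=False)
        for k in range(6):
            row = counts[k][counts[k] > 0]
            assert ours_chao.iloc[k] == pytest.approx(skbio_alpha.chao1(row))
            assert ours_ace.iloc[k] == pytest.approx(skbio_alpha.ace(row))


class TestSplit:
    def test_eighty_twenty(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.random((100, 3)))
        y = pd.Series([0] * 50 + [1] * 50)
        train, test = split_train_test(X, y, seed=0)
        assert (len(train), len(test)) == (80, 20)
        assert y.loc[test].value_counts().tolist() == [10, 10]
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(X.index)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.random((40, 2)))
        y = pd.Series([0] * 22 + [1] * 18)
        a = split_train_test(X, y, seed=11)
        b = split_train_test(X, y, seed=11)
        assert a[0].tolist() == b[0].tolist() and a[1].tolist() == b[1].tolist()

    def test_singleton_class_errors(self):
        X = pd.DataFrame(np.zeros((6, 2)))
        y = pd.Series([0, 0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="single sample"):
            split_train_test(X, y)
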