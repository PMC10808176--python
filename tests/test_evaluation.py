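"""Cross-validation engine, collection prediction, culling, passport links."""

import numpy as np
import pandas as pd
import pytest

from genebankgp import (
    ModelSpec,
    altitude_association,
    compare_derived_strategies,
    compute_epistatic,
    compute_grm,
    cross_validate,
    culling_select,
    make_folds,
    predict_collection,
    simulate_altitude,
)

from conftest import centered, make_blues


class TestMakeFolds:
    def test_small_exact_partition(self):
        plans = make_folds([f"A{i}" for i in range(10)], k=5, repeats=3, seed=0)
        for plan in plans:
            sizes = plan.assignments.value_counts()
            assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_unbalanced_sizes_differ_by_at_most_one(self):
        accs = [f"A{i}" for i in range(337)]
        plans = make_folds(accs, k=5, repeats=2, seed=1)
        for plan in plans:
            sizes = plan.assignments.value_counts()
            assert set(sizes) == {67, 68}
            assert sizes.sum() == 337
            train, test = plan.split(3)
            assert sorted(train + test) == sorted(accs)

    def test_deterministic_but_repeats_differ(self):
        accs = [f"A{i}" for i in range(30)]
        a = make_folds(accs, k=5, repeats=2, seed=9)
        b = make_folds(accs, k=5, repeats=2, seed=9)
        pd.testing.assert_series_equal(a[0].assignments, b[0].assignments)
        pd.testing.assert_series_equal(a[1].assignments, b[1].assignments)
        assert not a[0].assignments.equals(a[1].assignments)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["A0", "A1"], k=5, repeats=1, seed=0)


def oracle_model(blues_all):
    def _oracle(train_blues, test_labels):
        return blues_all.estimates.loc[test_labels]

    _oracle.__name__ = "oracle"
    return _oracle


def anti_oracle_model(blues_all):
    def _anti(train_blues, test_labels):
        return -blues_all.estimates.loc[test_labels]

    _anti.__name__ = "anti_oracle"
    return _anti


def train_mean_model(train_blues, test_labels):
    return pd.Series(train_blues.estimates.mean(), index=test_labels)


train_mean_model.__name__ = "train_mean"


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def blues300(self):
        rng = np.random.default_rng(17)
        idx = [f"A{i}" for i in range(300)]
        return make_blues(pd.Series(rng.normal(0, 1, 300), index=idx))

    def test_oracle_and_anti_oracle_abilities(self, blues300):
        folds = make_folds(blues300.accessions, k=5, repeats=3, seed=2)
        res = cross_validate(
            blues300, [oracle_model(blues300), anti_oracle_model(blues300)], folds
        )
        ab = res.abilities
        assert np.allclose(ab.loc[ab.model == "oracle", "ability"], 1.0)
        assert np.allclose(ab.loc[ab.model == "anti_oracle", "ability"], -1.0)

    def test_training_mean_model_is_uninformative(self, blues300):
        # the constant-per-fold model carries no marker information; its
        # pooled ability is a small negative artifact (each fold constant
        # is anti-correlated with its fold mean, magnitude ~ sqrt((k-1)/n))
        folds = make_folds(blues300.accessions, k=5, repeats=20, seed=3)
        res = cross_validate(blues300, [train_mean_model], folds)
        assert res.abilities["ability"].abs().mean() < 0.2
        assert res.abilities["ability"].mean() < 0.05

    def test_each_accession_tested_once_and_folds_shared(self, blues300):
        folds = make_folds(blues300.accessions, k=5, repeats=2, seed=4)
        calls = []

        def spy(train_blues, test_labels):
            calls.append(list(test_labels))
            return pd.Series(0.1 * np.arange(len(test_labels)), index=test_labels)

        spy.__name__ = "spy"
        res = cross_validate(blues300, [spy], folds)
        assert len(calls) == 10  # 2 repeats x 5 folds
        for rep in range(2):
            labels = [a for fold in calls[5 * rep : 5 * rep + 5] for a in fold]
            assert sorted(labels) == sorted(blues300.accessions)
        assert len(res.abilities) == 2


class TestDerivedStrategies:
    def test_strategies_agree_under_noise_free_linear_coupling(self, small_genotypes):
        # lysine is exactly linear in protein and TGW plus a genetic
        # residual: both prediction routes carry the same information
        gm = small_genotypes
        rng = np.random.default_rng(23)
        z = centered(gm)
        gp = z @ rng.normal(0, 1, gm.n_markers)
        gt = z @ rng.normal(0, 1, gm.n_markers)
        gr = z @ rng.normal(0, 1, gm.n_markers)
        for v in (gp, gt, gr):
            v /= v.std(ddof=1)
        idx = gm.accession_ids
        protein = make_blues(pd.Series(17.0 + 2 * gp, index=idx), "protein")
        tgw = make_blues(pd.Series(40.0 + 5 * gt, index=idx), "tgw")
        lysine = make_blues(
            pd.Series(4.0 + 0.1 * (protein.estimates - 17.0) - 0.02 * (tgw.estimates - 40.0) + 0.2 * gr, index=idx),
            "lysine",
        )
        from genebankgp import adjust_lysine, fit_adjustment

        adj_model = fit_adjustment(lysine, protein, tgw)
        adjusted = adjust_lysine(lysine, protein, tgw, adj_model)
        g = compute_grm(gm)
        h = compute_epistatic(g)
        folds = make_folds(idx, k=5, repeats=3, seed=5)
        res = compare_derived_strategies(
            lysine, protein, tgw, adjusted, folds,
            model=ModelSpec(model="gblup"), G=g, H=h,
        )
        means = res.abilities.groupby("model")["ability"].mean()
        assert abs(means["direct"] - means["component"]) < 0.05
        assert (res.abilities.groupby("model").size() == 3).all()


class TestPredictCollection:
    def test_fitted_values_track_blues_at_high_heritability(self, small_genotypes):
        gm = small_genotypes
        rng = np.random.default_rng(29)
        z = centered(gm)
        g_true = z @ rng.normal(0, 1, gm.n_markers)
        g_true = g_true / g_true.std(ddof=1) * np.sqrt(0.8)
        y = 10 + g_true + rng.normal(0, np.sqrt(0.2), gm.n_accessions)
        blues = make_blues(pd.Series(y, index=gm.accession_ids))
        g = compute_grm(gm)
        preds, summary = predict_collection(
            {"trait": blues}, ModelSpec(model="gblup"), G=g
        )
        r = np.corrcoef(preds["trait"], blues.estimates.loc[preds.index])[0, 1]
        assert r > 0.9
        assert summary.loc[summary.group == "unphenotyped", "n"].iloc[0] == 0

    def test_offspring_of_poor_parents_score_below_training(self):
        from genebankgp import GenotypeMatrix

        rng = np.random.default_rng(31)
        n_train, n_off = 60, 30
        codes_train = rng.choice([0.0, 2.0], size=(n_train, 200))
        beta = rng.normal(0, 1, 200)
        g_train = codes_train @ beta
        g_train = (g_train - g_train.mean()) / g_train.std(ddof=1)
        y = g_train + rng.normal(0, 0.3, n_train)
        # unphenotyped accessions descend from the lowest-value parents
        poor = np.argsort(y)[:n_off]
        codes_off = codes_train[poor].copy()
        flip = rng.random(codes_off.shape) < 0.02
        codes_off[flip] = 2.0 - codes_off[flip]
        codes = np.vstack([codes_train, codes_off])
        ids = [f"T{i}" for i in range(n_train)] + [f"O{i}" for i in range(n_off)]
        gm = GenotypeMatrix(
            accession_ids=ids, marker_ids=[f"M{j}" for j in range(200)], codes=codes
        )
        gm.allele_freqs = codes.mean(axis=0) / 2.0
        blues = make_blues(pd.Series(y, index=ids[:n_train]))
        preds, summary = predict_collection(
            {"trait": blues}, ModelSpec(model="gblup"), G=compute_grm(gm)
        )
        s = summary.set_index("group")
        assert s.loc["unphenotyped", "mean"] < s.loc["training", "mean"]


class TestCullingSelect:
    def test_independent_traits_binomial_expectation(self):
        rng = np.random.default_rng(37)
        n = 10000
        preds = pd.DataFrame(
            {
                "protein": rng.standard_normal(n),
                "lysine_adjusted": rng.standard_normal(n),
            },
            index=[f"A{i}" for i in range(n)],
        )
        strict = culling_select(preds, 0.999)
        relaxed = culling_select(preds, 0.99)
        # expected counts n*(1-level)^2: 0.01 and 1
        assert len(strict.selected) <= 2
        assert len(relaxed.selected) <= 8

    def test_perfectly_correlated_traits_single_trait_reduction(self):
        rng = np.random.default_rng(41)
        v = rng.standard_normal(20000)
        preds = pd.DataFrame({"a": v, "b": v}, index=[f"A{i}" for i in range(20000)])
        res = culling_select(preds, 0.99)
        frac = len(res.selected) / 20000
        assert 0.005 < frac < 0.016

    def test_stringent_subset_of_relaxed_and_threshold_monotonicity(self):
        rng = np.random.default_rng(43)
        preds = pd.DataFrame(
            {
                "a": rng.normal(10, 2, 2000),
                "b": rng.normal(4, 0.3, 2000),
            },
            index=[f"A{i}" for i in range(2000)],
        )
        prev = None
        for level in (0.9, 0.95, 0.99, 0.999):
            res = culling_select(preds, level)
            if prev is not None:
                assert set(res.selected) <= set(prev.selected)
                assert all(
                    res.thresholds[t] > prev.thresholds[t] for t in res.thresholds
                )
            prev = res

    def test_empirical_mode_and_errors(self):
        preds = pd.DataFrame({"a": np.arange(1000.0)}, index=[f"A{i}" for i in range(1000)])
        res = culling_select(preds, 0.99, empirical=True)
        assert len(res.selected) == 10
        with pytest.raises(ValueError, match="level"):
            culling_select(preds, 0.4)
        with pytest.raises(ValueError, match="zero variance"):
            culling_select(pd.DataFrame({"a": np.ones(10)}), 0.99)


class TestAltitudeAssociation:
    def test_coupling_recovered(self):
        rng = np.random.default_rng(47)
        idx = [f"A{i}" for i in range(500)]
        g = pd.Series(rng.standard_normal(500), index=idx)
        alt = simulate_altitude(g, 0.5, rng)
        res = altitude_association(pd.DataFrame({"lysine": g}), alt)
        assert abs(res.loc[0, "r"] - 0.5) < 0.15
        assert res.loc[0, "n"] == 500

    def test_identity_gives_r_one(self):
        idx = ["A0", "A1", "A2", "A3"]
        v = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        res = altitude_association(pd.DataFrame({"t": v}), v)
        assert res.loc[0, "r"] == pytest.approx(1.0)

    def test_error_paths(self):
        idx = ["A0", "A1", "A2"]
        preds = pd.DataFrame({"t": [1.0, 2.0, 3.0]}, index=idx)
        with pytest.raises(ValueError, match="constant"):
            altitude_association(preds, pd.Series([5.0, 5.0, 5.0], index=idx))
        with pytest.raises(ValueError, match=">= 3"):
            altitude_association(preds, pd.Series([5.0], index=["A0"]))
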