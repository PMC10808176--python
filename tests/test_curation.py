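"""Record trimming, REML year model, outlier detection and heritability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from genebankgp import (
    SimulationConfig,
    compute_blues,
    detect_outliers,
    estimate_heritability,
    fit_year_model,
    simulate_genotypes,
    simulate_trial,
    trim_records,
)


def table_from(rows):
    return pd.DataFrame(rows, columns=["accession_id", "year", "trait", "value"])


class TestTrimRecords:
    def test_balanced_table_unchanged(self):
        rows = [(f"A{i}", y, "p", float(i)) for i in range(3) for y in ("Y1", "Y2")]
        trimmed, report = trim_records(table_from(rows))
        assert len(trimmed) == 6
        assert report.n_single_datapoint_accessions_removed == 0
        assert report.years_removed_for_no_overlap == []
        assert report.mean_records_per_accession == 2.0

    def test_disconnected_year_dropped_entirely(self):
        # a year holding six accessions that appear nowhere else must go
        rows = [(f"A{i}", y, "p", 1.0) for i in range(4) for y in ("Y1", "Y2")]
        rows += [(f"B{i}", "Y3", "p", 1.0) for i in range(6)]
        trimmed, report = trim_records(table_from(rows))
        assert report.years_removed_for_no_overlap == ["Y3"]
        assert set(trimmed["year"]) == {"Y1", "Y2"}

    def test_single_datapoint_accession_removed(self):
        rows = [(f"A{i}", y, "p", 1.0) for i in range(3) for y in ("Y1", "Y2")]
        rows.append(("LONER", "Y1", "p", 9.0))
        trimmed, report = trim_records(table_from(rows))
        assert "LONER" not in set(trimmed["accession_id"])
        assert report.n_single_datapoint_accessions_removed == 1

    def test_cascade_reaches_fixed_point(self):
        # dropping the disconnected year leaves A3 with one record, which
        # must then be dropped too
        rows = [(f"A{i}", y, "p", 1.0) for i in range(3) for y in ("Y1", "Y2")]
        rows += [("A3", "Y1", "p", 1.0), ("A3", "Y3", "p", 1.0), ("B0", "Y3", "p", 1.0), ("B1", "Y3", "p", 1.0)]
        # Y3 overlaps Y1 via A3, so it stays; but B0/B1 are singles -> out,
        # then re-check: Y3 still holds A3 which overlaps -> stable
        trimmed, _ = trim_records(table_from(rows))
        assert "B0" not in set(trimmed["accession_id"])
        assert "A3" in set(trimmed["accession_id"])
        counts = trimmed["accession_id"].value_counts()
        assert (counts >= 2).all()

    def test_empty_after_trimming_raises(self):
        rows = [("A0", "Y1", "p", 1.0), ("A1", "Y2", "p", 2.0)]
        with pytest.raises(ValueError, match="no connected replicated data"):
            trim_records(table_from(rows))

    def test_duplicate_records_rejected(self):
        rows = [("A0", "Y1", "p", 1.0), ("A0", "Y1", "p", 2.0), ("A1", "Y1", "p", 1.0)]
        with pytest.raises(ValueError, match="duplicated"):
            trim_records(table_from(rows))

    def test_multi_trait_rejected(self):
        rows = [("A0", "Y1", "p", 1.0), ("A0", "Y1", "q", 2.0)]
        with pytest.raises(ValueError, match="single trait"):
            trim_records(table_from(rows))


class TestYearModel:
    def test_balanced_toy_recovers_genotype_contrast(self):
        # two genotypes (0 and 2), year effects +1/-1, no noise:
        # the GLS solution on this balanced design is the plain
        # genotype-mean contrast, untouched by the year term
        rows = [
            ("G1", "Y1", "p", 0.0 + 1.0),
            ("G1", "Y2", "p", 0.0 - 1.0),
            ("G2", "Y1", "p", 2.0 + 1.0),
            ("G2", "Y2", "p", 2.0 - 1.0),
        ]
        fit = fit_year_model(table_from(rows), "fixed")
        diff = fit.genotype_effects["G2"] - fit.genotype_effects["G1"]
        assert diff == pytest.approx(2.0, abs=1e-6)
        assert fit.genotype_effects["G1"] == pytest.approx(0.0, abs=1e-4)
        assert fit.year_effects["Y1"] > fit.year_effects["Y2"]

    def test_single_year_rejected(self):
        rows = [("A0", "Y1", "p", 1.0), ("A1", "Y1", "p", 2.0)]
        with pytest.raises(ValueError, match="two years"):
            fit_year_model(table_from(rows), "fixed")

    def test_variance_recovery_on_simulated_trial(self, trial_config):
        gm = simulate_genotypes(trial_config)
        table, _ = simulate_trial(gm, trial_config)
        fit = fit_year_model(table, "random")
        assert fit.converged
        nbar = len(table) / table["accession_id"].nunique()
        stats = estimate_heritability(fit.sigma_g2, fit.sigma_e2_bar, nbar)
        assert abs(stats.h2_pb - trial_config.heritability_target) < 0.15
        # residual-likelihood field is a genuine log-likelihood
        assert np.isfinite(fit.restricted_log_likelihood)


def holm_oracle(z, alpha):
    """Brute-force Holm step-down on two-sided normal p-values."""
    p = 2.0 * norm.sf(np.abs(z))
    order = np.argsort(p)
    m = len(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return set(np.flatnonzero(reject))


class TestOutliers:
    def make_table(self, seed, n_acc=40):
        cfg = SimulationConfig(
            n_accessions=n_acc, n_markers=60, n_years=3,
            year_plan={"Y1": 1.0, "Y2": 0.8, "Y3": 0.8},
            outlier_rate=0.0, seed=seed,
        )
        gm = simulate_genotypes(cfg)
        table, _ = simulate_trial(gm, cfg)
        return table

    def test_gross_outlier_flagged_exactly(self):
        table = self.make_table(1, n_acc=80).reset_index(drop=True)
        # plant the shift in a fully replicated accession: with a fixed
        # genotype term, part of a shift leaks into the entry mean, so
        # detectability needs replication beyond a single record pair
        counts = table["accession_id"].value_counts()
        acc = counts[counts == counts.max()].index[0]
        idx = table.index[table["accession_id"] == acc][0]
        fit = fit_year_model(table, "fixed")
        sd = np.sqrt(fit.sigma_e2_by_year[table.loc[idx, "year"]])
        table.loc[idx, "value"] += 10 * sd
        fit = fit_year_model(table, "fixed")
        flagged = detect_outliers(table, fit, alpha=0.05)
        assert flagged == [idx]

    @pytest.mark.parametrize("seed", range(10))
    def test_flags_match_holm_oracle(self, seed):
        table = self.make_table(seed).reset_index(drop=True)
        rng = np.random.default_rng(seed)
        bump = rng.choice(len(table), size=3, replace=False)
        table.loc[bump, "value"] += rng.choice([-6.0, 6.0], size=3)
        fit = fit_year_model(table, "fixed")
        flagged = set(detect_outliers(table, fit, alpha=0.05))
        sds = table["year"].map(lambda y: np.sqrt(fit.sigma_e2_by_year[y]))
        z = (fit.residuals / sds).to_numpy()
        assert flagged == holm_oracle(z, 0.05)

    def test_familywise_type_i_control(self):
        # clean data: familywise-corrected flags are rare
        flags = 0
        runs = 40
        for seed in range(runs):
            table = self.make_table(100 + seed, n_acc=30)
            fit = fit_year_model(table, "fixed")
            flags += len(detect_outliers(table, fit, alpha=0.05))
        assert flags / runs < 0.2


class TestComputeBlues:
    def test_planted_outliers_recovered_and_h2_improves(self):
        cfg = SimulationConfig(
            n_accessions=500, n_markers=200, n_years=4,
            year_plan={"Y1": 0.9, "Y2": 0.6, "Y3": 0.6, "Y4": 0.5},
            heritability_target=0.4,
            outlier_rate=0.013, outlier_shift=9.0, seed=77,
        )
        gm = simulate_genotypes(cfg)
        table, truth = simulate_trial(gm, cfg)
        table = table.reset_index(drop=True)
        planted = set(np.flatnonzero(truth.outlier_flags["trait"]))
        assert len(planted) >= 15
        curated, blues, before, after = compute_blues(table, alpha=0.05)
        removed = set(table.index) - set(curated.index)
        recovered = planted & removed
        assert len(recovered) >= len(planted) - 2
        assert after.h2 >= before.h2
        assert blues.outliers_removed >= len(recovered)

    def test_outlier_free_table_is_a_fixed_point(self, trial_config):
        gm = simulate_genotypes(trial_config)
        table, _ = simulate_trial(gm, trial_config)
        _, blues, before, after = compute_blues(table, alpha=0.01)
        assert blues.outliers_removed == 0
        assert before.h2 == pytest.approx(after.h2, abs=1e-9)
        assert (blues.standard_errors > 0).all()

    def test_blues_match_means_on_balanced_noise_free_toy(self):
        # balanced design, no noise: BLUEs are genotype means, and the
        # year effect (+/-1) cancels out of every entry mean
        rows = []
        for i, g in enumerate((10.0, 12.0, 14.0)):
            rows += [(f"G{i}", "Y1", "p", g + 1.0), (f"G{i}", "Y2", "p", g - 1.0)]
        _, blues, _, _ = compute_blues(table_from(rows))
        for i, g in enumerate((10.0, 12.0, 14.0)):
            assert blues.estimates[f"G{i}"] == pytest.approx(g, abs=1e-4)


class TestHeritability:
    def test_boundaries(self):
        assert estimate_heritability(1.0, 0.0, 2.0).h2 == 1.0
        assert estimate_heritability(0.0, 1.0, 2.0).h2 == 0.0
        with pytest.raises(ValueError):
            estimate_heritability(0.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            estimate_heritability(1.0, 1.0, 0.5)

    @given(
        sg=st.floats(0.01, 100), se=st.floats(0.01, 100),
        nbar=st.floats(1.0, 10.0), bump=st.floats(0.01, 10.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotonicity_properties(self, sg, se, nbar, bump):
        base = estimate_heritability(sg, se, nbar)
        assert 0.0 <= base.h2 <= 1.0
        assert base.h2_pb <= base.h2 + 1e-12
        assert estimate_heritability(sg + bump, se, nbar).h2 >= base.h2
        assert estimate_heritability(sg, se, nbar + bump).h2 >= base.h2
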