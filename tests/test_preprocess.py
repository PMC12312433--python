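"""Imputation, standardization, and descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clpnet import (
    InputError,
    PanelDataset,
    descriptive_table,
    impute_random_forest,
    inject_missingness,
    simulate_panel,
    standardize,
)
from clpnet.preprocess import mean_impute

from conftest import make_config, sparse_B


def duplicated_column_panel(n=200, seed=0, n_hidden=8):
    """Panel where N1_t1 duplicates N0_t1; hide cells of N1_t1 to recover."""
    rng = np.random.default_rng(seed)
    x = rng.normal(50, 10, n)
    frame = pd.DataFrame(
        {
            "N0_t1": x,
            "N0_t2": x + rng.normal(0, 1, n),
            "N1_t1": x.copy(),
            "N1_t2": x + rng.normal(0, 1, n),
            "age": rng.normal(16, 1, n),
        }
    )
    data = PanelDataset(frame=frame, node_names=["N0", "N1"], covariates=["age"])
    hidden_rows = rng.choice(n, n_hidden, replace=False)
    truth = data.frame.loc[hidden_rows, "N1_t1"].to_numpy().copy()
    data.frame.loc[hidden_rows, "N1_t1"] = np.nan
    data.mask.loc[hidden_rows, "N1_t1"] = True
    return data, hidden_rows, truth


class TestImputation:
    def test_no_missing_returns_unchanged(self):
        data, _ = simulate_panel(make_config(n=60, seed=1))
        out = impute_random_forest(data, n_trees=10, seed=0)
        assert out.frame.equals(data.frame)

    def test_observed_cells_never_altered(self):
        data, _ = simulate_panel(make_config(n=120, seed=2, missing_rate=0.15))
        out = impute_random_forest(data, n_trees=20, max_iter=3, seed=0)
        for col in data.node_columns():
            obs = ~data.mask[col].to_numpy()
            np.testing.assert_array_equal(
                out.frame.loc[obs, col].to_numpy(), data.frame.loc[obs, col].to_numpy()
            )
        assert not out.frame[out.node_columns()].isna().to_numpy().any()

    def test_duplicated_column_recovery(self):
        data, rows, truth = duplicated_column_panel(seed=3)
        out = impute_random_forest(data, n_trees=100, max_iter=5, seed=0)
        sd = np.nanstd(data.frame["N1_t1"], ddof=1)
        err = np.abs(out.frame.loc[rows, "N1_t1"].to_numpy() - truth)
        assert (err < 0.1 * sd).all()

    def test_rmse_non_increasing_in_trees(self):
        data, rows, truth = duplicated_column_panel(n=300, seed=5, n_hidden=20)

        def rmse(trees):
            out = impute_random_forest(data, n_trees=trees, max_iter=3, seed=1)
            return np.sqrt(np.mean((out.frame.loc[rows, "N1_t1"].to_numpy() - truth) ** 2))

        # Monte-Carlo tolerance: a big forest must not be clearly worse
        assert rmse(100) <= rmse(5) * 1.25

    def test_beats_mean_imputation_under_mcar(self):
        cfg = make_config(n=250, B=sparse_B(auto=0.4), corr=0.3, residual=0.8,
                          means=50.0, sds=10.0, seed=7)
        complete, _ = simulate_panel(cfg)
        holed = inject_missingness(complete, 0.10, "MCAR", seed=99)
        m = holed.mask[holed.node_columns()].to_numpy()
        truth = complete.frame[complete.node_columns()].to_numpy()
        rf = impute_random_forest(holed, n_trees=50, max_iter=5, seed=0)
        mi = mean_impute(holed)
        rf_err = np.sqrt(np.mean((rf.frame[holed.node_columns()].to_numpy()[m] - truth[m]) ** 2))
        mi_err = np.sqrt(np.mean((mi.frame[holed.node_columns()].to_numpy()[m] - truth[m]) ** 2))
        assert rf_err < mi_err

    def test_fully_missing_column_rejected(self):
        data, _ = simulate_panel(make_config(n=30, seed=1))
        data.frame["N2_t1"] = np.nan
        data.mask["N2_t1"] = True
        with pytest.raises(InputError, match="N2_t1"):
            impute_random_forest(data, n_trees=5, seed=0)

    def test_deterministic_under_seed(self):
        data, _ = simulate_panel(make_config(n=100, seed=4, missing_rate=0.1))
        a = impute_random_forest(data, n_trees=15, seed=7)
        b = impute_random_forest(data, n_trees=15, seed=7)
        assert a.frame.equals(b.frame)


class TestStandardize:
    def test_zscore_definition(self):
        data, _ = simulate_panel(make_config(n=80, means=30.0, sds=5.0, seed=1))
        std, _ = standardize(data)
        for col in std.node_columns() + ["age"]:
            vals = std.frame[col].to_numpy()
            assert abs(vals.mean()) < 1e-10
            assert abs(vals.std(ddof=1) - 1) < 1e-10

    def test_roundtrip_inversion(self):
        data, _ = simulate_panel(make_config(n=80, means=30.0, sds=5.0, seed=2))
        std, rec = standardize(data)
        back = rec.invert(std)
        np.testing.assert_allclose(
            back.frame[data.node_columns()].to_numpy(),
            data.frame[data.node_columns()].to_numpy(),
            atol=1e-10,
        )

    def test_constant_column_rejected(self):
        data, _ = simulate_panel(make_config(n=40, seed=3))
        data.frame["N0_t1"] = 5.0
        with pytest.raises(InputError, match="N0_t1"):
            standardize(data)

    def test_binary_covariate_centered_not_scaled(self):
        data, _ = simulate_panel(make_config(n=40, seed=3))
        data.frame["code"] = (np.arange(40) % 2).astype(float)
        data.covariates = ["age", "code"]
        data.mask["code"] = False
        std, rec = standardize(data)
        assert rec.scales["code"] == 1.0
        assert abs(std.frame["code"].mean()) < 1e-12
        assert set(np.round(np.unique(std.frame["code"]), 6)) == {-0.5, 0.5}


class TestDescriptives:
    def _two_group_panel(self, a_vals, b_vals):
        n = len(a_vals) + len(b_vals)
        vals = np.concatenate([a_vals, b_vals]).astype(float)
        frame = pd.DataFrame(
            {
                "N0_t1": vals,
                "N0_t2": vals,
                "age": np.full(n, 16.0),
                "group": ["a"] * len(a_vals) + ["b"] * len(b_vals),
            }
        )
        return PanelDataset(frame=frame, node_names=["N0"], covariates=[], group_col="group")

    def test_identical_groups_give_t0_p1(self):
        x = np.random.default_rng(0).normal(size=30)
        data = self._two_group_panel(x, x)
        tab = descriptive_table(data)
        row = tab[tab["variable"] == "N0_t1"].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_degenerate_zero_variance_convention(self):
        same = self._two_group_panel([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert descriptive_table(same)["p"].iloc[0] == 1.0
        diff = self._two_group_panel([3.0, 3.0, 3.0], [4.0, 4.0, 4.0])
        assert descriptive_table(diff)["p"].iloc[0] == 0.0

    def test_matches_welch_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 40), rng.normal(0.4, 2, 25)
        tab = descriptive_table(self._two_group_panel(a, b))
        t, p = stats.ttest_ind(a, b, equal_var=False)
        row = tab[tab["variable"] == "N0_t1"].iloc[0]
        assert row["statistic"] == pytest.approx(t)
        assert row["p"] == pytest.approx(p)
        assert tab.groupby("variable")["n"].sum().eq(65).all()

    def test_type_one_error_calibration(self):
        """Under the null, ~5% of Welch tests reject at alpha=0.05."""
        rng = np.random.default_rng(2)
        reps = 1000
        rejections = 0
        for _ in range(reps):
            a, b = rng.normal(size=(2, 25))
            _, p = stats.ttest_ind(a, b, equal_var=False)
            rejections += p < 0.05
        # verify the same engine drives descriptive_table on one replicate
        a, b = rng.normal(size=(2, 25))
        tab = descriptive_table(self._two_group_panel(a, b))
        assert tab["p"].iloc[0] == pytest.approx(stats.ttest_ind(a, b, equal_var=False)[1])
        assert 0.028 <= rejections / reps <= 0.075

    def test_more_than_two_groups_rejected(self):
        data = self._two_group_panel([1.0, 2.0], [3.0, 4.0])
        data.frame.loc[0, "group"] = "c"
        with pytest.raises(InputError):
            descriptive_table(data)


def test_estimation_invariant_to_affine_input_rescaling():
    """Standardize-then-estimate is unchanged by affine rescaling of raw columns."""
    from clpnet import EstimationOptions, estimate_network

    data, _ = simulate_panel(make_config(n=300, B=sparse_B(), seed=11))
    scaled = data.copy()
    scaled.frame["N0_t1"] = scaled.frame["N0_t1"] * 10 + 7
    scaled.frame["N3_t2"] = scaled.frame["N3_t2"] * -2 + 1
    opts = EstimationOptions(lambda_grid=[0.05], seed=5)  # fixed penalty
    net_a = estimate_network(standardize(data)[0], ["age"], opts)
    net_b = estimate_network(standardize(scaled)[0], ["age"], opts)
    # sign flip on a rescaled column flips its edges; compare magnitudes
    np.testing.assert_allclose(np.abs(net_a.B), np.abs(net_b.B), atol=1e-8)
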