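"""Difference-frame construction, masking, and the ensemble reconstruction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from diffgblup import (
    GenomicRelMatrix,
    build_difference_frame,
    ensemble_predictions,
    enumerate_pairs,
    fit_difference_model,
    mask_for_target_env,
    run_m2,
)
from conftest import balanced_table


def random_table(J, I, seed=0, lines=None):
    rng = np.random.default_rng(seed)
    envs = [f"E{i + 1}" for i in range(I)]
    return balanced_table(
        {e: rng.normal(0, 1, J) for e in envs}, lines=lines
    )


def oracle_dhat(masked_frame, target_env, wide):
    """Perfect difference predictions from the true phenotypes."""
    sub = masked_frame.frame[masked_frame.masked]
    out = []
    for row in sub.itertuples():
        out.append(
            wide.at[row.line, row.env_i] - wide.at[row.line, row.env_iprime]
        )
    return np.array(out)


class TestEnumeratePairs:
    def test_three_environments(self):
        assert enumerate_pairs(["E1", "E2", "E3"]) == [
            ("E1", "E2"),
            ("E1", "E3"),
            ("E2", "E3"),
        ]

    def test_single_pair(self):
        assert enumerate_pairs(["E1", "E2"]) == [("E1", "E2")]

    def test_six_environments_exhaustive(self):
        envs = [f"E{i}" for i in range(1, 7)]
        pairs = enumerate_pairs(envs)
        brute = [
            (envs[a], envs[b])
            for a in range(6)
            for b in range(a + 1, 6)
        ]
        assert pairs == brute and len(pairs) == 15

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_pairs(["E1", "E1", "E2"])


class TestBuildDifferenceFrame:
    def test_three_by_three_layout(self, toy_phenos):
        diff = build_difference_frame(toy_phenos, "yield")
        f = diff.frame
        assert len(f) == 9
        assert list(f["obs"]) == list(range(1, 10))
        assert list(f["env_i"]) == ["E1"] * 3 + ["E1"] * 3 + ["E2"] * 3
        assert list(f["env_iprime"]) == ["E2"] * 3 + ["E3"] * 3 + ["E3"] * 3
        assert list(f["line"]) == ["g1", "g2", "g3"] * 3
        np.testing.assert_allclose(f["d"], f["y_i"] - f["y_iprime"])

    def test_identical_environments_give_zero_differences(self):
        tbl = balanced_table({"E1": (1, 2), "E2": (1, 2), "E3": (1, 2)})
        diff = build_difference_frame(tbl, "yield")
        np.testing.assert_array_equal(diff.frame["d"], 0.0)

    def test_hand_computed_difference_column(self):
        tbl = balanced_table({"E1": (1, 2), "E2": (3, 5), "E3": (0, 0)})
        diff = build_difference_frame(tbl, "yield")
        np.testing.assert_allclose(diff.frame["d"], [-2, -3, 1, 2, 3, 5])

    def test_two_environments_rejected_by_default(self):
        tbl = balanced_table({"E1": (1, 2), "E2": (3, 4)})
        with pytest.raises(ValueError, match="at least 3"):
            build_difference_frame(tbl, "yield")

    @given(
        J=st.integers(min_value=2, max_value=10),
        I=st.integers(min_value=3, max_value=6),
    )
    def test_row_count_law(self, J, I):
        tbl = random_table(J, I, seed=J * 10 + I)
        diff = build_difference_frame(tbl, "yield")
        assert len(diff.frame) == J * I * (I - 1) // 2


class TestMaskForTargetEnv:
    def test_table_two_masking(self, toy_phenos):
        diff = build_difference_frame(toy_phenos, "yield")
        masked = mask_for_target_env(diff, "E1")
        d = masked.frame["d"]
        assert d.isna().tolist() == [True] * 6 + [False] * 3
        np.testing.assert_allclose(d[6:], diff.frame["d"][6:])

    def test_absent_target_rejected(self, toy_phenos):
        diff = build_difference_frame(toy_phenos, "yield")
        with pytest.raises(ValueError, match="E9"):
            mask_for_target_env(diff, "E9")

    @given(
        I=st.integers(min_value=3, max_value=6),
        target=st.integers(min_value=0, max_value=5),
    )
    def test_masked_row_count_is_lines_times_envs_minus_one(self, I, target):
        target = target % I
        J = 4
        tbl = random_table(J, I, seed=I)
        diff = build_difference_frame(tbl, "yield")
        masked = mask_for_target_env(diff, f"E{target + 1}")
        assert int(masked.masked.sum()) == J * (I - 1)


class TestEnsemblePredictions:
    def test_worked_numeric_example(self):
        # one line, target E1: ((5.0 + 1.0) + (7.0 - 0.5)) / 2 = 6.25
        tbl = balanced_table(
            {"E1": (0.0, 1.0), "E2": (5.0, 1.0), "E3": (7.0, 1.0)},
            lines=["g1", "g2"],
        )
        diff = mask_for_target_env(build_difference_frame(tbl, "yield"), "E1")
        d_hat = np.array([1.0, 0.0, -0.5, 0.0])  # pairs (E1,E2) then (E1,E3)
        res = ensemble_predictions(diff, d_hat, "E1")
        assert res.loc[res["line"] == "g1", "predicted"].item() == pytest.approx(6.25)

    def test_single_pair_reduction(self):
        # I=2 tolerated here (frame built with a relaxed guard): the
        # ensemble is the single term y_i' + d_hat
        tbl = balanced_table({"E1": (0.0, 0.0), "E2": (3.0, 4.0)})
        diff = mask_for_target_env(
            build_difference_frame(tbl, "yield", min_envs=2), "E1"
        )
        res = ensemble_predictions(diff, np.array([1.5, -2.0]), "E1")
        np.testing.assert_allclose(res["predicted"], [3.0 + 1.5, 4.0 - 2.0])

    @given(
        J=st.integers(min_value=2, max_value=50),
        I=st.integers(min_value=3, max_value=6),
        target=st.integers(min_value=0, max_value=5),
    )
    def test_telescoping_identity(self, J, I, target):
        """Perfect difference predictions recover the target phenotypes
        exactly, for every choice of target environment."""
        target_env = f"E{(target % I) + 1}"
        tbl = random_table(J, I, seed=J + 7 * I)
        wide = tbl.pivot(index="line", columns="env", values="value")
        diff = mask_for_target_env(build_difference_frame(tbl, "yield"), target_env)
        d_hat = oracle_dhat(diff, target_env, wide)
        res = ensemble_predictions(diff, d_hat, target_env)
        lines = list(res["line"])
        np.testing.assert_allclose(
            res["predicted"],
            wide.loc[lines, target_env],
            atol=1e-12,
        )

    def test_antisymmetry_under_environment_reordering(self):
        """Swapping two environments in the input ordering flips the sign
        of the affected difference blocks but leaves the ensemble
        reconstruction unchanged (given correspondingly perfect d_hat)."""
        J = 5
        tbl_a = random_table(J, 4, seed=3)
        order_b = ["E3", "E2", "E1", "E4"]
        tbl_b = (
            tbl_a.assign(_k=tbl_a["env"].map({e: i for i, e in enumerate(order_b)}))
            .sort_values(["_k", "line"], kind="stable")
            .drop(columns="_k")
            .reset_index(drop=True)
        )
        wide = tbl_a.pivot(index="line", columns="env", values="value")
        preds = []
        for tbl in (tbl_a, tbl_b):
            diff = mask_for_target_env(build_difference_frame(tbl, "yield"), "E2")
            d_hat = oracle_dhat(diff, "E2", wide)
            res = ensemble_predictions(diff, d_hat, "E2").set_index("line")
            preds.append(res["predicted"])
        pd.testing.assert_series_equal(preds[0], preds[1].reindex(preds[0].index))

    def test_wrong_dhat_length_rejected(self, toy_phenos):
        diff = mask_for_target_env(build_difference_frame(toy_phenos, "yield"), "E1")
        with pytest.raises(ValueError, match="J"):
            ensemble_predictions(diff, np.zeros(5), "E1")


class TestFitDifferenceModel:
    def test_zero_training_differences_give_zero_predictions(self, identity_grm):
        tbl = balanced_table({"E1": (9, 5, 7), "E2": (1, 2, 3), "E3": (1, 2, 3)})
        diff = mask_for_target_env(build_difference_frame(tbl, "yield"), "E1")
        d_hat = fit_difference_model(diff, identity_grm)
        np.testing.assert_allclose(d_hat, 0.0, atol=1e-8)

    def test_ridge_closed_form_with_fixed_components(self, identity_grm):
        tbl = balanced_table({"E1": (0, 0, 0), "E2": (1, -1, 2), "E3": (2, 0, 1)})
        diff = mask_for_target_env(build_difference_frame(tbl, "yield"), "E1")
        s2g, s2e = 0.8, 0.3
        d_hat = fit_difference_model(
            diff, identity_grm, fixed_components={"line": s2g, "residual": s2e}
        )
        # oracle: kernel ridge on the 3 training rows (pair E2,E3)
        d = diff.frame["d"].to_numpy(float)
        obs = ~np.isnan(d)
        lines = diff.frame["line"].to_numpy()
        ix = identity_grm.index_of(lines)
        K = identity_grm.values[np.ix_(ix, ix)]
        Koo = K[np.ix_(obs, obs)]
        V = s2g * Koo + s2e * np.eye(int(obs.sum()))
        one = np.ones(int(obs.sum()))
        Vinv = np.linalg.inv(V)
        mu = one @ Vinv @ d[obs] / (one @ Vinv @ one)
        pred = mu + s2g * K[np.ix_(~obs, obs)] @ Vinv @ (d[obs] - mu)
        np.testing.assert_allclose(d_hat, pred, atol=1e-8)

    def test_line_signal_recovered_in_differences(self):
        """Training differences carrying a line-specific component are
        predictive of the masked differences of the same lines."""
        rng = np.random.default_rng(0)
        corrs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            J, I = 40, 4
            lines = [f"g{j}" for j in range(J)]
            G = GenomicRelMatrix(
                line_ids=np.array(lines, dtype=object), values=np.eye(J)
            )
            # environment-specific line deviations induce correlated
            # differences: d_(i,i'),j = u_ij - u_i'j
            u = rng.normal(0, 1.0, size=(I, J))
            envs = [f"E{i + 1}" for i in range(I)]
            tbl = balanced_table(
                {envs[i]: u[i] + 0.3 * rng.normal(size=J) for i in range(I)},
                lines=lines,
            )
            diff = mask_for_target_env(build_difference_frame(tbl, "yield"), "E1")
            d_hat = fit_difference_model(diff, G)
            wide = tbl.pivot(index="line", columns="env", values="value")
            d_true = oracle_dhat(diff, "E1", wide)
            corrs.append(np.corrcoef(d_hat, d_true)[0, 1])
        assert np.mean(corrs) > 0.0


class TestRunM2:
    def test_constant_phenotypes_predict_constant(self, identity_grm):
        tbl = balanced_table({"E1": (4, 4, 4), "E2": (4, 4, 4), "E3": (4, 4, 4)})
        res = run_m2(tbl, identity_grm, "E1", "yield")
        np.testing.assert_allclose(res["predicted"], 4.0, atol=1e-6)

    def test_target_env_shift_leaves_predictions_unchanged(self, identity_grm):
        """Adding a constant to every target-environment phenotype cannot
        move the predictions: they are built solely from training
        environments and predicted differences."""
        tbl = balanced_table({"E1": (1, 2, 3), "E2": (2, 4, 1), "E3": (0, 1, 2)})
        res0 = run_m2(tbl, identity_grm, "E1", "yield")
        shifted = tbl.copy()
        shifted.loc[shifted["env"] == "E1", "value"] += 100.0
        res1 = run_m2(shifted, identity_grm, "E1", "yield")
        np.testing.assert_allclose(res1["predicted"], res0["predicted"], atol=1e-10)
        np.testing.assert_allclose(res1["observed"], res0["observed"] + 100.0)

    def test_observed_column_attached(self, identity_grm, toy_phenos):
        res = run_m2(toy_phenos, identity_grm, "E2", "yield")
        wide = toy_phenos.pivot(index="line", columns="env", values="value")
        np.testing.assert_allclose(res["observed"], wide.loc[res["line"], "E2"])
        assert set(res["model"]) == {"M2"}
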