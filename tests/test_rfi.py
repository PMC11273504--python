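"""Expected-DMI models, residual extraction, classes, and tallies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rfitrial.errors import DomainError, IdMismatchError, SingularDesignError
from rfitrial.rfi import (
    RFIClassification,
    RFIModelSpec,
    classify_rfi,
    class_summary,
    compute_rfi_models,
    dmi_excess_percent,
    fit_dmi_model,
    rank_change_tally,
)
from rfitrial.simulate import GroupConfig, SimConfig, generate_trial


def toy_table(n=6, seed=0):
    rng = np.random.default_rng(seed)
    adg = rng.uniform(1.0, 1.8, n)
    mmwt = rng.uniform(60, 72, n)
    dmi = 1.0 + 2.0 * adg + 0.1 * mmwt + rng.normal(0, 0.3, n)
    return pd.DataFrame(
        {
            "id": [f"h{i}" for i in range(n)],
            "group": "g",
            "adg1": adg,
            "mmwt1": mmwt,
            "adg2": adg,
            "mmwt2": mmwt,
            "mean_dmi": dmi,
            "ubf_mm": rng.uniform(5, 10, n),
        }
    )


class TestFitDMIModel:
    def test_exact_linear_data_gives_zero_residuals(self):
        t = toy_table(8)
        t["mean_dmi"] = 1.0 + 2.0 * t["adg1"] + 0.1 * t["mmwt1"]
        fit = fit_dmi_model(t, RFIModelSpec("regression"))
        assert fit.r_squared == pytest.approx(1.0)
        assert np.allclose(fit.residuals, 0.0, atol=1e-8)

    def test_coefficients_match_normal_equations_oracle(self):
        t = toy_table(6)
        fit = fit_dmi_model(t, RFIModelSpec("regression"))
        X = np.column_stack([np.ones(6), t["adg1"], t["mmwt1"]])
        beta = np.linalg.solve(X.T @ X, X.T @ t["mean_dmi"].to_numpy())
        assert fit.coefficients["const"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.coefficients["adg1"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.coefficients["mmwt1"] == pytest.approx(beta[2], abs=1e-8)

    def test_residuals_sum_to_zero_per_scope(self, growth_table):
        for scope in ("pooled", "per_group", "group_fixed_effect"):
            fit = fit_dmi_model(growth_table, RFIModelSpec("regression", fit_scope=scope))
            if scope == "per_group":
                by_group = fit.residuals.groupby(growth_table.set_index("id")["group"])
                for _, resid in by_group:
                    assert abs(resid.sum()) < 1e-8 * len(resid) + 1e-8
            else:
                assert abs(fit.residuals.sum()) < 1e-8 * fit.n

    def test_residuals_orthogonal_to_predictors(self, growth_table):
        fit = fit_dmi_model(growth_table, RFIModelSpec("regression"))
        table = growth_table.set_index("id")
        for col in ("adg1", "mmwt1"):
            dot = float(np.dot(fit.residuals, table.loc[fit.residuals.index, col]))
            scale = float(np.abs(table[col]).mean())
            assert abs(dot) <= 1e-6 * fit.n * scale

    def test_missing_ubf_dropped_only_from_ubf_models(self):
        t = toy_table(12, seed=3)
        t.loc[t.index[:3], "ubf_mm"] = np.nan
        plain = fit_dmi_model(t, RFIModelSpec("regression", include_ubf=False))
        adj = fit_dmi_model(t, RFIModelSpec("regression", include_ubf=True))
        assert plain.n == 12
        assert adj.n == 9
        assert adj.n_dropped_missing_ubf == 3

    def test_singular_design_names_collinear_columns(self):
        t = toy_table(8)
        t["mmwt1"] = 2.0 * t["adg1"]  # perfectly collinear
        with pytest.raises(SingularDesignError, match="adg1|mmwt1"):
            fit_dmi_model(t, RFIModelSpec("regression"))

    def test_nested_ubf_model_never_decreases_r2(self, growth_table):
        fits = compute_rfi_models(growth_table)
        assert fits["RFI_bf1"].r_squared >= fits["RFI_1"].r_squared
        assert fits["RFI_bf2"].r_squared >= fits["RFI_2"].r_squared


class TestFourModels:
    def test_zero_noise_no_ubf_coupling_gives_null_residuals(self):
        cfg = SimConfig(
            groups=(GroupConfig("A", "1", 8, 300.0, 25.0, 1.3, 0.2),),
            sigma_rfi=0.0,
            sigma_daily_intake=0.0,
            sigma_weighing=0.0,
            dmi_coef_ubf=0.0,
            ubf_rfi_corr=0.0,
        )
        t = generate_trial(cfg, seed=9)
        from rfitrial.growth import summarize_cohort

        table = summarize_cohort(t.heifers, t.intake, t.weights)
        fits = compute_rfi_models(table)
        # generated CSV values carry 4-decimal rounding, hence the tolerance
        assert np.allclose(fits["RFI_1"].residuals, 0.0, atol=1e-3)
        assert np.allclose(fits["RFI_2"].residuals, 0.0, atol=1e-3)

    def test_adg_variants_produce_nearly_identical_rfi(self, pipeline_result):
        fits = pipeline_result.fits
        r = np.corrcoef(fits["RFI_1"].residuals, fits["RFI_2"].residuals)[0, 1]
        assert r >= 0.97

    def test_true_rfi_recovered_from_model1(self, default_trial, pipeline_result):
        resid = pipeline_result.fits["RFI_1"].residuals
        truth = default_trial.truth.set_index("id").loc[resid.index, "true_rfi"]
        assert np.corrcoef(truth, resid)[0, 1] >= 0.80


class TestClassification:
    def make_fit(self, values, ids=None):
        ids = ids or [f"h{i}" for i in range(len(values))]
        resid = pd.Series(values, index=ids, dtype=float)
        return RFIClassification, resid

    def test_boundary_and_interior_labels(self):
        # group stats: mean 0, sd 1 for values [-2,-1,0,1,2] -> sd = sqrt(2.5)
        resid = pd.Series([-2.0, -1.0, 0.0, 1.0, 2.0], index=list("abcde"))
        from rfitrial.rfi import RFIFit

        fit = RFIFit(RFIModelSpec("regression"), {}, 0.5, resid, 5)
        groups = pd.Series("g", index=resid.index)
        cls = classify_rfi(fit, groups)
        sd = resid.std(ddof=1)
        for hid, value in resid.items():
            if value > sd:
                assert cls.labels[hid] == "high"
            elif value < -sd:
                assert cls.labels[hid] == "low"
            else:
                assert cls.labels[hid] == "medium"

    def test_exact_one_sd_boundary_is_medium(self):
        from rfitrial.rfi import RFIFit

        # mean 0, sample sd exactly 1, with animals sitting exactly at +/-1 SD
        vals = pd.Series([-1.0, -1.0, 0.0, 1.0, 1.0], index=list("abcde"))
        assert vals.std(ddof=1) == 1.0
        fit = RFIFit(RFIModelSpec("regression"), {}, 0.5, vals, 5)
        cls = classify_rfi(fit, pd.Series("g", index=vals.index))
        assert (cls.labels == "medium").all()  # strict "> 1 SD" reading

    def test_above_one_sd_is_high(self):
        from rfitrial.rfi import RFIFit

        vals = pd.Series([-1.5, -0.2, 0.0, 0.2, 1.5], index=list("abcde"))
        fit = RFIFit(RFIModelSpec("regression"), {}, 0.5, vals, 5)
        cls = classify_rfi(fit, pd.Series("g", index=vals.index))
        sd = vals.std(ddof=1)
        assert 1.5 > sd  # the extreme animals sit beyond 1 SD
        assert cls.labels["e"] == "high" and cls.labels["a"] == "low"

    def test_normal_residuals_class_proportions(self):
        from rfitrial.rfi import RFIFit

        rng = np.random.default_rng(12)
        vals = pd.Series(rng.standard_normal(10_000))
        vals.index = [f"h{i}" for i in range(len(vals))]
        fit = RFIFit(RFIModelSpec("regression"), {}, 0.5, vals, len(vals))
        cls = classify_rfi(fit, pd.Series("g", index=vals.index))
        props = cls.labels.value_counts(normalize=True)
        assert props["low"] == pytest.approx(0.1587, abs=0.02)
        assert props["medium"] == pytest.approx(0.6827, abs=0.02)
        assert props["high"] == pytest.approx(0.1587, abs=0.02)

    def test_zero_sd_group_all_medium(self):
        from rfitrial.rfi import RFIFit

        vals = pd.Series([0.5, 0.5, 0.5], index=list("abc"))
        fit = RFIFit(RFIModelSpec("regression"), {}, 0.0, vals, 3)
        cls = classify_rfi(fit, pd.Series("g", index=vals.index))
        assert set(cls.labels) == {"medium"}

    @given(shift=st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_constant_shift_within_group(self, shift):
        from rfitrial.rfi import RFIFit

        rng = np.random.default_rng(7)
        vals = pd.Series(rng.normal(0, 1, 40), index=[f"h{i}" for i in range(40)])
        groups = pd.Series("g", index=vals.index)
        base = classify_rfi(RFIFit(RFIModelSpec("regression"), {}, 0.5, vals, 40), groups)
        moved = classify_rfi(
            RFIFit(RFIModelSpec("regression"), {}, 0.5, vals + shift, 40), groups
        )
        assert (base.labels == moved.labels).all()


class TestClassSummary:
    def test_printed_class_means_give_33_percent_excess(self):
        assert dmi_excess_percent(8.27, 11.01) == 33
        assert dmi_excess_percent(9.0, 9.0) == 0

    def test_three_animal_toy_means(self):
        from rfitrial.rfi import RFIFit

        table = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "group": "g",
                "initial_bw": [300.0, 310.0, 290.0],
                "final_bw": [390.0, 400.0, 380.0],
                "adg1": [1.3, 1.3, 1.3],
                "adg2": [1.3, 1.3, 1.3],
                "mmwt1": [65.0, 66.0, 64.0],
                "mmwt2": [65.0, 66.0, 64.0],
                "mean_dmi": [8.0, 9.5, 11.0],
            }
        )
        resid = pd.Series([-1.2, 0.0, 1.2], index=["a", "b", "c"])
        fit = RFIFit(RFIModelSpec("regression"), {}, 0.5, resid, 3)
        labels = pd.Series(["low", "medium", "high"], index=["a", "b", "c"])
        cls = RFIClassification(labels=labels, group_stats=pd.DataFrame())
        out = class_summary(table, cls, fit)
        assert out.loc["low", ("mean", "mean_dmi")] == pytest.approx(8.0)
        assert out.loc["high", ("mean", "initial_bw")] == pytest.approx(290.0)
        assert out.attrs["dmi_excess_pct"] == pytest.approx(round(100 * 3 / 8.0))


class TestRankChangeTally:
    def labels(self, counts):
        """Build two label vectors realizing the given (from, to) counts."""
        a, b = [], []
        for (fr, to), n in counts.items():
            a += [fr] * n
            b += [to] * n
        idx = [f"h{i}" for i in range(len(a))]
        return pd.Series(a, index=idx), pd.Series(b, index=idx)

    def test_identical_classifications_change_nothing(self):
        a, b = self.labels({("low", "low"): 5, ("medium", "medium"): 8, ("high", "high"): 3})
        _, changed = rank_change_tally(a, b)
        assert changed == 0

    @pytest.mark.parametrize(
        "transitions, total",
        [
            # the two published rank-change scenarios among 176 animals
            ({("high", "medium"): 7, ("medium", "low"): 8, ("medium", "high"): 4, ("low", "medium"): 9}, 28),
            ({("high", "medium"): 2, ("medium", "high"): 9, ("low", "medium"): 7, ("medium", "low"): 6}, 24),
        ],
    )
    def test_off_diagonal_totals(self, transitions, total):
        diagonal = {("low", "low"): 20, ("medium", "medium"): 100, ("high", "high"): 176 - 120 - total}
        a, b = self.labels({**transitions, **diagonal})
        matrix, changed = rank_change_tally(a, b)
        assert changed == total
        assert matrix.to_numpy().sum() == 176
        for (fr, to), n in transitions.items():
            assert matrix.at[fr, to] == n

    def test_id_mismatch_raises(self):
        a = pd.Series(["low"], index=["x"])
        b = pd.Series(["low"], index=["y"])
        with pytest.raises(IdMismatchError, match="x"):
            rank_change_tally(a, b)
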