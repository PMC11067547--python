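"""Crossed random-intercept mixed models and inter-visit differencing."""

import numpy as np
import pandas as pd
import pytest

from fcpoct import (
    BIOMARKERS,
    LAYERS,
    ModelSpec,
    fit_cross_sectional,
    fit_intervisit,
    intervisit_differences,
)


def synth_table(seed=0, n_pat=12, n_vis=3, n_grid=56, sds=(1.2, 0.4, 0.7, 1.0),
                beta=None):
    """Point-wise table drawn directly from the model the fitter assumes."""
    rng = np.random.default_rng(seed)
    beta = beta or {"intercept": 4.0, "age": -0.08, "pseudophakic": 0.3,
                    "flag_ped": -1.3, "flag_hrf": -0.9}
    idx = pd.MultiIndex.from_product(
        [range(n_pat), range(n_vis), range(n_grid)],
        names=["p", "v", "k"]).to_frame(index=False)
    n = len(idx)
    df = pd.DataFrame({
        "eye_id": "E" + idx.p.astype(str),
        "patient_id": "P" + idx.p.astype(str),
        "group": "amd", "valid": True,
        "visit_index": idx.v,
        "months_since_baseline": idx.v * 12.0,
        "grid_index": idx.k,
        "age_years": np.repeat(rng.normal(70, 9, n_pat), n_vis * n_grid),
        "pseudophakic": np.repeat(rng.random(n_pat) < 0.3, n_vis * n_grid),
        "mesopic_censored": False, "scotopic_censored": False,
    })
    for b in BIOMARKERS:
        df[f"flag_{b}"] = rng.random(n) < 0.15
    for layer in LAYERS:
        df[f"z_{layer}"] = rng.standard_normal(n)
    u = rng.normal(0, sds[0], n_pat)[idx.p]
    v = rng.normal(0, sds[1], (n_pat, n_vis))[idx.p, idx.v]
    w = rng.normal(0, sds[2], n_grid)[idx.k]
    lin = np.full(n, beta["intercept"], dtype=float)
    lin += beta["age"] * df["age_years"].to_numpy()
    lin += beta["pseudophakic"] * df["pseudophakic"].to_numpy()
    for key, val in beta.items():
        if key.startswith("flag_") or key.startswith("z_"):
            lin += val * df[key].to_numpy(dtype=float)
    eps = rng.normal(0, sds[3], n) if sds[3] > 0 else 0.0
    df["mesopic_dev"] = lin + u + v + w + eps
    df["scotopic_dev"] = df["mesopic_dev"]
    return df


class TestCrossSectionalFit:
    def test_profiled_reml_matches_statsmodels_mixedlm(self):
        """Dual-route check: custom solver vs statsmodels on one dataset."""
        df = synth_table(seed=5)
        fast = fit_cross_sectional(df, ModelSpec(modality="mesopic"))
        slow = fit_cross_sectional(
            df, ModelSpec(modality="mesopic", backend="mixedlm"))
        fe_f, fe_s = fast.fixed_effects, slow.fixed_effects
        np.testing.assert_allclose(fe_f["estimate"], fe_s["estimate"],
                                   atol=2e-4)
        np.testing.assert_allclose(fe_f["se"], fe_s["se"], rtol=2e-3)
        for term in ("patient", "visit", "grid", "residual"):
            assert fast.vcomp[term] == pytest.approx(slow.vcomp[term],
                                                     rel=0.02, abs=1e-3)

    def test_zero_variance_reduces_to_ols(self):
        df = synth_table(seed=2, sds=(0, 0, 0, 0))
        res = fit_cross_sectional(df, ModelSpec(modality="mesopic"))
        X = np.column_stack([
            np.ones(len(df)), df["age_years"], df["pseudophakic"].astype(float),
            *[df[f"flag_{b}"].astype(float) for b in BIOMARKERS]])
        ols = np.linalg.lstsq(X, df["mesopic_dev"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.fixed_effects["estimate"], ols,
                                   atol=1e-6)
        assert all(v == pytest.approx(0.0, abs=1e-8)
                   for k, v in res.vcomp.items() if k != "residual")

    def test_constant_shift_moves_only_the_intercept(self):
        df = synth_table(seed=7)
        base = fit_cross_sectional(df, ModelSpec(modality="mesopic"))
        shifted = df.copy()
        shifted["mesopic_dev"] += 3.25
        res = fit_cross_sectional(shifted, ModelSpec(modality="mesopic"))
        assert res.coef("intercept") == pytest.approx(
            base.coef("intercept") + 3.25, abs=1e-6)
        for term in base.fixed_effects.index[1:]:
            assert res.coef(term) == pytest.approx(base.coef(term), abs=1e-6)

    def test_absent_biomarker_reported_as_nan(self):
        df = synth_table(seed=3)
        df["flag_refractile"] = False
        res = fit_cross_sectional(df, ModelSpec(modality="mesopic"))
        assert np.isnan(res.coef("flag_refractile"))
        assert np.isfinite(res.coef("flag_ped"))

    def test_ci_brackets_estimate_and_se_positive(self):
        df = synth_table(seed=9)
        res = fit_cross_sectional(df, ModelSpec(modality="mesopic"))
        fe = res.fixed_effects.dropna()
        assert (fe["ci_low"] <= fe["estimate"]).all()
        assert (fe["estimate"] <= fe["ci_high"]).all()
        assert (fe["se"] > 0).all()
        assert res.converged


class TestIntervisitDifferences:
    def test_identical_consecutive_visits_give_zero_change(self):
        df = synth_table(seed=1, n_pat=2, n_vis=1)
        later = df.copy()
        later["visit_index"] = 1
        later["months_since_baseline"] = 13.0
        stacked = pd.concat([df, later], ignore_index=True)
        diffs = intervisit_differences(stacked)
        np.testing.assert_allclose(diffs["d_mesopic_dev"], 0.0)
        assert (diffs["years_elapsed"] > 0).all()

    def test_row_count_is_eyes_times_pairs_times_points(self):
        df = synth_table(seed=4, n_pat=3, n_vis=4)
        diffs = intervisit_differences(df)
        assert len(diffs) == 3 * (4 - 1) * 56

    def test_single_visit_cohort_yields_empty_table(self):
        df = synth_table(seed=4, n_pat=3, n_vis=1)
        assert intervisit_differences(df).empty

    def test_covariates_taken_from_earlier_visit(self):
        df = synth_table(seed=8, n_pat=2, n_vis=2)
        diffs = intervisit_differences(df)
        earlier = df[df["visit_index"] == 0].set_index(
            ["eye_id", "grid_index"])
        merged = diffs.set_index(["eye_id", "grid_index"])
        for col in ("flag_ped", "z_RPEDC"):
            np.testing.assert_array_equal(
                merged[col].to_numpy(),
                earlier.loc[merged.index, col].to_numpy())


class TestIntervisitFit:
    def test_recovers_change_model_written_into_differences(self):
        df = synth_table(seed=6, n_pat=14, n_vis=3, sds=(0, 0, 0, 0))
        # eye-specific visit spacing so the years-elapsed slope is identified
        pat = df["patient_id"].str.removeprefix("P").astype(int)
        df["months_since_baseline"] = df["visit_index"] * (12.0 + 0.5 * pat)
        gamma = {"intercept": 1.0, "age": -0.05, "years_elapsed": -0.5,
                 "pseudophakic": 0.4, "flag_crora": -2.15, "z_RPEDC": -0.046}
        # rebuild sensitivities as a random walk driven by the change model
        df = df.sort_values(["eye_id", "grid_index", "visit_index"])
        y = np.zeros(len(df))
        for (eye, k), g in df.groupby(["eye_id", "grid_index"], sort=False):
            acc = 10.0
            prev_months = 0.0
            for idx, row in g.iterrows():
                if row["visit_index"] > 0:
                    dyears = (row["months_since_baseline"] - prev_months) / 12.0
                    acc += (gamma["intercept"] + gamma["age"] * row["age_years"]
                            + gamma["years_elapsed"] * dyears
                            + gamma["pseudophakic"] * row["pseudophakic"]
                            + gamma["flag_crora"] * prev_crora
                            + gamma["z_RPEDC"] * prev_z)
                y[df.index.get_loc(idx)] = acc
                prev_months = row["months_since_baseline"]
                prev_crora, prev_z = float(row["flag_crora"]), row["z_RPEDC"]
        df["mesopic_dev"] = y
        df["scotopic_dev"] = y
        diffs = intervisit_differences(df)
        res = fit_intervisit(diffs, ModelSpec(modality="mesopic",
                                              kind="intervisit"))
        for term, val in gamma.items():
            assert res.coef(term) == pytest.approx(val, abs=1e-6), term

    def test_drop_censored_removes_flagged_pairs(self):
        df = synth_table(seed=12, n_pat=4, n_vis=3)
        df.loc[df.sample(frac=0.1, random_state=0).index,
               "mesopic_censored"] = True
        diffs = intervisit_differences(df)
        full = fit_intervisit(diffs, ModelSpec(modality="mesopic",
                                               kind="intervisit"))
        dropped = fit_intervisit(
            diffs, ModelSpec(modality="mesopic", kind="intervisit",
                             drop_censored=True))
        assert dropped.n_obs < full.n_obs


def test_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(modality="photopic")
    with pytest.raises(ValueError):
        ModelSpec(kind="survival")
    with pytest.raises(ValueError):
        fit_cross_sectional(synth_table(), ModelSpec(kind="intervisit"))
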