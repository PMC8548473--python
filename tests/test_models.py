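"""Model-frame assembly and the lagged LMM/OLS machinery."""

import numpy as np
import pandas as pd
import pytest

from morphnet.measures import measure_table
from morphnet.models import (
    DENSITY_COLUMNS,
    MEASURE_COLUMNS,
    FrameAssemblyError,
    assemble_network_frame,
    assemble_node_frame,
    effect_summary,
    fit_density_lm,
    fit_node_lmm,
    predictors_for,
)
from morphnet.networks import build_network_series


def measure_frame_from_rows(rows):
    """Minimal measure table (node + network rows) from terse tuples."""
    out = []
    for sess, speaker, node, deg, cen in rows:
        out.append(
            {"dyad_id": "d", "session_index": sess, "age_days": 660 + 4 * sess,
             "speaker": speaker, "level": "node", "node": node, "degree": deg,
             "centrality": cen, "density": np.nan, "m": 5, "n": 6}
        )
    sessions = sorted({r[0] for r in rows})
    rng = np.random.default_rng(0)
    for sess in sessions:
        for speaker in ("CS", "CDS"):
            out.append(
                {"dyad_id": "d", "session_index": sess, "age_days": 660 + 4 * sess,
                 "speaker": speaker, "level": "network", "node": "",
                 "degree": np.nan, "centrality": np.nan,
                 "density": rng.uniform(0.1, 0.5), "m": 5, "n": 6}
            )
    return pd.DataFrame(out)


def synthetic_node_measures(n_nodes=30, n_sessions=10, seed=0, p_active=0.8):
    rng = np.random.default_rng(seed)
    rows = []
    for sess in range(1, n_sessions + 1):
        for speaker in ("CS", "CDS"):
            for i in range(n_nodes):
                if rng.random() < p_active:
                    rows.append((sess, speaker, f"r-{i}-x",
                                 rng.poisson(3) + 1.0, rng.random()))
    return measure_frame_from_rows(rows)


class TestPredictorSets:
    def test_degree_cs_predictors_match_published_order(self):
        assert predictors_for("degree.cs") == [
            "age", "degree.cds", "prior.degree.cds", "prior.degree.cs",
            "centrality.cs", "prior.centrality.cs", "centrality.cds",
            "prior.centrality.cds", "density.cs", "prior.density.cs",
            "density.cds", "prior.density.cds",
        ]

    def test_density_cs_predictors(self):
        assert predictors_for("density.cs") == [
            "age", "density.cds", "prior.density.cs", "prior.density.cds"
        ]

    @pytest.mark.parametrize(
        "response", ["degree.cs", "degree.cds", "centrality.cs", "centrality.cds"]
    )
    def test_node_models_exclude_own_response_only(self, response):
        preds = predictors_for(response)
        assert response not in preds
        assert set(preds) == {"age"} | (set(MEASURE_COLUMNS) - {response})

    def test_exclusion_list_drops_blank_cells(self):
        preds = predictors_for("centrality.cs", exclude=("prior.degree.cs",))
        assert "prior.degree.cs" not in preds and len(preds) == 11


class TestFrameAssembly:
    def test_shared_node_filter(self):
        rows = [
            (1, "CS", "r-0-x", 2.0, 0.5), (1, "CDS", "r-0-x", 4.0, 0.3),
            (2, "CS", "r-0-x", 3.0, 0.6), (2, "CDS", "r-0-x", 4.0, 0.4),
            (2, "CS", "r-1-x", 1.0, 0.2),  # CS-only at session 2 -> no row
        ]
        frame = assemble_node_frame(measure_frame_from_rows(rows), scale=False)
        assert list(frame.data["node"]) == ["r-0-x"]
        assert list(frame.data["session_index"]) == [2]

    def test_no_rows_for_first_session(self):
        measures = synthetic_node_measures()
        frame = assemble_node_frame(measures, scale=False)
        assert frame.data["session_index"].min() == 2

    def test_prior_imputation_zero_vs_drop(self):
        rows = [
            (1, "CS", "r-0-x", 2.0, 0.5), (1, "CDS", "r-0-x", 4.0, 0.3),
            # r-1-x newly active at session 2 with no session-1 history
            (2, "CS", "r-0-x", 3.0, 0.6), (2, "CDS", "r-0-x", 4.0, 0.4),
            (2, "CS", "r-1-x", 1.0, 0.2), (2, "CDS", "r-1-x", 2.0, 0.1),
        ]
        measures = measure_frame_from_rows(rows)
        zero = assemble_node_frame(measures, impute_prior="zero", scale=False)
        drop = assemble_node_frame(measures, impute_prior="drop", scale=False)
        assert len(zero) == 2 and len(drop) == 1
        new_row = zero.data[zero.data["node"] == "r-1-x"].iloc[0]
        assert new_row["prior.degree.cs"] == 0.0
        assert new_row["prior.centrality.cds"] == 0.0

    def test_columns_are_centered_and_scaled(self):
        frame = assemble_node_frame(synthetic_node_measures())
        for col in MEASURE_COLUMNS:
            assert abs(frame.data[col].mean()) < 1e-10
            assert abs(frame.data[col].std(ddof=0) - 1) < 1e-10
        assert set(frame.scaling.index) == set(MEASURE_COLUMNS)

    def test_constant_column_raises_naming_it(self):
        rows = [
            (s, spk, "r-0-x", 2.0, 0.5)
            for s in (1, 2, 3)
            for spk in ("CS", "CDS")
        ]
        with pytest.raises(FrameAssemblyError, match="degree.cs"):
            assemble_node_frame(measure_frame_from_rows(rows))

    def test_network_frame_shape(self, small_sim):
        params, table, _ = small_sim
        measures = measure_table(build_network_series(table, "dyad1"),
                                 include_centrality=False)
        frame = assemble_network_frame(measures)
        assert len(frame) == params.n_sessions - 1
        for col in DENSITY_COLUMNS:
            assert abs(frame.data[col].mean()) < 1e-10


def ols_normal_equations(X, y):
    """Independent closed-form least squares oracle."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


class TestDensityModels:
    def test_ols_matches_normal_equations(self, small_sim):
        _, table, _ = small_sim
        measures = measure_table(build_network_series(table, "dyad1"),
                                 include_centrality=False)
        frame = assemble_network_frame(measures)
        for response in ("density.cs", "density.cds"):
            fit = fit_density_lm(frame, response)
            X = np.column_stack(
                [np.ones(len(frame.data))]
                + [frame.data[c].to_numpy() for c in predictors_for(response)]
            )
            beta, se = ols_normal_equations(X, frame.data[response].to_numpy())
            np.testing.assert_allclose(fit.params["estimate"], beta, atol=1e-8)
            np.testing.assert_allclose(fit.params["se"], se, atol=1e-8)

    def test_intercept_only_structure_has_zero_r2(self):
        rng = np.random.default_rng(4)
        rows = []
        for sess in range(1, 12):
            dens = {"CS": 0.3, "CDS": 0.2}  # constant response would fail scaling
            rows.append({"dyad_id": "d", "session_index": sess,
                         "age_days": 660 + sess, "speaker": "CS",
                         "level": "network", "node": "", "degree": np.nan,
                         "centrality": np.nan, "density": rng.uniform(),
                         "m": 3, "n": 4})
            rows.append({"dyad_id": "d", "session_index": sess,
                         "age_days": 660 + sess, "speaker": "CDS",
                         "level": "network", "node": "", "degree": np.nan,
                         "centrality": np.nan, "density": rng.uniform(),
                         "m": 3, "n": 4})
        frame = assemble_network_frame(pd.DataFrame(rows))
        fit = fit_density_lm(frame, "density.cs")
        # with i.i.d. noise the adjusted R^2 hovers near zero
        assert fit.r2 < 0.5

    def test_too_few_sessions_rejected(self):
        rows = [(s, spk, "r-0-x", float(s), 0.5)
                for s in (1, 2, 3) for spk in ("CS", "CDS")]
        measures = measure_frame_from_rows(rows)
        frame = assemble_network_frame(measures)
        with pytest.raises(ValueError, match="at least 5"):
            fit_density_lm(frame, "density.cs")


def simulate_lmm_frame(n_nodes, n_sessions, beta_age, tau, sigma, seed,
                       noise_sd=1.0, intercepts_centered=True):
    """Frame drawn from the node-LMM model class with known coefficients."""
    rng = np.random.default_rng(seed)
    nodes = [f"r-{i}-x" for i in range(n_nodes)]
    b = rng.normal(0, tau, n_nodes)
    if intercepts_centered:
        b -= b.mean()
    ages = np.linspace(660, 810, n_sessions)
    rows = []
    for j, node in enumerate(nodes):
        for s in range(n_sessions):
            row = {"node": node, "session_index": s + 2, "age": ages[s]}
            for col in MEASURE_COLUMNS:
                row[col] = rng.normal()
            row["response"] = (
                beta_age * ages[s] + b[j] + rng.normal(0, sigma)
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    df["degree.cs"] = df.pop("response")
    from morphnet.models import ModelFrame

    return ModelFrame(dyad_id="d", level="node", data=df,
                      scaling=pd.DataFrame(columns=["mean", "sd"]))


class TestNodeMixedModels:
    def test_noiseless_slope_recovery(self):
        frame = simulate_lmm_frame(
            n_nodes=25, n_sessions=12, beta_age=0.02, tau=0.5, sigma=0.0, seed=1
        )
        fit = fit_node_lmm(frame, "degree.cs")
        assert abs(fit.params.loc["age", "estimate"] - 0.02) < 1e-6
        assert fit.r2_conditional > 0.999

    def test_tau_zero_limit_reproduces_ols(self):
        frame = simulate_lmm_frame(
            n_nodes=20, n_sessions=8, beta_age=0.01, tau=0.0, sigma=0.4, seed=2
        )
        fit = fit_node_lmm(frame, "degree.cs", tau_zero=True)
        X = np.column_stack(
            [np.ones(len(frame.data))]
            + [frame.data[c].to_numpy() for c in predictors_for("degree.cs")]
        )
        beta, _ = ols_normal_equations(X, frame.data["degree.cs"].to_numpy())
        np.testing.assert_allclose(fit.params["estimate"], beta, atol=1e-6)
        assert fit.tau00 == pytest.approx(0.0, abs=1e-8)

    def test_variance_components_and_icc(self):
        frame = simulate_lmm_frame(
            n_nodes=120, n_sessions=25, beta_age=0.0, tau=0.8, sigma=0.5, seed=3
        )
        fit = fit_node_lmm(frame, "degree.cs")
        assert fit.sigma2 == pytest.approx(0.25, rel=0.15)
        assert fit.tau00 == pytest.approx(0.64, rel=0.25)
        assert fit.icc == pytest.approx(
            fit.tau00 / (fit.tau00 + fit.sigma2), abs=1e-12
        )
        assert fit.r2_conditional >= fit.r2_marginal

    def test_fixed_effect_estimation_error_within_two_se(self):
        frame = simulate_lmm_frame(
            n_nodes=150, n_sessions=40, beta_age=0.005, tau=0.5, sigma=0.6, seed=4
        )
        fit = fit_node_lmm(frame, "degree.cs")
        errors = fit.params["estimate"].copy()
        errors.loc["age"] -= 0.005  # all other true coefficients are 0
        errors = errors.drop("(Intercept)")
        ratio = (errors.abs() / fit.params["se"].drop("(Intercept)")).median()
        assert ratio < 2

    def test_wald_interval_covers_null_predictor(self):
        covered = 0
        n_reps = 100
        for rep in range(n_reps):
            frame = simulate_lmm_frame(
                n_nodes=40, n_sessions=10, beta_age=0.0, tau=0.4, sigma=0.5,
                seed=1000 + rep,
            )
            fit = fit_node_lmm(frame, "degree.cs")
            row = fit.params.loc["degree.cds"]  # true coefficient is zero
            covered += row["ci_low"] <= 0 <= row["ci_high"]
        assert covered / n_reps >= 0.90


class TestEffectLedger:
    def test_signs_and_significance(self, small_sim):
        _, table, _ = small_sim
        measures = measure_table(build_network_series(table, "dyad1"),
                                 include_centrality=False)
        frame = assemble_network_frame(measures)
        fits = [fit_density_lm(frame, r) for r in ("density.cs", "density.cds")]
        ledger = effect_summary(fits)
        assert set(ledger.table["model"]) == {"density.cs", "density.cds"}
        assert len(ledger.table) == 10  # (intercept + 4 predictors) x 2 models
        for _, row in ledger.table.iterrows():
            assert row["sign"] == ("positive" if row["estimate"] >= 0 else "negative")
            assert row["significant"] == (row["p"] < 0.05)
        for edge in ledger.edges():
            assert edge["from"] != "(Intercept)"

    def test_no_significant_effects_means_no_edges(self):
        fits_frame = pd.DataFrame(
            {"estimate": [0.1], "se": [1.0], "ci_low": [-1.9], "ci_high": [2.1],
             "p": [0.9]},
            index=["age"],
        )
        from morphnet.models import ModelFit

        fit = ModelFit(response="density.cs", level="network", kind="ols",
                       params=fits_frame, n_obs=10, r2=0.0, r2_adj=0.0)
        assert effect_summary([fit]).edges() == []
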