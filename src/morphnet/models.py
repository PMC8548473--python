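"""Lagged dyadic adaptation models over network measures.

Six model families relate each participant's network measures at
recording *N* to the partner's measures and to both parties' measures at
recording *N-1*:

* four node-level linear mixed models (responses ``degree.cs``,
  ``degree.cds``, ``centrality.cs``, ``centrality.cds``) with a random
  intercept per node name, fitted by REML with Wald 95% intervals;
* two network-level ordinary least squares models (``density.cs``,
  ``density.cds``) with exactly four predictors each.

Node-level frames keep only nodes active in *both* strata at a session
(a construct must exist for child and parent for adaptation to be
defined), take ``prior.*`` columns from the preceding recording with 0
imputed (pre-scaling) when a node was inactive then, and z-score every
measure column.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

MEASURE_COLUMNS: tuple[str, ...] = (
    "degree.cs",
    "prior.degree.cs",
    "degree.cds",
    "prior.degree.cds",
    "centrality.cs",
    "prior.centrality.cs",
    "centrality.cds",
    "prior.centrality.cds",
    "density.cs",
    "prior.density.cs",
    "density.cds",
    "prior.density.cds",
)

DENSITY_COLUMNS: tuple[str, ...] = (
    "density.cs",
    "prior.density.cs",
    "density.cds",
    "prior.density.cds",
)

#: Fixed-effect predictor lists per response, in the order the model
#: tables print them.
PREDICTORS: dict[str, tuple[str, ...]] = {
    "degree.cs": (
        "age",
        "degree.cds",
        "prior.degree.cds",
        "prior.degree.cs",
        "centrality.cs",
        "prior.centrality.cs",
        "centrality.cds",
        "prior.centrality.cds",
        "density.cs",
        "prior.density.cs",
        "density.cds",
        "prior.density.cds",
    ),
    "degree.cds": (
        "age",
        "degree.cs",
        "prior.degree.cs",
        "prior.degree.cds",
        "centrality.cs",
        "prior.centrality.cs",
        "centrality.cds",
        "prior.centrality.cds",
        "density.cs",
        "prior.density.cs",
        "density.cds",
        "prior.density.cds",
    ),
    "centrality.cs": (
        "age",
        "centrality.cds",
        "prior.centrality.cs",
        "prior.centrality.cds",
        "degree.cs",
        "prior.degree.cs",
        "degree.cds",
        "prior.degree.cds",
        "density.cs",
        "prior.density.cs",
        "density.cds",
        "prior.density.cds",
    ),
    "centrality.cds": (
        "age",
        "centrality.cs",
        "prior.centrality.cs",
        "prior.centrality.cds",
        "degree.cs",
        "prior.degree.cs",
        "degree.cds",
        "prior.degree.cds",
        "density.cs",
        "prior.density.cs",
        "density.cds",
        "prior.density.cds",
    ),
    "density.cs": ("age", "density.cds", "prior.density.cs", "prior.density.cds"),
    "density.cds": ("age", "density.cs", "prior.density.cds", "prior.density.cs"),
}

NODE_RESPONSES = ("degree.cs", "degree.cds", "centrality.cs", "centrality.cds")
DENSITY_RESPONSES = ("density.cs", "density.cds")


class FrameAssemblyError(ValueError):
    """Raised when a model frame cannot be assembled or scaled."""


@dataclass
class ModelFrame:
    """A centered-and-scaled long frame feeding one model family.

    ``scaling`` records each column's pre-scaling mean and sd so model
    estimates can be mapped back to the measure's native units.
    """

    dyad_id: str
    level: str  # "node" | "network"
    data: pd.DataFrame
    scaling: pd.DataFrame  # index: column; mean, sd

    def __len__(self) -> int:
        return len(self.data)


def predictors_for(response: str, exclude: Sequence[str] = ()) -> list[str]:
    """The fixed-effect predictor list for a response, minus exclusions."""
    if response not in PREDICTORS:
        raise KeyError(f"unknown response {response!r}")
    return [p for p in PREDICTORS[response] if p not in exclude]


def _zscore(df: pd.DataFrame, cols: Iterable[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = df.copy()
    rows = []
    for col in cols:
        mean = float(df[col].mean())
        sd = float(df[col].std(ddof=0))
        if not np.isfinite(sd) or sd == 0:
            raise FrameAssemblyError(f"column {col!r} is constant; cannot scale")
        df[col] = (df[col] - mean) / sd
        rows.append({"column": col, "mean": mean, "sd": sd})
    return df, pd.DataFrame(rows).set_index("column")


def _wide_measures(measures: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a measure table into node-level and session-level wide frames."""
    node = measures[measures["level"] == "node"]
    net = measures[measures["level"] == "network"]
    dens = net.pivot_table(
        index="session_index", columns="speaker", values="density", aggfunc="first"
    )
    return node, dens


def assemble_node_frame(
    measures: pd.DataFrame,
    impute_prior: str = "zero",
    scale: bool = True,
) -> ModelFrame:
    """Shared-node, lag-1 node-level model frame from a measure table.

    Rows exist only for (session, node) pairs active in both CS and CDS,
    and only for sessions with a predecessor.  ``impute_prior="zero"``
    treats inactivity at N-1 as zero degree/centrality before scaling;
    ``"drop"`` instead drops rows whose node was inactive at N-1 in
    either stratum.
    """
    if impute_prior not in ("zero", "drop"):
        raise ValueError(f"impute_prior must be 'zero' or 'drop', got {impute_prior!r}")
    dyads = measures["dyad_id"].unique()
    if len(dyads) != 1:
        raise FrameAssemblyError(f"one dyad per frame; got {list(dyads)}")
    node, dens = _wide_measures(measures)
    sessions = sorted(measures["session_index"].unique())
    if len(sessions) < 2:
        raise FrameAssemblyError("need at least 2 sessions to build a lagged frame")
    ages = measures.groupby("session_index")["age_days"].first()

    # (session, node) -> (degree, centrality) per speaker
    piv = node.pivot_table(
        index=["session_index", "node"],
        columns="speaker",
        values=["degree", "centrality"],
        aggfunc="first",
    )
    rows = []
    for prev, sess in zip(sessions[:-1], sessions[1:]):
        try:
            cur = piv.loc[sess]
        except KeyError:
            continue
        shared = cur.dropna(subset=[("degree", "CS"), ("degree", "CDS")]).index
        prior = piv.loc[prev] if prev in piv.index.get_level_values(0) else None
        for nd in shared:
            row = {
                "dyad_id": dyads[0],
                "session_index": sess,
                "node": nd,
                "age": float(ages[sess]),
                "degree.cs": cur.loc[nd, ("degree", "CS")],
                "degree.cds": cur.loc[nd, ("degree", "CDS")],
                "centrality.cs": cur.loc[nd, ("centrality", "CS")],
                "centrality.cds": cur.loc[nd, ("centrality", "CDS")],
                "density.cs": dens.loc[sess, "CS"],
                "density.cds": dens.loc[sess, "CDS"],
                "prior.density.cs": dens.loc[prev, "CS"],
                "prior.density.cds": dens.loc[prev, "CDS"],
            }
            seen_prior = prior is not None and nd in prior.index
            for meas in ("degree", "centrality"):
                for spk, suffix in (("CS", "cs"), ("CDS", "cds")):
                    if seen_prior and not pd.isna(prior.loc[nd, (meas, spk)]):
                        val = float(prior.loc[nd, (meas, spk)])
                    else:
                        val = 0.0 if impute_prior == "zero" else np.nan
                    row[f"prior.{meas}.{suffix}"] = val
            rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise FrameAssemblyError("no shared nodes across sessions")
    frame = frame.dropna().reset_index(drop=True)
    if scale:
        frame, scaling = _zscore(frame, MEASURE_COLUMNS)
    else:
        scaling = pd.DataFrame(columns=["mean", "sd"])
    return ModelFrame(dyad_id=str(dyads[0]), level="node", data=frame, scaling=scaling)


def assemble_network_frame(measures: pd.DataFrame, scale: bool = True) -> ModelFrame:
    """Session-level density frame (one row per session with a predecessor)."""
    dyads = measures["dyad_id"].unique()
    if len(dyads) != 1:
        raise FrameAssemblyError(f"one dyad per frame; got {list(dyads)}")
    _, dens = _wide_measures(measures)
    sessions = sorted(dens.index)
    if len(sessions) < 2:
        raise FrameAssemblyError("need at least 2 sessions to build a lagged frame")
    ages = measures.groupby("session_index")["age_days"].first()
    rows = []
    for prev, sess in zip(sessions[:-1], sessions[1:]):
        rows.append(
            {
                "dyad_id": dyads[0],
                "session_index": sess,
                "age": float(ages[sess]),
                "density.cs": dens.loc[sess, "CS"],
                "density.cds": dens.loc[sess, "CDS"],
                "prior.density.cs": dens.loc[prev, "CS"],
                "prior.density.cds": dens.loc[prev, "CDS"],
            }
        )
    frame = pd.DataFrame(rows).dropna().reset_index(drop=True)
    if frame.empty:
        raise FrameAssemblyError("no sessions with defined densities")
    if scale:
        frame, scaling = _zscore(frame, DENSITY_COLUMNS)
    else:
        scaling = pd.DataFrame(columns=["mean", "sd"])
    return ModelFrame(dyad_id=str(dyads[0]), level="network", data=frame, scaling=scaling)


def assemble_model_frame(
    measures: pd.DataFrame, level: str, impute_prior: str = "zero", scale: bool = True
) -> ModelFrame:
    """Dispatch to the node-level or network-level frame assembler."""
    if level == "node":
        return assemble_node_frame(measures, impute_prior=impute_prior, scale=scale)
    if level == "network":
        return assemble_network_frame(measures, scale=scale)
    raise ValueError(f"level must be 'node' or 'network', got {level!r}")


@dataclass
class ModelFit:
    """A fitted adaptation model: estimates, Wald CIs, variance components."""

    response: str
    level: str
    kind: str  # "lmm" | "ols"
    params: pd.DataFrame  # index: predictor; estimate, se, ci_low, ci_high, p
    n_obs: int
    converged: bool = True
    reml: bool = True
    sigma2: Optional[float] = None
    tau00: Optional[float] = None
    icc: Optional[float] = None
    n_groups: Optional[int] = None
    r2_marginal: Optional[float] = None
    r2_conditional: Optional[float] = None
    r2: Optional[float] = None
    r2_adj: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "response": self.response,
            "level": self.level,
            "kind": self.kind,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "fixed_effects": {
                name: {
                    "estimate": float(row["estimate"]),
                    "se": float(row["se"]),
                    "ci_low": float(row["ci_low"]),
                    "ci_high": float(row["ci_high"]),
                    "p": float(row["p"]),
                }
                for name, row in self.params.iterrows()
            },
        }
        for key in ("sigma2", "tau00", "icc", "n_groups", "r2_marginal",
                    "r2_conditional", "r2", "r2_adj"):
            val = getattr(self, key)
            if val is not None:
                d[key] = float(val) if key != "n_groups" else int(val)
        return d

    def to_text(self) -> str:
        """Fixed-width report shaped like the published model tables."""
        lines = [f"Response: {self.response}  ({self.kind.upper()}, n={self.n_obs})"]
        lines.append(f"{'Predictors':<24}{'Estimates':>10}  {'CI':>16}  {'p':>8}")
        for name, row in self.params.iterrows():
            ci = f"{row['ci_low']:.2f} - {row['ci_high']:.2f}"
            lines.append(
                f"{name:<24}{row['estimate']:>10.2f}  {ci:>16}  {row['p']:>8.3f}"
            )
        if self.kind == "lmm":
            lines.append("Random Effects")
            lines.append(f"  sigma^2    {self.sigma2:.2f}")
            lines.append(f"  tau00 name {self.tau00:.2f}")
            lines.append(f"  ICC        {self.icc:.2f}")
            lines.append(f"  N name     {self.n_groups}")
            lines.append(f"Observations  {self.n_obs}")
            lines.append(
                f"Marg.R^2/Cond.R^2  {self.r2_marginal:.3f}/{self.r2_conditional:.3f}"
            )
        else:
            lines.append(f"Observations  {self.n_obs}")
            lines.append(f"R^2/R^2 adj.  {self.r2:.3f}/{self.r2_adj:.3f}")
        return "\n".join(lines)


def _param_table(names, est, se, p, z=1.959963984540054) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - z * se,
            "ci_high": est + z * se,
            "p": p,
        },
        index=names,
    )


def fit_node_lmm(
    frame: ModelFrame,
    response: str,
    exclude: Sequence[str] = (),
    reml: bool = True,
    tau_zero: bool = False,
) -> ModelFit:
    """Random-intercept-per-node linear mixed model for a node-level response.

    Fixed effects are age plus the current/lag-1 measures of both
    parties excluding the response itself; inference is Wald.
    ``exclude`` drops predictors (some published fits omit blank cells);
    ``tau_zero`` pins the random-intercept variance at zero, a
    degenerate limit that must reproduce OLS.
    """
    if response not in NODE_RESPONSES:
        raise ValueError(f"node-level response must be one of {NODE_RESPONSES}")
    if frame.level != "node":
        raise ValueError("fit_node_lmm needs a node-level frame")
    data = frame.data
    if data["node"].nunique() < 2:
        raise ValueError("need at least 2 node groups for a mixed model")
    preds = predictors_for(response, exclude)
    exog = sm.add_constant(data[preds].to_numpy(), has_constant="add")
    names = ["(Intercept)"] + preds
    endog = data[response].to_numpy()
    model = MixedLM(endog, exog, groups=data["node"].to_numpy())
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if tau_zero:
                free = MixedLMParams.from_components(
                    fe_params=np.ones(len(names)), cov_re=np.zeros((1, 1))
                )
                # pinning the variance at a negligible value avoids the
                # singular profile the exact-zero boundary produces
                start = MixedLMParams.from_components(
                    fe_params=np.zeros(len(names)), cov_re=np.array([[1e-10]])
                )
                result = model.fit(reml=reml, free=free, start_params=start)
            else:
                result = model.fit(reml=reml)
            converged = bool(getattr(result, "converged", True))
        except Exception:
            result = model.fit(reml=reml, method="powell", maxiter=2000)
            converged = False
    fe = np.asarray(result.fe_params)
    se = np.asarray(result.bse_fe)
    p = np.asarray(result.pvalues)[: len(fe)]
    sigma2 = float(result.scale)
    tau00 = float(np.asarray(result.cov_re)[0, 0])
    var_fixed = float(np.var(exog @ fe))
    total = var_fixed + tau00 + sigma2
    return ModelFit(
        response=response,
        level="node",
        kind="lmm",
        params=_param_table(names, fe, se, p),
        n_obs=len(data),
        converged=converged,
        reml=reml,
        sigma2=sigma2,
        tau00=tau00,
        icc=tau00 / (tau00 + sigma2) if (tau00 + sigma2) > 0 else 0.0,
        n_groups=int(data["node"].nunique()),
        r2_marginal=var_fixed / total if total > 0 else np.nan,
        r2_conditional=(var_fixed + tau00) / total if total > 0 else np.nan,
    )


def fit_density_lm(frame: ModelFrame, response: str) -> ModelFit:
    """OLS for a network-level density response with its four predictors."""
    if response not in DENSITY_RESPONSES:
        raise ValueError(f"density response must be one of {DENSITY_RESPONSES}")
    if frame.level != "network":
        raise ValueError("fit_density_lm needs a network-level frame")
    data = frame.data
    if len(data) < 5:
        raise ValueError(f"need at least 5 sessions, got {len(data)}")
    preds = predictors_for(response)
    X = sm.add_constant(data[preds].to_numpy(), has_constant="add")
    converged = int(np.linalg.matrix_rank(X)) == X.shape[1]
    result = sm.OLS(data[response].to_numpy(), X).fit()
    names = ["(Intercept)"] + preds
    return ModelFit(
        response=response,
        level="network",
        kind="ols",
        params=_param_table(names, result.params, result.bse, result.pvalues),
        n_obs=len(data),
        converged=converged,
        reml=False,
        r2=float(result.rsquared),
        r2_adj=float(result.rsquared_adj),
    )


@dataclass
class EffectLedger:
    """Machine-readable summary of model effects (sign x significance)."""

    table: pd.DataFrame  # model, predictor, estimate, p, sign, significant

    def edges(self) -> list[dict]:
        """Significant affecting-measure -> affected-measure arrows."""
        sig = self.table[self.table["significant"]]
        return [
            {
                "from": row["predictor"],
                "to": row["model"],
                "sign": row["sign"],
                "estimate": float(row["estimate"]),
            }
            for _, row in sig.iterrows()
            if row["predictor"] != "(Intercept)"
        ]

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "effects": self.table.to_dict(orient="records"),
                "significant_edges": self.edges(),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc)
        return doc


def effect_summary(fits: Sequence[ModelFit], alpha: float = 0.05) -> EffectLedger:
    """One ledger row per (model, predictor) with sign and significance."""
    if not fits:
        raise ValueError("need at least one fitted model")
    rows = []
    for fit in fits:
        for name, row in fit.params.iterrows():
            rows.append(
                {
                    "model": fit.response,
                    "predictor": name,
                    "estimate": float(row["estimate"]),
                    "p": float(row["p"]),
                    "sign": "positive" if row["estimate"] >= 0 else "negative",
                    "significant": bool(row["p"] < alpha),
                }
            )
    return EffectLedger(pd.DataFrame(rows))
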