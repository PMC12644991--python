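"""Linear mixed-effects comparisons on metric and rewiring tables.

Three model families are fitted, all by REML through standard
mixed-model machinery (statsmodels MixedLM):

1. metric ~ treatment, random intercept for species nested within web
   pair — does the perturbation shift node-level properties of
   surviving species?
2. (drought - control) metric change ~ number of rewired links, crossed
   random intercepts for web pair and species — does rewiring move
   species through the network?
3. proportion of rewired links ~ control-web centrality, crossed random
   intercepts for web pair and species — do specialists rewire
   proportionally more?

Wald F statistics for the single fixed effect use denominator degrees
of freedom from Satterthwaite's approximation, computed here from the
REML variance-parameter information matrix:

    df = 2 g(theta)^2 / Var[g(theta_hat)],   g = c' (X' V^-1 X)^-1 c

with the variance of g obtained by the delta method. The reported r^2
is the marginal (fixed-effects) coefficient of determination
var(X beta) / (var(X beta) + sum of variance components + sigma^2).
Proportion responses are modelled on the identity scale by default; a
logit option is provided.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


class StatsError(ValueError):
    pass


@dataclass
class ModelResult:
    response: str
    fixed_effect: str
    slope: float
    intercept: float
    F: float
    df: tuple[float, float]
    p: float
    r2: float
    n_obs: int
    method: str = "mixedlm-reml"

    def as_row(self) -> dict:
        num, den = self.df
        return {
            "response": self.response,
            "fixed_effect": self.fixed_effect,
            "slope": self.slope,
            "intercept": self.intercept,
            "df_num": num,
            "df_den": den,
            "F": self.F,
            "p": self.p,
            "r2": self.r2,
            "n": self.n_obs,
        }


# ----------------------------------------------------------------------
# Core fitting


def _indicator(labels: Sequence) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(labels))
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _satterthwaite_df(
    X: np.ndarray,
    Zs: list[np.ndarray],
    variances: list[float],
    sigma2: float,
    c: np.ndarray,
) -> float:
    """Satterthwaite denominator df for the contrast ``c`` on beta.

    Builds V = sigma2 I + sum_k var_k Z_k Z_k', the REML information of
    the variance parameters (0.5 tr(P V_j P V_k)), and applies the delta
    method to g(theta) = c' (X' V^-1 X)^-1 c.
    """
    n, p = X.shape
    V = sigma2 * np.eye(n)
    parts = [Z @ Z.T for Z in Zs]
    for var_k, ZZt in zip(variances, parts):
        V += var_k * ZZt
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    C = np.linalg.inv(XtVinv @ X)
    g = float(c @ C @ c)
    P = Vinv - XtVinv.T @ C @ XtVinv

    dV = parts + [np.eye(n)]  # d V / d theta_k ; last entry: residual variance
    k = len(dV)
    # delta-method gradient: d g / d theta_k = c' C X'V^-1 V_k V^-1 X C c
    grad = np.empty(k)
    h = Vinv @ X @ C @ c
    for j in range(k):
        grad[j] = float(h @ dV[j] @ h)
    info = np.empty((k, k))
    PdV = [P @ d for d in dV]
    for i in range(k):
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * np.trace(PdV[i] @ PdV[j])
    cov_theta = np.linalg.pinv(info)
    var_g = float(grad @ cov_theta @ grad)
    if var_g <= 0 or not np.isfinite(var_g):
        return float(n - p)
    df = 2.0 * g * g / var_g
    return float(np.clip(df, 1.0, n - p))


def _fit_lmm(
    y: np.ndarray,
    x: np.ndarray,
    vc_labels: dict[str, Sequence],
    response: str,
    fixed_effect: str,
) -> ModelResult:
    """Fit y ~ 1 + x with independent random intercepts per label set."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 3:
        raise StatsError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise StatsError("fixed-effect predictor is constant")
    if np.ptp(y) == 0:
        # no variance to explain; report a null effect rather than failing
        return ModelResult(response, fixed_effect, 0.0, float(y[0]), 0.0,
                           (1.0, float(n - 2)), 1.0, 0.0, n)

    df = pd.DataFrame({"y": y, "x": x})
    vc_formula = {}
    for name, labels in vc_labels.items():
        df[name] = pd.Series(np.asarray(labels, dtype=object)).astype(str).values
        vc_formula[name] = f"0 + C({name})"
    df["_one"] = 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "y ~ x", data=df, groups="_one", re_formula="0", vc_formula=vc_formula
        )
        fit = model.fit(reml=True, method=["lbfgs", "powell"])

    beta = np.asarray(fit.fe_params)
    intercept, slope = float(beta[0]), float(beta[1])
    variances = [max(float(v), 0.0) for v in np.asarray(fit.vcomp)]
    sigma2 = max(float(fit.scale), 1e-12)

    X = np.column_stack([np.ones(n), x])
    Zs = [_indicator(df[name]) for name in vc_labels]
    c = np.array([0.0, 1.0])
    den_df = _satterthwaite_df(X, Zs, variances, sigma2, c)

    # Wald F from the model-based covariance at the REML estimates
    V = sigma2 * np.eye(n)
    for var_k, Z in zip(variances, Zs):
        V += var_k * (Z @ Z.T)
    C = np.linalg.inv(X.T @ np.linalg.solve(V, X))
    se2 = float(c @ C @ c)
    F = slope**2 / se2
    p = float(scipy.stats.f.sf(F, 1, den_df))

    var_fixed = float(np.var(X @ beta))
    r2 = var_fixed / (var_fixed + sum(variances) + sigma2)
    return ModelResult(response, fixed_effect, slope, intercept, float(F),
                       (1.0, den_df), p, r2, n)


# ----------------------------------------------------------------------
# The three model families


def treatment_comparison(
    metrics_table: pd.DataFrame,
    metric: str = "degree",
    subset: str = "all",
) -> ModelResult:
    """Family 1: metric ~ treatment with species-within-pair intercepts.

    ``metrics_table`` is long format with columns web_pair, treatment,
    species_id, is_consumer and one column per metric, containing the
    surviving species of both webs of each pair. ``subset`` restricts to
    consumers or resources (classified in the control web).
    """
    t = metrics_table
    required = {"web_pair", "treatment", "species_id", metric}
    missing = required - set(t.columns)
    if missing:
        raise StatsError(f"metrics table lacks column(s) {sorted(missing)}")
    if subset not in {"all", "consumers", "resources"}:
        raise StatsError(f"unknown subset {subset!r}")
    if subset != "all":
        if "is_consumer" not in t.columns:
            raise StatsError("subset filtering needs an is_consumer column")
        t = t[t["is_consumer"] == (subset == "consumers")]
    levels = sorted(t["treatment"].unique())
    if len(levels) != 2:
        raise StatsError(f"treatment must have 2 levels, found {levels}")
    x = (t["treatment"] == levels[1]).astype(float).values
    nested = t["web_pair"].astype(str) + ":" + t["species_id"].astype(str)
    res = _fit_lmm(t[metric].values, x, {"pair_species": nested},
                   response=metric, fixed_effect=f"treatment[{levels[1]}]")
    return res


def _crossed_fit(
    species_table: pd.DataFrame, response: str, predictor: str, transform: str
) -> ModelResult:
    required = {"web_pair", "species_id", response, predictor}
    missing = required - set(species_table.columns)
    if missing:
        raise StatsError(f"species table lacks column(s) {sorted(missing)}")
    t = species_table.dropna(subset=[response, predictor])
    y = t[response].values.astype(float)
    if transform == "logit":
        eps = 1e-6
        y = np.log(np.clip(y, eps, 1 - eps) / (1 - np.clip(y, eps, 1 - eps)))
    return _fit_lmm(
        y,
        t[predictor].values.astype(float),
        {"pair": t["web_pair"], "species": t["species_id"]},
        response=response,
        fixed_effect=predictor,
    )


def rewiring_regression(
    species_table: pd.DataFrame,
    response: str = "delta_degree",
    predictor: str = "n_rewired",
) -> ModelResult:
    """Family 2: metric change ~ rewired-link count, crossed intercepts."""
    return _crossed_fit(species_table, response, predictor, transform="identity")


def specialism_regression(
    species_table: pd.DataFrame,
    predictor: str = "degree",
    response: str = "prop_rewired",
    transform: str = "identity",
) -> ModelResult:
    """Family 3: proportion rewired ~ control-web centrality."""
    if transform not in {"identity", "logit"}:
        raise StatsError(f"unknown transform {transform!r}")
    return _crossed_fit(species_table, response, predictor, transform=transform)


def results_table(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Model outputs as one table (response, DF, F, p, ...) per row."""
    return pd.DataFrame([r.as_row() for r in results])


# ----------------------------------------------------------------------
# Independent engine for cross-validation of the fits

_R_TEMPLATE = """
suppressMessages({{library(lme4); library(lmerTest); library(jsonlite)}})
d <- read.csv("{csv}")
m <- lmerTest::lmer({formula}, data = d, REML = TRUE)
s <- summary(m)$coefficients
cat(toJSON(list(slope = s["x", "Estimate"],
                df = s["x", "df"],
                t = s["x", "t value"],
                p = s["x", "Pr(>|t|)"]), digits = 12, auto_unbox = TRUE))
"""


def fit_lmer_reference(
    data: pd.DataFrame, random_terms: Sequence[str], timeout: int = 120
) -> Optional[dict]:
    """Fit y ~ x with lme4/lmerTest through Rscript, as an external check.

    ``data`` needs columns y and x plus the grouping columns named in
    ``random_terms`` (each becomes a random intercept). Returns the
    slope, Satterthwaite df, t and p, or None if Rscript is unavailable.
    """
    terms = " + ".join(f"(1|{g})" for g in random_terms)
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "d.csv"
        data.to_csv(csv, index=False)
        script = Path(tmp) / "fit.R"
        script.write_text(_R_TEMPLATE.format(csv=csv, formula=f"y ~ x + {terms}"))
        try:
            out = subprocess.run(
                ["Rscript", "--vanilla", str(script)],
                capture_output=True, text=True, timeout=timeout, check=True,
            )
        except (FileNotFoundError, subprocess.SubprocessError):
            return None
    return json.loads(out.stdout.strip())
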