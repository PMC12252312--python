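"""Association models: linear trait-on-score effects, adjusted logistic
odds ratios, the TG/HDL-C ratio, and F-test power.

Linear models are ordinary least squares; logistic models are
maximum-likelihood fits with Wald 95% confidence intervals on the
log-odds scale (exponentiated for odds ratios).  The default adjustment
set is age, sex, BMI, T2DM and CVD medical treatment.  Results carry the
number of events and a sparse-data warning below 10 events per parameter;
no automatic penalisation is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .wprs import ScoreSet

logger = logging.getLogger(__name__)

DEFAULT_ADJUSTMENT = ["age", "sex", "bmi", "t2dm", "treatment"]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class AssocResult:
    """One fitted association term.

    ``beta`` is in trait units per unit predictor for linear models and
    log-odds for logistic models; ``or_value`` and the 95% CI are on the
    odds-ratio scale for logistic models (CI on the beta scale for
    linear).
    """

    model: str
    term: str
    beta: float
    se: float
    p: float
    ci95: tuple[float, float]
    or_value: float | None = None
    adjustment_set: list[str] = field(default_factory=list)
    n: int = 0
    n_events: int | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model, "term": self.term, "beta": self.beta,
            "se": self.se, "or": self.or_value, "ci_low": self.ci95[0],
            "ci_high": self.ci95[1], "p": self.p,
            "adjustment": "+".join(self.adjustment_set), "n": self.n,
            "n_events": self.n_events, "warnings": ";".join(self.warnings),
        }


@dataclass(frozen=True)
class PowerSpec:
    """Fixed-effects linear-regression F-test power inputs.

    ``f2`` is Cohen's f² (dimensionless); noncentrality is f²·n.
    """

    f2: float
    n: int
    df_num: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.f2 < 0:
            raise ValueError("f2 must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.df_num < 1:
            raise ValueError("df_num must be >= 1")
        if self.n <= self.df_num + 1:
            raise ValueError("need n > df_num + 1")


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _encode(cohort: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns; 'sex' becomes a male indicator."""
    X = pd.DataFrame(index=cohort.index)
    for col in columns:
        if col not in cohort.columns:
            raise ValueError(f"covariate {col!r} absent from cohort")
        if col == "sex":
            X["sex_male"] = (cohort["sex"] == "M").astype(float)
        else:
            X[col] = pd.to_numeric(cohort[col])
    return X


def _check_collinear(X: pd.DataFrame) -> None:
    cols = [c for c in X.columns if X[c].std() > 0]
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = np.corrcoef(X[a], X[b])[0, 1]
            if abs(r) > 0.9999:
                raise ValueError(f"collinear covariates: {a!r} and {b!r}")


# ---------------------------------------------------------------------------
# Linear model
# ---------------------------------------------------------------------------

def linear_trait_on_score(
    cohort: pd.DataFrame,
    scores: ScoreSet | pd.Series,
    trait: str,
    covariates: Sequence[str] | None = None,
) -> AssocResult:
    """OLS of a lipid trait (mg/dL) on the wPRS with covariate adjustment.

    Reports the per-unit-wPRS effect in trait units.  Score and cohort
    are aligned on index; covariates default to
    :data:`DEFAULT_ADJUSTMENT` (members absent from the cohort must be
    dropped explicitly by passing the list).
    """
    if covariates is None:
        covariates = DEFAULT_ADJUSTMENT
    score = scores.scores if isinstance(scores, ScoreSet) else scores
    idx = cohort.index.intersection(score.index)
    if trait not in cohort.columns:
        raise ValueError(f"trait {trait!r} absent from cohort")
    y = pd.to_numeric(cohort.loc[idx, trait])
    X = _encode(cohort.loc[idx], covariates)
    X.insert(0, "wprs", score.loc[idx].astype(float))
    _check_collinear(X)
    if len(idx) <= X.shape[1] + 2:
        raise ValueError("too few subjects for the requested adjustment set")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    beta = float(fit.params["wprs"])
    se = float(fit.bse["wprs"])
    return AssocResult(
        model="linear", term=f"{trait}~wprs", beta=beta, se=se,
        p=float(fit.pvalues["wprs"]),
        ci95=(beta - _Z95 * se, beta + _Z95 * se),
        adjustment_set=list(covariates), n=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# Logistic model
# ---------------------------------------------------------------------------

def logistic_outcome_on_group(
    cohort: pd.DataFrame,
    outcome: pd.Series | Sequence[int],
    group: pd.Series | Sequence[int],
    covariates: Sequence[str] = (),
    term: str = "group",
) -> AssocResult:
    """Adjusted odds ratio of a binary outcome for a binary group.

    Maximum-likelihood logistic fit; OR = exp(beta_group) with a Wald 95%
    CI on the log scale.  With an empty covariate list this reproduces
    the closed-form 2x2 cross-product odds ratio.  Perfect separation
    yields a flagged result with a non-finite OR rather than an error;
    empty outcome-by-group cells attach a sparse-data warning.
    """
    y = pd.Series(outcome).astype(float)
    g = pd.Series(group)
    if g.dtype == object or str(g.dtype) == "category":
        g = (g == "high").astype(float)
    g = g.astype(float)
    idx = cohort.index.intersection(y.index).intersection(g.index)
    y, g = y.loc[idx], g.loc[idx]
    warns: list[str] = []
    if y.nunique() < 2:
        raise ValueError("outcome has a single class")
    cells = pd.crosstab(g, y)
    if (cells == 0).any().any() or cells.size < 4:
        warns.append("sparse-data: empty outcome-by-group cell")
    X = _encode(cohort.loc[idx], covariates)
    X.insert(0, term, g)
    _check_collinear(X)
    n_events = int(y.sum())
    n_params = X.shape[1] + 1
    if n_events < 10 * n_params:
        warns.append(f"sparse-data: {n_events} events for {n_params} parameters")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
            beta = float(fit.params[term])
            se = float(fit.bse[term])
            p = float(fit.pvalues[term])
        except Exception:
            beta, se, p = float("inf"), float("inf"), 1.0
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 30:
        warns.append("perfect separation: odds ratio not estimable")
        logger.warning("logistic fit separated for term %s", term)
        beta = float("inf") if not np.isfinite(beta) or beta > 0 else float("-inf")
        return AssocResult(
            model="logistic", term=term, beta=beta, se=float("inf"), p=1.0,
            ci95=(0.0, float("inf")), or_value=float(np.exp(beta)) if beta < 0 else float("inf"),
            adjustment_set=list(covariates), n=len(idx), n_events=n_events,
            warnings=warns,
        )
    with np.errstate(over="ignore"):  # huge SE near separation: inf CI is fine
        ci = (float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se)))
    return AssocResult(
        model="logistic", term=term, beta=beta, se=se, p=p,
        ci95=ci,
        or_value=float(np.exp(beta)),
        adjustment_set=list(covariates), n=len(idx), n_events=n_events,
        warnings=warns,
    )


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR).

    Not applied anywhere by default — the stratified tables report raw
    p-values — but available for users running many comparisons.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# TG/HDL-C ratio
# ---------------------------------------------------------------------------

def tg_hdl_ratio(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject TG/HDL-C ratio and the strict > 2 adverse indicator.

    Subjects with HDL-C <= 0 are flagged missing (NaN ratio, missing
    indicator True).
    """
    for col in ("tg", "hdl"):
        if col not in cohort.columns:
            raise ValueError(f"cohort has no {col!r} column")
    tg = cohort["tg"].to_numpy(dtype=float)
    hdl = cohort["hdl"].to_numpy(dtype=float)
    bad = ~(hdl > 0)
    ratio = np.where(bad, np.nan, tg / np.where(bad, np.nan, hdl))
    above = np.where(np.isnan(ratio), np.nan, (ratio > 2.0).astype(float))
    return pd.DataFrame(
        {"ratio": ratio, "above_2": above, "missing": bad}, index=cohort.index
    )


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def ftest_power(spec: PowerSpec) -> float:
    """Power of the fixed-effects linear-regression F-test.

    Noncentrality lambda = f²·n; numerator df as given; denominator df
    n - df_num - 1.  Power is the upper-tail probability of the
    noncentral F beyond the central-F critical value at alpha.  At
    f² = 0 this returns alpha exactly.
    """
    df_den = spec.n - spec.df_num - 1
    fcrit = stats.f.isf(spec.alpha, spec.df_num, df_den)
    if spec.f2 == 0.0:
        return float(spec.alpha)
    nc = spec.f2 * spec.n
    return float(stats.ncf.sf(fcrit, spec.df_num, df_den, nc))
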