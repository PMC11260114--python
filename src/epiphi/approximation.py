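"""Regression analyses of the factorial study.

Three families of fits, all ordinary least squares on the per-run records:

* *identity fits* — each run's sample phi (or chi-squared) regressed on the
  closed form evaluated at that run's **observed** measures.  Because the
  closed form is an algebraic identity on the observed 2x2 table, these fits
  return R-squared = 1 to numerical tolerance; they verify that the
  translation equations are exact, not approximate.
* *approximation tables* — main-effect ("Model A": rho, d, rr, ir) and
  interaction-augmented ("Model B": + ir*rr, d*rr, d*ir) fits per response
  and per at-risk-incidence stratum, with t-based 95% CIs, p-values and
  variance inflation factors.
* *R-squared decomposition* — a cumulative ladder adding rho, d, ir, rr in
  order, and the individual/combined R-squared of extra predictors (the four
  table cells and higher-order interaction terms).

Predictors default to the measures *derived from each simulated table*
(``predictor_source="observed"``); the derived risk ratio is then naturally
capped at ``1/ir``, which in the reaching-1 stratum makes ``ir*rr`` nearly
constant at 1 and produces the enormous offsetting intercept/interaction
coefficients that the VIF diagnostics flag.  ``predictor_source="assumed"``
uses the design-grid values instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .measures import LESS_THAN_1, REACHING_1

__all__ = [
    "ModelSpec",
    "FitResult",
    "SequentialR2",
    "design_frame",
    "fit_ols",
    "identity_fit",
    "table_models",
    "sequential_r2",
    "MEASURE_TERMS",
    "MODEL_A_TERMS",
    "MODEL_B_TERMS",
    "EXTRA_TERMS",
    "VIF_THRESHOLD",
]

#: the four epidemiologic measures, in the cumulative-addition order
MEASURE_TERMS = ["rho", "d", "ir", "rr"]
MODEL_A_TERMS = ["rho", "d", "rr", "ir"]
MODEL_B_TERMS = MODEL_A_TERMS + ["ir_rr", "d_rr", "d_ir"]
#: extra predictors for the R-squared decomposition: the four cell counts
#: and the interaction terms read off the closed-form equations
EXTRA_TERMS = ["a", "b", "c", "ndd", "ir_rr", "d_rr", "d_ir", "d_ir_rr", "d2_ir"]
#: collinearity flag threshold
VIF_THRESHOLD = 10.0

_OBSERVED_BASE = {"rho": "rho_hat", "d": "d_hat", "ir": "ir_hat", "rr": "rr_hat"}
_ASSUMED_BASE = {"rho": "rho", "d": "d", "ir": "ir", "rr": "rr"}


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, over which stratum."""

    response: str  # "phi" or "chi2"
    terms: tuple[str, ...]
    stratum: str = "all"  # LESS_THAN_1, REACHING_1 or "all"
    predictor_source: str = "observed"  # "observed" or "assumed"


@dataclass(frozen=True)
class FitResult:
    """OLS fit summary: coefficients with 95% CIs and p-values, R2, VIFs."""

    spec: ModelSpec
    params: pd.Series
    conf_int: pd.DataFrame  # columns: low, high
    pvalues: pd.Series
    r_squared: float
    residual_df: int
    vif: pd.Series
    n_obs: int
    n_excluded: int = 0

    def coefficient(self, term: str) -> float:
        return float(self.params[term])

    @property
    def high_vif_terms(self) -> list[str]:
        return [t for t, v in self.vif.items() if v > VIF_THRESHOLD or np.isinf(v)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-term table (term, estimate, ci_low, ci_high, p_value, vif)."""
        rows = []
        for term in self.params.index:
            rows.append({
                "term": term,
                "estimate": self.params[term],
                "ci_low": self.conf_int.loc[term, "low"],
                "ci_high": self.conf_int.loc[term, "high"],
                "p_value": self.pvalues[term],
                "vif": self.vif.get(term, np.nan),
            })
        return pd.DataFrame(rows)


def _phi_closed(df: pd.DataFrame) -> pd.Series:
    """Vectorized closed-form phi at each run's observed measures."""
    d, ir, rr = df["d_hat"], df["ir_hat"], df["rr_hat"]
    q = np.minimum(ir * rr, 1.0)
    p = d * q + (1.0 - d) * ir
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(p * (1.0 - p) * d * (1.0 - d))
        out = d * (q - p) / denom
    return pd.Series(np.where(denom > 0, out, np.nan), index=df.index)


def design_frame(records: pd.DataFrame, predictor_source: str = "observed") -> pd.DataFrame:
    """Resolve every nameable predictor from the run records.

    Returns a frame with the base measures (``rho, d, ir, rr`` — taken from
    the assumed grid or the per-run observed estimates), their interactions,
    the four cell counts (``ndd`` = n - a - b - c), the closed-form
    predictions, the responses and the stratum label.
    """
    base = {"observed": _OBSERVED_BASE, "assumed": _ASSUMED_BASE}.get(predictor_source)
    if base is None:
        raise ValueError(f"unknown predictor_source {predictor_source!r}")
    out = pd.DataFrame(index=records.index)
    for term, col in base.items():
        out[term] = records[col]
    out["ir_rr"] = out["ir"] * out["rr"]
    out["d_rr"] = out["d"] * out["rr"]
    out["d_ir"] = out["d"] * out["ir"]
    out["d_ir_rr"] = out["d"] * out["ir"] * out["rr"]
    out["d2_ir"] = out["d"] ** 2 * out["ir"]
    out["a"] = records["a"]
    out["b"] = records["b"]
    out["c"] = records["c"]
    out["ndd"] = records["dd"]
    out["phi_closed_form"] = _phi_closed(records)
    out["chi2_closed_form"] = records["n"] * out["phi_closed_form"] ** 2
    out["phi"] = records["phi"]
    out["chi2"] = records["chi2"]
    out["stratum"] = records["stratum"]
    out["valid"] = records["valid"].astype(bool)
    return out


def _subset(design: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    sub = design[design["valid"]]
    if spec.stratum != "all":
        if spec.stratum not in (LESS_THAN_1, REACHING_1):
            raise ValueError(f"unknown stratum {spec.stratum!r}")
        sub = sub[sub["stratum"] == spec.stratum]
    return sub


def _vifs(exog: pd.DataFrame) -> pd.Series:
    """Per-term variance inflation factors; inf marks a rank-deficient term."""
    vals = {}
    arr = np.asarray(exog, dtype=float)
    for i, name in enumerate(exog.columns):
        if name == "const":
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    v = variance_inflation_factor(arr, i)
                except Exception:
                    v = np.inf
        vals[name] = float(v) if np.isfinite(v) else np.inf
    return pd.Series(vals)


def fit_ols(records: pd.DataFrame, spec: ModelSpec,
            design: pd.DataFrame | None = None) -> FitResult:
    """Ordinary least squares of ``spec.response`` on ``spec.terms``.

    Rows outside the stratum, flagged invalid, or with NaN in any used
    column are excluded (the exclusion count is reported).  Collinear terms
    are reported with infinite VIF rather than raising.
    """
    if design is None:
        design = design_frame(records, spec.predictor_source)
    sub = _subset(design, spec)
    cols = list(spec.terms) + [spec.response]
    n_before = len(sub)
    sub = sub.dropna(subset=cols)
    if len(sub) < len(spec.terms) + 2:
        raise ValueError(
            f"need at least {len(spec.terms) + 2} valid records for {spec}, have {len(sub)}"
        )
    exog = sm.add_constant(sub[list(spec.terms)].astype(float), has_constant="add")
    res = sm.OLS(sub[spec.response].astype(float), exog).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["low", "high"]
    return FitResult(
        spec=spec,
        params=res.params,
        conf_int=ci,
        pvalues=res.pvalues,
        r_squared=float(res.rsquared),
        residual_df=int(res.df_resid),
        vif=_vifs(exog),
        n_obs=int(res.nobs),
        n_excluded=n_before - len(sub),
    )


def identity_fit(records: pd.DataFrame, response: str = "phi") -> FitResult:
    """Regress a sample statistic on its closed form at the observed measures.

    Because the closed form reproduces each run's statistic exactly from that
    run's own table, the fit is an identity: slope 1, intercept 0 and
    R-squared = 1 up to floating-point error, at every grid size.
    """
    spec = ModelSpec(response=response, terms=(f"{response}_closed_form",),
                     stratum="all", predictor_source="observed")
    return fit_ols(records, spec)


def table_models(records: pd.DataFrame,
                 predictor_source: str = "observed") -> dict[tuple[str, str, str], FitResult]:
    """The eight approximation fits: (response, stratum, model) -> FitResult.

    Model "A" regresses on the four measures; model "B" adds the three
    pairwise interactions ir*rr, d*rr and d*ir.  Both at-risk-incidence
    strata are fitted for both responses.
    """
    design = design_frame(records, predictor_source)
    out = {}
    for response in ("phi", "chi2"):
        for strat in (LESS_THAN_1, REACHING_1):
            for model, terms in (("A", MODEL_A_TERMS), ("B", MODEL_B_TERMS)):
                spec = ModelSpec(response=response, terms=tuple(terms), stratum=strat,
                                 predictor_source=predictor_source)
                out[(response, strat, model)] = fit_ols(records, spec, design)
    return out


@dataclass(frozen=True)
class SequentialR2:
    """R-squared decomposition for one response within one stratum.

    ``cumulative`` adds rho, d, ir, rr in order (non-decreasing by nesting);
    ``individual`` gives, for each extra variable, its R-squared alone and
    the R-squared of the four measures plus that variable.
    """

    response: str
    stratum: str
    cumulative: pd.DataFrame  # columns: term_added, r_squared
    individual: pd.DataFrame  # columns: variable, alone_r_squared, with_measures_r_squared
    four_measure_r2: float = field(default=np.nan)


def sequential_r2(records: pd.DataFrame, response: str, stratum: str,
                  predictor_source: str = "observed",
                  extras: list[str] | None = None) -> SequentialR2:
    """Cumulative and individual R-squared ladders for one response/stratum."""
    design = design_frame(records, predictor_source)
    extras = EXTRA_TERMS if extras is None else extras

    def r2(terms: list[str]) -> float:
        spec = ModelSpec(response=response, terms=tuple(terms), stratum=stratum,
                         predictor_source=predictor_source)
        return fit_ols(records, spec, design).r_squared

    cum_rows = []
    for k in range(1, len(MEASURE_TERMS) + 1):
        cum_rows.append({"term_added": MEASURE_TERMS[k - 1],
                         "r_squared": r2(MEASURE_TERMS[:k])})
    cumulative = pd.DataFrame(cum_rows)
    four = float(cumulative["r_squared"].iloc[-1])
    ind_rows = []
    for var in extras:
        ind_rows.append({
            "variable": var,
            "alone_r_squared": r2([var]),
            "with_measures_r_squared": r2(MEASURE_TERMS + [var]),
        })
    return SequentialR2(response=response, stratum=stratum, cumulative=cumulative,
                        individual=pd.DataFrame(ind_rows), four_measure_r2=four)
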