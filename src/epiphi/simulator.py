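"""Finite-population simulation of two correlated diseases and one symptom.

Each subject carries two binary disease indicators and one binary symptom.
Disease 1 causes the symptom (probability ``min(ir*rr, 1)`` if diseased,
``ir`` otherwise); disease 2 is correlated with disease 1 at a target Pearson
correlation ``rho`` but has no effect on the symptom — it is deliberately
causally inert, so any apparent contribution of ``rho`` to the
disease–symptom association is an artefact.

The correlated pair is generated from its exact joint probabilities (not by
dichotomizing a Gaussian), so the target ``rho`` holds exactly in expectation:
for equal margins ``d``, ``cov = rho * d * (1 - d)`` pins the joint cell
``P(1,1) = d**2 + rho * d * (1 - d)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .measures import ContingencyTable, Scenario, at_risk_incidence, chi2_from_table, phi_from_table

__all__ = [
    "PopulationSample",
    "ObservedMeasures",
    "AssociationStats",
    "disease_joint_probs",
    "simulate_population",
    "observe_table",
    "derive_measures",
    "association_stats",
]


@dataclass(frozen=True)
class PopulationSample:
    """0/1 indicator vectors for one simulated population."""

    disease1: np.ndarray  # the symptom-causing disease
    disease2: np.ndarray  # the associated, causally inert disease
    symptom: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.disease1)
        if not (len(self.disease2) == len(self.symptom) == n):
            raise ValueError("indicator vectors must have identical length")

    @property
    def n(self) -> int:
        return len(self.disease1)


@dataclass(frozen=True)
class ObservedMeasures:
    """Epidemiologic measures estimated from one simulated population.

    Fields that would require division by zero are NaN.  Because the observed
    at-risk incidence ``q_hat`` is a probability, the derived risk ratio obeys
    the upper-limit law ``rr_hat <= 1 / ir_hat`` whenever defined.
    """

    d_hat: float  #: (a+c)/n, observed proportion diseased
    ir_hat: float  #: b/(b+dd), observed baseline incidence
    rr_hat: float  #: q_hat/ir_hat, observed risk ratio
    p_hat: float  #: (a+b)/n, observed overall incidence
    q_hat: float  #: a/(a+c), observed at-risk incidence
    rho_hat: float  #: sample correlation of the two diseases


@dataclass(frozen=True)
class AssociationStats:
    """Disease-symptom association statistics for one run.

    ``phi`` is the sample Pearson correlation of the two 0/1 vectors; its
    p-value comes from the t transform ``t = phi*sqrt((n-2)/(1-phi^2))`` with
    n-2 degrees of freedom, two-tailed.  ``chi2`` (uncorrected) satisfies
    ``chi2 = n * phi**2``; ``chi2_corrected`` applies the Yates adjustment.
    Both chi-squared p-values use the 1-df upper tail.  ``valid`` is False
    when either indicator has zero variance, in which case all statistics
    are NaN.
    """

    phi: float
    phi_p: float
    chi2: float
    chi2_corrected: float
    chi2_p: float
    chi2_corrected_p: float
    valid: bool


def disease_joint_probs(d: float, rho: float) -> tuple[float, float, float, float]:
    """Joint probabilities (P11, P10, P01, P00) of two correlated diseases.

    Both diseases have prevalence ``d``; solving ``cov = rho * d * (1-d)``
    for the joint cell gives ``P11 = d**2 + rho*d*(1-d)`` and the remaining
    cells by the margins.  Raises ValueError when any probability falls
    outside [0, 1] (infeasible rho for the given margins).
    """
    p11 = d * d + rho * d * (1.0 - d)
    p10 = d - p11
    p00 = 1.0 - 2.0 * d + p11
    probs = (p11, p10, p10, p00)
    if min(probs) < -1e-12 or max(probs) > 1.0 + 1e-12:
        raise ValueError(f"rho={rho} infeasible for margins d={d}: joint cells {probs}")
    return tuple(min(max(p, 0.0), 1.0) for p in probs)


def simulate_population(scn: Scenario, rng: np.random.Generator | None = None) -> PopulationSample:
    """Draw one population of ``scn.n`` independent subjects.

    The disease pair is drawn from :func:`disease_joint_probs`; the symptom
    is Bernoulli with probability ``min(ir*rr, 1)`` for subjects with
    disease 1 and ``ir`` otherwise.  Disease 2 never enters the symptom law.
    """
    if rng is None:
        rng = np.random.default_rng(scn.seed)
    p11, p10, p01, _ = disease_joint_probs(scn.d, scn.rho)
    u = rng.random(scn.n)
    # categorical draw over the four joint cells, in order 11, 10, 01, 00
    cell = np.searchsorted(np.cumsum([p11, p10, p01]), u, side="right")
    disease1 = (cell <= 1).astype(np.uint8)
    disease2 = ((cell == 0) | (cell == 2)).astype(np.uint8)
    q = at_risk_incidence(scn.ir, scn.rr)
    p_sym = np.where(disease1 == 1, q, scn.ir)
    symptom = (rng.random(scn.n) < p_sym).astype(np.uint8)
    return PopulationSample(disease1=disease1, disease2=disease2, symptom=symptom)


def observe_table(pop: PopulationSample) -> ContingencyTable:
    """Count the disease-1-by-symptom 2x2 table from a population."""
    d1 = pop.disease1.astype(bool)
    sym = pop.symptom.astype(bool)
    a = int(np.count_nonzero(d1 & sym))
    b = int(np.count_nonzero(~d1 & sym))
    c = int(np.count_nonzero(d1 & ~sym))
    return ContingencyTable(a=a, b=b, c=c, dd=pop.n - a - b - c)


def _binary_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 0/1 vectors via their 2x2 counts."""
    n = len(x)
    a = int(np.count_nonzero((x == 1) & (y == 1)))
    b = int(np.count_nonzero((x == 0) & (y == 1)))
    c = int(np.count_nonzero((x == 1) & (y == 0)))
    return phi_from_table(ContingencyTable(a=a, b=b, c=c, dd=n - a - b - c))


def derive_measures(t: ContingencyTable, pop: PopulationSample | None = None) -> ObservedMeasures:
    """Estimate the epidemiologic measures from an observed table.

    ``rho_hat`` (the between-disease correlation) needs the population and is
    NaN when ``pop`` is not given.  Ratios with zero denominators are NaN.
    """
    n = t.n
    n_dis = t.a + t.c
    n_ndis = t.b + t.dd
    d_hat = n_dis / n
    ir_hat = t.b / n_ndis if n_ndis > 0 else math.nan
    q_hat = t.a / n_dis if n_dis > 0 else math.nan
    rr_hat = q_hat / ir_hat if ir_hat and not math.isnan(ir_hat) and not math.isnan(q_hat) else math.nan
    rho_hat = _binary_corr(pop.disease1, pop.disease2) if pop is not None else math.nan
    return ObservedMeasures(
        d_hat=d_hat, ir_hat=ir_hat, rr_hat=rr_hat, p_hat=(t.a + t.b) / n, q_hat=q_hat, rho_hat=rho_hat
    )


def association_stats(pop: PopulationSample) -> AssociationStats:
    """Compute phi, chi-squared (both variants) and their p-values for a run."""
    return association_stats_from_table(observe_table(pop))


def association_stats_from_table(t: ContingencyTable) -> AssociationStats:
    """Association statistics from an already-counted 2x2 table."""
    n = t.n
    if t.is_degenerate:
        nan = math.nan
        return AssociationStats(nan, nan, nan, nan, nan, nan, valid=False)
    phi = phi_from_table(t)
    if abs(phi) >= 1.0:
        phi_p = 0.0
    else:
        tval = phi * math.sqrt((n - 2) / (1.0 - phi * phi))
        phi_p = 2.0 * stats.t.sf(abs(tval), n - 2)
    chi2 = chi2_from_table(t, corrected=False)
    chi2c = chi2_from_table(t, corrected=True)
    return AssociationStats(
        phi=phi,
        phi_p=float(phi_p),
        chi2=chi2,
        chi2_corrected=chi2c,
        chi2_p=float(stats.chi2.sf(chi2, 1)),
        chi2_corrected_p=float(stats.chi2.sf(chi2c, 1)),
        valid=True,
    )
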