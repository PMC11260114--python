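"""Closed-form translation of epidemiologic measures into association statistics.

In a cohort where a single disease raises the probability of a symptom, three
epidemiologic measures determine the joint distribution of disease and symptom:

``d``
    proportion diseased (prevalence of the causal disease),
``ir``
    baseline cumulative incidence of the symptom among the non-diseased,
``rr``
    risk ratio of the symptom given disease.

The symptom probability among the diseased (the *at-risk incidence*) is
``q = min(ir * rr, 1)`` — a probability cannot exceed 1, which puts an upper
limit of ``1/ir`` on any observable risk ratio and splits parameter
combinations into two regimes: at-risk incidence *less than 1* and *reaching 1*.

Writing the expected 2x2 disease-by-symptom table in terms of (d, ir, rr, n)
gives closed forms for the phi coefficient (the Pearson correlation of the two
binary indicators) and the chi-squared statistic, linked by the identity
``chi2 = n * phi**2`` (without continuity correction).

Everything here is pure algebra on probabilities and table cells; no
randomness, no I/O.  Expected tables carry fractional cells — closed forms are
population identities and are never rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "LESS_THAN_1",
    "REACHING_1",
    "Scenario",
    "ContingencyTable",
    "at_risk_incidence",
    "stratum",
    "rr_upper_limit",
    "overall_incidence",
    "expected_table",
    "phi_from_table",
    "phi_from_measures",
    "chi2_from_measures",
    "chi2_from_table",
]

#: Stratum label: at-risk incidence ir*rr stays strictly below 1.
LESS_THAN_1 = "less_than_1"
#: Stratum label: at-risk incidence ir*rr attains the ceiling of 1 (all
#: diseased symptomatic).  Products exactly equal to 1 are classified here:
#: they behave identically to capped combinations.
REACHING_1 = "reaching_1"


def _check_ir_rr(ir: float, rr: float) -> None:
    if not 0.0 < ir <= 1.0:
        raise ValueError(f"baseline incidence ir must be in (0, 1], got {ir}")
    if not rr > 0.0:
        raise ValueError(f"risk ratio rr must be > 0, got {rr}")


@dataclass(frozen=True)
class Scenario:
    """One parameter combination of the factorial design.

    Parameters
    ----------
    rho : float
        Target Pearson correlation between the causal disease and a second,
        causally inert disease of the same prevalence.  Must lie in the
        feasible range for two equal-prevalence binary variables,
        ``-min(d, 1-d)/max(d, 1-d) <= rho <= 1``.
    d : float
        Proportion diseased, strictly inside (0, 1).
    ir : float
        Baseline symptom incidence among the non-diseased, in (0, 1].
    rr : float
        Risk ratio of the symptom given disease, > 0.
    n : int
        Population size per simulated run, >= 2.
    replicate : int
        Replicate index within the parameter combination.
    seed : int or None
        Seed material for the run; recorded for reproducibility.
    """

    rho: float
    d: float
    ir: float
    rr: float
    n: int = 10_000
    replicate: int = 0
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.d < 1.0:
            raise ValueError(f"proportion diseased d must be in (0, 1), got {self.d}")
        _check_ir_rr(self.ir, self.rr)
        if self.n < 2:
            raise ValueError(f"population size n must be >= 2, got {self.n}")
        lo = -min(self.d, 1.0 - self.d) / max(self.d, 1.0 - self.d)
        if not lo - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(
                f"rho={self.rho} infeasible for equal margins d={self.d}; "
                f"feasible range is [{lo:.6g}, 1]"
            )

    @property
    def at_risk_incidence(self) -> float:
        return at_risk_incidence(self.ir, self.rr)

    @property
    def stratum(self) -> str:
        return stratum(self.ir, self.rr)


@dataclass(frozen=True)
class ContingencyTable:
    """Four cells of the disease-by-symptom 2x2 table.

    Cell naming follows the epidemiologic convention: ``a`` diseased and
    symptomatic, ``b`` symptomatic only, ``c`` diseased only, ``dd`` neither.
    Cells may be fractional (expected-value tables) or integer counts; they
    must be nonnegative.
    """

    a: float
    b: float
    c: float
    dd: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.dd) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.dd

    @property
    def margins(self) -> tuple[float, float, float, float]:
        """(symptomatic, asymptomatic, diseased, non-diseased) totals."""
        return (self.a + self.b, self.c + self.dd, self.a + self.c, self.b + self.dd)

    @property
    def is_degenerate(self) -> bool:
        """True when any margin is zero, leaving phi/chi2 undefined."""
        return min(self.margins) == 0


def at_risk_incidence(ir: float, rr: float) -> float:
    """Symptom probability among the diseased, ``min(ir * rr, 1)``.

    The product of the baseline incidence and the risk ratio cannot exceed 1
    (a maximum of 100% incidence among the diseased), so it is capped.

    Examples
    --------
    >>> at_risk_incidence(0.1, 2)
    0.2
    >>> at_risk_incidence(0.8, 25)
    1.0
    """
    _check_ir_rr(ir, rr)
    return min(ir * rr, 1.0)


def stratum(ir: float, rr: float) -> str:
    """Classify a (ir, rr) pair by whether its at-risk incidence reaches 1.

    Returns :data:`REACHING_1` iff ``ir * rr >= 1`` else :data:`LESS_THAN_1`.
    Products exactly equal to 1 (e.g. 0.1 x 10) count as reaching: all
    diseased subjects are symptomatic, exactly as in capped combinations.
    """
    _check_ir_rr(ir, rr)
    return REACHING_1 if ir * rr >= 1.0 else LESS_THAN_1


def rr_upper_limit(ir: float) -> float:
    """Largest observable risk ratio for a given baseline incidence, ``1/ir``.

    Since the at-risk incidence ``ir * rr`` cannot exceed 1, the risk ratio
    estimated from any population is bounded by the multiplicative inverse of
    the baseline incidence: 20, 10, 5, 2.5 and 1.25 for baseline incidences
    0.05, 0.1, 0.2, 0.4 and 0.8.
    """
    if not 0.0 < ir <= 1.0:
        raise ValueError(f"baseline incidence ir must be in (0, 1], got {ir}")
    return 1.0 / ir


def overall_incidence(d: float, ir: float, rr: float) -> float:
    """Population symptom incidence ``d*q + (1-d)*ir`` with ``q = min(ir*rr, 1)``.

    This is the prevalence-weighted mixture of the at-risk and baseline
    incidences; it always lies between ``min(ir, q)`` and ``max(ir, q)``.
    """
    if not 0.0 < d < 1.0:
        raise ValueError(f"proportion diseased d must be in (0, 1), got {d}")
    return d * at_risk_incidence(ir, rr) + (1.0 - d) * ir


def expected_table(scn: Scenario) -> ContingencyTable:
    """Expected (fractional) disease-by-symptom table for a scenario.

    With ``q = min(ir*rr, 1)``::

        a  = n * d * q          (diseased, symptomatic)
        c  = n * d * (1 - q)    (diseased, asymptomatic)
        b  = n * (1-d) * ir     (non-diseased, symptomatic)
        dd = n * (1-d) * (1-ir) (neither)

    The four cells sum to ``n`` exactly.
    """
    q = at_risk_incidence(scn.ir, scn.rr)
    nd = scn.n * scn.d
    nnd = scn.n - nd
    return ContingencyTable(a=nd * q, b=nnd * scn.ir, c=nd * (1.0 - q), dd=nnd * (1.0 - scn.ir))


def phi_from_table(t: ContingencyTable) -> float:
    """Phi coefficient of a 2x2 table, ``(a*dd - b*c) / sqrt of margin product``.

    Equals the Pearson correlation of the two 0/1 indicator vectors that
    produce the table.  Returns NaN when any margin is zero (a zero-variance
    indicator leaves the correlation undefined).
    """
    if t.is_degenerate:
        return math.nan
    m1, m2, m3, m4 = t.margins
    return (t.a * t.dd - t.b * t.c) / math.sqrt(m1 * m2 * m3 * m4)


def phi_from_measures(d: float, ir: float, rr: float) -> float:
    """Closed-form phi coefficient from the three epidemiologic measures.

    With ``q = min(ir*rr, 1)`` the at-risk incidence and ``p`` the overall
    incidence::

        phi = d * (q - p) / sqrt(p * (1-p) * d * (1-d))

    Algebraically identical to :func:`phi_from_table` applied to
    :func:`expected_table`; the sign matches the sign of ``rr - 1`` whenever
    the cap is not binding.  Returns NaN when ``p`` is 0 or 1 (degenerate
    symptom margin).
    """
    p = overall_incidence(d, ir, rr)
    if p <= 0.0 or p >= 1.0:
        return math.nan
    q = at_risk_incidence(ir, rr)
    return d * (q - p) / math.sqrt(p * (1.0 - p) * d * (1.0 - d))


def chi2_from_measures(d: float, ir: float, rr: float, n: float) -> float:
    """Closed-form chi-squared statistic, ``n * phi_from_measures(...)**2``.

    Unlike phi, the chi-squared statistic scales linearly with the population
    size at fixed measures.
    """
    phi = phi_from_measures(d, ir, rr)
    return n * phi * phi


def chi2_from_table(t: ContingencyTable, corrected: bool = False) -> float:
    """Chi-squared statistic of a 2x2 table against independence.

    Sums ``(observed - expected)**2 / expected`` over the four cells, where
    expected cells are the margin products divided by ``n``.  Without
    correction this equals ``n * phi_from_table(t)**2``.  With
    ``corrected=True`` the Yates continuity adjustment shrinks each
    ``|observed - expected|`` by 0.5 (floored at 0) before squaring, so the
    corrected statistic never exceeds the uncorrected one.

    Returns NaN on a degenerate table.
    """
    if t.is_degenerate:
        return math.nan
    sym, asym, dis, ndis = t.margins
    n = t.n
    total = 0.0
    for obs, exp in (
        (t.a, sym * dis / n),
        (t.b, sym * ndis / n),
        (t.c, asym * dis / n),
        (t.dd, asym * ndis / n),
    ):
        dev = abs(obs - exp)
        if corrected:
            dev = max(dev - 0.5, 0.0)
        total += dev * dev / exp
    return total
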