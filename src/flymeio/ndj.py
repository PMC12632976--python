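"""X-chromosome nondisjunction (NDJ) assay arithmetic and tests.

In the standard cross (females x *B^s Y* males), maternal NDJ products are
recovered as diplo-X females and nullo-X males; the reciprocal exceptional
classes (triplo-X, YO) die.  Each surviving exceptional progeny therefore
represents two exceptional meioses, giving the adjusted total

    adjusted = regular + 2 * (diplo_X + nullo_X)

and the NDJ frequency 100 * 2*exceptions / adjusted (percent of meioses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NdjTally",
    "NdjSummary",
    "ndj_summary",
    "ndj_test",
    "ndj_wald_test",
    "NdjTestResult",
]


@dataclass(frozen=True)
class NdjTally:
    """Raw progeny tallies for one genotype."""

    regular_females: int
    regular_males: int
    diplo_X: int
    nullo_X: int
    n_parent_females: int = 0

    def __post_init__(self) -> None:
        for name in ("regular_females", "regular_males", "diplo_X", "nullo_X",
                     "n_parent_females"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def regular(self) -> int:
        return self.regular_females + self.regular_males

    @property
    def exceptional(self) -> int:
        return self.diplo_X + self.nullo_X

    @property
    def adjusted_total(self) -> int:
        return self.regular + 2 * self.exceptional


@dataclass(frozen=True)
class NdjSummary:
    exceptional_total: int
    adjusted_total: int
    #: percent of meioses that were nondisjunctional (full precision)
    ndj_percent: float
    progeny_per_female: float | None

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        out = {
            "ndj_percent": round(self.ndj_percent, ndigits),
            "adjusted_total": self.adjusted_total,
        }
        if self.progeny_per_female is not None:
            out["progeny_per_female"] = round(self.progeny_per_female, ndigits)
        return out


def ndj_summary(tally: NdjTally) -> NdjSummary:
    """Adjusted total, NDJ percentage and fertility summary for one tally."""
    adjusted = tally.adjusted_total
    if adjusted == 0:
        raise ValueError("adjusted total is zero; nothing was recovered")
    ndj_percent = 100.0 * 2 * tally.exceptional / adjusted
    ppf = (
        adjusted / tally.n_parent_females if tally.n_parent_females >= 1 else None
    )
    return NdjSummary(
        exceptional_total=tally.exceptional,
        adjusted_total=adjusted,
        ndj_percent=ndj_percent,
        progeny_per_female=ppf,
    )


@dataclass(frozen=True)
class NdjTestResult:
    p_value: float
    #: Monte-Carlo standard error of the (one-sided, pre-doubling) tail
    mc_se: float | None
    statistic: float
    method: str


def _p_hat(tally: NdjTally) -> float:
    return 2 * tally.exceptional / tally.adjusted_total


def ndj_test(
    tally_a: NdjTally,
    tally_b: NdjTally,
    reps: int = 100_000,
    seed: int | None = None,
) -> NdjTestResult:
    """Monte-Carlo two-sided test of equal NDJ rates between genotypes.

    Generative null model: each of the (adjusted-total) scored meioses is
    nondisjunctional with the pooled probability p0; an exceptional
    meiosis yields a *recovered* exceptional progeny with probability 1/2
    (the reciprocal product dies); regular meioses yield regular progeny.
    The statistic is the difference of estimated rates p_hat = 2X/(2X+R).
    Two-sided p doubles the smaller Monte-Carlo tail (capped at 1).
    Seed-deterministic and symmetric in its two arguments.
    """
    if reps < 10_000:
        raise ValueError("reps must be >= 10^4 for a stable Monte-Carlo p")
    for t in (tally_a, tally_b):
        if t.adjusted_total == 0:
            raise ValueError("zero adjusted total")
    # canonical ordering makes the simulation streams, and hence the
    # p-value, invariant under swapping the arguments
    key = lambda t: (t.adjusted_total, t.exceptional, t.regular_females)
    first, second = sorted((tally_a, tally_b), key=key)
    n1, n2 = first.adjusted_total, second.adjusted_total
    p0 = (2 * first.exceptional + 2 * second.exceptional) / (n1 + n2)
    d_obs = _p_hat(first) - _p_hat(second)

    rng = np.random.default_rng(seed)

    def sim_rates(n: int) -> np.ndarray:
        x = rng.binomial(n, p0, size=reps)          # NDJ meioses
        x_rec = rng.binomial(x, 0.5)                # surviving exceptions
        regular = n - x
        return 2.0 * x_rec / (2.0 * x_rec + regular)

    d_sim = sim_rates(n1) - sim_rates(n2)
    hi = (1 + np.count_nonzero(d_sim >= d_obs)) / (reps + 1)
    lo = (1 + np.count_nonzero(d_sim <= d_obs)) / (reps + 1)
    tail = min(hi, lo)
    p = min(1.0, 2.0 * tail)
    mc_se = float(np.sqrt(tail * (1 - tail) / reps))
    return NdjTestResult(p_value=float(p), mc_se=mc_se, statistic=float(d_obs),
                         method="monte-carlo")


def ndj_wald_test(tally_a: NdjTally, tally_b: NdjTally) -> NdjTestResult:
    """Analytic two-sided Wald test on the NDJ rate difference.

    Delta-method variance of p_hat = 2X/(2X + R) under the viability
    model with n = adjusted-total meioses: with X ~ Bin(n, p/2) recovered
    exceptions and R ~ Bin(n, 1-p) regulars (negatively correlated via
    the trinomial), Var(p_hat) ~= p((1-p)(2-p) + p(1-p/2)) / n evaluated
    at the pooled estimate.  Secondary, approximate alternative to
    :func:`ndj_test`.
    """
    for t in (tally_a, tally_b):
        if t.adjusted_total == 0:
            raise ValueError("zero adjusted total")
    n1, n2 = tally_a.adjusted_total, tally_b.adjusted_total
    p0 = (2 * tally_a.exceptional + 2 * tally_b.exceptional) / (n1 + n2)
    d = _p_hat(tally_a) - _p_hat(tally_b)

    def var(n: int) -> float:
        # trinomial meiosis outcome: recovered exception (p/2), dead
        # exception (p/2), regular (1-p); delta method on 2x/(2x+r)
        p = p0
        gx = 2 * (1 - p)          # d p_hat / d (x/n) at the mean
        gr = -p                   # d p_hat / d (r/n) at the mean
        vx = (p / 2) * (1 - p / 2) / n
        vr = (1 - p) * p / n
        cxr = -(p / 2) * (1 - p) / n
        return gx * gx * vx + gr * gr * vr + 2 * gx * gr * cxr

    se = np.sqrt(var(n1) + var(n2))
    if se == 0:
        return NdjTestResult(p_value=1.0, mc_se=None, statistic=float(d),
                             method="wald")
    z = d / se
    p = 2 * stats.norm.sf(abs(z))
    return NdjTestResult(p_value=float(min(1.0, p)), mc_se=None,
                         statistic=float(z), method="wald")
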