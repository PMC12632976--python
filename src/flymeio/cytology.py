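"""Germarium screen scoring rules and per-nucleus foci statistics.

Encodes the visual-scoring rules of an RNAi screen of early female
meiosis: each germarium is scored for full-length synaptonemal complex
(SC) assembly in region 2A, SC maintenance at the region-3 oocyte
nucleus, and the presence of gamma-H2Av foci (double-strand-break
marker) in regions 2A and 3.  A line is assigned a defect label when at
least half of its scorable germaria show that defect, with a minimum of
ten scorable germaria.  Per-nucleus count data (gamma-H2Av foci,
centromere CID clusters) are summarised as mean (+/- SD) N and compared
between genotypes with the Mann-Whitney U test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb as _comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REGIONS",
    "GermariumObservation",
    "LineClassification",
    "classify_line",
    "mann_whitney",
    "MannWhitneyResult",
    "summarize_foci",
]

logger = logging.getLogger(__name__)

#: fixed vocabulary of germarium / egg-chamber stages
REGIONS = ("2A", "2B", "3", "mid-prophase")

#: defect label -> (flag name, flag value meaning "defective")
_DEFECT_RULES = {
    # few/no nuclei with robust full-length SC in region 2A
    "SC assembly defect": ("full_length_SC_2A", False),
    # full-length SC not retained at the region-3 nucleus
    "SC maintenance defect": ("SC_maintained_region3", False),
    # no gamma-H2Av foci in region 2A: breaks never induced
    "DSB initiation defect": ("gH2Av_present_2A", False),
    # gamma-H2Av foci persisting in region 3: breaks not repaired
    "DSB repair defect": ("gH2Av_present_region3", True),
    "underdeveloped": ("underdeveloped", True),
}


@dataclass(frozen=True)
class GermariumObservation:
    """Boolean scoring flags for one germarium (None = not scorable)."""

    germarium_id: str
    full_length_SC_2A: Optional[bool] = None
    SC_maintained_region3: Optional[bool] = None
    gH2Av_present_2A: Optional[bool] = None
    gH2Av_present_region3: Optional[bool] = None
    underdeveloped: Optional[bool] = None

    def any_usable(self) -> bool:
        return any(
            getattr(self, f) is not None
            for f, _ in _DEFECT_RULES.values()
        )


@dataclass(frozen=True)
class LineClassification:
    """Defect labels for one RNAi line with per-label defective fractions."""

    labels: frozenset[str]
    fractions: dict[str, float]
    n_germaria: int

    def __post_init__(self) -> None:
        if "none" in self.labels and len(self.labels) > 1:
            raise ValueError('"none" is exclusive of other labels')


def classify_line(
    observations: Sequence[GermariumObservation],
    *,
    min_germaria: int = 10,
    threshold: float = 0.5,
) -> LineClassification:
    """Rule-based phenotype classification of one RNAi line.

    For each defect category the defective fraction is computed over the
    germaria with a non-missing flag for that category (missing flags are
    excluded from the denominator, not imputed); the label is assigned iff
    the fraction is at least ``threshold`` (inclusive, i.e. "at least
    50%" by default).

    Raises
    ------
    ValueError
        If fewer than ``min_germaria`` observations carry any usable flag.
    """
    usable = [o for o in observations if o.any_usable()]
    if len(usable) < min_germaria:
        raise ValueError(
            f"only {len(usable)} germaria with usable flags; "
            f"at least {min_germaria} required"
        )
    labels: set[str] = set()
    fractions: dict[str, float] = {}
    for label, (flag, defective_value) in _DEFECT_RULES.items():
        vals = [getattr(o, flag) for o in usable if getattr(o, flag) is not None]
        if not vals:
            logger.warning("no scorable germaria for %r; label skipped", label)
            continue
        frac = sum(bool(v) == defective_value for v in vals) / len(vals)
        fractions[label] = frac
        if frac >= threshold:
            labels.add(label)
    if not labels:
        labels = {"none"}
    return LineClassification(
        labels=frozenset(labels), fractions=fractions, n_germaria=len(usable)
    )


@dataclass(frozen=True)
class MannWhitneyResult:
    #: min-U convention: min(U_a, U_b)
    U: float
    p_value: float
    method: str

    def stars(self) -> str:
        """Significance annotation at the conventional 0.05/0.01 levels."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _exact_mw(a: np.ndarray, b: np.ndarray) -> MannWhitneyResult:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks handle ties
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    mu = n_a * n_b / 2.0

    def u_from_idx(idx: tuple[int, ...]) -> float:
        ra = ranks[list(idx)].sum()
        return ra - n_a * (n_a + 1) / 2.0

    u_obs = u_from_idx(tuple(range(n_a)))
    dev_obs = abs(u_obs - mu)
    total = _comb(n, n_a)
    hits = 0
    for idx in combinations(range(n), n_a):
        if abs(u_from_idx(idx) - mu) >= dev_obs - 1e-12:
            hits += 1
    p = hits / total
    return MannWhitneyResult(
        U=float(min(u_obs, n_a * n_b - u_obs)), p_value=float(p), method="exact"
    )


def mann_whitney(
    a: Sequence[float], b: Sequence[float], *, exact_max_n: int = 16
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (min-U convention).

    Uses the exact permutation distribution (midranks for ties) when
    ``len(a) + len(b) <= exact_max_n``, otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if a.size + b.size <= exact_max_n:
        return _exact_mw(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    u = float(res.statistic)
    return MannWhitneyResult(
        U=float(min(u, a.size * b.size - u)),
        p_value=float(res.pvalue),
        method="normal-approximation",
    )


def summarize_foci(data: pd.DataFrame) -> pd.DataFrame:
    """Per genotype x region (x measure) foci-count summaries.

    Parameters
    ----------
    data : DataFrame
        Columns ``genotype, region, nucleus_id, count`` and optionally
        ``measure`` (e.g. ``gH2Av`` vs ``CID_clusters``).  Counts are
        non-negative integers; regions from :data:`REGIONS`.

    Returns
    -------
    DataFrame
        One row per cell with ``mean``, ``sd`` (n-1 denominator), ``n``
        and a ``display`` column formatted ``"mean (+/-sd) N=n"`` at one
        decimal, matching the conventional table presentation.
    """
    required = {"genotype", "region", "count"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"foci table lacks columns {sorted(missing)}")
    bad_regions = set(data["region"]) - set(REGIONS)
    if bad_regions:
        raise ValueError(f"unknown regions {sorted(bad_regions)}; "
                         f"allowed: {list(REGIONS)}")
    if (data["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    keys = ["genotype", "region"] + (["measure"] if "measure" in data.columns else [])
    rows = []
    for key, grp in data.groupby(keys, sort=False):
        counts = grp["count"].to_numpy(dtype=float)
        if counts.size == 0:
            warnings.warn(f"empty cell {key}; omitted", UserWarning)
            continue
        mean = float(counts.mean())
        sd = float(counts.std(ddof=1)) if counts.size > 1 else float("nan")
        sd_disp = "NA" if np.isnan(sd) else f"{sd:.1f}"
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            mean=mean, sd=sd, n=counts.size,
            display=f"{mean:.1f} (+/-{sd_disp}) N={counts.size}",
        )
        rows.append(row)
    return pd.DataFrame(rows)
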