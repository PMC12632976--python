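"""Crossover scoring of multi-marker backcross progeny.

Converts per-progeny phenotype records into interval recombination calls,
per-interval genetic map lengths (cM = 100 x recombinant fraction), and
chromatid crossover-class tallies (NCO/SCO/DCO/TCO).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .markers import (
    MISSING,
    CrossoverClassCounts,
    IntervalRecombinationResult,
    MarkerMap,
    ProgenyRecord,
    SchemaError,
    ScoringError,
)

__all__ = [
    "call_crossovers",
    "tally_classes",
    "interval_map_lengths",
    "IntervalMapLengths",
    "compare_interval",
]

logger = logging.getLogger(__name__)


def call_crossovers(
    record: ProgenyRecord,
    marker_map: MarkerMap,
    *,
    allow_male: bool = False,
) -> IntervalRecombinationResult:
    """Score one progeny chromatid for crossovers.

    An interval is recombinant iff the nearest non-missing calls flanking
    it differ and those calls are at the interval's own endpoints; a phase
    switch whose flanking calls span two or more intervals (because of a
    missing call between them) is counted once in ``crossover_count`` but
    assigned to no single interval.

    Parameters
    ----------
    record : ProgenyRecord
    marker_map : MarkerMap
    allow_male : bool
        By default male progeny are rejected (markers are scored in female
        progeny only in the standard cross design); pass True for cross
        designs where males are informative.

    Raises
    ------
    ScoringError
        If the record is male (and ``allow_male`` is False) or has no
        non-missing call.
    SchemaError
        If the record's loci do not match the map.
    """
    if record.sex == "male" and not allow_male:
        raise ScoringError(
            f"record {record.progeny_id!r} is male; markers are scored in "
            "female progeny (pass allow_male=True to override)"
        )
    calls = record.calls_in_order(marker_map)
    observed = [(i, c) for i, c in enumerate(calls) if c != MISSING]
    if not observed:
        raise ScoringError(
            f"record {record.progeny_id!r} has no non-missing call"
        )
    flags = [False] * marker_map.n_intervals
    crossover_count = 0
    unassigned = 0
    for (i, a), (j, b) in zip(observed[:-1], observed[1:]):
        if a != b:
            crossover_count += 1
            if j - i == 1:
                flags[i] = True
            else:
                unassigned += 1
    return IntervalRecombinationResult(
        progeny_id=record.progeny_id,
        interval_recombinant=tuple(flags),
        crossover_count=crossover_count,
        unassigned_switches=unassigned,
    )


def _score_usable(
    records: Sequence[ProgenyRecord],
    marker_map: MarkerMap,
    allow_male: bool,
) -> list[IntervalRecombinationResult]:
    if not records:
        raise ScoringError("empty record list")
    results = []
    for rec in records:
        try:
            results.append(call_crossovers(rec, marker_map, allow_male=allow_male))
        except (ScoringError, SchemaError) as exc:
            logger.warning("excluding record %r: %s", rec.progeny_id, exc)
    if not results:
        raise ScoringError("no usable records after exclusions")
    return results


def tally_classes(
    records: Sequence[ProgenyRecord],
    marker_map: MarkerMap,
    *,
    allow_male: bool = False,
) -> CrossoverClassCounts:
    """Tally chromatids by observed crossover count (NCO/SCO/DCO/...).

    Records failing :func:`call_crossovers` preconditions are excluded
    with a logged warning; N counts included records only.
    """
    results = _score_usable(records, marker_map, allow_male)
    return CrossoverClassCounts.from_crossover_counts(
        r.crossover_count for r in results
    )


@dataclass(frozen=True)
class IntervalMapLengths:
    """Per-interval map lengths in centimorgans plus their arithmetic sum."""

    interval_labels: tuple[str, ...]
    recombinants: tuple[int, ...]
    n: int
    #: cM per interval = 100 * recombinants / n (full precision)
    cm: tuple[float, ...]
    total_cm: float

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Display values at table precision (default one decimal)."""
        out = {lab: round(v, ndigits) for lab, v in zip(self.interval_labels, self.cm)}
        out["total"] = round(self.total_cm, ndigits)
        return out


def interval_map_lengths(
    records: Sequence[ProgenyRecord],
    marker_map: MarkerMap,
    *,
    allow_male: bool = False,
) -> IntervalMapLengths:
    """Per-interval genetic map length: 100 x recombinants / N (cM).

    The total is the arithmetic sum over intervals.  When no record has a
    missing call this equals 100 x (mean crossovers per chromatid), since
    every phase switch lands in exactly one interval.
    """
    results = _score_usable(records, marker_map, allow_male)
    n = len(results)
    recomb = [0] * marker_map.n_intervals
    for r in results:
        for i, flag in enumerate(r.interval_recombinant):
            if flag:
                recomb[i] += 1
    cm = tuple(100.0 * r / n for r in recomb)
    return IntervalMapLengths(
        interval_labels=marker_map.interval_labels,
        recombinants=tuple(recomb),
        n=n,
        cm=cm,
        total_cm=float(sum(cm)),
    )


def compare_interval(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> float:
    """Two-sided Fisher's exact test on one interval between genotypes.

    Parameters
    ----------
    counts_a, counts_b : (recombinants, N)
        Recombinant count and total progeny scored for each genotype.

    Returns
    -------
    float
        Two-sided p-value (sum of point probabilities no larger than the
        observed table's, the standard two-sided convention).
    """
    for rec, n in (counts_a, counts_b):
        if n <= 0:
            raise ValueError("total progeny N must be positive")
        if not 0 <= rec <= n:
            raise ValueError("recombinants must satisfy 0 <= recomb <= N")
    table = [
        [counts_a[0], counts_a[1] - counts_a[0]],
        [counts_b[0], counts_b[1] - counts_b[0]],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)
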