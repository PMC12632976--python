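"""Core data structures for backcross crossover scoring.

A recombination mapping cross recovers one of the four chromatids of each
maternal tetrad in each progeny.  Progeny are phenotyped at an ordered set
of recessive visible markers spanning one chromosome arm; at each marker a
progeny either shows the marked (parental, ``P``) or wild-type
(recombinant-informative, ``R``) phenotype.  A switch of phase between
adjacent markers reveals a crossover in that interval.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PARENTAL",
    "RECOMBINANT",
    "MISSING",
    "MarkerMap",
    "ProgenyRecord",
    "IntervalRecombinationResult",
    "CrossoverClassCounts",
    "SchemaError",
    "ScoringError",
]

PARENTAL = "P"
RECOMBINANT = "R"
MISSING = "NA"

_VALID_CALLS = frozenset({PARENTAL, RECOMBINANT, MISSING})
_VALID_SEXES = frozenset({"female", "male"})


class SchemaError(ValueError):
    """Input does not conform to the declared tabular/marker schema."""


class ScoringError(ValueError):
    """A record cannot be scored (e.g. all calls missing, wrong sex)."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered visible markers on one chromosome arm.

    Parameters
    ----------
    chromosome_label : str
        Free-text label of the chromosome/arm (e.g. ``"2L-2R"``).
    loci : tuple of str
        Marker names in map order, e.g. ``("net", "dpp", "dpy", "b",
        "pr", "cn")``.  At least two, all unique.
    """

    chromosome_label: str
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        loci = tuple(self.loci)
        object.__setattr__(self, "loci", loci)
        if len(loci) < 2:
            raise SchemaError("a marker map needs at least two loci")
        if len(set(loci)) != len(loci):
            dup = [name for name, k in Counter(loci).items() if k > 1]
            raise SchemaError(f"duplicate locus names: {dup}")

    @property
    def intervals(self) -> tuple[tuple[str, str], ...]:
        """Adjacent-locus pairs, one per scoring interval."""
        return tuple(zip(self.loci[:-1], self.loci[1:]))

    @property
    def interval_labels(self) -> tuple[str, ...]:
        return tuple(f"{a}-{b}" for a, b in self.intervals)

    @property
    def n_intervals(self) -> int:
        return len(self.loci) - 1

    def index_of(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise SchemaError(
                f"unknown locus {locus!r}; map defines {list(self.loci)}"
            ) from None


@dataclass(frozen=True)
class ProgenyRecord:
    """One scored progeny: a per-locus parental/recombinant phenotype call.

    ``calls`` maps every locus of the associated :class:`MarkerMap` to
    ``"P"`` (parental / recessive-marked), ``"R"`` (recombinant /
    wild-type) or ``"NA"`` (not scored).
    """

    progeny_id: str
    sex: str
    calls: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.sex not in _VALID_SEXES:
            raise SchemaError(
                f"sex must be one of {sorted(_VALID_SEXES)}, got {self.sex!r}"
            )
        bad = {v for v in self.calls.values()} - _VALID_CALLS
        if bad:
            raise SchemaError(
                f"invalid calls {sorted(bad)}; allowed: {sorted(_VALID_CALLS)}"
            )
        object.__setattr__(self, "calls", dict(self.calls))

    def calls_in_order(self, marker_map: MarkerMap) -> list[str]:
        """Calls ordered along the map; raises if any locus is absent."""
        missing = [l for l in marker_map.loci if l not in self.calls]
        if missing:
            raise SchemaError(
                f"record {self.progeny_id!r} lacks calls for loci {missing}"
            )
        extra = set(self.calls) - set(marker_map.loci)
        if extra:
            raise SchemaError(
                f"record {self.progeny_id!r} has calls for unknown loci "
                f"{sorted(extra)}"
            )
        return [self.calls[l] for l in marker_map.loci]


@dataclass(frozen=True)
class IntervalRecombinationResult:
    """Per-interval recombination calls for one chromatid.

    ``crossover_count`` is the number of phase switches along the ordered
    loci (using nearest non-missing flanking calls).  A switch that cannot
    be localised to a single interval because of missing calls is counted
    in ``crossover_count`` but flagged in no interval; such switches are
    tallied in ``unassigned_switches``.
    """

    progeny_id: str
    interval_recombinant: tuple[bool, ...]
    crossover_count: int
    unassigned_switches: int = 0

    def __post_init__(self) -> None:
        assigned = sum(self.interval_recombinant)
        if assigned + self.unassigned_switches != self.crossover_count:
            raise ValueError(
                "crossover_count must equal assigned + unassigned switches"
            )


@dataclass(frozen=True)
class CrossoverClassCounts:
    """Counts of recovered chromatids by number of observed crossovers.

    ``counts[k]`` is the number of chromatids with *k* crossovers
    (k = 0 non-crossover, 1 single, 2 double, 3 triple, ...).
    """

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        clean = {int(k): int(v) for k, v in self.counts.items() if v != 0}
        if any(k < 0 for k in clean):
            raise ValueError("crossover class k must be >= 0")
        if any(v < 0 for v in clean.values()):
            raise ValueError("class counts must be >= 0")
        if not clean:
            raise ValueError("at least one nonzero class count required")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_sequence(cls, seq: Sequence[int]) -> "CrossoverClassCounts":
        """Build from a dense vector ``(n_0, n_1, ..., n_K)``."""
        return cls({k: int(v) for k, v in enumerate(seq)})

    @classmethod
    def from_crossover_counts(cls, ks: Iterable[int]) -> "CrossoverClassCounts":
        return cls(Counter(int(k) for k in ks))

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def max_class(self) -> int:
        return max(self.counts)

    def as_vector(self, length: int | None = None) -> "list[int]":
        """Dense vector of counts for k = 0..length-1 (default max class+1)."""
        if length is None:
            length = self.max_class + 1
        if length <= self.max_class:
            raise ValueError("length too short for observed classes")
        return [self.counts.get(k, 0) for k in range(length)]

    def fractions(self, length: int | None = None) -> "list[float]":
        n = self.n
        return [c / n for c in self.as_vector(length)]
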