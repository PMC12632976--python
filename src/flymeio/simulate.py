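"""Seeded generators emulating the statistical structure of each assay.

Every generator is bit-reproducible given its config and seed.  A single
global seed fans out to per-generator substreams through a fixed
derivation rule: stream(seed, label) feeds ``numpy.random.SeedSequence``
with ``(seed, LABEL_ID)``, where the label ids are frozen below; two
generators run from the same global seed therefore never share a stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import SpectralCountTable
from .markers import (
    MISSING,
    PARENTAL,
    RECOMBINANT,
    CrossoverClassCounts,
    MarkerMap,
    ProgenyRecord,
)
from .ndj import NdjTally
from .tetrad import TetradDistribution, chromatid_class_probs

__all__ = [
    "stream",
    "MeiosisSimConfig",
    "simulate_progeny",
    "simulate_class_counts",
    "NdjSimConfig",
    "simulate_ndj",
    "FociSimConfig",
    "FociCell",
    "simulate_foci",
    "SpcSimConfig",
    "simulate_spectral",
]

#: frozen substream ids of the global-seed derivation rule
_STREAM_IDS = {"progeny": 1, "ndj": 2, "foci": 3, "spectral": 4, "acceptance": 5}


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent generator substream for a named pipeline stage."""
    try:
        sid = _STREAM_IDS[label]
    except KeyError:
        raise ValueError(f"unknown stream label {label!r}; "
                         f"known: {sorted(_STREAM_IDS)}") from None
    return np.random.default_rng(np.random.SeedSequence([int(seed), sid]))


# ---------------------------------------------------------------- meiosis


@dataclass(frozen=True)
class MeiosisSimConfig:
    """Backcross progeny simulation under the Weinstein tetrad model.

    ``interval_weights`` are the genetic fractions of the marker map's
    intervals (sum to 1); an exchange lands in interval *i* with
    probability ``interval_weights[i]``, independently across exchanges
    (no interference).
    """

    E: TetradDistribution
    marker_map: MarkerMap
    interval_weights: tuple[float, ...]
    n_progeny: int
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.interval_weights, dtype=float)
        if w.size != self.marker_map.n_intervals:
            raise ValueError("one weight per interval required")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("interval weights must be a probability vector")
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if not self.E.valid:
            raise ValueError("E must be a valid distribution")
        object.__setattr__(self, "interval_weights", tuple(w))


def _simulate_switch_matrix(
    config: MeiosisSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_progeny x n_intervals) phase-switch matrix.

    A tetrad of rank n passes each of its n exchanges to the recovered
    chromatid independently with probability 1/2; transmitted exchanges
    fall into intervals with the configured weights; an even number of
    exchanges in one interval cancels in the phenotype (undetectable by
    flanking-marker scoring).
    """
    n = config.n_progeny
    w = np.asarray(config.interval_weights)
    ranks = rng.choice(config.E.E.size, size=n, p=config.E.E)
    transmitted = rng.binomial(ranks, 0.5)
    hits = np.zeros((n, w.size), dtype=np.int64)
    for t in np.unique(transmitted):
        if t == 0:
            continue
        idx = np.nonzero(transmitted == t)[0]
        hits[idx] = rng.multinomial(int(t), w, size=idx.size)
    return (hits % 2).astype(bool)


def simulate_progeny(config: MeiosisSimConfig) -> list[ProgenyRecord]:
    """Simulate scored female backcross progeny (deterministic per seed)."""
    rng = stream(config.seed, "progeny")
    switches = _simulate_switch_matrix(config, rng)
    start_parental = rng.random(config.n_progeny) < 0.5
    loci = config.marker_map.loci
    records = []
    # phase at locus j = start XOR (odd number of switches before j)
    phases = np.cumsum(switches, axis=1) % 2  # after each interval
    for i in range(config.n_progeny):
        phase = np.concatenate([[0], phases[i]]) ^ (0 if start_parental[i] else 1)
        calls = {
            locus: (PARENTAL if p == 0 else RECOMBINANT)
            for locus, p in zip(loci, phase)
        }
        records.append(
            ProgenyRecord(progeny_id=f"sim{i:06d}", sex="female", calls=calls)
        )
    return records


def simulate_class_counts(
    E: TetradDistribution, n: int, seed: int = 0
) -> CrossoverClassCounts:
    """Chromatid class counts drawn directly from the forward model.

    Multinomial sampling from f = chromatid_class_probs(E); bypasses the
    marker map (no interval-cancellation effect).
    """
    rng = stream(seed, "progeny")
    f = chromatid_class_probs(E)
    draw = rng.multinomial(n, f)
    return CrossoverClassCounts({k: int(c) for k, c in enumerate(draw) if c})


# -------------------------------------------------------------------- NDJ


@dataclass(frozen=True)
class NdjSimConfig:
    """Nondisjunction assay simulation under the viability model.

    Each scored meiosis is nondisjunctional with probability ``p_ndj``;
    an exceptional meiosis yields a recovered progeny with probability
    1/2 (diplo-X or nullo-X with equal probability), the reciprocal
    product dying.  ``mean_brood`` is the Poisson mean number of scored
    meioses per parent female, so the expected adjusted total equals the
    expected number of meioses.
    """

    p_ndj: float
    n_females: int
    mean_brood: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_ndj <= 1.0:
            raise ValueError("p_ndj must be in [0, 1]")
        if self.n_females < 1 or self.mean_brood < 0:
            raise ValueError("need n_females >= 1 and mean_brood >= 0")


def simulate_ndj(config: NdjSimConfig) -> NdjTally:
    rng = stream(config.seed, "ndj")
    n_meioses = int(rng.poisson(config.mean_brood, size=config.n_females).sum())
    exceptional = rng.binomial(n_meioses, config.p_ndj)
    recovered = rng.binomial(exceptional, 0.5)
    diplo = rng.binomial(recovered, 0.5)
    regular = n_meioses - exceptional
    reg_f = rng.binomial(regular, 0.5)
    return NdjTally(
        regular_females=int(reg_f),
        regular_males=int(regular - reg_f),
        diplo_X=int(diplo),
        nullo_X=int(recovered - diplo),
        n_parent_females=config.n_females,
    )


# ------------------------------------------------------------------- foci


@dataclass(frozen=True)
class FociCell:
    """Moment targets for one genotype x region cell."""

    genotype: str
    region: str
    mean: float
    sd: float
    n_nuclei: int
    measure: str = "gH2Av"

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0 or self.n_nuclei < 1:
            raise ValueError("mean, sd >= 0 and n_nuclei >= 1 required")


@dataclass(frozen=True)
class FociSimConfig:
    """Overdispersed per-nucleus count simulation.

    Counts are negative-binomial, moment-matched to (mean, sd) per cell;
    when the variance does not exceed the mean the generator falls back
    to Poisson (with a warning when a negative-binomial was implied but
    infeasible).  dispersion_family: "negative-binomial" or "poisson".
    """

    cells: tuple[FociCell, ...]
    dispersion_family: str = "negative-binomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion_family not in ("negative-binomial", "poisson"):
            raise ValueError("unknown dispersion family")
        object.__setattr__(self, "cells", tuple(self.cells))


def _draw_counts(
    rng: np.random.Generator, mean: float, sd: float, n: int, family: str
) -> np.ndarray:
    if mean == 0:
        return np.zeros(n, dtype=np.int64)
    var = sd * sd
    if family == "poisson" or var <= mean:
        if family != "poisson" and var < mean:
            warnings.warn(
                f"SD^2={var:.3g} < mean={mean:.3g}: negative binomial "
                "infeasible, falling back to Poisson", UserWarning,
            )
        return rng.poisson(mean, size=n)
    # NB moment match: var = mean + mean^2 / r
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def simulate_foci(config: FociSimConfig) -> pd.DataFrame:
    """Simulate a per-nucleus foci dataset (FociDataset layout)."""
    rng = stream(config.seed, "foci")
    rows = []
    for cell in config.cells:
        counts = _draw_counts(
            rng, cell.mean, cell.sd, cell.n_nuclei, config.dispersion_family
        )
        for j, c in enumerate(counts):
            rows.append(
                {
                    "genotype": cell.genotype,
                    "region": cell.region,
                    "nucleus_id": f"{cell.genotype}_{cell.region}_{j:04d}",
                    "count": int(c),
                    "measure": cell.measure,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- spectral


@dataclass(frozen=True)
class SpcSimConfig:
    """Spectral-count table simulation with bait-specific spiked proteins.

    Background proteins draw Poisson counts with rate proportional to
    protein length and a per-protein abundance; ``n_spiked`` proteins get
    their rate multiplied by ``fold_change`` in experiment samples only.
    Shared-peptide groups of two proteins are injected at rate
    ``shared_group_rate`` with shared counts at ``shared_count_frac`` of
    the members' expected unique counts.
    """

    n_background: int = 500
    n_spiked: int = 20
    fold_change: float = 8.0
    baseline_rate: float = 50.0
    mean_length: float = 450.0
    length_sigma: float = 0.35
    replicates: int = 2
    shared_group_rate: float = 0.05
    shared_count_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_background < 0 or self.n_spiked < 0:
            raise ValueError("protein counts must be >= 0")


def simulate_spectral(config: SpcSimConfig) -> tuple[SpectralCountTable, list[str]]:
    """Simulate a spectral-count table.

    Returns the table and the list of spiked protein ids.  Samples are
    named ``exp1..expR`` and ``ctrl1..ctrlR``.
    """
    rng = stream(config.seed, "spectral")
    n = config.n_background + config.n_spiked
    ids = [f"SPIKE{i:03d}" for i in range(config.n_spiked)] + [
        f"BG{i:04d}" for i in range(config.n_background)
    ]
    lengths = np.maximum(
        50,
        rng.lognormal(np.log(config.mean_length), config.length_sigma, size=n),
    ).astype(int)
    abundance = rng.gamma(2.0, 0.5, size=n)  # mean 1 per-protein abundance
    rel_len = lengths / lengths.mean()
    base = config.baseline_rate * abundance * rel_len
    fold = np.ones(n)
    fold[: config.n_spiked] = config.fold_change

    samples = [f"exp{r + 1}" for r in range(config.replicates)] + [
        f"ctrl{r + 1}" for r in range(config.replicates)
    ]
    unique = {}
    for s in samples:
        rate = base * (fold if s.startswith("exp") else 1.0)
        unique[s] = rng.poisson(rate)
    unique_df = pd.DataFrame(unique, index=ids)

    groups: dict[str, tuple[str, ...]] = {}
    shared_rows = {}
    n_groups = rng.binomial(n // 2, config.shared_group_rate)
    if n_groups > 0:
        members = rng.choice(n, size=(n_groups, 2), replace=False)
        for g in range(n_groups):
            i, j = members[g]
            gid = f"grp{g:03d}"
            groups[gid] = (ids[i], ids[j])
            row = {}
            for s in samples:
                mult = fold[[i, j]] if s.startswith("exp") else np.ones(2)
                lam = config.shared_count_frac * float((base[[i, j]] * mult).sum())
                row[s] = int(rng.poisson(lam))
            shared_rows[gid] = row
    shared_df = (
        pd.DataFrame.from_dict(shared_rows, orient="index")[samples]
        if shared_rows
        else None
    )
    table = SpectralCountTable(
        lengths=pd.Series(lengths, index=ids, name="length"),
        unique=unique_df,
        shared_groups=groups,
        shared_counts=shared_df,
    )
    return table, ids[: config.n_spiked]
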