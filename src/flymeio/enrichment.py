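"""Spectral-count proximity-enrichment pipeline (distributed NSAF).

Label-free quantitation by distributed normalized spectral abundance
factor (dNSAF): spectral counts shared between proteins of a shared-
peptide group are apportioned to members in proportion to their unique
counts, the distributed count is length-normalised, and normalised to
sum to one within each sample,

    d_i = u_i + sum_g s_g * u_i / sum_{j in g} u_j
    dNSAF_i = (d_i / L_i) / sum_j (d_j / L_j).

Bait-proximal proteins are called against enzyme-only controls with the
dual threshold log2 fold-change > 2 and Z > 5.  The Z statistic here is a
declared moderated two-sample statistic on log2 dNSAF (pseudocount =
half the smallest nonzero dNSAF; pooled per-protein variance floored at
the 10th percentile across proteins); it is *not* a re-implementation of
the QPROT Bayesian model and is documented as non-equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SpectralCountTable",
    "compute_dnsaf",
    "EnrichmentCaller",
    "enrichment_call",
    "overlap_sets",
    "OverlapResult",
]


@dataclass(frozen=True)
class SpectralCountTable:
    """Protein x sample spectral counts with unique/shared split.

    Parameters
    ----------
    lengths : Series
        Protein length in residues, indexed by protein id (all >= 1).
    unique : DataFrame
        Unique spectral counts, index = protein ids, columns = samples.
    shared_groups : mapping group id -> list of member protein ids
        Each group has >= 2 members.
    shared_counts : DataFrame or None
        Shared spectral counts, index = group ids, columns = samples.
    """

    lengths: pd.Series
    unique: pd.DataFrame
    shared_groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    shared_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.lengths < 1).any():
            raise ValueError("protein lengths must be >= 1")
        if not self.unique.index.equals(self.lengths.index):
            raise ValueError("unique counts and lengths must share the "
                             "same protein index")
        if (self.unique.to_numpy() < 0).any():
            raise ValueError("spectral counts must be >= 0")
        groups = {g: tuple(m) for g, m in self.shared_groups.items()}
        object.__setattr__(self, "shared_groups", groups)
        for g, members in groups.items():
            if len(members) < 2:
                raise ValueError(f"shared group {g!r} has < 2 members")
            unknown = set(members) - set(self.lengths.index)
            if unknown:
                raise ValueError(f"shared group {g!r} references unknown "
                                 f"proteins {sorted(unknown)}")
        if groups and self.shared_counts is None:
            raise ValueError("shared groups given without shared counts")
        if self.shared_counts is not None:
            if set(self.shared_counts.index) != set(groups):
                raise ValueError("shared_counts index must match group ids")
            if (self.shared_counts.to_numpy() < 0).any():
                raise ValueError("spectral counts must be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.unique.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.lengths.index)


def compute_dnsaf(table: SpectralCountTable) -> pd.DataFrame:
    """Per-sample dNSAF (proteins x samples); each column sums to 1.

    A group's shared counts are dropped in a sample where every member
    has zero unique counts (no basis for apportionment).
    """
    dist = table.unique.astype(float).copy()
    if table.shared_counts is not None:
        for g, members in table.shared_groups.items():
            u = table.unique.loc[list(members)].astype(float)
            tot = u.sum(axis=0)
            s = table.shared_counts.loc[g].astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                share = u.div(tot, axis=1).fillna(0.0)
            dist.loc[list(members)] += share.mul(s.where(tot > 0, 0.0), axis=1)
    saf = dist.div(table.lengths, axis=0)
    col_tot = saf.sum(axis=0)
    dead = col_tot[col_tot <= 0].index.tolist()
    if dead:
        raise ValueError(f"all-zero sample(s): {dead}")
    return saf.div(col_tot, axis=1)


@dataclass(frozen=True)
class OverlapResult:
    common: frozenset[str]
    a_only: frozenset[str]
    b_only: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
        }


def overlap_sets(enriched_a: Sequence[str], enriched_b: Sequence[str]) -> OverlapResult:
    """Set algebra on enriched protein ids from two baits."""
    a, b = set(enriched_a), set(enriched_b)
    return OverlapResult(
        common=frozenset(a & b),
        a_only=frozenset(a - b),
        b_only=frozenset(b - a),
    )


class EnrichmentCaller(BaseEstimator):
    """Threshold-based enrichment caller on replicate dNSAF profiles.

    Per protein, with pseudocount eps = half the smallest nonzero dNSAF
    across all supplied samples:

    * ``log2FC = log2(mean_exp + eps) - log2(mean_ctrl + eps)``
    * ``Z`` = difference of mean log2(dNSAF + eps) between conditions
      divided by a pooled standard error whose per-protein pooled
      variance is floored at the ``var_floor_quantile`` quantile of
      positive pooled variances across proteins.

    A protein is enriched iff *both* ``log2FC > log2fc_threshold`` and
    ``Z > z_threshold`` (strict inequalities).

    Attributes (after :meth:`fit`)
    ------------------------------
    records_ : DataFrame
        protein_id, mean_exp, mean_ctrl, log2fc, z, enriched.
    enriched_ : list of str
        Ids of enriched proteins.
    pseudocount_ : float
    variance_floor_ : float
    """

    def __init__(
        self,
        log2fc_threshold: float = 2.0,
        z_threshold: float = 5.0,
        var_floor_quantile: float = 0.10,
    ) -> None:
        self.log2fc_threshold = log2fc_threshold
        self.z_threshold = z_threshold
        self.var_floor_quantile = var_floor_quantile

    def fit(self, experiment: pd.DataFrame, control: pd.DataFrame) -> "EnrichmentCaller":
        """Call enrichment of experiment vs control dNSAF replicates.

        Both arguments are proteins x replicate-samples DataFrames on the
        same protein index (e.g. column subsets of :func:`compute_dnsaf`
        output).
        """
        if not experiment.index.equals(control.index):
            diff = set(experiment.index) ^ set(control.index)
            raise ValueError(
                f"mismatched protein universes; symmetric difference: "
                f"{sorted(diff)[:10]}{'...' if len(diff) > 10 else ''}"
            )
        n_exp, n_ctrl = experiment.shape[1], control.shape[1]
        if min(n_exp, n_ctrl) < 1:
            raise ValueError("each condition needs at least one replicate")
        if min(n_exp, n_ctrl) < 2:
            warnings.warn(
                "single replicate in a condition; Z relies entirely on the "
                "pooled variance floor", UserWarning,
            )
        X = experiment.to_numpy(dtype=float)
        C = control.to_numpy(dtype=float)
        allv = np.concatenate([X.ravel(), C.ravel()])
        nz = allv[allv > 0]
        if nz.size == 0:
            raise ValueError("all dNSAF values are zero")
        eps = nz.min() / 2.0
        self.pseudocount_ = float(eps)

        mean_exp = X.mean(axis=1)
        mean_ctrl = C.mean(axis=1)
        log2fc = np.log2(mean_exp + eps) - np.log2(mean_ctrl + eps)

        lx = np.log2(X + eps)
        lc = np.log2(C + eps)
        diff = lx.mean(axis=1) - lc.mean(axis=1)
        df = n_exp + n_ctrl - 2
        if df > 0:
            ss = lx.var(axis=1, ddof=0).clip(min=0) * n_exp + \
                 lc.var(axis=1, ddof=0).clip(min=0) * n_ctrl
            pooled = ss / df
        else:
            pooled = np.zeros(X.shape[0])
        positive = pooled[pooled > 0]
        if positive.size:
            floor = float(np.quantile(positive, self.var_floor_quantile))
        else:
            # degenerate input (no replicate scatter anywhere): fall back
            # to the scatter of log2 values across proteins
            floor = float(np.var(np.concatenate([lx, lc], axis=1)))
        self.variance_floor_ = floor
        var = np.maximum(pooled, floor)
        se = np.sqrt(var * (1.0 / n_exp + 1.0 / n_ctrl))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, diff / se, 0.0)

        enriched = (log2fc > self.log2fc_threshold) & (z > self.z_threshold)
        self.records_ = pd.DataFrame(
            {
                "protein_id": experiment.index,
                "mean_exp": mean_exp,
                "mean_ctrl": mean_ctrl,
                "log2fc": log2fc,
                "z": z,
                "enriched": enriched,
            }
        ).set_index("protein_id", drop=False)
        self.enriched_ = list(self.records_.index[enriched])
        return self


def enrichment_call(
    experiment: pd.DataFrame,
    control: pd.DataFrame,
    *,
    log2fc_threshold: float = 2.0,
    z_threshold: float = 5.0,
) -> pd.DataFrame:
    """Functional wrapper over :class:`EnrichmentCaller`; returns records."""
    caller = EnrichmentCaller(
        log2fc_threshold=log2fc_threshold, z_threshold=z_threshold
    ).fit(experiment, control)
    return caller.records_
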