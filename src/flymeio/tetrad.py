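"""Weinstein tetrad analysis: exchange-rank estimation from chromatid classes.

In female *Drosophila* only one of the four chromatids of each meiotic
tetrad is recovered in a progeny.  Under the classical no-chromatid-
interference assumption, each of the *n* exchanges of a rank-*n* tetrad
involves the recovered chromatid independently with probability 1/2, so a
rank-*n* tetrad yields a recovered chromatid with *k* observed crossovers
with probability ``C(n, k) / 2**n``.  Writing ``E_n`` for the frequency of
rank-*n* tetrads (the Weinstein E values) the chromatid class
probabilities are

    f_k = sum_{n >= k} E_n * C(n, k) / 2**n .

This module provides the forward model, the classical direct inversion
(back-substitution, which can leave the probability simplex), and a
constrained maximum-likelihood estimator via EM with the latent tetrad
rank, plus a nonparametric bootstrap for interval estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import comb
from sklearn.base import BaseEstimator

from .markers import CrossoverClassCounts

__all__ = [
    "TetradDistribution",
    "TetradFitResult",
    "transmission_matrix",
    "chromatid_class_probs",
    "weinstein_invert",
    "TetradMLE",
    "tetrad_mle",
    "map_length_from_classes",
    "bootstrap_tetrad_ci",
    "BootstrapCI",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class TetradDistribution:
    """Exchange-rank frequencies E_0..E_max.

    ``valid`` is False when the vector leaves the probability simplex
    (possible for direct-inversion output); entries always sum to 1.
    """

    E: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", E)
        if E.ndim != 1 or E.size == 0:
            raise ValueError("E must be a nonempty 1-d vector")
        if abs(E.sum() - 1.0) > 1e-6:
            raise ValueError(f"E must sum to 1, got {E.sum()!r}")
        object.__setattr__(self, "valid", bool(self.valid and (E >= -_SIMPLEX_TOL).all()))

    @property
    def max_rank(self) -> int:
        return self.E.size - 1

    def rounded(self, ndigits: int = 4) -> list[float]:
        """Display values at table precision (default four decimals)."""
        return [round(float(e), ndigits) for e in self.E]


def transmission_matrix(max_rank: int) -> np.ndarray:
    """Matrix A with A[k, n] = C(n, k) / 2**n, for k, n = 0..max_rank.

    Columns are the chromatid-class distributions produced by each tetrad
    rank; ``f = A @ E``.  Upper triangular in the (k <= n) sense; each
    column sums to 1.
    """
    if max_rank < 0:
        raise ValueError("max_rank must be >= 0")
    n = np.arange(max_rank + 1)
    k = n[:, None]
    return comb(n[None, :], k) / 2.0 ** n[None, :]


def chromatid_class_probs(E: TetradDistribution | np.ndarray) -> np.ndarray:
    """Forward model: chromatid class probabilities f_0..f_max from E."""
    vec = E.E if isinstance(E, TetradDistribution) else np.asarray(E, dtype=float)
    if (vec < -_SIMPLEX_TOL).any():
        raise ValueError("forward model requires a valid (non-negative) E")
    if abs(vec.sum() - 1.0) > 1e-6:
        raise ValueError("E must sum to 1")
    return transmission_matrix(vec.size - 1) @ vec


def weinstein_invert(f: np.ndarray) -> TetradDistribution:
    """Classical Weinstein inversion of observed class fractions.

    Back-substitutes the upper-triangular system highest rank first:
    ``E_max = 2**max * f_max`` and
    ``E_n = 2**n * (f_n - sum_{m>n} E_m C(m,n)/2**m)``; the result may
    contain negative entries, in which case ``valid`` is False.
    """
    f = np.asarray(f, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("class fractions must sum to 1")
    K = f.size - 1
    A = transmission_matrix(K)
    E = np.zeros(K + 1)
    for n in range(K, -1, -1):
        tail = sum(E[m] * A[n, m] for m in range(n + 1, K + 1))
        E[n] = (f[n] - tail) * 2.0 ** n
    # re-express E_0 as the simplex complement (identical analytically;
    # keeps the sum exactly 1 in floating point)
    E[0] = 1.0 - E[1:].sum()
    return TetradDistribution(E=E, valid=bool((E >= -_SIMPLEX_TOL).all()))


@dataclass(frozen=True)
class TetradFitResult:
    """Constrained-ML fit of the exchange-rank distribution."""

    E_hat: TetradDistribution
    log_likelihood: float
    iterations: int
    converged: bool
    #: True when any E_n is pinned at the simplex boundary (zero)
    boundary: bool
    class_probs: np.ndarray
    #: per-iteration log-likelihood trace (monotone non-decreasing)
    loglik_path: np.ndarray


def _as_count_vector(
    counts: CrossoverClassCounts | np.ndarray, max_rank: int | None
) -> np.ndarray:
    if isinstance(counts, CrossoverClassCounts):
        top = counts.max_class
        if max_rank is None:
            max_rank = top
        vec = counts.as_vector(max_rank + 1)
    else:
        vec = np.asarray(counts, dtype=float)
        top = int(np.max(np.nonzero(vec)[0])) if vec.any() else 0
        if max_rank is None:
            max_rank = max(vec.size - 1, top)
        elif max_rank + 1 > vec.size:
            vec = np.concatenate([vec, np.zeros(max_rank + 1 - vec.size)])
    vec = np.asarray(vec, dtype=float)
    if (vec < 0).any():
        raise ValueError("class counts must be non-negative")
    if vec.sum() < 1:
        raise ValueError("need at least one observation")
    if max_rank < top:
        raise ValueError(
            f"max_rank={max_rank} below highest observed class {top}"
        )
    return vec[: max_rank + 1]


def _em_batch(
    counts: np.ndarray,
    *,
    tol_loglik: float,
    tol_param: float,
    max_iter: int,
    track_path: bool,
) -> tuple[np.ndarray, np.ndarray, int, bool, list[float]]:
    """Vectorised EM over a batch of count vectors (rows).

    Latent variable: tetrad rank n of each chromatid's tetrad.
    E-step responsibilities P(n | k) are proportional to E_n C(n,k)/2^n;
    M-step E_n = (1/N) sum_k c_k P(n | k).  Runs all rows to joint
    convergence (per-row changes below tolerance).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    B, K1 = counts.shape
    A = transmission_matrix(K1 - 1)  # (k, n)
    N = counts.sum(axis=1, keepdims=True)
    E = np.full((B, K1), 1.0 / K1)
    path: list[float] = []

    def loglik(E):
        f = E @ A.T
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(counts > 0, counts * np.log(f), 0.0)
        return terms.sum(axis=1)

    ll = loglik(E)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f = E @ A.T  # (B, k)
        # responsibilities: r[b, k, n] = E[b,n] A[k,n] / f[b,k]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = counts / f  # (B, k); 0/0 only where counts==0
        w = np.where(counts > 0, w, 0.0)
        E_new = (w @ A) * E / N  # (B, n)
        ll_new = loglik(E_new)
        dpar = np.abs(E_new - E).max(axis=1)
        dll = ll_new - ll
        E, ll = E_new, ll_new
        if track_path:
            path.append(float(ll[0]))
        if (dll < tol_loglik).all() and (dpar < tol_param).all():
            converged = True
            break
    return E, ll, it, converged, path


class TetradMLE(BaseEstimator):
    """Constrained maximum-likelihood Weinstein tetrad estimator.

    Maximises the multinomial log-likelihood
    ``sum_k counts[k] * log f_k(E)`` over the probability simplex via EM
    with the latent tetrad rank, starting from the uniform distribution
    over ranks 0..max_rank.  When the direct Weinstein inversion is
    non-negative the MLE coincides with it (interior optimum); otherwise
    the MLE lies on the simplex boundary.

    Parameters
    ----------
    max_rank : int or None
        Highest exchange rank fitted.  None (default) uses the highest
        observed crossover class.
    tol_loglik : float
        Convergence when the log-likelihood improves by less than this.
    tol_param : float
        ... and parameters move by less than this (max-norm).
    max_iter : int
        Iteration cap; non-convergence is flagged, never silent.

    Attributes
    ----------
    E_ : ndarray
        Fitted exchange-rank frequencies (non-negative, sums to 1).
    log_likelihood_ : float
    n_iter_ : int
    converged_ : bool
    boundary_ : bool
        Any fitted E_n at (numerically) zero.
    class_probs_ : ndarray
        Fitted chromatid class probabilities f_k.
    loglik_path_ : ndarray
        Per-iteration log-likelihood trace.
    """

    def __init__(
        self,
        max_rank: int | None = None,
        tol_loglik: float = 1e-12,
        tol_param: float = 1e-10,
        max_iter: int = 100_000,
    ) -> None:
        self.max_rank = max_rank
        self.tol_loglik = tol_loglik
        self.tol_param = tol_param
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "TetradMLE":
        """Fit to chromatid class counts.

        Parameters
        ----------
        X : CrossoverClassCounts or 1-d array of counts (index = class k)
        """
        counts = _as_count_vector(X, self.max_rank)
        E, ll, it, conv, path = _em_batch(
            counts[None, :],
            tol_loglik=self.tol_loglik,
            tol_param=self.tol_param,
            max_iter=self.max_iter,
            track_path=True,
        )
        E = E[0]
        E = np.clip(E, 0.0, None)
        E /= E.sum()
        # EM approaches a boundary optimum only sublinearly; snap nearly
        # zero ranks to the boundary when that does not hurt the likelihood
        E, ll0, conv = self._polish_boundary(counts, E, float(ll[0]), conv)
        ll = np.array([ll0])
        if not conv:
            warnings.warn(
                f"tetrad EM did not converge in {self.max_iter} iterations",
                RuntimeWarning,
            )
        self.E_ = E
        self.log_likelihood_ = float(ll[0])
        self.n_iter_ = it
        self.converged_ = bool(conv)
        self.boundary_ = bool((E <= 1e-8).any())
        if self.boundary_:
            warnings.warn(
                "tetrad MLE lies on the simplex boundary (some E_n = 0); "
                "boundary mixtures may be non-identifiable",
                RuntimeWarning,
            )
        self.class_probs_ = chromatid_class_probs(E)
        self.loglik_path_ = np.asarray(path)
        return self

    def _polish_boundary(
        self, counts: np.ndarray, E: np.ndarray, ll: float, conv: bool
    ) -> tuple[np.ndarray, float, bool]:
        def loglik(vec: np.ndarray) -> float:
            f = transmission_matrix(vec.size - 1) @ vec
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(counts > 0, counts * np.log(f), 0.0)
            return float(terms.sum())

        small = E < 1e-4
        if small.any() and not (E[small] == 0).all():
            cand = np.where(small, 0.0, E)
            cand /= cand.sum()
            ll_cand = loglik(cand)
            if ll_cand >= ll - 1e-12:
                E, ll = cand, ll_cand
                # an EM fixed point at the snapped vector certifies a
                # boundary optimum even when the EM path itself hit the cap
                A = transmission_matrix(E.size - 1)
                f = A @ E
                with np.errstate(divide="ignore", invalid="ignore"):
                    w = np.where(counts > 0, counts / f, 0.0)
                one_step = (w @ A) * E / counts.sum()
                if np.abs(one_step - E).max() < max(self.tol_param, 1e-9):
                    conv = True
        return E, ll, conv

    def result_(self) -> TetradFitResult:
        """Package fitted attributes as an immutable result object."""
        return TetradFitResult(
            E_hat=TetradDistribution(E=self.E_, valid=True),
            log_likelihood=self.log_likelihood_,
            iterations=self.n_iter_,
            converged=self.converged_,
            boundary=self.boundary_,
            class_probs=self.class_probs_,
            loglik_path=self.loglik_path_,
        )


def tetrad_mle(
    counts: CrossoverClassCounts | np.ndarray,
    max_rank: int | None = None,
    **kwargs,
) -> TetradFitResult:
    """Functional wrapper over :class:`TetradMLE`."""
    est = TetradMLE(max_rank=max_rank, **kwargs).fit(counts)
    return est.result_()


def map_length_from_classes(counts: CrossoverClassCounts | np.ndarray) -> float:
    """Total map length in cM: 100 x mean crossovers per chromatid."""
    if isinstance(counts, CrossoverClassCounts):
        vec = np.asarray(counts.as_vector(), dtype=float)
    else:
        vec = np.asarray(counts, dtype=float)
    n = vec.sum()
    if n < 1:
        raise ValueError("need at least one observation")
    return float(100.0 * (np.arange(vec.size) @ vec) / n)


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap intervals for each exchange rank."""

    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    reps: int
    #: True when the data are single-class (intervals collapse to a point)
    degenerate: bool


def bootstrap_tetrad_ci(
    counts: CrossoverClassCounts | np.ndarray,
    reps: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
    max_rank: int | None = None,
) -> BootstrapCI:
    """Nonparametric bootstrap CI for the tetrad MLE.

    Resamples N chromatids from the observed class fractions (multinomial),
    refits the MLE on each replicate, and returns percentile intervals.
    Deterministic under a fixed seed.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for percentile intervals")
    vec = _as_count_vector(counts, max_rank)
    n = int(vec.sum())
    point = tetrad_mle(vec).E_hat.E
    degenerate = np.count_nonzero(vec) == 1
    rng = np.random.default_rng(seed)
    boot_counts = rng.multinomial(n, vec / vec.sum(), size=reps)
    E_boot, _, _, conv, _ = _em_batch(
        boot_counts.astype(float),
        tol_loglik=1e-12,
        tol_param=1e-10,
        max_iter=100_000,
        track_path=False,
    )
    if not conv:
        warnings.warn("bootstrap EM batch hit the iteration cap", RuntimeWarning)
    E_boot = np.clip(E_boot, 0.0, None)
    E_boot /= E_boot.sum(axis=1, keepdims=True)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(E_boot, alpha, axis=0)
    upper = np.quantile(E_boot, 1.0 - alpha, axis=0)
    if degenerate:
        warnings.warn(
            "single observed class: bootstrap intervals collapse to a point",
            RuntimeWarning,
        )
    return BootstrapCI(
        point=point, lower=lower, upper=upper, level=level, reps=reps,
        degenerate=bool(degenerate),
    )
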