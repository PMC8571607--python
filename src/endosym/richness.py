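"""Nonparametric species-richness estimators and analytic rarefaction.

Point estimators only: Chao1 and ACE from a per-species abundance vector,
Chao2, ICE and first/second-order jackknife from a samples x species
incidence matrix, and the analytic sample-based rarefaction expectation.
Variance estimators are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "AbundanceVector",
    "IncidenceMatrix",
    "chao1",
    "chao2",
    "ace",
    "ice",
    "jackknife",
    "rarefaction",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Per-species individual counts pooled over all samples."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.size == 0 or np.any(c < 0):
            raise ValueError("abundance vector must be non-empty, counts >= 0")
        if c.sum() == 0:
            raise ValueError("abundance vector is all zero")
        object.__setattr__(self, "counts", c)

    @property
    def s_obs(self) -> int:
        return int((self.counts >= 1).sum())

    def f(self, i: int) -> int:
        """Number of species observed exactly i times."""
        return int((self.counts == i).sum())

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary samples x species presence matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.ndim != 2 or m.shape[0] < 1:
            raise ValueError("incidence matrix must be 2-D with >= 1 sample")
        if not set(np.unique(m)) <= {0, 1}:
            raise ValueError("incidence matrix must be binary")
        object.__setattr__(self, "matrix", m)

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def species_incidence(self) -> np.ndarray:
        """Per-species number of samples in which it occurs."""
        return self.matrix.sum(axis=0)

    @property
    def s_obs(self) -> int:
        return int((self.species_incidence >= 1).sum())

    def q(self, i: int) -> int:
        """Number of species found in exactly i samples."""
        return int((self.species_incidence == i).sum())


def _chao(s_obs: int, f1: int, f2: int) -> float:
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def chao1(abundance: AbundanceVector) -> float:
    """Chao's abundance-based lower-bound estimator (classic form)."""
    return _chao(abundance.s_obs, abundance.f(1), abundance.f(2))


def chao2(incidence: IncidenceMatrix) -> float:
    """Incidence analogue of Chao1 using uniques Q1 and duplicates Q2."""
    return _chao(incidence.s_obs, incidence.q(1), incidence.q(2))


def ace(abundance: AbundanceVector, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator.

    Species with <= ``rare_cutoff`` individuals form the rare group used
    to estimate sample coverage; when coverage is zero (all rare species
    are singletons) the estimator is undefined and Chao1 is returned with
    a warning.
    """
    c = abundance.counts[abundance.counts >= 1]
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(abundance.s_obs)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == f1:
        warnings.warn(
            "ACE coverage is zero (all rare species are singletons); "
            "falling back to Chao1",
            stacklevel=2,
        )
        return chao1(abundance)
    c_ace = 1.0 - f1 / n_rare
    fsum = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma2 = max(
        s_rare * fsum / (c_ace * n_rare * (n_rare - 1)) - 1.0, 0.0
    ) if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def ice(incidence: IncidenceMatrix, cutoff: int = 10) -> float:
    """Incidence-based coverage estimator (infrequent-species cutoff 10)."""
    inc = incidence.species_incidence
    inc = inc[inc >= 1]
    infreq = inc[inc <= cutoff]
    s_freq = int((inc > cutoff).sum())
    s_infreq = int(infreq.size)
    if s_infreq == 0:
        return float(incidence.s_obs)
    n_infreq = int(infreq.sum())
    q1 = int((infreq == 1).sum())
    if n_infreq == q1:
        warnings.warn(
            "ICE coverage is zero (all infrequent species are uniques); "
            "falling back to Chao2",
            stacklevel=2,
        )
        return chao2(incidence)
    # number of samples containing at least one infrequent species
    infreq_cols = np.nonzero(
        (incidence.species_incidence >= 1)
        & (incidence.species_incidence <= cutoff)
    )[0]
    m_infreq = int((incidence.matrix[:, infreq_cols].sum(axis=1) > 0).sum())
    c_ice = 1.0 - q1 / n_infreq
    qsum = sum(i * (i - 1) * int((infreq == i).sum()) for i in range(1, cutoff + 1))
    if m_infreq > 1 and n_infreq > 1:
        gamma2 = max(
            s_infreq / c_ice
            * m_infreq / (m_infreq - 1)
            * qsum / (n_infreq * (n_infreq - 1))
            - 1.0,
            0.0,
        )
    else:
        gamma2 = 0.0
    return s_freq + s_infreq / c_ice + (q1 / c_ice) * gamma2


def jackknife(incidence: IncidenceMatrix, order: int = 1) -> float:
    """First- or second-order jackknife richness estimator."""
    m = incidence.m
    s = incidence.s_obs
    q1, q2 = incidence.q(1), incidence.q(2)
    if order == 1:
        if m < 2:
            raise ValueError("first-order jackknife needs >= 2 samples")
        return s + q1 * (m - 1) / m
    if order == 2:
        if m < 3:
            raise ValueError("second-order jackknife needs >= 3 samples")
        return s + q1 * (2 * m - 3) / m - q2 * (m - 2) ** 2 / (m * (m - 1))
    raise ValueError("order must be 1 or 2")


def _log_comb(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction(incidence: IncidenceMatrix, t: int) -> float:
    """Expected species count in a random draw of t of the m samples.

    E[S_t] = S_obs - sum_k C(m - m_k, t) / C(m, t), where m_k is the
    number of samples containing species k.
    """
    m = incidence.m
    if not 1 <= t <= m:
        raise ValueError(f"t must lie in [1, {m}], got {t}")
    mk = incidence.species_incidence
    mk = mk[mk >= 1]
    s_obs = mk.size
    absent = np.zeros(s_obs)
    can = (m - mk) >= t
    if can.any():
        absent[can] = np.exp(
            _log_comb_vec(m - mk[can], t) - float(_log_comb(m, np.array(t)))
        )
    return float(s_obs - absent.sum())


def _log_comb_vec(n: np.ndarray, k: int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
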