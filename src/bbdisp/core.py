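"""Beta-binomial probability machinery in the (p, theta) parametrization.

A position with total depth t = n + m splits as n ~ BetaBinomial(t; alpha,
beta) with alpha = p/theta, beta = (1-p)/theta, so p = alpha/(alpha+beta)
is the expected proportion of sample-1 counts and theta = 1/(alpha+beta)
the overdispersion rate; theta = 0 degenerates to Binomial(t, p).

The per-gene log-likelihood used throughout drops the combinatorial
constant log C(n+m, n) — it cancels in every likelihood ratio, nested
comparison and AIC difference computed on the same data.  Per position it
equals

    sum_{k<n} log(p + k*theta) + sum_{k<m} log(1-p + k*theta)
                                - sum_{k<n+m} log(1 + k*theta)

evaluated through log-Gamma differences (each ascending-factorial sum is
c*log(theta) + lnG(x/theta + c) - lnG(x/theta)), with direct summation as
a fallback when x/theta is too large for the log-Gamma difference to be
accurate, and the binomial limit at theta = 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

#: switch from log-Gamma differences to direct summation above this x/theta;
#: the difference lnG(a+c) - lnG(a) loses ~1e-16*a*ln(a) absolutely, so the
#: cutoff keeps the absolute error of a likelihood term below ~1e-7
GAMMALN_CUTOFF = 1e8

P_EPS = 1e-9


@dataclass(frozen=True)
class BBParams:
    """Proportion / overdispersion pair; alpha = p/theta, beta = (1-p)/theta."""

    p: float
    theta: float

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must be in (0,1), got {self.p}")
        if self.theta < 0.0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")

    @property
    def alpha(self) -> float:
        if self.theta == 0:
            raise ValueError("alpha undefined at theta=0")
        return self.p / self.theta

    @property
    def beta(self) -> float:
        if self.theta == 0:
            raise ValueError("beta undefined at theta=0")
        return (1.0 - self.p) / self.theta


def bb_pmf(n: int, m: int, params: BBParams) -> float:
    """P(n successes out of n+m) under (p, theta); binomial at theta=0."""
    if n < 0 or m < 0 or n + m < 1:
        raise ValueError("need n, m >= 0 and n+m >= 1")
    if params.theta == 0.0:
        return float(stats.binom.pmf(n, n + m, params.p))
    return float(stats.betabinom.pmf(n, n + m, params.alpha, params.beta))


def _asc_sum_direct(x: float, c: int, theta: float) -> float:
    """sum_{k=0}^{c-1} log(x + k*theta) by direct summation."""
    if c == 0:
        return 0.0
    return float(np.log(x + theta * np.arange(c)).sum())


def loglik_positions(n, m, p, theta) -> np.ndarray:
    """Per-position log-likelihood terms (no combinatorial constant).

    ``p`` and ``theta`` broadcast against the count vectors, so a single
    call can span many genes with gene-wise proportions and position-wise
    overdispersion rates.
    """
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    m = np.atleast_1d(np.asarray(m, dtype=np.int64))
    if (n < 0).any() or (m < 0).any():
        raise ValueError("negative counts")
    theta = np.broadcast_to(np.asarray(theta, dtype=float), n.shape)
    p = np.broadcast_to(np.asarray(p, dtype=float), n.shape)
    if (theta < 0).any():
        raise ValueError("negative theta")

    out = np.zeros(n.shape, dtype=float)

    # degenerate proportions: all mass on one side
    lo = p <= 0.0
    hi = p >= 1.0
    out[lo & (n > 0)] = -np.inf
    out[hi & (m > 0)] = -np.inf
    ok = ~(lo | hi)

    zero = ok & (theta == 0.0)
    if zero.any():
        out[zero] = n[zero] * np.log(p[zero]) + m[zero] * np.log1p(-p[zero])

    pos = ok & (theta > 0.0)
    if pos.any():
        a = np.where(pos, p / np.where(pos, theta, 1.0), 1.0)
        b = np.where(pos, (1.0 - p) / np.where(pos, theta, 1.0), 1.0)
        big = pos & ((a > GAMMALN_CUTOFF) | (b > GAMMALN_CUTOFF))
        g = pos & ~big
        if g.any():
            ab = a[g] + b[g]
            out[g] = (gammaln(a[g] + n[g]) - gammaln(a[g])
                      + gammaln(b[g] + m[g]) - gammaln(b[g])
                      - gammaln(ab + n[g] + m[g]) + gammaln(ab))
        for i in np.flatnonzero(big):
            out[i] = (_asc_sum_direct(p[i], n[i], theta[i])
                      + _asc_sum_direct(1.0 - p[i], m[i], theta[i])
                      - _asc_sum_direct(1.0, n[i] + m[i], theta[i]))
    return out


def gene_loglik(n, m, p, theta) -> float:
    """Gene log-likelihood: sum of per-position terms."""
    return float(loglik_positions(n, m, p, theta).sum())


def gene_loglik_direct(n, m, p, theta) -> float:
    """Term-by-term summation of the same quantity (reference path)."""
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    m = np.atleast_1d(np.asarray(m, dtype=np.int64))
    theta = np.broadcast_to(np.asarray(theta, dtype=float), n.shape)
    tot = 0.0
    for nj, mj, tj in zip(n, m, theta):
        if tj == 0.0:
            if (nj > 0 and p <= 0) or (mj > 0 and p >= 1):
                return float("-inf")
            tot += nj * np.log(p) if nj else 0.0
            tot += mj * np.log1p(-p) if mj else 0.0
            continue
        tot += _asc_sum_direct(p, nj, tj)
        tot += _asc_sum_direct(1.0 - p, mj, tj)
        tot -= _asc_sum_direct(1.0, nj + mj, tj)
    return float(tot)


def update_p(n, m, theta, eps: float = P_EPS, xatol: float = 1e-10) -> float:
    """MLE of the gene proportion with the theta vector held fixed.

    Returns NaN for an all-zero gene (flagged untestable upstream).  With
    theta identically zero the binomial MLE sum(n)/sum(n+m) is returned in
    closed form (clipped into (eps, 1-eps)).
    """
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    m = np.atleast_1d(np.asarray(m, dtype=np.int64))
    tot = n.sum() + m.sum()
    if tot == 0:
        return float("nan")
    theta_arr = np.broadcast_to(np.asarray(theta, dtype=float), n.shape)
    if (theta_arr == 0.0).all():
        return float(np.clip(n.sum() / tot, eps, 1.0 - eps))
    res = optimize.minimize_scalar(
        lambda p: -gene_loglik(n, m, p, theta_arr),
        bounds=(eps, 1.0 - eps), method="bounded",
        options={"xatol": xatol})
    return float(res.x)


@dataclass
class DFitResult:
    D: float
    logD: float
    loglik: float
    flat: bool
    n_positions: int


def fit_pair_D(paired: Sequence,
               model,
               p: Mapping[str, float],
               log_bounds: tuple[float, float] = (-30.0, 8.0),
               xatol: float = 1e-6) -> DFitResult:
    """Pair-specific overdispersion scale D by 1-D likelihood maximization.

    The trained model supplies the per-position linear predictor without
    intercept (gamma*log depth + sequence effect); candidate overdispersion
    is theta_j = exp(logD + predictor_j).  The search runs in log D with a
    bounded scalar optimizer (tolerance ``xatol`` in log D).  A flat
    likelihood (no information about D, e.g. every position at depth 1) is
    detected and flagged.
    """
    ns, ms, ps, bs = [], [], [], []
    for pc in paired:
        mdl = model if hasattr(model, "base_log_theta") else model[pc.strand]
        pg = p.get(pc.gene_id, float("nan"))
        if not np.isfinite(pg):
            continue
        keep = pc.depth > 0
        if not keep.any():
            continue
        ns.append(pc.n[keep])
        ms.append(pc.m[keep])
        ps.append(np.full(int(keep.sum()), pg))
        bs.append(mdl.base_log_theta(pc.depth[keep], pc.context[keep]))
    if not ns:
        raise EstimationFailure("no usable positions for D fit")
    N = np.concatenate(ns)
    M = np.concatenate(ms)
    P = np.concatenate(ps)
    B = np.concatenate(bs)

    def neg(logD: float) -> float:
        theta = np.exp(np.clip(logD + B, -700.0, 30.0))
        return -float(loglik_positions(N, M, P, theta).sum())

    lo, hi = log_bounds
    probe = np.array([neg(lo), neg(0.5 * (lo + hi)), neg(hi)])
    if not np.isfinite(probe).any():
        raise EstimationFailure("non-finite likelihood across the D search range")
    flat = float(probe.max() - probe.min()) < 1e-7 * max(1.0, float(np.abs(probe).max()))
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": xatol})
    return DFitResult(D=float(np.exp(res.x)), logD=float(res.x),
                      loglik=-float(res.fun), flat=flat, n_positions=len(N))


class EstimationFailure(RuntimeError):
    """Likelihood optimization could not proceed."""
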