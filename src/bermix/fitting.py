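"""Annealed EM (deterministic annealing) MAP estimation.

The fitting procedure follows the classic annealing recipe for mixture
models: responsibilities are computed with the complete-data joint raised to
an inverse temperature ``beta`` in (0, 1], and ``beta`` is stepped up a
ladder ending at 1, at which point the updates are exactly those of standard
EM.  Low temperatures flatten the responsibility landscape, which reduces
sensitivity to initialization and the local-maxima problem of plain EM.

At each temperature the algorithm alternates:

* E-step: ``z_nl ∝ exp(beta * log f(y_n, w_n, l))`` row-normalized;
* M-step: ``phi_l = mean_n z_nl``; ``rho_l = sum_n z_nl y_n / sum_n z_nl``;
  ``p_lk = (sum_n z_nl w_nk + gamma) / (sum_n z_nl M_n + K gamma)``.

With ``gamma = 0`` the composition update is the weighted-count maximum
likelihood ratio; ``gamma > 0`` is the MAP posterior-mean-style smoothing
from the symmetric Dirichlet prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp, xlogy

from .exceptions import DegenerateSampleError, InvalidInputError, NumericalError
from .model import (
    CountData,
    ModelParameters,
    Responsibilities,
    log_component_joint,
    log_posterior,
)

logger = logging.getLogger(__name__)

# Geometric ladder spanning three decades.  With deep sequencing (M_n in the
# thousands) per-cluster log-likelihood differences are O(M_n) nats, so
# meaningful smoothing requires inverse temperatures of order 1/M_n; a ladder
# that only starts at O(0.1) barely anneals at all.
DEFAULT_BETAS = (0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0)


@dataclass
class AnnealingSchedule:
    """Inverse-temperature ladder plus inner-loop convergence settings.

    ``betas`` must be strictly increasing and end at exactly 1.0 so the final
    segment is standard EM.  ``inner_tol`` is a relative objective-change
    threshold; ``n_restarts`` independent initializations are run and the
    best final objective wins.
    """

    betas: Sequence[float] = DEFAULT_BETAS
    inner_tol: float = 1e-8
    inner_max_iter: int = 500
    n_restarts: int = 5

    def __post_init__(self):
        b = tuple(float(x) for x in self.betas)
        if len(b) == 0 or b[0] <= 0 or b[-1] != 1.0:
            raise InvalidInputError("betas must lie in (0, 1] and end at exactly 1.0")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise InvalidInputError("betas must be strictly increasing")
        self.betas = b
        if self.inner_tol <= 0 or self.inner_max_iter < 1 or self.n_restarts < 1:
            raise InvalidInputError("invalid inner-loop settings")


@dataclass
class FitResult:
    """Output of :func:`fit`: parameters, responsibilities and diagnostics."""

    params: ModelParameters
    responsibilities: Responsibilities
    objective_trace: list[tuple[float, int, float]] = field(repr=False)
    converged: bool
    n_restarts_used: int
    seed: int


def e_step(data: CountData, params: ModelParameters, beta: float) -> Responsibilities:
    """Tempered posterior responsibilities ``z_nl ∝ f(y_n, w_n, l)^beta``.

    At ``beta = 1`` this is the exact posterior over cluster membership given
    both the counts and the observed label.
    """
    if not 0 < beta <= 1:
        raise InvalidInputError(f"beta must be in (0, 1], got {beta}")
    lj = log_component_joint(data, params)
    return _responsibilities_from_logjoint(lj, beta, data.sample_ids)


def _responsibilities_from_logjoint(
    lj: np.ndarray, beta: float, sample_ids: Sequence[str]
) -> Responsibilities:
    scaled = beta * lj
    row_max = scaled.max(axis=1)
    dead = ~np.isfinite(row_max)
    if dead.any():
        raise DegenerateSampleError(sample_ids[int(np.nonzero(dead)[0][0])])
    log_norm = logsumexp(scaled, axis=1, keepdims=True)
    Z = np.exp(scaled - log_norm)
    # flush denormal-scale weights: they carry no information but can pair a
    # "z > 0" with a cluster whose mixing weight underflowed to exactly 0
    Z[Z < 1e-250] = 0.0
    Z /= Z.sum(axis=1, keepdims=True)
    return Responsibilities(Z)


def m_step(data: CountData, Z: Responsibilities, gamma: float) -> ModelParameters:
    """MAP parameter updates given soft assignments.

    Empty clusters (``sum_n z_nl = 0``) are handled explicitly: the risk
    falls back to the overall disease prevalence, and with ``gamma = 0`` the
    composition row is re-seeded from the pooled composition (with
    ``gamma > 0`` the prior already yields the uniform posterior mean).
    """
    if gamma < 0:
        raise InvalidInputError("gamma must be nonnegative")
    z = Z.Z
    n, L = z.shape
    if n != data.n_samples:
        raise InvalidInputError("responsibilities do not match the data")
    K = data.n_taxa
    cluster_mass = z.sum(axis=0)  # sum_n z_nl
    empty = cluster_mass <= 0.0

    phi = cluster_mass / n

    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (z * data.labels[:, None]).sum(axis=0) / cluster_mass
    rho[empty] = data.labels.mean()  # 0/0: claim no label information

    weighted_counts = z.T @ data.counts  # (L, K)
    read_mass = z.T @ data.totals  # (L,)
    num = weighted_counts + gamma
    den = read_mass + K * gamma
    if gamma == 0 and empty.any():
        logger.warning(
            "m_step: %d empty cluster(s) with gamma=0; re-seeding from pooled "
            "composition",
            int(empty.sum()),
        )
        pooled = data.counts.sum(axis=0) / data.totals.sum()
        num[empty] = pooled
        den[empty] = 1.0
        phi = phi.copy()
        phi[empty] = 1.0 / n
        phi = phi / phi.sum()
    P = num / den[:, None]
    return ModelParameters(phi=phi, rho=np.clip(rho, 0.0, 1.0), P=P, gamma=gamma)


def _annealed_objective(
    data: CountData, params: ModelParameters, Z: Responsibilities, beta: float
) -> float:
    """Free-energy objective that a fixed-beta sweep cannot decrease.

    ``beta * (expected complete-data log posterior) + H(Z)``; at beta = 1
    this is exactly :func:`bermix.model.log_posterior`.
    """
    if beta == 1.0:
        return log_posterior(data, params, Z)
    lp = log_posterior(data, params, Z)
    # log_posterior = fit+prior + H; rescale the fit+prior part only.
    entropy = -float(xlogy(Z.Z, Z.Z).sum())
    return beta * (lp - entropy) + entropy


def _initial_responsibilities(
    data: CountData, L: int, seed: int, restart: int
) -> Responsibilities:
    """Seeded flat-Dirichlet soft assignment, independent of row order.

    Rows are drawn in sample_id-sorted order and scattered back, so the same
    (seed, restart) gives each sample the same initial responsibility vector
    regardless of how the input rows are arranged.
    """
    rng = np.random.default_rng([seed, restart, 0x5EED])
    order = sorted(range(data.n_samples), key=lambda i: data.sample_ids[i])
    draws = rng.dirichlet(np.ones(L), size=data.n_samples)
    Z = np.empty((data.n_samples, L))
    for rank, i in enumerate(order):
        Z[i] = draws[rank]
    return Responsibilities(Z)


def _single_fit(
    data: CountData,
    L: int,
    gamma: float,
    schedule: AnnealingSchedule,
    seed: int,
    restart: int,
):
    Z = _initial_responsibilities(data, L, seed, restart)
    params = m_step(data, Z, gamma)
    trace: list[tuple[float, int, float]] = []
    converged = False
    for beta in schedule.betas:
        prev = -np.inf
        for it in range(schedule.inner_max_iter):
            Z = e_step(data, params, beta)
            params = m_step(data, Z, gamma)
            obj = _annealed_objective(data, params, Z, beta)
            if not np.isfinite(obj):
                raise NumericalError(
                    f"non-finite objective at beta={beta}, iteration {it}",
                    trace=trace,
                )
            trace.append((beta, it, obj))
            if np.isfinite(prev) and abs(obj - prev) <= schedule.inner_tol * (
                abs(prev) + 1.0
            ):
                converged = True
                break
            prev = obj
        else:
            converged = False
    return params, Z, trace, converged


def fit(
    data: CountData,
    L: int,
    gamma: float = 1e-9,
    schedule: AnnealingSchedule | None = None,
    seed: int = 0,
) -> FitResult:
    """MAP-fit an ``L``-cluster model by annealed EM with random restarts.

    Runs ``schedule.n_restarts`` independent annealed-EM optimizations and
    keeps the one with the highest final objective (ties go to the earliest
    restart).  Output clusters are relabeled so the estimated disease risks
    ``rho`` are non-decreasing, which resolves label switching and makes
    cluster 1 the lowest-risk group by convention.
    """
    if schedule is None:
        schedule = AnnealingSchedule()
    if L < 1:
        raise InvalidInputError("L must be >= 1")
    if L > data.n_samples:
        raise InvalidInputError(
            f"L={L} exceeds the number of samples N={data.n_samples}"
        )
    best = None
    for restart in range(schedule.n_restarts):
        params, Z, trace, converged = _single_fit(
            data, L, gamma, schedule, seed, restart
        )
        final = trace[-1][2]
        if best is None or final > best[0]:
            best = (final, params, Z, trace, converged)
    _, params, Z, trace, converged = best
    params, perm = params.sorted_by_risk()
    Z = Responsibilities(Z.Z[:, perm])
    return FitResult(
        params=params,
        responsibilities=Z,
        objective_trace=trace,
        converged=converged,
        n_restarts_used=schedule.n_restarts,
        seed=seed,
    )
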