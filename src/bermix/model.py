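"""Core data containers and log-domain likelihood computations.

The model assumes ``N`` samples, each with a vector of nonnegative taxon
counts ``w_n`` (``K`` taxa, total reads ``M_n``) and a binary disease label
``y_n``.  Samples belong to one of ``L`` unobserved clusters; cluster ``l``
has mixing weight ``phi_l``, disease risk ``rho_l`` and a composition vector
``p_l`` on the ``K``-simplex:

    z_n ~ Multinomial(1, phi)
    y_n | z_n ~ Bernoulli(rho_l)
    w_n | z_n ~ Multinomial(M_n, p_l)
    p_l ~ Dirichlet(alpha, ..., alpha)        (symmetric prior, gamma = alpha - 1)

All likelihood computation is done in natural-log space.  The multinomial
coefficient ``M_n! / prod_k w_nk!`` is omitted throughout: it does not
depend on the cluster or the label, so it cancels in every posterior ratio
the package computes, and objective values are therefore reported "up to an
additive constant".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .exceptions import InvalidInputError

# Bernoulli risks are clipped before taking logs: the M-step can return an
# exact 0 or 1 in a small cluster and an unclipped log would cascade -inf
# through otherwise healthy samples.
RHO_CLIP = 1e-12
SIMPLEX_TOL = 1e-10


def _as_2d_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise InvalidInputError(f"counts must be a 2-D matrix, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
            raise InvalidInputError("counts must be integers")
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise InvalidInputError("counts must be nonnegative")
    return arr.astype(np.int64)


@dataclass
class CountData:
    """Observed sample-by-taxon count matrix with binary disease labels.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, length ``N``.
    taxon_ids : list of str
        Unique taxon identifiers, length ``K``.
    counts : (N, K) int array
        Nonnegative read counts ``w_nk``.
    labels : (N,) int array
        Disease status ``y_n`` in {0, 1}.
    totals : (N,) int array
        Per-sample read totals ``M_n`` (derived row sums, all positive).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    labels: np.ndarray
    totals: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = _as_2d_counts(self.counts)
        n, k = self.counts.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if len(self.sample_ids) != n:
            raise InvalidInputError(
                f"{len(self.sample_ids)} sample ids for {n} count rows"
            )
        if len(self.taxon_ids) != k:
            raise InvalidInputError(
                f"{len(self.taxon_ids)} taxon ids for {k} count columns"
            )
        if len(set(self.sample_ids)) != n:
            raise InvalidInputError("sample ids must be unique")
        if len(set(self.taxon_ids)) != k:
            raise InvalidInputError("taxon ids must be unique")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (n,):
            raise InvalidInputError(f"labels must have shape ({n},)")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise InvalidInputError("labels must be 0 or 1")
        self.labels = self.labels.astype(np.int64)
        self.totals = self.counts.sum(axis=1)
        if np.any(self.totals <= 0):
            bad = [self.sample_ids[i] for i in np.nonzero(self.totals <= 0)[0]]
            raise InvalidInputError(f"samples with zero total counts: {bad}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, idx: Sequence[int]) -> "CountData":
        """Row-subset (used by cross-validation folds)."""
        idx = np.asarray(idx)
        return CountData(
            sample_ids=[self.sample_ids[i] for i in idx],
            taxon_ids=list(self.taxon_ids),
            counts=self.counts[idx],
            labels=self.labels[idx],
        )


@dataclass
class ModelParameters:
    """Fitted or true parameters (phi, rho, P, gamma) of the mixture.

    ``phi`` is the length-``L`` mixing simplex, ``rho`` the per-cluster
    disease risks in [0, 1], ``P`` the row-stochastic ``L x K`` composition
    matrix and ``gamma >= 0`` the symmetric Dirichlet offset (``alpha - 1``)
    acting as a pseudo-count inside the M-step.
    """

    phi: np.ndarray
    rho: np.ndarray
    P: np.ndarray
    gamma: float = 0.0

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.gamma = float(self.gamma)
        if self.phi.ndim != 1 or self.rho.ndim != 1 or self.P.ndim != 2:
            raise InvalidInputError("phi and rho must be vectors, P a matrix")
        L = self.phi.shape[0]
        if self.rho.shape[0] != L or self.P.shape[0] != L:
            raise InvalidInputError("phi, rho and P disagree on the cluster count")
        if np.any(~np.isfinite(self.phi)) or np.any(~np.isfinite(self.rho)) or np.any(
            ~np.isfinite(self.P)
        ):
            raise InvalidInputError("parameters contain non-finite values")
        if np.any(self.phi < 0) or abs(self.phi.sum() - 1.0) > SIMPLEX_TOL:
            raise InvalidInputError("phi must be a probability simplex vector")
        if np.any((self.rho < 0) | (self.rho > 1)):
            raise InvalidInputError("rho entries must lie in [0, 1]")
        if np.any(self.P < 0) or np.any(np.abs(self.P.sum(axis=1) - 1.0) > SIMPLEX_TOL):
            raise InvalidInputError("rows of P must be probability simplex vectors")
        if self.gamma < 0:
            raise InvalidInputError("gamma must be nonnegative")

    @property
    def n_clusters(self) -> int:
        return self.phi.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.P.shape[1]

    def reorder(self, perm: np.ndarray) -> "ModelParameters":
        """Return a copy with clusters permuted (label-switching resolution)."""
        perm = np.asarray(perm)
        return ModelParameters(
            phi=self.phi[perm], rho=self.rho[perm], P=self.P[perm], gamma=self.gamma
        )

    def sorted_by_risk(self) -> tuple["ModelParameters", np.ndarray]:
        """Relabel clusters so rho is non-decreasing; returns (params, perm)."""
        perm = np.argsort(self.rho, kind="stable")
        return self.reorder(perm), perm


@dataclass
class Responsibilities:
    """Soft cluster memberships: ``Z[n, l]`` = posterior P(cluster l | sample n)."""

    Z: np.ndarray

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise InvalidInputError("Z must be 2-D")
        if np.any(self.Z < -SIMPLEX_TOL) or np.any(
            np.abs(self.Z.sum(axis=1) - 1.0) > SIMPLEX_TOL
        ):
            raise InvalidInputError("responsibility rows must sum to 1")

    @property
    def hard_assignment(self) -> np.ndarray:
        """1-based cluster labels via argmax (lowest index wins ties)."""
        return np.argmax(self.Z, axis=1) + 1


def _check_compatible(data: CountData, params: ModelParameters) -> None:
    if data.n_taxa != params.n_taxa:
        raise InvalidInputError(
            f"data has {data.n_taxa} taxa but parameters have {params.n_taxa}"
        )


def log_composition_likelihood(counts: np.ndarray, P: np.ndarray) -> np.ndarray:
    """(N, L) matrix of sum_k w_nk log p_lk, without the multinomial coefficient.

    A zero ``p_lk`` facing a positive count yields -inf; a zero count facing a
    zero probability contributes 0 (the ``0 log 0 = 0`` convention).
    """
    counts = np.asarray(counts, dtype=float)
    zero = P <= 0.0
    logP = np.log(np.where(zero, 1.0, P))
    out = counts @ logP.T
    if zero.any():
        impossible = (counts > 0) @ zero.T.astype(float) > 0
        out[impossible] = -np.inf
    return out


def log_component_joint(data: CountData, params: ModelParameters) -> np.ndarray:
    """Log complete-data joint log f(y_n, w_n, z_n=l) up to the multinomial constant.

    Entry ``(n, l)`` is ``log phi_l + y_n log rho_l + (1-y_n) log(1-rho_l)
    + sum_k w_nk log p_lk``.  Risks are clipped to ``[1e-12, 1-1e-12]``
    before the log; a structurally impossible count (``p_lk = 0`` with
    ``w_nk > 0``) gives -inf.
    """
    _check_compatible(data, params)
    rho = np.clip(params.rho, RHO_CLIP, 1.0 - RHO_CLIP)
    with np.errstate(divide="ignore"):
        log_phi = np.log(params.phi)
    y = data.labels[:, None].astype(float)
    bern = y * np.log(rho)[None, :] + (1.0 - y) * np.log1p(-rho)[None, :]
    return log_phi[None, :] + bern + log_composition_likelihood(data.counts, params.P)


def log_posterior(
    data: CountData, params: ModelParameters, Z: Responsibilities
) -> float:
    """EM evidence lower bound on the log posterior, up to an additive constant.

    ``sum_nl z_nl log f(y_n, w_n, l) + gamma sum_lk log p_lk + H(Z)`` where
    ``H`` is the responsibility entropy.  At convergence this equals the log
    posterior of the fitted parameters (up to the dropped multinomial
    coefficient and Dirichlet normalizer); it is the quantity whose
    monotone increase certifies each EM sweep.
    """
    lj = log_component_joint(data, params)
    z = Z.Z
    if z.shape != lj.shape:
        raise InvalidInputError("responsibilities shape does not match data/params")
    with np.errstate(invalid="ignore"):
        weighted = np.where(z > 0, z * lj, 0.0)
    fit_term = float(weighted.sum())
    if params.gamma > 0:
        with np.errstate(divide="ignore"):
            prior = params.gamma * float(np.log(params.P).sum())
    else:
        prior = 0.0
    entropy = -float(xlogy(z, z).sum())
    return fit_term + prior + entropy
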