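"""Posterior disease-probability prediction and hard cluster assignment.

Given fitted parameters, the disease probability of a sample with counts
``w`` is the posterior

    P(y=1 | w) = sum_l r_l rho_l,    r_l ∝ phi_l prod_k p_lk^{w_k},

a convex combination of the per-cluster risks weighted by the label-free
cluster responsibilities.  Hard assignment takes the argmax of the posterior
responsibilities, either conditioning on the observed label (the natural
choice when classifying the training samples) or marginalizing over it
(the only valid choice for genuinely new samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from .exceptions import DegenerateSampleError, InvalidInputError
from .model import (
    RHO_CLIP,
    CountData,
    ModelParameters,
    Responsibilities,
    log_component_joint,
    log_composition_likelihood,
)


@dataclass
class Prediction:
    """Per-sample disease probabilities, hard cluster labels and posteriors."""

    disease_prob: np.ndarray
    cluster: np.ndarray  # 1-based labels
    posterior: Responsibilities


def _label_free_log_weights(counts: np.ndarray, params: ModelParameters) -> np.ndarray:
    """log of phi_l * prod_k p_lk^{w_k} for each (sample, cluster)."""
    with np.errstate(divide="ignore"):
        log_phi = np.log(params.phi)
    return log_phi[None, :] + log_composition_likelihood(counts, params.P)


def disease_probability_matrix(
    counts: np.ndarray, params: ModelParameters, sample_ids=None
) -> np.ndarray:
    """Vectorized posterior P(y=1 | w) for each row of a count matrix."""
    counts = np.atleast_2d(np.asarray(counts))
    lw = _label_free_log_weights(counts, params)
    dead = ~np.isfinite(lw.max(axis=1))
    if dead.any():
        i = int(np.nonzero(dead)[0][0])
        sid = sample_ids[i] if sample_ids is not None else str(i)
        raise DegenerateSampleError(sid)
    rho = np.clip(params.rho, RHO_CLIP, 1.0 - RHO_CLIP)
    log_num = logsumexp(lw + np.log(rho)[None, :], axis=1)
    log_den = logsumexp(
        np.concatenate(
            [lw + np.log(rho)[None, :], lw + np.log1p(-rho)[None, :]], axis=1
        ),
        axis=1,
    )
    return np.exp(log_num - log_den)


def disease_probability(counts_row: np.ndarray, params: ModelParameters) -> float:
    """Posterior probability that a sample with counts ``w`` is diseased.

    Never uses an observed label: the numerator sums the joint over clusters
    at ``y=1`` and the denominator additionally sums over both label values.
    """
    counts_row = np.asarray(counts_row)
    if counts_row.ndim != 1:
        raise InvalidInputError("counts_row must be a vector")
    return float(disease_probability_matrix(counts_row[None, :], params)[0])


def classify(
    data: CountData, params: ModelParameters, use_labels: bool = False
) -> Prediction:
    """Hard-assign each sample to its maximum-posterior cluster.

    With ``use_labels=True`` the posterior conditions on the observed disease
    label (the in-sample classification rule); with ``False`` the label is
    marginalized, as required at prediction time.  Ties break to the lowest
    cluster index.
    """
    if use_labels:
        scaled = log_component_joint(data, params)
    else:
        scaled = _label_free_log_weights(data.counts, params)
    dead = ~np.isfinite(scaled.max(axis=1))
    if dead.any():
        raise DegenerateSampleError(data.sample_ids[int(np.nonzero(dead)[0][0])])
    log_norm = logsumexp(scaled, axis=1, keepdims=True)
    post = Responsibilities(np.exp(scaled - log_norm))
    return Prediction(
        disease_prob=disease_probability_matrix(
            data.counts, params, sample_ids=data.sample_ids
        ),
        cluster=post.hard_assignment,
        posterior=post,
    )


def classification_accuracy(
    pred_cluster: np.ndarray, true_cluster: np.ndarray, align: bool = False
) -> float:
    """Fraction of samples assigned to the correct cluster.

    With ``align=False`` labels are compared as given (appropriate when both
    labelings already follow the risk-ascending convention).  With
    ``align=True`` the comparison is made after the best one-to-one relabeling
    of predicted clusters (Hungarian assignment on the confusion matrix), which
    is immune to label switching.
    """
    pred = np.asarray(pred_cluster)
    true = np.asarray(true_cluster)
    if pred.shape != true.shape or pred.ndim != 1:
        raise InvalidInputError("cluster label vectors must have equal length")
    if align:
        labels = np.union1d(pred, true)
        index = {lab: i for i, lab in enumerate(labels)}
        conf = np.zeros((labels.size, labels.size))
        for p, t in zip(pred, true):
            conf[index[p], index[t]] += 1
        rows, cols = linear_sum_assignment(-conf)
        return float(conf[rows, cols].sum() / pred.size)
    return float(np.mean(pred == true))
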