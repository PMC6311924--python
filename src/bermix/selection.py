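"""Cross-validated choice of the number of latent clusters L.

The selection criterion is the held-out log-loss (Bernoulli cross-entropy)
of the label-free disease-probability predictor:

    LL = - sum_j [ y_j log(rho~_j) + (1 - y_j) log(1 - rho~_j) ],

accumulated over repeated (optionally stratified) K-fold splits.  The L with
the smallest mean per-sample loss wins; ties go to the smaller, more
parsimonious L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import BermixError, InvalidInputError
from .fitting import AnnealingSchedule, fit
from .model import CountData
from .prediction import disease_probability_matrix

logger = logging.getLogger(__name__)

PROB_CLIP = 1e-12


@dataclass
class CVConfig:
    """Settings for repeated K-fold cross-validation over a grid of L."""

    L_grid: list[int]
    n_folds: int = 10
    n_repeats: int = 20
    gamma: float = 1e-9
    schedule: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        self.L_grid = [int(L) for L in self.L_grid]
        if len(self.L_grid) == 0 or min(self.L_grid) < 1:
            raise InvalidInputError("L_grid must contain integers >= 1")
        if len(set(self.L_grid)) != len(self.L_grid):
            raise InvalidInputError("L_grid values must be distinct")
        if self.n_folds < 2 or self.n_repeats < 1:
            raise InvalidInputError("need n_folds >= 2 and n_repeats >= 1")


@dataclass
class CVResult:
    """Per-L loss table and the selected cluster count."""

    per_L: pd.DataFrame  # columns: L, mean_log_loss, se, n_folds_used, mean_raw_loss
    selected_L: int
    fold_losses: pd.DataFrame = field(repr=False)  # long table, one row per fold fit


def log_loss(labels: np.ndarray, probs: np.ndarray) -> float:
    """Summed Bernoulli cross-entropy of predicted disease probabilities.

    Probabilities are clipped to ``[1e-12, 1 - 1e-12]`` so a confidently
    wrong prediction stays finite.
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape or y.ndim != 1 or y.size < 1:
        raise InvalidInputError("labels and probs must be equal-length vectors")
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum())


def _fold_iterator(data: CountData, config: CVConfig, repeat: int):
    seed = (config.seed + 104729 * repeat) % (2**31)
    if config.stratified:
        splitter = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=seed
        )
        return splitter.split(np.zeros(data.n_samples), data.labels)
    splitter = KFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
    return splitter.split(np.zeros(data.n_samples))


def cross_validate(data: CountData, config: CVConfig) -> CVResult:
    """Repeated K-fold CV of the held-out log-loss for each candidate L.

    For every repeat and fold, each L is fitted on the training split and the
    label-free predictor is evaluated on the held-out samples (the held-out
    label enters only the loss).  Mean and standard error are computed over
    all repeat x fold values of the per-sample loss; at least 80% of folds
    must fit successfully for an L to be eligible.
    """
    if config.n_folds > data.n_samples:
        raise InvalidInputError("more folds than samples")
    records = []
    for repeat in range(config.n_repeats):
        for fold_id, (train_idx, test_idx) in enumerate(
            _fold_iterator(data, config, repeat)
        ):
            if len(test_idx) == 0 or len(train_idx) == 0:
                raise InvalidInputError("empty fold; reduce n_folds")
            train = data.subset_samples(train_idx)
            test = data.subset_samples(test_idx)
            fit_seed = (config.seed + 7919 * repeat + 13 * fold_id) % (2**31)
            for L in config.L_grid:
                try:
                    result = fit(
                        train, L, gamma=config.gamma,
                        schedule=config.schedule, seed=fit_seed,
                    )
                    probs = disease_probability_matrix(
                        test.counts, result.params, sample_ids=test.sample_ids
                    )
                    raw = log_loss(test.labels, probs)
                except BermixError as exc:  # recorded, fold skipped
                    logger.warning(
                        "fold %d repeat %d L=%d failed: %s", fold_id, repeat, L, exc
                    )
                    records.append(
                        dict(repeat=repeat, fold=fold_id, L=L, J=len(test_idx),
                             raw_loss=np.nan, mean_loss=np.nan, ok=False)
                    )
                    continue
                records.append(
                    dict(repeat=repeat, fold=fold_id, L=L, J=len(test_idx),
                         raw_loss=raw, mean_loss=raw / len(test_idx), ok=True)
                )
    fold_losses = pd.DataFrame.from_records(records)

    rows = []
    for L in config.L_grid:
        sub = fold_losses[fold_losses["L"] == L]
        ok = sub[sub["ok"]]
        if len(ok) < 0.8 * len(sub):
            raise BermixError(
                f"fewer than 80% of folds fitted successfully for L={L}"
            )
        losses = ok["mean_loss"].to_numpy()
        rows.append(
            dict(
                L=L,
                mean_log_loss=float(losses.mean()),
                se=float(losses.std(ddof=1) / np.sqrt(losses.size))
                if losses.size > 1
                else 0.0,
                n_folds_used=int(losses.size),
                mean_raw_loss=float(ok["raw_loss"].mean()),
            )
        )
    per_L = pd.DataFrame(rows)
    # argmin of the mean loss; ties go to the smaller L.  Ties are assessed
    # with a small numerical tolerance: superfluous clusters often collapse
    # into exact duplicates, leaving per-L losses equal up to float noise,
    # and the parsimonious choice should win rather than the rounding error.
    lo = per_L["mean_log_loss"].min()
    tied = per_L[per_L["mean_log_loss"] <= lo + 1e-9 * (abs(lo) + 1.0)]
    return CVResult(
        per_L=per_L, selected_L=int(tied["L"].min()), fold_losses=fold_losses
    )
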