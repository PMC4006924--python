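"""Class prediction: LOOCV misclassification with a permutation null.

The question is whether the class labels (control / model A / model B)
are recoverable from the transcriptome alone.  Each sample is held out
in turn; gene selection (a one-way F-test at ``selector_alpha``) is
re-run on the remaining samples by default, so the selection step cannot
leak information from the held-out sample; a nearest-centroid classifier
on per-probe standardised log2 values predicts the held-out label.  A
Monte-Carlo permutation of the class labels, repeating the full LOOCV
(including per-fold reselection) each time, yields the null distribution
of the misclassification rate and an add-one p-value

    p = (1 + #{null rate <= observed rate}) / (n_permutations + 1),

which is never zero and is exact under exchangeability.

Samples are ordered canonically (sorted by sample id) before any
computation, so results do not depend on the column order of the input
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .filtering import one_way_f


@dataclass
class PredictionResult:
    """LOOCV misclassification with its permutation null."""

    observed_rate: float
    predictions: pd.DataFrame  # per-sample true vs predicted label
    n_permutations: int
    null_rates: np.ndarray
    p_value: float
    seed: int | None = None


def _standardize(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe mean and sd from the training block; sd 0 -> 1 so
    constant probes contribute no distance rather than NaNs."""
    mean = train.mean(axis=1)
    sd = train.std(axis=1, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def nearest_centroid_predict(
    train: np.ndarray,
    train_labels: np.ndarray,
    test: np.ndarray,
) -> np.ndarray:
    """Predict test columns by standardized-Euclidean distance to class
    centroids.  Ties go to the lexicographically first class."""
    classes = np.unique(train_labels)
    mean, sd = _standardize(train)
    z_train = (train - mean[:, None]) / sd[:, None]
    z_test = (np.atleast_2d(test.T).T - mean[:, None]) / sd[:, None]
    centroids = np.stack(
        [z_train[:, train_labels == c].mean(axis=1) for c in classes], axis=1
    )
    # distances: classes x test samples
    d2 = ((z_test[:, None, :] - centroids[:, :, None]) ** 2).sum(axis=0)
    return classes[np.argmin(d2, axis=0)]


def _loocv(
    values: np.ndarray,
    labels: np.ndarray,
    selector_alpha: float,
    reselect_per_fold: bool,
    min_selected_fallback: bool = True,
) -> np.ndarray:
    """Predicted label per sample.  ``values`` is probes x samples."""
    n = values.shape[1]
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ValidationError(f"class(es) with <2 samples: {small}")
    predictions = np.empty(n, dtype=labels.dtype)
    all_cols = np.arange(n)

    def select(cols: np.ndarray, labs: np.ndarray) -> np.ndarray:
        groups = [np.flatnonzero(labs == c) for c in np.unique(labs)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = one_way_f(values[:, cols], groups)
        kept = np.flatnonzero(p < selector_alpha)
        if len(kept) == 0 and min_selected_fallback:
            kept = np.arange(values.shape[0])
        return kept

    if not reselect_per_fold:
        fixed_kept = select(all_cols, labels)

    for i in range(n):
        train_cols = np.delete(all_cols, i)
        train_labels = labels[train_cols]
        if np.unique(train_labels).size < classes.size:
            raise ValidationError(
                f"holding out sample {i} empties a class"
            )
        kept = select(train_cols, train_labels) if reselect_per_fold else fixed_kept
        pred = nearest_centroid_predict(
            values[np.ix_(kept, train_cols)], train_labels,
            values[kept][:, [i]],
        )
        predictions[i] = pred[0]
    return predictions


def loocv_rate(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    selector_alpha: float = 0.001,
    reselect_per_fold: bool = True,
) -> tuple[float, pd.DataFrame]:
    """LOOCV misclassification rate and per-sample calls.

    With ``reselect_per_fold=False`` the F-test selection is run once on
    the full data (the optimistic variant some legacy analyses used).
    If no probe passes ``selector_alpha`` in a fold, all probes are used
    for that fold.
    """
    order = matrix.columns.sort_values()
    values = matrix[order].to_numpy()
    labels = samples.loc[order, "class_label"].to_numpy()
    preds = _loocv(values, labels, selector_alpha, reselect_per_fold)
    calls = pd.DataFrame(
        {"true_label": labels, "predicted_label": preds}, index=order
    )
    rate = float((preds != labels).mean())
    return rate, calls


def permutation_pvalue(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int | None = None,
    selector_alpha: float = 0.001,
    reselect_per_fold: bool = True,
) -> PredictionResult:
    """Observed LOOCV rate with a Monte-Carlo permutation null.

    Class labels are permuted over the whole cohort (controls included);
    the complete LOOCV procedure is repeated per permutation.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    order = matrix.columns.sort_values()
    values = matrix[order].to_numpy()
    labels = samples.loc[order, "class_label"].to_numpy()

    preds = _loocv(values, labels, selector_alpha, reselect_per_fold)
    observed = float((preds != labels).mean())

    rng = np.random.default_rng(seed)
    null_rates = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(labels)
        perm_preds = _loocv(values, perm, selector_alpha, reselect_per_fold)
        null_rates[b] = (perm_preds != perm).mean()

    p = (1 + int((null_rates <= observed).sum())) / (n_permutations + 1)
    calls = pd.DataFrame(
        {"true_label": labels, "predicted_label": preds}, index=order
    )
    return PredictionResult(
        observed_rate=observed,
        predictions=calls,
        n_permutations=n_permutations,
        null_rates=null_rates,
        p_value=p,
        seed=seed,
    )
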