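"""Distance-from-reference (DFR): a scalar per-sample perturbation score.

Heat maps and gene lists make it hard to judge the OVERALL magnitude of
a transcriptomic perturbation.  The DFR reduces a sample's expression
profile over a set of significant probes to one number: the variance-
normalized squared deviation from the healthy-control reference,

    D = sum_i (e_i - M_i)**2 / V_i,        dfr = ln(D)

where e_i is the sample's expression at probe i and M_i, V_i are the
control group's mean and (unbiased, n-1 denominator) variance.  The
natural log tames the scale: D grows linearly with the number of probes
scored, so ln(D) stays in single digits for thousands of genes.

Under the null (a sample drawn from the control population, reference
estimated from n controls) each term is a scaled F statistic and

    E[D / G] = (1 + 1/n) * (n - 1) / (n - 3)

for G probes — the calibration the tests check (≈1.414 at n = 10).

An absolute-value variant |e - M| / sqrt(V) is available behind a flag
for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateResultError, ValidationError
from .simulate import CONTROL

SQUARED = "squared"
ABSOLUTE = "absolute"


@dataclass
class ControlReference:
    """Per-probe control mean and variance over a probe universe."""

    mean: pd.Series  # M_i
    variance: pd.Series  # V_i, sample variance with n-1 denominator
    n_control: int
    excluded_zero_variance: list[str]

    @property
    def probes(self) -> pd.Index:
        return self.mean.index


@dataclass
class DfrScore:
    """One sample's distance from the control reference."""

    sample_id: str
    raw_distance: float  # D
    dfr: float | None  # ln(D); None when D == 0 (degenerate)
    n_probes: int
    degenerate: bool = False


def build_reference(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    probe_subset: pd.Index | None = None,
) -> ControlReference:
    """Estimate M_i and V_i from the control samples.

    Probes with zero control variance cannot be scored (division by V)
    and are excluded with a warning listing them.
    """
    annot = samples.loc[matrix.columns]
    ctrl_cols = annot.index[annot["class_label"] == CONTROL]
    if len(ctrl_cols) < 3:
        raise ValidationError(
            f"need >=3 control samples to build a reference, got {len(ctrl_cols)}"
        )
    sub = matrix if probe_subset is None else matrix.loc[probe_subset]
    block = sub[ctrl_cols]
    mean = block.mean(axis=1)
    var = block.var(axis=1, ddof=1)
    zero = var.index[var == 0].tolist()
    if zero:
        warnings.warn(
            f"{len(zero)} probe(s) with zero control variance excluded "
            f"from DFR reference: {zero[:5]}"
        )
        mean = mean.drop(zero)
        var = var.drop(zero)
    mean.name = "control_mean"
    var.name = "control_variance"
    return ControlReference(
        mean=mean,
        variance=var,
        n_control=len(ctrl_cols),
        excluded_zero_variance=zero,
    )


def dfr_score(
    sample: pd.Series,
    reference: ControlReference,
    variant: str = SQUARED,
) -> DfrScore:
    """Score one expression profile against the control reference."""
    missing = reference.probes.difference(sample.index).tolist()
    if missing:
        raise ValidationError(
            f"sample {sample.name!r} missing reference probes: {missing[:5]}"
        )
    e = sample.loc[reference.probes].to_numpy(dtype=float)
    m = reference.mean.to_numpy()
    v = reference.variance.to_numpy()
    if variant == SQUARED:
        d = float(((e - m) ** 2 / v).sum())
    elif variant == ABSOLUTE:
        d = float((np.abs(e - m) / np.sqrt(v)).sum())
    else:
        raise ValueError(f"unknown DFR variant {variant!r}")
    degenerate = d == 0.0
    return DfrScore(
        sample_id=str(sample.name),
        raw_distance=d,
        dfr=None if degenerate else float(np.log(d)),
        n_probes=len(reference.probes),
        degenerate=degenerate,
    )


def dfr_scores(
    matrix: pd.DataFrame,
    reference: ControlReference,
    variant: str = SQUARED,
) -> pd.DataFrame:
    """Score every sample (column) of a matrix.  Vectorized equivalent of
    calling :func:`dfr_score` per column."""
    missing = reference.probes.difference(matrix.index).tolist()
    if missing:
        raise ValidationError(f"matrix missing reference probes: {missing[:5]}")
    e = matrix.loc[reference.probes].to_numpy(dtype=float)
    m = reference.mean.to_numpy()[:, None]
    v = reference.variance.to_numpy()[:, None]
    if variant == SQUARED:
        d = ((e - m) ** 2 / v).sum(axis=0)
    elif variant == ABSOLUTE:
        d = (np.abs(e - m) / np.sqrt(v)).sum(axis=0)
    else:
        raise ValueError(f"unknown DFR variant {variant!r}")
    with np.errstate(divide="ignore"):
        dfr = np.where(d > 0, np.log(d), np.nan)
    return pd.DataFrame(
        {"raw_distance": d, "dfr": dfr, "n_probes": len(reference.probes),
         "degenerate": d == 0.0},
        index=matrix.columns,
    )


def group_dfr(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    reference: ControlReference,
    variant: str = SQUARED,
) -> pd.DataFrame:
    """Mean DFR ± SEM per (class, timepoint) group.

    The control group appears as its own row (timepoint NA) — its mean
    is the baseline a plot would draw as the dashed reference line.
    SEM is undefined (NA) for groups of one.
    """
    scores = dfr_scores(matrix, reference, variant=variant)
    annot = samples.loc[matrix.columns]
    joined = scores.join(annot)
    if joined["degenerate"].any():
        bad = joined.index[joined["degenerate"]].tolist()
        raise DegenerateResultError(
            f"sample(s) with zero distance have no log score: {bad[:5]}"
        )
    key = joined["timepoint"].fillna("")
    grouped = joined.groupby(["class_label", key], sort=False)["dfr"]
    out = grouped.agg(
        mean_dfr="mean",
        sem_dfr=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan,
        n="size",
    ).reset_index()
    out["timepoint"] = out["timepoint"].replace({"": None})
    return out
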