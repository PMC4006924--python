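"""Genome-wide concordance between the two sepsis models.

For each timepoint, the mean log2 change versus control is computed per
probe for both models over a common "sepsis-responsive" probe universe,
and the two change vectors are correlated (Pearson).  A summary
"maximum-change" correlation takes, per probe and model, the largest-
magnitude change across timepoints (sign retained) and correlates those.
Correlations are computed on log2 changes, not signed folds.

The default probe universe is the UNION of the two models' significant
probe sets; an intersection rule is available (union preserves
model-unique responders whose exclusion would inflate r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .filtering import ChangeProfile, SelectionResult, change_profile, per_model_selection
from .simulate import MODEL_A, MODEL_B

UNION = "union"
INTERSECTION = "intersection"


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("change vectors must be 1-D and equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant change vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def max_change_vector(profiles: dict[str, pd.Series]) -> pd.Series:
    """Per-probe signed change of largest magnitude across timepoints.

    ``profiles`` maps timepoint label -> per-probe log2 change, in
    timepoint order; ties in magnitude go to the earliest timepoint.
    """
    if not profiles:
        raise ValidationError("need at least one timepoint")
    items = list(profiles.items())
    index = items[0][1].index
    for t, series in items[1:]:
        if not series.index.equals(index):
            raise ValidationError(
                f"probe universe at {t!r} differs from the first timepoint"
            )
    best = items[0][1].copy()
    for _, series in items[1:]:
        take = series.abs() > best.abs()  # strict: ties keep earlier timepoint
        best = best.where(~take, series)
    best.name = "max_change"
    return best


@dataclass
class ConcordanceReport:
    """Between-model correlation structure over time."""

    per_timepoint: pd.DataFrame  # index timepoint; columns r, p, n_probes
    max_change_r: float
    max_change_p: float
    max_change_r2: float
    universe: pd.Index
    universe_rule: str
    profiles_a: dict[str, ChangeProfile]
    profiles_b: dict[str, ChangeProfile]


def build_probe_universe(
    sel_a: SelectionResult,
    sel_b: SelectionResult,
    rule: str = UNION,
) -> pd.Index:
    """Combine two models' significant probe sets."""
    if rule == UNION:
        return sel_a.kept.union(sel_b.kept)
    if rule == INTERSECTION:
        return sel_a.kept.intersection(sel_b.kept)
    raise ValueError(f"unknown universe rule {rule!r}")


def concordance_report(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    probe_universe: pd.Index,
    timepoints: tuple[str, ...] | None = None,
    universe_rule: str = UNION,
) -> ConcordanceReport:
    """Per-timepoint and maximum-change Pearson correlations between the
    two models' mean log2 changes over ``probe_universe``."""
    if len(probe_universe) == 0:
        raise ValidationError("probe universe is empty")
    if timepoints is None:
        tps = samples.loc[matrix.columns, "timepoint"].dropna()
        timepoints = tuple(pd.unique(tps))
    profiles_a: dict[str, ChangeProfile] = {}
    profiles_b: dict[str, ChangeProfile] = {}
    rows = []
    for t in timepoints:
        pa = change_profile(matrix, samples, MODEL_A, t, probe_universe)
        pb = change_profile(matrix, samples, MODEL_B, t, probe_universe)
        profiles_a[t] = pa
        profiles_b[t] = pb
        r, p = pearson(pa.log2_change.to_numpy(), pb.log2_change.to_numpy())
        rows.append({"timepoint": t, "r": r, "p": p,
                     "n_probes": len(probe_universe)})
    per_tp = pd.DataFrame(rows).set_index("timepoint")

    max_a = max_change_vector({t: profiles_a[t].log2_change for t in timepoints})
    max_b = max_change_vector({t: profiles_b[t].log2_change for t in timepoints})
    mr, mp = pearson(max_a.to_numpy(), max_b.to_numpy())
    return ConcordanceReport(
        per_timepoint=per_tp,
        max_change_r=mr,
        max_change_p=mp,
        max_change_r2=mr * mr,
        universe=probe_universe,
        universe_rule=universe_rule,
        profiles_a=profiles_a,
        profiles_b=profiles_b,
    )


def model_concordance(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.001,
    universe_rule: str = UNION,
    timepoints: tuple[str, ...] | None = None,
) -> ConcordanceReport:
    """Convenience wrapper: per-model F-test selection at ``alpha``,
    universe combination, then the full concordance report."""
    sel_a = per_model_selection(matrix, samples, MODEL_A, alpha=alpha)
    sel_b = per_model_selection(matrix, samples, MODEL_B, alpha=alpha)
    universe = build_probe_universe(sel_a, sel_b, universe_rule)
    if len(universe) == 0:
        raise ValidationError(
            "no significant probes in either model; cannot compute concordance"
        )
    return concordance_report(matrix, samples, universe,
                              timepoints=timepoints, universe_rule=universe_rule)
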