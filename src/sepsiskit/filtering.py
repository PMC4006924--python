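"""Gene selection and per-group change statistics.

Two selection routes mirror the usual microarray workflow:

* unsupervised — keep probes whose coefficient of variation (sd/mean)
  across all samples exceeds a threshold.  The CV is computed on the
  LINEAR (anti-logged) intensity scale by default: on log2-normalised
  data a CV > 0.5 cut would retain almost nothing, whereas on the linear
  scale it retains the broadly varying minority a heat map is built from.
* supervised — keep probes significant in a one-way F-test across a
  chosen grouping (three classes, or every (model, timepoint) cell), at
  a raw p cutoff (no multiple-testing correction; a Benjamini–Hochberg
  FDR column is emitted for reference).

Change profiles give each probe's mean log2 change versus the control
group and the equivalent signed fold change, using the reciprocal
convention (a halving is −2, not 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .simulate import CONTROL, MODEL_A, MODEL_B, MODELS

THREE_CLASS = "three-class"
MODEL_TIME = "model-time"


@dataclass
class SelectionResult:
    """Outcome of a probe-selection step."""

    kept: pd.Index
    statistic: pd.Series  # CV per probe, or F-test p-value per probe
    threshold: float
    kind: str  # "cv" or "f-test"
    n_probes_kept: int = field(init=False)
    n_genes_kept: int | None = None
    extra: pd.DataFrame | None = None  # e.g. F statistic + FDR columns

    def __post_init__(self) -> None:
        self.n_probes_kept = len(self.kept)

    def gene_symbols(self, probes: pd.DataFrame) -> set[str]:
        """Collapse the kept probes to gene symbols (a gene counts as
        selected if at least one of its probes is kept; unannotated
        probes are skipped)."""
        symbols = probes.loc[self.kept.intersection(probes.index), "gene_symbol"]
        return set(symbols.dropna()) - {""}


def cv_filter(
    matrix: pd.DataFrame,
    threshold: float = 0.5,
    scale: str = "linear",
) -> SelectionResult:
    """Keep probes with coefficient of variation strictly above ``threshold``.

    ``scale="linear"`` anti-logs the matrix (2**x) before computing
    sd/mean; ``scale="log2"`` uses the stored values directly (probes
    with mean 0 on that scale are excluded with a warning).
    """
    if matrix.shape[1] < 2:
        raise ValidationError("CV filter needs at least 2 samples")
    if scale == "linear":
        values = np.exp2(matrix.to_numpy())
    elif scale == "log2":
        values = matrix.to_numpy()
    else:
        raise ValueError(f"unknown scale {scale!r}")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    zero_mean = matrix.index[mean == 0]
    if len(zero_mean):
        warnings.warn(
            f"{len(zero_mean)} probe(s) with zero mean excluded from CV "
            f"filter: {zero_mean.tolist()[:5]}"
        )
    statistic = pd.Series(cv, index=matrix.index, name="cv")
    kept = matrix.index[np.nan_to_num(cv, nan=-np.inf) > threshold]
    return SelectionResult(kept=kept, statistic=statistic,
                           threshold=threshold, kind="cv")


def one_way_f(values: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-way ANOVA F statistic and p-value.

    ``values`` is probes x samples; ``groups`` are column index arrays,
    one per group.  Rows with zero within-group variance get p = 0
    (infinite F) — a perfectly separated probe is maximally significant.
    """
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    if (sizes < 2).any():
        raise ValidationError(
            f"every group needs >=2 samples, got sizes {sizes.tolist()}"
        )
    n_total = sizes.sum()
    group_means = np.stack([values[:, g].mean(axis=1) for g in groups], axis=1)
    grand = (group_means * sizes).sum(axis=1) / n_total
    ss_between = (sizes * (group_means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.zeros(values.shape[0])
    for j, g in enumerate(groups):
        resid = values[:, g] - group_means[:, j][:, None]
        ss_within += (resid * resid).sum(axis=1)
    df_between = k - 1
    df_within = n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    p = np.where(ss_within > 0, stats.f.sf(f, df_between, df_within), 0.0)
    n_degenerate = int((ss_within == 0).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} probe(s) with zero within-group variance; "
            f"p set to 0"
        )
    return f, p


def _grouping_columns(
    matrix: pd.DataFrame, samples: pd.DataFrame, grouping: str
) -> list[np.ndarray]:
    annot = samples.loc[matrix.columns]
    positions = np.arange(matrix.shape[1])
    if grouping == THREE_CLASS:
        keys = annot["class_label"]
    elif grouping == MODEL_TIME:
        keys = annot.apply(
            lambda r: r["class_label"] if r["class_label"] == CONTROL
            else f"{r['class_label']}:{r['timepoint']}", axis=1)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    groups = [positions[(keys == level).to_numpy()] for level in pd.unique(keys)]
    return groups


def f_test_selection(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    grouping: str = THREE_CLASS,
    alpha: float = 0.001,
) -> SelectionResult:
    """Supervised selection: keep probes with one-way F-test p < alpha.

    ``grouping="three-class"`` compares control vs model A vs model B
    pooling timepoints; ``grouping="model-time"`` uses control plus each
    (model, timepoint) cell as its own group.
    """
    groups = _grouping_columns(matrix, samples, grouping)
    if len(groups) < 2:
        raise ValidationError("F-test needs at least 2 groups")
    f, p = one_way_f(matrix.to_numpy(), groups)
    pvals = pd.Series(p, index=matrix.index, name="p_value")
    fdr = pd.Series(_bh_fdr(p), index=matrix.index, name="fdr")
    extra = pd.DataFrame({"f_statistic": f, "fdr": fdr}, index=matrix.index)
    kept = matrix.index[p < alpha]
    return SelectionResult(kept=kept, statistic=pvals, threshold=alpha,
                           kind="f-test", extra=extra)


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (reference column only)."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def per_model_selection(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    model: str,
    alpha: float = 0.001,
) -> SelectionResult:
    """Sepsis-responsive probes for one model: F-test over control plus
    that model's timepoint groups."""
    annot = samples.loc[matrix.columns]
    keep_cols = annot.index[annot["class_label"].isin([CONTROL, model])]
    sub = matrix[keep_cols]
    return f_test_selection(sub, samples, grouping=MODEL_TIME, alpha=alpha)


def signed_fold(d: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Reciprocal signed fold change: 2**d for d >= 0, -(2**-d) otherwise."""
    return np.where(np.asarray(d) >= 0, np.exp2(d), -np.exp2(-np.asarray(d)))


@dataclass
class ChangeProfile:
    """Mean log2 change and signed fold of a (model, timepoint) group
    versus the control group."""

    model: str
    timepoint: str
    log2_change: pd.Series
    fold_change: pd.Series

    @property
    def probes(self) -> pd.Index:
        return self.log2_change.index


def change_profile(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    model: str,
    timepoint: str,
    probe_subset: pd.Index | None = None,
) -> ChangeProfile:
    """Per-probe mean log2 change of (model, timepoint) vs control."""
    annot = samples.loc[matrix.columns]
    ctrl_cols = annot.index[annot["class_label"] == CONTROL]
    grp_cols = annot.index[(annot["class_label"] == model)
                           & (annot["timepoint"] == timepoint)]
    if len(ctrl_cols) == 0 or len(grp_cols) == 0:
        raise ValidationError(
            f"empty group: control n={len(ctrl_cols)}, "
            f"{model}@{timepoint} n={len(grp_cols)}"
        )
    sub = matrix if probe_subset is None else matrix.loc[probe_subset]
    if sub.shape[0] == 0:
        raise ValidationError("empty probe subset")
    d = sub[grp_cols].mean(axis=1) - sub[ctrl_cols].mean(axis=1)
    d.name = "log2_change"
    fold = pd.Series(signed_fold(d), index=d.index, name="fold_change")
    return ChangeProfile(model=model, timepoint=timepoint,
                         log2_change=d, fold_change=fold)


@dataclass
class OverlapReport:
    """Probe- and gene-level overlap between two selections."""

    genes_a: set[str]
    genes_b: set[str]
    genes_shared: set[str]
    genes_only_a: set[str]
    genes_only_b: set[str]
    probes_a: set[str]
    probes_b: set[str]
    probes_shared: set[str]

    def counts(self) -> dict[str, int]:
        return {
            "probes_a": len(self.probes_a),
            "probes_b": len(self.probes_b),
            "probes_shared": len(self.probes_shared),
            "genes_a": len(self.genes_a),
            "genes_b": len(self.genes_b),
            "genes_shared": len(self.genes_shared),
            "genes_only_a": len(self.genes_only_a),
            "genes_only_b": len(self.genes_only_b),
        }


def collapse_and_overlap(
    sel_a: SelectionResult,
    sel_b: SelectionResult,
    probes: pd.DataFrame,
) -> OverlapReport:
    """Gene-level overlap accounting between two models' selections."""
    if not sel_a.statistic.index.equals(sel_b.statistic.index):
        raise ValidationError("selections come from different probe universes")
    genes_a = sel_a.gene_symbols(probes)
    genes_b = sel_b.gene_symbols(probes)
    return OverlapReport(
        genes_a=genes_a,
        genes_b=genes_b,
        genes_shared=genes_a & genes_b,
        genes_only_a=genes_a - genes_b,
        genes_only_b=genes_b - genes_a,
        probes_a=set(sel_a.kept),
        probes_b=set(sel_b.kept),
        probes_shared=set(sel_a.kept) & set(sel_b.kept),
    )


def _correlation_order(values: np.ndarray, ids: pd.Index):
    """Average-linkage ordering under 1 - Pearson distance.

    Constant rows (undefined correlation) are placed last, in input
    order, with a warning.  Returns (ordered ids, linkage or None,
    constant ids).
    """
    sd = values.std(axis=1)
    ok = sd > 0
    constant = ids[~ok]
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant row(s) placed last in ordering: "
            f"{constant.tolist()[:5]}"
        )
    usable = values[ok]
    usable_ids = ids[ok]
    if usable.shape[0] < 2:
        return list(usable_ids) + list(constant), None, list(constant)
    corr = np.corrcoef(usable)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    ordered = [usable_ids[i] for i in order] + list(constant)
    return ordered, link, list(constant)


def cluster_order(
    matrix: pd.DataFrame,
    probe_subset: pd.Index | None = None,
):
    """Deterministic row and column orderings for heat-map export.

    Average linkage on 1 − Pearson distance, applied to probes (rows)
    and samples (columns) independently.  Returns a dict with ordered
    probe ids, ordered sample ids and the two linkage matrices.
    """
    sub = matrix if probe_subset is None else matrix.loc[probe_subset]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 probes and 2 samples")
    row_order, row_link, row_const = _correlation_order(sub.to_numpy(), sub.index)
    col_order, col_link, col_const = _correlation_order(sub.to_numpy().T, sub.columns)
    return {
        "probe_order": row_order,
        "sample_order": col_order,
        "probe_linkage": row_link,
        "sample_linkage": col_link,
        "constant_probes": row_const,
        "constant_samples": col_const,
    }
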