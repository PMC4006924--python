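"""Gene-set statistics: Fisher over-representation and activation Z.

Two statistics stand in for a desktop pathway tool, applied to
user-supplied gene sets:

* over-representation — a 2x2 Fisher exact test of set membership
  against significance, reported as -log10(p) so that the conventional
  p = 0.05 line sits at 1.3;
* directional activation — for a set whose members carry an expected
  regulation sign (+1 up, -1 down), the z-score

      Z = (N_consistent - N_inconsistent) / sqrt(N)

  over the member genes whose observed |signed fold change| passes a
  threshold (default 2-fold).  A gene is consistent when the sign of its
  observed change matches its expected direction.  |Z| >= 2 is the
  conventional significance rule (two-sided normal 95% band; under a
  random-sign null P(|Z| >= 2) ≈ 4.6%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .filtering import ChangeProfile
from .io import GeneSet

Z_SIGNIFICANCE = 2.0


@dataclass
class EnrichmentResult:
    """Fisher over-representation of one gene set, with the optional
    directional activation Z."""

    name: str
    n_set_significant: int
    n_set_not_significant: int
    n_out_significant: int
    n_out_not_significant: int
    p_value: float
    minus_log10_p: float
    activation_z: float | None = None
    n_direction_scored: int | None = None
    significant_z: bool | None = None

    def contingency(self) -> np.ndarray:
        return np.array(
            [[self.n_set_significant, self.n_set_not_significant],
             [self.n_out_significant, self.n_out_not_significant]]
        )


def fisher_enrichment(
    gene_set: GeneSet,
    significant_genes: set[str],
    universe: set[str],
) -> EnrichmentResult:
    """Two-sided Fisher exact test of set membership vs significance.

    The set is intersected with the universe first; significant genes
    must be a subset of the universe.
    """
    if not universe:
        raise ValidationError("empty gene universe")
    stray = set(significant_genes) - set(universe)
    if stray:
        raise ValidationError(
            f"significant genes outside the universe: {sorted(stray)[:5]}"
        )
    members = set(gene_set.genes) & set(universe)
    if not members:
        raise ValidationError(
            f"gene set {gene_set.name!r} has no genes in the universe"
        )
    sig = set(significant_genes)
    a = len(members & sig)
    b = len(members - sig)
    c = len(sig - members)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        name=gene_set.name,
        n_set_significant=a,
        n_set_not_significant=b,
        n_out_significant=c,
        n_out_not_significant=d,
        p_value=float(p),
        minus_log10_p=float(-np.log10(p)) if p > 0 else float("inf"),
    )


def gene_level_change(
    profile: ChangeProfile,
    probes: pd.DataFrame,
) -> pd.Series:
    """Collapse a probe-level change profile to gene symbols.

    Each gene takes the log2 change of its largest-|change| probe (the
    same largest-magnitude convention the max-change correlation uses);
    unannotated probes are skipped.
    """
    annotated = probes.loc[probes.index.intersection(profile.probes)]
    annotated = annotated[annotated["gene_symbol"].notna()
                          & (annotated["gene_symbol"] != "")]
    d = profile.log2_change.loc[annotated.index]
    frame = pd.DataFrame(
        {"gene_symbol": annotated["gene_symbol"], "d": d, "abs_d": d.abs()}
    )
    idx = frame.groupby("gene_symbol")["abs_d"].idxmax()
    out = frame.loc[idx].set_index("gene_symbol")["d"]
    out.name = "log2_change"
    return out


def activation_z(
    gene_set: GeneSet,
    gene_changes: pd.Series,
    fold_threshold: float = 2.0,
) -> tuple[float, int]:
    """Directional activation z-score over a gene set.

    ``gene_changes`` maps gene symbol -> observed log2 change.  Member
    genes present in the profile and passing |signed fold| >=
    ``fold_threshold`` (i.e. |log2 change| >= log2(threshold)) are
    scored: consistent if sign(change) equals the expected direction.
    Returns (Z, N scored); Z = 0 when no gene qualifies.
    """
    if gene_set.directions is None:
        raise ValidationError(
            f"gene set {gene_set.name!r} has no expected directions"
        )
    if fold_threshold < 1:
        raise ValidationError("fold_threshold must be >= 1")
    min_abs_d = float(np.log2(fold_threshold))
    n_consistent = 0
    n_inconsistent = 0
    for gene in gene_set.genes:
        if gene not in gene_changes.index:
            continue
        d = float(gene_changes.loc[gene])
        if abs(d) < min_abs_d or d == 0.0:
            continue
        observed_sign = 1 if d > 0 else -1
        if observed_sign == gene_set.directions[gene]:
            n_consistent += 1
        else:
            n_inconsistent += 1
    n = n_consistent + n_inconsistent
    if n == 0:
        return 0.0, 0
    return float((n_consistent - n_inconsistent) / np.sqrt(n)), n


def enrichment_table(
    gene_sets: list[GeneSet],
    significant_genes: set[str],
    universe: set[str],
    gene_changes: pd.Series | None = None,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Fisher -log10 p (and activation Z where directions exist) for a
    collection of gene sets, one row per set."""
    rows = []
    for gs in gene_sets:
        res = fisher_enrichment(gs, significant_genes, universe)
        if gs.directions is not None and gene_changes is not None:
            z, n = activation_z(gs, gene_changes, fold_threshold)
            res.activation_z = z
            res.n_direction_scored = n
            res.significant_z = abs(z) >= Z_SIGNIFICANCE
        rows.append({
            "set_name": res.name,
            "n_set_significant": res.n_set_significant,
            "n_set_not_significant": res.n_set_not_significant,
            "n_out_significant": res.n_out_significant,
            "n_out_not_significant": res.n_out_not_significant,
            "p_value": res.p_value,
            "minus_log10_p": res.minus_log10_p,
            "activation_z": res.activation_z,
            "n_direction_scored": res.n_direction_scored,
            "significant_z": res.significant_z,
        })
    return pd.DataFrame(rows).set_index("set_name")
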