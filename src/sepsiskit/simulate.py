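"""Synthetic expression datasets with known differential-expression truth.

The generator emulates the statistical structure of a two-model murine
sepsis microarray study: a healthy control group plus two sepsis models
("modelA", e.g. cecal ligation and puncture; "modelB", e.g. cecal slurry)
sampled at three timepoints.  Per-probe baselines are uniform on a log2
intensity range, a designated fraction of probes carries model- and
timepoint-specific log2 effects, and the two models' effect vectors at
each timepoint are drawn from a bivariate normal with a tunable
correlation ``rho_t`` — the dial that downstream concordance analysis is
expected to recover.  Several probe sets may map to one gene symbol, so
probe-level and gene-level counts differ, as on real arrays.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError

CONTROL = "control"
MODEL_A = "modelA"
MODEL_B = "modelB"
MODELS = (MODEL_A, MODEL_B)
DEFAULT_TIMEPOINTS = ("2h", "1d", "3d")

#: Default between-model effect correlations per timepoint.  These are the
#: study conditions the concordance analysis targets: strongest agreement
#: early (2 h), weaker at 1 day, inverse by 3 days.
DEFAULT_RHO = {"2h": 0.6, "1d": 0.4, "3d": -0.3}


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of a synthetic two-model expression dataset.

    Parameters
    ----------
    n_probes
        Number of probe sets on the simulated array.
    probes_per_gene_pattern
        Cycle of probe-set multiplicities per gene symbol.  The default
        ``(1, 2)`` alternates singleton and duplicated genes (average 1.5
        probes per gene), so probe-set counts exceed gene counts.
    n_control
        Healthy control samples.
    n_per_group
        Samples per (model, timepoint) cell.
    timepoints
        Ordered timepoint labels.
    de_fraction
        Fraction of probes that are differentially expressed (DE).
    de_fraction_b
        Optional separate DE fraction for model B.  When set, the smaller
        DE set is shared (with correlated effects); the surplus probes of
        the larger set respond in that model only.  ``None`` means both
        models perturb the same probes.
    effect_sd
        Standard deviation, in log2 units, of DE effect sizes.
    rho_per_timepoint
        Correlation in [-1, 1], per timepoint, between the two models'
        effect vectors over the shared DE probes.
    noise_sd
        Gaussian measurement noise on the log2 scale.
    baseline_range
        Interval for per-probe baseline means (log2 intensities).
    seed
        RNG seed; identical designs with identical seeds yield
        bit-identical datasets.
    """

    n_probes: int = 10_000
    probes_per_gene_pattern: tuple[int, ...] = (1, 2)
    n_control: int = 6
    n_per_group: int = 4
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    de_fraction: float = 0.2
    de_fraction_b: float | None = None
    effect_sd: float = 1.0
    rho_per_timepoint: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RHO)
    )
    noise_sd: float = 0.3
    baseline_range: tuple[float, float] = (4.0, 14.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise DesignError("n_probes must be positive")
        if self.n_control < 0 or self.n_per_group < 1:
            raise DesignError("group sizes must be positive integers")
        if not all(isinstance(k, int) and k >= 1 for k in self.probes_per_gene_pattern):
            raise DesignError("probes_per_gene_pattern entries must be positive ints")
        for frac, name in ((self.de_fraction, "de_fraction"),
                           (self.de_fraction_b, "de_fraction_b")):
            if frac is None:
                continue
            if not 0.0 <= frac <= 1.0:
                raise DesignError(f"{name} must lie in [0, 1], got {frac}")
            n_de = frac * self.n_probes
            if abs(n_de - round(n_de)) > 1e-6:
                raise DesignError(
                    f"{name} * n_probes = {n_de} is not an integer DE count"
                )
        if len(set(self.timepoints)) != len(self.timepoints):
            raise DesignError("timepoints must be unique")
        for t in self.timepoints:
            if t not in self.rho_per_timepoint:
                raise DesignError(f"rho_per_timepoint missing timepoint {t!r}")
            rho = self.rho_per_timepoint[t]
            if not -1.0 <= rho <= 1.0:
                raise DesignError(f"rho at {t!r} must lie in [-1, 1], got {rho}")
        if self.effect_sd < 0 or self.noise_sd < 0:
            raise DesignError("effect_sd and noise_sd must be non-negative")
        lo, hi = self.baseline_range
        if not lo < hi:
            raise DesignError("baseline_range must be an increasing interval")

    @property
    def n_de(self) -> int:
        return round(self.de_fraction * self.n_probes)

    @property
    def n_de_b(self) -> int:
        if self.de_fraction_b is None:
            return self.n_de
        return round(self.de_fraction_b * self.n_probes)

    @property
    def n_samples(self) -> int:
        return self.n_control + 2 * self.n_per_group * len(self.timepoints)

    def replace(self, **kwargs) -> "SyntheticDesign":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TruthRecord:
    """Ground truth of a generated dataset.

    ``effects`` holds the injected log2 effect delta per probe for every
    (model, timepoint) cell; it is exactly zero for non-DE probes.
    ``realized_rho`` is the empirical Pearson correlation of the two
    models' effect vectors per timepoint, computed over the shared DE
    probes only.
    """

    de_flags: pd.Series
    de_flags_per_model: pd.DataFrame
    effects: pd.DataFrame  # columns: MultiIndex (model, timepoint)
    probe_to_gene: pd.Series
    realized_rho: dict[str, float]


def _probe_gene_map(design: SyntheticDesign) -> tuple[pd.Index, pd.Series]:
    """Assign probes to genes in blocks cycling the multiplicity pattern."""
    width = len(str(design.n_probes))
    probe_ids = pd.Index(
        [f"probe_{i + 1:0{width}d}" for i in range(design.n_probes)], name="probe_id"
    )
    genes: list[str] = []
    gene_idx = 0
    pattern = design.probes_per_gene_pattern
    while len(genes) < design.n_probes:
        mult = pattern[gene_idx % len(pattern)]
        gene_idx += 1
        genes.extend([f"Gene{gene_idx:0{width}d}"] * mult)
    return probe_ids, pd.Series(genes[: design.n_probes], index=probe_ids,
                                name="gene_symbol")


def _bivariate_effects(rng: np.random.Generator, n: int, sd: float,
                       rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Draw n pairs from a bivariate normal with common sd and correlation rho.

    Built from independent normals via the Cholesky factor so that
    rho = +/-1 is exact rather than numerically near-singular.
    """
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    a = sd * z1
    b = sd * (rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2)
    return a, b


def generate_dataset(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate an expression matrix with annotations and ground truth.

    Returns
    -------
    expression : DataFrame, probes x samples, log2 intensities.
    samples : DataFrame indexed by sample_id with ``class_label`` and
        ``timepoint`` columns (timepoint is NA for controls).
    probes : DataFrame indexed by probe_id with a ``gene_symbol`` column.
    truth : TruthRecord
    """
    rng = np.random.default_rng(design.seed)
    probe_ids, probe_to_gene = _probe_gene_map(design)

    mu = rng.uniform(*design.baseline_range, size=design.n_probes)

    # DE assignment: a random permutation; the first shared block responds
    # in both models, surplus probes of the larger set in one model only.
    n_a, n_b = design.n_de, design.n_de_b
    n_shared = min(n_a, n_b)
    order = rng.permutation(design.n_probes)
    idx_shared = order[:n_shared]
    idx_a_only = order[n_shared:n_a] if n_a > n_shared else order[:0]
    idx_b_only = order[n_shared:n_b] if n_b > n_shared else order[:0]

    cols = pd.MultiIndex.from_product(
        [MODELS, list(design.timepoints)], names=["model", "timepoint"]
    )
    effects = pd.DataFrame(0.0, index=probe_ids, columns=cols)
    realized_rho: dict[str, float] = {}
    for t in design.timepoints:
        rho = design.rho_per_timepoint[t]
        da, db = _bivariate_effects(rng, n_shared, design.effect_sd, rho)
        effects.loc[probe_ids[idx_shared], (MODEL_A, t)] = da
        effects.loc[probe_ids[idx_shared], (MODEL_B, t)] = db
        if len(idx_a_only):
            effects.loc[probe_ids[idx_a_only], (MODEL_A, t)] = (
                design.effect_sd * rng.standard_normal(len(idx_a_only))
            )
        if len(idx_b_only):
            effects.loc[probe_ids[idx_b_only], (MODEL_B, t)] = (
                design.effect_sd * rng.standard_normal(len(idx_b_only))
            )
        if n_shared >= 2 and design.effect_sd > 0:
            realized_rho[t] = float(np.corrcoef(da, db)[0, 1])
        else:
            realized_rho[t] = float("nan")

    # sample sheet: controls first, then (timepoint, model) cells
    sample_ids: list[str] = []
    class_labels: list[str] = []
    tp_labels: list[str | None] = []
    for i in range(design.n_control):
        sample_ids.append(f"ctrl_{i + 1:02d}")
        class_labels.append(CONTROL)
        tp_labels.append(None)
    for t in design.timepoints:
        for model, tag in ((MODEL_A, "A"), (MODEL_B, "B")):
            for i in range(design.n_per_group):
                sample_ids.append(f"{tag}_{t}_{i + 1:02d}")
                class_labels.append(model)
                tp_labels.append(t)
    samples = pd.DataFrame(
        {"class_label": class_labels, "timepoint": tp_labels},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    values = np.empty((design.n_probes, design.n_samples))
    values[:, : design.n_control] = mu[:, None]
    col = design.n_control
    for t in design.timepoints:
        for model in MODELS:
            delta = effects[(model, t)].to_numpy()
            values[:, col : col + design.n_per_group] = (mu + delta)[:, None]
            col += design.n_per_group
    values += rng.normal(0.0, design.noise_sd, size=values.shape)

    expression = pd.DataFrame(values, index=probe_ids,
                              columns=pd.Index(sample_ids, name="sample_id"))

    de_a = np.zeros(design.n_probes, dtype=bool)
    de_a[np.concatenate([idx_shared, idx_a_only])] = True
    de_b = np.zeros(design.n_probes, dtype=bool)
    de_b[np.concatenate([idx_shared, idx_b_only])] = True
    de_flags_per_model = pd.DataFrame({MODEL_A: de_a, MODEL_B: de_b},
                                      index=probe_ids)
    truth = TruthRecord(
        de_flags=pd.Series(de_a | de_b, index=probe_ids, name="is_de"),
        de_flags_per_model=de_flags_per_model,
        effects=effects,
        probe_to_gene=probe_to_gene,
        realized_rho=realized_rho,
    )
    probes = probe_to_gene.to_frame()
    return expression, samples, probes, truth


def write_dataset(
    outdir,
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    probes: pd.DataFrame,
    truth: TruthRecord | None = None,
) -> dict[str, str]:
    """Write the standard input files (matrix TSV, sample CSV, probe TSV)
    plus an optional truth table.  Returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(outdir / "expression.tsv"),
        "samples": str(outdir / "samples.csv"),
        "probes": str(outdir / "probes.tsv"),
    }
    expression.to_csv(paths["expression"], sep="\t")
    samples.to_csv(paths["samples"])
    probes.to_csv(paths["probes"], sep="\t")
    if truth is not None:
        flat = truth.effects.copy()
        flat.columns = [f"delta_{m}_{t}" for m, t in flat.columns]
        flat.insert(0, "gene_symbol", truth.probe_to_gene)
        flat.insert(1, "is_de", truth.de_flags)
        paths["truth"] = str(outdir / "truth.tsv")
        flat.to_csv(paths["truth"], sep="\t")
    return paths
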