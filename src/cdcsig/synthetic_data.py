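"""Synthetic bulk compendia, single-cell matrices and drug panels with planted truth.

Every downstream stage of the pipeline is exercised on data generated here, so
each generator plants a known structure and returns it in a :class:`SimTruth`
record:

* :func:`simulate_bulk_compendium` emulates several small tumor/normal bulk
  datasets sharing one gene space — per-dataset additive batch shifts on the
  log2 scale, a set of genes upregulated specifically in one tumor class
  (``tumorA``), a set shared by both tumor classes, and optionally a set
  downregulated in both tumors.
* :func:`simulate_single_cell` emulates a log-normalized single-cell matrix
  with discrete cell types, planted marker genes and Bernoulli dropout.
* :func:`simulate_cell_line_panel` emulates a cell-line panel whose drug
  response AUC is linearly coupled (negatively, for active compounds) to a
  latent per-line activity of a supplied gene signature.

All generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, GeneSet

__all__ = [
    "SimBulkConfig",
    "SimSingleCellConfig",
    "SimPanelConfig",
    "SimTruth",
    "simulate_bulk_compendium",
    "simulate_single_cell",
    "simulate_cell_line_panel",
]

CLASSES = ("tumorA", "tumorB", "normal")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated object.

    Only the fields relevant to the generator that produced it are filled.
    """

    gene_classes: pd.Series | None = None  # specific_up / shared_up / down / null
    sample_info: pd.DataFrame | None = None
    cell_types: pd.Series | None = None
    marker_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    compound_active: pd.Series | None = None
    latent_activity: pd.Series | None = None

    def genes_of_class(self, cls: str) -> list[str]:
        if self.gene_classes is None:
            raise ValueError("no gene class truth recorded")
        return list(self.gene_classes.index[self.gene_classes == cls])


# ---------------------------------------------------------------------------
# Bulk compendium
# ---------------------------------------------------------------------------

@dataclass
class SimBulkConfig:
    """Configuration of the multi-dataset bulk simulation.

    ``datasets`` maps each dataset name to samples-per-class over the labels
    tumorA / tumorB / normal. Fold changes are applied on the log2 scale before
    batch shifts and residual noise. In ``count_mode`` the log2 means are
    exponentiated into negative-binomial means with dispersion
    ``nb_dispersion`` (variance mu + phi mu^2).
    """

    n_genes: int = 2000
    datasets: Sequence[tuple[str, Mapping[str, int]]] = (
        ("d1", {"tumorA": 8, "tumorB": 5, "normal": 8}),
    )
    planted_specific_genes: int = 30
    specific_log2_fc: float = 2.0
    planted_shared_genes: int = 100
    shared_log2_fc: float = 2.0
    planted_down_genes: int = 0
    down_log2_fc: float = 2.0
    batch_sd: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    count_mode: bool = False
    nb_dispersion: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        n_planted = (
            self.planted_specific_genes
            + self.planted_shared_genes
            + self.planted_down_genes
        )
        if n_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        if min(self.planted_specific_genes, self.planted_shared_genes,
               self.planted_down_genes) < 0:
            raise ValueError("planted gene counts must be non-negative")
        for name, per_class in self.datasets:
            for cls, n in per_class.items():
                if cls not in CLASSES:
                    raise ValueError(f"unknown class {cls!r} in dataset {name!r}")
                if n < 0:
                    raise ValueError("negative sample count")


def simulate_bulk_compendium(
    config: SimBulkConfig,
) -> tuple[list[ExpressionMatrix | CountMatrix], SimTruth]:
    """Generate one matrix per configured dataset plus the planted truth.

    The planted gene classes (specific-up, shared-up, down) are disjoint by
    construction; all remaining genes are null.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")

    n_spec, n_shared, n_down = (
        config.planted_specific_genes,
        config.planted_shared_genes,
        config.planted_down_genes,
    )
    planted = rng.choice(config.n_genes, size=n_spec + n_shared + n_down, replace=False)
    spec_idx = planted[:n_spec]
    shared_idx = planted[n_spec:n_spec + n_shared]
    down_idx = planted[n_spec + n_shared:]

    gene_classes = pd.Series("null", index=genes, name="gene_class")
    gene_classes.iloc[spec_idx] = "specific_up"
    gene_classes.iloc[shared_idx] = "shared_up"
    gene_classes.iloc[down_idx] = "down"

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)

    # class-specific log2 offsets
    offsets = {cls: np.zeros(config.n_genes) for cls in CLASSES}
    offsets["tumorA"][spec_idx] += config.specific_log2_fc
    offsets["tumorA"][shared_idx] += config.shared_log2_fc
    offsets["tumorB"][shared_idx] += config.shared_log2_fc
    offsets["tumorA"][down_idx] -= config.down_log2_fc
    offsets["tumorB"][down_idx] -= config.down_log2_fc

    matrices: list[ExpressionMatrix | CountMatrix] = []
    infos = []
    for name, per_class in config.datasets:
        batch = (
            rng.normal(0.0, config.batch_sd, config.n_genes)
            if config.batch_sd > 0
            else np.zeros(config.n_genes)
        )
        cols, labels = [], []
        for cls in CLASSES:
            n = per_class.get(cls, 0)
            for i in range(n):
                cols.append(f"{name}_{cls}_{i + 1}")
                labels.append(cls)
        mean_log2 = np.column_stack(
            [baseline + offsets[cls] + batch for cls in labels]
        )
        noise = (
            rng.normal(0.0, config.noise_sd, mean_log2.shape)
            if config.noise_sd > 0
            else 0.0
        )
        info = pd.DataFrame(
            {"dataset": name, "class_label": labels}, index=pd.Index(cols, name="sample_id")
        )
        if config.count_mode:
            mu = 2.0 ** (mean_log2 + noise)
            phi = config.nb_dispersion
            if phi > 0:
                lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
            else:
                lam = mu
            vals = rng.poisson(lam).astype(np.int64)
            matrices.append(
                CountMatrix(pd.DataFrame(vals, index=genes, columns=cols), info)
            )
        else:
            matrices.append(
                ExpressionMatrix(
                    pd.DataFrame(mean_log2 + noise, index=genes, columns=cols), info
                )
            )
        infos.append(info)

    truth = SimTruth(gene_classes=gene_classes, sample_info=pd.concat(infos))
    return matrices, truth


# ---------------------------------------------------------------------------
# Single cell
# ---------------------------------------------------------------------------

@dataclass
class SimSingleCellConfig:
    """Configuration for the single-cell simulation.

    ``cell_types`` is a list of (name, n_cells, n_markers, marker log2 effect).
    Marker sets are disjoint across types. Dropout is independent Bernoulli
    zeroing applied after expression generation.
    """

    n_genes: int = 2000
    cell_types: Sequence[tuple[str, int, int, float]] = (
        ("typeA", 100, 50, 2.0),
        ("typeB", 100, 50, 2.0),
        ("typeC", 100, 50, 2.0),
    )
    dropout_rate: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        total_markers = sum(t[2] for t in self.cell_types)
        if total_markers > self.n_genes:
            raise ValueError("marker requests exceed n_genes")


def simulate_single_cell(
    config: SimSingleCellConfig,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate a log-normalized-style gene-by-cell matrix with planted markers."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")

    total_markers = sum(t[2] for t in config.cell_types)
    marker_pool = rng.choice(config.n_genes, size=total_markers, replace=False)
    marker_sets: dict[str, tuple[str, ...]] = {}
    pos = 0
    for name, _n, n_markers, _eff in config.cell_types:
        idx = marker_pool[pos:pos + n_markers]
        marker_sets[name] = tuple(genes[idx])
        pos += n_markers

    baseline = rng.uniform(0.5, 2.0, config.n_genes)
    cols, types = [], []
    blocks = []
    for name, n_cells, n_markers, effect in config.cell_types:
        mean = baseline.copy()
        if n_markers:
            idx = genes.get_indexer(marker_sets[name])
            mean[idx] += effect
        block = mean[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, n_cells))
        blocks.append(block)
        cols += [f"{name}_c{i + 1}" for i in range(n_cells)]
        types += [name] * n_cells

    vals = np.concatenate(blocks, axis=1)
    np.clip(vals, 0.0, None, out=vals)
    if config.dropout_rate > 0:
        keep = rng.random(vals.shape) >= config.dropout_rate
        vals = vals * keep

    info = pd.DataFrame(
        {"class_label": types}, index=pd.Index(cols, name="cell_id")
    )
    matrix = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols), info)
    truth = SimTruth(
        cell_types=info["class_label"].rename("cell_type"),
        marker_sets=marker_sets,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Cell-line drug panel
# ---------------------------------------------------------------------------

@dataclass
class SimPanelConfig:
    """Configuration for the cell-line panel / drug-response simulation.

    Each cell line carries a latent standard-normal signature activity; the
    expression of signature genes is shifted by ``expression_effect`` times
    that activity. Active compounds couple their AUC linearly to the activity
    with coefficient ``slope`` (negative = signature-high lines are more
    sensitive); inert compounds are independent of it. AUC is clipped to [0, 1].
    """

    n_cell_lines: int = 200
    n_compounds: int = 100
    n_active_compounds: int = 20
    slope: float = -0.5
    auc_noise_sd: float = 0.05
    auc_baseline: float = 0.5
    expression_effect: float = 1.0
    n_genes: int = 2000
    noise_sd: float = 0.5
    seed: int = 0
    activity_seed: int | None = None  # share the active-compound truth across panels

    def validate(self) -> None:
        if not 0 <= self.n_active_compounds <= self.n_compounds:
            raise ValueError("need 0 <= n_active_compounds <= n_compounds")
        if self.n_cell_lines < 2:
            raise ValueError("need >= 2 cell lines")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")


def simulate_cell_line_panel(
    config: SimPanelConfig, signature: GeneSet
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Generate (expression matrix, compound-by-line AUC table, truth).

    The generated gene space contains all signature genes; remaining
    identifiers are filled from a generic pool. Raises on an empty signature.
    """
    config.validate()
    if len(signature) == 0:
        raise ValueError("empty signature")
    if len(signature) > config.n_genes:
        raise ValueError("signature larger than the generated gene space")
    rng = np.random.default_rng(config.seed)

    sig_genes = list(signature.genes)
    n_fill = config.n_genes - len(sig_genes)
    fill = [f"bg{i:05d}" for i in range(n_fill)]
    genes = pd.Index(sig_genes + fill, name="gene_id")
    lines = pd.Index(
        [f"line{i + 1:04d}" for i in range(config.n_cell_lines)], name="cell_line"
    )

    activity = rng.normal(0.0, 1.0, config.n_cell_lines)
    baseline = rng.normal(7.0, 1.0, config.n_genes)
    vals = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, (config.n_genes, config.n_cell_lines)
    )
    vals[: len(sig_genes), :] += config.expression_effect * activity[None, :]
    expr = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=lines))

    compounds = pd.Index(
        [f"cmpd{i + 1:03d}" for i in range(config.n_compounds)], name="compound"
    )
    rng_active = (
        rng if config.activity_seed is None
        else np.random.default_rng(config.activity_seed)
    )
    active_idx = rng_active.choice(
        config.n_compounds, size=config.n_active_compounds, replace=False
    )
    active = pd.Series(False, index=compounds, name="active")
    active.iloc[active_idx] = True

    auc = config.auc_baseline + rng.normal(
        0.0, config.auc_noise_sd, (config.n_compounds, config.n_cell_lines)
    )
    auc[active.to_numpy(), :] += config.slope * activity[None, :]
    np.clip(auc, 0.0, 1.0, out=auc)
    responses = pd.DataFrame(auc, index=compounds, columns=lines)

    truth = SimTruth(
        compound_active=active,
        latent_activity=pd.Series(activity, index=lines, name="activity"),
    )
    return expr, responses, truth
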