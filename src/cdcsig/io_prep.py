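"""Reading/writing standard formats and all normalization / merging transforms.

Count normalization follows the standard RNA-seq toolchain: between-library
scaling by the trimmed mean of M-values (TMM), counts-per-million (optionally
log2 with a prior count), and FPKM when gene lengths are available. Cross-
dataset integration standardizes each gene within each dataset (z-score) and
then quantile-normalizes the merged matrix, which removes additive per-dataset
shifts while preserving within-sample rank order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotations",
    "read_gmt",
    "write_gmt",
    "collapse_features",
    "tmm_factors",
    "cpm",
    "fpkm",
    "quantile_normalize",
    "zscore_genes",
    "merge_datasets",
]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path,
    counts: bool = False,
    sample_info: pd.DataFrame | None = None,
) -> ExpressionMatrix | CountMatrix:
    """Read a tab-separated gene-by-sample matrix.

    First column holds gene identifiers, header row holds sample identifiers.
    Duplicate gene rows are rejected — collapsing features to genes must be an
    explicit :func:`collapse_features` call.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()[0]
        raise ValueError(f"duplicate gene row {dup!r} in {path}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric values in columns {non_numeric[:3]}")
    if counts:
        return CountMatrix(df, sample_info)
    return ExpressionMatrix(df, sample_info)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV with columns sample_id, dataset, class."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "dataset", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file needs columns {sorted(required)}")
    df = df.set_index("sample_id").rename(columns={"class": "class_label"})
    return df


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, then genes, tab-separated).

    Duplicate genes within a set are dropped; the total number dropped is
    logged as a warning. A line with fewer than three fields is an error.
    """
    sets = []
    n_dupes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            n_dupes += len(genes) - len(unique)
            sets.append(GeneSet(name, tuple(unique), desc))
    if n_dupes:
        logger.warning("read_gmt: dropped %d duplicate genes within sets", n_dupes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection | Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Feature collapse
# ---------------------------------------------------------------------------

def collapse_features(
    matrix: ExpressionMatrix, feature_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe/transcript rows to genes by the MaxMean rule.

    For each gene the single feature row with the highest mean across samples
    is retained; ties go to the lexicographically smaller feature identifier.
    Every matrix row must appear in the map.
    """
    unmapped = [f for f in matrix.genes if f not in feature_to_gene]
    if unmapped:
        raise ValueError(f"features without gene mapping: {unmapped[:5]}")
    means = matrix.values.mean(axis=1)
    frame = pd.DataFrame(
        {
            "feature": matrix.genes,
            "gene": [feature_to_gene[f] for f in matrix.genes],
            "mean": means.to_numpy(),
        }
    )
    # highest mean wins; ties resolved by feature id (ascending)
    frame = frame.sort_values(["gene", "mean", "feature"], ascending=[True, False, True])
    winners = frame.drop_duplicates("gene", keep="first")
    out = matrix.values.loc[winners["feature"]]
    out.index = winners["gene"].to_numpy()
    out = out.sort_index()
    return ExpressionMatrix(out, matrix.sample_info)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Weighted doubly-trimmed mean of M-values for one sample pair.

    Genes with a zero count in either library are excluded. Weights are the
    inverse of the asymptotic (delta-method) variance of each gene's M value.
    """
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if obs.size == 0:
        raise ValueError("no gene with positive count in both libraries")
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = 1.0 / ((n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref))

    if np.max(np.abs(m)) < 1e-10:  # identical proportions
        return 1.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n - np.floor(n * trim_m)
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n - np.floor(n * trim_a)
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    return float(2.0 ** f)


def tmm_factors(
    counts: CountMatrix,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference library defaults to the sample whose upper-quartile CPM is
    closest to the panel mean of upper quartiles.
    """
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib == 0).any():
        bad = counts.samples[lib == 0][0]
        raise ValueError(f"all-zero sample {bad!r}")
    vals = counts.values.to_numpy(dtype=float)

    if reference is None:
        uq = np.array(
            [np.quantile(vals[:, j] / lib[j], 0.75) for j in range(vals.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.samples.get_loc(reference)

    factors = np.ones(counts.n_samples)
    ref_col = vals[:, ref_idx]
    for j in range(counts.n_samples):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(vals[:, j], ref_col, lib[j], lib[ref_idx], trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.samples, name="norm_factor")


# ---------------------------------------------------------------------------
# CPM / FPKM
# ---------------------------------------------------------------------------

def cpm(
    counts: CountMatrix,
    log: bool = False,
    prior_count: float = 0.5,
    lib_offset: float = 1.0,
) -> ExpressionMatrix:
    """Counts per million over TMM-effective library sizes.

    In log mode a prior count of ``prior_count`` is added to each count and
    ``lib_offset`` to each effective library size before log2 (the voom-style
    transform).
    """
    eff = counts.library_sizes.to_numpy(dtype=float) * counts.norm_factors.to_numpy()
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    vals = counts.values.to_numpy(dtype=float)
    if log:
        out = np.log2((vals + prior_count) / (eff + lib_offset) * 1e6)
    else:
        out = vals / eff * 1e6
    return ExpressionMatrix(
        pd.DataFrame(out, index=counts.genes, columns=counts.samples),
        counts.sample_info,
    )


def fpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million: count / (kb * lib/1e6)."""
    if counts.gene_lengths is None:
        raise ValueError("gene_lengths (kb) required for FPKM")
    if counts.gene_lengths.isna().any():
        missing = counts.genes[counts.gene_lengths.isna()][:5]
        raise ValueError(f"missing gene lengths for {list(missing)}")
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    kb = counts.gene_lengths.to_numpy(dtype=float)
    vals = counts.values.to_numpy(dtype=float)
    out = vals / (kb[:, None] * (lib[None, :] / 1e6))
    return ExpressionMatrix(
        pd.DataFrame(out, index=counts.genes, columns=counts.samples),
        counts.sample_info,
    )


# ---------------------------------------------------------------------------
# Quantile normalization / z-scoring / merging
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Map every sample onto the mean of the per-sample order statistics.

    Ties within a sample receive the mean of the reference values their block
    spans, so the transform is deterministic and within-sample rank order is
    preserved.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    vals = matrix.values.to_numpy(dtype=float)
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average assigned reference values over tied input blocks
        s = pd.Series(assigned).groupby(col).transform("mean")
        out[:, j] = s.to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.genes, columns=matrix.samples),
        matrix.sample_info,
    )


def zscore_genes(
    matrix: ExpressionMatrix, by_dataset: bool = False
) -> ExpressionMatrix:
    """Standardize each gene to mean 0 / sd 1 across samples.

    With ``by_dataset`` the standardization is stratified by the ``dataset``
    annotation. Uses the sample (n-1) standard deviation. Zero-variance genes
    are set to 0; their count is logged.
    """
    if by_dataset:
        if matrix.sample_info is None or "dataset" not in matrix.sample_info:
            raise ValueError("by_dataset requires a 'dataset' annotation")
        strata = [
            matrix.samples[matrix.sample_info["dataset"] == d]
            for d in matrix.sample_info["dataset"].unique()
        ]
    else:
        strata = [matrix.samples]

    out = matrix.values.astype(float).copy()
    n_flat = 0
    for cols in strata:
        if len(cols) < 2:
            raise ValueError("standardization stratum of size 1")
        block = out.loc[:, cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        flat = sd == 0
        n_flat += int(flat.sum())
        sd = sd.replace(0.0, 1.0)
        out.loc[:, cols] = block.sub(mu, axis=0).div(sd, axis=0)
        out.loc[flat, cols] = 0.0
    if n_flat:
        logger.warning("zscore_genes: %d zero-variance gene/stratum pairs set to 0", n_flat)
    return ExpressionMatrix(out, matrix.sample_info)


def merge_datasets(
    matrices: Sequence[ExpressionMatrix],
    names: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Merge datasets on the intersection of their gene spaces.

    Each dataset is gene-wise z-scored, the blocks are concatenated, and the
    merged matrix is quantile-normalized. Dataset provenance is kept in the
    sample annotations.
    """
    if len(matrices) < 2:
        raise ValueError("need >= 2 datasets to merge")
    common = matrices[0].genes
    for m in matrices[1:]:
        common = common.intersection(m.genes)
    if len(common) == 0:
        raise ValueError("empty gene intersection across datasets")
    common = common.sort_values()

    if names is None:
        names = []
        for i, m in enumerate(matrices):
            if m.sample_info is not None and "dataset" in m.sample_info:
                names.append(str(m.sample_info["dataset"].iloc[0]))
            else:
                names.append(f"dataset{i + 1}")

    blocks, infos = [], []
    for m, name in zip(matrices, names):
        z = zscore_genes(m.subset_genes(common))
        blocks.append(z.values)
        info = (
            m.sample_info.copy()
            if m.sample_info is not None
            else pd.DataFrame(index=m.samples)
        )
        info["dataset"] = name
        infos.append(info)
    merged = ExpressionMatrix(pd.concat(blocks, axis=1), pd.concat(infos, axis=0))
    return quantile_normalize(merged)
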