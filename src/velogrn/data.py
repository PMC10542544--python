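"""Core containers and shared preprocessing.

Raw UMI counts are depth-normalized per cell and then scaled per gene so no
gene has variance above one: genes whose variance exceeds their squared
interquartile range are divided by their standard deviation, genes below it by
their IQR (robust to heavy tails), and genes with zero IQR are left unscaled.
Zero-variance genes carry no information and are dropped.

The module also handles the binary TF->gene prior-knowledge network and the
two kinds of holdout the modeling stack needs: a cell-level train/validation
split and a gene-level holdout of prior-network rows for network scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "RawCounts",
    "ExpressionMatrix",
    "PriorNetwork",
    "DataSplit",
    "standardize_counts",
    "load_counts",
    "save_counts",
    "load_prior_network",
    "write_prior_network",
    "split_cells",
    "holdout_prior_genes",
]


@dataclass
class RawCounts:
    """Cells x genes nonnegative integer UMI counts with per-cell metadata."""

    Z: np.ndarray
    gene_ids: list[str]
    cell_meta: pd.DataFrame = None

    def __post_init__(self):
        if sp.issparse(self.Z):
            self.Z = np.asarray(self.Z.todense())
        self.Z = np.asarray(self.Z)
        if self.Z.ndim != 2 or self.Z.shape[0] < 1 or self.Z.shape[1] < 1:
            raise ValueError("count matrix must be 2-D and non-empty")
        if np.any(self.Z < 0) or not np.allclose(self.Z, np.round(self.Z)):
            raise ValueError("counts must be nonnegative integers")
        self.gene_ids = list(self.gene_ids)
        if len(self.gene_ids) != self.Z.shape[1]:
            raise ValueError("gene_ids length must match gene dimension")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(
                {"pool_id": np.zeros(self.Z.shape[0], dtype=int)}
            )
        if "pool_id" not in self.cell_meta.columns:
            raise ValueError("cell_meta must contain a pool_id column")
        if len(self.cell_meta) != self.Z.shape[0]:
            raise ValueError("cell_meta length must match cell dimension")

    @property
    def n_cells(self) -> int:
        return self.Z.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Z.shape[1]


@dataclass
class ExpressionMatrix:
    """Depth- and variance-standardized expression (cells x kept genes)."""

    X: np.ndarray
    gene_ids: list[str]
    depth_target: float
    gene_scale: np.ndarray
    kept_genes: np.ndarray  # indices into the original gene order

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]


@dataclass
class PriorNetwork:
    """Binary genes x TFs prior-knowledge matrix."""

    P: np.ndarray
    gene_ids: list[str]
    tf_ids: list[str]

    def __post_init__(self):
        self.P = np.asarray(self.P)
        if not np.isin(self.P, (0, 1)).all():
            raise ValueError("prior network entries must be binary")
        if len(self.tf_ids) != len(set(self.tf_ids)):
            raise ValueError("tf_ids must be unique")
        if self.P.shape != (len(self.gene_ids), len(self.tf_ids)):
            raise ValueError("P shape must be (genes, TFs)")
        if len(self.tf_ids) < 1:
            raise ValueError("at least one TF required")

    @property
    def k(self) -> int:
        return self.P.shape[1]

    @property
    def edge_count(self) -> int:
        return int(self.P.sum())


@dataclass
class DataSplit:
    """Disjoint, exhaustive train/validation cell index sets."""

    train_idx: np.ndarray
    validation_idx: np.ndarray
    seed: int
    fraction: float


def _depth_scale(Z: np.ndarray, depth_target) -> tuple[np.ndarray, float]:
    sums = Z.sum(axis=1)
    if np.any(sums == 0):
        bad = int(np.where(sums == 0)[0][0])
        raise ValueError(f"cell {bad} has zero total counts")
    if depth_target == "median":
        depth_target = float(np.median(sums))
    depth_target = float(depth_target)
    return Z * (depth_target / sums)[:, None], depth_target


def standardize_counts(Z, depth_target="median") -> ExpressionMatrix:
    """Depth-normalize cells, then scale genes so that variance <= 1.

    Parameters
    ----------
    Z
        `RawCounts`, or any nonnegative cells x genes array (gene labels are
        then synthesized). Real-valued input is accepted so the operation can
        be re-applied to its own output.
    depth_target
        Counts per cell after depth scaling. ``"median"`` (default) uses the
        median per-cell sum of the input; ``None`` skips depth scaling
        entirely (the input is taken as already depth-normalized).
    """
    if isinstance(Z, RawCounts):
        M = Z.Z.astype(float)
        gene_ids = list(Z.gene_ids)
    else:
        M = np.asarray(Z, dtype=float)
        gene_ids = [f"gene_{i}" for i in range(M.shape[1])]
    if M.size == 0:
        raise ValueError("empty matrix")
    if np.any(M < 0):
        raise ValueError("negative entries in expression input")

    if depth_target is None:
        X = M.copy()
        target = float(np.median(M.sum(axis=1)))
    else:
        X, target = _depth_scale(M, depth_target)

    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    q1, q3 = np.percentile(X, [25, 75], axis=0)
    iqr = q3 - q1

    keep = var > 0
    scale = np.ones_like(var)
    # var >= IQR^2 -> sd; var < IQR^2 -> IQR; IQR == 0 -> unscaled
    zero_iqr = iqr == 0
    sd_branch = (~zero_iqr) & (var >= iqr**2)
    iqr_branch = (~zero_iqr) & (var < iqr**2)
    scale[sd_branch] = np.sqrt(var[sd_branch])
    scale[iqr_branch] = iqr[iqr_branch]
    # already-standardized genes (scale within tolerance of 1) stay untouched
    scale[np.abs(scale - 1.0) < 1e-12] = 1.0

    kept = np.where(keep)[0]
    return ExpressionMatrix(
        X=X[:, kept] / scale[kept],
        gene_ids=[gene_ids[i] for i in kept],
        depth_target=target,
        gene_scale=scale[kept],
        kept_genes=kept,
    )


def load_counts(path, meta_path=None) -> RawCounts:
    """Read a cells x genes count matrix with optional cell metadata.

    ``path`` is either a matrix-market ``.mtx`` file (with ``barcodes.tsv``
    and ``features.tsv`` next to it holding cell and gene labels) or a dense
    TSV with cells as rows, gene labels in the header and cell barcodes in
    the first column. ``meta_path`` points to a metadata TSV keyed by
    barcode; without one, all cells fall into pool 0.
    """
    import os

    from scipy.io import mmread

    path = os.fspath(path)
    if path.endswith(".mtx"):
        Z = np.asarray(mmread(path).todense())
        base = os.path.dirname(path)
        barcodes = pd.read_csv(
            os.path.join(base, "barcodes.tsv"), sep="\t", header=None
        )[0].tolist()
        genes = pd.read_csv(
            os.path.join(base, "features.tsv"), sep="\t", header=None
        )[0].tolist()
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        Z = df.to_numpy()
        barcodes = [str(b) for b in df.index]
        genes = [str(g) for g in df.columns]
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        meta = meta.loc[[str(b) for b in barcodes]].reset_index(drop=True)
    counts = RawCounts(Z=Z.astype(int), gene_ids=genes, cell_meta=meta)
    counts.cell_meta.index = pd.Index(barcodes, name="barcode")
    return counts


def save_counts(counts: RawCounts, path, meta_path=None) -> None:
    """Write counts as a dense TSV (and metadata TSV); mirror of the reader."""
    barcodes = [str(b) for b in counts.cell_meta.index]
    if len(set(barcodes)) != len(barcodes):
        barcodes = [f"cell_{i}" for i in range(counts.n_cells)]
    pd.DataFrame(counts.Z, index=barcodes, columns=counts.gene_ids).to_csv(
        path, sep="\t"
    )
    if meta_path is not None:
        meta = counts.cell_meta.copy()
        meta.index = pd.Index(barcodes, name="barcode")
        meta.to_csv(meta_path, sep="\t")


def load_prior_network(path, gene_ids) -> PriorNetwork:
    """Read a TF->gene prior from a TSV edge list or dense binary table.

    Edge lists have two columns (tf, gene); dense tables are genes x TFs with
    gene labels in the first column and TF labels in the header. Rows for
    genes absent from the file are all-zero; duplicate edges collapse to 1.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    gene_ids = list(gene_ids)
    if df.shape[1] == 2 and not _looks_dense(df):
        edges = df.rename(columns={0: "tf", 1: "gene"})
        if edges["tf"].isna().any() or (edges["tf"].str.len() == 0).any():
            raise ValueError("empty TF column in edge list")
        tf_ids = sorted(edges["tf"].unique())
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        tf_pos = {t: j for j, t in enumerate(tf_ids)}
        P = np.zeros((len(gene_ids), len(tf_ids)), dtype=int)
        for tf, gene in edges.itertuples(index=False):
            if gene in gene_pos:
                P[gene_pos[gene], tf_pos[tf]] = 1
        return PriorNetwork(P=P, gene_ids=gene_ids, tf_ids=tf_ids)
    # dense table with header
    dense = pd.read_csv(path, sep="\t", index_col=0)
    vals = dense.to_numpy(dtype=float)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("dense prior table must be binary")
    dense = dense.reindex(gene_ids, fill_value=0)
    return PriorNetwork(
        P=dense.to_numpy(dtype=int),
        gene_ids=gene_ids,
        tf_ids=list(dense.columns),
    )


def _looks_dense(df: pd.DataFrame) -> bool:
    # a 2-column file whose second row parses as 0/1 is a (tiny) dense table
    try:
        tail = df.iloc[1:, 1:].to_numpy(dtype=float)
    except ValueError:
        return False
    return np.isin(tail, (0, 1)).all() and df.shape[0] > 1


def write_prior_network(prior: PriorNetwork, path) -> None:
    """Write the dense genes x TFs table; exact round-trip partner of the reader."""
    pd.DataFrame(prior.P, index=prior.gene_ids, columns=prior.tf_ids).to_csv(
        path, sep="\t"
    )


def split_cells(n: int, fraction: float, seed: int) -> DataSplit:
    """Seeded disjoint train/validation split of ``n`` cells."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_val = int(np.clip(round(n * fraction), 1, n - 1))
    perm = rng.permutation(n)
    return DataSplit(
        train_idx=np.sort(perm[n_val:]),
        validation_idx=np.sort(perm[:n_val]),
        seed=seed,
        fraction=fraction,
    )


def holdout_prior_genes(
    P: PriorNetwork, fraction: float, seed: int
) -> tuple[PriorNetwork, np.ndarray]:
    """Withhold a fraction of edge-bearing genes' prior rows for evaluation.

    Returns the training prior (held rows zeroed) and the held gene indices,
    which form the evaluation universe for network scoring.
    """
    edge_genes = np.where(P.P.sum(axis=1) > 0)[0]
    if len(edge_genes) < 4:
        raise ValueError("need at least 4 genes with prior edges")
    n_held = round(fraction * len(edge_genes))
    if n_held < 1:
        raise ValueError("fraction leaves zero held-out genes")
    rng = np.random.default_rng(seed)
    held = np.sort(rng.choice(edge_genes, size=n_held, replace=False))
    P_train = P.P.copy()
    P_train[held, :] = 0
    return (
        PriorNetwork(P=P_train, gene_ids=list(P.gene_ids), tf_ids=list(P.tf_ids)),
        held,
    )
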