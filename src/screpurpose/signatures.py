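"""Disease-side inputs: cell annotations and per-cluster differential-expression signatures.

The query side of signature-reversal drug repurposing is a per-cluster table of
differentially expressed (DE) genes (log2 fold change, p, BH-adjusted p) together
with the cell annotation table that supplies cluster membership, condition labels
and the cellular proportions used by the multi-cluster drug score. DE tables are
normally produced by an external method (Limma, DESeq2, edgeR, a Wilcoxon
rank-sum test on log-normalized counts, ...) and imported; a convenience
rank-sum DE test is provided for self-contained runs on raw counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reversal import bh_adjust

CONDITIONS = ("disease", "control")

CELL_TABLE_COLUMNS = ["cell_id", "sample_id", "condition", "cluster_id", "cell_type"]
SIGNATURE_COLUMNS = ["gene", "logFC", "p", "adj_p"]

UNASSIGNED = "unassigned"


@dataclass
class CellTable:
    """Per-cell annotations: sample, condition ({disease, control}), cluster, cell type."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cell table missing columns: {missing}")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValueError(f"duplicate cell: {dup!r}")
        bad = ~df["condition"].isin(CONDITIONS)
        if bad.any():
            raise ValueError(f"bad condition: {df.loc[bad, 'condition'].iloc[0]!r}")
        if len(df) and (df["cluster_id"].astype(str).str.len() == 0).any():
            raise ValueError("empty cluster_id")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def clusters(self) -> list[str]:
        return sorted(self.df["cluster_id"].unique())

    def disease_counts(self) -> pd.Series:
        """Number of disease-condition cells per cluster."""
        d = self.df[self.df["condition"] == "disease"]
        return d.groupby("cluster_id").size()

    def subset(self, mask: pd.Series) -> "CellTable":
        return CellTable(self.df[mask].reset_index(drop=True))


@dataclass
class ClusterSignature:
    """Per-cluster DE table; genes unique, adj_p >= p enforced at construction."""

    cluster_id: str
    n_disease_cells: int
    table: pd.DataFrame  # columns gene, logFC, p, adj_p

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SIGNATURE_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"signature missing columns: {missing}")
        t = t.copy()
        t["gene"] = t["gene"].astype(str).str.upper()
        if t["gene"].duplicated().any():
            dup = t.loc[t["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene: {dup!r}")
        if not np.isfinite(t["logFC"].to_numpy(float)).all():
            raise ValueError("non-finite logFC")
        p = t["p"].to_numpy(float)
        q = t["adj_p"].to_numpy(float)
        if ((p < 0) | (p > 1) | (q < 0) | (q > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        # adj_p below p is impossible for any valid adjustment; tolerate tiny float slack
        if (q < p - 1e-12).any():
            raise ValueError("inconsistent adjustment: adj_p < p")
        self.table = t.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DiseaseRankList:
    """Total order over the shared gene universe; rank 1 = most up-regulated in disease."""

    cluster_id: str
    ranks: dict[str, int]
    G: int = field(init=False)

    def __post_init__(self) -> None:
        self.G = len(self.ranks)
        if sorted(self.ranks.values()) != list(range(1, self.G + 1)):
            raise ValueError("ranks are not a permutation of 1..G")


def read_cell_table(path: str | Path) -> CellTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    return CellTable(df[CELL_TABLE_COLUMNS])


def write_cell_table(cells: CellTable, path: str | Path) -> None:
    cells.df.to_csv(path, sep="\t", index=False)


def read_cluster_signature(
    path: str | Path, cluster_id: str, n_disease_cells: int = 0
) -> ClusterSignature:
    df = pd.read_csv(path, sep="\t")
    return ClusterSignature(cluster_id, n_disease_cells, df[SIGNATURE_COLUMNS])


def read_signatures(path: str | Path, cells: CellTable | None = None) -> list[ClusterSignature]:
    """Read per-cluster DE tables.

    `path` is either a directory of `<cluster_id>.tsv` files, or one TSV with a
    `cluster_id` column. Disease-cell counts are filled from `cells` when given.
    """
    counts = cells.disease_counts() if cells is not None else pd.Series(dtype=int)
    path = Path(path)
    sigs: list[ClusterSignature] = []
    if path.is_dir():
        for f in sorted(path.glob("*.tsv")):
            cid = f.stem
            sigs.append(read_cluster_signature(f, cid, int(counts.get(cid, 0))))
    else:
        df = pd.read_csv(path, sep="\t")
        if "cluster_id" not in df.columns:
            raise ValueError("combined signature file requires a cluster_id column")
        for cid, sub in df.groupby("cluster_id", sort=True):
            cid = str(cid)
            sigs.append(
                ClusterSignature(cid, int(counts.get(cid, 0)), sub[SIGNATURE_COLUMNS])
            )
    return sigs


def write_cluster_signature(sig: ClusterSignature, path: str | Path) -> None:
    sig.table.to_csv(path, sep="\t", index=False)


def filter_significant(
    sig: ClusterSignature, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Split a signature into significantly up- and down-regulated disease genes.

    Returns ``(up, down)`` where up = {adj_p < alpha, logFC > 0} and
    down = {adj_p < alpha, logFC < 0}; genes with logFC exactly 0 are excluded.
    ``|up| + |down|`` is the cluster's count of significantly deregulated genes.
    """
    t = sig.table
    sig_mask = t["adj_p"].to_numpy(float) < alpha
    lfc = t["logFC"].to_numpy(float)
    up = set(t.loc[sig_mask & (lfc > 0), "gene"])
    down = set(t.loc[sig_mask & (lfc < 0), "gene"])
    return up, down


def to_rank_list(sig: ClusterSignature, universe: Iterable[str]) -> DiseaseRankList:
    """Order the signature genes shared with the reference universe.

    Sort key: decreasing logFC, ties broken by increasing p, then by gene symbol;
    rank 1 is the most disease-up-regulated gene.
    """
    universe = {g.upper() for g in universe}
    t = sig.table[sig.table["gene"].isin(universe)]
    if t.empty:
        raise ValueError("disjoint gene universes")
    t = t.sort_values(
        by=["logFC", "p", "gene"], ascending=[False, True, True], kind="mergesort"
    )
    ranks = {g: i + 1 for i, g in enumerate(t["gene"])}
    return DiseaseRankList(sig.cluster_id, ranks)


def cluster_proportions(
    cells: CellTable, selected: Iterable[str] | None = None
) -> dict[str, float]:
    """Proportion of all disease cells that fall in each selected cluster.

    The denominator is the total number of disease cells in the table, even when
    only a subset of clusters is selected, so proportions of a subset do not
    renormalize to 1.
    """
    counts = cells.disease_counts()
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no diseased cells")
    if selected is None:
        selected = list(counts.index)
    selected = list(selected)
    if not selected:
        raise ValueError("no clusters selected")
    return {k: float(counts.get(k, 0)) / total for k in selected}


def annotate_majority(cells: CellTable) -> dict[str, str]:
    """Assign each cluster the cell type covering strictly more than half its cells."""
    out: dict[str, str] = {}
    for cid, sub in cells.df.groupby("cluster_id"):
        types = sub["cell_type"].replace("", np.nan).dropna()
        if types.empty:
            out[str(cid)] = UNASSIGNED
            continue
        counts = types.value_counts()
        if counts.iloc[0] * 2 > len(sub):
            out[str(cid)] = str(counts.index[0])
        else:
            out[str(cid)] = UNASSIGNED
    return out


def pseudobulk_signature(
    counts: pd.DataFrame, cells: CellTable
) -> tuple[pd.Series, pd.Series]:
    """Per-gene mean expression across all cells of each condition.

    Emulates bulk expression from single-cell data ("pseudo-bulk") so the sample
    can feed bulk-style comparisons. Returns ``(disease_mean, control_mean)``.
    """
    out = []
    for cond in CONDITIONS:
        ids = cells.df.loc[cells.df["condition"] == cond, "cell_id"]
        ids = [c for c in ids if c in counts.columns]
        if not ids:
            raise ValueError(f"empty condition: {cond}")
        out.append(counts[ids].mean(axis=1))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Convenience DE test


def _normalize_log(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    lib = counts.sum(axis=0)
    lib[lib == 0] = 1.0
    return np.log2(counts / lib * target_sum + 1.0)


def _ranksum_p(x: np.ndarray, y: np.ndarray, exact_max_total: int = 14) -> float:
    """Two-sided rank-sum p; exact by enumeration over label assignments for small n.

    The exact path conditions on the observed (possibly tied) pooled values and
    enumerates every assignment of group labels, so ties need no special casing.
    The large-sample path uses the tie-corrected normal approximation.
    """
    from scipy.stats import rankdata, norm

    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    if n + m <= exact_max_total:
        count = 0
        total = 0
        for idx in combinations(range(n + m), n):
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
                count += 1
            total += 1
        return count / total
    # tie-corrected variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n + m) * (n + m - 1))
    var = n * m / 12.0 * ((n + m + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (w_obs - mu) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_de(
    counts: pd.DataFrame, cells: CellTable, cluster_id: str
) -> ClusterSignature:
    """Disease-vs-control rank-sum DE within one cluster on normalized counts.

    Counts are library-size normalized to 10,000 per cell and log2(x+1)
    transformed; logFC is the difference of group means on that log scale and
    p-values are BH-adjusted across all genes.
    """
    sub = cells.df[cells.df["cluster_id"] == cluster_id]
    d_ids = [c for c in sub.loc[sub["condition"] == "disease", "cell_id"] if c in counts.columns]
    c_ids = [c for c in sub.loc[sub["condition"] == "control", "cell_id"] if c in counts.columns]
    if len(d_ids) < 2 or len(c_ids) < 2:
        raise ValueError("insufficient cells")
    mat = _normalize_log(counts[d_ids + c_ids].to_numpy(float))
    nd = len(d_ids)
    lfc = mat[:, :nd].mean(axis=1) - mat[:, nd:].mean(axis=1)
    pvals = np.array([_ranksum_p(row[:nd], row[nd:]) for row in mat])
    adj = bh_adjust(pvals)
    table = pd.DataFrame(
        {"gene": counts.index.astype(str), "logFC": lfc, "p": pvals, "adj_p": adj}
    )
    return ClusterSignature(cluster_id, nd, table)


def read_counts_mtx(
    mtx_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> pd.DataFrame:
    """Load a MatrixMarket count matrix with gene/barcode sidecar lists."""
    from scipy.io import mmread

    mat = np.asarray(mmread(str(mtx_path)).todense(), dtype=float)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    return pd.DataFrame(mat, index=genes, columns=cells)
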