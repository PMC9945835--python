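"""Drug-perturbation reference: per-treatment-instance gene rank lists.

One treatment instance is a single perturbation profile (drug x cell line x
condition) summarized as a rank permutation over the shared gene universe,
with rank 1 the gene most up-regulated by the treatment. Real perturbation
compendia (e.g. LINCS L1000) distribute such profiles at far larger scale; the
format here is a plain rank matrix plus an instance metadata table, and the
method is scale-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ["instance_id", "drug", "cell_line", "tissue"]


@dataclass
class ReferenceInstance:
    """A single treatment profile: metadata plus a gene -> rank mapping (1 = most up)."""

    instance_id: str
    drug: str
    cell_line: str
    tissue: str
    ranks: Mapping[str, int]


class DrugReference:
    """Collection of treatment instances over one gene universe.

    Parameters
    ----------
    universe
        Ordered gene symbols (size G); stored uppercased.
    rank_matrix
        Integer array of shape (G, n_instances); each column is a permutation
        of 1..G giving that instance's treatment-response ranking.
    meta
        DataFrame with columns instance_id, drug, cell_line, tissue, one row
        per rank-matrix column, in column order.
    """

    def __init__(self, universe: Iterable[str], rank_matrix: np.ndarray, meta: pd.DataFrame):
        self.universe = [str(g).upper() for g in universe]
        self.rank_matrix = np.asarray(rank_matrix, dtype=np.int64)
        self.meta = meta.reset_index(drop=True)
        G = len(self.universe)
        if self.rank_matrix.shape != (G, len(self.meta)):
            raise ValueError("rank matrix shape does not match universe/metadata")
        if len(self.meta) == 0:
            raise ValueError("empty reference")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.meta["instance_id"].duplicated().any():
            raise ValueError("duplicate instance_id")
        expected = np.arange(1, G + 1)
        for j in range(self.rank_matrix.shape[1]):
            col = np.sort(self.rank_matrix[:, j])
            if not np.array_equal(col, expected):
                raise ValueError(
                    f"invalid rank column: {self.meta['instance_id'].iloc[j]!r}"
                )
        self._gene_index = {g: i for i, g in enumerate(self.universe)}
        self._drug_cols: dict[str, list[int]] = {}
        for j, d in enumerate(self.meta["drug"]):
            self._drug_cols.setdefault(str(d), []).append(j)

    # -- basic accessors ---------------------------------------------------

    @property
    def G(self) -> int:
        return len(self.universe)

    @property
    def n_instances(self) -> int:
        return self.rank_matrix.shape[1]

    @property
    def drugs(self) -> list[str]:
        return sorted(self._drug_cols)

    def drug_columns(self, drug: str) -> list[int]:
        return list(self._drug_cols[drug])

    def instance(self, j: int) -> ReferenceInstance:
        row = self.meta.iloc[j]
        ranks = dict(zip(self.universe, self.rank_matrix[:, j].tolist()))
        return ReferenceInstance(
            str(row["instance_id"]), str(row["drug"]), str(row["cell_line"]),
            str(row["tissue"]), ranks,
        )

    def instances(self) -> list[ReferenceInstance]:
        return [self.instance(j) for j in range(self.n_instances)]

    # -- restriction / filtering -------------------------------------------

    def restrict(self, genes: Iterable[str]) -> "DrugReference":
        """Restrict to a gene subset, re-ranking each instance contiguously.

        The relative treatment-response order within each instance is preserved;
        ranks become a permutation of 1..|subset|.
        """
        keep = [g.upper() for g in genes if g.upper() in self._gene_index]
        if not keep:
            raise ValueError("disjoint gene universes")
        idx = [self._gene_index[g] for g in keep]
        sub = self.rank_matrix[idx, :]
        # order within the subset: argsort twice turns retained ranks into 1..n
        order = np.argsort(sub, axis=0, kind="stable")
        new = np.empty_like(sub)
        rows = np.arange(len(idx))
        for j in range(sub.shape[1]):
            new[order[:, j], j] = rows + 1
        return DrugReference(keep, new, self.meta)

    def filter_by_tissue(self, tissue: str) -> "DrugReference":
        """Keep only instances annotated with the given tissue (case-insensitive)."""
        mask = self.meta["tissue"].str.lower() == tissue.lower()
        if not mask.any():
            raise ValueError(f"empty tissue subset: {tissue!r}")
        cols = np.flatnonzero(mask.to_numpy())
        return DrugReference(
            self.universe, self.rank_matrix[:, cols], self.meta.iloc[cols]
        )


def filter_by_tissue(ref: DrugReference, tissue: str) -> DrugReference:
    return ref.filter_by_tissue(tissue)


def read_reference(rank_path: str | Path, meta_path: str | Path) -> DrugReference:
    """Load a reference from a rank-matrix TSV and an instance-metadata TSV.

    The rank matrix has a leading ``gene`` column and one column per instance;
    metadata rows without a matrix column are ignored with a warning, while
    matrix columns without metadata are an error.
    """
    rank_df = pd.read_csv(rank_path, sep="\t")
    if rank_df.columns[0] != "gene":
        raise ValueError("rank matrix must start with a 'gene' column")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    instance_ids = list(rank_df.columns[1:])
    known = set(meta["instance_id"])
    orphans = [i for i in instance_ids if i not in known]
    if orphans:
        raise ValueError(f"orphan instance: {orphans[0]!r}")
    extra = meta[~meta["instance_id"].isin(instance_ids)]
    if len(extra):
        logger.warning(
            "ignoring %d metadata rows without matrix columns: %s",
            len(extra), extra["instance_id"].tolist(),
        )
    meta = meta[meta["instance_id"].isin(instance_ids)]
    meta = meta.set_index("instance_id").loc[instance_ids].reset_index()
    universe = rank_df["gene"].astype(str).tolist()
    mat = rank_df[instance_ids].to_numpy(dtype=np.int64)
    return DrugReference(universe, mat, meta)


def write_reference(
    ref: DrugReference, rank_path: str | Path, meta_path: str | Path
) -> None:
    """Write a reference so that :func:`read_reference` round-trips it exactly."""
    rank_df = pd.DataFrame(
        ref.rank_matrix, columns=list(ref.meta["instance_id"])
    )
    rank_df.insert(0, "gene", ref.universe)
    rank_df.to_csv(rank_path, sep="\t", index=False)
    ref.meta[META_COLUMNS].to_csv(meta_path, sep="\t", index=False)


def ranks_from_scores(scores: Mapping[str, float]) -> dict[str, int]:
    """Convert signed perturbation scores to ranks (1 = most up-regulated).

    Ties are broken lexicographically by gene symbol so the output is always a
    permutation, as the rank-matrix format requires.
    """
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return {g: i + 1 for i, (g, _) in enumerate(items)}
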