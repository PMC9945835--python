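"""Multi-cluster drug scoring and ranking.

The drug score aggregates per-cluster reversal significance across the
selected cell clusters of one patient/sample:

    score(drug) = sum_k  prop_k * (-log10 FDR_k) * (reversed_k / diseased_k)

where prop_k is cluster k's share of all disease cells, FDR_k the drug's
BH-adjusted K-S p in cluster k, and reversed_k / diseased_k the fraction of
that cluster's significantly deregulated genes the drug reverses. The
standardized score 1 - rank/total rescales the ranking to [0, 1) for
cross-patient comparison, and Fisher's method combines the per-cluster K-S
p-values into one drug-level p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .reversal import P_FLOOR, ClusterDrugResult, bh_adjust
from .signatures import CellTable, cluster_proportions

logger = logging.getLogger(__name__)


@dataclass
class DrugScoreRecord:
    """One drug's aggregate ranking entry.

    ``rank`` uses average ranks for ties (so ``std_score = 1 - rank/total``
    holds exactly); it is integral whenever scores are untied.
    """

    drug: str
    score: float
    std_score: float
    fisher_p: float
    fisher_fdr: float
    rank: float
    selected: bool


def drug_score(
    results: Mapping[str, ClusterDrugResult], proportions: Mapping[str, float]
) -> float:
    """Formula-1 aggregate over selected clusters for one drug.

    ``results`` maps cluster_id -> the drug's result in that cluster; clusters
    without a result (drug untestable there) contribute 0, as do clusters with
    no diseased genes.
    """
    total = 0.0
    for k, prop in proportions.items():
        res = results.get(k)
        if res is None:
            continue
        if res.n_diseased == 0:
            logger.warning("cluster %s has no diseased genes; contributes 0", k)
            continue
        fdr = max(res.fdr, P_FLOOR)
        total += prop * (-math.log10(fdr)) * (res.n_reversed / res.n_diseased)
    return total


def standardized_scores(scores: Mapping[str, float]) -> dict[str, float]:
    """Formula-2 rescaling: 1 - rank/total, rank 1 = largest score, ties averaged."""
    drugs = list(scores)
    vals = np.array([scores[d] for d in drugs], dtype=float)
    ranks = rankdata(-vals, method="average")
    total = len(drugs)
    return {d: float(1.0 - r / total) for d, r in zip(drugs, ranks)}


def fisher_combined(
    pvals: Sequence[float], log_base: Literal["natural", "ten"] = "natural"
) -> float:
    """Fisher's combined probability over per-cluster p-values.

    With the natural log (default) t = -2 sum ln p_i is chi-square with 2n
    degrees of freedom under the null, and the n=1 case returns p_1 exactly.
    ``log_base="ten"`` instead accumulates t = -2 sum log10 p_i against the
    same chi-square reference — a deliberately available non-calibrated
    variant some published pipelines print.
    """
    p = np.maximum(np.asarray(pvals, dtype=float), P_FLOOR)
    if p.size == 0:
        raise ValueError("empty input")
    if log_base == "natural":
        t = -2.0 * np.log(p).sum()
    elif log_base == "ten":
        t = -2.0 * np.log10(p).sum()
    else:
        raise ValueError(f"unknown log base: {log_base!r}")
    return float(chi2.sf(t, 2 * p.size))


def rank_table(
    cluster_results: Sequence[ClusterDrugResult],
    proportions: Mapping[str, float],
    fdr_cut: float = 0.05,
    score_quantile: float = 0.99,
    fisher_base: Literal["natural", "ten"] = "natural",
) -> list[DrugScoreRecord]:
    """Assemble the per-drug ranking across clusters.

    A drug is ``selected`` when it is significant (FDR < ``fdr_cut``) in at
    least one cluster and its score exceeds the ``score_quantile`` quantile of
    all drug scores. Records are sorted by descending score (ties by drug name).
    """
    by_drug: dict[str, dict[str, ClusterDrugResult]] = {}
    for res in cluster_results:
        by_drug.setdefault(res.drug, {})[res.cluster_id] = res
    if not by_drug:
        return []
    drugs = sorted(by_drug)
    scores = {d: drug_score(by_drug[d], proportions) for d in drugs}
    stds = standardized_scores(scores)
    ranks = dict(
        zip(drugs, rankdata([-scores[d] for d in drugs], method="average"))
    )
    fisher_ps = {
        d: fisher_combined(
            [r.ks_p for r in by_drug[d].values()], log_base=fisher_base
        )
        for d in drugs
    }
    fdrs = dict(zip(drugs, bh_adjust([fisher_ps[d] for d in drugs])))
    cutoff = float(np.quantile(list(scores.values()), score_quantile))
    records = []
    for d in drugs:
        sig_any = any(r.fdr < fdr_cut for r in by_drug[d].values())
        records.append(
            DrugScoreRecord(
                drug=d,
                score=scores[d],
                std_score=stds[d],
                fisher_p=fisher_ps[d],
                fisher_fdr=float(fdrs[d]),
                rank=float(ranks[d]),
                selected=bool(sig_any and scores[d] > cutoff),
            )
        )
    records.sort(key=lambda r: (-r.score, r.drug))
    return records


def records_to_frame(
    records: Sequence[DrugScoreRecord],
    cluster_results: Sequence[ClusterDrugResult] | None = None,
) -> pd.DataFrame:
    """Tabulate ranking records, optionally adding per-cluster FDR columns."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if cluster_results:
        wide = (
            pd.DataFrame([r.__dict__ for r in cluster_results])
            .pivot(index="drug", columns="cluster_id", values="fdr")
            .add_prefix("fdr_")
        )
        df = df.merge(wide, left_on="drug", right_index=True, how="left")
    return df


def drop_one_out(
    cells: CellTable,
    cluster_results: Sequence[ClusterDrugResult],
    annotation: Mapping[str, str],
    drop_type: str,
) -> dict[str, float]:
    """Contribution of one cell type: score change when its clusters are removed.

    All clusters annotated as ``drop_type`` are removed from both the numerator
    and the denominator of the cluster proportions (i.e. their cells leave the
    sample), scores are recomputed over the remaining clusters, and
    ``delta = score_without - score_full`` is returned per drug.
    """
    if drop_type not in set(annotation.values()):
        raise ValueError(f"unknown cell type: {drop_type!r}")
    scored = sorted({r.cluster_id for r in cluster_results})
    dropped = {k for k, t in annotation.items() if t == drop_type}
    full_props = cluster_proportions(cells, scored)
    kept = [k for k in scored if k not in dropped]
    reduced = cells.subset(~cells.df["cluster_id"].isin(dropped))
    by_drug: dict[str, dict[str, ClusterDrugResult]] = {}
    for res in cluster_results:
        by_drug.setdefault(res.drug, {})[res.cluster_id] = res
    if kept:
        new_props = cluster_proportions(reduced, kept)
    else:
        new_props = {}
    deltas = {}
    for d, res in by_drug.items():
        full = drug_score(res, full_props)
        without = drug_score(res, new_props) if new_props else 0.0
        deltas[d] = without - full
    return deltas
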