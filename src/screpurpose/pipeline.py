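"""End-to-end convenience: cluster scoring -> multi-cluster ranking for one sample."""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Sequence

import pandas as pd

from .reference import DrugReference
from .reversal import ClusterDrugResult, score_cluster
from .scoring import DrugScoreRecord, rank_table, records_to_frame
from .signatures import CellTable, ClusterSignature, cluster_proportions

logger = logging.getLogger(__name__)


def score_sample(
    cells: CellTable,
    signatures: Sequence[ClusterSignature],
    ref: DrugReference,
    clusters: Iterable[str] | None = None,
    ceg_alpha: float = 0.05,
    alpha: float = 0.05,
    majority_fraction: float = 0.5,
    fdr_cut: float = 0.05,
    score_quantile: float = 0.99,
    fisher_base: Literal["natural", "ten"] = "natural",
    ks_alternative: Literal["greater", "two-sided"] = "greater",
) -> tuple[list[DrugScoreRecord], list[ClusterDrugResult]]:
    """Score every reference drug across the selected clusters of one sample.

    Clusters whose signature has no significant gene are skipped with a log
    message (the drug score treats them as contributing nothing). When no
    cluster is scoreable at all, every drug receives a zero score so the
    ranking stays defined.
    """
    selected = set(clusters) if clusters is not None else None
    results: list[ClusterDrugResult] = []
    scored_clusters: list[str] = []
    for sig in signatures:
        if selected is not None and sig.cluster_id not in selected:
            continue
        try:
            res = score_cluster(
                sig, ref,
                ceg_alpha=ceg_alpha,
                majority_fraction=majority_fraction,
                alpha=alpha,
                ks_alternative=ks_alternative,
            )
        except ValueError as exc:
            if "empty signature" in str(exc):
                logger.info("cluster %s: no significant genes, skipped", sig.cluster_id)
                continue
            raise
        results.extend(res)
        scored_clusters.append(sig.cluster_id)

    if not scored_clusters:
        # all scores tie at 0: average rank, std_score = 1 - rank/total
        total = len(ref.drugs)
        tie_rank = (total + 1) / 2.0
        records = [
            DrugScoreRecord(
                drug=d, score=0.0, std_score=1.0 - tie_rank / total,
                fisher_p=1.0, fisher_fdr=1.0, rank=tie_rank, selected=False,
            )
            for d in ref.drugs
        ]
        return records, results

    proportions = cluster_proportions(cells, scored_clusters)
    records = rank_table(
        results, proportions,
        fdr_cut=fdr_cut, score_quantile=score_quantile, fisher_base=fisher_base,
    )
    return records, results


def score_frame(
    records: Sequence[DrugScoreRecord], results: Sequence[ClusterDrugResult]
) -> pd.DataFrame:
    return records_to_frame(records, results)
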