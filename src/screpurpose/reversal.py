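"""Per-cluster drug significance by signature reversal.

A drug "reverses" a cluster's disease signature when genes up-regulated in
disease sit in the drug's down-regulated tail and vice versa. Concordantly
reversed genes are detected with an order statistic on the product of the two
tail ranks; per-instance reversal evidence is summarized, a drug's excess
evidence over the all-drug background is measured with the outlier-sum (OS)
statistic, and significance is assigned with a two-sample Kolmogorov-Smirnov
test of the drug's instances against every other drug's, followed by
Benjamini-Hochberg adjustment across drugs within the cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import TYPE_CHECKING, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

if TYPE_CHECKING:  # pragma: no cover - circular at runtime only
    from .reference import DrugReference, ReferenceInstance
    from .signatures import ClusterSignature, DiseaseRankList

P_FLOOR = 1e-300

RESULT_COLUMNS = [
    "drug", "cluster_id", "os_stat", "ks_p", "fdr",
    "n_reversed", "n_diseased", "n_instances",
]


@dataclass
class CegCall:
    """A concordantly reversed gene: disease-extreme in one tail, drug-extreme in the other."""

    gene: str
    direction: Literal["disease-up-drug-down", "disease-down-drug-up"]
    rank_product_p: float


@dataclass
class ClusterDrugResult:
    """Per (drug, cluster) reversal summary feeding the multi-cluster drug score."""

    drug: str
    cluster_id: str
    os_stat: float
    ks_p: float
    fdr: float
    n_reversed: int
    n_diseased: int
    n_instances: int


def rank_product_p(u: int, v: int, G: int) -> float:
    """Tail probability of the product of two tail ranks under independence.

    With u the rank from the relevant disease tail and v the rank from the
    opposing drug tail (1 = most extreme for both), r = (u/G)(v/G) behaves under
    the null like a product of two independent Uniform(0,1] variables, whose
    exact lower-tail probability is r(1 - ln r).
    """
    if not (1 <= u <= G and 1 <= v <= G):
        raise ValueError("rank out of range")
    r = (u / G) * (v / G)
    return float(r * (1.0 - math.log(r))) if r < 1.0 else 1.0


def detect_cegs(
    disease: "DiseaseRankList",
    sig_sets: tuple[set[str], set[str]],
    inst: "ReferenceInstance",
    ceg_alpha: float = 0.05,
) -> list[CegCall]:
    """Call concordantly reversed genes for one treatment instance.

    Only significant disease genes are eligible. A disease-up gene is tested
    with u = its disease rank (1 = most up) against v = G+1-rank in the
    instance (1 = most drug-down); disease-down genes symmetrically against the
    drug-up tail. A gene is called when rank_product_p(u, v, G) < ceg_alpha.
    """
    up, down = sig_sets
    G = disease.G
    calls: list[CegCall] = []
    for gene, rank in disease.ranks.items():
        if gene in up:
            u, v = rank, G + 1 - inst.ranks[gene]
            direction = "disease-up-drug-down"
        elif gene in down:
            u, v = G + 1 - rank, inst.ranks[gene]
            direction = "disease-down-drug-up"
        else:
            continue
        p = rank_product_p(u, v, G)
        if p < ceg_alpha:
            calls.append(CegCall(gene, direction, p))
    return calls


def instance_score(cegs: Sequence[CegCall]) -> float:
    """Reversal evidence of one instance: sum of -log10 p over its CEG calls."""
    return float(sum(-math.log10(max(c.rank_product_p, P_FLOOR)) for c in cegs))


def outlier_sum(
    scores: Mapping[str, float], drug_index: Mapping[str, Sequence[str]]
) -> dict[str, float]:
    """Outlier-sum statistic per drug over standardized instance scores.

    Scores are centred by the median and scaled by the (unscaled) median
    absolute deviation — falling back to the mean absolute deviation when the
    MAD is zero, and to all-zero OS when both vanish. A drug's OS is the sum of
    its standardized scores exceeding q75 + IQR of all standardized scores
    (linear-interpolation quantiles); drugs with no instance above the
    threshold get 0.
    """
    ids = list(scores)
    s = np.array([scores[i] for i in ids], dtype=float)
    zeros = {d: 0.0 for d in drug_index}
    if len(np.unique(s)) < 2:
        return zeros
    med = float(np.median(s))
    mad = float(np.median(np.abs(s - med)))
    if mad == 0.0:
        mad = float(np.mean(np.abs(s - med)))
        if mad == 0.0:
            return zeros
    z = (s - med) / mad
    q25, q75 = np.quantile(z, [0.25, 0.75])
    t = q75 + (q75 - q25)
    by_id = dict(zip(ids, z))
    out = {}
    for drug, inst_ids in drug_index.items():
        vals = [by_id[i] for i in inst_ids if by_id[i] > t]
        out[drug] = float(sum(vals)) if vals else 0.0
    return out


# ---------------------------------------------------------------------------
# Two-sample Kolmogorov-Smirnov test


def _ks_stat(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """ECDF-difference statistic oriented so large x values give large D."""
    pooled = np.concatenate([x, y])
    grid = np.unique(pooled)
    fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
    fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
    if alternative == "greater":
        return float(max(0.0, np.max(fy - fx)))
    return float(np.max(np.abs(fx - fy)))


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["greater", "two-sided"] = "greater",
) -> tuple[float, float]:
    """Two-sample K-S test oriented so large drug scores give large D.

    For total sample sizes up to 12 the p-value is exact by enumerating every
    assignment of group labels to the pooled values (tie-safe permutation
    null). For larger samples the exact distribution-free p is used while
    n*m stays cheap, and the classical asymptotic tail beyond that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("empty sample")
    d_obs = _ks_stat(x, y, alternative)
    if n + m <= 12:
        pooled = np.concatenate([x, y])
        hits = total = 0
        for idx in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            d = _ks_stat(pooled[mask], pooled[~mask], alternative)
            if d >= d_obs - 1e-12:
                hits += 1
            total += 1
        return d_obs, hits / total
    if n * m <= 50_000:
        from scipy.stats import ks_2samp

        # scipy's "less" alternative corresponds to x stochastically larger
        alt = "less" if alternative == "greater" else "two-sided"
        res = ks_2samp(x, y, alternative=alt, method="exact")
        return d_obs, float(min(1.0, max(res.pvalue, 0.0)))
    en = n * m / (n + m)
    if alternative == "greater":
        p = math.exp(-2.0 * en * d_obs * d_obs)
    else:
        from scipy.stats import kstwobign

        p = float(kstwobign.sf(d_obs * math.sqrt(en)))
    return d_obs, float(min(1.0, max(p, 0.0)))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# End-to-end cluster scoring


def score_cluster(
    sig: "ClusterSignature",
    ref: "DrugReference",
    ceg_alpha: float = 0.05,
    majority_fraction: float = 0.5,
    alpha: float = 0.05,
    ks_alternative: Literal["greater", "two-sided"] = "greater",
) -> list[ClusterDrugResult]:
    """Score every reference drug against one cluster signature.

    For each treatment instance the concordantly reversed genes are detected
    and summarized into an instance score; per drug, the outlier-sum statistic,
    the K-S p of its instance scores against all other drugs' and the BH FDR
    across drugs are computed. A gene counts as reversed by a drug when it is a
    CEG in at least ``majority_fraction`` of the drug's instances.
    """
    from .signatures import filter_significant, to_rank_list

    up, down = filter_significant(sig, alpha=alpha)
    shared = set(ref.universe) & set(sig.genes)
    if not shared:
        raise ValueError("disjoint gene universes")
    up &= shared
    down &= shared
    n_diseased = len(up) + len(down)
    if n_diseased == 0:
        raise ValueError("empty signature")

    sub = ref if len(shared) == ref.G else ref.restrict(sorted(shared))
    rank_list = to_rank_list(sig, sub.universe)
    G = rank_list.G
    gene_row = {g: i for i, g in enumerate(sub.universe)}

    sig_genes = sorted(up) + sorted(down)
    u = np.empty(len(sig_genes), dtype=float)
    is_up = np.zeros(len(sig_genes), dtype=bool)
    rows = np.empty(len(sig_genes), dtype=int)
    for i, g in enumerate(sig_genes):
        rows[i] = gene_row[g]
        if g in up:
            u[i] = rank_list.ranks[g]
            is_up[i] = True
        else:
            u[i] = G + 1 - rank_list.ranks[g]

    R = sub.rank_matrix[rows, :].astype(float)  # (n_sig, n_inst)
    v = np.where(is_up[:, None], G + 1 - R, R)
    r = (u[:, None] / G) * (v / G)
    with np.errstate(divide="ignore"):
        p_mat = np.where(r < 1.0, r * (1.0 - np.log(r)), 1.0)
    ceg = p_mat < ceg_alpha
    contrib = np.where(ceg, -np.log10(np.maximum(p_mat, P_FLOOR)), 0.0)
    inst_scores = contrib.sum(axis=0)

    inst_ids = list(sub.meta["instance_id"])
    scores_by_id = dict(zip(inst_ids, inst_scores.tolist()))
    drug_index = {d: [inst_ids[j] for j in sub.drug_columns(d)] for d in sub.drugs}
    os_by_drug = outlier_sum(scores_by_id, drug_index)

    drugs = sub.drugs
    ks_ps = np.empty(len(drugs))
    results: list[ClusterDrugResult] = []
    all_idx = np.arange(len(inst_ids))
    for i, d in enumerate(drugs):
        cols = np.asarray(sub.drug_columns(d))
        mask = np.zeros(len(inst_ids), dtype=bool)
        mask[cols] = True
        if mask.all():
            ks_ps[i] = 1.0  # single-drug reference: no background to compare against
        else:
            _, ks_ps[i] = ks_two_sample(
                inst_scores[mask], inst_scores[~mask], alternative=ks_alternative
            )
        ks_ps[i] = max(ks_ps[i], P_FLOOR)
    fdrs = bh_adjust(ks_ps)

    for i, d in enumerate(drugs):
        cols = np.asarray(sub.drug_columns(d))
        frac = ceg[:, cols].mean(axis=1)
        n_rev = int((frac >= majority_fraction).sum())
        results.append(
            ClusterDrugResult(
                drug=d,
                cluster_id=sig.cluster_id,
                os_stat=os_by_drug[d],
                ks_p=float(ks_ps[i]),
                fdr=float(fdrs[i]),
                n_reversed=n_rev,
                n_diseased=n_diseased,
                n_instances=len(cols),
            )
        )
    return results


def results_to_frame(results: Sequence[ClusterDrugResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results], columns=RESULT_COLUMNS)


def write_cluster_results(
    results: Sequence[ClusterDrugResult], path: str | Path
) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_cluster_results(path: str | Path) -> list[ClusterDrugResult]:
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "cluster_id": str})
    return [
        ClusterDrugResult(
            drug=row.drug,
            cluster_id=row.cluster_id,
            os_stat=float(row.os_stat),
            ks_p=float(row.ks_p),
            fdr=float(row.fdr),
            n_reversed=int(row.n_reversed),
            n_diseased=int(row.n_diseased),
            n_instances=int(row.n_instances),
        )
        for row in df.itertuples()
    ]
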