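"""Benchmarking: ROC/AUC of drug rankings against labeled positives, and
robustness simulations over population size, DE attenuation and disease-cell
proportion unbalance."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .pipeline import score_sample
from .synthetic import SyntheticConfig, generate_case_study, generate_reference

ROBUSTNESS_COLUMNS = ["setting", "level", "replicate", "auc"]


def read_labels(path: str | Path) -> dict[str, bool]:
    """TSV with columns drug, label (0/1); drug names matched case-insensitively."""
    df = pd.read_csv(path, sep="\t", dtype={"drug": str})
    return {str(d).upper(): bool(int(v)) for d, v in zip(df["drug"], df["label"])}


def roc_auc(
    scores: Mapping[str, float], labels: Mapping[str, bool]
) -> tuple[float, list[tuple[float, float]]]:
    """AUC (rank-sum formulation, ties counted half) and the ROC curve.

    ``labels`` must cover every scored drug and contain at least one positive
    and one negative; names are matched case-insensitively.
    """
    norm_labels = {str(k).upper(): bool(v) for k, v in labels.items()}
    drugs = list(scores)
    missing = [d for d in drugs if str(d).upper() not in norm_labels]
    if missing:
        raise ValueError(f"unlabeled drug: {missing[0]!r}")
    y = np.array([norm_labels[str(d).upper()] for d in drugs], dtype=bool)
    s = np.array([scores[d] for d in drugs], dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate labels")
    ranks = rankdata(s, method="average")
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y.astype(int), s, drop_intermediate=False)
    curve = list(zip(fpr.tolist(), tpr.tolist()))
    return float(auc), curve


def _level_config(
    base: SyntheticConfig,
    setting: Literal["size", "attenuation", "unbalance"],
    level: float,
    seed: int,
) -> SyntheticConfig:
    """Derive the study configuration for one robustness level."""
    if setting == "attenuation":
        if not (0.0 < level <= 1.0):
            raise ValueError("attenuation level must be in (0, 1]")
        return base.replace(seed=seed, attenuation=float(level))
    if setting == "size":
        # level = total cells per condition, split across clusters like the base
        n = int(level)
        if n < 2 * base.n_clusters:
            raise ValueError("size level too small")
        d = _split(n, base.disease_cells_per_cluster)
        c = _split(n, base.control_cells_per_cluster)
        return base.replace(
            seed=seed, disease_cells_per_cluster=d, control_cells_per_cluster=c
        )
    if setting == "unbalance":
        # level = diseased proportion of a 5000-cell draw
        if not (0.0 < level < 1.0):
            raise ValueError("unbalance level must be in (0, 1)")
        total = 5000
        n_d = int(round(total * level))
        d = _split(n_d, base.disease_cells_per_cluster)
        c = _split(total - n_d, base.control_cells_per_cluster)
        return base.replace(
            seed=seed, disease_cells_per_cluster=d, control_cells_per_cluster=c
        )
    raise ValueError(f"unknown setting: {setting!r}")


def _split(total: int, weights: Sequence[int]) -> list[int]:
    """Split a total across clusters proportionally, at least one cell each."""
    w = np.asarray(weights, dtype=float)
    raw = np.maximum(1, np.floor(total * w / w.sum()).astype(int))
    # distribute any remainder to the largest clusters
    order = np.argsort(-w)
    i = 0
    while raw.sum() < total:
        raw[order[i % len(raw)]] += 1
        i += 1
    while raw.sum() > total and (raw > 1).any():
        j = order[::-1][i % len(raw)]
        if raw[j] > 1:
            raw[j] -= 1
        i += 1
    return raw.astype(int).tolist()


def run_replicate(cfg: SyntheticConfig) -> float:
    """Generate one synthetic study, run the pipeline, return the planted-label AUC."""
    cells, sigs = generate_case_study(cfg)
    ref = generate_reference(cfg)
    records, _ = score_sample(cells, sigs, ref)
    scores = {r.drug: r.score for r in records}
    auc, _ = roc_auc(scores, cfg.labels())
    return auc


def robustness_experiment(
    base_config: SyntheticConfig,
    setting: Literal["size", "attenuation", "unbalance"],
    levels: Sequence[float],
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Per-replicate AUC table across robustness levels; deterministic given seed.

    Each (level, replicate) regenerates the synthetic case study and reference
    at that level with a derived sub-seed and scores the planted positives.
    """
    rows = []
    for li, level in enumerate(levels):
        for rep in range(replicates):
            sub = int(
                np.random.default_rng(
                    np.random.SeedSequence([seed, li, rep])
                ).integers(2**31)
            )
            cfg = _level_config(base_config, setting, level, sub)
            rows.append((setting, float(level), rep, run_replicate(cfg)))
    return pd.DataFrame(rows, columns=ROBUSTNESS_COLUMNS)


def trend_pvalue(table: pd.DataFrame) -> float:
    """One-sided Spearman p for AUC increasing with level (small p = clear trend)."""
    from scipy.stats import spearmanr

    rho, p_two = spearmanr(table["level"], table["auc"])
    if np.isnan(rho):
        return 1.0
    return float(p_two / 2.0) if rho > 0 else float(1.0 - p_two / 2.0)
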