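"""Seeded synthetic fixtures: a drug reference with planted reverser drugs and
a matched single-cell case study.

The generator emulates the statistical structure the pipeline consumes — a
cell annotation table, per-cluster DE signatures whose p-values reflect a
power model (evidence grows with effect size and cell numbers), and a
reference of rank-permutation treatment instances in which designated
"planted" drugs place each cluster's true disease-up genes into their
down-regulated tail (and vice versa) with a configurable probability. Planted
drugs are the ground-truth positives for benchmarking; everything is
deterministic given the seed.

It does not attempt realistic scRNA-seq counts (dropout, library-size
variation); signature p-values are drawn from the effect model directly so
fixtures stay fast. A small Poisson count-level mode exists for integration
tests of the built-in DE path.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .reference import DrugReference
from .reversal import bh_adjust
from .signatures import CellTable, ClusterSignature, write_cell_table, write_cluster_signature
from .reference import write_reference

# power-model noise scale: per-cell log2-expression SD feeding the z statistic
_S0 = 2.0
_CELL_TYPES = ["T cell", "B cell", "NK cell", "monocyte", "epithelial"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults give a moderate 3-cluster case.

    ``planted`` maps drug names to the set of clusters they reverse;
    ``reversal_strength`` is the probability a true DE gene of those clusters
    lands in the planted drug's opposite extreme tail; ``attenuation`` scales
    every true log fold change (1.0 = full effect).
    """

    seed: int = 0
    n_genes: int = 2000
    n_drugs: int = 100
    instances_per_drug: int = 3
    n_clusters: int = 3
    disease_cells_per_cluster: list[int] = field(default_factory=lambda: [150, 100, 50])
    control_cells_per_cluster: list[int] = field(default_factory=lambda: [100, 100, 100])
    de_fraction: float = 0.05
    effect_size: float = 1.0
    attenuation: float = 1.0
    planted: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"D001": ("C1", "C2", "C3")}
    )
    reversal_strength: float = 0.9

    def __post_init__(self) -> None:
        if len(self.disease_cells_per_cluster) != self.n_clusters:
            raise ValueError("disease_cells_per_cluster length != n_clusters")
        if len(self.control_cells_per_cluster) != self.n_clusters:
            raise ValueError("control_cells_per_cluster length != n_clusters")
        if not (0.0 < self.attenuation <= 1.0):
            raise ValueError("attenuation must be in (0, 1]")
        if not (0.0 <= self.reversal_strength <= 1.0):
            raise ValueError("reversal_strength must be in [0, 1]")
        bad = [d for d in self.planted if d not in set(self.drug_names)]
        if bad:
            raise ValueError(f"planted drug not in reference: {bad[0]!r}")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]

    @property
    def drug_names(self) -> list[str]:
        return [f"D{i + 1:03d}" for i in range(self.n_drugs)]

    @property
    def cluster_names(self) -> list[str]:
        return [f"C{k + 1}" for k in range(self.n_clusters)]

    def labels(self) -> dict[str, bool]:
        """Ground-truth benchmark labels: planted drugs are the positives."""
        return {d: d in self.planted for d in self.drug_names}

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


def _rng(cfg: SyntheticConfig, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *salt]))


def _de_assignment(cfg: SyntheticConfig, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True-DE genes of cluster k: (gene indices, signs, base |log2FC|).

    Drawn from a dedicated stream keyed only by (seed, cluster) so the case
    study and the reference agree on which genes each cluster perturbs,
    independent of attenuation or other knobs.
    """
    rng = _rng(cfg, 101, k)
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    base = rng.exponential(scale=cfg.effect_size, size=n_de)
    return idx, signs, base


def generate_case_study(cfg: SyntheticConfig) -> tuple[CellTable, list[ClusterSignature]]:
    """Cell table plus per-cluster DE signatures under the configured effect model.

    True DE genes get logFC = sign * base * attenuation and p-values from a
    two-sided z test with non-centrality |logFC| * sqrt(n_eff) / s0, where
    n_eff is the harmonic sample size of the cluster's disease/control cells;
    the remaining genes get small null fold changes and uniform p-values.
    adj_p is BH within the cluster.
    """
    genes = np.array(cfg.gene_names)
    rows = []
    sigs: list[ClusterSignature] = []
    for k, cname in enumerate(cfg.cluster_names):
        nd = cfg.disease_cells_per_cluster[k]
        nc = cfg.control_cells_per_cluster[k]
        if nd <= 0 or nc <= 0:
            raise ValueError(f"zero cells in cluster {cname}")
        ctype = _CELL_TYPES[k % len(_CELL_TYPES)]
        for i in range(nd):
            rows.append((f"d{cname}_{i:05d}", "S1", "disease", cname, ctype))
        for i in range(nc):
            rows.append((f"c{cname}_{i:05d}", "S1", "control", cname, ctype))

        idx, signs, base = _de_assignment(cfg, k)
        rng = _rng(cfg, 202, k)
        eps = rng.normal(size=cfg.n_genes)
        null_lfc = rng.normal(scale=0.1, size=cfg.n_genes)
        lfc = null_lfc.copy()
        lfc[idx] = signs * base * cfg.attenuation
        n_eff = nd * nc / (nd + nc)
        mu = lfc * np.sqrt(n_eff) / _S0
        z = mu + eps
        p = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
        adj = bh_adjust(p)
        table = pd.DataFrame({"gene": genes, "logFC": lfc, "p": p, "adj_p": adj})
        sigs.append(ClusterSignature(cname, nd, table))

    cells = CellTable(
        pd.DataFrame(rows, columns=["cell_id", "sample_id", "condition", "cluster_id", "cell_type"])
    )
    return cells, sigs


def generate_reference(cfg: SyntheticConfig) -> DrugReference:
    """Reference of rank permutations with the configured planted reversers.

    Non-planted instances are uniform random permutations. For a planted drug,
    each instance sends (with probability ``reversal_strength`` per gene) the
    true disease-up genes of its target clusters to the bottom of the rank
    list and the true disease-down genes to the top; all other genes are
    shuffled in between.
    """
    G = cfg.n_genes
    up_by_drug: dict[str, np.ndarray] = {}
    down_by_drug: dict[str, np.ndarray] = {}
    cluster_pos = {c: k for k, c in enumerate(cfg.cluster_names)}
    for drug, clusters in cfg.planted.items():
        ups: set[int] = set()
        downs: set[int] = set()
        for c in clusters:
            idx, signs, _ = _de_assignment(cfg, cluster_pos[c])
            ups.update(idx[signs > 0].tolist())
            downs.update(idx[signs < 0].tolist())
        both = ups & downs  # discordant across clusters: leave unplanted
        up_by_drug[drug] = np.array(sorted(ups - both), dtype=int)
        down_by_drug[drug] = np.array(sorted(downs - both), dtype=int)

    rng = _rng(cfg, 303)
    cols = []
    meta_rows = []
    for drug in cfg.drug_names:
        for j in range(cfg.instances_per_drug):
            iid = f"{drug}_i{j + 1}"
            meta_rows.append((iid, drug, f"CL{(j % 3) + 1}", "generic"))
            if drug in up_by_drug:
                take_up = up_by_drug[drug][
                    rng.random(len(up_by_drug[drug])) < cfg.reversal_strength
                ]
                take_down = down_by_drug[drug][
                    rng.random(len(down_by_drug[drug])) < cfg.reversal_strength
                ]
                planted = set(take_up.tolist()) | set(take_down.tolist())
                middle = np.array(
                    [g for g in range(G) if g not in planted], dtype=int
                )
                rng.shuffle(middle)
                top = rng.permutation(take_down)
                bottom = rng.permutation(take_up)
                order = np.concatenate([top, middle, bottom])
                ranks = np.empty(G, dtype=np.int64)
                ranks[order] = np.arange(1, G + 1)
                cols.append(ranks)
            else:
                cols.append(rng.permutation(G) + 1)
    meta = pd.DataFrame(meta_rows, columns=["instance_id", "drug", "cell_line", "tissue"])
    return DrugReference(cfg.gene_names, np.column_stack(cols), meta)


def resample_cells(
    cells: CellTable, n: int, disease_proportion: float, seed: int
) -> CellTable:
    """Bootstrap a cell table to size n with a chosen disease-cell proportion.

    Draws round(n*p) disease and n - round(n*p) control cells with
    replacement; resampled cell ids get a uniqueness suffix.
    """
    if not (0.0 < disease_proportion < 1.0):
        raise ValueError("disease_proportion must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_d = int(round(n * disease_proportion))
    parts = []
    for cond, size in (("disease", n_d), ("control", n - n_d)):
        pool = cells.df[cells.df["condition"] == cond]
        if pool.empty:
            raise ValueError(f"empty condition: {cond}")
        take = pool.iloc[rng.integers(0, len(pool), size=size)].copy()
        parts.append(take)
    out = pd.concat(parts, ignore_index=True)
    out["cell_id"] = [f"{c}#b{i}" for i, c in enumerate(out["cell_id"])]
    return CellTable(out)


def generate_counts(
    cfg: SyntheticConfig, baseline_mean: float = 5.0
) -> tuple[pd.DataFrame, CellTable]:
    """Small Poisson count matrix consistent with the configured effects.

    Intended for integration tests of the built-in rank-sum DE path; keep
    n_genes and cell counts small when using this mode.
    """
    cells, _ = generate_case_study(cfg)
    rng = _rng(cfg, 505)
    base = rng.gamma(shape=2.0, scale=baseline_mean / 2.0, size=cfg.n_genes)
    mats = []
    order = []
    for k, cname in enumerate(cfg.cluster_names):
        idx, signs, mag = _de_assignment(cfg, k)
        lfc = np.zeros(cfg.n_genes)
        lfc[idx] = signs * mag * cfg.attenuation
        sub = cells.df[cells.df["cluster_id"] == cname]
        for _, row in sub.iterrows():
            mean = base * np.power(2.0, lfc) if row["condition"] == "disease" else base
            mats.append(rng.poisson(mean))
            order.append(row["cell_id"])
    counts = pd.DataFrame(
        np.column_stack(mats), index=cfg.gene_names, columns=order
    )
    return counts, cells


def write_fixtures(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, str]:
    """Write cell table, DE tables, reference and labels; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells, sigs = generate_case_study(cfg)
    ref = generate_reference(cfg)
    paths = {
        "cell_table": str(outdir / "cell_table.tsv"),
        "de_dir": str(outdir / "de"),
        "reference_ranks": str(outdir / "reference_ranks.tsv"),
        "reference_meta": str(outdir / "reference_meta.tsv"),
        "labels": str(outdir / "labels.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_cell_table(cells, paths["cell_table"])
    de_dir = Path(paths["de_dir"])
    de_dir.mkdir(exist_ok=True)
    for sig in sigs:
        write_cluster_signature(sig, de_dir / f"{sig.cluster_id}.tsv")
    write_reference(ref, paths["reference_ranks"], paths["reference_meta"])
    labels = pd.DataFrame(
        {"drug": cfg.drug_names, "label": [int(v) for v in cfg.labels().values()]}
    )
    labels.to_csv(paths["labels"], sep="\t", index=False)
    manifest = dataclasses.asdict(cfg)
    manifest["planted"] = {d: list(c) for d, c in cfg.planted.items()}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
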