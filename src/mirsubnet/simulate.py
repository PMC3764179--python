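"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates, without any download, the five inputs of the study:
pathway gene graphs, per-miRNA predicted-target tables with predictor
support counts, a tumor/normal expression matrix for DEG calling, miRNA
direction labels, and per-patient two-miRNA expression with survival
follow-up.  Groups of co-regulating miRNAs are planted by drawing a stated
fraction of each member's targets from the genes of shared subpathways, so
downstream recovery can be scored against recorded truth labels.

Defaults mirror the study conditions: 56 differentially expressed miRNAs
(24 up, 32 down), mining at distance k = 4, support threshold 4 of 11
predictors, a 1.5-fold DEG threshold, and 89 patients in two latent
survival groups with opposite two-miRNA expression shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PathwayGraph
from .subpathways import Subpathway, mine_all

TOPOLOGIES = ("path", "lattice", "smallworld")


@dataclass(frozen=True)
class PlantedGroup:
    """A group of miRNAs that co-regulate the same shared subpathways.

    ``shared_subpathways`` is either an explicit tuple of subpathway ids or
    an integer count, in which case the generator picks that many mined
    subpathways deterministically (the first subpathway of each successive
    pathway).  ``sharing`` is the fraction of each member's target budget
    drawn from the shared subpathways' genes.
    """

    members: tuple[str, ...]
    shared_subpathways: int | tuple[str, ...] = 3
    sharing: float = 0.9


@dataclass(frozen=True)
class SimulationConfig:
    n_pathways: int = 20
    genes_per_pathway: int = 40
    pathway_topology: str = "path"
    n_mirnas: int = 56
    n_up: int = 24
    n_down: int = 32
    planted_groups: tuple[PlantedGroup, ...] | None = None
    background_target_rate: float = 0.02
    universe_size: int = 1200
    n_targets_per_mirna: int = 60
    support_pass_rate_background: float = 0.5
    deg_rate_background_target: float = 0.7
    deg_rate_nontarget: float = 0.05
    deg_log2fc_low: float = 0.85   # ~1.8-fold, safely beyond the 1.5 threshold
    deg_log2fc_high: float = 2.0
    noise_sd: float = 0.2          # log2-scale Gaussian expression noise
    n_tumor: int = 10
    n_normal: int = 10
    k_subpathway: int = 4
    n_patients: int = 89
    hazard_ratio: float = 3.0
    censor_rate: float = 0.3
    baseline_median_survival: float = 36.0  # months
    cluster_separation: float = 1.5         # mean shift (SD units) per miRNA
    seed: int = 0

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i:03d}" for i in range(1, self.n_mirnas + 1)]

    def directions(self) -> dict[str, str]:
        ids = self.mirna_ids()
        return {
            m: ("up" if i < self.n_up else "down") for i, m in enumerate(ids)
        }

    def resolved_groups(self) -> tuple[PlantedGroup, ...]:
        """Planted groups, defaulting to one 5-member group per direction."""
        if self.planted_groups is not None:
            return self.planted_groups
        ids = self.mirna_ids()
        groups = []
        if self.n_up >= 5:
            groups.append(PlantedGroup(members=tuple(ids[:5])))
        if self.n_down >= 5:
            groups.append(
                PlantedGroup(
                    members=tuple(ids[self.n_up : self.n_up + 5]),
                    shared_subpathways=3,
                )
            )
        return tuple(groups)

    def validate(self) -> None:
        positive = {
            "n_pathways": self.n_pathways,
            "genes_per_pathway": self.genes_per_pathway,
            "n_mirnas": self.n_mirnas,
            "universe_size": self.universe_size,
            "n_targets_per_mirna": self.n_targets_per_mirna,
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
            "n_patients": self.n_patients,
        }
        for name, value in positive.items():
            if value < 1:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.pathway_topology not in TOPOLOGIES:
            raise ValueError(
                f"pathway_topology must be one of {TOPOLOGIES}, "
                f"got {self.pathway_topology!r}"
            )
        if self.n_up + self.n_down != self.n_mirnas:
            raise ValueError("n_up + n_down must equal n_mirnas")
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("n_up and n_down must be non-negative")
        for name in (
            "background_target_rate", "support_pass_rate_background",
            "deg_rate_background_target", "deg_rate_nontarget", "censor_rate",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.universe_size < self.genes_per_pathway:
            raise ValueError("universe smaller than one pathway's gene count")
        valid_ids = set(self.mirna_ids())
        seen: set[str] = set()
        for group in self.resolved_groups():
            if not 0 <= group.sharing <= 1:
                raise ValueError(f"sharing fraction must be in [0, 1], got {group.sharing}")
            bad = set(group.members) - valid_ids
            if bad:
                raise ValueError(f"planted group members are not miRNA ids: {sorted(bad)}")
            overlap = set(group.members) & seen
            if overlap:
                raise ValueError(f"miRNAs in multiple planted groups: {sorted(overlap)}")
            seen |= set(group.members)


@dataclass(frozen=True)
class SyntheticBundle:
    pathways: list[PathwayGraph]
    subpathways: list[Subpathway]
    targets: pd.DataFrame        # mirna, gene, support
    expression: ExpressionMatrix
    directions: dict[str, str]
    patients: pd.DataFrame       # patient_id, expr_a, expr_b, time, event
    truth: dict
    config: SimulationConfig = field(repr=False)


def _make_pathway(pathway_id: str, genes: Sequence[str], topology: str,
                  rng: np.random.Generator) -> PathwayGraph:
    n = len(genes)
    if topology == "path":
        base = nx.path_graph(n)
    elif topology == "lattice":
        base = nx.watts_strogatz_graph(n, k=4, p=0.0)
    else:  # smallworld: ring lattice with rewired shortcuts
        base = nx.watts_strogatz_graph(
            n, k=4, p=0.1, seed=int(rng.integers(2**31))
        )
    graph = nx.relabel_nodes(base, dict(enumerate(genes)))
    return PathwayGraph(pathway_id, graph)


def _resolve_shared(
    groups: Sequence[PlantedGroup], subpathways: Sequence[Subpathway]
) -> dict[tuple[str, ...], tuple[str, ...]]:
    """Pick concrete shared subpathway ids for each planted group."""
    by_id = {sp.subpathway_id: sp for sp in subpathways}
    by_pathway: dict[str, list[Subpathway]] = {}
    for sp in subpathways:
        by_pathway.setdefault(sp.pathway_id, []).append(sp)
    pathway_order = sorted(by_pathway)
    resolved: dict[tuple[str, ...], tuple[str, ...]] = {}
    cursor = 0
    for group in groups:
        if isinstance(group.shared_subpathways, int):
            count = group.shared_subpathways
            if count < 1:
                raise ValueError("a planted group needs at least one shared subpathway")
            picked = []
            while len(picked) < count:
                if cursor >= len(pathway_order) * max(
                    len(v) for v in by_pathway.values()
                ):
                    raise ValueError(
                        "not enough mined subpathways to satisfy planted groups"
                    )
                pw = pathway_order[cursor % len(pathway_order)]
                idx = cursor // len(pathway_order)
                cursor += 1
                candidates = by_pathway[pw]
                if idx < len(candidates):
                    picked.append(candidates[idx].subpathway_id)
            resolved[group.members] = tuple(picked)
        else:
            missing = [s for s in group.shared_subpathways if s not in by_id]
            if missing:
                raise ValueError(f"unknown shared subpathway ids: {missing}")
            resolved[group.members] = tuple(group.shared_subpathways)
    return resolved


def _draw_targets(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    universe: list[str],
    shared_pool: dict[str, list[str]],
) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    """Target table plus per-miRNA truth ('planted'/'background' per gene)."""
    rows = []
    truth: dict[str, dict[str, str]] = {}
    group_sharing = {}
    for group in cfg.resolved_groups():
        for member in group.members:
            group_sharing[member] = group.sharing
    for mirna in cfg.mirna_ids():
        chosen: dict[str, str] = {}
        pool = shared_pool.get(mirna, [])
        sharing = group_sharing.get(mirna, 0.0)
        n_planted = min(round(sharing * cfg.n_targets_per_mirna), len(pool))
        if n_planted:
            for gene in rng.choice(pool, size=n_planted, replace=False):
                chosen[str(gene)] = "planted"
        remaining = [g for g in universe if g not in chosen]
        n_background = rng.binomial(len(remaining), cfg.background_target_rate)
        if n_background:
            for gene in rng.choice(remaining, size=n_background, replace=False):
                chosen[str(gene)] = "background"
        for gene in sorted(chosen):
            origin = chosen[gene]
            if origin == "planted":
                support = int(rng.integers(4, 12))
            else:
                passes = rng.random() < cfg.support_pass_rate_background
                support = int(rng.integers(4, 12) if passes else rng.integers(0, 4))
            rows.append((mirna, gene, support))
        truth[mirna] = chosen
    table = pd.DataFrame(rows, columns=["mirna", "gene", "support"])
    return table, truth


def _draw_expression(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    universe: list[str],
    target_truth: dict[str, dict[str, str]],
) -> tuple[ExpressionMatrix, frozenset[str]]:
    """Tumor/normal expression with DEG status planted per gene.

    Planted target genes always differ by more than the fold threshold;
    background target genes are DEGs at ``deg_rate_background_target`` and
    untargeted genes at ``deg_rate_nontarget``.  Values are linear-scale
    (2**log2) and strictly positive.
    """
    planted_genes: set[str] = set()
    background_genes: set[str] = set()
    for per_gene in target_truth.values():
        for gene, origin in per_gene.items():
            (planted_genes if origin == "planted" else background_genes).add(gene)
    background_genes -= planted_genes

    is_deg = {}
    for gene in universe:
        if gene in planted_genes:
            is_deg[gene] = True
        elif gene in background_genes:
            is_deg[gene] = rng.random() < cfg.deg_rate_background_target
        else:
            is_deg[gene] = rng.random() < cfg.deg_rate_nontarget

    n_genes = len(universe)
    base = rng.uniform(6.0, 10.0, size=n_genes)
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    magnitude = rng.uniform(cfg.deg_log2fc_low, cfg.deg_log2fc_high, size=n_genes)
    shift = np.array([is_deg[g] for g in universe], dtype=float) * sign * magnitude

    samples = [f"T{i:02d}" for i in range(1, cfg.n_tumor + 1)] + [
        f"N{i:02d}" for i in range(1, cfg.n_normal + 1)
    ]
    conditions = ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal
    log2 = np.empty((n_genes, len(samples)))
    for col, condition in enumerate(conditions):
        noise = rng.normal(0.0, cfg.noise_sd, size=n_genes)
        log2[:, col] = base + (shift if condition == "tumor" else 0.0) + noise
    values = pd.DataFrame(2.0 ** log2, index=universe, columns=samples)
    expr = ExpressionMatrix(values, pd.Series(conditions, index=samples))
    deg_truth = frozenset(g for g in universe if is_deg[g])
    return expr, deg_truth


def _draw_patients(
    cfg: SimulationConfig, rng: np.random.Generator, hazard_ratio: float
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two latent groups with opposite two-miRNA shifts and exponential
    survival whose hazards differ by ``hazard_ratio`` (group 1 is the
    high-expr_a / low-expr_b, higher-hazard group)."""
    n = cfg.n_patients
    latent = rng.integers(1, 3, size=n)  # 1 or 2
    mu = cfg.cluster_separation
    mean_a = np.where(latent == 1, mu, -mu)
    mean_b = np.where(latent == 1, -mu, mu)
    expr_a = mean_a + rng.normal(0.0, 1.0, size=n)
    expr_b = mean_b + rng.normal(0.0, 1.0, size=n)

    lam0 = math.log(2.0) / cfg.baseline_median_survival
    lam = np.where(latent == 1, lam0 * hazard_ratio, lam0)
    event_time = rng.exponential(1.0 / lam)
    if cfg.censor_rate > 0:
        lam_censor = (
            cfg.censor_rate / (1.0 - cfg.censor_rate) * float(lam.mean())
            if cfg.censor_rate < 1 else np.inf
        )
        censor_time = (
            rng.exponential(1.0 / lam_censor, size=n)
            if np.isfinite(lam_censor) else np.zeros(n)
        )
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(1, n + 1)],
            "expr_a": expr_a,
            "expr_b": expr_b,
            "time": time,
            "event": event,
        }
    )
    return patients, latent


def simulate(cfg: SimulationConfig) -> SyntheticBundle:
    """Generate a full synthetic input bundle, deterministic given the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    universe = [f"g{i:04d}" for i in range(cfg.universe_size)]
    pathways = []
    for p in range(cfg.n_pathways):
        genes = [
            str(g) for g in rng.choice(
                universe, size=cfg.genes_per_pathway, replace=False
            )
        ]
        pathways.append(
            _make_pathway(f"path{p + 1:03d}", genes, cfg.pathway_topology, rng)
        )
    subpathways = mine_all(pathways, k=cfg.k_subpathway)

    groups = cfg.resolved_groups()
    shared_ids = _resolve_shared(groups, subpathways)
    by_id = {sp.subpathway_id: sp for sp in subpathways}
    shared_pool: dict[str, list[str]] = {}
    for group in groups:
        pool = sorted(
            set().union(*(by_id[s].genes for s in shared_ids[group.members]))
        )
        for member in group.members:
            shared_pool[member] = pool

    targets, target_truth = _draw_targets(cfg, rng, universe, shared_pool)
    expression, deg_truth = _draw_expression(cfg, rng, universe, target_truth)
    patients, latent = _draw_patients(cfg, rng, cfg.hazard_ratio)

    truth = {
        "planted_groups": [
            {
                "members": list(group.members),
                "shared_subpathways": list(shared_ids[group.members]),
                "sharing": group.sharing,
            }
            for group in groups
        ],
        "target_origin": target_truth,
        "degs": deg_truth,
        "survival_group": latent,
    }
    return SyntheticBundle(
        pathways=pathways,
        subpathways=subpathways,
        targets=targets,
        expression=expression,
        directions=cfg.directions(),
        patients=patients,
        truth=truth,
        config=cfg,
    )


def survival_cohort(cfg: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw only the patient cohort (two latent groups at the configured
    hazard ratio), without the rest of the bundle."""
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    patients, latent = _draw_patients(cfg, rng, cfg.hazard_ratio)
    patients = patients.copy()
    patients["latent_group"] = latent
    return patients


def survival_null(cfg: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Patients under the survival null: hazard ratio forced to 1.

    Both latent groups are exchangeable, so any split of the cohort has the
    nominal log-rank type-I error; used for calibration checks.
    """
    cfg = replace(cfg, hazard_ratio=1.0, seed=cfg.seed if seed is None else seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    patients, _ = _draw_patients(cfg, rng, hazard_ratio=1.0)
    return patients
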