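"""Curation of effective miRNA target sets.

Predicted targets are kept when supported by at least ``min_programs`` of the
eleven prediction algorithms, then intersected with fold-change DEGs called
from tumor/normal expression.  Fold change is the ratio of group means on the
linear scale; a gene is differentially expressed when that ratio is at least
the threshold in either direction.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .io import ExpressionMatrix

log = logging.getLogger(__name__)

N_PREDICTION_PROGRAMS = 11


def filter_by_support(
    table: pd.DataFrame, min_programs: int = 4
) -> dict[str, frozenset[str]]:
    """Per-miRNA predicted target sets supported by >= ``min_programs``.

    ``table`` has columns mirna, gene, support (0..11).  Every miRNA in the
    table appears in the result, possibly with an empty set.
    """
    if not 1 <= min_programs <= N_PREDICTION_PROGRAMS:
        raise ValueError(
            f"min_programs must be in 1..{N_PREDICTION_PROGRAMS}, got {min_programs}"
        )
    if len(table) and (
        (table["support"] < 0) | (table["support"] > N_PREDICTION_PROGRAMS)
    ).any():
        raise ValueError("support counts must be in 0..11")
    kept = table[table["support"] >= min_programs]
    result = {mirna: frozenset() for mirna in table["mirna"].unique()}
    for mirna, group in kept.groupby("mirna"):
        result[str(mirna)] = frozenset(group["gene"])
    return result


def deg_table(
    expression: ExpressionMatrix, fold_threshold: float = 1.5
) -> pd.DataFrame:
    """Per-gene fold change (tumor mean / normal mean) and DEG flag.

    Genes whose normal or tumor mean is non-positive are excluded with a
    warning (expression is assumed background-corrected and positive).
    """
    if fold_threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    tumor, normal = expression.tumor, expression.normal
    if tumor.shape[1] == 0 or normal.shape[1] == 0:
        raise ValueError("need at least one tumor and one normal sample")
    tumor_mean = tumor.mean(axis=1)
    normal_mean = normal.mean(axis=1)
    bad = (normal_mean <= 0) | (tumor_mean <= 0)
    if bad.any():
        log.warning(
            "%d gene(s) with non-positive group mean excluded from DEG calling: %s",
            int(bad.sum()), list(expression.values.index[bad][:10]),
        )
    fold = tumor_mean[~bad] / normal_mean[~bad]
    is_deg = (fold >= fold_threshold) | (fold <= 1.0 / fold_threshold)
    return pd.DataFrame(
        {"gene": fold.index, "fold_change": fold.values, "is_deg": is_deg.values}
    )


def call_degs(
    expression: ExpressionMatrix, fold_threshold: float = 1.5
) -> frozenset[str]:
    """Genes with tumor/normal fold change >= threshold or <= 1/threshold."""
    table = deg_table(expression, fold_threshold)
    return frozenset(table.loc[table["is_deg"], "gene"])


def combine_degs(
    deg_sets: Iterable[Iterable[str]], rule: str = "union"
) -> frozenset[str]:
    """Merge DEG calls from several expression series (union or intersection)."""
    sets = [frozenset(s) for s in deg_sets]
    if not sets:
        return frozenset()
    if rule == "union":
        return frozenset().union(*sets)
    if rule == "intersection":
        return frozenset.intersection(*sets)
    raise ValueError(f"unknown DEG combination rule {rule!r}")


def effective_targets(
    filtered: Mapping[str, Iterable[str]], degs: Iterable[str]
) -> dict[str, frozenset[str]]:
    """Intersect each miRNA's supported targets with the DEG set.

    miRNAs whose intersection is empty are retained with an empty set and
    logged, so downstream stages see the full miRNA roster.
    """
    degs = frozenset(degs)
    result: dict[str, frozenset[str]] = {}
    for mirna, genes in filtered.items():
        result[mirna] = frozenset(genes) & degs
        if not result[mirna]:
            log.info("miRNA %s has no effective targets after DEG intersection", mirna)
    return result
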