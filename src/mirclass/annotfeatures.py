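"""Binary target-gene and pathway descriptors per miRNA.

A miRNA gets ``gene_<SYMBOL> = 1`` when a prediction links it to that gene
with a confidence score at or above the "high-potential" threshold
(default 80, the conventional cutoff for confident miRDB predictions), and
``path_<slug> = 1`` when at least one of its passing target genes belongs to
the pathway's gene set.  Pathway membership is binary, not count-valued.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, DomainError
from .seqio import BINARY, FeatureTable, PathwayGeneSets, TargetGeneMap
from .seqio import merge_tables as merge_tables  # re-export: same exchange layer

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationDescriptorConfig",
    "target_gene_descriptors",
    "pathway_descriptors",
    "merge_tables",
]


@dataclass(frozen=True)
class AnnotationDescriptorConfig:
    """Configuration for the annotation-descriptor blocks.

    Parameters
    ----------
    score_threshold : minimum prediction score (0-100) for a target to count
        as high-potential.  Default 80.
    max_genes_per_mirna : optional cap; keeps only the top-scoring genes per
        miRNA before building descriptors.
    gene_universe : optional explicit gene list fixing the descriptor
        columns (for reproducible deployment); default is the union of all
        passing targets of the miRNAs being featurized.
    """

    score_threshold: float = 80.0
    max_genes_per_mirna: int | None = None
    gene_universe: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 100.0:
            raise ConfigError("score_threshold must lie in [0, 100]")
        if self.max_genes_per_mirna is not None and self.max_genes_per_mirna < 1:
            raise ConfigError("max_genes_per_mirna must be >= 1 when set")


def _passing_targets(
    targets: TargetGeneMap, mirnas: Sequence[str], config: AnnotationDescriptorConfig
) -> dict[str, set[str]]:
    """High-potential gene set per miRNA after threshold and optional cap."""
    per_mirna: dict[str, list[tuple[str, float]]] = {m: [] for m in mirnas}
    for (mirna, gene), score in targets.entries.items():
        if mirna in per_mirna and score >= config.score_threshold:
            per_mirna[mirna].append((gene, score))
    out: dict[str, set[str]] = {}
    for mirna, pairs in per_mirna.items():
        if config.max_genes_per_mirna is not None:
            pairs = sorted(pairs, key=lambda p: (-p[1], p[0]))[
                : config.max_genes_per_mirna
            ]
        out[mirna] = {g for g, _ in pairs}
    return out


def target_gene_descriptors(
    targets: TargetGeneMap,
    mirnas: Sequence[str],
    config: AnnotationDescriptorConfig | None = None,
) -> FeatureTable:
    """One binary ``gene_<SYMBOL>`` attribute per gene in the universe.

    The cell is 1 iff the (miRNA, gene) prediction passes the score
    threshold.  miRNAs with no passing target get all-zero rows and are
    reported in the coverage log.  Columns are sorted by gene symbol unless
    an explicit ``gene_universe`` fixes the order.
    """
    if not mirnas:
        raise DomainError("target_gene_descriptors requires at least one miRNA id")
    config = config or AnnotationDescriptorConfig()
    passing = _passing_targets(targets, mirnas, config)
    if config.gene_universe is not None:
        universe = [g.upper() for g in config.gene_universe]
    else:
        universe = sorted(set().union(*passing.values()))
    if not universe:
        raise ConfigError(
            "empty gene universe: no target passes "
            f"score_threshold={config.score_threshold}"
        )
    uncovered = [m for m in mirnas if not passing[m]]
    if uncovered:
        logger.info(
            "target coverage: %d/%d miRNAs have no passing target (%s)",
            len(uncovered),
            len(mirnas),
            ", ".join(uncovered[:5]) + ("..." if len(uncovered) > 5 else ""),
        )
    values = np.zeros((len(mirnas), len(universe)))
    col = {g: j for j, g in enumerate(universe)}
    for i, mirna in enumerate(mirnas):
        for gene in passing[mirna]:
            if gene in col:
                values[i, col[gene]] = 1.0
    return FeatureTable(
        ids=list(mirnas),
        attributes=[(f"gene_{g}", BINARY) for g in universe],
        values=values,
    )


_SLUG_RE = re.compile(r"[^A-Za-z0-9]+")


def _slug(name: str) -> str:
    return _SLUG_RE.sub("_", name).strip("_")


def pathway_descriptors(
    targets: TargetGeneMap,
    pathways: PathwayGeneSets,
    mirnas: Sequence[str],
    config: AnnotationDescriptorConfig | None = None,
) -> FeatureTable:
    """One binary ``path_<slug>`` attribute per pathway.

    The cell is 1 iff any high-potential target gene of the miRNA belongs to
    the pathway's gene set.  Pathways disjoint from every passing target are
    kept as all-zero columns (with a log warning).
    """
    if not mirnas:
        raise DomainError("pathway_descriptors requires at least one miRNA id")
    if not pathways.pathways:
        raise ConfigError("no pathways provided")
    config = config or AnnotationDescriptorConfig()
    passing = _passing_targets(targets, mirnas, config)
    names = list(pathways.pathways)
    values = np.zeros((len(mirnas), len(names)))
    for j, name in enumerate(names):
        gene_set = pathways.pathways[name]
        for i, mirna in enumerate(mirnas):
            if passing[mirna] & gene_set:
                values[i, j] = 1.0
        if not values[:, j].any():
            logger.warning(
                "pathway %r shares no gene with any passing target "
                "(all-zero column retained)",
                name,
            )
    return FeatureTable(
        ids=list(mirnas),
        attributes=[(f"path_{_slug(n)}", BINARY) for n in names],
        values=values,
    )
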