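"""High-level composition helpers tying the pipeline stages together."""

from __future__ import annotations

from .annotfeatures import (
    AnnotationDescriptorConfig,
    pathway_descriptors,
    target_gene_descriptors,
)
from .seqfeatures import SequenceDescriptorConfig, featurize_sequences
from .seqio import FeatureTable, merge_tables
from .synthdata import SyntheticConfig, generate

__all__ = ["synthetic_feature_table"]


def synthetic_feature_table(
    config: SyntheticConfig,
    seq_config: SequenceDescriptorConfig | None = None,
    annot_config: AnnotationDescriptorConfig | None = None,
) -> FeatureTable:
    """Draw a synthetic benchmark and featurize it into one labeled table.

    Sequence block + target-gene block + pathway block, merged over the
    generated miRNAs, with class labels attached.
    """
    records, labels, targets, pathways = generate(config)
    ids = [r.id for r in records]
    blocks = [
        featurize_sequences(records, seq_config),
        target_gene_descriptors(targets, ids, annot_config),
        pathway_descriptors(targets, pathways, ids, annot_config),
    ]
    return merge_tables(blocks).with_labels(labels)
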