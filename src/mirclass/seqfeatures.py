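"""Sequence-based descriptors for mature miRNAs.

For each miRNA the package computes nucleotide composition (counts and
frequencies of A/C/G/U), sequence length and GC fraction, single-strand
molecular weight, Watson-Crick hydrogen-bond capacity, optionally the 16
dinucleotide frequencies, and binary presence flags for a configurable motif
list.  The hypothesis behind these descriptors is that sequence composition
governs a miRNA's ability to bind its target mRNAs.

The molecular-weight model is the standard single-stranded RNA sum of
residue masses plus one water (5'-OH/3'-OH convention); the hydrogen-bond
count is the pairing capacity of the strand were every base paired
(3 bonds per G or C, 2 per A or U).  Both conventions are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigError, DomainError
from .seqio import BINARY, NUMERIC, RNA_ALPHABET, FeatureTable, MiRNARecord

BASES = "ACGU"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

#: Average residue (nucleotide monophosphate minus water) masses in daltons.
DEFAULT_RESIDUE_MASSES: dict[str, float] = {
    "A": 329.2,
    "C": 305.2,
    "G": 345.2,
    "U": 306.2,
}
#: One water for the free 5'-OH / 3'-OH ends.
DEFAULT_TERMINAL_MASS = 18.0

#: Default motif panel: seed heptamers (positions 2-8) of broadly studied
#: cancer-implicated miRNA families.  Placeholders — the panel is expected to
#: be replaced per study via :class:`SequenceDescriptorConfig`.
DEFAULT_MOTIFS: tuple[str, ...] = (
    "AGCUUAU",  # miR-21 seed
    "GAGGUAG",  # let-7 seed
    "UAAUGCU",  # miR-155 seed
    "GGCAGUG",  # miR-34a seed
    "GGCAAGA",  # miR-31 seed
    "AAUACUG",  # miR-200a seed
    "AAAGUGC",  # miR-17/92 seed
    "CCUUCAU",  # miR-205 seed
)


def _check_rna(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise DomainError(f"empty {what}")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise DomainError(
            f"{what} contains non-RNA characters: {''.join(sorted(bad))}"
        )


@dataclass(frozen=True)
class SequenceDescriptorConfig:
    """Configuration for the sequence-descriptor block.

    Parameters
    ----------
    motifs : RNA strings tested for substring presence (one binary
        attribute each, in list order).
    include_dinucleotides : add the 16 dinucleotide frequencies.
    residue_masses : per-base residue mass in daltons.
    terminal_mass : constant added once per sequence (water, 18 Da).
    """

    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    include_dinucleotides: bool = True
    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_MASSES)
    )
    terminal_mass: float = DEFAULT_TERMINAL_MASS

    def __post_init__(self) -> None:
        for m in self.motifs:
            if not m:
                raise ConfigError("motifs must be non-empty strings")
            bad = set(m) - RNA_ALPHABET
            if bad:
                raise ConfigError(
                    f"motif {m!r} contains non-RNA characters: {''.join(sorted(bad))}"
                )
        if set(self.residue_masses) != set(BASES):
            raise ConfigError("residue_masses must define exactly A, C, G, U")
        if any(v <= 0 for v in self.residue_masses.values()):
            raise ConfigError("residue masses must be positive")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SequenceDescriptorConfig":
        kwargs = {}
        if "motifs" in data:
            kwargs["motifs"] = tuple(data["motifs"])
        if "include_dinucleotides" in data:
            kwargs["include_dinucleotides"] = bool(data["include_dinucleotides"])
        if "residue_masses" in data:
            kwargs["residue_masses"] = {
                str(k).upper(): float(v) for k, v in data["residue_masses"].items()
            }
        if "terminal_mass" in data:
            kwargs["terminal_mass"] = float(data["terminal_mass"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# elementary descriptors
# ---------------------------------------------------------------------------


def composition(seq: str) -> dict[str, float]:
    """Counts and frequencies per base, plus length and GC fraction.

    Returns a dict with keys ``n_A .. n_U``, ``f_A .. f_U``, ``length`` and
    ``gc_fraction``.  Counts sum to the length and frequencies to 1.
    """
    _check_rna(seq)
    n = len(seq)
    counts = {b: seq.count(b) for b in BASES}
    out: dict[str, float] = {f"n_{b}": float(counts[b]) for b in BASES}
    out.update({f"f_{b}": counts[b] / n for b in BASES})
    out["length"] = float(n)
    out["gc_fraction"] = (counts["G"] + counts["C"]) / n
    return out


def molecular_weight(
    seq: str,
    residue_masses: Mapping[str, float] | None = None,
    terminal_mass: float = DEFAULT_TERMINAL_MASS,
) -> float:
    """Single-strand molecular weight: sum of residue masses plus one water."""
    _check_rna(seq)
    masses = DEFAULT_RESIDUE_MASSES if residue_masses is None else residue_masses
    return sum(masses[b] for b in seq) + terminal_mass


def hydrogen_bond_count(seq: str) -> int:
    """Watson-Crick pairing capacity: 3 bonds per G/C, 2 per A/U."""
    _check_rna(seq)
    gc = seq.count("G") + seq.count("C")
    return 3 * gc + 2 * (len(seq) - gc)


def dinucleotide_frequencies(seq: str) -> dict[str, float]:
    """Frequencies of the 16 dinucleotides over the length-1 sliding windows.

    For a single-base sequence all 16 frequencies are 0.
    """
    _check_rna(seq)
    counts = {d: 0 for d in DINUCLEOTIDES}
    n_windows = len(seq) - 1
    if n_windows < 1:
        return {f"f_{d}": 0.0 for d in DINUCLEOTIDES}
    for i in range(n_windows):
        counts[seq[i : i + 2]] += 1
    return {f"f_{d}": counts[d] / n_windows for d in DINUCLEOTIDES}


def motif_presence(seq: str, motifs: Sequence[str]) -> list[int]:
    """1 per motif occurring as a contiguous substring (overlaps allowed)."""
    _check_rna(seq)
    for m in motifs:
        if not m or set(m) - RNA_ALPHABET:
            raise ConfigError(f"motif {m!r} is not a valid RNA string")
    return [1 if m in seq else 0 for m in motifs]


# ---------------------------------------------------------------------------
# sklearn-style extractor + table-level wrapper
# ---------------------------------------------------------------------------

_COMPOSITION_NAMES = (
    [f"n_{b}" for b in BASES]
    + [f"f_{b}" for b in BASES]
    + ["length", "gc_fraction", "mol_weight", "h_bond_count"]
)


class SequenceDescriptorExtractor(TransformerMixin, BaseEstimator):
    """Transform RNA sequences into the numeric/binary descriptor matrix.

    Analogous to a text vectorizer: ``fit`` only freezes the output schema,
    ``transform`` maps a list of RNA strings to a ``(n, p)`` float array with
    ``p = 12 + 16*include_dinucleotides + len(motifs)``.

    Parameters
    ----------
    motifs : sequence of RNA strings; one binary presence column each.
    include_dinucleotides : whether to emit the 16 dinucleotide frequencies.
    residue_masses, terminal_mass : molecular-weight model constants.
    """

    def __init__(
        self,
        motifs: Sequence[str] = DEFAULT_MOTIFS,
        include_dinucleotides: bool = True,
        residue_masses: Mapping[str, float] | None = None,
        terminal_mass: float = DEFAULT_TERMINAL_MASS,
    ):
        self.motifs = motifs
        self.include_dinucleotides = include_dinucleotides
        self.residue_masses = residue_masses
        self.terminal_mass = terminal_mass

    def _config(self) -> SequenceDescriptorConfig:
        return SequenceDescriptorConfig(
            motifs=tuple(self.motifs),
            include_dinucleotides=self.include_dinucleotides,
            residue_masses=dict(self.residue_masses)
            if self.residue_masses is not None
            else dict(DEFAULT_RESIDUE_MASSES),
            terminal_mass=self.terminal_mass,
        )

    def fit(self, X: Iterable[str] | None = None, y=None):
        cfg = self._config()
        names = list(_COMPOSITION_NAMES)
        kinds = [NUMERIC] * len(names)
        if cfg.include_dinucleotides:
            names += [f"f_{d}" for d in DINUCLEOTIDES]
            kinds += [NUMERIC] * 16
        names += [f"motif_{m}" for m in cfg.motifs]
        kinds += [BINARY] * len(cfg.motifs)
        self.feature_names_out_ = np.asarray(names, dtype=object)
        self.feature_kinds_ = kinds
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        cfg = self._config()
        rows = []
        for seq in X:
            comp = composition(seq)
            row = [comp[k] for k in _COMPOSITION_NAMES[:10]]
            row.append(molecular_weight(seq, cfg.residue_masses, cfg.terminal_mass))
            row.append(float(hydrogen_bond_count(seq)))
            if cfg.include_dinucleotides:
                dn = dinucleotide_frequencies(seq)
                row += [dn[f"f_{d}"] for d in DINUCLEOTIDES]
            row += [float(v) for v in motif_presence(seq, cfg.motifs)]
            rows.append(row)
        return np.asarray(rows, dtype=float).reshape(len(rows), len(self.feature_names_out_))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        return self.feature_names_out_


def featurize_sequences(
    records: Sequence[MiRNARecord],
    config: SequenceDescriptorConfig | None = None,
) -> FeatureTable:
    """Compute the full sequence-descriptor block as a :class:`FeatureTable`.

    Attribute order is deterministic: the 12-column composition block
    (4 counts, 4 frequencies, length, GC fraction, molecular weight,
    hydrogen-bond count), then the optional 16 dinucleotide frequencies,
    then the motif flags in config order.
    """
    if not records:
        raise DomainError("featurize_sequences requires at least one record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise DomainError("duplicate miRNA ids in input records")
    config = config or SequenceDescriptorConfig()
    extractor = SequenceDescriptorExtractor(
        motifs=config.motifs,
        include_dinucleotides=config.include_dinucleotides,
        residue_masses=dict(config.residue_masses),
        terminal_mass=config.terminal_mass,
    ).fit()
    values = extractor.transform([r.sequence for r in records])
    attributes = list(
        zip([str(n) for n in extractor.feature_names_out_], extractor.feature_kinds_)
    )
    return FeatureTable(ids=ids, attributes=attributes, values=values)
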