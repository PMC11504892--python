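"""Readers and writers for the formats the pipeline touches.

* mature-miRNA FASTA in the miRBase ``mature.fa`` layout (id is the first
  header token, the rest of the line is a free-text description),
* miRDB-export-style target tables (TSV: miRNA id, gene symbol, score 0-100),
* pathway gene sets (TSV ``name<TAB>genes`` or GMT, auto-detected by
  extension),
* feature tables as WEKA ARFF (nominal class last) and as CSV.

The :class:`FeatureTable` defined here is the central exchange object of the
pipeline: an instances x attributes matrix with named, typed (numeric or
binary) attributes and an optional binary class label per instance.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .exceptions import (
    AlphabetError,
    DomainError,
    FormatError,
    TableAlignmentError,
)

RNA_ALPHABET = frozenset("ACGU")

POSITIVE_LABEL = "positive"
NEGATIVE_LABEL = "negative"
LABELS = (NEGATIVE_LABEL, POSITIVE_LABEL)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MiRNARecord:
    """One mature miRNA: accession-like id, RNA sequence, free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise DomainError("miRNA record requires a non-empty id")
        if len(self.sequence) < 1:
            raise DomainError(f"miRNA {self.id!r} has an empty sequence")


@dataclass
class TargetGeneMap:
    """Predicted miRNA -> target-gene interactions with confidence scores.

    ``entries`` maps ``(mirna_id, gene_symbol)`` to a score in [0, 100]
    (miRDB convention).  Gene symbols are uppercase-canonicalized; duplicate
    pairs are rejected on construction.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (mirna, gene), score in self.entries.items():
            if not 0.0 <= score <= 100.0:
                raise DomainError(
                    f"target score for ({mirna}, {gene}) outside [0, 100]: {score}"
                )

    def add(self, mirna: str, gene: str, score: float) -> None:
        gene = gene.upper()
        key = (mirna, gene)
        if key in self.entries:
            raise FormatError(f"duplicate target entry for ({mirna}, {gene})")
        if not 0.0 <= score <= 100.0:
            raise DomainError(
                f"target score for ({mirna}, {gene}) outside [0, 100]: {score}"
            )
        self.entries[key] = float(score)

    def genes_for(self, mirna: str, min_score: float = 0.0) -> set[str]:
        return {
            g for (m, g), s in self.entries.items() if m == mirna and s >= min_score
        }

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PathwayGeneSets:
    """Named pathway -> member gene symbols (uppercase-canonicalized)."""

    pathways: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise FormatError(f"pathway {name!r} has an empty gene set")

    def add(self, name: str, genes: Iterable[str]) -> None:
        if name in self.pathways:
            raise FormatError(f"duplicate pathway name {name!r}")
        gene_set = frozenset(g.upper() for g in genes if g)
        if not gene_set:
            raise FormatError(f"pathway {name!r} has an empty gene set")
        self.pathways[name] = gene_set

    def __len__(self) -> int:
        return len(self.pathways)


NUMERIC = "numeric"
BINARY = "binary"
_KINDS = (NUMERIC, BINARY)


@dataclass
class FeatureTable:
    """Instances x named attributes, plus an optional binary class label.

    Parameters
    ----------
    ids : ordered unique instance identifiers (miRNA ids).
    attributes : ordered ``(name, kind)`` pairs, kind in ``{numeric, binary}``.
    values : float matrix of shape ``(len(ids), len(attributes))``.
    labels : optional array of ``"positive"``/``"negative"`` per instance.
    """

    ids: list[str]
    attributes: list[tuple[str, str]]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.attributes = [(str(n), str(k)) for n, k in self.attributes]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.ids),
            len(self.attributes),
        ):
            raise DomainError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.attributes)} attributes"
            )
        if len(set(self.ids)) != len(self.ids):
            raise DomainError("instance ids must be unique")
        names = [n for n, _ in self.attributes]
        if len(set(names)) != len(names):
            raise DomainError("attribute names must be unique")
        for j, (name, kind) in enumerate(self.attributes):
            if kind not in _KINDS:
                raise DomainError(f"attribute {name!r} has unknown kind {kind!r}")
            if kind == BINARY and self.values.shape[0]:
                col = self.values[:, j]
                if not np.all(np.isin(col, (0.0, 1.0))):
                    raise DomainError(f"binary attribute {name!r} has non-0/1 values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (len(self.ids),):
                raise DomainError("labels length does not match instance count")
            bad = set(self.labels) - set(LABELS)
            if bad:
                raise DomainError(f"unknown class labels: {sorted(bad)}")

    # -- convenience accessors ------------------------------------------------

    @property
    def n_instances(self) -> int:
        return len(self.ids)

    @property
    def attribute_names(self) -> list[str]:
        return [n for n, _ in self.attributes]

    @property
    def attribute_kinds(self) -> list[str]:
        return [k for _, k in self.attributes]

    @property
    def X(self) -> np.ndarray:
        return self.values

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise DomainError("feature table has no class labels")
        return self.labels

    def select(self, names: Sequence[str]) -> "FeatureTable":
        """Column subset preserving the requested order."""
        index = {n: j for j, (n, _) in enumerate(self.attributes)}
        missing = [n for n in names if n not in index]
        if missing:
            raise DomainError(f"unknown attributes: {missing}")
        cols = [index[n] for n in names]
        return FeatureTable(
            ids=list(self.ids),
            attributes=[self.attributes[j] for j in cols],
            values=self.values[:, cols].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def with_labels(self, labels: Mapping[str, str] | Sequence[str]) -> "FeatureTable":
        if isinstance(labels, Mapping):
            try:
                arr = [labels[i] for i in self.ids]
            except KeyError as exc:
                raise DomainError(f"no label for instance {exc.args[0]!r}") from exc
        else:
            arr = list(labels)
        return FeatureTable(
            ids=list(self.ids),
            attributes=list(self.attributes),
            values=self.values.copy(),
            labels=np.asarray(arr, dtype=object),
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, index=self.ids, columns=self.attribute_names)
        if self.labels is not None:
            df["class"] = self.labels
        return df


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _canonicalize_sequence(
    record_id: str, seq: str, canonicalize: bool, strict: bool
) -> str:
    if canonicalize:
        seq = seq.upper()
        if not strict:
            seq = seq.replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"record {record_id!r}: non-RNA characters after canonicalization: "
            f"{''.join(sorted(bad))}"
        )
    return seq


def read_mirna_fasta(
    path: str | Path, canonicalize: bool = True, strict: bool = False
) -> list[MiRNARecord]:
    """Read mature miRNAs from a miRBase-dialect FASTA file.

    The first whitespace-delimited header token is the record id; the rest of
    the header line is kept as the description.  With ``canonicalize`` (the
    default) sequences are uppercased and DNA ``T`` is mapped to RNA ``U``;
    ``strict`` disables the T->U mapping so DNA-alphabet input is rejected.

    Raises
    ------
    FormatError
        on malformed FASTA (with the offending line number) or duplicate ids.
    AlphabetError
        if a sequence contains non-``ACGU`` characters after canonicalization.
    """
    path = Path(path)
    # Pre-scan so malformed input is reported with a line number; Bio.SeqIO
    # does not carry that information.
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}:{lineno}: expected FASTA header starting with '>'"
                    )
                break
    records: list[MiRNARecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate miRNA id {rec.id!r} in {path}")
            seen.add(rec.id)
            description = rec.description[len(rec.id) :].strip()
            seq = _canonicalize_sequence(rec.id, str(rec.seq), canonicalize, strict)
            records.append(MiRNARecord(id=rec.id, sequence=seq, description=description))
    return records


def write_mirna_fasta(records: Iterable[MiRNARecord], path: str | Path) -> None:
    """Write records as single-line-sequence FASTA (deterministic bytes)."""
    with open(path, "w", newline="\n") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(f"{header}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# target tables and pathway sets
# ---------------------------------------------------------------------------


def read_target_table(path: str | Path) -> TargetGeneMap:
    """Read a miRDB-export-style TSV of (miRNA id, gene symbol, score).

    A header row is tolerated (detected by a non-numeric third field on the
    first line).  Rows whose score does not parse raise a
    :class:`FormatError` naming the row number.
    """
    path = Path(path)
    targets = TargetGeneMap()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns "
                    f"(miRNA, gene, score), got {len(fields)}"
                )
            mirna, gene, score_text = fields[0], fields[1], fields[2]
            try:
                score = float(score_text)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise FormatError(
                    f"{path}:{lineno}: unparseable score {score_text!r}"
                ) from None
            try:
                targets.add(mirna, gene, score)
            except DomainError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return targets


def read_pathway_sets(path: str | Path) -> PathwayGeneSets:
    """Read pathway gene sets from TSV or GMT (chosen by file extension).

    TSV lines are ``pathway name<TAB>gene,gene,...`` (comma- or
    tab-separated genes); GMT lines are ``name<TAB>description<TAB>gene...``.
    Gene symbols are uppercased; blank lines are skipped; a pathway with no
    genes or a duplicated name is a format error.
    """
    path = Path(path)
    gmt = path.suffix.lower() == ".gmt"
    sets = PathwayGeneSets()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            name = fields[0].strip()
            if gmt:
                genes = [g.strip() for g in fields[2:] if g.strip()]
            else:
                rest = fields[1:]
                if len(rest) == 1 and "," in rest[0]:
                    genes = [g.strip() for g in rest[0].split(",") if g.strip()]
                else:
                    genes = [g.strip() for g in rest if g.strip()]
            try:
                sets.add(name, genes)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return sets


# ---------------------------------------------------------------------------
# ARFF
# ---------------------------------------------------------------------------

_ARFF_SAFE = re.compile(r"^[A-Za-z0-9_.+-]+$")


def _arff_quote(name: str) -> str:
    if _ARFF_SAFE.match(name):
        return name
    escaped = name.replace("\\", "\\\\").replace("'", "\\'")
    return f"'{escaped}'"


def _format_numeric(v: float) -> str:
    # repr() of a float is the shortest string that round-trips exactly,
    # which satisfies the >= 10 significant digit contract.
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def write_arff(
    table: FeatureTable,
    path: str | Path,
    relation: str = "mirna_features",
    comment: str | None = None,
) -> None:
    """Write a feature table as WEKA ARFF.

    Instance ids are written as a leading ``string`` attribute; binary
    attributes are declared as nominal ``{0,1}``; the class is declared as
    nominal ``{negative,positive}`` and placed last (``?`` when the table has
    no labels).  Output bytes are deterministic for a given table.
    """
    buf = io.StringIO()
    if comment:
        for line in comment.splitlines():
            buf.write(f"% {line}\n")
    buf.write(f"@relation {_arff_quote(relation)}\n\n")
    buf.write("@attribute id string\n")
    for name, kind in table.attributes:
        if kind == BINARY:
            buf.write(f"@attribute {_arff_quote(name)} {{0,1}}\n")
        else:
            buf.write(f"@attribute {_arff_quote(name)} numeric\n")
    buf.write("@attribute class {negative,positive}\n\n@data\n")
    for i, inst_id in enumerate(table.ids):
        cells = [_arff_quote(inst_id)]
        for j, (_, kind) in enumerate(table.attributes):
            v = table.values[i, j]
            cells.append(str(int(v)) if kind == BINARY else _format_numeric(v))
        cells.append("?" if table.labels is None else str(table.labels[i]))
        buf.write(",".join(cells) + "\n")
    with open(path, "w", newline="\n") as handle:
        handle.write(buf.getvalue())


_ATTR_RE = re.compile(
    r"@attribute\s+(?:'((?:[^'\\]|\\.)*)'|(\S+))\s+(.+?)\s*$", re.IGNORECASE
)


def _split_arff_row(line: str) -> list[str]:
    reader = csv.reader([line], delimiter=",", quotechar="'", skipinitialspace=True)
    return next(reader)


def read_arff(path: str | Path) -> FeatureTable:
    """Read a feature table written by :func:`write_arff`.

    Accepts the subset of ARFF that writer emits: a leading ``id`` string
    attribute, numeric and ``{0,1}`` nominal attributes, and a trailing
    ``class {negative,positive}`` attribute (``?`` meaning unlabeled).
    """
    path = Path(path)
    attributes: list[tuple[str, str]] = []  # includes id/class markers
    data_lines: list[tuple[int, str]] = []
    in_data = False
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if in_data:
                data_lines.append((lineno, line))
            elif low.startswith("@relation"):
                continue
            elif low.startswith("@attribute"):
                m = _ATTR_RE.match(line)
                if not m:
                    raise FormatError(f"{path}:{lineno}: malformed @attribute line")
                name = (
                    m.group(1).replace("\\'", "'").replace("\\\\", "\\")
                    if m.group(1) is not None
                    else m.group(2)
                )
                spec = m.group(3).strip()
                if spec.lower() == "string":
                    kind = "string"
                elif spec.lower() in ("numeric", "real", "integer"):
                    kind = NUMERIC
                elif spec.startswith("{"):
                    values = {v.strip() for v in spec.strip("{}").split(",")}
                    if values == {"0", "1"}:
                        kind = BINARY
                    elif values == {"negative", "positive"}:
                        kind = "class"
                    else:
                        raise FormatError(
                            f"{path}:{lineno}: unsupported nominal domain {spec}"
                        )
                else:
                    raise FormatError(
                        f"{path}:{lineno}: unsupported attribute type {spec!r}"
                    )
                attributes.append((name, kind))
            elif low.startswith("@data"):
                in_data = True
            else:
                raise FormatError(f"{path}:{lineno}: unexpected line {line!r}")
    if not in_data:
        raise FormatError(f"{path}: missing @data section")
    if not attributes or attributes[0] != ("id", "string"):
        raise FormatError(f"{path}: first attribute must be 'id string'")
    if attributes[-1][1] != "class":
        raise FormatError(f"{path}: last attribute must be the nominal class")
    feature_attrs = [(n, k) for n, k in attributes[1:-1]]

    ids: list[str] = []
    rows: list[list[float]] = []
    labels: list[str | None] = []
    for lineno, line in data_lines:
        cells = _split_arff_row(line)
        if len(cells) != len(attributes):
            raise FormatError(
                f"{path}:{lineno}: expected {len(attributes)} fields, got {len(cells)}"
            )
        ids.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:-1]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        labels.append(None if cells[-1] == "?" else cells[-1])
    if any(l is None for l in labels):
        if not all(l is None for l in labels):
            raise FormatError(f"{path}: mixture of labeled and unlabeled instances")
        label_arr = None
    else:
        label_arr = np.asarray(labels, dtype=object)
    values = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, len(feature_attrs)), dtype=float)
    )
    return FeatureTable(
        ids=ids, attributes=feature_attrs, values=values, labels=label_arr
    )


# ---------------------------------------------------------------------------
# CSV mirror
# ---------------------------------------------------------------------------


def write_csv(
    table: FeatureTable, path: str | Path, comment: str | None = None
) -> None:
    """CSV mirror of the ARFF writer (header row, comma delimiter, UTF-8).

    Columns: ``id``, one per attribute, ``class`` last (empty when
    unlabeled).  Optional ``comment`` lines are prefixed with ``#`` and are
    skipped by :func:`read_csv`.
    """
    with open(path, "w", newline="", encoding="utf-8") as handle:
        if comment:
            for line in comment.splitlines():
                handle.write(f"# {line}\n")
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["id", *table.attribute_names, "class"])
        for i, inst_id in enumerate(table.ids):
            cells: list[str] = [inst_id]
            for j, (_, kind) in enumerate(table.attributes):
                v = table.values[i, j]
                cells.append(str(int(v)) if kind == BINARY else _format_numeric(v))
            cells.append("" if table.labels is None else str(table.labels[i]))
            writer.writerow(cells)


def read_csv(
    path: str | Path, kinds: Sequence[str] | None = None
) -> FeatureTable:
    """Read a feature table written by :func:`write_csv`.

    CSV does not carry attribute kinds; unless ``kinds`` is given, a column
    is inferred binary iff every value is 0 or 1.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        lines = [l for l in handle if not l.startswith("#")]
    reader = csv.reader(lines)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError(f"{path}: empty CSV") from None
    if not header or header[0] != "id" or header[-1] != "class":
        raise FormatError(f"{path}: expected 'id' first and 'class' last in header")
    names = header[1:-1]
    ids: list[str] = []
    rows: list[list[float]] = []
    labels: list[str] = []
    for row in reader:
        if not row:
            continue
        if len(row) != len(header):
            raise FormatError(f"{path}: ragged CSV row for id {row[0]!r}")
        ids.append(row[0])
        rows.append([float(c) for c in row[1:-1]])
        labels.append(row[-1])
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(names)))
    if kinds is None:
        kinds = [
            BINARY
            if values.shape[0] and np.all(np.isin(values[:, j], (0.0, 1.0)))
            else NUMERIC
            for j in range(len(names))
        ]
    label_arr = None
    if labels and all(labels):
        label_arr = np.asarray(labels, dtype=object)
    elif labels and any(labels):
        raise FormatError(f"{path}: mixture of labeled and unlabeled instances")
    return FeatureTable(
        ids=ids,
        attributes=list(zip(names, kinds)),
        values=values,
        labels=label_arr,
    )


# ---------------------------------------------------------------------------
# label files
# ---------------------------------------------------------------------------


def read_labels(path: str | Path) -> dict[str, str]:
    """Read an ``id,label`` CSV (header optional) into a dict."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, row in enumerate(csv.reader(handle), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() == "id":
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'id,label'")
            mirna, label = row[0], row[1]
            if label not in LABELS:
                raise FormatError(
                    f"{path}:{lineno}: label must be one of {LABELS}, got {label!r}"
                )
            if mirna in out:
                raise FormatError(f"{path}:{lineno}: duplicate id {mirna!r}")
            out[mirna] = label
    return out


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["id", "label"])
        for mirna, label in labels.items():
            writer.writerow([mirna, label])


def write_target_table(targets: TargetGeneMap, path: str | Path) -> None:
    """Write a TSV target table (miRNA, gene, score) with a header row."""
    with open(path, "w", newline="\n") as handle:
        handle.write("mirna\tgene\tscore\n")
        for (mirna, gene), score in sorted(targets.entries.items()):
            handle.write(f"{mirna}\t{gene}\t{_format_numeric(score)}\n")


def write_pathway_sets(sets: PathwayGeneSets, path: str | Path) -> None:
    """Write pathway gene sets as TSV (name, comma-joined genes)."""
    with open(path, "w", newline="\n") as handle:
        for name, genes in sets.pathways.items():
            handle.write(f"{name}\t{','.join(sorted(genes))}\n")


def merge_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Column-wise concatenation of feature tables over identical instances.

    All tables must list the same instance ids in the same order and have
    disjoint attribute names; labels, where present, must agree.
    """
    if not tables:
        raise DomainError("merge_tables requires at least one table")
    first = tables[0]
    for t in tables[1:]:
        if t.ids != first.ids:
            raise TableAlignmentError(
                "tables do not share the same instance ids in the same order"
            )
    names: set[str] = set()
    for t in tables:
        dup = names & set(t.attribute_names)
        if dup:
            raise DomainError(f"duplicate attribute names across tables: {sorted(dup)}")
        names |= set(t.attribute_names)
    labels = None
    for t in tables:
        if t.labels is not None:
            if labels is not None and not np.array_equal(labels, t.labels):
                raise DomainError("merged tables carry conflicting labels")
            labels = t.labels
    return FeatureTable(
        ids=list(first.ids),
        attributes=[a for t in tables for a in t.attributes],
        values=np.hstack([t.values for t in tables])
        if first.n_instances
        else np.empty((0, sum(len(t.attributes) for t in tables))),
        labels=None if labels is None else labels.copy(),
    )
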