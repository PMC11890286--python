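"""File formats and dataset assembly for multi-modal ncRNA classification.

Four plain-text inputs describe a dataset: a FASTA file of sequences, a
Vienna-style dot-bracket file of secondary structures (three lines per
record: header, sequence, structure), a tab-separated expression matrix
(transcripts x conditions), and a tab-separated labels table (id, class).
A transcript absent from the expression file has a *missing* expression
modality; an all-zero row does not (absence, not zeros, signals missingness).

Coordinates in :class:`StructureGraph` are 0-based; anything serialised for
human consumption reports 1-based positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

#: IUPAC nucleotide letters accepted on input (after T->U normalisation).
IUPAC_LETTERS = set("ACGURYSWKMBDHVN")
#: Letters that carry a definite nucleotide identity; everything else maps to
#: the "other" category in graphs and to an all-zero one-hot column.
CANONICAL = ("A", "C", "G", "U")

MODALITY_NAMES = ("sequence", "structure", "expression")


class FormatError(ValueError):
    """Malformed input file."""


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class StructureRecord:
    id: str
    seq: str
    db: str

    def __post_init__(self):
        if len(self.db) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: structure length {len(self.db)} != "
                f"sequence length {len(self.seq)}")


@dataclass(frozen=True)
class StructureGraph:
    """Secondary structure as a graph: one node per nucleotide, backbone edges
    between adjacent positions, pair edges between base-paired positions."""
    node_types: Tuple[str, ...]           # each in {A, C, G, U, other}
    backbone_edges: Tuple[Tuple[int, int], ...]
    pair_edges: Tuple[Tuple[int, int], ...]

    @property
    def n_nodes(self) -> int:
        return len(self.node_types)


@dataclass
class ExpressionTable:
    values: pd.DataFrame                  # rows: transcripts, cols: conditions
    missing_rows: set = field(default_factory=set)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def condition_ids(self) -> List[str]:
        return list(self.values.columns)


@dataclass
class MultiModalSample:
    id: str
    seq: Optional[str]
    graph: Optional[StructureGraph]
    expression: Optional[np.ndarray]
    mask: np.ndarray                      # bool, one entry per modality
    label: Optional[int] = None


@dataclass
class MultiModalDataset:
    samples: List[MultiModalSample]
    modality_names: Tuple[str, ...]
    class_names: List[str]
    n_conditions: Optional[int] = None

    @property
    def M(self) -> int:
        return len(self.modality_names)

    def __len__(self) -> int:
        return len(self.samples)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def masks(self) -> np.ndarray:
        return np.stack([s.mask for s in self.samples])

    def subset(self, indices) -> "MultiModalDataset":
        return MultiModalDataset([self.samples[i] for i in indices],
                                 self.modality_names, list(self.class_names),
                                 self.n_conditions)


# --------------------------------------------------------------------- FASTA

def _normalise_seq(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_LETTERS:
            raise FormatError(
                f"record {rec_id!r}: non-IUPAC character {ch!r} at position {pos}")
    return seq


def read_fasta(path) -> List[SequenceRecord]:
    """Read a FASTA file; T is transcribed to U, case normalised to upper."""
    records: List[SequenceRecord] = []
    seen = set()
    with open(path) as fh:
        parsed = list(SeqIO.parse(fh, "fasta"))
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalise_seq(str(rec.seq), rec.id)
        if not seq:
            raise FormatError(f"record {rec.id!r}: empty sequence")
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise FormatError(f"empty FASTA file: {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


# --------------------------------------------------------- dot-bracket files

_OPEN, _CLOSE, _UNPAIRED = "(", ")", "."
_IGNORED_BRACKETS = set("[]{}<>") | set("abcdefghijklmnopqrstuvwxyz") \
    | set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


def _check_balanced(db: str, rec_id: str) -> None:
    depth = 0
    for ch in db:
        if ch == _OPEN:
            depth += 1
        elif ch == _CLOSE:
            depth -= 1
            if depth < 0:
                raise FormatError(f"record {rec_id!r}: unbalanced dot-bracket")
    if depth != 0:
        raise FormatError(f"record {rec_id!r}: unbalanced dot-bracket")


def read_dotbracket(path) -> List[StructureRecord]:
    """Read 3-line Vienna records (>id / sequence / dot-bracket)."""
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise FormatError(f"empty dot-bracket file: {path}")
    if len(lines) % 3 != 0:
        raise FormatError(f"{path}: expected (header, sequence, structure) triplets")
    records: List[StructureRecord] = []
    seen = set()
    for i in range(0, len(lines), 3):
        header, seq_line, db = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise FormatError(f"{path}: line {i + 1}: expected '>' header, got {header!r}")
        rec_id = header[1:].split()[0]
        if rec_id in seen:
            raise FormatError(f"duplicate id {rec_id!r} in {path}")
        seen.add(rec_id)
        seq = _normalise_seq(seq_line, rec_id)
        _check_balanced(db, rec_id)
        records.append(StructureRecord(id=rec_id, seq=seq, db=db))
    return records


def write_dotbracket(records: Sequence[StructureRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n{r.db}\n")


def dotbracket_to_graph(record: StructureRecord) -> StructureGraph:
    """Convert a dot-bracket structure to its graph representation.

    Backbone edges connect each adjacent pair of positions; pair edges come
    from stack-matching '(' with ')'. Non-round bracket characters (pseudoknot
    annotations such as '[' or '{') are treated as unpaired with a warning.
    """
    if len(record.db) == 0:
        raise FormatError(f"record {record.id!r}: empty structure string")
    node_types = tuple(ch if ch in CANONICAL else "other" for ch in record.seq)
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    warned = False
    for i, ch in enumerate(record.db):
        if ch == _OPEN:
            stack.append(i)
        elif ch == _CLOSE:
            if not stack:
                raise FormatError(f"record {record.id!r}: unbalanced dot-bracket")
            pairs.append((stack.pop(), i))
        elif ch == _UNPAIRED:
            continue
        elif ch in _IGNORED_BRACKETS:
            if not warned:
                warnings.warn(
                    f"record {record.id!r}: non-round bracket {ch!r} treated as "
                    "unpaired (pseudoknots are not modelled)")
                warned = True
        else:
            raise FormatError(
                f"record {record.id!r}: invalid structure character {ch!r}")
    if stack:
        raise FormatError(f"record {record.id!r}: unbalanced dot-bracket")
    n = len(record.db)
    backbone = tuple((i, i + 1) for i in range(n - 1))
    return StructureGraph(node_types=node_types,
                          backbone_edges=backbone,
                          pair_edges=tuple(sorted(pairs)))


# ---------------------------------------------------------------- expression

def read_expression(path) -> ExpressionTable:
    """Read a TSV expression matrix: header row of condition ids, first column
    of transcript ids, strictly numeric finite cells."""
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise FormatError(f"empty expression file: {path}")
    header = lines[0].split("\t")
    conditions = header[1:]
    if not conditions:
        raise FormatError(f"{path}: no condition columns in header")
    ids: List[str] = []
    rows: List[List[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(conditions) + 1:
            raise FormatError(
                f"{path}: line {lineno}: ragged row "
                f"({len(fields) - 1} values, expected {len(conditions)})")
        rid = fields[0]
        if rid in ids:
            raise FormatError(f"duplicate transcript id {rid!r} in {path}")
        vals = []
        for col, cell in zip(conditions, fields[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row {rid!r}, "
                    f"column {col!r}") from None
            if not np.isfinite(v):
                raise FormatError(
                    f"{path}: non-finite value at row {rid!r}, column {col!r}")
            vals.append(v)
        ids.append(rid)
        rows.append(vals)
    df = pd.DataFrame(rows, index=ids, columns=conditions, dtype=float)
    return ExpressionTable(values=df)


def write_expression(table: ExpressionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(table.values.columns) + "\n")
        for rid, row in table.values.iterrows():
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# -------------------------------------------------------------------- labels

def read_labels(path) -> Dict[str, str]:
    """Read the TSV labels table (columns: id, class). Consistent duplicate
    rows are tolerated; contradictory ones are an error."""
    labels: Dict[str, str] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise FormatError(f"empty labels file: {path}")
    start = 1 if lines[0].lower().startswith("id\t") else 0
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 'id<TAB>class'")
        rid, cls = fields
        if rid in labels and labels[rid] != cls:
            raise FormatError(
                f"contradictory labels for id {rid!r}: {labels[rid]!r} vs {cls!r}")
        labels[rid] = cls
    return labels


def write_labels(labels: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tclass\n")
        for rid, cls in labels.items():
            fh.write(f"{rid}\t{cls}\n")


# ------------------------------------------------------------------ assembly

def assemble_dataset(seqs: Optional[Sequence[SequenceRecord]],
                     structs: Optional[Sequence[StructureRecord]],
                     expr: Optional[ExpressionTable],
                     labels: Optional[Dict[str, str]],
                     modality_names: Sequence[str] = MODALITY_NAMES,
                     ) -> MultiModalDataset:
    """Align the per-modality inputs into one dataset with presence masks.

    The id universe is the labels table when given, otherwise the union of ids
    across modalities (prediction mode). Each sample's mask entry m is true
    iff that sample has data for modality m; samples present in no modality
    are an error. Class indices follow the lexicographic order of class names.
    """
    modality_names = tuple(modality_names)
    seq_by_id = {r.id: r for r in (seqs or [])}
    struct_by_id = {r.id: r for r in (structs or [])}
    expr_ids = set(expr.values.index) if expr is not None else set()

    if labels is not None:
        universe = list(labels.keys())
    else:
        universe = sorted(set(seq_by_id) | set(struct_by_id) | expr_ids)
    if not universe:
        raise FormatError("no samples to assemble")

    class_names: List[str] = sorted(set(labels.values())) if labels else []
    class_index = {c: i for i, c in enumerate(class_names)}

    n_conditions = expr.n_conditions if expr is not None else None
    samples: List[MultiModalSample] = []
    for rid in universe:
        present, seq, graph, vec = {}, None, None, None
        if "sequence" in modality_names:
            rec = seq_by_id.get(rid)
            present["sequence"] = rec is not None
            seq = rec.seq if rec else None
        if "structure" in modality_names:
            srec = struct_by_id.get(rid)
            present["structure"] = srec is not None
            graph = dotbracket_to_graph(srec) if srec else None
        if "expression" in modality_names:
            has = expr is not None and rid in expr_ids
            present["expression"] = has
            vec = expr.values.loc[rid].to_numpy(dtype=float) if has else None
        mask = np.array([present[m] for m in modality_names], dtype=bool)
        if not mask.any():
            raise FormatError(f"id {rid!r} is present in no modality")
        samples.append(MultiModalSample(
            id=rid, seq=seq, graph=graph, expression=vec, mask=mask,
            label=class_index[labels[rid]] if labels else None))

    if expr is not None and labels is not None:
        expr.missing_rows = set(universe) - expr_ids
    return MultiModalDataset(samples=samples, modality_names=modality_names,
                             class_names=class_names, n_conditions=n_conditions)


def load_dataset(fasta=None, structures=None, expression=None, labels=None,
                 modality_names: Optional[Sequence[str]] = None) -> MultiModalDataset:
    """Read the given files and assemble a dataset (convenience wrapper)."""
    if modality_names is None:
        modality_names = tuple(
            name for name, p in zip(MODALITY_NAMES, (fasta, structures, expression))
            if p is not None)
    seqs = read_fasta(fasta) if fasta else None
    structs = read_dotbracket(structures) if structures else None
    expr = read_expression(expression) if expression else None
    lab = read_labels(labels) if labels else None
    return assemble_dataset(seqs, structs, expr, lab, modality_names)
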