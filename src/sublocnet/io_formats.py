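"""Readers and writers for the external formats the pipeline touches.

The pipeline consumes four plain-text formats: a STRING-links style edge
list (``protein1 protein2 combined_score``), GMT term catalogs, FASTA
sequences and a two-column ``protein_id<TAB>class`` label table. All
readers transparently accept gzip-compressed files. Protein identifiers
are treated as opaque strings throughout; callers are responsible for
using a consistent identifier namespace across files.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from Bio import SeqIO

# the 20 standard one-letter amino-acid codes
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ParseError(ValueError):
    """Malformed input file; message carries the 1-based line number."""


@dataclass
class ProteinRecord:
    """A protein with optional sequence and class label."""

    id: str
    sequence: str | None = None
    label: str | None = None

    def sequence_valid(self) -> bool:
        """True when the sequence uses only the 20 standard residues."""
        if self.sequence is None:
            return False
        return bool(self.sequence) and set(self.sequence) <= STANDARD_RESIDUES


@dataclass
class ExcludedRecord:
    record: ProteinRecord
    reason: str  # one of: too_short, too_long, invalid_alphabet, no_sequence


class WeightedNetwork:
    """Undirected protein interaction network with confidence weights in (0, 1].

    Backed by a :class:`networkx.Graph`; node order is fixed at
    construction time and defines the feature order of the network
    encoder.
    """

    def __init__(self, nodes: Sequence[str] = (), edges: Iterable[tuple[str, str, float]] = ()):
        self._graph = nx.Graph()
        self._graph.add_nodes_from(nodes)
        for a, b, w in edges:
            self.add_edge(a, b, w)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> list[str]:
        return list(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def add_edge(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-edge not allowed: {a!r}")
        if not 0.0 < score <= 1.0:
            raise ValueError(f"confidence score {score} for ({a}, {b}) outside (0, 1]")
        # duplicate undirected pairs keep the max score (order-independent)
        if self._graph.has_edge(a, b):
            score = max(score, self._graph[a][b]["weight"])
        self._graph.add_edge(a, b, weight=score)

    def has_node(self, p: str) -> bool:
        return self._graph.has_node(p)

    def score(self, a: str, b: str) -> float:
        """Edge confidence, 0.0 when the interaction is absent."""
        if self._graph.has_edge(a, b):
            return self._graph[a][b]["weight"]
        return 0.0

    def neighbors(self, p: str) -> dict[str, float]:
        """Neighbor -> confidence map; empty for unknown proteins."""
        if not self._graph.has_node(p):
            return {}
        return {v: d["weight"] for v, d in self._graph[p].items()}

    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["weight"]) for a, b, d in self._graph.edges(data=True)]


@dataclass
class TermCatalog:
    """Named protein sets (GO- or KEGG-pathway-style annotation terms)."""

    terms: list[str] = field(default_factory=list)
    membership: dict[str, set[str]] = field(default_factory=dict)
    kind: str = "other"  # pathway | go | other

    def add(self, term: str, members: Iterable[str]) -> None:
        if term in self.membership:
            raise ValueError(f"duplicate term id {term!r}")
        member_set = set(members)
        if not member_set:
            raise ValueError(f"term {term!r} has no members")
        self.terms.append(term)
        self.membership[term] = member_set

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for s in self.membership.values():
            out |= s
        return out

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class LabeledDataset:
    """Protein records with class labels and a fixed, reproducible class order."""

    records: list[ProteinRecord]
    classes: list[str]

    def __post_init__(self) -> None:
        class_set = set(self.classes)
        if len(class_set) < 2:
            raise ValueError("a labeled dataset needs at least 2 classes")
        for r in self.records:
            if r.label not in class_set:
                raise ValueError(f"record {r.id!r} has label {r.label!r} not in class index")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]  # type: ignore[misc]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for r in self.records:
            counts[r.label] += 1  # type: ignore[index]
        return counts


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_network(path, score_scale: str = "thousandths") -> WeightedNetwork:
    """Load a STRING-links style TSV (``protein1 protein2 combined_score``).

    ``score_scale='thousandths'`` divides integer scores by 1000 (STRING
    publishes combined scores as integers 150-999); ``'unit'`` takes the
    score as-is. Scores must land in (0, 1] after scaling. Duplicate
    undirected pairs keep the maximum score.
    """
    if score_scale not in ("unit", "thousandths"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    net = WeightedNetwork()
    with _open_text(path) as fh:
        header = fh.readline()
        if not header:
            return net
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts
            try:
                score = float(raw)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad score {raw!r}") from exc
            if score_scale == "thousandths":
                score /= 1000.0
            if not 0.0 < score <= 1.0:
                raise ValueError(
                    f"line {lineno}: score {score} outside (0, 1] after {score_scale} scaling"
                )
            net.add_edge(a, b, score)
    return net


def write_network(net: WeightedNetwork, path, score_scale: str = "thousandths") -> None:
    """Write the STRING-links dialect that :func:`read_network` reads."""
    with _open_text(path, "wt") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b, w in sorted(net.edges()):
            if score_scale == "thousandths":
                fh.write(f"{a} {b} {int(round(w * 1000))}\n")
            else:
                fh.write(f"{a} {b} {w!r}\n")


def read_gmt(path, kind: str = "other") -> TermCatalog:
    """Read a GMT catalog (``term<TAB>description<TAB>member...``).

    Term order follows file order; duplicate members within a line are
    deduplicated; a duplicate term id is an error.
    """
    catalog = TermCatalog(kind=kind)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: GMT line needs >=3 tab-separated fields")
            term, _desc, *members = fields
            try:
                catalog.add(term, members)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return catalog


def write_gmt(catalog: TermCatalog, path) -> None:
    with _open_text(path, "wt") as fh:
        for term in catalog.terms:
            members = "\t".join(sorted(catalog.membership[term]))
            fh.write(f"{term}\t{catalog.kind}\t{members}\n")


def read_fasta(path) -> list[ProteinRecord]:
    """Read FASTA; id is the first whitespace token of the header.

    Sequences are uppercased and order preserved. Records with
    non-standard residues (B, J, O, U, X, Z, ...) are kept but will be
    flagged by :func:`filter_records`.
    """
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "rt") as fh:
            text = fh.read()
        handle = io.StringIO(text)
    else:
        handle = path  # type: ignore[assignment]
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(handle, "fasta")
    ]


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence or ""
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_labels(path) -> dict[str, str]:
    """Read a ``protein_id<TAB>class`` table (no header)."""
    labels: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected 2 tab-separated columns")
            pid, label = parts
            if pid in labels:
                raise ParseError(f"line {lineno}: duplicate protein id {pid!r}")
            labels[pid] = label
    return labels


def write_labels(labels: dict[str, str], path) -> None:
    with _open_text(path, "wt") as fh:
        for pid in sorted(labels):
            fh.write(f"{pid}\t{labels[pid]}\n")


def filter_records(
    records: Sequence[ProteinRecord],
    min_len: int = 50,
    max_len: int = 5000,
) -> tuple[list[ProteinRecord], list[ExcludedRecord]]:
    """Partition records into kept and excluded-with-reason.

    Length bounds are inclusive: proteins *shorter than* ``min_len`` or
    *longer than* ``max_len`` residues are excluded, so sequences of
    exactly ``min_len`` or ``max_len`` are kept. Sequences containing
    residues outside the 20-letter standard alphabet (the unknown-residue
    code X in particular) are excluded with reason ``invalid_alphabet``.

    Similarity-based redundancy reduction (e.g. CD-HIT at 0.7 identity)
    is an external pre-processing step: run it on the FASTA before
    loading if required.
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    kept: list[ProteinRecord] = []
    excluded: list[ExcludedRecord] = []
    for rec in records:
        if rec.sequence is None:
            excluded.append(ExcludedRecord(rec, "no_sequence"))
        elif not rec.sequence_valid():
            excluded.append(ExcludedRecord(rec, "invalid_alphabet"))
        elif len(rec.sequence) < min_len:
            excluded.append(ExcludedRecord(rec, "too_short"))
        elif len(rec.sequence) > max_len:
            excluded.append(ExcludedRecord(rec, "too_long"))
        else:
            kept.append(rec)
    return kept, excluded


def assemble_dataset(
    records: Sequence[ProteinRecord], labels: dict[str, str]
) -> LabeledDataset:
    """Attach labels to records and fix the class order (sorted class names).

    Records without a label entry are dropped; the class index is the
    sorted set of label values, making the order reproducible across runs.
    """
    labeled = [
        ProteinRecord(r.id, r.sequence, labels[r.id]) for r in records if r.id in labels
    ]
    classes = sorted({r.label for r in labeled})  # type: ignore[arg-type]
    return LabeledDataset(records=labeled, classes=classes)
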