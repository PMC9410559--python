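"""Readers, writers and benchmark/independent splits for piRNA-disease data.

The on-disk formats are deliberately plain: FASTA for piRNA sequences, either
an OBO file or a two-column parent<TAB>child TSV for the disease ontology, and
a two-column piRNA-id<TAB>disease-id TSV for known associations.  Splitting
supports the two evaluation scenarios of bipartite link prediction:

* ``association-wise`` -- a fraction of (piRNA, disease) *pairs* is held out,
  so every piRNA may appear on both sides (the "missing association" setting);
* ``pirna-wise`` -- a fraction of *piRNAs* is held out with all their pairs,
  so held-out queries are never seen during training (the cold-start setting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

ASSOCIATION_WISE = "association-wise"
PIRNA_WISE = "pirna-wise"


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and map DNA T to RNA U."""
    return seq.upper().replace("T", "U")


@dataclass
class SequenceSet:
    """An ordered collection of uniquely identified RNA sequences."""

    ids: list[str]
    sequences: list[str]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise DataError("ids and sequences must have equal length")
        self.index = {}
        for pos, sid in enumerate(self.ids):
            if sid in self.index:
                raise DataError(f"duplicate sequence id: {sid!r}")
            self.index[sid] = pos
        for sid, seq in zip(self.ids, self.sequences):
            if not seq:
                raise DataError(f"empty sequence for id {sid!r}")
            for pos, ch in enumerate(seq):
                if ch not in RNA_ALPHABET:
                    raise DataError(
                        f"non-ACGU character {ch!r} at position {pos} in {sid!r}"
                    )

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[self.index[sid]]

    def subset(self, indices) -> "SequenceSet":
        return SequenceSet(
            [self.ids[i] for i in indices], [self.sequences[i] for i in indices]
        )

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Sequences are uppercased and T is mapped to U; duplicate record ids,
    empty sequences and residual non-ACGU characters are errors.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        seqs.append(normalize_rna(str(record.seq)))
    return SequenceSet(ids, seqs)


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


@dataclass
class OntologyDAG:
    """A rooted (possibly multi-rooted) DAG of disease terms.

    Edges are stored parent -> child, so ontology ancestors of a node are its
    :func:`networkx.ancestors` in this orientation.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise DataError("ontology contains a self-edge")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise DataError(f"ontology contains a cycle: {cycle}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def roots(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def ancestors(self, node: str) -> set[str]:
        if node not in self.graph:
            raise DataError(f"node {node!r} not in ontology")
        return nx.ancestors(self.graph, node)

    def children(self, node: str):
        return self.graph.successors(node)

    def write_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for parent, child in self.graph.edges:
                fh.write(f"{parent}\t{child}\n")


def read_ontology(path, dialect: str = "edge-tsv") -> OntologyDAG:
    """Read a disease ontology as a parent->child DAG.

    ``obo`` keeps only is_a edges among non-obsolete terms; ``edge-tsv`` reads
    plain ``parent<TAB>child`` lines (blank lines and ``#`` comments ignored).
    """
    if dialect == "obo":
        import obonet

        # obonet orients edges child -> parent and drops obsolete terms.
        raw = obonet.read_obo(str(path))
        graph = nx.DiGraph()
        graph.add_nodes_from(raw.nodes)
        for child, parent, key in raw.edges(keys=True):
            if key == "is_a":
                graph.add_edge(parent, child)
        return OntologyDAG(graph)
    if dialect == "edge-tsv":
        graph = nx.DiGraph()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise DataError(f"line {lineno}: expected parent<TAB>child")
                graph.add_edge(parts[0], parts[1])
        return OntologyDAG(graph)
    raise DataError(f"unknown ontology dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------


@dataclass
class AssociationMatrix:
    """Binary piRNA x disease label matrix (1 = known association)."""

    pirna_ids: list[str]
    disease_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.pirna_ids), len(self.disease_ids)):
            raise DataError("label matrix shape does not match id lists")
        if not np.isin(self.labels, (0, 1)).all():
            raise DataError("labels must be 0/1")
        self.pirna_index = {p: i for i, p in enumerate(self.pirna_ids)}
        self.disease_index = {d: j for j, d in enumerate(self.disease_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_positives(self) -> int:
        return int(self.labels.sum())

    @property
    def n_pairs(self) -> int:
        return self.labels.size

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for i, j in zip(*np.nonzero(self.labels)):
                fh.write(f"{self.pirna_ids[i]}\t{self.disease_ids[j]}\n")


def read_associations(path, seqs: SequenceSet, dag: OntologyDAG | None = None,
                      disease_ids: list[str] | None = None) -> AssociationMatrix:
    """Read a piRNA-id<TAB>disease-id TSV into an :class:`AssociationMatrix`.

    Only the first two columns are read; duplicate pair lines collapse to one.
    Disease columns follow ``disease_ids`` when given, otherwise the order of
    first appearance in the file (restricted to ``dag`` when one is supplied).
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"line {lineno}: expected piRNA<TAB>disease")
            pairs.append((parts[0], parts[1]))

    if disease_ids is None:
        seen: dict[str, None] = {}
        for _, d in pairs:
            seen.setdefault(d, None)
        disease_ids = list(seen)
    labels = np.zeros((len(seqs), len(disease_ids)), dtype=np.int8)
    d_index = {d: j for j, d in enumerate(disease_ids)}
    for p, d in pairs:
        if p not in seqs.index:
            raise DataError(f"unknown piRNA id in associations: {p!r}")
        if dag is not None and d not in dag:
            raise DataError(f"disease id not in ontology: {d!r}")
        if d not in d_index:
            raise DataError(f"disease id not in disease list: {d!r}")
        labels[seqs.index[p], d_index[d]] = 1
    return AssociationMatrix(list(seqs.ids), disease_ids, labels)


# ---------------------------------------------------------------------------
# Benchmark / independent splits
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkSplit:
    """A partition of all (piRNA, disease) pairs into benchmark and independent.

    ``bench_pairs`` / ``ind_pairs`` are integer index pairs of shape (n, 2)
    into the association matrix.  For the ``pirna-wise`` scenario the piRNA
    sets touched by the two sides are disjoint.
    """

    scenario: str
    bench_pairs: np.ndarray
    ind_pairs: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.bench_pairs = np.asarray(self.bench_pairs, dtype=np.int64).reshape(-1, 2)
        self.ind_pairs = np.asarray(self.ind_pairs, dtype=np.int64).reshape(-1, 2)

    def bench_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        if len(self.bench_pairs):
            mask[self.bench_pairs[:, 0], self.bench_pairs[:, 1]] = True
        return mask

    def ind_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        if len(self.ind_pairs):
            mask[self.ind_pairs[:, 0], self.ind_pairs[:, 1]] = True
        return mask

    @property
    def bench_pirnas(self) -> np.ndarray:
        return np.unique(self.bench_pairs[:, 0])

    @property
    def ind_pirnas(self) -> np.ndarray:
        return np.unique(self.ind_pairs[:, 0])


def split_associations(assoc: AssociationMatrix, ind_fraction: float,
                       seed: int) -> BenchmarkSplit:
    """Hold out ``floor(ind_fraction * N)`` positives and unknowns as pairs.

    Positives and unknowns are sampled uniformly without replacement with the
    given seed; the remainder forms the benchmark side.
    """
    if not 0.0 <= ind_fraction <= 1.0:
        raise DataError("ind_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    positives = np.argwhere(assoc.labels == 1)
    unknowns = np.argwhere(assoc.labels == 0)
    n_pos_ind = math.floor(ind_fraction * len(positives))
    n_unk_ind = math.floor(ind_fraction * len(unknowns))
    pos_pick = rng.choice(len(positives), size=n_pos_ind, replace=False)
    unk_pick = rng.choice(len(unknowns), size=n_unk_ind, replace=False)
    pos_mask = np.zeros(len(positives), dtype=bool)
    pos_mask[pos_pick] = True
    unk_mask = np.zeros(len(unknowns), dtype=bool)
    unk_mask[unk_pick] = True
    ind_pairs = np.vstack([positives[pos_mask], unknowns[unk_mask]])
    bench_pairs = np.vstack([positives[~pos_mask], unknowns[~unk_mask]])
    return BenchmarkSplit(ASSOCIATION_WISE, bench_pairs, ind_pairs, seed)


def split_pirnas(assoc: AssociationMatrix, ind_fraction: float,
                 seed: int) -> BenchmarkSplit:
    """Hold out ``floor(ind_fraction * n_piRNAs)`` piRNAs with all their pairs."""
    if not 0.0 < ind_fraction < 1.0:
        raise DataError("ind_fraction must be in (0, 1)")
    n_pi, n_d = assoc.shape
    n_ind = math.floor(ind_fraction * n_pi)
    if n_ind == 0:
        raise DataError("ind_fraction yields zero independent piRNAs")
    rng = np.random.default_rng(seed)
    ind_set = rng.choice(n_pi, size=n_ind, replace=False)
    ind_flag = np.zeros(n_pi, dtype=bool)
    ind_flag[ind_set] = True
    cols = np.arange(n_d)
    ind_rows = np.nonzero(ind_flag)[0]
    bench_rows = np.nonzero(~ind_flag)[0]
    ind_pairs = np.column_stack(
        [np.repeat(ind_rows, n_d), np.tile(cols, len(ind_rows))]
    )
    bench_pairs = np.column_stack(
        [np.repeat(bench_rows, n_d), np.tile(cols, len(bench_rows))]
    )
    return BenchmarkSplit(PIRNA_WISE, bench_pairs, ind_pairs, seed)


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ["pirna_id", "disease_id", "score", "rank"]


def write_predictions(path, ranked_lists) -> None:
    """Write ranked lists as a TSV (pirna_id, disease_id, score, rank).

    ``ranked_lists`` is an iterable of objects with ``query`` and ``entries``
    attributes (see :class:`pirank.ranker.RankedList`) or of
    ``(query, [(disease, score, rank), ...])`` tuples.
    """
    rows = []
    for item in ranked_lists:
        if hasattr(item, "entries"):
            query, entries = item.query, item.entries
        else:
            query, entries = item
        for disease, score, rank in entries:
            rows.append((query, disease, float(score), int(rank)))
    frame = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"prediction file missing columns: {missing}")
    return frame
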