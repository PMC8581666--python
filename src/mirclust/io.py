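"""Readers, writers and core containers for the formats the pipeline touches.

Sequences are held internally in the RNA alphabet (``U``); DNA input is
accepted and converted on parse.  Trees are rooted species trees parsed from
newick.  Expression matrices are genes x samples with an explicit unit.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

VALID_BASES = set("ACGUN")
_UNITS = ("counts", "TPM", "FPKM")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U.  Idempotent."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (RNA alphabet internally)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def parse_fasta(path: str | Path, alphabet: str = "rna") -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Parameters
    ----------
    path
        FASTA file.
    alphabet
        ``"rna"`` (default) converts T to U; ``"dna"`` keeps the input
        alphabet but still validates characters.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(" ", "")
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r}")
        norm = normalize_rna(seq) if alphabet == "rna" else seq.upper()
        check = norm if alphabet == "rna" else norm.replace("T", "U")
        bad = set(check) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, norm, desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f"{rec.id} {rec.description}" if rec.description else rec.id
            fh.write(f">{header}\n{rec.seq}\n")


class SpeciesTree:
    """Rooted species tree with stable node ids.

    Leaves are identified by their taxon label; internal nodes get the
    newick label when present, otherwise a deterministic postorder id
    ``n0, n1, ...``.  A branch is identified by the id of its child node.
    """

    def __init__(self, tree: dendropy.Tree):
        self._parent: dict[str, str | None] = {}
        self._children: dict[str, list[str]] = {}
        self._leafsets: dict[str, frozenset[str]] = {}
        self._post: list[str] = []
        counter = 0
        ids: dict[int, str] = {}
        labels_seen: set[str] = set()
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                nid = node.taxon.label if node.taxon else (node.label or "")
                if not nid:
                    raise ValueError("leaf without a label")
            else:
                nid = node.label
                if not nid:
                    nid = f"n{counter}"
                    counter += 1
            if nid in labels_seen:
                raise ValueError(f"duplicate node label {nid!r}")
            labels_seen.add(nid)
            ids[id(node)] = nid
            kids = [ids[id(c)] for c in node.child_nodes()]
            self._children[nid] = kids
            for k in kids:
                self._parent[k] = nid
            if node.is_leaf():
                self._leafsets[nid] = frozenset([nid])
            else:
                self._leafsets[nid] = frozenset().union(
                    *(self._leafsets[k] for k in kids)
                )
            self._post.append(nid)
        self.root: str = self._post[-1]
        self._parent[self.root] = None
        self.leaves: list[str] = [n for n in self._post if not self._children[n]]
        if len(self.leaves) < 2:
            raise ValueError("tree must have at least 2 leaves")

    # -- topology queries ---------------------------------------------------
    def is_leaf(self, node: str) -> bool:
        return not self._children[node]

    def children(self, node: str) -> list[str]:
        return list(self._children[node])

    def parent(self, node: str) -> str | None:
        return self._parent[node]

    def nodes(self) -> list[str]:
        """All node ids in postorder."""
        return list(self._post)

    def leaf_labels(self, node: str) -> frozenset[str]:
        """Leaves of the subtree rooted at *node*."""
        return self._leafsets[node]

    def __contains__(self, node: str) -> bool:
        return node in self._children

    def mrca(self, labels: Iterable[str]) -> str:
        """Most recent common ancestor of a set of leaf labels."""
        want = frozenset(labels)
        missing = want - frozenset(self.leaves)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        if not want:
            raise ValueError("empty label set")
        node = next(iter(want))
        while not want <= self._leafsets[node]:
            node = self._parent[node]  # type: ignore[assignment]
        return node

    def is_descendant(self, node: str, ancestor: str, proper: bool = False) -> bool:
        """True if *node* lies in the subtree rooted at *ancestor*."""
        if node not in self or ancestor not in self:
            raise ValueError("node not in tree")
        if node == ancestor:
            return not proper
        cur = self._parent[node]
        while cur is not None:
            if cur == ancestor:
                return True
            cur = self._parent[cur]
        return False

    def edges(self) -> list[tuple[str, str]]:
        """(parent, child) pairs; the branch id is the child node id."""
        return [(p, c) for c, p in self._parent.items() if p is not None]

    def subtree_nodes(self, node: str) -> list[str]:
        out: list[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self._children[n])
        return out


def parse_newick(source: str | Path) -> SpeciesTree:
    """Parse a newick tree from a file path or a literal newick string."""
    text = str(source)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"invalid newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf names in newick tree")
    return SpeciesTree(tree)


@dataclass
class ExpressionTable:
    """Gene x sample expression matrix with an explicit unit."""

    data: pd.DataFrame  # index = genes, columns = samples
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if (self.data.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def load_expression_table(path: str | Path, unit: str = "counts") -> ExpressionTable:
    """Load a TSV with gene ids in the first column and samples as headers."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty expression file: {path}") from exc
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"no data rows/columns in {path}")
    if df.isna().any().any():
        raise ValueError(f"ragged or missing values in {path}")
    df = df.astype(float)
    return ExpressionTable(df, unit=unit)


def write_expression_table(
    table: ExpressionTable, path: str | Path, producer: str = "mirclust"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# produced by {producer}; unit={table.unit}\n")
        table.data.to_csv(fh, sep="\t", index_label="gene")


def write_tsv(
    df: pd.DataFrame, path: str | Path, producer: str, index: bool = False
) -> None:
    """Write a TSV with a commented provenance header line."""
    with open(path, "w") as fh:
        fh.write(f"# produced by {producer}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def load_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Members x species 0/1 TSV -> boolean DataFrame (members as index)."""
    df = read_tsv(path, index_col=0)
    return df.astype(int).astype(bool)


def write_bed(loci: Sequence[tuple[str, GenomicInterval]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, iv in loci:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    out: list[tuple[str, GenomicInterval]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
        strand = parts[5] if len(parts) > 5 else "+"
        out.append((name, GenomicInterval(chrom, start, end, strand)))
    return out
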