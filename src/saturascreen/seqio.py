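"""Alignment, chronogram and partition-scheme I/O with stride-range site arithmetic.

Coordinates are 1-based inclusive at every public interface, matching the
``start-end\\3`` charset dialect used for codon-position partitions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import AlignIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

# IUPAC nucleotide codes -> set of compatible bases (used downstream as
# indicator partial likelihoods).  '-' and '?' are both treated as missing.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class PartitionError(ValueError):
    """Malformed partition-scheme text."""


class UltrametryError(ValueError):
    """Tree violates the equal root-to-tip path requirement."""


@dataclass
class Alignment:
    """A rectangular nucleotide alignment (taxa x sites)."""

    taxa: list[str]
    data: np.ndarray  # dtype '<U1', shape (n_taxa, length)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("alignment matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        # zero length is permitted only as the degenerate pruning result
        bad = set(np.unique(self.data)) - set(IUPAC)
        if bad:
            raise ValueError(f"illegal states in alignment: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def column(self, site: int) -> dict[str, str]:
        """States at a 1-based site, keyed by taxon."""
        self._check_site(site)
        return dict(zip(self.taxa, self.data[:, site - 1]))

    def _check_site(self, site: int) -> None:
        if not 1 <= site <= self.length:
            raise IndexError(f"site {site} outside [1, {self.length}]")

    @classmethod
    def from_strings(cls, rows: dict[str, str]) -> "Alignment":
        taxa = list(rows)
        mat = np.array([list(s.upper()) for s in rows.values()], dtype="<U1")
        return cls(taxa, mat)


def read_alignment(path_or_handle, fmt: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    ``fmt`` is a Biopython AlignIO format name ("fasta", "phylip-relaxed").
    """
    aln = AlignIO.read(path_or_handle, fmt)
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    return Alignment.from_strings(rows)


def write_alignment(aln: Alignment, path_or_handle, fmt: str = "fasta") -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=name, description="")
        for name, row in zip(aln.taxa, aln.data)
    ]
    AlignIO.write(MultipleSeqAlignment(records), path_or_handle, fmt)


# ---------------------------------------------------------------------------
# Stride ranges and partition schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrideRange:
    """1-based inclusive site range with a positive stride (3 for codon sets)."""

    start: int
    end: int
    step: int = 1

    def __post_init__(self) -> None:
        if self.step < 1:
            raise PartitionError(f"zero or negative step in {self}")
        if not 1 <= self.start <= self.end:
            raise PartitionError(f"start > end or start < 1 in {self}")

    def members(self) -> range:
        return range(self.start, self.end + 1, self.step)

    def member_set(self) -> set[int]:
        return set(self.members())

    def __str__(self) -> str:
        if self.step == 1:
            return f"{self.start}-{self.end}"
        return f"{self.start}-{self.end}\\{self.step}"


@dataclass
class PartitionScheme:
    """Ordered mapping of subset name -> stride ranges, with model hints."""

    subsets: dict[str, list[StrideRange]]
    models: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subsets:
            raise PartitionError("scheme has no subsets")
        for name, ranges in self.subsets.items():
            seen: set[int] = set()
            for r in ranges:
                ms = r.member_set()
                if seen & ms:
                    warnings.warn(
                        f"overlapping ranges in subset {name!r}; union taken"
                    )
                seen |= ms

    def sites(self, name: str) -> set[int]:
        return set().union(*(r.member_set() for r in self.subsets[name]))

    def all_sites(self) -> set[int]:
        return set().union(*(self.sites(n) for n in self.subsets))

    def validate_against(self, aln: Alignment) -> None:
        mx = max(self.all_sites())
        if mx > aln.length:
            raise PartitionError(
                f"scheme site {mx} exceeds alignment length {aln.length}"
            )

    def site_to_subset(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for name in self.subsets:
            for s in self.sites(name):
                out[s] = name
        return out


_TOKEN = re.compile(r"^(\d+)-(\d+)(?:\\(\d+))?$")


def parse_token(tok: str) -> StrideRange:
    tok = tok.strip()
    m = _TOKEN.match(tok)
    if m is None:
        if re.fullmatch(r"\d+", tok):  # a bare single site
            v = int(tok)
            return StrideRange(v, v, 1)
        raise PartitionError(f"malformed stride-range token: {tok!r}")
    start, end, step = int(m.group(1)), int(m.group(2)), int(m.group(3) or 1)
    if step == 0:
        raise PartitionError(f"zero step in token {tok!r}")
    if start > end:
        raise PartitionError(f"start > end in token {tok!r}")
    return StrideRange(start, end, step)


def parse_stride_ranges(text: str) -> PartitionScheme:
    """Parse a partition scheme from charset-style text.

    Accepted record shapes, one subset per record:

    * NEXUS charset lines: ``charset name = 1-1145\\3, 1832-2008\\3;``
      (optionally inside a ``begin sets; ... end;`` block)
    * RAxML-style lines: ``DNA, name = 1-1145\\3, 1832-2008\\3``
    * bare lines: ``name = 1-1145\\3, 1832-2008\\3``
    """
    subsets: dict[str, list[StrideRange]] = {}
    models: dict[str, str] = {}
    text = re.sub(r"\[[^\]]*\]", "", text, flags=re.DOTALL)  # NEXUS comments
    for raw in text.splitlines():
        line = raw.strip().rstrip(";").strip()
        if not line or line.startswith("#"):
            continue
        low = line.lower()
        if low.startswith(("begin ", "end", "#nexus")) or low == "begin sets":
            continue
        if low.startswith("charset "):
            line = line[len("charset "):]
        elif "," in line.split("=")[0] and "=" in line:
            # RAxML style: "<model>, name = ranges"
            model, line = line.split(",", 1)
            line = line.strip()
            if "=" in line:
                name = line.split("=")[0].strip()
                models[name] = model.strip()
        if "=" not in line:
            raise PartitionError(f"cannot parse record: {raw!r}")
        name, rhs = line.split("=", 1)
        name = name.strip()
        ranges = [parse_token(t) for t in rhs.split(",") if t.strip()]
        if not ranges:
            raise PartitionError(f"subset {name!r} has no ranges")
        if name in subsets:
            raise PartitionError(f"duplicate subset name {name!r}")
        subsets[name] = ranges
    return PartitionScheme(subsets, models)


def write_scheme(scheme: PartitionScheme, path) -> None:
    with open(path, "w") as fh:
        fh.write("#nexus\nbegin sets;\n")
        for name, ranges in scheme.subsets.items():
            body = ", ".join(str(r) for r in ranges)
            fh.write(f"  charset {name} = {body};\n")
        fh.write("end;\n")


def count_sites(ranges: list[StrideRange]) -> int:
    """Cardinality of the union of member sets (duplicates counted once)."""
    if not ranges:
        return 0
    return len(set().union(*(r.member_set() for r in ranges)))


def extract_subalignment(
    aln: Alignment, sites, *, allow_empty: bool = False
) -> Alignment:
    """Columns at the given 1-based sites, in ascending original order."""
    sites = sorted(set(sites))
    if not sites:
        if allow_empty:
            return Alignment(list(aln.taxa), np.empty((aln.n_taxa, 0), dtype="<U1"))
        raise ValueError("empty site set")
    if sites[0] < 1 or sites[-1] > aln.length:
        raise IndexError(
            f"sites outside [1, {aln.length}]: {sites[0]}..{sites[-1]}"
        )
    idx = np.asarray(sites) - 1
    return Alignment(list(aln.taxa), aln.data[:, idx])


def complement_sites(aln: Alignment, sites) -> list[int]:
    return sorted(set(range(1, aln.length + 1)) - set(sites))


# ---------------------------------------------------------------------------
# Chronograms
# ---------------------------------------------------------------------------

class Chronogram:
    """A rooted ultrametric tree with node ages in Ma (tips at age 0).

    Thin wrapper over a dendropy Tree; branch durations are
    parent_age - child_age.
    """

    def __init__(self, tree: dendropy.Tree, *, tol: float = 1e-6,
                 require_ultrametric: bool = True):
        self.tree = tree
        self._assign_ages(tol, require_ultrametric)

    def _assign_ages(self, tol: float, require: bool) -> None:
        tree = self.tree
        # depth from root along branch lengths
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                nd._depth = 0.0
            else:
                el = nd.edge.length or 0.0
                if el < 0:
                    raise ValueError("negative branch length")
                nd._depth = nd.parent_node._depth + el
        leaves = tree.leaf_node_iter()
        depths = {lf.taxon.label: lf._depth for lf in tree.leaf_node_iter()}
        height = max(depths.values())
        if require:
            worst = max(abs(d - height) for d in depths.values())
            if worst > tol:
                offender = max(depths, key=lambda k: abs(depths[k] - height))
                raise UltrametryError(
                    f"tree is not ultrametric: tip {offender!r} root-to-tip "
                    f"path differs from root age {height:.6g} by {worst:.6g}"
                )
        self.root_age = height
        for nd in tree.preorder_node_iter():
            nd.age = 0.0 if nd.is_leaf() else height - nd._depth
        for lf in tree.leaf_node_iter():
            lf.age = 0.0

    @property
    def taxa(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def node_ages(self) -> dict[frozenset, float]:
        """Ages keyed by the frozenset of descendant taxon labels (clade key)."""
        out = {}
        for nd in self.tree.preorder_internal_node_iter():
            key = frozenset(l.taxon.label for l in nd.leaf_iter())
            out[key] = nd.age
        return out

    def edges(self) -> list[tuple]:
        """(parent, child, duration Ma) for every edge below the root."""
        out = []
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is not None:
                out.append((nd.parent_node, nd, nd.parent_node.age - nd.age))
        return out

    def scaled(self, factor: float) -> "Chronogram":
        t = self.tree.clone(depth=1)
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length *= factor
        return Chronogram(t)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_chronogram(source: str, *, tol: float = 1e-6,
                    require_ultrametric: bool = True) -> Chronogram:
    """Read a Newick chronogram from a string or a file path."""
    if "(" in source:
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=source, schema="newick")
    return Chronogram(tree, tol=tol, require_ultrametric=require_ultrametric)


def write_chronogram(chrono: Chronogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(chrono.newick() + "\n")
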