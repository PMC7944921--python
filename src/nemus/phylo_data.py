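"""Rooted trees, codon alignments, and branch-to-model assignments.

Trees are rooted, strictly bifurcating, with branch lengths in model time
units (1 unit = 1 expected neutral substitution per site).  Branches are
addressed by the id of their *child* node; node ids are assigned in
post-order (root last, id ``2n - 2`` for ``n`` leaves), which is stable
across Newick round-trips.

Alignments are matrices of codon indices in the package's fixed codon
ordering (see :mod:`nemus.mutsel_core`); ``-1`` marks missing data.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .mutsel_core import CODON_SPACE, STOP_CODONS, FitnessProfile

__all__ = [
    "Phylogeny",
    "CodonAlignment",
    "ShiftConfiguration",
    "read_newick",
    "write_newick",
    "read_codon_fasta",
    "write_codon_fasta",
    "node_time_depth",
    "assign_models",
]


class TreeError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class Phylogeny:
    """A rooted binary phylogeny stored as flat parent/child arrays.

    Attributes
    ----------
    n_nodes : total node count (``2 n_leaves - 1``).
    parent : ndarray, parent node id per node (-1 for the root).
    children : list of tuples of child ids (empty for leaves).
    branch_length : ndarray, length of the branch above each node
        (``nan`` for the root, which has no branch).
    leaf_labels : dict node id -> taxon name.
    postorder : node ids in post-order; equals ``range(n_nodes)``.
    """

    def __init__(
        self,
        parent: np.ndarray,
        children: list[tuple[int, ...]],
        branch_length: np.ndarray,
        leaf_labels: dict[int, str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.intp)
        self.children = [tuple(c) for c in children]
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.leaf_labels = dict(leaf_labels)
        self.n_nodes = len(self.children)
        self.postorder = list(range(self.n_nodes))
        self.root = self.n_nodes - 1
        self.leaves = sorted(self.leaf_labels)
        self.n_leaves = len(self.leaves)

    # -- structure queries -------------------------------------------------

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    @property
    def branches(self) -> list[int]:
        """All branch ids (= non-root node ids)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    @property
    def basal_branches(self) -> tuple[int, ...]:
        """The two branches attached to the root."""
        return self.children[self.root]

    def subtree_nodes(self, node: int) -> list[int]:
        """Nodes of the clade rooted at ``node`` (inclusive), post-order."""
        out: list[int] = []

        def rec(v: int) -> None:
            for c in self.children[v]:
                rec(c)
            out.append(v)

        rec(node)
        return out

    def depth(self, node: int) -> float:
        """Sum of branch lengths from the root down to ``node``."""
        d = 0.0
        v = node
        while v != self.root:
            d += self.branch_length[v]
            v = self.parent[v]
        return d

    def max_depth(self) -> float:
        return max(self.depth(v) for v in range(self.n_nodes) if self.is_leaf(v))

    def node_level(self, node: int) -> int:
        """Number of edges between the root and ``node``."""
        k = 0
        v = node
        while v != self.root:
            k += 1
            v = self.parent[v]
        return k

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = [self.depth(v) for v in range(self.n_nodes) if self.is_leaf(v)]
        return max(depths) - min(depths) <= tol * max(max(depths), 1e-12)

    def total_length(self) -> float:
        return float(np.nansum(self.branch_length))


def _from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    seed = tree.seed_node
    if len(seed.child_nodes()) != 2:
        raise TreeError(
            f"tree must have an explicit root with 2 children, found "
            f"{len(seed.child_nodes())} basal lineages (unrooted input?)"
        )
    order = [nd for nd in tree.postorder_node_iter()]
    ids = {id(nd): i for i, nd in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.intp)
    children: list[tuple[int, ...]] = [()] * n
    blen = np.full(n, np.nan)
    labels: dict[int, str] = {}
    for nd in order:
        i = ids[id(nd)]
        kids = nd.child_nodes()
        if kids and len(kids) != 2:
            raise TreeError(f"polytomy with {len(kids)} children is not supported")
        children[i] = tuple(ids[id(c)] for c in kids)
        for c in kids:
            parent[ids[id(c)]] = i
        if nd is not seed:
            if nd.edge.length is None:
                raise TreeError("all branches must carry lengths")
            if nd.edge.length < 0:
                raise TreeError(f"negative branch length {nd.edge.length}")
            blen[i] = float(nd.edge.length)
        if not kids:
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("every leaf must be labelled")
            labels[i] = nd.taxon.label
    if len(set(labels.values())) != len(labels):
        raise TreeError("leaf labels must be unique")
    return Phylogeny(parent, children, blen, labels)


def read_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(tree)


def write_newick(tree: Phylogeny, precision: int = 12) -> str:
    """Serialise back to Newick (lengths at ``precision`` significant digits)."""

    def rec(v: int) -> str:
        if tree.is_leaf(v):
            core = tree.leaf_labels[v]
        else:
            core = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        if v == tree.root:
            return core
        return f"{core}:{tree.branch_length[v]:.{precision}g}"

    return rec(tree.root) + ";"


def node_time_depth(tree: Phylogeny, node: int) -> float:
    """Age of a node measured root-ward in model time units.

    Defined as (max root-to-leaf path length) - (root-to-node path length):
    on an ultrametric tree this is the usual node age above the tips; on
    non-ultrametric trees distance-to-tips is ambiguous, so this rootward
    convention is used throughout.
    """
    return tree.max_depth() - tree.depth(node)


# ---------------------------------------------------------------------------
# Codon alignments


class CodonAlignment:
    """Taxa-by-sites matrix over the 61 sense codons.

    ``codes[i, j]`` is the codon index of taxon ``i`` at codon site ``j`` in
    the fixed A<C<G<T lexicographic ordering; ``-1`` encodes missing data.
    """

    def __init__(self, taxa: list[str], codes: np.ndarray) -> None:
        codes = np.asarray(codes, dtype=np.intp)
        if codes.ndim != 2 or codes.shape[0] != len(taxa):
            raise AlignmentError("codes must be (n_taxa, n_sites)")
        if len(set(taxa)) != len(taxa):
            raise AlignmentError("duplicate taxon names")
        if codes.size and (codes.max() >= 61 or codes.min() < -1):
            raise AlignmentError("codon indices must be in [-1, 60]")
        self.taxa = list(taxa)
        self.codes = codes

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxa.index(taxon)]


def read_codon_fasta(text: str, allow_ambiguous: bool = False) -> CodonAlignment:
    """Parse an in-frame codon FASTA alignment.

    Stops anywhere in frame are an error (the state space excludes them).
    With ``allow_ambiguous`` codons containing non-ACGT symbols become
    missing data (``-1``); otherwise they are rejected.
    """
    names: list[str] = []
    seqs: list[str] = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            names.append(line[1:].split()[0])
            seqs.append("")
        else:
            if not names:
                raise AlignmentError("sequence data before first FASTA header")
            seqs[-1] += line.upper()
    if not names:
        raise AlignmentError("no sequences found")
    if len(set(names)) != len(names):
        raise AlignmentError("duplicate taxon names in FASTA")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    (L,) = lengths
    if L % 3 != 0:
        raise AlignmentError(f"alignment length {L} is not a multiple of 3")
    idx = CODON_SPACE.index
    rows = []
    for name, seq in zip(names, seqs):
        row = []
        for j in range(0, L, 3):
            codon = seq[j : j + 3]
            if codon in STOP_CODONS:
                raise AlignmentError(
                    f"in-frame stop codon {codon} in taxon {name!r} at codon site {j // 3}"
                )
            if codon in idx:
                row.append(idx[codon])
            elif codon == "---" or not set(codon) <= set("ACGT"):
                if allow_ambiguous or codon == "---":
                    row.append(-1)
                else:
                    raise AlignmentError(
                        f"ambiguous codon {codon!r} in taxon {name!r} at codon site "
                        f"{j // 3} (pass allow_ambiguous to treat as missing)"
                    )
            else:  # pragma: no cover - ACGT triplet not in table must be a stop
                raise AlignmentError(f"unexpected codon {codon!r}")
        rows.append(row)
    return CodonAlignment(names, np.array(rows, dtype=np.intp))


def write_codon_fasta(aln: CodonAlignment, width: int = 60) -> str:
    out = []
    for i, name in enumerate(aln.taxa):
        out.append(f">{name}")
        seq = "".join(
            CODON_SPACE.codons[c] if c >= 0 else "---" for c in aln.codes[i]
        )
        for j in range(0, len(seq), width):
            out.append(seq[j : j + width])
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Shift configurations


EQUILIBRIUM = "equilibrium"


@dataclass
class ShiftConfiguration:
    """Assignment of fitness profiles to a tree plus root codon frequencies.

    A shift on branch ``b`` applies its profile to ``b`` and everything below
    it, until another shift intervenes.  ``root_frequencies`` is either the
    string ``"equilibrium"`` (use the stationary distribution of the base
    model) or an explicit 61-vector (free mode, 60 free parameters).
    """

    base_profile: FitnessProfile
    shifts: list[tuple[int, FitnessProfile]] = field(default_factory=list)
    root_frequencies: object = EQUILIBRIUM

    def __post_init__(self) -> None:
        branches = [b for b, _ in self.shifts]
        if len(set(branches)) != len(branches):
            raise ConfigurationError("duplicate shift branches")
        if not (
            isinstance(self.root_frequencies, str)
            and self.root_frequencies == EQUILIBRIUM
        ):
            rf = np.asarray(self.root_frequencies, dtype=float)
            if rf.shape != (61,) or np.any(rf < 0) or abs(rf.sum() - 1.0) > 1e-6:
                raise ConfigurationError("root_frequencies must be a 61-simplex vector")
            self.root_frequencies = rf / rf.sum()

    @property
    def free_root(self) -> bool:
        return not (
            isinstance(self.root_frequencies, str)
            and self.root_frequencies == EQUILIBRIUM
        )

    @property
    def n_shifts(self) -> int:
        return len(self.shifts)

    @property
    def profiles(self) -> list[FitnessProfile]:
        """Base profile followed by shift profiles, in shift order."""
        return [self.base_profile] + [p for _, p in self.shifts]

    # -- JSON round trip ---------------------------------------------------

    def to_json(self) -> str:
        obj = {
            "base_profile": list(self.base_profile.f),
            "shifts": [
                {"branch": int(b), "profile": list(p.f)} for b, p in self.shifts
            ],
            "root_frequencies": (
                EQUILIBRIUM
                if not self.free_root
                else [float(x) for x in self.root_frequencies]
            ),
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str, bound: float | None = None) -> "ShiftConfiguration":
        obj = json.loads(text)
        kw = {} if bound is None else {"bound": bound}
        base = FitnessProfile(tuple(obj["base_profile"]), **kw)
        shifts = [
            (int(s["branch"]), FitnessProfile(tuple(s["profile"]), **kw))
            for s in obj["shifts"]
        ]
        return cls(base, shifts, obj["root_frequencies"])


def assign_models(tree: Phylogeny, config: ShiftConfiguration) -> np.ndarray:
    """Profile index per branch under nearest-rootward-shift semantics.

    Returns an array over node ids where entry ``b`` is an index into
    ``config.profiles`` for the branch above node ``b`` (the root entry is 0,
    the base profile, by convention).  Raises if both basal branches carry
    shifts: the root process must persist on at least one basal lineage.
    """
    shift_at = {}
    for i, (b, _) in enumerate(config.shifts):
        if b == tree.root or not (0 <= b < tree.n_nodes):
            raise ConfigurationError(f"shift branch {b} is not a branch of the tree")
        shift_at[b] = i + 1
    basal = tree.basal_branches
    if all(b in shift_at for b in basal):
        raise ConfigurationError(
            "selective shifts on both basal branches are not permitted"
        )
    out = np.zeros(tree.n_nodes, dtype=np.intp)

    def rec(v: int, current: int) -> None:
        if v in shift_at:
            current = shift_at[v]
        out[v] = current
        for c in tree.children[v]:
            rec(c, current)

    rec(tree.root, 0)
    return out
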