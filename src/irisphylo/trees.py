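"""Rooted, branch-length-annotated phylogenies.

A thin immutable wrapper around :mod:`dendropy` trees that adds the
operations the reconstruction pipeline needs: polytomy grafting of taxa
missing from a reference tree, pruning that preserves pairwise path
lengths among kept tips, clade extraction, ultrametricity checks, and a
flat array view (postorder child lists, branch lengths, stable node
names) consumed by the likelihood machinery.

Node naming: tips are named by their taxon labels; internal nodes keep
their Newick labels when present and otherwise receive names ``N<i>``
where ``i`` is the node's postorder index. These names key every
per-node output (ancestral state probabilities, presence calls,
reconstructed shade values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeArrays",
    "parse_newick",
    "write_newick",
    "align_to_tips",
]


@dataclass(frozen=True)
class TreeArrays:
    """Flat postorder view of a rooted tree.

    Nodes are indexed ``0 .. n-1`` in postorder; the root is ``n - 1``.
    ``blen[i]`` is the length of the edge *above* node ``i`` (0 for the
    root). ``children`` is flattened into ``child_flat`` with per-node
    offsets so numba kernels can traverse it.
    """

    n: int
    child_flat: np.ndarray
    child_start: np.ndarray
    child_count: np.ndarray
    parent: np.ndarray
    blen: np.ndarray
    is_tip: np.ndarray
    names: tuple
    index: dict = field(repr=False)

    @property
    def root(self) -> int:
        return self.n - 1

    @property
    def tip_indices(self) -> np.ndarray:
        return np.nonzero(self.is_tip)[0]

    @property
    def tip_labels(self) -> list:
        return [self.names[i] for i in self.tip_indices]

    def children_of(self, i: int) -> np.ndarray:
        s, c = self.child_start[i], self.child_count[i]
        return self.child_flat[s : s + c]

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n)
        for i in range(self.n - 2, -1, -1):
            d[i] = d[self.parent[i]] + self.blen[i]
        return d

    def descendant_tips(self) -> list:
        """Per-node sorted array of descendant tip indices (tips include themselves)."""
        desc = [None] * self.n
        for i in range(self.n):
            if self.child_count[i] == 0:
                desc[i] = np.array([i], dtype=np.int64)
            else:
                desc[i] = np.sort(np.concatenate([desc[c] for c in self.children_of(i)]))
        return desc

    def tip_shared_depths(self) -> tuple[np.ndarray, np.ndarray]:
        """(tip_index_position map, m x m matrix of MRCA depths between tips).

        Entry ``[a, b]`` is the root-to-MRCA distance for the a-th and
        b-th tips (in ``tip_indices`` order); the diagonal holds tip depths.
        """
        tips = self.tip_indices
        pos = {int(t): k for k, t in enumerate(tips)}
        depth = self.depths()
        m = len(tips)
        M = np.zeros((m, m))
        desc = self.descendant_tips()
        for i in range(self.n):
            cc = self.child_count[i]
            if cc < 2:
                continue
            groups = [np.array([pos[int(t)] for t in desc[c]]) for c in self.children_of(i)]
            for a in range(cc):
                for b in range(a + 1, cc):
                    ga, gb = groups[a], groups[b]
                    M[np.ix_(ga, gb)] = depth[i]
                    M[np.ix_(gb, ga)] = depth[i]
        M[np.diag_indices(m)] = depth[tips]
        return tips, M


class Phylogeny:
    """A rooted phylogeny with unique tip labels and nonnegative branch lengths."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._arrays: TreeArrays | None = None
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        except Exception as exc:  # dendropy raises schema-specific subclasses
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls(dtree)

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("every tip must carry a label")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        if len(labels) < 1:
            raise ValueError("empty tree")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length: {edge.length}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def arrays(self) -> TreeArrays:
        if self._arrays is None:
            self._arrays = self._build_arrays()
        return self._arrays

    def _build_arrays(self) -> TreeArrays:
        nodes = list(self._tree.postorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        is_tip = np.zeros(n, dtype=bool)
        names = []
        child_lists = []
        for i, nd in enumerate(nodes):
            kids = [idx[id(c)] for c in nd.child_nodes()]
            child_lists.append(kids)
            for c in kids:
                parent[c] = i
            blen[i] = nd.edge.length or 0.0
            if not kids:
                is_tip[i] = True
                names.append(nd.taxon.label)
            else:
                names.append(nd.label if nd.label else f"N{i}")
        blen[n - 1] = 0.0
        child_flat = np.array([c for kids in child_lists for c in kids], dtype=np.int64)
        child_count = np.array([len(k) for k in child_lists], dtype=np.int64)
        child_start = np.concatenate([[0], np.cumsum(child_count)[:-1]]).astype(np.int64)
        index = {nm: i for i, nm in enumerate(names)}
        return TreeArrays(
            n=n,
            child_flat=child_flat,
            child_start=child_start,
            child_count=child_count,
            parent=parent,
            blen=blen,
            is_tip=is_tip,
            names=tuple(names),
            index=index,
        )

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- manipulation ------------------------------------------------------

    def graft_polytomy(self, new_tip: str, anchor: str) -> "Phylogeny":
        """Attach ``new_tip`` at the parent of ``anchor`` (tip label or clade name).

        The new pendant branch length equals the anchor's own branch
        length (its "nearest resolved neighboring branch"); when the
        anchor already has siblings this creates or extends a polytomy.
        Existing edges are never rescaled, so the grafted tree may no
        longer be ultrametric.
        """
        if new_tip in self.tip_labels:
            raise ValueError(f"tip {new_tip!r} already present")
        clone = self._tree.clone(depth=1)
        target = None
        for nd in clone.preorder_node_iter():
            label = nd.taxon.label if nd.taxon else nd.label
            if label == anchor:
                target = nd
                break
        if target is None:
            # allow addressing unnamed internal nodes by their array name
            arr = self.arrays
            if anchor in arr.index and not arr.is_tip[arr.index[anchor]]:
                post = list(clone.postorder_node_iter())
                target = post[arr.index[anchor]]
        if target is None:
            raise KeyError(f"anchor {anchor!r} not found")
        if target.parent_node is None:
            raise ValueError("cannot graft next to the root")
        taxon = clone.taxon_namespace.require_taxon(label=new_tip)
        target.parent_node.new_child(taxon=taxon, edge_length=target.edge.length or 0.0)
        return Phylogeny(clone)

    def prune_keep(self, keep: Iterable[str], allow_single: bool = False) -> "Phylogeny":
        """Restrict the tree to ``keep`` tips.

        Degree-2 internal nodes left by the pruning are removed with
        their incident branch lengths summed, so every pairwise path
        length among kept tips is unchanged.
        """
        keep = list(dict.fromkeys(keep))
        if not keep:
            raise ValueError("empty keep set")
        missing = sorted(set(keep) - set(self.tip_labels))
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        if len(keep) == 1:
            if not allow_single:
                raise ValueError(
                    "pruning to a single tip yields a degenerate one-branch tree; "
                    "pass allow_single=True to permit it"
                )
            label = keep[0]
            ns = dendropy.TaxonNamespace()
            t = dendropy.Tree(taxon_namespace=ns)
            lone = t.seed_node.new_child(taxon=ns.require_taxon(label=label))
            # pendant length = full root-to-tip distance, keeping depth
            arr = self.arrays
            lone.edge.length = float(arr.depths()[arr.index[label]])
            return Phylogeny(t)
        sub = self._tree.extract_tree_with_taxa_labels(keep)
        return Phylogeny(sub)

    def extract_clade(self, node_name: str) -> "Phylogeny":
        """Return the subtree rooted at the named node (tips keep their depths below it)."""
        arr = self.arrays
        if node_name not in arr.index:
            raise KeyError(f"node {node_name!r} not found")
        i = arr.index[node_name]
        if arr.is_tip[i]:
            raise ValueError("clade extraction requires an internal node")
        tips = [arr.names[t] for t in arr.descendant_tips()[i]]
        return self.prune_keep(tips)

    # -- checks ------------------------------------------------------------

    def is_ultrametric(self, tol: float = 1e-6) -> tuple[bool, float]:
        """True iff all root-to-tip depths agree within ``tol``; also the max deviation."""
        arr = self.arrays
        d = arr.depths()[arr.tip_indices]
        dev = float(d.max() - d.min())
        return dev <= tol, dev

    @property
    def height(self) -> float:
        arr = self.arrays
        return float(arr.depths()[arr.tip_indices].max())

    def has_zero_length_edges(self) -> bool:
        arr = self.arrays
        return bool(np.any(arr.blen[: arr.n - 1] == 0.0))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, height={self.height:.4g})"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required downstream) into a Phylogeny."""
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def align_to_tips(tree: Phylogeny, mapping: Mapping[str, object]) -> list:
    """Return ``mapping``'s values in tip-label order, reporting any mismatch.

    Raises ``KeyError`` listing tips without data and data without tips,
    so trait tables are joined to trees only by exact label match.
    """
    tips = tree.tip_labels
    missing = [t for t in tips if t not in mapping]
    extra = sorted(set(mapping) - set(tips))
    if missing or extra:
        raise KeyError(f"trait/tree tip mismatch: tips without data {missing}, data without tips {extra}")
    return [mapping[t] for t in tips]
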