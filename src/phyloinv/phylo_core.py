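"""Dated-tree container and patristic-distance machinery.

A :class:`DatedTree` is a rooted phylogeny with branch lengths in millions
of years (My).  It is stored as flat arrays in topological order (every
parent precedes its children), which makes depth computation, pruning,
Brownian-motion simulation and the batched down-passes used elsewhere in
the package cheap and allocation-free.

Newick parsing and the associated error reporting are delegated to
dendropy; this module only adds the validation the analyses require
(unique tip labels, explicit branch lengths) and the distance machinery.
"""

from __future__ import annotations

import numpy as np
import dendropy

__all__ = [
    "DatedTree",
    "TreeError",
    "read_newick",
    "write_newick",
    "check_ultrametric",
    "patristic_distance",
    "distance_matrix",
    "normalize_label",
]


class TreeError(ValueError):
    """Raised for malformed or invalid trees."""


def normalize_label(label: str) -> str:
    """Canonical form used to match tip labels to species tables.

    A single documented normalization: surrounding whitespace is trimmed
    and internal spaces become underscores, so ``"Poa annua"`` and
    ``"Poa_annua"`` refer to the same taxon.
    """
    return label.strip().replace(" ", "_")


class DatedTree:
    """Rooted tree with branch lengths, stored as parent-pointer arrays.

    Parameters
    ----------
    parent
        Integer array; ``parent[0] == -1`` (node 0 is the root) and
        ``parent[i] < i`` for all other nodes (topological order).
    length
        Branch length of the edge above each node (My); the root entry is 0.
    tip_labels
        Mapping node id -> label for every leaf.
    """

    def __init__(self, parent, length, tip_labels: dict[int, str]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        n = self.parent.size
        if n == 0:
            raise TreeError("empty tree")
        if self.length.size != n:
            raise TreeError("parent/length size mismatch")
        if self.parent[0] != -1:
            raise TreeError("node 0 must be the root")
        if n > 1 and not np.all(self.parent[1:] >= 0):
            raise TreeError("exactly one root allowed")
        if n > 1 and not np.all(self.parent[1:] < np.arange(1, n)):
            raise TreeError("nodes must be in topological order")
        if np.any(self.length < 0):
            raise TreeError("negative branch length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.tip_ids = np.array(
            [i for i in range(n) if not self.children[i]], dtype=np.int64
        )
        if set(tip_labels) != set(self.tip_ids.tolist()):
            raise TreeError("tip_labels must cover exactly the leaves")
        self.tip_labels = [str(tip_labels[i]) for i in self.tip_ids]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = sorted(
                {x for x in self.tip_labels if self.tip_labels.count(x) > 1}
            )
            raise TreeError(f"duplicate tip labels: {dupes}")
        self._label_to_tip = {
            lab: int(tid) for lab, tid in zip(self.tip_labels, self.tip_ids)
        }
        self._depths: np.ndarray | None = None

    # ------------------------------------------------------------------ #
    # basic properties
    # ------------------------------------------------------------------ #
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size

    @property
    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (My)."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for i in range(1, self.n_nodes):
                d[i] = d[self.parent[i]] + self.length[i]
            self._depths = d
        return self._depths

    def tip_depths(self) -> np.ndarray:
        return self.depths()[self.tip_ids]

    def tip_id(self, label: str) -> int:
        try:
            return self._label_to_tip[label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    # ------------------------------------------------------------------ #
    # construction / I/O
    # ------------------------------------------------------------------ #
    @classmethod
    def from_dendropy(cls, tree: "dendropy.Tree") -> "DatedTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n)
        tip_labels: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeError(
                        "missing branch length on an edge; dated analyses "
                        "require explicit lengths"
                    )
                length[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise TreeError("unlabeled tip")
                tip_labels[i] = normalize_label(nd.taxon.label)
        return cls(parent, length, tip_labels)

    @classmethod
    def from_newick_string(cls, newick: str) -> "DatedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree)

    def to_newick(self, precision: int = 12) -> str:
        pieces: list[str | None] = [None] * self.n_nodes
        fmt = f"%.{precision}g"
        for i in range(self.n_nodes - 1, -1, -1):
            if not self.children[i]:
                lab = self.tip_labels[
                    int(np.searchsorted(self.tip_ids, i))
                ]
                pieces[i] = f"{lab}:{fmt % self.length[i]}"
            else:
                inner = ",".join(pieces[c] for c in self.children[i])
                if i == 0:
                    pieces[i] = f"({inner})"
                else:
                    pieces[i] = f"({inner}):{fmt % self.length[i]}"
        return pieces[0] + ";"

    # ------------------------------------------------------------------ #
    # distances
    # ------------------------------------------------------------------ #
    def patristic(self, a: str, b: str) -> float:
        """Patristic distance: total branch length on the path a -> b."""
        i, j = self.tip_id(a), self.tip_id(b)
        if i == j:
            return 0.0
        # nodes are topologically ordered, so an ancestor always has the
        # smaller index: climbing the larger index converges on the MRCA
        # even across zero-length edges
        total = 0.0
        while i != j:
            if i > j:
                total += self.length[i]
                i = int(self.parent[i])
            else:
                total += self.length[j]
                j = int(self.parent[j])
        return total

    def distance_matrix(self, labels=None) -> tuple[list[str], np.ndarray]:
        """Pairwise patristic distances for ``labels`` (default: all tips).

        One post-order traversal: for every internal node, tip pairs that
        straddle two of its child subtrees have that node as MRCA, and
        ``dist(a, b) = depth(a) + depth(b) - 2 * depth(mrca)``.  Polytomies
        are handled naturally.  O(n^2) time overall.
        """
        if labels is None:
            labels = list(self.tip_labels)
        labels = list(labels)
        if len(labels) == 0:
            raise ValueError("empty label subset")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in subset")
        col = {self.tip_id(lab): k for k, lab in enumerate(labels)}
        m = len(labels)
        depth = self.depths()
        td = np.zeros(m)
        for tid, k in col.items():
            td[k] = depth[tid]
        D = np.zeros((m, m))
        below: list[np.ndarray | None] = [None] * self.n_nodes
        for i in range(self.n_nodes - 1, -1, -1):
            if not self.children[i]:
                below[i] = (
                    np.array([col[i]], dtype=np.int64)
                    if i in col
                    else np.empty(0, dtype=np.int64)
                )
            else:
                parts = [below[c] for c in self.children[i]]
                for a in range(len(parts)):
                    if parts[a].size == 0:
                        continue
                    for b in range(a + 1, len(parts)):
                        if parts[b].size == 0:
                            continue
                        la, lb = parts[a], parts[b]
                        block = (
                            td[la][:, None] + td[lb][None, :] - 2.0 * depth[i]
                        )
                        D[np.ix_(la, lb)] = block
                        D[np.ix_(lb, la)] = block.T
                below[i] = np.concatenate(parts)
                for c in self.children[i]:
                    below[c] = None
        return labels, D

    # ------------------------------------------------------------------ #
    # topology manipulation
    # ------------------------------------------------------------------ #
    def prune(self, keep_labels) -> "DatedTree":
        """Subtree induced by ``keep_labels``.

        Unary nodes created by the pruning are suppressed (their branch
        lengths summed); the new root is the MRCA of the kept tips with a
        zero-length root edge.
        """
        keep = {self.tip_id(lab) for lab in keep_labels}
        if not keep:
            raise ValueError("cannot prune to an empty tip set")
        cnt = np.zeros(self.n_nodes, dtype=np.int64)
        for i in range(self.n_nodes - 1, -1, -1):
            if not self.children[i]:
                cnt[i] = 1 if i in keep else 0
            else:
                cnt[i] = sum(cnt[c] for c in self.children[i])

        def kept_children(node):
            return [c for c in self.children[node] if cnt[c] > 0]

        # descend to the MRCA of the kept tips
        root = 0
        while cnt[root] > 0 and root not in keep:
            kc = kept_children(root)
            if len(kc) != 1:
                break
            root = kc[0]

        parent_new: list[int] = [-1]
        length_new: list[float] = [0.0]
        labels_new: dict[int, str] = {}
        if root in keep:
            labels_new[0] = self.tip_labels[
                int(np.searchsorted(self.tip_ids, root))
            ]
            return DatedTree(parent_new, length_new, labels_new)
        stack = [(root, 0)]  # (old internal node, new index)
        while stack:
            old, new = stack.pop()
            for c in kept_children(old):
                ln = self.length[c]
                node = c
                while node not in keep and len(kept_children(node)) == 1:
                    node = kept_children(node)[0]
                    ln += self.length[node]
                idx = len(parent_new)
                parent_new.append(new)
                length_new.append(float(ln))
                if node in keep:
                    labels_new[idx] = self.tip_labels[
                        int(np.searchsorted(self.tip_ids, node))
                    ]
                else:
                    stack.append((node, idx))
        return DatedTree(parent_new, length_new, labels_new)

    def resolve_polytomies(self) -> "DatedTree":
        """Binary version of the tree.

        Each polytomy is replaced by a ladder of zero-length internal
        edges; the grouping is deterministic (children taken in stored
        order, last two first), so repeated calls give identical trees.
        """
        if self.is_binary:
            return self
        children = [list(c) for c in self.children]
        parent = list(self.parent)
        length = list(self.length)
        for i in range(len(children)):
            ch = children[i]
            while len(ch) > 2:
                a = ch.pop()
                b = ch.pop()
                idx = len(parent)
                parent.append(i)
                length.append(0.0)
                children.append([b, a])
                parent[b] = idx
                parent[a] = idx
                ch.append(idx)
        # relinearize in topological order
        order: list[int] = []
        stack = [0]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(children[node]))
        newidx = {old: new for new, old in enumerate(order)}
        n = len(order)
        parent2 = np.full(n, -1, dtype=np.int64)
        length2 = np.zeros(n)
        labels2: dict[int, str] = {}
        tiplab = dict(zip(self.tip_ids.tolist(), self.tip_labels))
        for old in order:
            new = newidx[old]
            if parent[old] != -1:
                parent2[new] = newidx[parent[old]]
            length2[new] = length[old]
            if old in tiplab:
                labels2[new] = tiplab[old]
        return DatedTree(parent2, length2, labels2)

    # ------------------------------------------------------------------ #
    # simulation support
    # ------------------------------------------------------------------ #
    def simulate_brownian(
        self, n_reps: int, rng: np.random.Generator, rate: float = 1.0
    ) -> np.ndarray:
        """Brownian-motion tip values, shape ``(n_tips, n_reps)``.

        Each edge contributes an independent Normal(0, rate * length)
        increment; tip values are the root-to-tip sums (root value 0).
        """
        sd = np.sqrt(rate * self.length)
        vals = rng.standard_normal((self.n_nodes, n_reps)) * sd[:, None]
        vals[0] = 0.0
        for i in range(1, self.n_nodes):
            vals[i] += vals[self.parent[i]]
        return vals[self.tip_ids]


# ---------------------------------------------------------------------- #
# module-level functional interface
# ---------------------------------------------------------------------- #
def read_newick(path) -> DatedTree:
    """Read a rooted newick tree with branch lengths.

    Malformed strings raise dendropy's parse error (with position);
    missing branch lengths and duplicate tip labels raise
    :class:`TreeError` rather than being silently defaulted.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return DatedTree.from_dendropy(tree)


def write_newick(tree: DatedTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def check_ultrametric(
    tree: DatedTree, tol: float = 1e-6
) -> tuple[bool, float]:
    """Whether all root-to-tip depths agree within relative tolerance ``tol``.

    Returns ``(is_ultrametric, max_absolute_deviation)`` where the
    deviation is measured against the maximum tip depth.
    """
    d = tree.tip_depths()
    dev = float(d.max() - d.min())
    scale = float(d.max()) if d.max() > 0 else 1.0
    return dev <= tol * scale, dev


def patristic_distance(tree: DatedTree, a: str, b: str) -> float:
    return tree.patristic(a, b)


def distance_matrix(tree: DatedTree, labels=None):
    return tree.distance_matrix(labels)
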