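"""Tree handling: Newick I/O, Brownian-motion covariance matrices, Pagel
branch-length transformations, and random tip subsampling.

The central object is :class:`Phylogeny`, a thin validated wrapper around a
rooted :class:`dendropy.Tree`.  All statistics in this package consume either
the tree itself or its tip variance-covariance matrix under Brownian motion
(:class:`PhyloCovariance`), whose (i, j) entry is the root-to-MRCA path
length shared by tips i and j.

Matrix rows/columns follow the tree's traversal tip order; trait tables are
always aligned to tips by label (see :func:`normalize_label`), never by
position.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "TransformParams",
    "PhyloError",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "vcv_matrix",
    "transform_lambda",
    "transform_kappa",
    "transform_delta",
    "random_subtree",
    "normalize_label",
]


class PhyloError(ValueError):
    """Base class for tree-related errors."""


class NewickParseError(PhyloError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(PhyloError):
    """Raised when a parsed tree violates a structural invariant."""


_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Canonical form of a species label for matching across files.

    Strips surrounding whitespace, collapses internal runs of whitespace,
    and unifies spaces to underscores, so ``" D. busckii "`` and
    ``"D._busckii"`` match the same tip.
    """
    return _WS.sub("_", label.strip().replace("_", " "))


@dataclass(frozen=True)
class TransformParams:
    """Pagel branch-length transformation parameters.

    lambda_ scales the off-diagonal covariance (signal strength, in [0, 1]);
    kappa exponentiates individual branch lengths (tempo along branches,
    in [0, 3]); delta exponentiates node depths (tempo along root-to-tip
    paths, in (0, 3]).  All three equal to 1 is the identity (pure Brownian
    motion).
    """

    lambda_: float = 1.0
    kappa: float = 1.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lambda_}")
        if not 0.0 <= self.kappa <= 3.0:
            raise ValueError(f"kappa must lie in [0, 3], got {self.kappa}")
        if not 0.0 < self.delta <= 3.0:
            raise ValueError(f"delta must lie in (0, 3], got {self.delta}")

    @property
    def is_identity(self) -> bool:
        return self.lambda_ == 1.0 and self.kappa == 1.0 and self.delta == 1.0


@dataclass
class PhyloCovariance:
    """Tip variance-covariance matrix implied by a tree under Brownian motion.

    ``matrix[i, j]`` is the depth (root-to-MRCA path length) of the most
    recent common ancestor of tips ``labels[i]`` and ``labels[j]``; the
    diagonal holds root-to-tip distances.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def copy(self) -> "PhyloCovariance":
        return PhyloCovariance(self.labels, self.matrix.copy())

    def cholesky(self, ridge: float = 1e-10) -> np.ndarray:
        """Lower Cholesky factor, adding a ridge of at most ``ridge`` on the
        diagonal only if the plain factorization fails."""
        try:
            return np.linalg.cholesky(self.matrix)
        except np.linalg.LinAlgError:
            scale = max(float(np.max(np.diag(self.matrix))), 1.0)
            try:
                return np.linalg.cholesky(self.matrix + ridge * scale * np.eye(self.n))
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise PhyloError(
                    "covariance matrix is not positive semi-definite even "
                    f"after a ridge of {ridge}"
                ) from exc


class Phylogeny:
    """A rooted phylogeny with branch lengths.

    Wraps a :class:`dendropy.Tree` and caches an integer-indexed view of the
    topology (parent pointers, edge lengths, tip MRCA matrix) so covariance
    matrices under branch-length transformations can be rebuilt cheaply
    during likelihood optimization.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._index: _TreeIndex | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return parse_newick(fh.read())

    def _validate(self) -> None:
        leaves = self._tree.leaf_node_iter()
        seen: set[str] = set()
        for leaf in leaves:
            if leaf.taxon is None or not str(leaf.taxon.label).strip():
                raise TreeValidationError("tree contains an unlabeled tip")
            label = str(leaf.taxon.label)
            if label in seen:
                raise TreeValidationError(f"duplicate tip label: {label!r}")
            seen.add(label)
        if len(seen) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        root = self._tree.seed_node
        internal_labels = []
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            length = node.edge.length
            if length is None:
                raise TreeValidationError(
                    f"edge above {_node_name(node)} has no branch length"
                )
            if not np.isfinite(length) or length < 0:
                raise TreeValidationError(
                    f"edge above {_node_name(node)} has invalid length {length}"
                )
            if not node.is_leaf() and node.taxon is not None:
                internal_labels.append(str(node.taxon.label))
        if internal_labels:
            warnings.warn(
                f"ignoring internal node labels: {internal_labels[:5]}",
                stacklevel=3,
            )

    # -- basic views ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._get_index().tip_labels

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_internal_node_labels=True,
        )
        return s.strip() + "\n"

    def __repr__(self) -> str:
        return f"<Phylogeny with {self.n_tips} tips>"

    # -- cached integer index ------------------------------------------

    def _get_index(self) -> "_TreeIndex":
        if self._index is None:
            self._index = _TreeIndex.build(self._tree)
        return self._index

    # -- derived quantities --------------------------------------------

    def vcv(self, kappa: float | None = None) -> PhyloCovariance:
        """Brownian covariance matrix, optionally under a kappa transform
        of the branch lengths (each length b replaced by b**kappa)."""
        idx = self._get_index()
        bl = idx.edge_lengths
        if kappa is not None:
            if not 0.0 <= kappa <= 3.0:
                raise ValueError(f"kappa must lie in [0, 3], got {kappa}")
            # numpy's 0**0 == 1 and 0**k == 0 match the conventional
            # punctuational limit for zero-length branches
            bl = np.power(bl, kappa)
        depth = idx.node_depths(bl)
        C = depth[idx.mrca]
        return PhyloCovariance(idx.tip_labels, C)

    def patristic_matrix(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Pairwise path-length (patristic) distances between tips."""
        cov = self.vcv()
        d = np.diag(cov.matrix)
        D = d[:, None] + d[None, :] - 2.0 * cov.matrix
        np.fill_diagonal(D, 0.0)
        return cov.labels, D

    # -- pruning -------------------------------------------------------

    def prune_to(self, labels) -> "Phylogeny":
        """Subtree spanned by ``labels``, with unifurcations suppressed by
        summing their incident branch lengths so patristic distances among
        the retained tips are unchanged."""
        keep = list(labels)
        have = set(self.tip_labels)
        missing = [lab for lab in keep if lab not in have]
        if missing:
            raise TreeValidationError(f"labels not in tree: {missing}")
        if len(set(keep)) < 2:
            raise TreeValidationError("must retain at least 2 tips")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=set(keep), suppress_unifurcations=True
        )
        sub.seed_node.edge.length = None
        return Phylogeny(sub)


def _node_name(node) -> str:
    if node.taxon is not None:
        return repr(str(node.taxon.label))
    return "an internal node"


@dataclass
class _TreeIndex:
    """Preorder integer encoding of a rooted tree.

    parent[i] is the preorder index of node i's parent (-1 for the root);
    mrca[a, b] is the preorder index of the MRCA of tips a and b (tip order
    as in tip_labels); tip_nodes[a] is the preorder index of tip a.
    """

    tip_labels: tuple[str, ...]
    parent: np.ndarray
    edge_lengths: np.ndarray
    tip_nodes: np.ndarray
    mrca: np.ndarray = field(repr=False)

    @classmethod
    def build(cls, tree: dendropy.Tree) -> "_TreeIndex":
        nodes = list(tree.preorder_node_iter())
        pos = {id(nd): i for i, nd in enumerate(nodes)}
        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        elen = np.zeros(n_nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = pos[id(nd.parent_node)]
                elen[i] = float(nd.edge.length or 0.0)
        tip_nodes_list: list[int] = []
        tip_labels: list[str] = []
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                tip_nodes_list.append(i)
                tip_labels.append(str(nd.taxon.label))
        n_tips = len(tip_labels)
        tip_pos = {node_i: t for t, node_i in enumerate(tip_nodes_list)}
        mrca = np.zeros((n_tips, n_tips), dtype=np.int64)
        # post-order sweep: at each internal node, tip pairs drawn from two
        # different child subtrees have that node as their MRCA
        below: dict[int, np.ndarray] = {}
        for nd in tree.postorder_node_iter():
            i = pos[id(nd)]
            if nd.is_leaf():
                below[i] = np.array([tip_pos[i]], dtype=np.int64)
                mrca[tip_pos[i], tip_pos[i]] = i
                continue
            child_sets = [below.pop(pos[id(ch)]) for ch in nd.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    mrca[np.ix_(child_sets[a], child_sets[b])] = i
                    mrca[np.ix_(child_sets[b], child_sets[a])] = i
            below[i] = np.concatenate(child_sets)
        return cls(
            tip_labels=tuple(tip_labels),
            parent=parent,
            edge_lengths=elen,
            tip_nodes=np.array(tip_nodes_list, dtype=np.int64),
            mrca=mrca,
        )

    def node_depths(self, edge_lengths: np.ndarray) -> np.ndarray:
        depth = np.zeros(len(self.parent))
        for i in range(1, len(self.parent)):
            depth[i] = depth[self.parent[i]] + edge_lengths[i]
        return depth


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick tree with branch lengths.

    Raises :class:`NewickParseError` on malformed input (the message names
    the offending position when the parser reports one) and
    :class:`TreeValidationError` for structural problems such as duplicate
    tip labels or missing branch lengths.
    """
    if not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip label in Newick: {exc}") from exc
        raise NewickParseError(_describe_parse_error(text, exc)) from exc
    return Phylogeny(tree)


def _describe_parse_error(text: str, exc: Exception) -> str:
    msg = str(exc)
    col = getattr(exc, "col_num", None)
    if col is not None:
        return f"malformed Newick at character offset {col}: {msg}"
    return f"malformed Newick: {msg}"


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialize to Newick; writes to ``path`` when given, returns the string."""
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def vcv_matrix(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance of tip values implied by the tree:
    entry (i, j) is the shared root-to-MRCA path length, the diagonal the
    root-to-tip distance."""
    return tree.vcv()


def transform_lambda(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda: multiply off-diagonal covariance entries by ``lam``.

    lam = 1 leaves the matrix unchanged (full Brownian signal); lam = 0
    yields a diagonal matrix, statistically a star phylogeny.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(C.labels, M)


def transform_kappa(tree: Phylogeny, kap: float) -> Phylogeny:
    """Pagel's kappa: raise every branch length to the power ``kap``.

    kap < 1 compresses long branches (change concentrated in speciation
    events, the punctuational limit at kap = 0 where every positive branch
    becomes 1); kap = 1 is gradual change.
    """
    if not 0.0 <= kap <= 3.0:
        raise ValueError(f"kappa must lie in [0, 3], got {kap}")
    clone = dendropy.Tree(tree.dendropy_tree)
    for node in clone.preorder_node_iter():
        if node.parent_node is None:
            continue
        b = float(node.edge.length or 0.0)
        node.edge.length = float(np.power(b, kap))
    return Phylogeny(clone)


def transform_delta(C: PhyloCovariance, del_: float) -> PhyloCovariance:
    """Pagel's delta: raise every covariance entry (node depth) to ``del_``.

    del_ < 1 means rapid change early in the tree followed by deceleration;
    del_ > 1 an accelerating rate toward the tips; del_ = 1 gradual change.
    """
    if not 0.0 < del_ <= 3.0:
        raise ValueError(f"delta must lie in (0, 3], got {del_}")
    if np.any(C.matrix < 0):
        raise ValueError("delta transform requires non-negative covariance entries")
    return PhyloCovariance(C.labels, np.power(C.matrix, del_))


def random_subtree(tree: Phylogeny, n: int, seed: int) -> Phylogeny:
    """Prune to ``n`` tips chosen uniformly at random without replacement.

    Unifurcations created by pruning are suppressed by summing the two
    incident branch lengths, so pairwise patristic distances among the
    retained tips equal those in the parent tree.
    """
    if not 2 <= n <= tree.n_tips:
        raise ValueError(f"n must lie in [2, {tree.n_tips}], got {n}")
    if n == tree.n_tips:
        return tree
    rng = np.random.default_rng(seed)
    keep = rng.choice(np.array(tree.tip_labels, dtype=object), size=n, replace=False)
    return tree.prune_to(list(keep))
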