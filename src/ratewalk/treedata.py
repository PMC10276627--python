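"""Phylogeny and trait-data containers.

Trees are rooted, time-calibrated (branch lengths in time units, not
necessarily ultrametric). Time is 0 at the root and increases tipward.
Multifurcations are resolved into bifurcations by inserting zero-length
"pseudo-branches"; pseudo-branches never receive a rate parameter.

Branches are identified by their child node. Node ids are assigned in a
deterministic preorder at read time (root = 0), so branch ids are the node
ids 1..n_nodes-1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy


class TreeError(ValueError):
    """Raised for malformed or unsupported input trees."""


class _Node:
    __slots__ = ("label", "length", "children", "pseudo", "orig_edge")

    def __init__(self, label=None, length=0.0, pseudo=False, orig_edge=-1):
        self.label = label
        self.length = length
        self.children = []
        self.pseudo = pseudo
        self.orig_edge = orig_edge


class Phylogeny:
    """Indexed rooted bifurcating phylogeny.

    Attributes
    ----------
    parent, left, right : (n_nodes,) int arrays; -1 where absent.
    t : (n_nodes,) branch length above each node (0 at the root).
    tau1, tau2 : (n_nodes,) start/end times of the branch above each node
        (time 0 at the root); tau2[k] = tau1[k] + t[k].
    T : tree height (maximum tip time).
    is_pseudo : (n_nodes,) bool, True for inserted zero-length branches.
    rate_index : (n_nodes,) int; index into the branchwise-rate vector for
        non-pseudo branches, -1 for the root and pseudo-branches.
    rate_nodes : (n_rate_branches,) node ids in rate-index order.
    tip_ids, tip_labels : tips in preorder appearance.
    orig_edge_index : (n_nodes,) index of the corresponding edge in the
        unresolved input tree (-1 for pseudo-branches and the root).
    """

    def __init__(self, root: _Node):
        nodes: list[_Node] = []
        parent_of: list[int] = []

        def walk(nd, par):
            my_id = len(nodes)
            nodes.append(nd)
            parent_of.append(par)
            for ch in nd.children:
                walk(ch, my_id)

        walk(root, -1)
        n = len(nodes)
        self.n_nodes = n
        self.parent = np.array(parent_of, dtype=np.int64)
        self.left = np.full(n, -1, dtype=np.int64)
        self.right = np.full(n, -1, dtype=np.int64)
        self.t = np.zeros(n)
        self.is_pseudo = np.zeros(n, dtype=bool)
        self.orig_edge_index = np.full(n, -1, dtype=np.int64)
        labels = [None] * n

        id_of = {id(nd): i for i, nd in enumerate(nodes)}
        for i, nd in enumerate(nodes):
            self.t[i] = nd.length if parent_of[i] >= 0 else 0.0
            self.is_pseudo[i] = nd.pseudo
            self.orig_edge_index[i] = nd.orig_edge if parent_of[i] >= 0 else -1
            labels[i] = nd.label
            if nd.children:
                if len(nd.children) != 2:
                    raise TreeError("internal error: unresolved multifurcation")
                self.left[i] = id_of[id(nd.children[0])]
                self.right[i] = id_of[id(nd.children[1])]

        self.tau1 = np.zeros(n)
        self.tau2 = np.zeros(n)
        for i in range(1, n):
            self.tau1[i] = self.tau2[self.parent[i]]
            self.tau2[i] = self.tau1[i] + self.t[i]

        is_tip = self.left < 0
        self.is_tip = is_tip
        self.tip_ids = np.nonzero(is_tip)[0]
        self.tip_labels = [labels[i] for i in self.tip_ids]
        self.n_tips = len(self.tip_ids)
        self.T = float(self.tau2[self.tip_ids].max())

        # rate-branch indexing: non-root, non-pseudo branches in preorder
        self.rate_index = np.full(n, -1, dtype=np.int64)
        rate_nodes = [i for i in range(1, n) if not self.is_pseudo[i]]
        self.rate_nodes = np.array(rate_nodes, dtype=np.int64)
        self.rate_index[self.rate_nodes] = np.arange(len(rate_nodes))
        self.n_rate_branches = len(rate_nodes)

        # postorder over internal nodes (children before parents)
        post = []
        stack = [(0, False)]
        while stack:
            node, done = stack.pop()
            if self.left[node] < 0:
                continue
            if done:
                post.append(node)
            else:
                stack.append((node, True))
                stack.append((self.right[node], False))
                stack.append((self.left[node], False))
        self.postorder = np.array(post, dtype=np.int64)

    # ------------------------------------------------------------------
    def ancestral_path(self, i: int) -> set[int]:
        """Branches (node ids) on the root-to-i path, including branch i."""
        if not (1 <= i < self.n_nodes):
            raise IndexError(f"invalid branch/tip index {i}")
        out = set()
        while i > 0:
            out.add(int(i))
            i = int(self.parent[i])
        return out

    def shared_ancestral_branches(self, i: int, j: int) -> set[int]:
        """anc(i, j): branches ancestral to both i and j.

        A branch counts as ancestral to itself, so anc(i, i) is the whole
        root path of i. This convention makes the diagonal of the log-rate
        covariance reduce to t/3 on a root branch — the variance of the
        time-average of a standard Brownian path.
        """
        return self.ancestral_path(i) & self.ancestral_path(j)

    def ancestor_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_nodes); M[k, i] = branch k on root path of i."""
        n = self.n_nodes
        M = np.zeros((n, n), dtype=bool)
        for i in range(1, n):
            M[i, i] = True
            p = int(self.parent[i])
            if p > 0:
                M[:, i] |= M[:, p]
        return M

    def mrca(self, i: int, j: int) -> int:
        a = self.ancestral_path(i) | {0}
        k = j
        while k not in a:
            k = int(self.parent[k])
        return k

    def rescaled(self, height: float = 1.0) -> "Phylogeny":
        """Return a copy with all branch lengths scaled so the height is `height`."""
        nwk = self.to_newick()
        phy = read_tree(nwk)
        c = height / phy.T
        phy.t *= c
        phy.tau1 *= c
        phy.tau2 *= c
        phy.T = float(phy.tau2[phy.tip_ids].max())
        return phy

    def to_newick(self, branch_labels: dict[int, str] | None = None) -> str:
        """Serialize to Newick. `branch_labels` optionally annotates branches
        (by node id) with a comment appended to the branch length."""

        def rec(i):
            com = ""
            if branch_labels and i in branch_labels:
                com = f"[&{branch_labels[i]}]"
            if self.left[i] < 0:
                return f"{self.tip_labels[list(self.tip_ids).index(i)]}:{self.t[i]:.12g}{com}"
            l, r = rec(int(self.left[i])), rec(int(self.right[i]))
            if i == 0:
                return f"({l},{r});"
            return f"({l},{r}):{self.t[i]:.12g}{com}"

        return rec(0)

    def __repr__(self):
        return (f"Phylogeny(n_tips={self.n_tips}, n_branches={self.n_nodes - 1}, "
                f"n_rate_branches={self.n_rate_branches}, T={self.T:.4g})")


def _resolve(nd: _Node) -> None:
    """Binarize multifurcations in place, grouping children left-to-right
    under zero-length pseudo-branches. The likelihood is invariant to the
    grouping; left-to-right keeps the result reproducible."""
    for ch in nd.children:
        _resolve(ch)
    while len(nd.children) > 2:
        ps = _Node(length=0.0, pseudo=True)
        ps.children = nd.children[:2]
        nd.children = [ps] + nd.children[2:]


def read_tree(newick: str) -> Phylogeny:
    """Parse a rooted Newick string into an indexed :class:`Phylogeny`.

    Branch lengths are required on every edge; a root edge length, if
    present, is ignored. Multifurcations are resolved with zero-length
    pseudo-branches. Raises :class:`TreeError` on unrooted trees, missing
    or negative branch lengths, or fewer than two tips.
    """
    if "[&U]" in newick.upper().replace(" ", ""):
        raise TreeError("tree is explicitly unrooted ([&U]); a rooted tree is required")
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
    except Exception as e:  # dendropy raises various error classes
        raise TreeError(f"could not parse Newick: {e}") from None

    edge_counter = [0]

    def convert(dnode, is_root):
        if is_root:
            length = 0.0
        else:
            if dnode.edge.length is None:
                raise TreeError("missing branch length (all edges must have lengths)")
            length = float(dnode.edge.length)
            if length < 0:
                raise TreeError(f"negative branch length {length}")
        label = dnode.taxon.label if dnode.taxon is not None else None
        nd = _Node(label=label, length=length,
                   orig_edge=-1 if is_root else edge_counter[0])
        if not is_root:
            edge_counter[0] += 1
        for ch in dnode.child_nodes():
            nd.children.append(convert(ch, False))
        if not nd.children and nd.label is None:
            raise TreeError("tip without a label")
        if len(nd.children) == 1:
            raise TreeError("unifurcation (node with a single child) is not supported")
        return nd

    root = convert(dtree.seed_node, True)
    _resolve(root)
    phy = Phylogeny(root)
    if phy.n_tips < 2:
        raise TreeError("tree must have at least 2 tips")
    if len(set(phy.tip_labels)) != phy.n_tips:
        raise TreeError("duplicate tip labels")
    return phy


# ----------------------------------------------------------------------
@dataclass
class TraitData:
    """Raw trait measurements aligned to the tips of a phylogeny.

    y[i] holds the raw measurements for tip i (tree tip order); m[i] their
    count (0 marks a missing-data tip). Tips whose value encodes a normal
    prior carry a fixed error variance in fixed_var (NaN = free tip whose
    error variance is estimated). sigma_raw2 is the variance of all pooled
    raw measurements, used to scale default priors.
    """

    labels: list[str]
    y: list[np.ndarray]
    m: np.ndarray
    fixed_var: np.ndarray
    sigma_raw2: float = field(default=0.0)

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=np.int64)
        assert all(len(self.y[i]) == self.m[i] for i in range(len(self.labels)))
        pooled = np.concatenate([v for v in self.y if len(v)]) if self.m.sum() else np.array([])
        if len(np.unique(pooled)) >= 2:
            self.sigma_raw2 = float(np.var(pooled, ddof=1))
        else:
            self.sigma_raw2 = 0.0

    @property
    def n_observed(self) -> int:
        return int((self.m > 0).sum())

    def tip_means(self) -> np.ndarray:
        return np.array([v.mean() if len(v) else np.nan for v in self.y])


def trait_data_from_dict(values: dict[str, object], tree: Phylogeny,
                         fixed_var: dict[str, float] | None = None) -> TraitData:
    """Build TraitData from {tip label: scalar or sequence of measurements}."""
    fixed_var = fixed_var or {}
    unknown = [k for k in values if k not in tree.tip_labels]
    unknown += [k for k in fixed_var if k not in tree.tip_labels]
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(set(unknown))}")
    y, fv = [], []
    for lab in tree.tip_labels:
        v = values.get(lab, ())
        arr = np.atleast_1d(np.asarray(v, dtype=float)).ravel()
        y.append(arr)
        fv.append(fixed_var.get(lab, np.nan))
    m = np.array([len(v) for v in y])
    return TraitData(list(tree.tip_labels), y, m, np.array(fv))


def read_traits(path_or_buf, tree: Phylogeny) -> TraitData:
    """Read a delimited trait table (CSV/TSV autodetected) aligned to `tree`.

    Expected columns: tip label, measurement value, optional fixed_var.
    A header row with names {tip, value[, fixed_var]} is recognized;
    otherwise columns are taken positionally. Repeated rows for a tip are
    repeated measurements; tips absent from the table get m = 0.
    """
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf, sep=None, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if "tip" in first or "value" in first:
        df.columns = first
        df = df.iloc[1:].reset_index(drop=True)
        if "tip" not in df.columns or "value" not in df.columns:
            raise ValueError("header must include 'tip' and 'value' columns")
    else:
        names = ["tip", "value", "fixed_var"][: df.shape[1]]
        df.columns = names
    try:
        vals = pd.to_numeric(df["value"])
    except (ValueError, TypeError) as e:
        raise ValueError(f"non-numeric trait measurement: {e}") from None
    values: dict[str, list[float]] = {}
    fixed: dict[str, float] = {}
    fv_col = pd.to_numeric(df["fixed_var"]) if "fixed_var" in df.columns else None
    for idx, row in df.iterrows():
        lab = str(row["tip"]).strip()
        values.setdefault(lab, []).append(float(vals[idx]))
        if fv_col is not None and np.isfinite(fv_col[idx]):
            fixed[lab] = float(fv_col[idx])
    return trait_data_from_dict(values, tree, fixed)
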