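"""Ward agglomerative clustering of a precomputed distance matrix, dendrogram
annotation (LCV / completeness), non-overlapping cluster selection at a
completeness cutover, and dendrogram serialization (Newick / JSON).

The linkage follows the usual Ward convention: the Lance-Williams
recurrence is run on squared distances and node heights are the square
roots, so two singletons merge at exactly their input distance.  Ties are
broken deterministically on the lowest (row, column) pair.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientDataError,
    MissingAnnotationError,
    MissingLabelError,
    SerialMergeError,
)
from .lattice import UnitCell, lcv
from .reflections import ReflectionSet, asu_key_set

__all__ = [
    "Dendrogram",
    "DendrogramNode",
    "ClusterSelection",
    "ward_linkage",
    "annotate_lcv",
    "annotate_completeness",
    "select_nonoverlapping",
    "cut_count",
    "cut_height",
    "cut_largest_gap",
    "dendrogram_to_newick",
    "dendrogram_to_json",
    "dendrogram_from_json",
]


@dataclass(frozen=True)
class DendrogramNode:
    """Internal merge node: children are node ids (leaves are 0..n-1)."""

    node_id: int
    left: int
    right: int
    height: float


@dataclass
class Dendrogram:
    """Binary merge tree over named leaves.

    Leaves carry ids 0..n-1 (in ``leaves`` order); internal nodes n..2n-2 in
    merge order.  ``annotations[node_id]`` holds optional per-node values
    (lcv_percent, alcv_angstrom, completeness).
    """

    leaves: list[str]
    nodes: list[DendrogramNode]
    annotations: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.leaves)
        if len(self.nodes) != max(n - 1, 0):
            raise SerialMergeError(
                f"{n} leaves require {n - 1} internal nodes, got {len(self.nodes)}"
            )
        self._members: dict[int, tuple[int, ...]] = {}

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root_id(self) -> int:
        return 2 * len(self.leaves) - 2 if self.nodes else 0

    def all_node_ids(self):
        return range(2 * len(self.leaves) - 1)

    def is_leaf(self, node_id: int) -> bool:
        return node_id < len(self.leaves)

    def node(self, node_id: int) -> DendrogramNode:
        return self.nodes[node_id - len(self.leaves)]

    def members(self, node_id: int) -> tuple[int, ...]:
        """Leaf indices under a node (sorted)."""
        cached = self._members.get(node_id)
        if cached is not None:
            return cached
        if self.is_leaf(node_id):
            out = (node_id,)
        else:
            nd = self.node(node_id)
            out = tuple(sorted(self.members(nd.left) + self.members(nd.right)))
        self._members[node_id] = out
        return out

    def member_ids(self, node_id: int) -> list[str]:
        return [self.leaves[i] for i in self.members(node_id)]

    def heights(self) -> np.ndarray:
        return np.array([nd.height for nd in self.nodes])


def ward_linkage(dist: np.ndarray, ids=None) -> Dendrogram:
    """Agglomerative Ward clustering of a symmetric distance matrix.

    Implements the Lance-Williams recurrence on squared distances,
    d2(i+j, k) = ((ni+nk) d2(i,k) + (nj+nk) d2(j,k) - nk d2(i,j)) / (ni+nj+nk),
    merging at each step the active pair with the smallest current distance
    (lowest index pair on ties).
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise SerialMergeError("distance matrix must be square")
    if n < 2:
        raise InsufficientDataError("need at least 2 items to cluster")
    if not np.allclose(D, D.T, atol=1e-8):
        raise SerialMergeError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise SerialMergeError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise SerialMergeError("distance matrix must be non-negative")
    if ids is None:
        ids = [str(i) for i in range(n)]
    ids = list(ids)
    if len(ids) != n:
        raise SerialMergeError("ids length does not match matrix size")

    D2 = D.astype(float) ** 2
    np.fill_diagonal(D2, np.inf)
    # mask the lower triangle so argmin scans the upper triangle row-major,
    # which is exactly the lowest-(i,j) tie-break
    D2[np.tril_indices(n, k=0)] = np.inf
    sizes = np.ones(n)
    node_of_slot = np.arange(n)
    active = np.ones(n, dtype=bool)
    nodes: list[DendrogramNode] = []

    for step in range(n - 1):
        flat = np.argmin(D2)
        i, j = divmod(int(flat), n)
        d2_ij = D2[i, j]
        new_id = n + step
        left, right = sorted((int(node_of_slot[i]), int(node_of_slot[j])))
        nodes.append(DendrogramNode(new_id, left, right,
                                    float(np.sqrt(d2_ij))))
        # Lance-Williams update into slot i (i < j by construction)
        k = active.copy()
        k[i] = k[j] = False
        si, sj, sk = sizes[i], sizes[j], sizes[k]
        dik = np.where(np.arange(n) < i, D2[:, i], D2[i, :])[k]
        djk = np.where(np.arange(n) < j, D2[:, j], D2[j, :])[k]
        new_d2 = ((si + sk) * dik + (sj + sk) * djk - sk * d2_ij) / (si + sj + sk)
        idx = np.flatnonzero(k)
        lower = idx[idx < i]
        upper = idx[idx > i]
        D2[lower, i] = new_d2[idx < i]
        D2[i, upper] = new_d2[idx > i]
        active[j] = False
        D2[j, :] = np.inf
        D2[:, j] = np.inf
        sizes[i] = si + sj
        node_of_slot[i] = new_id

    return Dendrogram(leaves=ids, nodes=nodes)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def annotate_lcv(d: Dendrogram, cells: dict[str, UnitCell]) -> Dendrogram:
    """Attach lcv_percent / alcv_angstrom to every node (leaves get 0)."""
    for leaf in d.leaves:
        if leaf not in cells:
            raise MissingLabelError(f"no unit cell for leaf {leaf!r}")
    for node_id in d.all_node_ids():
        member_cells = [cells[d.leaves[i]] for i in d.members(node_id)]
        pct, ang = lcv(member_cells)
        ann = d.annotations.setdefault(node_id, {})
        ann["lcv_percent"] = pct
        ann["alcv_angstrom"] = ang
    return d


def annotate_completeness(d: Dendrogram, sets: dict[str, ReflectionSet],
                          d_min: float) -> Dendrogram:
    """Attach the completeness of the union of member ASU indices per node.

    The denominator is enumerated from the unweighted mean cell of the
    node's members (each leaf uses its own cell); no intensity merging is
    involved in the count.
    """
    for leaf in d.leaves:
        if leaf not in sets:
            raise MissingLabelError(f"no reflection set for leaf {leaf!r}")
    n = d.n_leaves
    key_sets: dict[int, frozenset] = {}
    cell_sums: dict[int, np.ndarray] = {}
    for node_id in d.all_node_ids():
        if d.is_leaf(node_id):
            s = sets[d.leaves[node_id]]
            if s.cell is None or s.laue_group is None:
                raise SerialMergeError(
                    f"set {s.dataset_id} needs cell and Laue group"
                )
            key_sets[node_id] = frozenset(np.unique(s.asu_keys()).tolist())
            cell_sums[node_id] = np.array(s.cell.parameters())
        else:
            nd = d.node(node_id)
            key_sets[node_id] = key_sets[nd.left] | key_sets[nd.right]
            cell_sums[node_id] = cell_sums[nd.left] + cell_sums[nd.right]
        size = len(d.members(node_id))
        mean_cell = UnitCell(*(cell_sums[node_id] / size))
        group = sets[d.leaves[d.members(node_id)[0]]].laue_group
        # 0.1 A / 0.1 deg cache granularity: the reflection count inside the
        # resolution sphere moves by well under the cutover granularity
        full = asu_key_set(mean_cell, group, d_min, cell_decimals=1)
        comp = len(key_sets[node_id] & full) / len(full)
        d.annotations.setdefault(node_id, {})["completeness"] = comp
    return d


# ---------------------------------------------------------------------------
# Selection and flat cuts
# ---------------------------------------------------------------------------


@dataclass
class ClusterSelection:
    """Non-overlapping dendrogram nodes chosen at a completeness cutover."""

    clusters: list[tuple[int, list[str], float]]  # (node_id, member ids, completeness)
    unassigned: list[str]

    def __post_init__(self):
        seen: set[str] = set()
        for _, members, _ in self.clusters:
            overlap = seen & set(members)
            if overlap:
                raise SerialMergeError(f"overlapping selection: {sorted(overlap)}")
            seen |= set(members)

    def __len__(self):
        return len(self.clusters)

    def n_datasets(self) -> int:
        return sum(len(m) for _, m, _ in self.clusters)

    def to_tsv(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node_id\tsize\tcompleteness\tmembers\n")
            for node_id, members, comp in self.clusters:
                fh.write(f"{node_id}\t{len(members)}\t{comp:.6f}\t"
                         f"{','.join(members)}\n")
            for ds in self.unassigned:
                fh.write(f"unassigned\t1\tnan\t{ds}\n")


def select_nonoverlapping(d: Dendrogram, min_completeness: float) -> ClusterSelection:
    """Lowest dendrogram nodes reaching ``min_completeness``.

    A node is selected iff it qualifies and no strict descendant qualifies;
    qualifying leaves are therefore selectable, and the selected member sets
    are pairwise disjoint.  Leaves under no qualifying node are reported as
    unassigned.
    """
    for node_id in d.all_node_ids():
        if "completeness" not in d.annotations.get(node_id, {}):
            raise MissingAnnotationError(
                "dendrogram lacks completeness annotations; run "
                "annotate_completeness first"
            )
    comp = {nid: d.annotations[nid]["completeness"] for nid in d.all_node_ids()}
    qualifies = {nid: comp[nid] >= min_completeness for nid in d.all_node_ids()}
    has_qual_desc: dict[int, bool] = {}
    for node_id in d.all_node_ids():  # children precede parents
        if d.is_leaf(node_id):
            has_qual_desc[node_id] = False
        else:
            nd = d.node(node_id)
            has_qual_desc[node_id] = any(
                qualifies[ch] or has_qual_desc[ch] for ch in (nd.left, nd.right)
            )
    clusters = [
        (nid, d.member_ids(nid), comp[nid])
        for nid in d.all_node_ids()
        if qualifies[nid] and not has_qual_desc[nid]
    ]
    covered = {ds for _, members, _ in clusters for ds in members}
    unassigned = [ds for ds in d.leaves if ds not in covered]
    return ClusterSelection(clusters=clusters, unassigned=unassigned)


def _cut_after(d: Dendrogram, n_merges: int) -> dict[str, int]:
    """Flat clusters after applying the first ``n_merges`` merges."""
    parent: dict[int, int] = {}

    def find(x):
        while x in parent:
            x = parent[x]
        return x

    for nd in d.nodes[:n_merges]:
        parent[find(nd.left)] = nd.node_id
        parent[find(nd.right)] = nd.node_id
    roots: dict[int, int] = {}
    out = {}
    for i, name in enumerate(d.leaves):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        out[name] = roots[r]
    return out


def cut_count(d: Dendrogram, k: int) -> dict[str, int]:
    """Cut into exactly k flat clusters (merges applied in height order)."""
    if not 1 <= k <= d.n_leaves:
        raise SerialMergeError(f"cluster count {k} out of range")
    return _cut_after(d, d.n_leaves - k)


def cut_height(d: Dendrogram, h: float) -> dict[str, int]:
    """Cut below height h: apply all merges with height < h."""
    n_merges = int(np.sum(d.heights() < h))
    return _cut_after(d, n_merges)


def cut_largest_gap(d: Dendrogram) -> dict[str, int]:
    """Cut at the largest gap in the sorted merge heights.

    A cut is only taken when the largest inter-height gap exceeds the
    smallest merge height: otherwise the heights form one continuum with no
    convincing separation and the tree is one cluster (a homogeneous set of
    inputs merges in one wave of comparable heights).  Ties take the
    earliest (lowest) gap, which favours more, smaller clusters.
    """
    h = np.sort(d.heights())
    if len(h) < 2:
        return _cut_after(d, len(d.nodes))
    gaps = np.diff(h)
    if gaps.max() <= max(h[0], 0.0):
        return _cut_after(d, len(d.nodes))
    i = int(np.argmax(gaps))
    return _cut_after(d, i + 1)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _newick_label(d: Dendrogram, node_id: int) -> str:
    ann = d.annotations.get(node_id, {})
    if "lcv_percent" in ann:
        return f"LCV_{ann['lcv_percent']:.2f}pct_({ann['alcv_angstrom']:.3f}A)"
    return ""


def _sanitize(name: str) -> str:
    for ch in "(),:;\t\n '\"":
        name = name.replace(ch, "_")
    return name


def dendrogram_to_newick(d: Dendrogram) -> str:
    """Newick text with branch lengths = parent height - child height and
    internal labels carrying "LCV (aLCV)" where annotated."""

    def height(node_id):
        return 0.0 if d.is_leaf(node_id) else d.node(node_id).height

    def render(node_id, parent_h):
        bl = max(parent_h - height(node_id), 0.0)
        if d.is_leaf(node_id):
            return f"{_sanitize(d.leaves[node_id])}:{bl:.6g}"
        nd = d.node(node_id)
        inner = ",".join(render(ch, nd.height) for ch in (nd.left, nd.right))
        return f"({inner}){_newick_label(d, node_id)}:{bl:.6g}"

    root = d.root_id
    if d.is_leaf(root):
        return f"{_sanitize(d.leaves[root])}:0;"
    nd = d.node(root)
    inner = ",".join(render(ch, nd.height) for ch in (nd.left, nd.right))
    return f"({inner}){_newick_label(d, root)};"


def dendrogram_to_json(d: Dendrogram) -> str:
    payload = {
        "leaves": list(d.leaves),
        "nodes": [
            {"node_id": nd.node_id, "left": nd.left, "right": nd.right,
             "height": nd.height}
            for nd in d.nodes
        ],
        "annotations": {str(k): v for k, v in d.annotations.items()},
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def dendrogram_from_json(text: str) -> Dendrogram:
    payload = json.loads(text)
    nodes = [
        DendrogramNode(nd["node_id"], nd["left"], nd["right"], nd["height"])
        for nd in payload["nodes"]
    ]
    ann = {int(k): dict(v) for k, v in payload.get("annotations", {}).items()}
    return Dendrogram(leaves=list(payload["leaves"]), nodes=nodes, annotations=ann)


def cluster_report_tsv(d: Dendrogram, path):
    """Per-node TSV: node_id, size, completeness, lcv_percent, alcv, members."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tsize\tcompleteness\tlcv_percent\talcv_angstrom\tmembers\n")
        for node_id in d.all_node_ids():
            ann = d.annotations.get(node_id, {})
            comp = ann.get("completeness", float("nan"))
            pct = ann.get("lcv_percent", float("nan"))
            alcv = ann.get("alcv_angstrom", float("nan"))
            members = ",".join(d.member_ids(node_id))
            fh.write(f"{node_id}\t{len(d.members(node_id))}\t{comp:.6f}\t"
                     f"{pct:.6f}\t{alcv:.6f}\t{members}\n")
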