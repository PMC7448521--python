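"""Flexibly shaped scan windows from variant positions in protein 3D space.

A window is a connected component of the graph whose edges join variant
pairs at Euclidean distance <= w.  Sweeping the threshold w over the sorted
unique pairwise distances yields a laminar family of at most 2m-1 windows
per structure (exactly 2m-1 when all merge events are distinct binary
merges) — equivalently the nodes of the single-linkage dendrogram.  The
per-gene window set adds one window for unmapped variants and one global
window spanning the whole gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import SpatialMap, VariantTable

__all__ = [
    "Window",
    "WindowTree",
    "WindowSet",
    "pairwise_distances",
    "enumerate_windows",
    "assemble_window_set",
    "filter_windows",
    "build_window_set",
]

STRUCTURE = "STRUCTURE"
UNMAPPED_PROV = "UNMAPPED"
GLOBAL = "GLOBAL"


@dataclass(frozen=True)
class Window:
    """A candidate test region: a set of variant indices with provenance."""

    members: frozenset
    provenance: str
    mac: int = 0
    eligible: bool = True

    def __post_init__(self):
        if not self.members:
            raise ValueError("window must be non-empty")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple:
        return tuple(sorted(self.members))


@dataclass
class WindowTree:
    """Merge tree of the threshold sweep for one structure.

    ``nodes[i]`` is the member frozenset of node i (leaves first, then merge
    nodes in creation order); ``parent[i]`` is the parent node index or -1
    for the root; ``height[i]`` is the merging distance w at which a
    non-leaf node formed (0 for leaves).
    """

    structure_id: str
    nodes: list
    parent: list
    height: list

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes if len(n) == 1)

    def edges(self) -> list[tuple[int, int]]:
        return [(p, i) for i, p in enumerate(self.parent) if p >= 0]

    def to_dot(self, labels=None) -> str:
        lines = ["digraph windows {"]
        for i, members in enumerate(self.nodes):
            lab = ",".join(
                str(labels[j]) if labels is not None else str(j)
                for j in sorted(members)
            )
            lines.append(f'  n{i} [label="{{{lab}}}"];')
        for p, c in self.edges():
            lines.append(f"  n{p} -> n{c};")
        lines.append("}")
        return "\n".join(lines)


@dataclass
class WindowSet:
    """The per-gene family of windows, with per-structure trees."""

    windows: list
    trees: dict = field(default_factory=dict)
    m: int = 0

    def __len__(self) -> int:
        return len(self.windows)

    def eligible(self) -> list:
        return [w for w in self.windows if w.eligible]

    def member_sets(self) -> set:
        return {w.members for w in self.windows}

    def to_dataframe(self, variants: VariantTable | None = None):
        import pandas as pd

        rows = []
        for k, w in enumerate(self.windows):
            ids = (
                ",".join(str(variants.variant_id[j]) for j in w.sorted_members())
                if variants is not None
                else ",".join(map(str, w.sorted_members()))
            )
            rows.append((k, w.provenance, w.mac, w.eligible, ids))
        return pd.DataFrame(
            rows, columns=["window_id", "provenance", "mac", "eligible", "members"]
        )


def pairwise_distances(smap: SpatialMap, structure_id: str) -> np.ndarray:
    """Symmetric Euclidean distance matrix among a structure's variants."""
    idx = smap.structure_indices(structure_id)
    if idx.size == 0:
        raise ValueError(f"no mapped variants on structure {structure_id!r}")
    coords = smap.coords[idx]
    if idx.size == 1:
        return np.zeros((1, 1))
    return squareform(pdist(coords))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def enumerate_windows(smap: SpatialMap, structure_id: str) -> WindowTree:
    """All distinct connected components over the threshold sweep.

    Tied distances are processed together (all equal-length edges added
    simultaneously), so a single merge event may join more than two
    components and the node count can fall below 2m-1.  The output is
    independent of variant input order and of any positive rescaling of the
    coordinates.
    """
    idx = smap.structure_indices(structure_id)
    m = idx.size
    if m == 0:
        raise ValueError(f"no mapped variants on structure {structure_id!r}")
    global_index = idx  # local k -> gene-level variant index

    nodes: list[frozenset] = [frozenset({int(global_index[k])}) for k in range(m)]
    parent = [-1] * m
    height = [0.0] * m
    if m == 1:
        return WindowTree(structure_id, nodes, parent, height)

    D = squareform(pdist(smap.coords[idx]))
    iu, ju = np.triu_indices(m, k=1)
    dists = D[iu, ju]
    order = np.argsort(dists, kind="stable")
    iu, ju, dists = iu[order], ju[order], dists[order]

    uf = _UnionFind(m)
    comp_node = {k: k for k in range(m)}  # union-find root -> tree node index
    comp_members = {k: nodes[k] for k in range(m)}

    pos = 0
    n_pairs = dists.size
    while pos < n_pairs:
        w = dists[pos]
        end = pos
        changed = False
        while end < n_pairs and dists[end] == w:
            a, b = int(iu[end]), int(ju[end])
            ra, rb = uf.find(a), uf.find(b)
            if ra != rb:
                uf.union(ra, rb)
                new_root = uf.find(ra)
                merged = comp_members[ra] | comp_members[rb]
                comp_members.pop(ra, None)
                comp_members.pop(rb, None)
                comp_members[new_root] = merged
                changed = True
            end += 1
        if changed:
            # every component that grew at this threshold becomes one node
            new_comp_node = {}
            for root, members in comp_members.items():
                if root in comp_node and comp_members[root] == nodes[comp_node[root]]:
                    new_comp_node[root] = comp_node[root]
                else:
                    node_id = len(nodes)
                    nodes.append(frozenset(members))
                    parent.append(-1)
                    height.append(float(w))
                    # children: previous nodes whose member sets are subsets
                    for old_root, old_node in comp_node.items():
                        if nodes[old_node] <= members and parent[old_node] == -1 and old_node != node_id:
                            parent[old_node] = node_id
                    new_comp_node[root] = node_id
            comp_node = new_comp_node
        pos = end

    return WindowTree(structure_id, nodes, parent, height)


def _window_mac(members: frozenset, variants: VariantTable) -> int:
    return int(variants.mac[list(members)].sum())


def assemble_window_set(
    trees: dict,
    smap: SpatialMap,
    variants: VariantTable,
) -> WindowSet:
    """Union of all per-structure tree nodes, plus one window holding all
    unmapped variants (if any) and one global window over the whole gene;
    duplicate member-sets are kept once, the global window surviving
    deduplication."""
    m = len(variants)
    if m == 0:
        raise ValueError("gene has zero variants")
    windows: list[Window] = []
    seen: set[frozenset] = set()
    all_members = frozenset(range(m))

    def add(members: frozenset, provenance: str) -> None:
        if members in seen:
            return
        seen.add(members)
        windows.append(
            Window(members=members, provenance=provenance, mac=_window_mac(members, variants))
        )

    # the global window first so it survives dedup against a spanning root
    add(all_members, GLOBAL)
    unmapped_idx = frozenset(int(i) for i in np.flatnonzero(~smap.mapped))
    if unmapped_idx and unmapped_idx != all_members:
        add(unmapped_idx, UNMAPPED_PROV)
    for sid, tree in trees.items():
        for members in tree.nodes:
            add(members, f"{STRUCTURE}({sid})")
    return WindowSet(windows=windows, trees=dict(trees), m=m)


def filter_windows(ws: WindowSet, variants: VariantTable, min_mac: int = 10) -> WindowSet:
    """Mark windows with cumulative MAC below ``min_mac`` ineligible.

    Analytic set-based p-values are unreliable with too few minor alleles,
    so such windows are excluded from testing (but retained for display).
    """
    new = [
        Window(
            members=w.members,
            provenance=w.provenance,
            mac=w.mac,
            eligible=w.mac >= min_mac,
        )
        for w in ws.windows
    ]
    out = WindowSet(windows=new, trees=ws.trees, m=ws.m)
    if not out.eligible():
        import logging

        logging.getLogger("protscan").warning(
            "all windows fall below the MAC threshold (%d); gene untestable", min_mac
        )
    return out


def build_window_set(
    smap: SpatialMap, variants: VariantTable, min_mac: int = 10
) -> WindowSet:
    """Convenience: enumerate per-structure trees, assemble, MAC-filter."""
    trees = {sid: enumerate_windows(smap, sid) for sid in smap.structures()}
    ws = assemble_window_set(trees, smap, variants)
    return filter_windows(ws, variants, min_mac=min_mac)
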