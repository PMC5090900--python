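"""Neighbor-joining tree, clade grouping and habitat composition.

The tree stage converts percent identity into a p-style distance
(d = 100 - identity, no multiple-hit correction by default), builds an
unrooted neighbor-joining tree (Saitou-Nei agglomeration, represented with
one trifurcating root node), and operationalises the visual clade grouping
of the ortholog tree: the k groups are obtained by cutting the longest
edges, preferring internal edges, keeping only cuts that actually split a
leaf-bearing component so that exactly k leaf groups result.  Habitat
composition (marine / freshwater / both / unknown) is then summarised per
group.

Negative branch lengths produced by the NJ length formulas are clamped to
zero after assignment, matching what standard tree viewers display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .identity import IdentityMatrix


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if self.values.min() < 0:
            raise ValueError("distances must be non-negative")

    def to_phylip(self, path: str | Path) -> None:
        """Write square PHYLIP distance format."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.ids)}\n")
            for rid, row in zip(self.ids, self.values):
                fh.write(rid + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path, encoding="utf-8") as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        if len(ids) != n:
            raise ValueError(f"expected {n} taxa, found {len(ids)}")
        return cls(ids=ids, values=np.array(rows))


def to_distance(identity: IdentityMatrix, correction: str = "none") -> DistanceMatrix:
    """Distance matrix from percent identity.

    ``correction="none"`` (default) gives the linear p-distance
    d = 100 - identity.  ``correction="poisson"`` applies the Poisson
    multiple-hit correction d = -100 ln(identity / 100).
    """
    if correction == "none":
        d = 100.0 - identity.values
    elif correction == "poisson":
        frac = identity.values / 100.0
        if (frac <= 0).any():
            raise ValueError("Poisson correction undefined at 0% identity")
        d = -100.0 * np.log(frac)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(identity.ids), values=d)


@dataclass
class Node:
    """Tree node; leaves carry the taxon label."""

    label: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree represented with a trifurcating (or bifurcating) root."""

    root: Node

    def leaves(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]  # type: ignore[misc]

    def edges(self) -> Iterator[tuple[int, Node, Node, float]]:
        """Preorder edges as (index, parent, child, length)."""
        index = 0
        stack = [self.root]
        while stack:
            node = stack.pop(0)
            for child, length in node.children:
                yield index, node, child, length
                index += 1
                stack.append(child)

    def path_distances(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (sums of branch lengths)."""
        # distances from every node to each leaf below it, then combine at
        # internal nodes
        labels = self.leaf_labels()
        pos = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))

        def below(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}  # type: ignore[dict-item]
            groups = []
            for child, length in node.children:
                sub = below(child)
                groups.append({lab: d + length for lab, d in sub.items()})
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for la, da in groups[i].items():
                        for lb, db in groups[j].items():
                            dist[pos[la], pos[lb]] = dist[pos[lb], pos[la]] = da + db
            merged: dict[str, float] = {}
            for g in groups:
                merged.update(g)
            return merged

        below(self.root)
        return labels, dist

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions induced by internal edges.

        Each split is recorded as the frozenset of leaf labels on the child
        side; the complementary side is implied.
        """
        all_leaves = frozenset(self.leaf_labels())
        out: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])  # type: ignore[list-item]
            labels: set[str] = set()
            for child, _ in node.children:
                sub = walk(child)
                if not child.is_leaf and 1 < len(sub) < len(all_leaves) - 1:
                    out.add(min(sub, all_leaves - sub, key=sorted))
                labels |= sub
            return frozenset(labels)

        walk(self.root)
        return out


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    For 2 taxa the single edge of length d is split equally.  Co-minimal
    Q entries are broken toward the lexicographically smallest index pair,
    so output is deterministic.  Negative branch lengths are clamped to 0.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[Node] = [Node(label=rid) for rid in d.ids]
    dist = d.values.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        return max(0.0, float(x))

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, m, m)
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        ai, aj = active[i], active[j]
        new = Node(children=[(nodes[ai], clamp(li)), (nodes[aj], clamp(lj))])
        # distances from the new node to every remaining taxon
        new_row = np.zeros(dist.shape[0] + 1)
        for pos, k in enumerate(active):
            if k in (ai, aj):
                continue
            new_row[k] = 0.5 * (dist[ai, k] + dist[aj, k] - dij)
        new_row = np.clip(new_row, 0.0, None)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (ai, aj)] + [len(nodes) - 1]

    if len(active) == 2:
        a, b = active
        half = clamp(dist[a, b] / 2.0)
        root = Node(children=[(nodes[a], half), (nodes[b], half)])
    else:
        a, b, c = active
        la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
        lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
        lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
        root = Node(
            children=[
                (nodes[a], clamp(la)),
                (nodes[b], clamp(lb)),
                (nodes[c], clamp(lc)),
            ]
        )
    return Tree(root=root)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Newick string with branch lengths; labels needing it are quoted."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return _quote_label(node.label or "")
        inner = ",".join(f"{fmt(child)}:{length:.10g}" for child, length in node.children)
        return f"({inner})"

    return fmt(tree.root) + ";"


@dataclass
class CladeGrouping:
    """Assignment of every leaf id to exactly one group label."""

    assignment: dict[str, str]

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid, label in self.assignment.items():
            out.setdefault(label, []).append(rid)
        return out

    @property
    def counts(self) -> dict[str, int]:
        return {label: len(members) for label, members in self.groups.items()}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tgroup\n")
            for rid, label in self.assignment.items():
                fh.write(f"{rid}\t{label}\n")


def clade_groups(tree: Tree, k: int) -> CladeGrouping:
    """Partition leaves into k groups by longest-edge cuts.

    Candidate edges are ranked internal-first, by decreasing length with
    ties broken by preorder edge index; a cut is applied only if it splits
    a component that still holds leaves on both sides, so exactly k
    leaf-bearing groups result for any 1 <= k <= leaf count.
    """
    leaves = tree.leaves()
    n = len(leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")

    edges = list(tree.edges())
    internal = [(idx, p, c, ln) for idx, p, c, ln in edges if not c.is_leaf]
    pendant = [(idx, p, c, ln) for idx, p, c, ln in edges if c.is_leaf]
    ranked = sorted(internal, key=lambda e: (-e[3], e[0])) + sorted(
        pendant, key=lambda e: (-e[3], e[0])
    )

    # union-find over node ids; cutting an edge = not unioning it
    cut: set[int] = set()

    def components() -> dict[int, set[str]]:
        parent: dict[int, int] = {}

        def find(x: int) -> int:
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for idx, p, c, _ in edges:
            if idx in cut:
                continue
            parent[find(id(p))] = find(id(c))
        comps: dict[int, set[str]] = {}
        for leaf in leaves:
            comps.setdefault(find(id(leaf)), set()).add(leaf.label)  # type: ignore[arg-type]
        return comps

    n_groups = 1
    for idx, _, _, _ in ranked:
        if n_groups == k:
            break
        cut.add(idx)
        comps = components()
        if len(comps) > n_groups:
            n_groups = len(comps)
        else:
            cut.remove(idx)  # cut did not separate leaves

    comps = components()
    # stable group labels: order components by first leaf in tree order
    order: dict[int, int] = {}
    comp_of_leaf = {}
    for root_id, members in comps.items():
        for leaf in leaves:
            if leaf.label in members:
                comp_of_leaf[leaf.label] = root_id
    for leaf in leaves:
        root_id = comp_of_leaf[leaf.label]
        if root_id not in order:
            order[root_id] = len(order) + 1
    assignment = {
        leaf.label: f"group{order[comp_of_leaf[leaf.label]]}" for leaf in leaves
    }
    return CladeGrouping(assignment=assignment)


@dataclass
class HabitatSummary:
    """Per-group habitat counts and fractions.

    ``fractions`` are over habitat-labelled leaves (``unknown`` excluded);
    with ``exclude_both`` the ``both`` category is also excluded from the
    marine/freshwater denominator and reported only as a count.
    """

    counts: dict[str, dict[str, int]]
    fractions: dict[str, dict[str, float]]

    def to_tsv(self, path: str | Path) -> None:
        habitats = ("marine", "freshwater", "both", "unknown")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "group\t"
                + "\t".join(f"n_{h}" for h in habitats)
                + "\t"
                + "\t".join(f"frac_{h}" for h in habitats if h != "unknown")
                + "\n"
            )
            for group in sorted(self.counts):
                cnt = self.counts[group]
                frc = self.fractions[group]
                fh.write(
                    group
                    + "\t"
                    + "\t".join(str(cnt.get(h, 0)) for h in habitats)
                    + "\t"
                    + "\t".join(
                        f"{frc.get(h, float('nan')):.6g}"
                        for h in habitats
                        if h != "unknown"
                    )
                    + "\n"
                )


def habitat_summary(
    grouping: CladeGrouping,
    habitats: dict[str, str],
    exclude_both: bool = False,
) -> HabitatSummary:
    """Habitat composition of each clade group."""
    counts: dict[str, dict[str, int]] = {}
    fractions: dict[str, dict[str, float]] = {}
    for label, members in grouping.groups.items():
        cnt = {"marine": 0, "freshwater": 0, "both": 0, "unknown": 0}
        for rid in members:
            cnt[habitats.get(rid, "unknown")] += 1
        counts[label] = cnt
        cats = ("marine", "freshwater") if exclude_both else ("marine", "freshwater", "both")
        denom = sum(cnt[c] for c in cats)
        fractions[label] = {
            c: (cnt[c] / denom if denom else float("nan")) for c in cats
        }
    return HabitatSummary(counts=counts, fractions=fractions)
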