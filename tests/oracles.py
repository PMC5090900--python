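"""Independent brute-force oracles used by the unit and acceptance tests.

Nothing here calls the package's own alignment or tree code: alignment
scores come from explicit enumeration of all monotone alignments, and
additive distance matrices come from a stand-alone random-tree generator
with its own path-length and split computation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_align_score(
    a: str, b: str, open_cost: float = 11.0, ext_cost: float = 1.0
) -> float:
    """Maximum global affine-gap score by recursive enumeration.

    A gap of length k costs open + k*ext; every monotone path (including
    ones with adjacent insertion/deletion runs) is visited.
    """
    best = -math.inf

    def rec(i: int, j: int, score: float, last: str | None) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "M")
        if i < len(a):
            cost = ext_cost if last == "X" else open_cost + ext_cost
            rec(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = ext_cost if last == "Y" else open_cost + ext_cost
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, None)
    return best


def _op_sequences(m: int, n: int):
    """All op strings (M=match col, X=gap in b, Y=gap in a) from (0,0) to (m,n)."""
    out = []

    def rec(i: int, j: int, ops: list[str]) -> None:
        if i == m and j == n:
            out.append("".join(ops))
            return
        if i < m and j < n:
            rec(i + 1, j + 1, ops + ["M"])
        if i < m:
            rec(i + 1, j, ops + ["X"])
        if j < n:
            rec(i, j + 1, ops + ["Y"])

    rec(0, 0, [])
    return out


def _gap_cost(ops: str, open_cost: float, ext_cost: float) -> float:
    cost = 0.0
    for op, run in itertools.groupby(ops):
        if op in "XY":
            cost += open_cost + ext_cost * len(list(run))
    return cost


def exhaustive_score_table(
    alphabet: str, m: int, n: int, open_cost: float = 11.0, ext_cost: float = 1.0
) -> tuple[list[str], list[str], np.ndarray]:
    """Best alignment scores for *all* sequence pairs of lengths (m, n).

    Enumerates every alignment shape once, then scores all letter
    combinations vectorised.  Returns (seqs_a, seqs_b, score matrix).
    """
    letters = list(alphabet)
    sub = np.array([[BLOSUM62[x, y] for y in letters] for x in letters], dtype=float)
    seqs_a = ["".join(t) for t in itertools.product(letters, repeat=m)]
    seqs_b = ["".join(t) for t in itertools.product(letters, repeat=n)]
    enc_a = np.array(
        [[letters.index(ch) for ch in s] for s in seqs_a], dtype=int
    ).reshape(len(seqs_a), m)
    enc_b = np.array(
        [[letters.index(ch) for ch in s] for s in seqs_b], dtype=int
    ).reshape(len(seqs_b), n)
    best = np.full((len(seqs_a), len(seqs_b)), -np.inf)
    for ops in _op_sequences(m, n):
        gap = _gap_cost(ops, open_cost, ext_cost)
        score = np.full_like(best, -gap)
        i = j = 0
        for op in ops:
            if op == "M":
                score += sub[enc_a[:, i][:, None], enc_b[:, j][None, :]]
                i += 1
                j += 1
            elif op == "X":
                i += 1
            else:
                j += 1
        np.maximum(best, score, out=best)
    return seqs_a, seqs_b, best


# ---------------------------------------------------------------------------
# random additive trees (independent graph representation)


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator, min_len: float = 0.5, max_len: float = 5.0
):
    """Random unrooted binary tree; returns (labels, distance matrix, splits).

    Built by sequential leaf attachment on a plain adjacency dict; path
    lengths by breadth-first search; splits by removing internal edges.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    adj: dict[int, dict[int, float]] = {}
    next_node = n_taxa

    def add_edge(u: int, v: int, w: float) -> None:
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def drop_edge(u: int, v: int) -> None:
        del adj[u][v]
        del adj[v][u]

    center = next_node
    next_node += 1
    for leaf in range(min(3, n_taxa)):
        add_edge(leaf, center, float(rng.uniform(min_len, max_len)))
    for leaf in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        w = adj[u][v]
        mid, nn = next_node, next_node + 1
        next_node = nn + 1
        split = float(rng.uniform(0.25, 0.75))
        drop_edge(u, v)
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(leaf, mid, float(rng.uniform(min_len, max_len)))

    def distances_from(src: int) -> dict[int, float]:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node].items():
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    stack.append(nb)
        return dist

    matrix = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        d = distances_from(i)
        for j in range(n_taxa):
            matrix[i, j] = d[j]

    all_leaves = frozenset(labels)
    splits: set[frozenset[str]] = set()
    internal_edges = [
        (u, v) for u in adj for v in adj[u] if u < v and u >= n_taxa and v >= n_taxa
    ]
    for u, v in internal_edges:
        seen = {u}
        stack = [u]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb == v and node == u:
                    continue
                if (node, nb) == (u, v) or (node, nb) == (v, u):
                    continue
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(labels[x] for x in seen if x < n_taxa)
        if 1 < len(side) < n_taxa - 1:
            splits.add(min(side, all_leaves - side, key=sorted))
    return labels, matrix, splits


def three_point_lengths(dab: float, dac: float, dbc: float) -> tuple[float, float, float]:
    """Closed-form pendant lengths for three taxa."""
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    return la, lb, lc


def quartet_topology(d: np.ndarray) -> frozenset[str]:
    """Best 4-taxon split by four-point sums on labels a,b,c,d (indices 0-3).

    Returns the pair grouped together on the shortest-sum side.
    """
    sums = {
        frozenset(["a", "b"]): d[0, 1] + d[2, 3],
        frozenset(["a", "c"]): d[0, 2] + d[1, 3],
        frozenset(["a", "d"]): d[0, 3] + d[1, 2],
    }
    return min(sums, key=lambda k: sums[k])


def strict_column_oracle(
    rows: list[tuple[str, str]], ingroup_ids: set[str], max_outgroup_matches: int = 0
) -> list[int]:
    """Per-column brute-force re-check of the strict criterion (0-based cols)."""
    width = len(rows[0][1])
    hits = []
    for col in range(width):
        in_letters = {row[col] for rid, row in rows if rid in ingroup_ids}
        out_letters = [row[col] for rid, row in rows if rid not in ingroup_ids]
        if len(in_letters) != 1:
            continue
        r = next(iter(in_letters))
        if r in ("-", "X"):
            continue
        if out_letters.count(r) > max_outgroup_matches:
            continue
        hits.append(col)
    return hits
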