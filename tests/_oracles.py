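"""Independent brute-force oracles the tests compare the package against.

Everything here is written from first principles (exhaustive enumeration,
dense linear algebra, quadratic scans) and deliberately shares no code
with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


# -- ontology ---------------------------------------------------------------

def brute_ancestors(parent_edges: set[tuple[str, str]], term: str) -> set[str]:
    """Reflexive ancestor set by naive repeated expansion."""
    out = {term}
    changed = True
    while changed:
        changed = False
        for child, parent in parent_edges:
            if child in out and parent not in out:
                out.add(parent)
                changed = True
    return out


def brute_closure(
    parent_edges: set[tuple[str, str]], pairs: set[tuple[str, str]]
) -> set[tuple[str, str]]:
    """Ancestor closure of (term, target) annotation pairs."""
    out = set()
    for term, target in pairs:
        for anc in brute_ancestors(parent_edges, term):
            out.add((anc, target))
    return out


def brute_ic(
    parent_edges: set[tuple[str, str]], pairs: set[tuple[str, str]], term: str
) -> float | None:
    closed = brute_closure(parent_edges, pairs)
    targets = {n for _, n in pairs}
    n_term = len({n for t, n in closed if t == term})
    if n_term == 0:
        return None
    return -math.log(n_term / len(targets))


def brute_mica_ic(
    parent_edges: set[tuple[str, str]],
    pairs: set[tuple[str, str]],
    x: str,
    y: str,
) -> float:
    """IC of the most informative common ancestor; 0 when none informative."""
    common = brute_ancestors(parent_edges, x) & brute_ancestors(parent_edges, y)
    best = 0.0
    for c in common:
        ic = brute_ic(parent_edges, pairs, c)
        if ic is not None:
            best = max(best, ic)
    return best


def brute_set_similarity(
    parent_edges: set[tuple[str, str]],
    pairs: set[tuple[str, str]],
    X: list[str],
    Y: list[str],
) -> float:
    if not X or not Y:
        return 0.0
    total = 0.0
    for x in X:
        total += max(brute_mica_ic(parent_edges, pairs, x, y) for y in Y)
    return total / len(X)


# -- graphs -----------------------------------------------------------------

def floyd_warshall(nodes: list[str], dist_edges: dict[tuple[str, str], float]) -> np.ndarray:
    """All-pairs shortest paths by the classic triple loop."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for (a, b), d in dist_edges.items():
        i, j = idx[a], idx[b]
        D[i, j] = min(D[i, j], d)
        D[j, i] = min(D[j, i], d)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def restart_walk_solve(
    nodes: list[str],
    weight_edges: dict[tuple[str, str], float],
    query: str,
    alpha: float,
) -> dict[str, float]:
    """Closed-form stationary distribution of the restart walk:
    p = alpha * (I - (1 - alpha) P^T)^(-1) r, solved densely."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for (a, b), w in weight_edges.items():
        W[idx[a], idx[b]] = w
        W[idx[b], idx[a]] = w
    rs = W.sum(axis=1, keepdims=True)
    P = np.divide(W, rs, out=np.zeros_like(W), where=rs > 0)
    r = np.zeros(n)
    r[idx[query]] = 1.0
    p = alpha * np.linalg.solve(np.eye(n) - (1 - alpha) * P.T, r)
    return {nodes[i]: float(p[i]) for i in range(n)}


# -- intervals --------------------------------------------------------------

def quadratic_gene_overlap(
    cnv: tuple[str, int, int], genes: list[tuple[str, int, int, str]]
) -> list[str]:
    chrom, start, end = cnv
    hits = [
        (gs, ge, g)
        for gc, gs, ge, g in genes
        if gc == chrom and gs < end and start < ge
    ]
    return [g for _, _, g in sorted(hits)]


def sweep_merge(regions: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not regions:
        return []
    pts = sorted(regions)
    out = [list(pts[0])]
    for s, e in pts[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def covered_bases(regions: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in sweep_merge(regions))


def quadratic_dgv(
    cnv: tuple[str, int, int],
    merged_by_study: dict[str, dict[str, list[tuple[int, int]]]],
    threshold: float = 0.5,
) -> float:
    chrom, start, end = cnv
    length = end - start
    total = 0.0
    for study in merged_by_study.values():
        for s, e in study.get(chrom, []):
            ov = min(e, end) - max(s, start)
            if ov > 0 and ov >= threshold * length:
                total += ov / length
    return total


# -- metrics ----------------------------------------------------------------

def count_metrics(pred: list[bool], lab: list[bool]) -> tuple[float, float, float]:
    tp = sum(p and l for p, l in zip(pred, lab))
    fp = sum(p and not l for p, l in zip(pred, lab))
    fn = sum(l and not p for p, l in zip(pred, lab))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f
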