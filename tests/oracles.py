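"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, separately
from the package implementation: plain recursion for alignment scores,
all-pairs distance scans for interfaces, Monte-Carlo integration for
surface areas, exhaustive enumeration for rank tests and triangles, and
generic numerical optimisation for superposition.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_alignment_score(a: str, b: str, gap: float = -12.0) -> float:
    """Optimal global alignment score by exhaustive recursion (linear gap)."""

    @lru_cache(maxsize=None)
    def rec(x: str, y: str) -> float:
        if not x and not y:
            return 0.0
        best = -np.inf
        if x and y:
            best = max(best, _BLOSUM62[x[0], y[0]] + rec(x[1:], y[1:]))
        if x:
            best = max(best, gap + rec(x[1:], y))
        if y:
            best = max(best, gap + rec(x, y[1:]))
        return best

    return float(rec(a, b))


def brute_force_interface(chain_atoms: dict, cutoff: float) -> set:
    """All-pairs heavy-atom distance scan (full dense distance matrix).

    ``chain_atoms`` maps chain id -> list of ((chain, resseq), xyz).
    Returns the interface residue set."""
    out = set()
    chains = sorted(chain_atoms)
    for ca, cb in combinations(chains, 2):
        keys_a = [k for k, _ in chain_atoms[ca]]
        keys_b = [k for k, _ in chain_atoms[cb]]
        xa = np.asarray([x for _, x in chain_atoms[ca]], dtype=float)
        xb = np.asarray([x for _, x in chain_atoms[cb]], dtype=float)
        dist = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
        ia, ib = np.nonzero(dist <= cutoff)
        out.update(keys_a[i] for i in ia)
        out.update(keys_b[j] for j in ib)
    return out


def monte_carlo_sasa(centers, radii, probe: float, n_samples: int = 20000,
                     seed: int = 0) -> np.ndarray:
    """Per-atom SASA by uniform sampling on each expanded sphere."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, float)
    expanded = np.asarray(radii, float) + probe
    areas = np.empty(len(centers))
    for i, (c, r) in enumerate(zip(centers, expanded)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = c + r * v
        free = np.ones(n_samples, dtype=bool)
        for j, (cj, rj) in enumerate(zip(centers, expanded)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - cj, axis=1) >= rj
        areas[i] = 4.0 * np.pi * r * r * free.mean()
    return areas


def exact_mann_whitney_p(a, b, alternative: str = "greater") -> float:
    """Exact one-sided p by enumerating all group assignments (midranks)."""
    a, b = list(map(float, a)), list(map(float, b))
    pooled = np.array(a + b)
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    k = 0
    while k < len(pooled):
        m = k
        while m + 1 < len(pooled) and sorted_vals[m + 1] == sorted_vals[k]:
            m += 1
        ranks[order[k : m + 1]] = (k + m) / 2.0 + 1.0
        k = m + 1

    n1 = len(a)

    def u_of(idx: tuple) -> float:
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(tuple(range(n1)))
    if alternative == "less":
        u_obs = len(a) * len(b) - u_obs  # mirror
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = u_of(idx)
        if alternative == "less":
            u = len(a) * len(b) - u
        total += 1
        if u >= u_obs:
            count += 1
    return count / total


def brute_force_mimicry_triangles(human_loops, viral_loops, edges,
                                  similarities, threshold: float):
    """O(|H| * |V| * |X|) enumeration of shared-interactor mimicry hits.

    ``edges`` is an iterable of accession pairs; ``similarities`` maps
    (human accession, viral accession) -> similarity.  Returns the set of
    (human accession, viral accession, frozenset of shared interactors).
    """
    edge_set = {frozenset(e) for e in edges}
    nodes = {n for e in edge_set for n in e}

    def linked(x, y):
        return frozenset((x, y)) in edge_set

    hits = set()
    for h in human_loops:
        for v in viral_loops:
            sim = similarities.get((h, v))
            if sim is None or sim <= threshold:
                continue
            shared = frozenset(
                x for x in nodes if x not in (h, v) and linked(h, x) and linked(v, x)
            )
            if shared:
                hits.add((h, v, shared))
    return hits


def numeric_superposition_rmsd(x: np.ndarray, y: np.ndarray,
                               n_starts: int = 12, seed: int = 0) -> float:
    """Best RMSD over rigid transforms found by generic optimisation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)

    def cost(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        moved = x @ rot.T + params[3:]
        return np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1)))

    best = np.inf
    for _ in range(n_starts):
        p0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.normal(0, 5, 3)])
        res = minimize(cost, p0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)


def direct_js_score(column_residues, background: np.ndarray, aa_order: str,
                    n_rows: int) -> float:
    """Direct evaluation of the gap-weighted base-2 JS conservation score."""
    counts = np.zeros(len(aa_order))
    for ch in column_residues:
        if ch in aa_order:
            counts[aa_order.index(ch)] += 1
    n_valid = counts.sum()
    if n_valid == 0:
        return 0.0
    p = counts / n_valid
    q = np.asarray(background, float)
    m = 0.5 * (p + q)
    js = 0.0
    for k in range(len(aa_order)):
        if p[k] > 0:
            js += 0.5 * p[k] * np.log2(p[k] / m[k])
        if q[k] > 0:
            js += 0.5 * q[k] * np.log2(q[k] / m[k])
    return js * (n_valid / n_rows)
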