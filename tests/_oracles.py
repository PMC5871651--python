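"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import itertools

import numpy as np


def oracle_relatedness(parents: dict[str, tuple[str | None, str | None]],
                       a: str, b: str) -> float:
    """Path-counting relatedness over ancestors up to grandparents.

    Enumerates ancestor descriptors (ancestor, depth, nodes-on-route)
    by explicit case analysis rather than chain recursion, and sums
    (1/2)^(da+db) over matching ancestors whose routes meet only there.
    """

    def ancestors(x: str) -> list[tuple[str, int, frozenset[str]]]:
        out = [(x, 0, frozenset([x]))]
        mo_fa = parents.get(x, (None, None))
        for p in mo_fa:
            if p is None:
                continue
            out.append((p, 1, frozenset([x, p])))
            for g in parents.get(p, (None, None)):
                if g is not None:
                    out.append((g, 2, frozenset([x, p, g])))
        return out

    if a == b:
        return 1.0
    total = 0.0
    for ca, da, route_a in ancestors(a):
        for cb, db, route_b in ancestors(b):
            if ca == cb and route_a & route_b == {ca}:
                total += 0.5 ** (da + db)
    return total


def oracle_anosim_R(D: np.ndarray, labels: np.ndarray) -> float:
    """ANOSIM R by explicit pair listing and counting-based average ranks."""
    n = D.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dists = [D[i, j] for i, j in pairs]
    ranks = []
    for d in dists:
        less = sum(1 for e in dists if e < d)
        equal = sum(1 for e in dists if e == d)
        ranks.append(less + (equal + 1) / 2.0)
    within = [labels[i] == labels[j] for i, j in pairs]
    rw = np.mean([r for r, w in zip(ranks, within) if w])
    rb = np.mean([r for r, w in zip(ranks, within) if not w])
    M = len(pairs)
    return (rb - rw) / (M / 2.0)


def exhaustive_blocked_p(D: np.ndarray, block_of: list[int],
                         block_labels: list[str]) -> float:
    """Exact upper p of blocked ANOSIM by enumerating distinct assignments."""
    labels0 = np.array([block_labels[b] for b in block_of])
    R_obs = oracle_anosim_R(D, labels0)
    stats = []
    for assign in set(itertools.permutations(block_labels)):
        lab = np.array([assign[b] for b in block_of])
        stats.append(oracle_anosim_R(D, lab))
    stats = np.asarray(stats)
    return float(np.mean(stats >= R_obs - 1e-12))
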