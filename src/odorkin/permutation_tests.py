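"""Rank-based similarity tests with repeated-measures permutation nulls.

ANOSIM contrasts between-group versus within-group dissimilarity ranks:
with all M = n(n-1)/2 pairwise dissimilarities ranked (average ranks for
ties), R = (mean rank between - mean rank within) / (M/2), which lies in
[-1, 1] and is 0 in expectation under exchangeability.

Because individuals contribute repeated samples, samples are not
exchangeable: the permutation null instead shuffles labels at the block
(individual) level, keeping every individual's samples together. The
multiset of block labels is preserved under each draw; each sample
inherits its block's new label. Free (sample-level) permutation is
available for comparison and is anticonservative on blocked data.

The kin ANOSIM compares sample pairs of half-sibling dyads of one
parental line ("within") against sample pairs of distantly related or
unrelated dyads ("between"), excluding same-individual pairs, pairs of
the other half-sib line, and close-kin pairs. Its null permutes sibship
membership across individuals, preserving the sibship-size multiset.

All p-values are one-sided upper with the +1 small-sample correction:
p = (1 + #{permuted stat >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr, rankdata

from .dissimilarity import DissimilarityMatrix
from .pedigree import (
    DISTANT,
    MATERNAL_HALF_SIB,
    PATERNAL_HALF_SIB,
    UNRELATED,
    DyadKinship,
)

__all__ = [
    "BlockedLabels",
    "AnosimResult",
    "MantelResult",
    "anosim_statistic",
    "blocked_permutation",
    "anosim_test",
    "kin_anosim",
    "mantel_test",
]


@dataclass
class BlockedLabels:
    """Group labels tied to exchangeable blocks (individuals)."""

    sample_ids: list[str]
    block_of: dict[str, str]  # sample -> block
    label_of: dict[str, str]  # block -> group label

    def __post_init__(self) -> None:
        missing = [s for s in self.sample_ids if s not in self.block_of]
        if missing:
            raise ValueError(f"samples without block: {missing}")
        blocks = {self.block_of[s] for s in self.sample_ids}
        unlabeled = sorted(b for b in blocks if b not in self.label_of)
        if unlabeled:
            raise ValueError(f"blocks without label: {unlabeled}")
        if len({self.label_of[b] for b in blocks}) < 2:
            raise ValueError("need at least two distinct group labels")

    def sample_labels(self) -> np.ndarray:
        return np.asarray([self.label_of[self.block_of[s]] for s in self.sample_ids])

    def blocks(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            b = self.block_of[s]
            if b not in seen:
                seen.append(b)
        return seen


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int
    scheme: str
    seed: int | None
    n_within: int
    n_between: int
    degenerate_ties: bool = False
    null_R: np.ndarray | None = field(default=None, repr=False)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    alternative: str = "greater"


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _anosim_R_from_ranks(ranks: np.ndarray, within: np.ndarray) -> float:
    M = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (M / 2.0)


def anosim_statistic(D: DissimilarityMatrix, labels: BlockedLabels) -> float:
    """ANOSIM R for the observed labeling (no test)."""
    if list(labels.sample_ids) != list(D.ids):
        raise ValueError("label sample order must match distance matrix ids")
    lab = labels.sample_labels()
    uniq, counts = np.unique(lab, return_counts=True)
    thin = uniq[counts < 2].tolist()
    if thin:
        raise ValueError(f"labels with fewer than two samples have no within-pairs: {thin}")
    iu, ju = _pair_index(len(D.ids))
    ranks = rankdata(D.condensed())
    within = lab[iu] == lab[ju]
    return _anosim_R_from_ranks(ranks, within)


def blocked_permutation(labels: BlockedLabels, rng: np.random.Generator) -> BlockedLabels:
    """One draw of the repeated-measures null: shuffle labels over blocks."""
    blocks = labels.blocks()
    pool = [labels.label_of[b] for b in blocks]
    perm = rng.permutation(len(pool))
    new_label_of = dict(labels.label_of)
    for b, k in zip(blocks, perm):
        new_label_of[b] = pool[k]
    return BlockedLabels(labels.sample_ids, labels.block_of, new_label_of)


def anosim_test(
    D: DissimilarityMatrix,
    labels: BlockedLabels,
    n_perm: int = 999,
    seed: int | None = None,
    scheme: str = "blocked_individual",
) -> AnosimResult:
    """ANOSIM with a blocked (default) or free permutation null."""
    if scheme not in ("blocked_individual", "free"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    lab = labels.sample_labels()
    uniq, counts = np.unique(lab, return_counts=True)
    thin = uniq[counts < 2].tolist()
    if thin:
        raise ValueError(f"labels with fewer than two samples have no within-pairs: {thin}")

    n = len(D.ids)
    iu, ju = _pair_index(n)
    cond = D.condensed()
    ranks = rankdata(cond)
    degenerate = bool(np.ptp(cond) == 0)
    within = lab[iu] == lab[ju]
    R_obs = 0.0 if degenerate else _anosim_R_from_ranks(ranks, within)

    rng = np.random.default_rng(seed)
    blocks = labels.blocks()
    block_idx = np.asarray([blocks.index(labels.block_of[s]) for s in labels.sample_ids])
    block_labels = np.asarray([labels.label_of[b] for b in blocks])

    null = np.empty(n_perm)
    for t in range(n_perm):
        if scheme == "blocked_individual":
            permuted = block_labels[rng.permutation(len(blocks))][block_idx]
        else:
            permuted = lab[rng.permutation(n)]
        w = permuted[iu] == permuted[ju]
        null[t] = _anosim_R_from_ranks(ranks, w)
    p = (1.0 + np.count_nonzero(null >= R_obs)) / (1.0 + n_perm)
    return AnosimResult(
        R=float(R_obs), p=float(p), n_perm=n_perm, scheme=scheme, seed=seed,
        n_within=int(within.sum()), n_between=int((~within).sum()),
        degenerate_ties=degenerate, null_R=null,
    )


def _sibship_components(dyads: list[DyadKinship], line: str) -> dict[str, int]:
    """Connected components of half-sib dyads of one line -> component id."""
    want = MATERNAL_HALF_SIB if line == "maternal" else PATERNAL_HALF_SIB
    adj: dict[str, set[str]] = {}
    for d in dyads:
        if d.category == want:
            adj.setdefault(d.id_a, set()).add(d.id_b)
            adj.setdefault(d.id_b, set()).add(d.id_a)
    comp_of: dict[str, int] = {}
    cid = 0
    for start in sorted(adj):
        if start in comp_of:
            continue
        stack = [start]
        comp_of[start] = cid
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp_of:
                    comp_of[v] = cid
                    stack.append(v)
        cid += 1
    return comp_of


def kin_anosim(
    D: DissimilarityMatrix,
    dyads: list[DyadKinship],
    sample_map,
    line: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Half-sib versus distant/unrelated ANOSIM for one parental line.

    `sample_map` maps sample id -> individual id for every id in D.
    """
    if line not in ("maternal", "paternal"):
        raise ValueError("line must be 'maternal' or 'paternal'")
    want = MATERNAL_HALF_SIB if line == "maternal" else PATERNAL_HALF_SIB

    inds = [sample_map[s] for s in D.ids]
    uniq_inds = sorted(set(inds))
    ind_pos = {ind: k for k, ind in enumerate(uniq_inds)}
    n_ind = len(uniq_inds)
    cat = np.full((n_ind, n_ind), "", dtype=object)
    for d in dyads:
        if d.id_a in ind_pos and d.id_b in ind_pos:
            a, b = ind_pos[d.id_a], ind_pos[d.id_b]
            cat[a, b] = cat[b, a] = d.category

    comp_of = _sibship_components(dyads, line)
    sib0 = np.full(n_ind, -1, dtype=int)  # -1 = singleton
    for ind, c in comp_of.items():
        if ind in ind_pos:
            sib0[ind_pos[ind]] = c
    if not np.any(sib0 >= 0):
        raise ValueError(f"no {line} half-sib dyads among the sampled individuals")

    n = len(D.ids)
    iu, ju = _pair_index(n)
    ind_idx = np.asarray([ind_pos[i] for i in inds])
    a_idx, b_idx = ind_idx[iu], ind_idx[ju]
    cross = a_idx != b_idx
    pair_cat = cat[a_idx, b_idx]
    # pairs excluded regardless of permuted sibships: same individual,
    # other-line half-sibs, close kin, or unclassified
    eligible = cross & np.isin(pair_cat, [want, DISTANT, UNRELATED])
    if not eligible.any():
        raise ValueError("no eligible sample pairs for kin ANOSIM")

    cond = D.condensed()[eligible]
    ranks = rankdata(cond)
    degenerate = bool(np.ptp(cond) == 0)
    a_e, b_e = a_idx[eligible], b_idx[eligible]

    def stat(sib: np.ndarray) -> float | None:
        within = (sib[a_e] >= 0) & (sib[a_e] == sib[b_e])
        if not within.any() or within.all():
            return None
        return _anosim_R_from_ranks(ranks, within)

    within0 = (sib0[a_e] >= 0) & (sib0[a_e] == sib0[b_e])
    if not within0.any():
        raise ValueError(f"no within-pairs: sampled {line} half-sib dyads share no samples")
    if within0.all():
        raise ValueError("no between-pairs: every eligible pair is a half-sib pair")
    R_obs = 0.0 if degenerate else _anosim_R_from_ranks(ranks, within0)

    rng = np.random.default_rng(seed)
    null = []
    draws = 0
    while len(null) < n_perm and draws < 50 * n_perm:
        draws += 1
        sib = sib0[rng.permutation(n_ind)]
        s = stat(sib)
        if s is not None:
            null.append(s)
    null = np.asarray(null)
    p = (1.0 + np.count_nonzero(null >= R_obs)) / (1.0 + len(null))
    return AnosimResult(
        R=float(R_obs), p=float(p), n_perm=int(len(null)),
        scheme=f"blocked_sibship_{line}", seed=seed,
        n_within=int(within0.sum()), n_between=int((~within0).sum()),
        degenerate_ties=degenerate, null_R=null,
    )


def mantel_test(
    D1: DissimilarityMatrix,
    D2: DissimilarityMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices over the same ids.

    r is the Pearson correlation of the upper-triangle vectors; the null
    relabels D2's rows and columns simultaneously.
    """
    if list(D1.ids) != list(D2.ids):
        raise ValueError("distance matrices must share ids in the same order")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    n = len(D1.ids)
    iu, ju = _pair_index(n)
    v1 = D1.values[iu, ju]
    v2 = D2.values[iu, ju]
    for name, v in (("D1", v1), ("D2", v2)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} has a constant off-diagonal: correlation undefined")
    r_obs = float(pearsonr(v1, v2).statistic)

    rng = np.random.default_rng(seed)
    # center/scale once; permuted correlations via dot products
    z1 = (v1 - v1.mean()) / v1.std()
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        pv2 = D2.values[np.ix_(perm, perm)][iu, ju]
        z2 = (pv2 - pv2.mean()) / pv2.std()
        null[t] = float(np.dot(z1, z2) / z1.size)
    if alternative == "greater":
        p = (1.0 + np.count_nonzero(null >= r_obs)) / (1.0 + n_perm)
    else:
        p = (1.0 + np.count_nonzero(np.abs(null) >= abs(r_obs))) / (1.0 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed, alternative=alternative)
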