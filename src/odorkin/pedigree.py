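"""Pedigree handling and kin-category classification.

Relatedness is computed by path counting on a pedigree truncated at the
grandparental generation: only parents and grandparents contribute
connecting paths, and deeper known ancestry is deliberately ignored.
This matches the operational definition used in studies where pedigree
depth is uneven across individuals — two individuals are called
unrelated when they share no ancestor up to and including their
grandparents.

Unknown (missing) parents are treated as unique, mutually unrelated
founders: they contribute no connecting paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "PedigreeTable",
    "DyadKinship",
    "relatedness",
    "classify_dyads",
    "sibship_blocks",
    "MATERNAL_HALF_SIB",
    "PATERNAL_HALF_SIB",
    "DISTANT",
    "UNRELATED",
    "EXCLUDED_CLOSE",
]

MATERNAL_HALF_SIB = "maternal_half_sib"
PATERNAL_HALF_SIB = "paternal_half_sib"
DISTANT = "distant"
UNRELATED = "unrelated"
EXCLUDED_CLOSE = "excluded_close"


class PedigreeError(ValueError):
    """Raised for malformed pedigrees or unknown individuals."""


@dataclass(frozen=True)
class DyadKinship:
    """Kin classification of one unordered pair of individuals."""

    id_a: str
    id_b: str
    r: float
    category: str
    self_dyad: bool = False


@dataclass
class PedigreeTable:
    """Parent links for a set of individuals.

    Parameters
    ----------
    records : mapping individual_id -> (mother_id | None, father_id | None)
        Missing parents are ``None`` and act as unique unrelated founders.
        Parents that are not themselves listed as individuals are allowed
        (unprofiled founders).
    """

    parents: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind, (mo, fa) in self.parents.items():
            if ind in (mo, fa):
                raise PedigreeError(f"individual {ind!r} is its own parent")
        # no individual may be its own grandparent
        for ind in self.parents:
            if ind in self._grandparents(ind):
                raise PedigreeError(f"individual {ind!r} is its own grandparent")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PedigreeTable":
        required = {"id", "mother", "father"}
        if not required.issubset(df.columns):
            raise PedigreeError(f"pedigree table needs columns {sorted(required)}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise PedigreeError(f"duplicate individual ids: {dups}")
        parents: dict[str, tuple[str | None, str | None]] = {}
        for row in df.itertuples(index=False):
            mo = None if pd.isna(row.mother) or row.mother == "" else str(row.mother)
            fa = None if pd.isna(row.father) or row.father == "" else str(row.father)
            parents[str(row.id)] = (mo, fa)
        return cls(parents)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": i, "mother": mo if mo is not None else "", "father": fa if fa is not None else ""}
            for i, (mo, fa) in self.parents.items()
        ]
        return pd.DataFrame(rows, columns=["id", "mother", "father"])

    def __contains__(self, individual: str) -> bool:
        return individual in self.parents

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        if individual not in self.parents:
            # unprofiled founder: no known parents
            return (None, None)
        return self.parents[individual]

    def _grandparents(self, individual: str) -> set[str]:
        gps: set[str] = set()
        for p in self.parents_of(individual):
            if p is not None:
                gps.update(q for q in self.parents_of(p) if q is not None)
        return gps

    def ancestor_chains(self, individual: str) -> list[list[str]]:
        """All ancestor chains of length <= 2 starting at `individual`.

        Each chain is ``[individual]``, ``[individual, parent]`` or
        ``[individual, parent, grandparent]``; missing links stop a chain.
        """
        chains: list[list[str]] = [[individual]]
        for p in self.parents_of(individual):
            if p is None:
                continue
            chains.append([individual, p])
            for g in self.parents_of(p):
                if g is not None:
                    chains.append([individual, p, g])
        return chains


def relatedness(ped: PedigreeTable, a: str, b: str) -> float:
    """Pedigree relatedness of a dyad, truncated at the grandparents.

    Sums (1/2)**L over every connecting path a -> common ancestor -> b
    whose up- and down-legs share only the common ancestor, where L is
    the number of parent-offspring links on the path. Only parents and
    grandparents are considered, so the largest attainable value for a
    non-self dyad without a shared parent or direct descent is 0.25
    (four shared grandparents).
    """
    for x in (a, b):
        if x not in ped:
            raise PedigreeError(f"unknown individual id {x!r}")
    if a == b:
        return 1.0
    total = 0.0
    for ca in ped.ancestor_chains(a):
        for cb in ped.ancestor_chains(b):
            if ca[-1] != cb[-1]:
                continue
            # legs must meet only at the shared ancestor
            if set(ca) & set(cb) != {ca[-1]}:
                continue
            total += 0.5 ** (len(ca) + len(cb) - 2)
    return total


def _category(ped: PedigreeTable, a: str, b: str, r: float) -> str:
    mo_a, fa_a = ped.parents_of(a)
    mo_b, fa_b = ped.parents_of(b)
    shared_mother = mo_a is not None and mo_a == mo_b
    shared_father = fa_a is not None and fa_a == fa_b
    # direct descent within two generations
    if b in (mo_a, fa_a) or a in (mo_b, fa_b):
        return EXCLUDED_CLOSE
    if b in ped._grandparents(a) or a in ped._grandparents(b):
        return EXCLUDED_CLOSE
    if shared_mother and shared_father:
        return EXCLUDED_CLOSE  # full siblings
    if shared_mother:
        return MATERNAL_HALF_SIB
    if shared_father:
        return PATERNAL_HALF_SIB
    if r >= 0.0625:
        return DISTANT
    return UNRELATED


def classify_dyads(ped: PedigreeTable, ids: Iterable[str]) -> list[DyadKinship]:
    """Classify every unordered pair of `ids` into kin categories.

    Categories follow the truncated-pedigree definitions: half-sibs share
    exactly one parent (r >= 0.25), distant dyads share a grandparent but
    no parent (r in {0.0625, 0.125} in the usual cases), unrelated dyads
    share no ancestor through the grandparental generation. Full sibs,
    parent-offspring and grandparent-grandchild pairs are flagged
    excluded_close rather than dropped. When a dyad is half-sib through
    one parental line and additionally shares a grandparent on the other
    side, the half-sib tie wins while r still sums all paths.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise PedigreeError(f"duplicate ids in dyad request: {dups}")
    out: list[DyadKinship] = []
    for a, b in itertools.combinations(ids, 2):
        r = relatedness(ped, a, b)
        out.append(DyadKinship(a, b, r, _category(ped, a, b, r)))
    return out


def sibship_blocks(
    dyads: list[DyadKinship], parent_line: str
) -> dict[str, str]:
    """Map each individual to a sibship label along one parental line.

    Individuals connected by half-sib dyads of the requested line share
    a label (the shared parent's id would be ideal, but the dyad records
    do not carry it, so the lexicographically smallest member id of the
    connected component is used, prefixed by the line). All remaining
    individuals get a unique ``singleton:<id>`` label.
    """
    if parent_line not in ("maternal", "paternal"):
        raise ValueError("parent_line must be 'maternal' or 'paternal'")
    want = MATERNAL_HALF_SIB if parent_line == "maternal" else PATERNAL_HALF_SIB
    ids: set[str] = set()
    adj: dict[str, set[str]] = {}
    for d in dyads:
        ids.update((d.id_a, d.id_b))
        if d.category == want:
            adj.setdefault(d.id_a, set()).add(d.id_b)
            adj.setdefault(d.id_b, set()).add(d.id_a)
    labels: dict[str, str] = {}
    seen: set[str] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nb in adj.get(node, ()):
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        seen.update(comp)
        tag = f"{parent_line}:{min(comp)}"
        for member in comp:
            labels[member] = tag
    for i in sorted(ids - seen):
        labels[i] = f"singleton:{i}"
    return labels
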