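"""Genomic and pedigree inbreeding coefficients.

F_ROH is the fraction of the autosomal genome covered by runs of
homozygosity. The pedigree expectation comes from the standard recursive
kinship coefficient f(i, j) (the probability that random alleles drawn
from i and j are identical by descent): an offspring's inbreeding
coefficient equals the kinship of its parents, so a full-sib mating
yields F = 1/4 with non-inbred founders and F = (1 + F_base)/4 when the
founders themselves carry inbreeding F_base. The closed form
``expected_sib_f`` and the recursion with inbred founders are both
exposed and agree exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

#: Total autosome length of the CanFam6 dog assembly, in kb — the
#: denominator used for the case study's F_ROH values.
AUTOSOME_KB_CANFAM6 = 2_212_284.0


@dataclass(frozen=True)
class Individual:
    id: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: Optional[str] = None
    founder_f: float = 0.0  # inbreeding assigned when both parents are unknown


class Pedigree:
    """A directed acyclic set of parent links."""

    def __init__(self, individuals: Iterable[Individual]):
        self._by_id = {}
        for ind in individuals:
            if ind.id in self._by_id:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        for ind in self._by_id.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self._by_id:
                    raise ValueError(f"{ind.id}: unknown parent {parent!r}")
        self._depth: dict = {}
        for iid in self._by_id:
            self._compute_depth(iid, frozenset())
        self._kinship_memo: dict = {}

    def _compute_depth(self, iid: str, stack: frozenset) -> int:
        if iid in self._depth:
            return self._depth[iid]
        if iid in stack:
            raise ValueError(f"pedigree cycle through {iid!r}")
        ind = self._by_id[iid]
        parents = [p for p in (ind.father, ind.mother) if p is not None]
        depth = 0 if not parents else 1 + max(
            self._compute_depth(p, stack | {iid}) for p in parents)
        self._depth[iid] = depth
        return depth

    def __iter__(self):
        return iter(self._by_id.values())

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list:
        return list(self._by_id)

    def founders(self) -> list:
        return [i.id for i in self if i.father is None and i.mother is None]

    def topological_order(self) -> list:
        """Individuals ordered parents-before-children."""
        return sorted(self._by_id, key=self._depth.__getitem__)

    def depth(self, iid: str) -> int:
        return self._depth[iid]


def kinship(ped: Pedigree, i: str, j: str) -> float:
    """Recursive (tabular-method) kinship coefficient f(i, j).

    f(i, i) = (1 + F_i)/2 with F_i the inbreeding of i; for distinct
    individuals the recursion descends on the one farther from the
    founders, f(i, j) = [f(father_i, j) + f(mother_i, j)]/2, a missing
    parent contributing 0. Founders are unrelated to everyone else and
    carry their ``founder_f`` as own inbreeding.
    """
    for iid in (i, j):
        if iid not in ped:
            raise ValueError(f"unknown individual {iid!r}")
    return _kinship(ped, i, j)


def _kinship(ped: Pedigree, i: str, j: str) -> float:
    key = (i, j) if i <= j else (j, i)
    memo = ped._kinship_memo
    if key in memo:
        return memo[key]
    if i == j:
        value = 0.5 * (1.0 + inbreeding_of(ped, i))
    else:
        if ped.depth(i) < ped.depth(j):
            i, j = j, i
        ind = ped[i]
        if ind.father is None and ind.mother is None:
            value = 0.0  # founder: unrelated to any distinct individual
        else:
            value = 0.5 * sum(
                _kinship(ped, p, j) for p in (ind.father, ind.mother)
                if p is not None)
    memo[key] = value
    return value


def inbreeding_of(ped: Pedigree, iid: str) -> float:
    """Inbreeding coefficient: kinship of the parents, or founder_f for founders."""
    ind = ped[iid]
    if ind.father is None and ind.mother is None:
        return ind.founder_f
    if ind.father is None or ind.mother is None:
        return 0.0
    return _kinship(ped, ind.father, ind.mother)


def expected_inbreeding(ped: Pedigree, individual: str) -> Optional[float]:
    """Pedigree-expected inbreeding of ``individual`` (kinship of its parents).

    Returns None with a warning when a parent is unknown.
    """
    if individual not in ped:
        raise ValueError(f"unknown individual {individual!r}")
    ind = ped[individual]
    if ind.father is None or ind.mother is None:
        warnings.warn(f"{individual}: parent unknown, expected inbreeding "
                      "undefined", stacklevel=2)
        return None
    return kinship(ped, ind.father, ind.mother)


def expected_sib_f(baseline_f: float) -> float:
    """Expected inbreeding of a full-sib-mating offspring, (1 + baseline)/4.

    ``baseline_f`` is the inbreeding carried by the (otherwise unrelated)
    founder grandparents — in the case study, the mean F_ROH of the
    control genomes, taken as the breed's baseline autozygosity.
    """
    if not 0.0 <= baseline_f < 1.0:
        raise ValueError(f"baseline_f {baseline_f} outside [0, 1)")
    return 0.25 * (1.0 + baseline_f)


def baseline_from_controls(summaries: Sequence) -> float:
    """Mean F_ROH across control summaries (:class:`autozyg.roh.RohSummary`)."""
    if not summaries:
        raise ValueError("need at least one control summary")
    # fsum: exactly rounded, so the mean is permutation-invariant
    return math.fsum(s.f_roh for s in summaries) / len(summaries)


def f_roh(total_roh_kb: float, autosome_kb: float = AUTOSOME_KB_CANFAM6) -> float:
    """Genomic inbreeding coefficient: ROH-covered fraction of the autosomes."""
    if autosome_kb <= 0:
        raise ValueError("autosome_kb must be > 0")
    if not 0.0 <= total_roh_kb <= autosome_kb:
        raise ValueError(f"total_roh_kb {total_roh_kb} outside [0, {autosome_kb}]")
    return total_roh_kb / autosome_kb


def sib_mating_pedigree(baseline_f: float = 0.0) -> Pedigree:
    """Minimal full-sib-mating pedigree: two founders, two sib parents, offspring.

    The founders carry ``baseline_f`` as their own inbreeding; the
    offspring's expected inbreeding is then (1 + baseline_f)/4, matching
    :func:`expected_sib_f` exactly.
    """
    return Pedigree([
        Individual("founder_sire", founder_f=baseline_f),
        Individual("founder_dam", founder_f=baseline_f),
        Individual("sib1", father="founder_sire", mother="founder_dam"),
        Individual("sib2", father="founder_sire", mother="founder_dam"),
        Individual("offspring", father="sib1", mother="sib2"),
    ])


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding, the convention used for reported coefficients."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
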