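"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized/memoized code paths:
the ROH oracle materializes every scanning window and candidate run with
plain Python loops, and the kinship oracle evaluates Wright's
path-counting formula by exhaustive path enumeration.
"""

from __future__ import annotations

import numpy as np

from autozyg.inbreeding import Individual, Pedigree
from autozyg.roh import RohParams


def brute_force_roh(chromosome, positions, codes, p: RohParams):
    """Enumerate every window and candidate run; return (start, end, n_snps)."""
    positions = list(map(int, positions))
    codes = list(map(int, codes))
    n = len(positions)
    if n == 0:
        return []
    w = min(p.window_snps, n)
    window_hom = []
    for i in range(n - w + 1):
        win = codes[i:i + w]
        n_het = sum(1 for c in win if c == 1)
        n_mis = sum(1 for c in win if c == -1)
        window_hom.append(n_het <= p.window_het_max
                          and n_mis <= p.window_missing_max)
    candidate = []
    for j in range(n):
        covering = [window_hom[i] for i in range(len(window_hom))
                    if i <= j < i + w]
        candidate.append(sum(covering) / len(covering) >= p.window_hit_fraction)

    segments = []
    j = 0
    while j < n:
        if not candidate[j]:
            j += 1
            continue
        k = j
        while k + 1 < n and candidate[k + 1]:
            k += 1
        pieces, s = [], j
        for t in range(j, k):
            if positions[t + 1] - positions[t] > p.max_gap_kb * 1000:
                pieces.append((s, t))
                s = t + 1
        pieces.append((s, k))
        for s0, e0 in pieces:
            while s0 <= e0 and codes[s0] in (1, -1):
                s0 += 1
            while e0 >= s0 and codes[e0] in (1, -1):
                e0 -= 1
            if s0 > e0:
                continue
            n_snps = e0 - s0 + 1
            length_kb = (positions[e0] - positions[s0] + 1) / 1000.0
            if (n_snps >= p.min_snps and length_kb > p.min_kb
                    and length_kb / n_snps <= p.min_density_kb_per_snp):
                segments.append((chromosome, positions[s0], positions[e0],
                                 n_snps))
        j = k + 1
    return segments


def _ascending_paths(ped: Pedigree, iid: str):
    """All paths [iid, ..., ancestor] following parent links upward."""
    paths = [[iid]]
    ind = ped[iid]
    for parent in (ind.father, ind.mother):
        if parent is not None:
            for tail in _ascending_paths(ped, parent):
                paths.append([iid] + tail)
    return paths


def path_counting_kinship(ped: Pedigree, i: str, j: str) -> float:
    """Wright's sum over common ancestors A of (1/2)^(L1+L2+1) (1+F_A),
    restricted to path pairs sharing no individual but A."""
    if i == j:
        return 0.5 * (1.0 + path_counting_inbreeding(ped, i))
    total = 0.0
    for pi in _ascending_paths(ped, i):
        for pj in _ascending_paths(ped, j):
            if pi[-1] != pj[-1]:
                continue
            if set(pi[:-1]) & set(pj[:-1]):
                continue
            ancestor = pi[-1]
            l1, l2 = len(pi) - 1, len(pj) - 1
            total += 0.5 ** (l1 + l2 + 1) * (
                1.0 + path_counting_inbreeding(ped, ancestor))
    return total


def path_counting_inbreeding(ped: Pedigree, iid: str) -> float:
    ind = ped[iid]
    if ind.father is None and ind.mother is None:
        return ind.founder_f
    if ind.father is None or ind.mother is None:
        return 0.0
    return path_counting_kinship(ped, ind.father, ind.mother)


def random_pedigree(rng: np.random.Generator, n_founders: int = 4,
                    n_generations: int = 5, per_generation: int = 3
                    ) -> Pedigree:
    """A random multi-generation pedigree (every non-founder has two
    distinct parents drawn from any earlier generation)."""
    individuals = [Individual(f"F{i}") for i in range(n_founders)]
    pool = [ind.id for ind in individuals]
    counter = 0
    for _gen in range(n_generations):
        new_ids = []
        for _ in range(per_generation):
            father, mother = rng.choice(len(pool), size=2, replace=False)
            iid = f"I{counter}"
            counter += 1
            individuals.append(Individual(iid, father=pool[int(father)],
                                          mother=pool[int(mother)]))
            new_ids.append(iid)
        pool.extend(new_ids)
    return Pedigree(individuals)


def clopper_pearson_bisect(k: int, n: int, alpha: float = 0.05):
    """CI endpoints found by bisection on the regularized incomplete beta
    function (independent of scipy's inverse-CDF route)."""
    from scipy.special import betainc

    def solve(a, b, target):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if betainc(a, b, mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else solve(k, n - k + 1, alpha / 2)
    upper = 1.0 if k == n else solve(k + 1, n - k, 1 - alpha / 2)
    return lower, upper
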