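"""Independent brute-force oracles used to cross-check the implementation.

Everything here works directly on plain residue maps with explicit loops,
deliberately sharing no code with the package's distance/graph machinery.
"""

from __future__ import annotations

import random

from epletatlas.atlas import AlleleProfile
from epletatlas.registry import AlleleName, parse_allele_name

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def oracle_distance(p1: AlleleProfile, p2: AlleleProfile, policy: str = "difference") -> int:
    """Position-by-position scan over the full covered coordinate range."""
    all_pos = sorted(set(p1.residues) | set(p2.residues))
    d = 0
    for pos in all_pos:
        in1, in2 = pos in p1.residues, pos in p2.residues
        if in1 and in2:
            shared = set(p1.residues[pos]) & set(p2.residues[pos])
            if len(shared) == 0:
                d += 1
        elif policy == "difference" and (in1 or in2):
            d += 1
    return d


def oracle_nearest(
    profiles: dict[AlleleName, AlleleProfile],
    query: AlleleName,
    scope: str = "all",
    policy: str = "difference",
) -> set[tuple[AlleleName, int]]:
    """O(n) scan for the argmin set of neighbours."""
    best: dict[AlleleName, int] = {}
    for other, prof in profiles.items():
        if other == query:
            continue
        same_group = other.group_label == query.group_label
        if scope == "own_group" and not same_group:
            continue
        if scope == "other_groups" and same_group:
            continue
        best[other] = oracle_distance(profiles[query], prof, policy)
    if not best:
        return set()
    dmin = min(best.values())
    return {(a, d) for a, d in best.items() if d == dmin}


def oracle_cross_reactive(profiles: dict[AlleleName, AlleleProfile], query: AlleleName) -> bool:
    own = oracle_nearest(profiles, query, "own_group")
    other = oracle_nearest(profiles, query, "other_groups")
    if not other:
        return False
    if not own:
        return True
    return min(d for _, d in other) < min(d for _, d in own)


def random_profiles(
    rng: random.Random,
    n_alleles: int,
    n_groups: int = 3,
    n_positions: int = 25,
    max_set: int = 2,
    locus: str = "A",
) -> dict[AlleleName, AlleleProfile]:
    """Random sparse profiles spread over a handful of allele groups."""
    out: dict[AlleleName, AlleleProfile] = {}
    for i in range(n_alleles):
        g = rng.randrange(n_groups) + 1
        allele = parse_allele_name(f"{locus}*{g:02d}:{i + 1:02d}")
        residues = {}
        for pos in range(1, n_positions + 1):
            if rng.random() < 0.5:
                k = rng.randint(1, max_set)
                residues[pos] = frozenset(rng.sample(RESIDUES, k))
        out[allele] = AlleleProfile(allele=allele, residues=residues)
    return out
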