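"""Synthetic eplet registries with planted structure.

The generator emulates the shapes seen in real allele-group disparity
graphs: each group has a monomorphic core (alleles with identical eplet
sets), a halo of alleles differing from the core at a fixed number of
positions, and optionally planted cross-reactive alleles that are strictly
nearer to a foreign group's eplet signature than to their own group.

Construction is purely combinatorial: every group owns a disjoint block of
mature-protein positions and a signature of single-residue eplets there, so
all planted distances hold exactly by construction (cross-reactivity is
planted by eplet sharing with the foreign signature, never by editing
distances after the fact).  All randomness flows through one seeded PRNG
and all derived quantities are integer arithmetic, so a seed fully
determines the emitted registry byte-for-byte.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .registry import (
    AlleleName,
    EpletDefinition,
    Registry,
    locus_class,
    parse_allele_name,
    parse_eplet_name,
)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: loci assigned to simulated "loci" slots, in order
LOCUS_ORDER = ("A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1", "DRB3", "DRB4", "DRB5")


class SimulationError(ValueError):
    """Parameter combination cannot satisfy the planted-distance contract."""


@dataclass(frozen=True)
class SimulationParams:
    n_loci: int = 2
    groups_per_locus: int = 3
    alleles_per_group: int = 8
    monomorphic_core_size: int = 3
    n_positions: int = 30  # coordinate block reserved per group
    n_eplets_per_group: int = 8
    halo_mutation_distance: int = 2
    n_planted_cross_reactive: int = 2
    seed: int = 0

    def validate(self) -> None:
        p = self
        n_halo = p.alleles_per_group - p.monomorphic_core_size
        if not 1 <= p.n_loci <= len(LOCUS_ORDER):
            raise SimulationError(f"n_loci must be in 1..{len(LOCUS_ORDER)}")
        if p.monomorphic_core_size > p.alleles_per_group:
            raise SimulationError("monomorphic_core_size exceeds alleles_per_group")
        if p.monomorphic_core_size < 1 or n_halo < 0:
            raise SimulationError("invalid core/halo split")
        if n_halo > 18:
            raise SimulationError("at most 18 halo alleles per group (residue budget)")
        if not 1 <= p.halo_mutation_distance <= p.n_eplets_per_group:
            raise SimulationError(
                "halo_mutation_distance must be in 1..n_eplets_per_group"
            )
        if p.n_eplets_per_group > p.n_positions:
            raise SimulationError("n_eplets_per_group exceeds the position block")
        if p.n_planted_cross_reactive:
            if p.groups_per_locus < 2:
                raise SimulationError("cross-reactivity needs >= 2 groups per locus")
            if p.monomorphic_core_size < 2:
                raise SimulationError(
                    "planted cross-reactivity needs a monomorphic core of >= 2 "
                    "(a lone core allele would itself become cross-reactive)"
                )
        if p.n_planted_cross_reactive > p.n_loci * p.groups_per_locus * max(n_halo, 0):
            raise SimulationError("not enough halo slots for planted cross-reactive alleles")


@dataclass
class SimulationTruth:
    """Ground truth of the planted structure, keyed by raw allele names."""

    planted_cross_reactive: set[tuple[str, str]] = field(default_factory=set)
    planted_clusters: list[set[str]] = field(default_factory=list)
    planted_distances: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_cross_reactive": sorted(map(list, self.planted_cross_reactive)),
                "planted_clusters": [sorted(c) for c in self.planted_clusters],
                "planted_distances": {
                    f"{a}|{b}": d for (a, b), d in sorted(self.planted_distances.items())
                },
            },
            indent=1,
            sort_keys=True,
        )


def _eplet(pos: int, letter: str) -> str:
    return f"{pos}{letter}"


def simulate_registry(params: SimulationParams) -> tuple[Registry, SimulationTruth]:
    """Generate a registry with planted cores, halos and cross-reactivity.

    Per group g the signature is one single-residue eplet at each of
    ``n_eplets_per_group`` positions in g's private coordinate block.  Core
    alleles carry the signature verbatim; halo allele i substitutes the
    residues of ``halo_mutation_distance`` signature positions (a rotating
    window starting at i) with residues no other group member uses at those
    positions.  A planted cross-reactive allele of group g carries the
    signature of the next group of the same locus with exactly one
    substituted residue, making it distance 1 from that group's core but far
    from every member of g (the blocks are disjoint, so the distance is
    twice the signature length).
    """
    params.validate()
    rng = random.Random(params.seed)
    p = params
    n_halo = p.alleles_per_group - p.monomorphic_core_size

    loci = LOCUS_ORDER[: p.n_loci]
    group_index: dict[tuple[str, int], int] = {}
    signatures: dict[tuple[str, int], list[tuple[int, int]]] = {}  # (pos, residue idx)
    g_global = 0
    for locus in loci:
        for g in range(p.groups_per_locus):
            start = g_global * p.n_positions + 1
            signatures[(locus, g)] = [
                (start + j, rng.randrange(20)) for j in range(p.n_eplets_per_group)
            ]
            group_index[(locus, g)] = g_global
            g_global += 1

    # assign planted cross-reactive alleles to (locus, group) round-robin
    cr_slots: dict[tuple[str, int], list[int]] = {}  # group -> halo indices replaced
    cr_specs: list[tuple[str, int, int]] = []  # (locus, g_from, halo index)
    per_target_count: dict[tuple[str, int], int] = {}
    c = 0
    order = [(locus, g) for locus in loci for g in range(p.groups_per_locus)]
    while len(cr_specs) < p.n_planted_cross_reactive:
        locus, g = order[c % len(order)]
        c += 1
        used = cr_slots.setdefault((locus, g), [])
        if len(used) >= n_halo:
            continue
        halo_idx = n_halo - 1 - len(used)
        used.append(halo_idx)
        cr_specs.append((locus, g, halo_idx))
        target = (locus, (g + 1) % p.groups_per_locus)
        t = per_target_count.get(target, 0)
        if t >= p.n_eplets_per_group:
            raise SimulationError(
                "too many cross-reactive alleles aimed at one group "
                "(would collapse their pairwise distances)"
            )
        per_target_count[target] = t + 1

    eplets: dict[str, EpletDefinition] = {}
    assignments: dict[AlleleName, frozenset[str]] = {}
    truth = SimulationTruth()

    def register(locus: str, names: set[str]) -> None:
        for name in names:
            if name not in eplets:
                d = parse_eplet_name(name)
                eplets[name] = EpletDefinition(
                    name=name,
                    residues=d.residues,
                    hla_class=locus_class(locus),
                    confirmed=True,
                )

    per_target_seen: dict[tuple[str, int], int] = {}
    for locus in loci:
        for g in range(p.groups_per_locus):
            sig = signatures[(locus, g)]
            sig_eplets = {_eplet(pos, ALPHABET[r]) for pos, r in sig}
            register(locus, sig_eplets)
            replaced = set(cr_slots.get((locus, g), []))
            core_rep = f"{locus}*{g + 1:02d}:01"

            for s in range(p.monomorphic_core_size):
                allele = parse_allele_name(f"{locus}*{g + 1:02d}:{s + 1:02d}")
                assignments[allele] = frozenset(sig_eplets)
            if p.monomorphic_core_size >= 2:
                truth.planted_clusters.append(
                    {f"{locus}*{g + 1:02d}:{s + 1:02d}" for s in range(p.monomorphic_core_size)}
                )

            for i in range(n_halo):
                slot = p.monomorphic_core_size + 1 + i
                raw = f"{locus}*{g + 1:02d}:{slot:02d}"
                allele = parse_allele_name(raw)
                if i in replaced:
                    # planted cross-reactive: foreign signature, one substitution
                    tgt = (locus, (g + 1) % p.groups_per_locus)
                    t = per_target_seen.get(tgt, 0)
                    per_target_seen[tgt] = t + 1
                    tsig = signatures[tgt]
                    q = t % p.n_eplets_per_group
                    pos, r = tsig[q]
                    sub = ALPHABET[(r + 19 - (t // p.n_eplets_per_group)) % 20]
                    names = {_eplet(pp, ALPHABET[rr]) for k, (pp, rr) in enumerate(tsig) if k != q}
                    names.add(_eplet(pos, sub))
                    register(locus, names)
                    assignments[allele] = frozenset(names)
                    tgt_label = f"{locus}*{tgt[1] + 1:02d}"
                    truth.planted_cross_reactive.add((raw, tgt_label))
                    truth.planted_distances[(raw, f"{locus}*{tgt[1] + 1:02d}:01")] = 1
                else:
                    names = set(sig_eplets)
                    for j in range(p.halo_mutation_distance):
                        q = (i + j) % p.n_eplets_per_group
                        pos, r = sig[q]
                        names.discard(_eplet(pos, ALPHABET[r]))
                        names.add(_eplet(pos, ALPHABET[(r + 1 + i) % 20]))
                    register(locus, names)
                    assignments[allele] = frozenset(names)
                    truth.planted_distances[(raw, core_rep)] = p.halo_mutation_distance

    registry = Registry(eplets=eplets, assignments=dict(sorted(assignments.items())))
    registry.validate()
    return registry, truth
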