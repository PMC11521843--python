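"""Per-allele polymorphic amino-acid profiles and motif prevalence tables.

An allele's profile is the union of the residue maps of all its assigned
eplets: a sparse map position -> residue set over the mature-protein
coordinates.  Where two eplets cover the same position their residue sets
are merged by intersection; an empty intersection means the registry is
internally inconsistent and is surfaced as a hard error rather than patched.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

from .registry import AlleleName, Registry, RegistryError

log = logging.getLogger(__name__)


class ProfileConflictError(RegistryError):
    """Two eplets of one allele demand disjoint residues at one position."""

    def __init__(self, allele: AlleleName, position: int, eplets: Iterable[str]):
        self.allele, self.position, self.eplets = allele, position, sorted(eplets)
        super().__init__(
            f"allele {allele}: eplets {self.eplets} conflict at position {position}"
        )


@dataclass(frozen=True)
class AlleleProfile:
    """Sparse polymorphic amino-acid sequence of one allele."""

    allele: AlleleName
    residues: dict[int, frozenset[str]]
    source_eplets: frozenset[str] = frozenset()

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.residues))

    def same_residues(self, other: "AlleleProfile") -> bool:
        """Monomorphic in the eplet sense: identical residue maps."""
        return self.residues == other.residues


def build_profile(registry: Registry, allele: AlleleName) -> AlleleProfile:
    """Merge the residue maps of all eplets assigned to ``allele``."""
    if allele not in registry.assignments:
        raise RegistryError(f"allele {allele} not present in registry")
    residues: dict[int, frozenset[str]] = {}
    contributors: dict[int, list[str]] = {}
    for name in sorted(registry.assignments[allele]):
        for pos, letters in registry.eplets[name].residues.items():
            contributors.setdefault(pos, []).append(name)
            if pos in residues:
                merged = residues[pos] & letters
                if not merged:
                    raise ProfileConflictError(allele, pos, contributors[pos])
                residues[pos] = merged
            else:
                residues[pos] = letters
    return AlleleProfile(
        allele=allele,
        residues=residues,
        source_eplets=registry.assignments[allele],
    )


def build_atlas(
    registry: Registry,
    allele_filter: Callable[[AlleleName], bool] | None = None,
    *,
    lenient: bool = False,
) -> dict[AlleleName, AlleleProfile]:
    """One profile per allele passing the filter.

    Alleles with no assigned eplets cannot be placed in differential
    amino-acid space and are omitted with a logged warning.  In lenient mode
    conflicted alleles are skipped (logged) instead of aborting the build.
    """
    atlas: dict[AlleleName, AlleleProfile] = {}
    for allele in sorted(registry.assignments):
        if allele_filter is not None and not allele_filter(allele):
            continue
        if not registry.assignments[allele]:
            log.warning("allele %s has no eplets; omitted from atlas", allele)
            continue
        try:
            atlas[allele] = build_profile(registry, allele)
        except ProfileConflictError as exc:
            if not lenient:
                raise
            log.warning("%s; allele skipped", exc)
    return atlas


@dataclass
class MotifTable:
    """Per-position amino-acid prevalence across a set of profiles.

    ``prevalence[(pos, residue)]`` is the fraction of alleles carrying that
    residue at that position; an allele whose residue set at a position has
    k alternatives contributes 1/k to each, so prevalence plus the gap
    fraction (alleles not covering the position) sums to 1 per position.
    """

    positions: list[int]
    prevalence: dict[tuple[int, str], float]
    gap_fraction: dict[int, float]
    n_alleles: int

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: position, residue, prevalence (plus gap rows)."""
        rows = [
            {"position": p, "residue": r, "prevalence": v}
            for (p, r), v in sorted(self.prevalence.items())
        ]
        rows += [
            {"position": p, "residue": "-", "prevalence": self.gap_fraction[p]}
            for p in self.positions
            if self.gap_fraction[p] > 0
        ]
        return pd.DataFrame(rows, columns=["position", "residue", "prevalence"])


def motif_prevalence(profiles: Iterable[AlleleProfile]) -> MotifTable:
    """Amino-acid motif table over a group or locus of allele profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("motif_prevalence requires at least one profile")
    n = len(profiles)
    positions = sorted({p for prof in profiles for p in prof.residues})
    prevalence: dict[tuple[int, str], float] = {}
    gap: dict[int, float] = {}
    for pos in positions:
        covered = 0
        for prof in profiles:
            letters = prof.residues.get(pos)
            if not letters:
                continue
            covered += 1
            w = 1.0 / len(letters)
            for r in sorted(letters):
                prevalence[(pos, r)] = prevalence.get((pos, r), 0.0) + w
        gap[pos] = (n - covered) / n
    prevalence = {k: v / n for k, v in prevalence.items()}
    return MotifTable(positions=positions, prevalence=prevalence, gap_fraction=gap, n_alleles=n)


def profile_to_sequence_string(
    profile: AlleleProfile,
    position_range: Iterable[int],
    *,
    placeholder: str = ".",
) -> tuple[str, dict[int, str]]:
    """Render a profile as one character per position.

    Uncovered positions show the placeholder; positions with alternative
    residues show 'X' and their detail goes into the returned side map
    (e.g. ``{164: "S/G"}``).
    """
    chars: list[str] = []
    side: dict[int, str] = {}
    for pos in position_range:
        letters = profile.residues.get(pos)
        if not letters:
            chars.append(placeholder)
        elif len(letters) == 1:
            chars.append(next(iter(letters)))
        else:
            chars.append("X")
            side[pos] = "/".join(sorted(letters))
    return "".join(chars), side


def atlas_to_table(atlas: Mapping[AlleleName, AlleleProfile]) -> pd.DataFrame:
    """Long-form atlas export: allele, position, residues ('/'-joined)."""
    rows = [
        {
            "allele": allele.raw,
            "position": pos,
            "residues": "/".join(sorted(profile.residues[pos])),
        }
        for allele, profile in sorted(atlas.items())
        for pos in sorted(profile.residues)
    ]
    return pd.DataFrame(rows, columns=["allele", "position", "residues"])


def atlas_to_alignment(
    atlas: Mapping[AlleleName, AlleleProfile],
    position_range: Iterable[int] | None = None,
    *,
    placeholder: str = ".",
) -> str:
    """Aligned-text export over a shared position range (FASTA-like)."""
    atlas = dict(sorted(atlas.items()))
    if position_range is None:
        all_pos = sorted({p for prof in atlas.values() for p in prof.residues})
        position_range = range(all_pos[0], all_pos[-1] + 1) if all_pos else range(0)
    position_range = list(position_range)
    lines = []
    for allele, profile in atlas.items():
        seq, side = profile_to_sequence_string(
            profile, position_range, placeholder=placeholder
        )
        note = (
            " ".join(f"{p}={s}" for p, s in sorted(side.items())) if side else ""
        )
        lines.append(f">{allele.raw}" + (f" {note}" if note else ""))
        lines.append(seq)
    return "\n".join(lines) + "\n"
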