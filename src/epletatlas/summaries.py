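"""Group- and locus-level cross-reactivity and frequent-eplet summaries."""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .atlas import AlleleProfile
from .disparity import DistanceMatrix, classify_cross_reactive, nearest_neighbours
from .registry import AlleleName, Registry


def frequent_eplets(
    registry: Registry, group_label: str, threshold: float = 0.8
) -> list[str]:
    """Eplets confirmed for strictly more than ``threshold`` of the group.

    The 80% rule is read strictly: an eplet carried by exactly 4 of 5
    alleles (0.8) is excluded.  Ordered by first position, then name.
    """
    members = registry.alleles_of_group(group_label)
    if not members:
        raise ValueError(f"group {group_label!r} has no alleles in the registry")
    counts: dict[str, int] = {}
    for allele in members:
        for name in registry.assignments[allele]:
            counts[name] = counts.get(name, 0) + 1
    keep = [n for n, c in counts.items() if c / len(members) > threshold]
    return sorted(keep, key=lambda n: (registry.eplets[n].start, n))


@dataclass
class GroupSummary:
    group: str
    n_alleles: int
    n_cross_reactive: int
    pct_cross_reactive: float  # fraction in [0, 1]
    external_allele_counts: dict[str, int] = field(default_factory=dict)
    frequent_eplets: list[str] = field(default_factory=list)


def group_summary(
    atlas: Mapping[AlleleName, AlleleProfile],
    matrix: DistanceMatrix,
    group_label: str,
    registry: Registry | None = None,
    threshold: float = 0.8,
) -> GroupSummary:
    """Cross-reactivity overview of one allele group.

    ``external_allele_counts`` tallies, per foreign group, the distinct
    foreign alleles that appear as nearest neighbours of the group's
    cross-reactive members (alleles, not edges).  Frequent eplets are filled
    in when a registry is supplied.
    """
    members = matrix.group_members(group_label)
    if not members:
        raise ValueError(f"group {group_label!r} has no alleles in the matrix")
    external: dict[str, set[AlleleName]] = {}
    n_cr = 0
    for a in members:
        if not classify_cross_reactive(matrix, a).is_cross_reactive:
            continue
        n_cr += 1
        for b, _ in nearest_neighbours(matrix, a, "other_groups"):
            external.setdefault(b.group_label, set()).add(b)
    return GroupSummary(
        group=group_label,
        n_alleles=len(members),
        n_cross_reactive=n_cr,
        pct_cross_reactive=n_cr / len(members),
        external_allele_counts={g: len(s) for g, s in sorted(external.items())},
        frequent_eplets=(
            frequent_eplets(registry, group_label, threshold) if registry else []
        ),
    )


@dataclass
class LocusSummary:
    locus: str
    n_groups: int
    n_alleles: int
    avg_alleles_per_group: int  # rounded to nearest
    n_cross_reactive: int
    pct_cross_reactive: int  # percent, rounded to nearest


def locus_overview(
    atlas: Mapping[AlleleName, AlleleProfile],
    matrices: Iterable[DistanceMatrix],
) -> list[LocusSummary]:
    """One cross-reactivity row per locus present in the matrices."""
    out: list[LocusSummary] = []
    for matrix in matrices:
        for locus in sorted({a.locus for a in matrix.alleles}):
            members = [a for a in matrix.alleles if a.locus == locus]
            groups = sorted({a.group_label for a in members})
            n_cr = sum(
                classify_cross_reactive(matrix, a).is_cross_reactive for a in members
            )
            out.append(
                LocusSummary(
                    locus=locus,
                    n_groups=len(groups),
                    n_alleles=len(members),
                    avg_alleles_per_group=int(len(members) / len(groups) + 0.5),
                    n_cross_reactive=n_cr,
                    pct_cross_reactive=int(100 * n_cr / len(members) + 0.5),
                )
            )
    return sorted(out, key=lambda s: s.locus)


def group_summaries_frame(summaries: Iterable[GroupSummary]) -> pd.DataFrame:
    """Tabular rendering; empty cross-reactivity is rendered '-'."""
    rows = []
    for s in summaries:
        if s.n_cross_reactive:
            freq = f"{s.n_cross_reactive} ({round(100 * s.pct_cross_reactive)}%)"
            other = "; ".join(
                f"{g} ({n})" for g, n in sorted(
                    s.external_allele_counts.items(), key=lambda kv: (-kv[1], kv[0])
                )
            )
        else:
            freq, other = "-", "-"
        rows.append(
            {
                "group": s.group,
                "n_alleles": s.n_alleles,
                "cross_reactivity": freq,
                "other_group_alleles": other,
                "frequent_eplets": ", ".join(s.frequent_eplets),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "n_alleles",
            "cross_reactivity",
            "other_group_alleles",
            "frequent_eplets",
        ],
    )


def locus_overview_frame(summaries: Iterable[LocusSummary]) -> pd.DataFrame:
    rows = [
        {
            "locus": s.locus,
            "n_groups": s.n_groups,
            "n_alleles": s.n_alleles,
            "avg_alleles_per_group": s.avg_alleles_per_group,
            "cross_reactive": f"{s.n_cross_reactive}/{s.pct_cross_reactive}",
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=["locus", "n_groups", "n_alleles", "avg_alleles_per_group", "cross_reactive"],
    )


def frame_to_markdown(df: pd.DataFrame) -> str:
    """Small GitHub-pipe-table renderer (no extra dependency)."""
    cols = [str(c) for c in df.columns]
    widths = [
        max(len(c), *(len(str(v)) for v in df[c])) if len(df) else len(c)
        for c in cols
    ]
    def row(cells: Iterable[str]) -> str:
        return "| " + " | ".join(str(c).ljust(w) for c, w in zip(cells, widths)) + " |"

    lines = [row(cols), row("-" * w for w in widths)]
    lines += [row(str(v) for v in rec) for rec in df.itertuples(index=False)]
    return "\n".join(lines) + "\n"
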