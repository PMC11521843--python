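#!/usr/bin/env python
"""Validate a user-supplied eplet-registry snapshot.

Given the two registry tables (eplet definitions and allele assignments),
recompute locus-level cross-reactivity statistics and the within-group
distances of the HLA-A*01 group for manual comparison against published
registry-snapshot figures.  This is a convenience tool for users holding a
real registry export; nothing in the test suite depends on it.

Usage:
    python scripts/validate_registry.py --eplets eplets.tsv \
        --assignments assignments.tsv [--group A*01]
"""

from __future__ import annotations

import argparse

from epletatlas import (
    build_atlas,
    distance_matrix,
    frame_to_markdown,
    locus_overview,
    locus_overview_frame,
    monomorphic_clusters,
    nearest_neighbours,
    read_registry,
)
from epletatlas.disparity import namespace_of


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--eplets", required=True)
    parser.add_argument("--assignments", required=True)
    parser.add_argument("--group", default="A*01")
    parser.add_argument("--delimiter", default="\t")
    args = parser.parse_args()

    registry = read_registry(
        args.eplets, args.assignments, delimiter=args.delimiter, lenient=True
    )
    atlas = build_atlas(registry, lenient=True)
    spaces = sorted({namespace_of(a.locus) for a in atlas})
    matrices = [distance_matrix(atlas, ns) for ns in spaces]

    print("Locus overview (cross-reactive alleles as count/percent):\n")
    print(frame_to_markdown(locus_overview_frame(locus_overview(atlas, matrices))))

    label = args.group
    for m in matrices:
        members = m.group_members(label)
        if not members:
            continue
        print(f"\nGroup {label}: {len(members)} alleles")
        clusters = monomorphic_clusters(m, label)
        for c in clusters:
            print(f"  monomorphic cluster of {len(c)}: "
                  + ", ".join(a.raw for a in sorted(c)))
        print("  nearest-neighbour distances within the group:")
        for a in members:
            nn = nearest_neighbours(m, a, "own_group")
            if nn:
                d = min(x for _, x in nn)
                partners = ", ".join(b.raw for b, x in sorted(nn) if x == d)
                print(f"    {a.raw}: d={d} to {partners}")


if __name__ == "__main__":
    main()
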