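"""Packaged example registries built from published eplet lists.

Two small registries are bundled so every example and test runs without a
registry download:

* :func:`example_registry` — the confirmed eplet repertoire of HLA-A*01:01
  (10 eplets) together with its monomorphic partner A*01:02 (identical
  confirmed eplets; they differ only by the two unconfirmed eplets 9S and
  17S, here attached to A*01:02 — the choice of carrier is arbitrary and
  irrelevant under the default confirmed-only view), plus representative
  alleles per common HLA-A/-B/-C allele group carrying that group's
  frequent-eplet signature (the eplets confirmed for >80% of the group's
  alleles in a public registry snapshot).  A few printed signatures contain
  mutually incompatible eplets — alternative residues at a shared position,
  e.g. 62GE/62GK for A*02 — which no single allele can carry; the registry
  behind such a signature necessarily spreads the alternatives over
  different alleles, and the fixture mirrors that by splitting the
  signature over as many representative alleles as needed.

* :func:`cohort_registry` / :func:`cohort_pairs` — a self-contained class I
  registry and nine donor-recipient genotype pairs from a living kidney
  transplant cohort report.  The per-allele eplet content is reconstructed
  from the published per-pair mismatched-eplet lists: each mismatched donor
  allele carries the union of its printed mismatch lists, and the few eplets
  a row's recipient must cover for the printed lists to be mutually
  consistent are assigned to that recipient.  Alleles the table shows only
  in matched positions carry no eplets.  Note this snapshot's A*01:01
  differs from :func:`example_registry`'s (it includes 163R), reflecting the
  different registry versions behind the two published tables.
"""

from __future__ import annotations

from .mismatch import Genotype, PairRecord
from .registry import (
    AlleleName,
    EpletDefinition,
    Registry,
    locus_class,
    parse_allele_name,
    parse_eplet_name,
)

#: antibody-confirmed eplets of HLA-A*01:01
A0101_EPLETS = (
    "44KM", "62QE", "65RNA", "76ANT", "79GT",
    "90D", "138MI", "144KR", "163RG", "166DG",
)

#: eplets confirmed for >80% of each group's alleles (HLA-A, -B, -C)
GROUP_SIGNATURES: dict[str, tuple[str, ...]] = {
    "A*01": A0101_EPLETS,
    "A*02": ("62GE", "62GK", "79GT", "107W", "127K", "144TKH", "145KHA", "150AAH"),
    "A*03": ("62QE", "65RNA", "79GT", "138MI", "144KR", "150AAH", "161D"),
    "A*11": ("62QE", "65RNA", "79GT", "90D", "138MI", "144KR", "150AAH", "151AHA", "163RW"),
    "A*24": ("62EE", "65GK", "80I", "82LR", "127K", "138MI", "144KR", "150AAH", "166DG"),
    "A*25": ("62RR", "65RNA", "76ESI", "80I", "82LR", "90D", "138MI", "149TAH", "163RW"),
    "A*26": ("62RR", "65RNA", "76ANT", "79GT", "90D", "138MI", "145RT", "149TAH", "163RW"),
    "A*30": ("56R", "62QE", "65RNA", "79GT", "138MI"),
    "A*32": ("62QE", "65RNA", "76ESI", "80I", "82LR", "138MI"),
    "A*68": ("62RR", "65RNA", "79GT", "127K", "144TKH", "145KHA", "150AAH"),
    "B*07": ("65QIA", "69AA", "70IAQ", "76ESN", "80N", "163EW", "180E"),
    "B*08": ("69TNT", "71TTS", "76ESN", "80N", "156DA", "180E"),
    "B*13": ("41T", "44RMA", "69TNT", "80TLR", "82LR", "131S", "144QL", "163EW"),
    "B*15": ("69TNT", "71TTS", "76ESN", "80N", "131S", "163LW"),
    "B*18": ("44RT", "69TNT", "71TTS", "76ESN", "80N", "131S"),
    "B*27": ("65QIA", "69AA", "82LR", "131S", "163EW"),
    "B*35": ("44RT", "69TNT", "71TTS", "76ESN", "80N", "131S", "163LW"),
    "B*40": ("41T", "45KE", "69TNT", "71TTS", "76ESN", "80N", "163EW"),
    "B*44": ("41T", "45KE", "69TNT", "80TLR", "82LR", "131S", "163LS/G"),
    "B*51": ("44RT", "69TNT", "80I", "82LR", "131S", "163LW"),
    "C*01": ("65QKR", "73TVS", "76VRN", "80N"),
    "C*02": ("21H", "65QKR", "80K", "163EW"),
    "C*03": ("21H", "65QKR", "73TVS", "76VRN", "80N", "163LW", "173K"),
    "C*04": ("65QKR", "73AN", "80K", "90D"),
    "C*05": ("65QKR", "80K", "138K", "177KT"),
    "C*06": ("65QKR", "73AN", "80K", "90D"),
    "C*07": ("76VRN", "80N", "90D"),
    "C*12": ("65QKR", "80N"),
    "C*15": ("21H", "80K", "193PV"),
    "C*16": ("65QKR",),
}

#: unconfirmed eplets distinguishing A*01:02 from A*01:01
A0102_UNCONFIRMED = ("9S", "17S")


def _make_registry(
    assignments: dict[str, tuple[str, ...]],
    unconfirmed: dict[str, tuple[str, ...]] | None = None,
) -> Registry:
    eplets: dict[str, EpletDefinition] = {}
    assigned: dict[AlleleName, frozenset[str]] = {}

    def define(names: tuple[str, ...], locus: str, confirmed: bool) -> None:
        for name in names:
            if name not in eplets:
                d = parse_eplet_name(name)
                eplets[name] = EpletDefinition(
                    name=name,
                    residues=d.residues,
                    hla_class=locus_class(locus),
                    confirmed=confirmed,
                )

    for raw, names in assignments.items():
        allele = parse_allele_name(raw)
        define(names, allele.locus, confirmed=True)
        assigned[allele] = frozenset(names)
    for raw, names in (unconfirmed or {}).items():
        allele = parse_allele_name(raw)
        define(names, allele.locus, confirmed=False)
        assigned[allele] = assigned.get(allele, frozenset()) | frozenset(names)

    registry = Registry(eplets=eplets, assignments=dict(sorted(assigned.items())))
    registry.validate()
    return registry


def _compatible(names: set[str], name: str) -> bool:
    """Can ``name`` join ``names`` without an empty residue intersection?"""
    new = parse_eplet_name(name).residues
    merged: dict[int, frozenset[str]] = {}
    for other in names:
        for pos, letters in parse_eplet_name(other).residues.items():
            merged[pos] = merged.get(pos, letters) & letters
    return all(merged.get(pos, letters) & letters for pos, letters in new.items())


def _split_signature(sig: tuple[str, ...]) -> list[set[str]]:
    """Partition a signature into maximal mutually compatible variants.

    Eplets join every existing variant they are compatible with; an eplet
    compatible with none opens a new variant seeded with all compatible
    predecessors, so each variant is the full signature minus the
    alternatives it excludes.
    """
    variants: list[set[str]] = [set()]
    seen: list[str] = []
    for name in sig:
        placed = False
        for v in variants:
            if _compatible(v, name):
                v.add(name)
                placed = True
        if not placed:
            fresh = {name}
            fresh.update(p for p in seen if _compatible(fresh, p))
            variants.append(fresh)
        seen.append(name)
    return variants


def example_registry(*, confirmed_only: bool = True) -> Registry:
    """The A*01:01 worked example plus group-signature representatives."""
    assignments = {"A*01:01": A0101_EPLETS, "A*01:02": A0101_EPLETS}
    for group, sig in GROUP_SIGNATURES.items():
        if group == "A*01":
            continue
        for i, variant in enumerate(_split_signature(sig)):
            assignments[f"{group}:{i + 1:02d}"] = tuple(sorted(variant))
    unconfirmed = None if confirmed_only else {"A*01:02": A0102_UNCONFIRMED}
    return _make_registry(assignments, unconfirmed)


#: published mismatched-eplet lists per transplant pair (donor side)
_COHORT_DONOR_EPLETS: dict[str, tuple[str, ...]] = {
    "A*30:01": ("56R",),
    "A*01:01": ("44KM", "62QE", "76ANT", "138MI", "144KR", "163R", "163RG", "166DG"),
    "A*03:01": ("62EE", "65GK", "144KR", "161D", "166DG"),
    "A*24:02": ("62EE", "65GK", "144KR", "161D", "166DG"),
    "B*39:01": ("158T",),
    "B*44:02": ("41T", "44RMA", "45KE", "80TLR", "82LR", "156DA", "163LS/G"),
    "B*15:01": ("41T", "44RMA", "45KE", "80TLR", "156DA", "163LS/G"),
    "C*15:02": ("21H",),
    "C*03:04": ("21H", "73TVS", "138K", "163LW", "173K", "177KT", "193PV", "219W"),
    "C*05:01": ("21H", "73TVS", "138K", "173K", "177KT"),
}

#: recipient-side coverage entailed by the published lists (see module docs)
_COHORT_COVERAGE: dict[str, tuple[str, ...]] = {
    "B*56:01": ("44RMA",),
    "B*35:02": ("82LR",),
    "C*07:04": ("138K", "177KT"),
    "C*07:02": ("163LW", "193PV", "219W"),
}

#: alleles appearing in the cohort only in matched/recipient positions
_COHORT_EMPTY = (
    "A*02:01", "A*68:02", "A*02:05", "A*32:01",
    "B*35:03", "B*35:01", "B*07:02",
    "C*04:01", "C*07:01",
)

#: the nine pairs: (pair_id, locus, recipient genotype, donor genotype)
COHORT_PAIRS: tuple[tuple[str, str, str, str], ...] = (
    ("1", "A", "A*02:01/A*03:01", "A*02:01/A*30:01"),
    ("2", "A", "A*02:01/A*68:02", "A*01:01/A*02:01"),
    ("3", "A", "A*02:05/A*32:01", "A*03:01/A*24:02"),
    ("4", "B", "B*35:03/B*44:02", "B*35:03/B*39:01"),
    ("5", "B", "B*35:01/B*56:01", "B*35:01/B*44:02"),
    ("6", "B", "B*07:02/B*35:02", "B*15:01/B*44:02"),
    ("7", "C", "C*04:01/C*07:02", "C*07:02/C*15:02"),
    ("8", "C", "C*07:01/C*07:04", "C*03:04/C*07:01"),
    ("9", "C", "C*04:01/C*07:02", "C*03:04/C*05:01"),
)


def cohort_registry() -> Registry:
    """Class I registry consistent with the published cohort mismatch table."""
    assignments = dict(_COHORT_DONOR_EPLETS)
    assignments.update(_COHORT_COVERAGE)
    for raw in _COHORT_EMPTY:
        assignments.setdefault(raw, ())
    return _make_registry(assignments)


def cohort_pairs() -> list[PairRecord]:
    """The nine donor-recipient pairs, one typed locus each."""
    from .mismatch import parse_genotype_field

    records: list[PairRecord] = []
    for pid, locus, r_text, d_text in COHORT_PAIRS:
        recipient = Genotype(f"{pid}/recipient")
        donor = Genotype(f"{pid}/donor")
        recipient.add_locus(locus, parse_genotype_field(recipient.subject_id, locus, r_text))
        donor.add_locus(locus, parse_genotype_field(donor.subject_id, locus, d_text))
        records.append(PairRecord(pid, recipient, donor, [locus]))
    return records
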