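"""Donor-recipient antigen/allele mismatches and mismatched-eplet sets.

The mismatch direction is host-versus-graft: a donor allele absent from the
recipient's genotype at the locus is an allele mismatch, and an eplet of a
mismatched donor allele that the recipient's own eplet repertoire does not
contain is an eplet mismatch.  Genotypes use the slash dialect common in
transplant reports ("A*02:01/A*03:01"); homozygosity collapses to a single
allele.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable
from dataclasses import dataclass, field

import pandas as pd

from .registry import (
    AlleleName,
    AlleleParseError,
    Registry,
    RegistryError,
    locus_class,
    parse_allele_name,
)


class GenotypeError(ValueError):
    pass


@dataclass
class Genotype:
    """Typed loci of one subject: locus -> set of 1 or 2 alleles."""

    subject_id: str
    alleles: dict[str, frozenset[AlleleName]] = field(default_factory=dict)

    def add_locus(self, locus: str, alleles: Iterable[AlleleName]) -> None:
        alleles = frozenset(alleles)
        if not alleles or len(alleles) > 2:
            raise GenotypeError(
                f"{self.subject_id}: locus {locus} needs 1 or 2 alleles, got {len(alleles)}"
            )
        if any(a.locus != locus for a in alleles):
            raise GenotypeError(
                f"{self.subject_id}: allele of wrong locus in {locus} field"
            )
        self.alleles[locus] = alleles

    def at(self, locus: str) -> frozenset[AlleleName]:
        if locus not in self.alleles:
            raise GenotypeError(f"{self.subject_id}: not typed at locus {locus}")
        return self.alleles[locus]


def parse_genotype_field(subject_id: str, locus: str, text: str) -> frozenset[AlleleName]:
    """Parse "A*02:01/A*03:01" (or a single allele for homozygotes)."""
    parts = [p for p in text.strip().split("/") if p]
    if not parts:
        raise GenotypeError(f"{subject_id}: empty genotype field for locus {locus}")
    try:
        alleles = frozenset(parse_allele_name(p) for p in parts)
    except AlleleParseError as exc:
        raise GenotypeError(f"{subject_id}: {exc}") from exc
    if any(a.locus != locus for a in alleles):
        raise GenotypeError(
            f"{subject_id}: genotype {text!r} contains an allele outside locus {locus}"
        )
    return alleles


def allele_mismatches(
    recipient: Genotype, donor: Genotype, locus: str
) -> set[AlleleName]:
    """Donor alleles at the locus absent from the recipient (HvG direction)."""
    return set(donor.at(locus)) - set(recipient.at(locus))


def _repertoire(
    registry: Registry, alleles: Iterable[AlleleName]
) -> frozenset[str]:
    missing = [a for a in alleles if a not in registry.assignments]
    if missing:
        raise RegistryError(
            "allele(s) absent from registry: " + ", ".join(a.raw for a in sorted(missing))
        )
    out: set[str] = set()
    for a in alleles:
        out |= registry.assignments[a]
    return frozenset(out)


def eplet_mismatches(
    registry: Registry,
    recipient: Genotype,
    donor: Genotype,
    locus: str,
    scope: str = "locus",
    direction: str = "host_vs_graft",
) -> list[str]:
    """Eplets of mismatched donor alleles not in the recipient repertoire.

    ``scope`` controls the recipient repertoire: "locus" (default, the same
    locus only) or "class" (all typed loci of the same HLA class).  Eplets
    shared by both mismatched donor alleles count once.  Ordered by first
    position, then name.
    """
    if direction == "graft_vs_host":
        recipient, donor = donor, recipient
    elif direction != "host_vs_graft":
        raise ValueError(f"unknown direction {direction!r}")
    mismatched = allele_mismatches(recipient, donor, locus)
    foreign = _repertoire(registry, mismatched)
    if scope == "locus":
        own_alleles: set[AlleleName] = set(recipient.at(locus))
    elif scope == "class":
        cls = locus_class(locus)
        own_alleles = {
            a
            for loc, alleles in recipient.alleles.items()
            if locus_class(loc) == cls
            for a in alleles
        }
    else:
        raise ValueError(f"unknown scope {scope!r}")
    own = _repertoire(registry, own_alleles)
    out = foreign - own
    return sorted(out, key=lambda n: (registry.eplets[n].start, n))


@dataclass
class MismatchReport:
    pair_id: str
    locus: str
    mismatched_alleles: list[AlleleName]
    mismatched_eplets: list[str]

    @property
    def n_allele_mismatches(self) -> int:
        return len(self.mismatched_alleles)

    @property
    def n_eplet_mismatches(self) -> int:
        return len(self.mismatched_eplets)


@dataclass
class PairRecord:
    pair_id: str
    recipient: Genotype
    donor: Genotype
    loci: list[str] = field(default_factory=list)


def read_pairs(path, *, delimiter: str = "\t") -> list[PairRecord]:
    """Read a donor-recipient pairs table.

    Columns: pair_id, locus, recipient_genotype, donor_genotype; several
    rows with the same pair_id accumulate loci into one pair record.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"pair_id", "locus", "recipient_genotype", "donor_genotype"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise GenotypeError(f"{path}: header must contain {sorted(required)}")
        pairs: dict[str, PairRecord] = {}
        for i, row in enumerate(reader, start=2):
            pid = row["pair_id"].strip()
            locus = row["locus"].strip()
            try:
                r_alleles = parse_genotype_field(f"{pid}/recipient", locus, row["recipient_genotype"])
                d_alleles = parse_genotype_field(f"{pid}/donor", locus, row["donor_genotype"])
            except GenotypeError as exc:
                raise GenotypeError(f"{path} line {i}: {exc}") from exc
            rec = pairs.setdefault(
                pid,
                PairRecord(pid, Genotype(f"{pid}/recipient"), Genotype(f"{pid}/donor")),
            )
            rec.recipient.add_locus(locus, r_alleles)
            rec.donor.add_locus(locus, d_alleles)
            rec.loci.append(locus)
    return list(pairs.values())


def mismatch_report(
    registry: Registry,
    pairs: Iterable[PairRecord],
    scope: str = "locus",
    direction: str = "host_vs_graft",
) -> list[MismatchReport]:
    """One report per (pair, typed locus)."""
    out: list[MismatchReport] = []
    for pair in pairs:
        for locus in pair.loci:
            mm = sorted(allele_mismatches(pair.recipient, pair.donor, locus))
            eplets = eplet_mismatches(
                registry, pair.recipient, pair.donor, locus, scope, direction
            )
            out.append(MismatchReport(pair.pair_id, locus, mm, eplets))
    return out


def report_frame(reports: Iterable[MismatchReport]) -> pd.DataFrame:
    rows = [
        {
            "pair_id": r.pair_id,
            "locus": r.locus,
            "allele_mismatches": r.n_allele_mismatches,
            "mismatched_alleles": "/".join(a.raw for a in r.mismatched_alleles),
            "eplet_mismatches": r.n_eplet_mismatches,
            "mismatched_eplets": ", ".join(r.mismatched_eplets),
        }
        for r in reports
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "locus",
            "allele_mismatches",
            "mismatched_alleles",
            "eplet_mismatches",
            "mismatched_eplets",
        ],
    )
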