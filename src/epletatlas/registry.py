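"""Eplet and allele name parsing, and the in-memory eplet registry.

The registry model mirrors a public HLA Eplet Registry export: one table of
eplet definitions (name, HLA class, antibody-confirmation status) and one
table of allele-to-eplet assignments.  Eplet names follow the field's
convention: the leading integer is the position of the first residue in the
mature protein (1-based), the capital letters are 1-letter amino-acid symbols
placed at consecutive positions, and an optional ``/X`` suffix gives an
alternative residue for the last enumerated position (``163LS/G`` means L at
163 and S-or-G at 164).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace

log = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DRB1", "DRB3", "DRB4", "DRB5", "DQA1", "DQB1", "DPA1", "DPB1")
CLASSICAL_LOCI = CLASS_I_LOCI + CLASS_II_LOCI

#: expression suffixes of the HLA nomenclature (null, questionable, low, ...)
EXPRESSION_SUFFIXES = frozenset("NLSCAQ")


class RegistryError(ValueError):
    """Base class for registry parsing/validation failures."""


class EpletParseError(RegistryError):
    pass


class AlleleParseError(RegistryError):
    pass


_EPLET_RE = re.compile(r"^(\d+)([A-Z]+)(?:/([A-Z]))?$")


@dataclass(frozen=True)
class EpletDefinition:
    """A named eplet resolved to residue sets at mature-protein positions.

    ``residues`` maps 1-based consecutive positions to non-empty sets of
    amino-acid letters; only the last position may carry more than one
    residue (the ``/`` alternative).
    """

    name: str
    residues: dict[int, frozenset[str]]
    hla_class: str | None = None  # "I" or "II"; attached by the reader
    confirmed: bool | None = None

    @property
    def start(self) -> int:
        return min(self.residues)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.residues))

    def __hash__(self) -> int:
        return hash(self.name)


def parse_eplet_name(name: str) -> EpletDefinition:
    """Expand an eplet name into its per-position residue sets.

    ``44KM`` places K at 44 and M at 45; ``163LS/G`` places L at 163 and the
    alternative set {S, G} at 164.  Raises :class:`EpletParseError` for
    anything outside the grammar (lowercase letters, position 0, residues
    outside the 20-letter alphabet, ...).
    """
    if not name:
        raise EpletParseError("empty eplet name")
    m = _EPLET_RE.match(name)
    if m is None:
        raise EpletParseError(f"malformed eplet name {name!r}")
    start, letters, alt = int(m.group(1)), m.group(2), m.group(3)
    if start < 1:
        raise EpletParseError(f"eplet {name!r}: position must be >= 1")
    bad = [c for c in letters + (alt or "") if c not in AMINO_ACIDS]
    if bad:
        raise EpletParseError(f"eplet {name!r}: illegal residue letter(s) {bad}")
    residues = {start + i: frozenset(c) for i, c in enumerate(letters)}
    if alt is not None:
        last = start + len(letters) - 1
        residues[last] = residues[last] | {alt}
    return EpletDefinition(name=name, residues=residues)


@dataclass(frozen=True, order=True)
class AlleleName:
    """A classical HLA allele name split into nomenclature fields.

    Identity is the canonical string (locus*group:protein[...][suffix]); the
    optional ``HLA-`` prefix is stripped on parsing.
    """

    locus: str
    fields: tuple[str, ...]
    suffix: str = ""

    @property
    def group(self) -> str:
        return self.fields[0]

    @property
    def protein(self) -> str:
        return self.fields[1] if len(self.fields) > 1 else ""

    @property
    def group_label(self) -> str:
        """Allele-group label, e.g. ``A*01`` — the first nomenclature field."""
        return f"{self.locus}*{self.group}"

    @property
    def raw(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}{self.suffix}"

    @property
    def is_null(self) -> bool:
        return self.suffix == "N"

    def __str__(self) -> str:
        return self.raw


def parse_allele_name(name: str) -> AlleleName:
    """Parse ``[HLA-]locus*field1:field2[:...][suffix]`` into an AlleleName."""
    s = name.strip()
    if s.upper().startswith("HLA-"):
        s = s[4:]
    if "*" not in s:
        raise AlleleParseError(f"allele name {name!r} lacks the '*' separator")
    locus, _, rest = s.partition("*")
    if locus not in CLASSICAL_LOCI:
        raise AlleleParseError(f"unknown locus {locus!r} in allele name {name!r}")
    suffix = ""
    if rest and rest[-1] in EXPRESSION_SUFFIXES and not rest[-1].isdigit():
        suffix, rest = rest[-1], rest[:-1]
    fields = tuple(rest.split(":")) if rest else ()
    if not fields or not all(f.isdigit() and f for f in fields):
        raise AlleleParseError(f"allele name {name!r}: fields must be digit strings")
    return AlleleName(locus=locus, fields=fields, suffix=suffix)


def locus_class(locus: str) -> str:
    """HLA class ("I" or "II") of a classical locus."""
    if locus in CLASS_I_LOCI:
        return "I"
    if locus in CLASS_II_LOCI:
        return "II"
    raise AlleleParseError(f"unknown locus {locus!r}")


@dataclass
class Registry:
    """Validated eplet registry: definitions plus allele assignments.

    ``assignments`` may map an allele to an empty set, meaning the allele is
    known but carries none of the registry's eplets (such alleles are dropped
    by :func:`write_registry`, which emits one row per assignment).
    """

    eplets: dict[str, EpletDefinition] = field(default_factory=dict)
    assignments: dict[AlleleName, frozenset[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for allele, names in self.assignments.items():
            for n in names:
                if n not in self.eplets:
                    raise RegistryError(
                        f"allele {allele} assigned unknown eplet {n!r}"
                    )
                cls = self.eplets[n].hla_class
                if cls is not None and cls != locus_class(allele.locus):
                    raise RegistryError(
                        f"class mismatch: eplet {n!r} is class {cls} but "
                        f"allele {allele} is class {locus_class(allele.locus)}"
                    )

    def alleles_of_group(self, group_label: str) -> list[AlleleName]:
        return sorted(a for a in self.assignments if a.group_label == group_label)

    def eplets_of(self, allele: AlleleName) -> frozenset[str]:
        return self.assignments[allele]


def _read_rows(path, delimiter: str) -> tuple[list[str], list[dict[str, str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise RegistryError(f"{path}: missing header row")
        return list(reader.fieldnames), list(reader)


def read_registry(
    eplet_table_path,
    assignment_table_path,
    *,
    confirmed_only: bool = True,
    include_null_alleles: bool = False,
    lenient: bool = False,
    delimiter: str = "\t",
) -> Registry:
    """Read the two-table registry export and return a validated Registry.

    With ``confirmed_only`` (the default) eplets that are not
    antibody-confirmed are dropped, along with the assignments that then
    become empty — the analyses downstream are defined on the confirmed
    repertoire.  Null-expressed alleles (``N`` suffix) are excluded unless
    ``include_null_alleles``.  ``lenient`` downgrades unparseable rows to
    warnings instead of errors.
    """
    header, rows = _read_rows(eplet_table_path, delimiter)
    for col in ("name", "hla_class", "confirmed"):
        if col not in header:
            raise RegistryError(f"{eplet_table_path}: missing column {col!r}")
    eplets: dict[str, EpletDefinition] = {}
    for i, row in enumerate(rows, start=2):
        try:
            d = parse_eplet_name(row["name"].strip())
        except EpletParseError as exc:
            if lenient:
                log.warning("%s line %d: %s (skipped)", eplet_table_path, i, exc)
                continue
            raise RegistryError(f"{eplet_table_path} line {i}: {exc}") from exc
        cls = row["hla_class"].strip().upper()
        if cls not in ("I", "II"):
            raise RegistryError(
                f"{eplet_table_path} line {i}: hla_class must be I or II, got {cls!r}"
            )
        confirmed = row["confirmed"].strip().lower() in ("true", "1", "yes")
        if confirmed_only and not confirmed:
            continue
        eplets[d.name] = replace(d, hla_class=cls, confirmed=confirmed)

    header, rows = _read_rows(assignment_table_path, delimiter)
    for col in ("allele", "eplet"):
        if col not in header:
            raise RegistryError(f"{assignment_table_path}: missing column {col!r}")
    assignments: dict[AlleleName, set[str]] = {}
    for i, row in enumerate(rows, start=2):
        try:
            allele = parse_allele_name(row["allele"].strip())
        except AlleleParseError as exc:
            if lenient:
                log.warning("%s line %d: %s (skipped)", assignment_table_path, i, exc)
                continue
            raise RegistryError(f"{assignment_table_path} line {i}: {exc}") from exc
        if allele.is_null and not include_null_alleles:
            continue
        name = row["eplet"].strip()
        if name not in eplets:
            if confirmed_only and _is_parseable(name):
                continue  # assignment of a dropped unconfirmed eplet
            msg = f"{assignment_table_path} line {i}: unknown eplet {name!r}"
            if lenient:
                log.warning("%s (skipped)", msg)
                continue
            raise RegistryError(msg)
        assignments.setdefault(allele, set()).add(name)

    registry = Registry(
        eplets=eplets,
        assignments={a: frozenset(s) for a, s in sorted(assignments.items())},
    )
    registry.validate()
    return registry


def _is_parseable(name: str) -> bool:
    try:
        parse_eplet_name(name)
    except EpletParseError:
        return False
    return True


def write_registry(
    registry: Registry,
    eplet_table_path,
    assignment_table_path,
    *,
    delimiter: str = "\t",
) -> None:
    """Write the two-table export; raw eplet names are preserved verbatim.

    Round-trips with :func:`read_registry` (alleles with empty assignment
    sets have no rows to write and are therefore dropped).
    """
    registry.validate()
    with open(eplet_table_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["name", "hla_class", "confirmed"])
        for name in sorted(registry.eplets, key=lambda n: (registry.eplets[n].start, n)):
            d = registry.eplets[name]
            w.writerow([name, d.hla_class or "I", str(bool(d.confirmed)).lower()])
    with open(assignment_table_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["allele", "eplet"])
        for allele in sorted(registry.assignments):
            for name in sorted(registry.assignments[allele]):
                w.writerow([allele.raw, name])
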