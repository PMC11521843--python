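"""Donor-recipient allele and eplet mismatch computation."""

import pytest

from epletatlas import (
    Genotype,
    GenotypeError,
    RegistryError,
    allele_mismatches,
    eplet_mismatches,
    parse_allele_name,
    read_pairs,
)
from epletatlas.fixtures import _make_registry
from epletatlas.mismatch import parse_genotype_field


def _genotype(subject, locus, text):
    g = Genotype(subject)
    g.add_locus(locus, parse_genotype_field(subject, locus, text))
    return g


@pytest.mark.parametrize(
    "recipient, donor, expected",
    [
        ("A*02:01/A*03:01", "A*02:01/A*30:01", {"A*30:01"}),
        ("A*02:05/A*32:01", "A*03:01/A*24:02", {"A*03:01", "A*24:02"}),
        ("A*02:01/A*03:01", "A*02:01/A*03:01", set()),
        ("A*02:01/A*02:01", "A*02:01", set()),  # homozygous both sides
    ],
)
def test_allele_mismatches_host_versus_graft(recipient, donor, expected):
    r = _genotype("R", "A", recipient)
    d = _genotype("D", "A", donor)
    assert {a.raw for a in allele_mismatches(r, d, "A")} == expected


def test_untyped_locus_raises():
    r = _genotype("R", "A", "A*02:01/A*03:01")
    d = _genotype("D", "A", "A*02:01/A*03:01")
    with pytest.raises(GenotypeError):
        allele_mismatches(r, d, "B")


def _toy_registry():
    return _make_registry(
        {
            "A*01:01": ("44KM", "62QE", "90D"),
            "A*02:01": ("62QE", "90D"),
            "A*03:01": ("44KM", "62QE", "90D"),
            "A*30:01": ("56R",),
            "B*07:01": ("44KM",),
        }
    )


def test_eplet_mismatch_is_donor_minus_recipient_repertoire():
    reg = _toy_registry()
    r = _genotype("R", "A", "A*02:01/A*30:01")
    d = _genotype("D", "A", "A*01:01/A*02:01")
    # donor mismatch A*01:01 carries {44KM, 62QE, 90D}; recipient covers
    # {62QE, 90D, 56R} -> only 44KM is foreign
    assert eplet_mismatches(reg, r, d, "A") == ["44KM"]


def test_full_repertoire_coverage_gives_zero_eplet_mismatches():
    reg = _toy_registry()
    r = _genotype("R", "A", "A*03:01/A*30:01")
    d = _genotype("D", "A", "A*01:01/A*30:01")
    # A*01:01 is an allele mismatch, but A*03:01 carries its whole repertoire
    r_mm = allele_mismatches(r, d, "A")
    assert {a.raw for a in r_mm} == {"A*01:01"}
    assert eplet_mismatches(reg, r, d, "A") == []


def test_all_eplets_returned_when_recipient_covers_none(cohort):
    registry, _ = cohort
    r = _genotype("R", "A", "A*02:01/A*68:02")
    d = _genotype("D", "A", "A*01:01/A*02:01")
    got = eplet_mismatches(registry, r, d, "A")
    assert len(got) == 8
    assert got == sorted(got, key=lambda n: (registry.eplets[n].start, n))


def test_missing_registry_allele_is_named():
    reg = _toy_registry()
    r = _genotype("R", "A", "A*02:01/A*30:01")
    d = _genotype("D", "A", "A*99:01/A*02:01")
    with pytest.raises(RegistryError, match="A\\*99:01"):
        eplet_mismatches(reg, r, d, "A")


def test_class_scope_pools_recipient_loci():
    reg = _toy_registry()
    r = Genotype("R")
    r.add_locus("A", parse_genotype_field("R", "A", "A*02:01/A*30:01"))
    r.add_locus("B", parse_genotype_field("R", "B", "B*07:01"))
    d = Genotype("D")
    d.add_locus("A", parse_genotype_field("D", "A", "A*01:01/A*02:01"))
    d.add_locus("B", parse_genotype_field("D", "B", "B*07:01"))
    assert eplet_mismatches(reg, r, d, "A", scope="locus") == ["44KM"]
    # recipient's B*07:01 also carries 44KM -> covered class-wide
    assert eplet_mismatches(reg, r, d, "A", scope="class") == []


def test_graft_versus_host_direction_swaps_roles():
    reg = _toy_registry()
    r = _genotype("R", "A", "A*01:01/A*02:01")
    d = _genotype("D", "A", "A*02:01/A*30:01")
    assert eplet_mismatches(reg, r, d, "A") == ["56R"]
    assert eplet_mismatches(reg, r, d, "A", direction="graft_vs_host") == ["44KM"]


def test_monotonicity_of_recipient_repertoire():
    reg = _toy_registry()
    d = _genotype("D", "A", "A*01:01/A*30:01")
    small = _genotype("R", "A", "A*30:01")
    big = _genotype("R", "A", "A*30:01/A*02:01")
    assert set(eplet_mismatches(reg, big, d, "A")) <= set(
        eplet_mismatches(reg, small, d, "A")
    )


def test_no_allele_mismatch_implies_no_eplet_mismatch():
    reg = _toy_registry()
    r = _genotype("R", "A", "A*01:01/A*02:01")
    d = _genotype("D", "A", "A*01:01/A*02:01")
    assert allele_mismatches(r, d, "A") == set()
    assert eplet_mismatches(reg, r, d, "A") == []


def test_read_pairs_parses_slash_dialect(tmp_path):
    path = tmp_path / "pairs.tsv"
    path.write_text(
        "pair_id\tlocus\trecipient_genotype\tdonor_genotype\n"
        "p1\tA\tA*02:01/A*03:01\tA*02:01/A*30:01\n"
        "p1\tB\tB*07:01/B*07:01\tB*07:01\n"
        "p2\tA\tA*02:01\tA*02:01\n"
    )
    pairs = read_pairs(path)
    assert [p.pair_id for p in pairs] == ["p1", "p2"]
    p1 = pairs[0]
    assert p1.loci == ["A", "B"]
    assert len(p1.recipient.at("B")) == 1  # homozygous collapses
    assert parse_allele_name("A*30:01") in p1.donor.at("A")


def test_read_pairs_rejects_cross_locus_genotype(tmp_path):
    path = tmp_path / "pairs.tsv"
    path.write_text(
        "pair_id\tlocus\trecipient_genotype\tdonor_genotype\n"
        "p1\tA\tA*02:01/B*07:02\tA*02:01\n"
    )
    with pytest.raises(GenotypeError, match="line 2"):
        read_pairs(path)
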