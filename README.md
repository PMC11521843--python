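# epletatlas

Tools for analysing HLA alleles in *eplet space*: the coordinate system
spanned by the polymorphic amino-acid residues of antibody-confirmed HLA
eplets.  The package is aimed at transplantation immunologists and HLA
laboratory scientists who want to go beyond allele-name matching — to see
which alleles are effectively identical to antibodies, which allele groups
blur into each other, and how many eplets a given donor–recipient mismatch
actually exposes.

## What it computes

* **Allele profiles** — each allele's eplets (e.g. `44KM`, `62QE`,
  `163LS/G`; the number is the 1-based position in the mature protein, the
  capital letters are residues, `/X` an alternative for the last position)
  are expanded and merged into a sparse polymorphic amino-acid sequence.
* **Disparity** — the distance between two alleles is the Hamming distance
  between their profiles: the number of positions with differing residue
  content.  Distances are defined within coordinate namespaces (A/B/C
  share one; DRB1/3/4/5 share one; DQA1, DQB1, DPA1, DPB1 stand alone).
* **Disparity graphs** — per allele group (`A*01`, `B*07`, ...), a
  1-nearest-neighbour graph linking every allele to all of its most
  similar peers.  Alleles strictly nearer to a *different* group are
  flagged **cross-reactive** and linked to their foreign neighbours, which
  join the graph as external nodes.  Distance-0 edges mark *monomorphic*
  alleles (identical confirmed-eplet content).
* **Motif plots** — per-position residue prevalence across a group or
  locus, as a table and a stacked-bar image.
* **Summaries** — per-group cross-reactivity tables with the
  frequent-eplet rule (eplets confirmed for >80% of the group, strictly)
  and per-locus overviews.
* **Mismatch reports** — for donor–recipient pairs: donor alleles absent
  from the recipient genotype, and the eplets of those alleles that the
  recipient's own repertoire does not cover (host-versus-graft).

A synthetic-registry generator with planted monomorphic cores, halo
distances and cross-reactive alleles makes the whole pipeline testable
without any registry download, and two small registries built from
published eplet lists are packaged for worked examples.

## Worked example

```python
import epletatlas as ea

registry = ea.example_registry()            # packaged, no download
atlas = ea.build_atlas(registry)

a0101 = ea.parse_allele_name("A*01:01")
profile = atlas[a0101]
print(len(registry.assignments[a0101]))     # 10 confirmed eplets
print(len(profile.positions))               # 21 polymorphic positions
seq, _ = ea.profile_to_sequence_string(profile, range(44, 91))
print(seq)
```

prints

```
10
21
KM................QE.RNA........ANTGT.........D
```

— A*01:01's ten confirmed eplets place 21 polymorphic residues; the
rendered window (positions 44–90) shows K44/M45 from `44KM`, Q62/E63 from
`62QE`, R65-N66-A67 from `65RNA`, and so on.  A*01:02 carries the same
confirmed eplets, so `ea.hamming_distance(atlas[a0101],
atlas[ea.parse_allele_name("A*01:02")])` is `0`: to antibodies recognising
confirmed eplets the two alleles are indistinguishable.

The packaged kidney-transplant cohort shows why eplet counting matters:

```python
registry, pairs = ea.cohort_registry(), ea.cohort_pairs()
reports = ea.mismatch_report(registry, pairs)
print(ea.frame_to_markdown(ea.report_frame(reports)))
```

| pair_id | locus | allele_mismatches | eplet_mismatches | mismatched_eplets |
| ------- | ----- | ----------------- | ---------------- | ----------------- |
| 1 | A | 1 | 1 | 56R |
| 2 | A | 1 | 8 | 44KM, 62QE, 76ANT, 138MI, 144KR, 163R, 163RG, 166DG |
| 3 | A | 2 | 5 | 62EE, 65GK, 144KR, 161D, 166DG |
| 4 | B | 1 | 1 | 158T |
| 5 | B | 1 | 6 | 41T, 45KE, 80TLR, 82LR, 156DA, 163LS/G |
| 6 | B | 2 | 6 | 41T, 44RMA, 45KE, 80TLR, 156DA, 163LS/G |
| 7 | C | 1 | 1 | 21H |
| 8 | C | 1 | 6 | 21H, 73TVS, 163LW, 173K, 193PV, 219W |
| 9 | C | 2 | 5 | 21H, 73TVS, 138K, 173K, 177KT |

A single mismatched allele can expose one eplet (pairs 1, 4, 7) or eight
(pair 2), and a double allele mismatch can expose *fewer* eplets than some
single mismatches (pairs 3, 9) — the case for counting eplets rather than
alleles.

## Command line

The `epletatlas` console script wraps the library; without
`--registry-eplets/--registry-assignments` it uses the packaged example
registry.

```sh
epletatlas --out out atlas                 # profile atlas (TSV + alignment)
epletatlas --out out motif A*01 --image m.png
epletatlas --out out graph B*07            # GraphML + DOT + JSON
epletatlas --out out summarize             # group and locus tables
epletatlas --out out mismatch pairs.tsv
epletatlas --out out simulate --seed 7     # synthetic registry + truth JSON
```

Registry tables are TSV with headers `name, hla_class, confirmed` (eplets)
and `allele, eplet` (assignments).  Pairs tables use
`pair_id, locus, recipient_genotype, donor_genotype` with slash genotypes
(`A*02:01/A*03:01`).

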