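# Methods

## The model

HLA molecules are the dominant targets of alloimmune responses after
transplantation, transfusion and pregnancy.  Antibody reactivity against a
mismatched HLA allele is driven not by the allele as a whole but by small
surface patches of polymorphic residues — *eplets* — of which each allele
carries a characteristic set.  `epletatlas` works entirely in this
eplet-defined "differential amino-acid space":

1. **Eplet expansion.**  An eplet name such as `44KM` encodes consecutive
   residues starting at a 1-based mature-protein position: K44, M45.  A
   trailing `/X` (e.g. `163LS/G`) is read as an alternative residue for the
   last enumerated position: L163 and S-or-G at 164.  The registry export
   never states this rule; it is isolated in `parse_eplet_name` so it can be
   revised in one place if registry practice turns out to differ.

2. **Allele profiles.**  An allele's profile is the union of the residue
   maps of its assigned (by default antibody-confirmed) eplets.  Where two
   eplets overlap, residue sets are merged by intersection; an empty
   intersection is surfaced as `ProfileConflictError` rather than patched,
   because it means the registry assigns incompatible residues to one
   position of one allele.  Real exports do contain such combinations (the
   alternative eplets 62GE/62GK can never sit on the same allele), which is
   why atlas construction offers a lenient mode that skips and logs
   conflicted alleles.

3. **Disparity.**  The distance between two profiles is the number of
   positions with differing amino-acid content (a Hamming distance).  Two
   design points are not derivable from the verbal definition and are
   therefore explicit options:
   * *Coverage* (`policy`): alleles cover different position sets.  The
     default `difference` policy counts a position covered by only one
     profile as a difference — absence of a confirmed polymorphism is itself
     a repertoire difference.  `shared_only` restricts to jointly covered
     positions.
   * *Alternative residues*: sets compare by intersection, so `S/G` vs `G`
     is a match.  With alternatives present the distance is not guaranteed
     to be a metric (overlap is not transitive); with singleton residue
     sets and the default policy it is a true Hamming distance over a
     gap-extended alphabet and satisfies the triangle inequality
     (property-tested).

4. **Coordinate namespaces.**  Distances are only defined between loci with
   comparable mature-protein numbering: class I heavy chains (A, B, C) form
   one namespace, the DRB chains (DRB1/3/4/5) another, and DQA1, DQB1, DPA1
   and DPB1 each stand alone.  The partition is a configurable table; the
   default reflects the inter-locus similarities that are actually reported
   in practice (B–C, DRB1–DRB3/5).

5. **Disparity graphs.**  Per allele group (the first nomenclature field,
   e.g. `A*01`), every allele is connected to *all* of its minimal-distance
   neighbours — a 1-nearest-neighbour graph without arbitrary tie-breaking,
   so the data structure is deterministic and layout-free.  An allele
   strictly nearer to another group than to its own is *cross-reactive* in
   the computational sense; its foreign nearest neighbours are added to the
   graph as external nodes.  Ties resolve to the own group, which avoids
   inflating cross-reactivity counts.  A singleton group has no own-group
   distance and its allele is trivially cross-reactive whenever any foreign
   allele exists — this reproduces the degenerate pattern of DPB1, where
   almost every allele is its own group.  Distance-0 edges link
   *monomorphic* alleles (identical residue maps); equality of maps is
   transitive, so monomorphic clusters are genuine equivalence classes.

6. **Summaries.**  Group summaries report the number and fraction of
   cross-reactive alleles and, per foreign group, the count of *distinct*
   foreign alleles involved (alleles, not edges).  The frequent-eplet rule
   is strict: an eplet qualifies when confirmed for strictly more than 80%
   of the group's alleles (4/5 = 0.8 is excluded; the boundary is
   unit-tested).  Locus overviews round the average group size and the
   cross-reactive percentage to the nearest integer.

7. **Mismatch counting.**  For a donor–recipient pair, allele mismatches at
   a locus are the donor alleles absent from the recipient's genotype
   (host-versus-graft; the opposite direction is available as an option).
   Eplet mismatches are the union of the mismatched donor alleles' eplets
   minus the recipient's repertoire; by default the repertoire is the same
   locus (matching how per-locus tables are reported), optionally all typed
   loci of the same HLA class.  Eplets shared by two mismatched donor
   alleles count once.

## Packaged registries

No registry download is needed.  Two small registries are bundled, both
built exclusively from published eplet lists:

* `example_registry()` — A*01:01 with its 10 confirmed eplets, the
  monomorphic partner A*01:02 (identical confirmed eplets; the two
  unconfirmed eplets 9S/17S that separate the pair are included only under
  `confirmed_only=False`), and representative alleles carrying the
  frequent-eplet signatures of 30 common HLA-A/-B/-C groups.  Signatures
  containing mutually incompatible alternatives (62GE/62GK; 80TLR/82LR) are
  split over two representative alleles, since no single allele can carry
  both.
* `cohort_registry()` / `cohort_pairs()` — nine kidney-transplant
  donor–recipient pairs with class I genotypes and a registry reconstructed
  from the published per-pair mismatched-eplet lists.  Where the same donor
  allele appears in two pairs with different printed lists, the eplets
  missing from one list must be covered by that pair's recipient; these
  logically entailed coverage assignments are encoded explicitly (they are
  the only assignments not printed verbatim).  This registry reflects a
  different registry snapshot than the A*01:01 example (it assigns 163R to
  A*01:01), and the two are deliberately kept separate.

## The synthetic-data generator

`simulate_registry` emulates the structures seen in real group disparity
graphs: each group has a **monomorphic core** (identical eplet sets), a
**halo** of alleles differing from the core at exactly
`halo_mutation_distance` positions, and optionally **planted cross-reactive
alleles** carrying a foreign group's signature with one substituted residue.
Construction is combinatorial: every group owns a disjoint block of
`n_positions` coordinates (defaults: 2 loci × 3 groups × 8 alleles, core 3,
8 single-residue signature eplets per group, halo distance 2, 2 planted
cross-reactive alleles), so all planted distances hold exactly by
construction — cross-reactivity is planted by eplet sharing, never by
editing a distance matrix.  Residue choices for halos and planted alleles
are arranged so that no two alleles collide accidentally (no spurious
distance-0 pairs) and every planted inequality is strict; parameter
combinations that cannot guarantee this raise `SimulationError` before
anything is emitted.  All randomness flows through one seeded `random.Random`
and everything else is integer arithmetic, so a seed determines the
registry byte-for-byte across platforms.

What the generator does **not** emulate: realistic allele frequencies,
realistic eplet sizes (simulated eplets are single residues), overlapping
eplets, shared positions between groups, or registry inconsistencies.
Passing recovery tests therefore show that the pipeline's algebra is
correct on cleanly separable structure; they do not validate biological
conclusions on a real registry, for which `scripts/validate_registry.py`
accepts a user-supplied export.

## Numerical and design choices

* Coordinates are 1-based mature-protein positions everywhere in the public
  interface; no 0-based conversion occurs anywhere.
* Null-expressed alleles (`N` suffix) are dropped on registry read by
  default (`include_null_alleles=True` to keep them).
* Percentages in locus tables round half away from zero (`int(x + 0.5)`);
  group-level fractions are kept exact and only rendered as percentages.
* Graph, GraphML, DOT and JSON serializations sort nodes and edges, so
  identical inputs give byte-identical artifacts; images (matplotlib,
  seeded spring layout) are a thin layer over these serializations and are
  never asserted on.
* Registry reading validates referential integrity (assignments must
  reference defined eplets) and HLA-class consistency (class I loci carry
  class I eplets only); `lenient` downgrades unparseable rows to warnings.
* Alleles with zero confirmed eplets cannot be placed in differential
  amino-acid space; they are omitted from atlases with a logged warning and
  dropped by `write_registry` (which emits one row per assignment).

## Problem sizes

The test suite and the acceptance script run the oracle-equivalence check
on 50 random registries of 20–60 alleles, the planted-recovery check on 20
simulated registries (48 alleles each), and the motif-conservation check on
10 random atlases; these sizes give exhaustive pairwise coverage in seconds
while exercising every tie-breaking and namespace path.  Larger registries
(the full ~2,000-allele scale) are supported but not exercised by default.

## Known limitations

* The eplet grammar covers names of the forms `INT RESIDUES [/RESIDUE]`;
  decorated registry names (paired or quantified eplets) are rejected with
  a parse error rather than guessed at.
* With multi-residue alternatives the distance is not a metric; downstream
  code never assumes the triangle inequality.
* Published group tables report percentage denominators that are not always
  recomputable from their own counts; this package always uses the focus
  group's allele count as the denominator and makes no attempt to reproduce
  snapshot-dependent table cells.
* Cross-reactivity here is a nearest-neighbour statement in eplet space; it
  is related to, but not identical with, serological cross-reactive groups.
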