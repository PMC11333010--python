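# Methods

## Topology model

A pure parallel β-sheet topology is the left-to-right occupant list of an
open sheet whose strands, numbered 1..n from the N-terminus, all point the
same way.  Left-right mirror images are the same physical object, so the
canonical representative is the lexicographically smaller of the occupant
list and its reversal; this yields n!/2 classes per strand count and 435
classes for n = 3–6.  Strings are accepted in an arrow dialect ("2↑1↑3↑")
and an ASCII dialect ("2-1-3" / "213"); down arrows are rejected because
mixed-orientation sheets are out of scope.

**Connection geometry.**  Strands k and k+1 are joined by a crossover
connection through an α-helix.  Right-handedness is assumed for every
crossover (the overwhelmingly dominant case in real structures), which ties
the face the helix packs against to the crossing direction: rightward
crossings (Δ = p(k+1) − p(k) > 0) on one face, leftward on the other.  The
face labels "front"/"back" are a convention; every derived quantity is
invariant under the global flip.  A connection skipping more than two
intervening strands (|Δ| ≥ 4) is flagged long-distance.

**Clash rule.**  Each crossover arc descends from the C-terminal top of
strand k to the N-terminal bottom of strand k+1, so all same-face arcs run
in the same horizontal direction.  Two same-face arcs therefore cross if
and only if one position span strictly contains the other (nested spans);
interleaved spans give parallel, non-crossing arcs, and spans sharing an
endpoint (consecutive connections) never cross.  A topology is clash-free
when no same-face pair of connections is properly nested.  This geometric
rule is validated two ways in the tests: a literal segment-crossing
simulation over all small-n topologies, and the exhaustive census (167 of
435 clash-free, terminal-edge probability 62/167 = 37.1% for both termini).

**Frustration.**  N_j counts connections with |Δ| > 1 (jumps).  N_FαβP
counts unordered connection pairs {k, m} whose downstream strands k+1 and
m+1 sit at adjacent sheet positions (a parallel hydrogen-bonded pair) while
the two helices lie on opposite faces; such a pairing cannot satisfy the
right-handedness, αβ-orientation and N-terminal register-shift rules at
once, whereas its chain reversal — governed by the βα-unit and C-terminal
register-shift rules — can.  Frustration-free ⇔ (N_FαβP = 0 and N_j ≤ 1);
14 of the 167 clash-free topologies qualify.  Because reversal preserves
N_j and clash-freeness but not N_FαβP, exactly 23 clash-free
topology/reverse pairs differ in frustration; these are the pairs whose
real-world occurrence statistics are so lopsided.

Grid summaries bin N_FαβP as 0/1/2+ (rows) against N_j = 0..5 (columns);
percentages are printed to one decimal, rounding half-up.  βRCO is the mean
strand-index separation over the n − 1 sheet-adjacent pairs, normalised by
n, hence in [1/n, (n−1)/n].

## Lattice model

Chains of L residues are self-avoiding walks on the square lattice,
enumerated exhaustively modulo the 8 lattice symmetries (canonical form:
first point at the origin, first step +x, first off-axis step +y; 802,075
walks at L = 16).  Sequences are binary H/P strings.  The energy is
E = −ε_HH·n_HH + ε_penalty·n_penalty with defaults ε_HH = 1.0,
ε_penalty = 2.0.

**Motif templates.**  The penalty motifs are the 5-residue walks with turn
sequences S-L-S, S-L-L and S-L-R (S = straight, L/R = turns); the
frustrated local structure (FLS) is their common 4-residue prefix, a
straight step followed by a turn.  Matching is direction-aware (the N→C
orientation of the window must agree with the template) over all 8
point-group images, images deduplicated, one count per matching window,
overlapping windows all counted (a non-overlapping greedy mode exists for
sensitivity analysis only).  The template set is not free-floating: it is
pinned by the frustration-verification properties — every self-avoiding
one-residue C-terminal extension of the FLS contains a penalty motif, the
FLS itself contains none, and the reverse FLS extends on both ends
penalty-free — which `verify_fls_frustration` re-derives and which the
designability scan enforces before running.

**N_FLS counting.**  An FLS whose window ends at the chain's C-terminal
residue cannot be completed into a penalised shape and is therefore not
frustrated; N_FLS counts only the frustrated (interior) occurrences.  The
energy term n_penalty, by contrast, counts penalty-motif windows everywhere.
This distinction matters: it is what makes the maximally designable
structure's statistics (and the 48-structure compact FLS-free region) come
out as they do.

**Designability scan.**  For every sequence the ground-state energy over
all conformations and the exact number of conformations attaining it are
computed.  Conformations are grouped by (contact set, n_penalty) with
multiplicities — at L = 16 this compresses 802,075 conformations into
~49k classes — and energies are compared as exact scaled integers
(parameters are converted to integers via their rational form, e.g.
ε_penalty = 0.1 scales everything by 10), so ties are detected exactly.  A
sequence is protein-like iff exactly one conformation attains its minimum;
a class of multiplicity > 1 at the minimum disqualifies uniqueness.  The
per-structure designability N_s sums to the protein-like count by
construction, and the grouped kernel is checked against an independent,
ungrouped per-conformation float-energy census at L = 10.

Contact sets are stored as 64-bit masks over the possible non-covalent
adjacent pairs (odd separation ≥ 3; 49 pairs at L = 16), which caps the
exhaustive enumeration at L = 18 and the 2^L sequence scan at L = 16.  RCO
is the mean contact separation divided by chain length, undefined (NaN/None)
for contact-free structures.

**Robustness sweep.**  The acceptance suite re-runs the full L = 16 scan at
ε_penalty ∈ {0.1, 0.5, 1.0, 3.0, 4.0} (each scan takes seconds with the
numba kernels) and asserts the qualitative invariants: heavy-tailed
designability distributions, the FLS-free member of every unequal
structure/reverse pair out-designing its reverse in a strict majority of
cases (empirically: in all of them), and, at ε_penalty = 4.0, no penalised
structure surviving as any sequence's unique ground state.

## OFHT statistic

OR(T, i) is the mean over H-group i's F-groups of the fraction of each
F-group's domains labelled T; OFHT(T) = Σ_i OR(T, i).  Unlabelled domains
(no qualifying pure parallel sheet) stay in the denominators and feed no
numerator, so Σ_T OFHT(T) = N_homology exactly when every domain is
labelled, and less otherwise.  Labels are canonicalised on ingest so
flip-equivalent spellings aggregate.  Categories: superfold (OFHT ≥ 3,
inclusive), normal (0 < OFHT < 3), unobserved (0); observations outside the
supplied universe are kept in a separate bucket rather than silently
dropped.

Topology derivation from sheet records applies four criteria in order:
(i) every sheet-adjacent strand pair carries a declared parallel pairing
(any antiparallel pairing or non-up strand rejects), (ii) the sheet is open
(no barrel), (iii) the domain's strands belong to a single sheet — the
stricter of the two possible readings, with the laxer "no strand shared
with another sheet" available via `strict_single_sheet=False` — and
(iv) every inter-strand loop is shorter than 100 residues.  Rejections are
typed with the failed criterion.  Records with multiple candidate sheets
must be split upstream; the schema carries one sheet per record.

## Synthetic data generator

The table generator emulates the features the statistic is sensitive to:
a fixed H-group ⊃ F-group ⊃ domain hierarchy; a heavy-tailed global
topology-frequency distribution drawn by stick-breaking (Beta(1, 1/skew)
sticks, so larger `skew` concentrates mass on fewer topologies); a
multiplicative down-weighting (`frustration_bias`, default 0.08) of
topologies with N_FαβP > 0 or N_j > 1, mirroring their observed rarity;
within-family label rigidity (families are evolutionarily related; a family
inherits its H-group's dominant topology with probability 0.85); and an
unlabelled fraction (default 0.55) of domains without a pure parallel
sheet.  Defaults (30 H-groups, 1–6 families each, 1–20 domains per family)
give tables of a few hundred domains — large enough for stable statistics,
small enough for fast tests.  Each generator owns an independent seeded
stream, so adding one does not perturb another's output; identical specs
yield byte-identical tables.

What the generator does *not* emulate: real ECOD identifier conventions,
sequence content, 3D coordinates, the empirical shape of the real OFHT
histogram, or any correlation between topology frequency and domain count
per family.  Tests passing on synthetic tables therefore validate the
bookkeeping (formulas, normalisation identities, invariances, category
partitions), not any empirical claim about the PDB.

## Problem sizes and numerical choices

The package's own test suite runs the topology census at full scale
(n = 3–6), the lattice study at full scale (L = 16, all 2^16 sequences,
including the five-point penalty sweep), the naive-oracle designability
cross-check at L = 10, and the naive-enumeration cross-check at L = 12 in
the acceptance suite (L = 4–8 in unit tests); these sizes keep the whole
suite in the low minutes on one CPU.  Exact integer arithmetic removes any
tolerance question from the scan; floating point appears only in βRCO, RCO
and OFHT values, asserted to 1e-9-style relative tolerances.  Degenerate
inputs are defined explicitly: contact-free structures have undefined RCO,
empty topology selections summarise to explicit zeros, and an empty or
fully unlabelled table scores every topology 0.

## Known limitations

* Only pure parallel, single-sheet, open topologies are representable; the
  frustration calculus does not extend to mixed or antiparallel sheets.
* Clash detection and face assignment operate on the abstract diagram;
  they assume uniform right-handedness and cannot capture rescue by rare
  left-handed crossovers.
* The lattice study is 2D and ground-state-only (no thermodynamic
  ensembles, no kinetics); chain length is capped by the exact-mask design
  (L ≤ 18 enumeration, L ≤ 16 scan).
* Real structure ingestion (PDB/mmCIF parsing, secondary-structure
  assignment, register-shift measurement) is deliberately out of scope; the
  TSV/JSON schemas are the boundary where such data enters.
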