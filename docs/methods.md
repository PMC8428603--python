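# Methods

## Data model

A **contact map** over a sequence of length L is a sparse symmetric set of
scored residue pairs, stored once per pair in canonical order i < j with
1-based indices (the convention shared by RR files and PDB numbering) and
queryable in either orientation. Raw predictor output may contain both
triangle orders and duplicates; canonicalization folds (j, i) onto (i, j) and
keeps the **maximum** score of duplicates, since predictors that emit both
orders occasionally disagree between them and the larger confidence is the
one a user would act on. Self-contacts (i = j) are rejected outright.

A **distogram** attaches to each pair a probability vector over contiguous
distance bins (lower, upper] in Å. The default layout is the ten bins
(0,4], (4,6], …, (18,20], (20,∞) commonly used for binned-distance exchange
formats; the bin edges are a configuration parameter, not a constant, because
the exchange format itself does not fix them. Parsed vectors must sum to 1:
deviations up to 0.01 are renormalized (predictors round their output),
larger deviations are rejected as corrupt. After parsing and after any
transformation, vectors sum to 1 within 1e-6.

Collapsing a distogram to a contact map at a threshold t sums the mass of
all bins whose **upper edge is ≤ t**; t must coincide with a bin edge, and no
interpolation inside a bin is attempted. The inclusive upper edge matches the
contact convention d ≤ cutoff: a pair known to lie in (6,8] is a contact at
the 8 Å cutoff. With uniform mass over the ten default bins the score at
8 Å is therefore 0.3 (three bins end at or below 8).

An **annotation track** is a per-residue list of categorical states (H/E/C,
inside/outside/membrane/signal, conservation grades "1"–"9", or user-defined
labels), optionally with a real value per residue, plus a palette covering
every state that occurs.

## Contact extraction from models

One representative atom is chosen per residue: Cβ, falling back to Cα for
glycine or when Cβ is missing (the CASP assessment convention), with a pure
Cα scheme available. Two residues are in contact iff their representative
atoms lie within the cutoff, default **8 Å**, at sequence separation ≥
`min_sep`. Neighbour search uses a k-d tree; the test suite holds it equal to
a brute-force all-pairs oracle on random structures up to 200 residues, and
checks invariance under rigid-body motion and monotonicity in the cutoff.
Author residue numbers are preserved for reporting, but positions are
renumbered 1..N in chain order so model maps align with prediction maps;
numbering gaps are reported, never silently closed. Altloc conformers resolve
to the highest occupancy; residues lacking both Cβ and Cα are skipped with a
warning.

## Superposition and satisfaction

Given a predicted map P and model map M of equal length (comparison refuses
maps whose sequences are both known and disagree — aligning mismatched
sequences is out of scope), both are filtered to separation ≥ `min_sep` and
partitioned into matched = P ∩ M, model-only = M \ P, predicted-only = P \ M.
The three sets are disjoint and their union is P ∪ M by construction; the
display colours are black / red / grey respectively.

The satisfaction statistic selects the `top_n` highest-scoring predictions
(ties break by ascending (i, j) so output is deterministic), applies the
separation filter, and reports |matched| / |selected|. Defaults are the
standard evaluation conventions: `min_sep` = 23 (long-range) and `top_n` =
⌊L/2⌋. When no predictions survive selection the score is 0.0 with an
explicit warning rather than a division error. Note the statistic is not
monotone in `min_sep` in general — raising the cut-off removes predictions
from numerator and denominator alike — so the tests verify it against the
brute-force definition across a sweep instead of asserting a trend.

## Figure geometry

The plot is the square [1, L]² with residue i on x, j on y, origin at the
bottom left; the upper-left triangle (j > i) and lower-right triangle can
carry different maps of the same sequence. Contacts with |i − j| below the
blanking cut-off (default 5, matching the custom of omitting sequential
near neighbours) are excluded from the data layers.

Annotation tracks occupy nine slots k = −4…+4. Slot k is the diagonal band
of signed offset o = j − i in [k·w − w/2, k·w + w/2), where w is the band
width in residue units (default 2). The half-open interval makes bands of
distinct slots disjoint — rasterizing the square at integer cells assigns
each cell to at most one slot. Slot 0 straddles the diagonal; mirroring
copies slot +k's track into slot −k, whose band is the reflection across
i = j (mirroring slot 0 is a no-op). With four slots per side at w = 2 the
track zone reaches |i − j| ≤ 9, so the scene builder warns when the blanking
cut-off would let plotted contacts overlap tracks (the demo uses a display
cut-off of 10 for this reason).

A track's maximal run of identical states over residues [a, b] becomes one
coloured segment: the part of the band whose diagonal position (i + j)/2
lies in [a − ½, b + ½], clipped to the square. Clipping can swallow a very
short run at the extreme ends of an outer slot; segment counts otherwise
equal the run-length encoding of the state list. Runs whose palette colour
is "none" (the background of custom tracks) are not drawn.

Heatmap mode colours cell (i, j) either by contact probability (a scored
map, or a distogram's mass below the contact threshold) on a viridis scale,
or by the distogram's expected distance, using bin midpoints with the
open-ended last bin represented by its lower edge + 2 Å.

## Rendering

Output is static PNG or SVG via matplotlib: square aspect, axes labelled
with residue indices, a legend listing every (track, label) colour pair once.
SVG output is byte-deterministic for a fixed scene and library version (the
SVG hash salt is pinned, no timestamp metadata is written, and text is kept
as text rather than glyph paths), which makes golden-file comparison
possible.

## Default palettes

Topology: blue outside the cell, yellow inside, light red for transmembrane
segments, grey for signal peptides. Secondary structure: red helix, green
coil; strand is yellow (a package choice — common display conventions fix
only helix and coil). Conservation: a nine-step blue gradient, darker =
more conserved. Disorder: residues with IUPred score ≥ 0.5 are "disordered"
(the boundary counts as disordered). Every palette is overridable.

## Synthetic data

The fixtures module generates all test inputs programmatically.

The **ideal helix** generator places Cα atoms on a helix with 1.5 Å rise and
100° twist per residue at radius 2.3 Å (Cβ 1.5 Å further out) — the α-helix
geometry — so (i, i+3) and (i, i+4) pairs fall inside the 8 Å cutoff while
(i, i+5) falls outside, producing the classic near-diagonal band.

The **demo scenario** (length 140) emulates a membrane-protein analysis with
two re-entrant segments at residues 16–42 and 105–131: each is a pair of
short helices with a central two-residue break, modelled as two antiparallel
helical hairpins packed in parallel planes 6 Å apart so the two segments are
in mutual long-range contact. Helix interiors are simplified to straight
1.5 Å-spaced backbones, and all remaining residues sit on a well-separated
extended line; this reproduces the contact-map topology of such a fold (the
near-diagonal bands, hairpin ladders and long-range packing patches), not
its atomic detail. The predicted map keeps a random 80 % of the model's
contacts with confidences in [0.70, 0.99] and adds 20 long-range decoys with
confidences in [0.30, 0.99], so the superposition exhibits all three contact
classes and the satisfaction score is high but imperfect. Accompanying
tracks (topology with the central breaks, helix/coil states, conservation
concentrated in the re-entrant segments, purple custom-track segments over
16–42 and 105–131) are consistent with the structure by construction. All
randomness flows through one seeded generator; a fixed seed reproduces the
bundle byte for byte.

Because the generator writes exactly the dialects the parsers read and its
geometry is idealized, passing tests demonstrate correctness of parsing,
set algebra, geometry and scoring — they do not exercise the messier
corners of real predictor output (unusual headers, per-method TOPCONS
sections beyond the consensus block, models with missing density) beyond the
specific lenient behaviours tested.

## Numerical and format choices

- RR text has no explicit length field; a parsed map's length is the maximum
  residue index unless a sequence line supplies it. Round-trip tests
  therefore anchor one contact at the final residue.
- Scores are serialized at six decimals; round-trip equality tests use
  scores exactly representable at that precision.
- In the custom-track dialect, `#` begins a comment only at the start of a
  line, so hex colours remain parseable; later instructions win on overlaps
  within a slot; uncovered residues take an undrawn background state.
- Band/segment polygons are computed by exact polygon clipping; degenerate
  (zero-area) intersections are dropped.
- Problem sizes in the test suite (map pairs up to L = 100, structures up to
  N = 200, 500 round-trips) keep the full suite and the acceptance script in
  the tens of seconds while covering the combinatorics; all oracles are
  independent reimplementations (set algebra, all-pairs distances,
  sort-then-slice, run-length encoding).

## Known limitations

Single chain, single model: inter-chain contacts, ensembles and 3D
superposition are out of scope, as are interactive (web) displays and
session management. Sequence alignment of mismatched inputs is refused, not
attempted. mmCIF input is not supported. The satisfaction statistic is a
precision proxy, not a full model-quality estimate (no lDDT/CAD, no
per-residue profiles).
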