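# Methods

`moleculecloud` builds cloud diagrams of the most frequent substructures in
a molecule collection: the size of each depicted structure encodes the
(log-transformed) frequency of molecules containing it, in direct analogy
to word clouds for text. This note documents the model, the algorithms, the
defaults and their rationale, and the limits of what the synthetic test
fixtures demonstrate.

## Substructure reduction

Every molecule is represented by exactly one reduced structure:

* **Scaffold** (ring-containing molecules): the Murcko-style framework —
  all ring atoms, plus all *linker* atoms lying on a path between two ring
  systems, plus (by default) atoms attached to that framework by a double
  or triple bond, such as the oxygen of a ring carbonyl or the oxygens of a
  sulfonyl linker. Everything else (single-bonded side chains) is removed.
  Linkers are found by iteratively deleting non-ring atoms of degree one
  until fixpoint; whatever survives next to the rings necessarily lies
  between them.

  Retaining multiply-bonded exocyclic atoms is the established framework
  convention and maximizes comparability with standard scaffold tools; the
  `keep_exocyclic=False` switch yields the bare ring-and-linker skeleton
  instead. One chemical subtlety: removing the substituent of a pyrrole-type
  aromatic nitrogen (e.g. the N-methyls of caffeine) must restore that
  nitrogen's hydrogen, or the ring can no longer be kekulized; the package
  does this at the removal boundary, and the result agrees with RDKit's
  independent Murcko implementation on every case we test.

* **Major chain** (ring-free molecules): the longest simple path through
  heavy atoms; among equally long paths the one with the most heteroatoms;
  any residual tie broken by the lexicographically smallest canonical
  SMILES, which makes the choice deterministic across platforms. Acyclic
  molecules are trees, so the path between two atoms is unique and all
  simple paths can be enumerated as atom pairs — the implementation ranks
  those, and the tests rank the output of exhaustive path enumeration.

* **Substituents** (optional mode): every single bond from a framework atom
  to a non-framework atom is cut; detached fragments with at most
  `max_atoms` heavy atoms (default 15; the attachment dummy `*` does not
  count) are collected.

Aggregation keys are canonical SMILES with stereochemistry stripped (the
cloud shows flat 2D cores, so stereoisomeric scaffolds should pool) and
salts reduced to their largest covalent fragment. Charges and isotopes pass
through unchanged. Aromaticity perception is delegated entirely to RDKit's
default model. Unparseable inputs are skipped and counted, never fatal.
Reduction results are cached per distinct input SMILES, so collections with
many repeated structures aggregate in time proportional to the number of
distinct molecules.

## Selection and size scaling

Substructure frequencies in real databases follow a long-tail power law, so
raw counts are unusable as a size scale. The display set is formed by:

1. **Stop-structure removal** — benzene by default. It is the most frequent
   scaffold in essentially every large collection and carries no
   information, exactly like "the" in a text cloud. Matching is by
   canonical-SMILES equality, not substructure.
2. **Top-N selection** (default 200; 100–250 reads well at screen size),
   frequency-descending, ties by canonical SMILES.
3. **Log-linear magnification**: a structure with frequency *f* gets scale
   `min_scale + (max_scale − min_scale)·(log f − log f_min)/(log f_max − log f_min)`,
   with defaults 1.0 and 3.5 so the 30–50 most frequent structures are
   easily recognizable while the rest fill the background. The scale
   multiplies linear dimensions (width and height), not area; when all
   frequencies are equal the midpoint is used.

Because natural depiction sizes vary with the canvas and the number of
structures, the pipeline then rescales all frames uniformly so their summed
area is a fixed fraction (`fill_fraction`, default 0.45) of the canvas.
This preserves the relative log-frequency sizes while making any requested
image size work; the factor is capped so no frame exceeds 60% of a canvas
side.

## Two-pass layout

The layout engine operates purely on rectangles (the frames of the scaled
depictions); no chemistry is involved.

**Pass 1 — greedy placement.** Items are sorted by frame area, largest
first. The largest is pinned to the canvas center. Each subsequent item is
evaluated at every point of a regular grid whose frame fits fully inside
the canvas, scored by

```
score(p) = w_overlap · Σ_q overlap_area(p, q)  +  w_distance · Σ_q ‖center(p) − center(q)‖
```

over the already-placed items *q*, and fixed at the minimum-score point.
The distance term is a gentle compaction force: it pulls structures toward
the occupied region rather than letting them scatter. Its default weight is
the reciprocal of the canvas diagonal, so separating an item by a full
canvas costs about one unit square of overlap; `w_distance = 0` disables
compaction. Ties go to the first candidate in row-major scan order — no
randomness is involved anywhere, which is why two runs are byte-identical.

The grid pitch defaults to one quarter of the median frame dimension,
capped at 200×200 points: fine enough that a zero-overlap position is found
whenever one exists at realistic densities, coarse enough that a
200-structure layout takes seconds.

**Pass 2 — iterative refinement.** Sweeps visit every item in order; each
item tries nine candidates (stay, or one `step_size` move in each compass
direction), scored by the terms of the *total* objective that the move can
change (its pairwise terms plus its corner penalty), and accepts the best
candidate only if it strictly lowers the total. The total is therefore
non-increasing by construction — the property the tests assert on every
sweep. When a sweep improves less than the tolerance (default 10⁻⁶ of the
initial total) the step is halved, down to a floor of 1/16 of the initial
step, after which refinement stops; `max_iterations` (default 500) bounds
the sweep count. Candidate positions whose frame would cross the canvas
boundary are skipped, so frames remain inside the canvas at all times.

Optional corner repulsion adds `corner_strength · Σ 1/(ε + d_corner)` per
item, a mild potential pushing the layout into an oval; ε is 10⁻⁶ of the
canvas diagonal, so the penalty is finite even exactly at a corner. It is
off by default because the greedy pass already produces a centered oval.

## Color coding

Two schemes carry extra information on a rounded background box behind a
structure (5% padding, a fixed RGB palette pinned for reproducible output):

* **Activity intensity**: magenta with opacity equal to the fraction of
  bioactive molecules among those containing the scaffold; linear, and no
  box at ratio 0.
* **Target class**: six classes — GPCR (magenta), kinase (blue), protease
  (red), other enzyme (green), nuclear receptor (brown), ion channel
  (yellow). The box takes a class color only if at least 70% (inclusive;
  configurable, must exceed 50%) of the scaffold's molecules hit that one
  class; scaffolds with mixed activity stay uncolored.

## Depiction providers

All chemistry needed for rendering — parsing, canonicalization, measuring a
structure's natural extent, drawing — sits behind a small provider
interface, so the layout and composition code is toolkit-independent. The
default provider uses RDKit (SVG and Cairo/PNG backends; natural extent
from the 2D coordinate bounding box at 22 px/Å plus a 14 px margin). A mock
provider that renders labelled boxes sized by SMILES length makes the whole
pipeline testable with no depiction engine at all. Structures that fail to
depict are skipped with a warning; composition continues. Final images are
SVG 1.1 (primary) or PNG; structures are painted in ascending area so the
large ones are never fully hidden.

## Synthetic fixtures

The fixture generator emulates the statistical shape of real collections:
rank-*r* scaffold frequency proportional to *r*^(−exponent) (default 1.5),
integer-rounded to conserve the requested molecule total exactly, over a
built-in library of ~60 common ring systems (extended deterministically by
ring–ring couplings when more scaffolds are requested). The molecule-level
generator decorates each scaffold with random single-bonded C/N/O/halogen
side chains — which scaffold reduction removes again by construction — and
can attach per-molecule activity flags or target-class labels with a
dominant class per scaffold. Everything is deterministic under a seed.

What the fixtures do **not** emulate: real structural diversity (they reuse
a fixed scaffold library), parse failures and exotic valence states found
in raw database exports, correlation between scaffold size and frequency,
and database-scale singleton tails (half of all scaffolds in a 35M-molecule
collection occur once; a 10⁵-molecule fixture with 300 scaffolds has none).
Passing tests therefore demonstrate correctness of the reduction,
selection, layout and rendering machinery — not robustness to every
real-world SMILES, nor the visual character of a database-scale cloud.

## Problem sizes and numerical choices

The test suite and the acceptance run use desk-scale instances chosen as
the package's own defaults: 10⁵-molecule collections (aggregation and
end-to-end runs), 150–300 distinct scaffolds, 200 displayed structures,
layout oracles on ≤5 rectangles over ≤10×10 grids where exhaustive search
is exact, and refinement checks on 150-rectangle power-law instances.
Floating-point determinism is part of the contract: identical inputs give
bit-identical coordinates and byte-identical SVG. Degenerate inputs are
defined, not special-cased: one item lands at the canvas center; equal
frequencies scale to the midpoint; an all-stop-structure input is a
user-facing error.

## Known limitations

* Rectangles only: no rotation, no mask shapes, no spiral layouts.
* Hill climbing is local; it polishes the greedy layout rather than finding
  a global optimum, and with `w_distance > 0` it may trade a little overlap
  for compactness (the overlap term can rise while the total falls).
* The substituent mode records fragment frequencies only; it does not
  implement full substituent-analysis methodology.
* No interactive output; SVG is static.
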