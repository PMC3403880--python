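# moleculecloud

Compact visualization of large molecule collections as a **molecule
cloud**: the collection is reduced to its scaffolds (ring-free molecules to
their major chains), the most frequent ones are kept, and each structure is
drawn at a size proportional to the logarithm of its frequency — so one
glance at the image shows what the data set is made of. The idea is the
chemical analogue of a word cloud, and it is aimed at the everyday tasks of
cheminformatics and medicinal-chemistry groups: profiling a screening deck,
comparing vendor catalogues, summarizing HTS hit lists or bioactivity
databases.

## Method

* **Reduction.** A molecule with rings is represented by its framework:
  ring atoms, linker atoms on paths between rings, and atoms multiply
  bonded to either (a ring carbonyl oxygen stays; single-bonded side chains
  go). A ring-free molecule is represented by its longest heavy-atom chain,
  ties broken by heteroatom count. Identical cores aggregate by canonical
  SMILES; frequencies are molecule counts.
* **Selection and scaling.** Ubiquitous stop-structures (benzene by
  default) are removed like stop words; the top *N* (default 200) remaining
  cores are kept, and each is magnified by linear interpolation in
  log-frequency between a minimum and maximum scale, since scaffold
  frequencies follow a long-tail power law.
* **Layout.** A chemistry-free two-pass algorithm packs the depiction
  frames: greedy placement, largest structure first at the canvas center,
  each next structure at the grid point minimizing an overlap score
  `w_o·Σ overlap_area + w_d·Σ center_distance`; then iterative hill-climbing
  refinement that never increases the total score, with optional corner
  repulsion for an oval silhouette. The whole pipeline is deterministic:
  the same input yields a byte-identical image.
* **Color coding.** Optionally, each structure's background box encodes a
  bioactive fraction (magenta, opacity = fraction) or a protein target
  class (six fixed colors, assigned only when ≥70% of a scaffold's
  molecules hit a single class).

Details, defaults and design rationale are in [docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic 20 000-molecule collection with a power-law scaffold
distribution, then build a cloud:

```bash
moleculecloud fixtures --scaffolds 120 --molecules 20000 --seed 1 --out fixture.smi
moleculecloud build --in fixture.smi --top-n 100 --out cloud.svg
```

The build command prints its run counts:

```
{"parsed": 20000, "failed": 0, "records": 120, "stop_removed": 1,
 "singleton_removed": 0, "below_top_n": 19, "displayed": 100,
 "depiction_failures": 0}
```

Reading: all 20 000 SMILES parsed; they reduced to 120 distinct scaffolds;
benzene was removed as a stop-structure; the 100 most frequent of the
remaining 119 were displayed (19 fell below the top-N cutoff) and all 100
were depicted. Alongside `cloud.svg` the run writes `cloud.tsv` (the
selected structures with frequencies and scale factors — the exchange
format between pipeline stages) and `cloud.report.json` (every effective
setting and score, sufficient to reproduce the figure exactly).

Useful options: `--color activity|target-class` (with an annotated
aggregated table via `--format table`), `--width/--height` for the canvas,
`--stop` to add stop-structures, `--snapshots DIR` to dump the layout after
10/25/50/all placements, `--out cloud.png` for raster output.

The same pipeline is available as a library:

```python
from moleculecloud import (MoleculeInput, reduce_collection, CloudSpec,
                           select_top, scale_records)

records, report = reduce_collection([MoleculeInput("Cc1ccccc1"),
                                     MoleculeInput("CCc1ccccc1"),
                                     MoleculeInput("CCCCCC")])
# records: benzene scaffold (frequency 2) and a hexane chain (frequency 1)
```

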