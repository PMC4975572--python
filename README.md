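# fibreorder

Quantifying **myonuclear organization** in skeletal muscle fibres from 3D
nucleus coordinates.

Skeletal muscle fibres are huge multinucleated cells whose hundreds of nuclei
are normally spread along the fibre periphery, each serving its own
cytoplasmic territory (the myonuclear domain). How *evenly* the nuclei are
spaced is a regulated property: disease, hypertrophy and regeneration all
perturb it. `fibreorder` turns per-nucleus 3D coordinates — as exported from
confocal-stack spot detection on DAPI-stained single fibres — into a single
interpretable number per fibre, the **orderness score**

```
g = (ME − MR) / (MO − MR)
```

where, for a fibre idealized as a circular cylinder segment of constant
radius,

* **ME** is the observed mean nearest-neighbour (NN) distance of the nuclei
  on the cylinder surface,
* **MR** is the mean NN distance of the same number of nuclei placed
  **uniformly at random** on that surface (Monte-Carlo estimate — complete
  spatial randomness), and
* **MO** is the mean NN distance of a **maximally spread** ("optimal")
  arrangement of the same number of nuclei (wrapped triangular lattice plus
  maximin refinement).

So g = 0 (0%) means the nuclei are spaced no better than random, g = 1
(100%) means they are as evenly spread as an optimal packing; g < 0 indicates
clustering. Groups of fibres (e.g. genotypes) are compared on per-fibre
g with a one-way ANOVA followed by Bonferroni pairwise comparisons.

The package contains the full pipeline — cylinder fitting, surface
projection, NN statistics, both reference distributions, scoring, group
statistics, file I/O and a CLI — plus a synthetic-fibre generator that spans
the random → ordered continuum with a single integer (best-candidate
sampling parameter k), so everything is testable end to end without any
imaging data.

## Worked example

`examples/01_score_one_fibre.py` builds a moderately ordered synthetic fibre
(100 nuclei on a 20 µm × 500 µm cylinder, best-of-8 candidate placement) and
scores it:

```
fitted cylinder : R = 19.94 um, L = 507.3 um
ME (observed)   : 19.601 um   mean distance to the nearest nucleus
MR (random ref) : 12.764 um   +- 0.035 (Monte-Carlo SE)
MO (optimal ref): 25.635 um   maximally spread arrangement
orderness g     : 53.1 %
```

The fibre's nuclei sit 19.6 µm apart on average — well above the 12.8 µm a
random arrangement would give, about half-way to the 25.6 µm of an optimal
spread: g ≈ 53%. `examples/02_cohort_comparison.py` extends this to a
three-group cohort with ANOVA, and `examples/03_order_sweep.py` shows mean
g rising monotonically along the generator's order parameter
(k = 1 → ~0%, k = 20 → ~61%, lattice → ~100%).

## Using your own data

Coordinates are read from a comma-separated file with header
`fibre_id,group,x_um,y_um,z_um`, one row per nucleus (µm, any rigid pose;
multiple fibres per file). Then either from Python:

```python
import fibreorder as fo
from fibreorder.io import RunConfig

res = fo.run_pipeline("coordinates.csv", RunConfig(master_seed=1), "out/")
```

or from the shell:

```bash
fibreorder run --input coordinates.csv --out out/ --seed 1
fibreorder simulate --spec cohort.yaml --out sim/      # synthetic cohorts
fibreorder score ... / fibreorder compare ...          # the two stages separately
```

Outputs: a per-fibre table (`scores.tsv`, with a full-precision JSON
sidecar), a group summary (`groups.tsv`), an ANOVA report (`anova.txt` /
`anova.yaml`) and run metadata (config digest + seed). Identical input,
configuration and seed reproduce every file byte for byte.

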