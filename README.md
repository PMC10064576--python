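# rootphen

Automated histologic phenotyping of beet (*Beta vulgaris*) storage-root
tissue from transverse-section brightfield mosaics.

Beet storage roots are built from concentric **cambium rings** of
small-celled **vascular tissue (VT)** alternating with bands of large,
sugar-storing **parenchyma (SP)**.  Cell size, packing and ring spacing
differ between genotypes and relate to tissue strength, damage
susceptibility and storability — but counting and measuring thousands of
cells per section by hand is impractical.  `rootphen` does it
automatically.  Given a grayscale mosaic (TIFF/PNG, periderm at the left
margin), it:

1. binarises the section (Gaussian blur σ=2 → Otsu → two disc openings →
   hole filling) and masks the non-tissue peridermal margin and
   border-truncated cells;
2. splits touching/damaged cells by a distance-transform **watershed** and
   extracts per-cell morphometrics (area, perimeter, radius statistics,
   elliptical moments, diameter in µm);
3. finds the cambium rings as valleys of the smoothed diameter-vs-x
   profile (loess span 0.2, window-local extrema);
4. discriminates real cells from **intercellular spaces** and artifacts by
   iterating a size threshold, a k-nearest-neighbour diameter-outlier fence
   (remove if log₁₀ d < Q1 − 1.5·IQR of the gated neighbourhood) and a
   3-cluster majority rule (a smallest-cluster object surrounded by
   largest-cluster cells with SUM ≥ MAX − MEAN is a void) until a fixed
   point;
5. types the survivors VT/SP by a size-ordered 2-cluster k-means; and
6. writes per-image object tables, a master table, genotype summaries
   (mean ± sd over images), a Gaussian-kernel cell-size density
   (bandwidth 1 µm) and an Earth-Mover's-Distance genotype dendrogram.

Audience: plant phenotyping and histology groups who want reproducible
cell-level statistics from stained sections, and method developers who
need a fully ground-truthed synthetic tissue generator to test
segmentation/filtering chains.

## Worked example

No micrograph at hand?  The built-in generator renders a ring-structured
mosaic with known ground truth:

```bash
rootphen demo --out demo_out --seed 0 --n-images 2
```

which prints (numbers from this exact command):

```
synthetic_seed0.tif: 337 objects, 331 cells, 5 rings detected (5 planted)
synthetic_seed1.tif: 294 objects, 285 cells, 5 rings detected (5 planted)
demo outputs written to demo_out
```

Reading: the watershed found 337 candidate objects in the first mosaic;
the filtering stages removed six of them as intercellular spaces,
sub-cellular debris or over-segmentation fragments, leaving 331 cells; the
diameter profile shows five valleys — the five planted cambium rings.
`demo_out/master_table.csv` then holds one row per surviving cell with its
morphometrics, ring zone counts, 3-cluster label and VT/SP call, plus the
image-level pixel accounting, e.g. (abridged):

```
order  s.area  Meandiameterµm  nmdeep  Cluster_zw  Cellwallcount  Dataname
1      604     10.6            5       VT          293537         synthetic_seed0.tif
2      510     9.7             5       VT          293537         synthetic_seed0.tif
3      905     13.1            5       VT          293537         synthetic_seed0.tif
...
```

Real images run through the same door:

```bash
rootphen process section1.tif section2.tif --config my.yaml \
    --out results --genotype-map genotypes.csv --save-overlays
```

`genotypes.csv` maps each file to a genotype (`Dataname,genotype`); the
output directory gains per-image object tables and overlays, the master
table, a genotype summary CSV, the cell-size KDE plot and a Newick
dendrogram of genotype similarity.  `rootphen validate counts.csv` prints
the R² between automated and manual counts.

All parameters (smoothing σ, brush sizes, pixel pitch, neighbour count,
thresholds, k-means settings, seeds) live in a small YAML file; missing
keys take the defaults listed in `rootphen.config.PipelineConfig`.

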