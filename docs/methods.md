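# Methods

`rootphen` automates the histologic phenotyping of beet (*Beta vulgaris*)
storage-root tissue from transverse-section brightfield mosaics.  The root is
built from concentric cambium rings of small-celled vascular tissue (VT)
separated by bands of large, sugar-storing parenchyma (SP).  Given a
grayscale mosaic with the periderm at the left margin, the pipeline segments
every cell, discards intercellular spaces and imaging artifacts, locates the
cambium rings, types each surviving cell VT or SP, and reports per-image and
per-genotype morphometrics.

## Pipeline

1. **Binarisation.** Gaussian smoothing (σ = 2 px), Otsu thresholding
   (foreground = the brighter phase, i.e. cell interiors; inverted scans are
   corrected automatically), two morphological opening cycles with disc
   brushes of size 18 and 21 px (radius = size // 2, the brush convention of
   the R imaging toolbox this workflow descends from), then hole filling.
   A constant image yields an empty mask with a warning.

2. **Region of interest.** Within the left 5% of the width a high opening
   (brush 50) plus hole filling isolates the large non-tissue area that the
   rounded periderm leaves at the margin.  That area is removed together
   with any foreground fragments the opening shaved off inside the strip
   (they would otherwise survive as spurious tiny objects).  Components
   touching the image border are split off as incomplete "edge-touching"
   objects.  The ROI is the image minus the edge area and the border
   objects; `Innerpixarea` counts its pixels and `Cellwallcount` the
   non-foreground (wall) pixels inside it.  Note the wall count, by
   definition, absorbs every dark pixel in the ROI — thresholding widens
   thin walls and opening rounds cell corners, so it exceeds the geometric
   wall area; it is a comparative, not absolute, measure.

3. **Watershed segmentation.** The Euclidean distance transform of the cell
   interiors is lightly smoothed (Gaussian σ = 1 px) to suppress the
   staircase ridges of the discrete transform, seeded at its h-maxima
   (depth 1 px) and flooded on the negated map.  Merged cells with two
   distance peaks split at the neck, which re-draws the wall of damaged
   cells; single convex cells yield a single marker.

4. **Morphometry.** For every labelled object: area, perimeter,
   centroid-to-boundary radius statistics (mean, sd, max, min), centre of
   mass, elliptical-fit major axis, eccentricity and orientation (radians
   in (−π/2, π/2]).  Diameter = 2 × mean radius × pixel pitch (default
   1.015228 µm/px); its log10 accompanies it (a −999 sentinel marks
   degenerate zero-diameter objects).

5. **Cambium-ring detection.** Cells are ordered by x; the diameter series
   is smoothed by locally weighted regression (span 0.2) and scanned for
   window-local maxima (peaks = parenchyma band centres) and minima
   (valleys = cambium rings), window width 150 consecutive cells by
   default.  Ties resolve leftmost; runs of same-type extrema are collapsed
   so peaks and valleys interleave; a flat profile yields none.  Rings are
   numbered 1.. from the left (outermost).  Each cell's `ring_zone` is one
   plus the number of valleys strictly left of it.

6. **Artifact / intercellular-space filtering**, iterated until a full pass
   removes nothing:
   - *Size threshold.* The histogram of log10 diameter (bin width 0.05) is
     scanned for the valley between its two dominant modes; unimodal
     histograms fall back to 0.5 (≈3 µm) and valleys above 0.8 are capped
     at 0.8 so viable cells are never dropped.  Everything below the
     threshold goes.
   - *Neighbour gating.* For each object the k = 6 nearest neighbours by
     centroid distance (k-d tree); neighbours farther than Q2 + 1.5·IQR of
     those distances are not direct neighbours.  The median-based fence is
     intentional (fidelity to the original workflow); a conventional
     Q3-based fence is available via `median_distance_fence=False`.  All
     quantiles are type 7 (linear interpolation).
   - *Diameter outlier test.* Over the focal object and its gated
     neighbours' log-diameters, an object below Q1 − 1.5·IQR is removed as
     a probable intercellular space; the neighbourhood Q1/Q3/IQR at test
     time are stored.
   - *Cluster majority rule.* A 3-cluster k-means (z-scored morphological
     features only — never position or ring zone; 25 random restarts, max
     1000 iterations, seeded) is run per ring zone (zones under 10 objects
     fall back to the global clustering), relabelled so 1 = smallest cells,
     3 = largest.  A cluster-1 object whose gated neighbours are all
     cluster 3, or satisfy SUM ≥ MAX − MEAN (SUM/MEAN over neighbour
     labels, MAX = 3 × neighbour count), is an intercellular space.
     Neighbours are re-gated after the outlier pass removed anything, since
     its removals invalidate stored neighbour sets.
   - Removed areas from the two neighbourhood-based stages accumulate into
     `Intercellcount`; size-threshold removals are artifacts and are logged
     separately.  Termination is guaranteed because the table strictly
     shrinks or the loop stops.

7. **Tissue typing.** A final 2-cluster k-means on the same features,
   relabelled by mean diameter: cluster 1 → VT, cluster 2 → SP, so
   mean(diameter | VT) < mean(diameter | SP) always holds.  A pathological
   tie on means resolves by cardinality (the larger group is VT, which
   dominates beet tissue).  Fewer than two cells are labelled VT with a
   warning.

8. **Reporting.** Per-image tables concatenate into a master table with a
   fixed column set (`order`, the `s.*`/`m.*` morphometrics, diameter
   columns, neighbourhood quantiles, peak/valley counts, cluster labels,
   pixel accounting, image name).  Genotype summaries aggregate per-image
   statistics (cell count, max/mean diameter, ring count, wall fraction of
   ROI, VT share of cells and of area, per-cluster mean diameter) as
   mean ± sd over the images of a genotype.  Validation regresses automated
   on manual counts and reports R².  The cell-size distribution uses a
   Gaussian KDE with an absolute 1 µm bandwidth.  Genotype similarity:
   per-image feature vectors (mean, sd, max, min of every retained master
   variable; positions, neighbourhood quantiles, file name and sequence
   index excluded) are z-scored; each genotype's images form a point cloud
   (subsampled to at most 40); the Earth Mover's Distance between two
   clouds is normalised by the median EMD of 100 random re-partitions of
   the pooled cloud; average-linkage hierarchical clustering of the
   normalised distances gives the dendrogram (Newick output).  The linkage
   method is a configurable choice; average linkage is the default.

## Synthetic study conditions

The generator (`rootphen.synthetic`) renders ring-structured mosaics with
complete ground truth, so every stage is testable without micrographs.
Defaults define the study conditions and are not tuned per run:
2800 × 500 px at 0.4 µm/px, five ring bands, vascular cells 12 ± 1.5 µm,
parenchyma 35 ± 4 µm, 3 px walls, 5% of eligible parenchyma junctions
voided by ~16 µm intercellular spaces, sparse sub-resolution specks
(0.1 per 10⁴ px²), and an irregular bright non-tissue margin on the left.

Rendering uses a multiplicatively weighted Voronoi tessellation: seeds on a
jittered hexagonal sweep whose pitch follows a raised-cosine profile of the
target diameter (band half-width 0.22 of the band spacing — rings are a few
cell layers wide, parenchyma zones many cells wide, as in the tissue);
pixels go to the seed minimising distance/weight with weight = half the
target diameter.  Voids are extra low-weight seeds at triple junctions
whose whole one-cell-diameter neighbourhood is deep parenchyma, separated
from each other by at least one cell diameter (adjacent voids would
physically merge), so they always render smaller than all of their
neighbours — the property the filtering stage exploits.  Everything is
drawn from one seeded generator; outputs are bit-identical per seed.

Two scale notes.  First, the synthetic pixel pitch is 0.4 µm/px (a
20×-objective class pitch) so the smallest vascular cells span ~30 px and
survive the fixed-size openings; the config default stays at the 10×
mosaic pitch of 1.015228 µm/px.  Second, the ring-profile window is stated
in profile samples, so it must track sample density: `recommended_config`
sets it to one third of the expected cells per ring period (≈40 at default
scale, versus 150 on a full-size mosaic with thousands of cells), using a
closed-form estimate of the generated cell count.

What the generator does **not** emulate: staining colour and its
variability, illumination gradients, tearing and folding of sections,
partial-volume effects of 10 µm slices, cell-size gradients within a
single zone beyond the band profile, and non-convex cell shapes.  Passing
recovery tests therefore demonstrates the correctness and robustness of
the algorithmic chain under controlled geometry, not performance on any
particular stained section.

## Numerical choices and degenerate inputs

- Quantiles: type 7 everywhere, matching the default of the statistical
  environment the workflow originated in.
- Connectivity: 8-connected components and watershed connectivity 2.
- k-means: z-scoring uses the n−1 standard deviation; constant columns are
  left centred at zero.  Restarts draw from a seeded generator, so entire
  runs are reproducible; label identifiability comes from the size-ordered
  relabelling, not the solver.
- Ties in peak/valley detection: leftmost index wins; the detection is
  invariant to uniform diameter scaling.
- Empty masks, constant images, single-cell tables, zero-surviving-cell
  images and single-pixel objects all degrade to warnings or sentinel
  values, never exceptions; unreadable files and shape mismatches raise.

## Problem sizes

Tests and the acceptance script run on scaled-down mosaics
(~1100–3600 × 350–500 px, a few hundred cells each): ring recovery uses
twenty images with 4–7 planted bands, filtering and typing recovery use ten
seeded default-condition runs, and determinism is checked by processing one
mosaic twice and comparing bytes.  These sizes were chosen so the whole
suite exercises every stage end to end at a few hundred cells per image,
the smallest scale at which the ring profile remains well sampled.

## Known limitations

- The wall-pixel count is definitionally biased upward (see above).
- Cell-wall thickness is not estimated; the mosaic resolution targeted by
  the workflow is too coarse for reliable per-wall profiles.
- The small-object histogram threshold only operates when sub-cellular
  debris survives binarisation; with the default opening sizes most debris
  is already erased, and the stage simply falls back to 0.5 and removes
  nothing.
- Ring counts describe only the imaged distal zone, not the whole root.
- The EMD normalisation (permuted re-partitions) follows the cited
  procedure only at the level stated there; with few images per genotype
  the permutation median is itself noisy, so scores below ~1 should be
  read as "indistinguishable".
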