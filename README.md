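# tissuequant

Quantification of multiplexed tissue images — from spectral unmixing and
nuclear/cell segmentation through phenotype assignment, tumor–stroma and
tertiary-lymphoid-structure (TLS) detection, to segmentation-mask matching
and L-function-based cross-modality concordance scoring.

The package targets analysts working with multiplexed immunofluorescence
(mIF: ~6 markers + DAPI on whole slides) and imaging mass cytometry (IMC:
~40 metal-tagged antibodies over ~1 mm² regions) who need a tested,
scriptable implementation of the standard single-cell quantification steps
and of the rules used to compare the two modalities. Every stage is
exercisable on synthetic fixtures with exact ground truth — no external
image data required.

## What it implements

**Image to cell table (mIF-style).** The acquired signal of each channel is
modelled as a non-negative linear mix `c = M·a + b` of fluorophore signals,
autofluorescence, and a per-channel background; `M` is estimated from a
single-stain library and images are unmixed per pixel by non-negative least
squares. Nuclei are segmented from DAPI by adaptive (local-mean)
thresholding plus watershed on the distance map; whole cells are the
nuclei grown by up to 5 μm or until they meet a neighbour (a Voronoi
partition of the 5 μm shell), and the cytoplasm is cell minus nucleus.
Per-cell marker scores (mean/median/p75/p90 over nucleus, cytoplasm, cell)
are thresholded into positivity flags, and a phenotype key maps each flag
combination to a cell type, with marker priorities resolving conflicts
(e.g. a CD3⁺CD163⁺ cell is a T cell when CD3 outranks CD163).

**Tissue structure.** Tumor/stroma compartments start from cytokeratin
positivity; connected groups of fewer than 5 cells adjacent to an opposite
group of more than 10 are reassigned in one pass. TLS proxies are patches
of B cells (CD20⁺CK⁻) with local density above 2000 cells/mm² and at least
40 cells, outlined by an alpha shape. On IMC neighbourhood graphs, CD20
patches need ≥ 25 B/BnT cells (expanded by 10 μm) and tumor patches ≥ 25
tumor cells (cells within 25 μm included). Adjacency uses either
mask-expansion ("touch after each cell grows 4 μm") or distance-pruned
Delaunay edges.

**Comparison machinery.** Masks from two segmentation methods are matched by
the Szymkiewicz–Simpson overlap coefficient `|A∩B| / min(|A|,|B|)` (pairs
retained iff > 0.5) and classified 1-1 / 1-many / many-1 / many-many /
missing. Two aligned modalities (landmark similarity transform, ≥ 4 pairs)
are scored per cell type with the cross Ripley L function (translation edge
correction): the signed area `∫(L̂(r) − r) dr` plus a Monte-Carlo maximum-
absolute-deviation test against 99 realizations of complete spatial
randomness; a type is co-localized iff the area is positive and p ≤ 0.01.
Batch stability of control pellets is summarized by coefficients of
variation of cell-type fractions and of per-cell-type marker means.

## Worked example

`examples/01_simulate_and_quantify.py` simulates a 400×400 μm image with 60
cells of three phenotypes and runs the full pipeline:

```
cells segmented: 60 (ground truth 60)
phenotype counts: {'T': 24, 'Tumor': 22, 'B': 14}
compartments:    {'stroma': 38, 'tumor': 22}
TLS patches: 0   sample QC: PASS
phenotypes identical to ground truth: 100%
```

All 60 placed nuclei are recovered, every cell's phenotype matches the
generative truth (the fixture is noiseless), the 22 CK⁺ cells form the
tumor compartment, and no B-cell cluster is dense and large enough to be a
TLS. `examples/05_spatial_concordance.py` contrasts co-localized and
independent point patterns:

```
shared clusters  area=   38889.9 um^2  MAD p=0.01  -> colocalized
independent CSR  area=    -170.2 um^2  MAD p=0.88  -> not_colocalized
```

A positive area means the estimated L function sits above its theoretical
expectation L(r) = r; 0.01 is the smallest p attainable with 99 null
simulations. The other examples cover unmixing, mask matching, TLS/patch
detection, and batch QC.

There is also a thin CLI (`tissuequant simulate | unmix | segment |
quantify | phenotype | tissue | tls | patches | match-masks | qc |
run-mif | run-concord`) over the same functions; `tissuequant run-mif
--config config.yaml --out out/` runs the whole image-to-table workflow and
writes the cell table, masks, TLS polygons, QC verdict and a provenance
record.

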