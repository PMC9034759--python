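# Methods

## The model

`lobtype` treats cell typing in a dense connectome as clustering in a feature
space built from synapse positions and partner identities. The underlying
assumptions are those of optic-lobe anatomy: columnar cell types are
(i) stratified — each type arborizes at characteristic depths within the
layered neuropil; (ii) compact — their tangential extent is small and
type-characteristic; and (iii) wired stereotypically — cells of a type make
similar numbers of synapses onto the same downstream types regardless of
their retinotopic position. None of these features requires a proofread
skeleton; all are computable from synapse point clouds and an edge list.

### Layer-relative geometry

All coordinates are expressed in a frame derived from the postsynapses of a
reference tangential neuron whose dendrites form a thin, wide, monostratified
sheet in one layer (LT1 in the hemibrain; the reference type name is a config
key). PCA on that cloud (centered on its centroid) orders axes by variance:
two tangential axes and a normal. The layer surface is modelled as a
parabolic quadric ẑ(x, y) with six coefficients fit by ordinary least
squares, and innervation depth is z − ẑ. This treats the layers as parallel
offsets of one surface rather than concentric shells; the approximation is
excellent near the frame origin and degrades toward the neuropil rim, which
is acceptable because the depth features are binned at 5 µm.

Sign conventions, which PCA leaves undefined, are fixed as follows: e1 and
e2 are flipped so their largest-magnitude component is positive; e3 = e1×e2
(right-handed); finally, if the fitted surface has negative mean curvature
(a₃ + a₄ < 0), e2 and e3 are flipped together and the surface refit. The
last step anchors the *sign* of depth to the geometry (the normal points
toward the concave side of the layer), so reflected or re-oriented inputs
produce identical depths. Without it, half of all runs would flip the
asymmetric depth range [−20, 50) and silently drop deep synapses.

### Features and their weighting

* **Connectivity** — integer synapse counts onto each labeled downstream
  type, summed over all bodies of the type. The column panel is the union of
  labeled types downstream of at least one cell of interest.
* **Synapse spread** — per-cell sample SD (n−1 divisor; 0 for a single
  synapse) of presynapse coordinates along e1/e2/e3, in µm.
* **Innervation depth** — presynapse counts in half-open 5 µm bins over
  [−20, 50) µm (14 features). Out-of-range depths are dropped, not clipped:
  the range covers the whole neuropil, so strays are reconstruction noise.
  Before clustering the histogram is convolved with a normalized kernel
  (default (0.25, 0.5, 0.25)) under half-sample symmetric ("edge-repeated")
  reflection — the boundary convention under which convolution conserves
  total mass. The unsmoothed histogram is always retained.

Each block is normalized by its **total dispersion** (sum of per-feature
sample variances) and weighted by 5 (connectivity), 1 (spread), 3 (depth).
Two readings of "normalized by total dispersion" are implemented: the
default divides by √D, so each assembled block has unit total dispersion and
the weights are directly interpretable as relative block influence (the
assembled block's dispersion is the squared weight); `mode="linear"` divides
by D itself. The weights express relative confidence in the feature sets,
not a fitted quantity.

### Clustering and projection inputs

Ward's variance-minimization linkage on Euclidean distances (the metric
Ward's criterion presumes), cut to K clusters. K is a design input, not an
inferred quantity: when typing a real volume it is set near the expected
number of columnar types (~40 for Tm/TmY-scale inventories); on synthetic
benchmarks it equals the number of generated types. Cluster labels are
renumbered by dendrogram leaf order, so identical input yields identical
labels. The UMAP embedding (`embed_2d`, seeded) is a visualization aid only
and carries no numeric claims.

Relative input to each projection-neuron target type is the per-cluster
share of the synapses the target receives *from cells of interest* (not from
all presynaptic partners); each non-empty row therefore sums to 1. Lumping
moves sub-threshold (default 5%) contributions into an "others" column. The
conservation guarantee is stated on the integer synapse counts that back the
fractions — lumping is exact integer arithmetic there, while re-summed float
fractions can differ by an ulp. The target dendrogram is Ward on the
un-lumped rows; lumped-vs-unlumped is a config choice.

### Layer annotation

Depth-histogram mass is apportioned to layers Lo1–Lo6 at configurable
boundary depths. The defaults (−10, 0, 10, 20, 30 µm, reference surface at
depth 0 near the Lo2/Lo3 transition) are deliberately coarse, flagged
approximate, and used only for human-readable summaries — never as features.

## The synthetic connectome

The generator emulates exactly the statistics the pipeline consumes:

* a reference cloud with tangential coordinates uniform over the neuropil
  extent (half-widths 60 × 40 µm) and normal coordinate = quadric + Gaussian
  noise (SD 2 µm). The default surface coefficients are of the magnitude
  measured for the lobula layer-2 surface (a₀ = −5.21, curvature terms
  ~10⁻³), so the surface-recovery benchmarks run at realistic curvature;
* columnar cells with a uniform tangential column centre, Gaussian
  tangential scatter, depth drawn from a per-type stratification mixture and
  mapped through the quadric, presynapse counts uniform in a per-type range,
  postsynapse counts Poisson(0.4·n_pre), and per-target Poisson synapse
  counts onto 3 bodies per labeled type;
* a seeded rigid rotation + translation into "native" coordinates, so the
  PCA stage is exercised for real;
* optional dropout (truncated-reconstruction stand-in) and out-of-neuropil
  contamination to exercise the inclusion filter.

The default fixture is 8 unlabeled types × 60 cells over a 12-type labeled
panel, with depth profiles, spreads and wiring signatures loosely patterned
on reported lobula columnar types (T3-, T2-, Tm4-, Tm9-like, a wide
intrinsic type, etc.). Per-type parameter values are plausible placeholders,
not estimates — no published distributional data exist for them. Poisson
draws are truncated so labeled partners never exceed a cell's presynapses
(keeping per-synapse partner fields and the edge table consistent); fixture
rates sit far below presynapse counts, so truncation is essentially never
active. Postsynapse counts are capped so totals stay under 500 and every
generated cell passes the filter it exists to exercise (`max_total_sites`).

What the generator does **not** emulate: retinotopic lattices, skeleton or
mesh geometry, reconstruction merge/split errors beyond uniform dropout,
per-layer synapse-density differences, and realistic type-frequency
imbalance. Passing benchmarks therefore show the pipeline recovers types
whose stratification/wiring differences exceed the noise — they do not show
that real lobula fragments are this separable, nor validate any particular
biological type inventory.

## Numerical choices and degenerate inputs

* PCA degeneracy (rank < 2 cloud) and rank-deficient quadric designs raise
  typed errors rather than returning garbage axes.
* R² convention: SS_tot = 0 with SS_res ≈ 0 defines R² = 1.
* Quadric standard errors use the unbiased residual variance,
  σ̂² = SS_res/(n−6); recovery benchmarks count |â − a| ≤ 3 SE.
* Ward ties are broken by scipy's deterministic merge order; cluster
  renumbering by leaf order makes labels reproducible.
* A single-synapse cell has spread (0, 0, 0); an empty cell is an error.
* Inclusion bounds are strict on both sides (51–499 sites); "lobula-only" is
  an exact neuropil-set match with a configurable tolerance fraction
  (default 0).
* "Total synaptic sites" counts both polarities (pre + post); the polarity
  used for morphology features is a config key (presynapses for the cells of
  interest; the validation profiles of known types use postsynapses).

## Problem sizes

The standard fixture (480 cells, ~10⁵ synapses) runs end to end in a few
seconds; the acceptance script's heaviest items are 100 surface fits at 10⁴
points and 20 full pipeline replicates, together well under a minute. These
sizes were chosen as the smallest at which the statistical claims (3-SE
coefficient recovery, ARI medians) are stable across seeds.

## Known limitations

* The parallel-layer approximation biases depth at the neuropil rim.
* Layer boundaries for annotation are approximate config values, not fitted.
* K must be supplied; no internal model-selection criterion is provided.
* The live neuPrint fetcher is out of scope; input is file-based TSV only.
* Fixture realism is limited as described above; accession-scale numbers
  (e.g. cell-of-interest counts in a real volume) are not reproduced here.
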