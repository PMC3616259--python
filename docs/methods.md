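# Methods

## Pipeline model and assumptions

The package assumes a dual-channel laser-scanning confocal stack in which
one channel carries a volume-filling fluorescent marker that is homogeneously
distributed through the neuron (so the morphology channel's foreground is the
neuron's volume) and the other carries a punctate immunosignal. Both channels
come from the same imaging session, so a voxel coordinate addresses the same
physical location in both. Voxels are assumed near-isotropic (the default
phantom geometry, 0.080 × 0.080 × 0.084 μm, mirrors high-resolution confocal
sampling; a 0.16 × 0.16 × 0.17 μm variant mirrors half-format acquisition),
but nothing requires isotropy: every gradient, distance and window is
computed with the true per-axis spacing.

Stacks are processed in 8-bit form. The 12→8-bit conversion is a fixed
full-range linear map (4095 → 255, round half up) rather than per-stack
display-range scaling, so conversion is content-independent and two stacks
of the same scene always convert identically. A content-dependent min–max
mode exists but is off by default.

## Anisotropic diffusion filter

The filter integrates ∂u/∂t = div(D ∇u) explicitly. At each voxel the
structure tensor of the σ-presmoothed image is averaged at scale ρ and
eigen-decomposed; D gets diffusivity 1 along the eigenvector of least
intensity variation (the neurite axis) and, across it,
`1/r + (1 − 1/r)·exp(−λ/λ_c)` with r the along-to-across ratio and λ_c set
by the edge-contrast parameter (gray levels per gradient scale). In flat
regions all diffusivities approach 1 (isotropic smoothing of background
noise); at strong edges cross-structure diffusivity falls to 1/r.

Parameters (defaults): 10 iterations; time step 0.9 × the explicit-scheme
bound 1/(2·Σ h_a⁻²); σ = 1 lateral voxel; ρ = 4 lateral voxels; edge
contrast 10 gray levels; ratio 10. The exact diffusivity profile and
iteration count of the original interactive tooling this pipeline emulates
are not recoverable, so these are the package's own documented choices,
validated by the invariant suite rather than by matching any reference
implementation.

Numerics: fluxes are evaluated on voxel faces (the normal gradient
component exactly, tangential components as face averages of central
differences; the tensor as the face average) and differenced, with zero
flux through image boundaries. Face differencing telescopes, so the global
voxel sum is conserved to machine rounding at every iteration — the
conservation test asserts < 1e−6 relative drift and observes ~1e−16. With
the ratio forced to 1 the tensor is the identity and the scheme reduces to
the discrete heat equation; a 40-iteration impulse response matches the
closed-form Gaussian of equal diffusion time to < 1% relative RMS (the test
bound is 5%). Arithmetic is float64 throughout; re-quantization to the bit
range happens once at stage output.

## Segmentation

Automatic thresholding assumes a sparse-foreground image: the histogram
mode estimates the background level and 1.4826 × MAD its noise width; the
threshold is mode + k·MAD-width (k = 5). When the MAD is zero (noise-free
or constant background) the rule degenerates and Otsu's bimodal split is
used instead. Foreground is strictly above the threshold; an all-foreground
or all-background result warns rather than fails.

The 5 μm minimum-length criterion is applied in two places so that either
reading of "excluding small compartments" is reproducible: (a) mask
components whose maximal pairwise voxel-center distance is below the cutoff
are removed (cheap bounds — largest axis span as lower bound, bounding-box
diagonal as upper bound — resolve most components; ambiguous ones get an
exact convex-hull diameter); (b) skeleton spur branches below the same
criterion are pruned (below). The criterion is strict: extent exactly at
the cutoff survives. Connectivity is 26-neighborhood by default, the most
permissive choice, preserving thin diagonal neurites.

## Skeletonization and graph construction

Midline extraction is topology-preserving iterative 3D thinning
(Lee et al. 1994, via scikit-image): a one-voxel-thick curve skeleton with
the mask's connectivity and tunnels preserved, deterministic by
construction. The skeleton is rooted by snapping the user's soma seed to
the nearest skeleton voxel (hard error beyond 10 μm, logged otherwise);
only the seed's connected component is reconstructed, which is also how
overlapping processes from other cells are excluded. Shortest-path
(Dijkstra) distances in the 26-connected voxel graph with physical edge
weights order every compartment by geodesic distance from the root —
"distant-most" is deliberately geodesic, not Euclidean, which would
misorder curved dendrites. The shortest-path tree is condensed: unbranched
chains become edges named `dend[i]` in deterministic depth-first discovery
order; nodes are the soma, bifurcations (degree ≥ 3) and endpoints
(degree 1). One compartment per skeleton voxel; no resampling.

Spur pruning measures a candidate spur as its skeletal arc length plus a
tip-reprojection correction. Thinning retreats a terminal tip into the
volume by roughly one local radius, so raw arc length systematically
underestimates anatomical branch length; the correction ray-marches from
the tip along the branch's outgoing direction (tip minus the compartment
five steps back) through the mask to the boundary and adds the residual
distance transform there. The comparison is strict with a 1e−9 μm guard for
float accumulation, so a branch exactly at the criterion survives. Pruning
iterates to a fixed point (removing spurs can turn a bifurcation into a
pass-through or expose new leaves); a path containing the root is never
pruned.

Radius is the Euclidean distance transform of the mask, computed with
physical sampling, evaluated at each compartment voxel; compartments that
fall off foreground get radius 0 with a warning. On a digital cylinder of
radius 0.5 μm this recovers 0.50 ± one voxel away from end caps; within
about one local radius of a cap the transform is cap-limited and
underestimates, which is why radius-accuracy checks exclude a one-radius
margin at each end.

The hoc writer emits one `create`/section per edge, `pt3dadd(X, Y, Z, 2r)`
per compartment, a point soma section at the root, and `connect child(0),
parent(1)` statements; numbers use fixed 6-significant-digit formatting so
identical graphs produce byte-identical files. The reader inverts this
dialect (round-trip exact up to float formatting) and reports the line
number of anything it cannot parse. Whether the original tooling named
sections by branch order or discovery order is unknowable; discovery order
is fixed here because it is deterministic.

## Profiling

A compartment's spherical window contains every voxel whose center lies
within diameter/2 (default 3 μm) physical distance of the compartment's
voxel center — "scaled by the actual voxel dimensions" means the integer
offset set is computed per axis from the true spacing. At image borders the
window is clipped: only in-bounds voxels are averaged (no padding). The max
dataset is the maximum over the same window; this is one of two readings of
"the maximum in the compartment around the sphere" and is the documented
choice. The mean averages all in-bounds window voxels, with no
foreground/background discrimination inside the sphere.

Path selection concatenates adjacent edges (shared junction compartment
kept once, arc length continuous across joins). A configurable
soma-exclusion radius (default 0; typically ~6 μm) drops records whose arc
length falls inside it, because the first few μm of a soma-seeded
"dendrite" actually sample the cell body. Normalization divides signal
records by morphology records profiled identically on the raw, unfiltered
morphology channel; the denominator is clamped at epsilon (default 1 gray
level) and such records are flagged rather than dropped.

Writers: tab-separated text (header `arc_um point mean max radius_um`
plus `norm_point norm_mean` when normalized), one file per dendrite path;
ASCII AmiraMesh SpatialGraph with VERTEX/EDGE/POINT blocks and per-point
`thickness` (true radius in morphology mode, constant half-voxel in
filament mode) and `intensity` (point value by default; mean, max or
normalized selectable) fields. A bundled parser supports round-trip tests.

## Synthetic phantoms

`render_morphology` rasterizes tubes (polyline midline, constant or
linearly tapering radius) with a one-voxel anti-aliased surface; terminal
ends are cut flat by default so a branch "of length L" occupies exactly L
of physical extent — the property the length-criterion sweep relies on.
`render_signal` adds 3D Gaussian puncta at specified arc positions plus a
uniform baseline. Noise is Poisson shot noise plus additive Gaussian read
noise, seeded and deterministic; noise-free renders never touch an RNG.
Default intensity tiers follow what punctate immunostains show in practice:
baseline 0–40, faint clusters 40–120, prominent clusters 120–255 gray
levels; noise defaults (read σ ≈ 5–6 gray levels over a 10–12 baseline)
are chosen so automatic thresholding succeeds, and stress tests may raise
them.

What the phantoms do not emulate: a realistic confocal PSF (optional
Gaussian blur only), spectral bleed-through, intensity falloff with depth,
spines, or the soft boundary between soma and dendrite. Passing tests
therefore demonstrate correctness of the algorithms under controlled
geometry and noise, not segmentation robustness on difficult real tissue.

## Problem sizes

Fixtures are 20–40 μm structures at the fine (0.08 μm) or coarse (0.16 μm)
spacing, i.e. 0.3–4 M voxels — large enough for sub-voxel midline and
radius statistics to be meaningful, small enough for the whole suite to run
on a laptop-class single core. The branch-length sweep uses a 38 × 24 × 4 μm
volume (19 branches); profiling oracles run on a 22 μm tube with ~240
compartments and a ~210,000-voxel sphere per compartment.

## Known limitations

- The diffusion filter recomputes the structure tensor every iteration via
  a dense per-voxel eigen-decomposition; tens of millions of voxels per
  round become minutes of runtime.
- Automatic thresholding assumes a dominant background mode; dense
  foreground (a soma filling much of the field) can bias it — the fixed
  threshold mode is the escape hatch.
- Junction geometry at bifurcations is resolved by thinning, which can
  displace the branch node by a voxel or two from the analytic meeting
  point.
- read_hoc reconstructs physical positions but not voxel indices; profiling
  a graph read from hoc re-derives voxel indices by rounding positions with
  the supplied geometry.
- The soma is a point node; no soma surface is reconstructed, and the first
  few μm of seed-adjacent dendrites sample the cell body unless the
  soma-exclusion radius is set.
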