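# Methods

This note documents the models, estimators and numerical choices behind
`hemicorr`, in the package's own terms. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Geodesic distances

All surface distances are shortest paths on the mesh edge graph with
Euclidean edge weights (Dijkstra via `scipy.sparse.csgraph`). Exact
polyhedral geodesics (MMP, heat method) are deliberately out of scope:
edge-graph distances overestimate the true surface geodesic by a small,
tessellation-dependent factor, and in exchange are deterministic,
platform-stable, and exactly checkable against an independent
Floyd–Warshall brute force (the acceptance suite verifies agreement to
1e-9 mm, i.e. float associativity). Consequence: absolute distances
(label vectors, AFCD, FAD) are defined relative to this metric; on
well-tessellated meshes comparisons and thresholds behave like true
geodesics, but absolute values from a different geodesic engine may
differ by a few percent. Disconnected meshes are a hard error outside
validation (distances would be infinite); medial-wall vertices (the
reserved label −1) are excluded as seeds, targets and landmarks but
retained in the graph so paths may cross them.

## Landmark correspondence

A region centroid is the region vertex nearest (Euclidean) to the
arithmetic mean of the region's vertex coordinates, ties broken by
lowest vertex index. Label-vector matching standardizes each row once
(subtract mean, divide by norm) so the full Pearson field is a blocked
matrix product; the per-seed argmax ties break to the lowest vertex
index. Standard Pearson correlation is used (not cosine similarity,
the other defensible reading of "most similar"); with ≥ 3 regions of
non-degenerate geometry the two rarely disagree on the argmax. Across
hemispheres, regions are paired **by name**, not by numeric id, since
annotation files can order regions differently per hemisphere.

The coordinate-flip benchmark is transform-agnostic: callers supply
volume-space coordinates per vertex; the flipped estimate of a seed at
(x, y, z) is (−x, y, z), distances are Euclidean in mm, and flipped
locations are assigned to their nearest voxel when a grey-matter mask
is supplied (reporting the fraction that fall outside it). Template-
specific transforms are upstream.

## Surface smoothing and its FWHM target

Smoothing is explicit graph heat diffusion, `x ← (I − dt·L)x`, with
1-ring Gaussian weights `w_uv = exp(−ℓ²/2σ²)` (σ = mean edge length)
and `dt = 0.5/max degree` for stability. Because the weighting is
symmetric, the per-timepoint spatial sum is an exact invariant and
constant fields are exact fixed points. The contract is phrased in
terms of the *achieved* smoothness: iteration continues until the
estimated FWHM of the data reaches the target (±10%), re-estimated as
the iteration proceeds, and it is an error to request a target below
the data's current smoothness.

The smoothness estimator assumes a Gaussian spatial autocorrelation and
uses the variance of first differences along edges:

    FWHM = h · sqrt(−2 ln 2 / ln(1 − var_diff / (2·var_field))),

with h the mean edge length — the FWHM of the equivalent Gaussian
kernel that would give white noise the observed roughness. The ratio is
clipped to (1e−9, 1−1e−9); a field constant along every edge estimates
as infinitely smooth and is returned unchanged. The estimator pools
over edges with a single mean edge length, so it is calibrated for
near-regular meshes (icospheres, grids); on highly anisotropic meshes
it becomes a biased average.

## Functional correspondence

Cross-hemispheric Pearson correlation is computed exactly (no
approximation) but blockwise, so peak memory is O(block × n_targets)
and full dense matrices are only retained below 4,000 vertices or on
request. Group functional correspondence is the argmax of the
**subject-averaged** correlation matrix — not the average of
per-subject argmaxes — matching the averaging-then-argmax order of the
reference analysis; Fisher-z averaging is available behind a flag but
off by default (arithmetic mean of ρ is the default contract).
Zero-variance rows are excluded with a warning and sentinel outputs
(−1 index, NaN score); excluded vertices never appear as seed or
target. Nuisance regression, volume-to-surface mapping and other
preprocessing are upstream requirements: the package consumes clean
per-vertex series.

## AFCD, FAD, clusters

AFCD[v] is the geodesic distance on the target hemisphere between the
seed's AC and FC. FAD is reported on left-hemisphere seeds: with
w = ac_lr[v], FAD[v] = d_left(ac_rl[fc_lr[v]], fc_rl[w]). Either
hemisphere can anchor the display — recomputing with the roles of the
maps exchanged gives the right-referenced variant — and any chained
index that touches an excluded vertex propagates a NaN sentinel rather
than being silently dropped. Pairwise distances are vectorized through
a multi-source Dijkstra over the unique AC targets.

High-FAD clustering takes connected components (edge adjacency) of the
strictly supra-threshold vertex set and discards components below the
minimum vertex count, ordering clusters by descending mean FAD. The
reference rule is an absolute 100 mm threshold (empirically the upper
5% in the reference data) with a 20-vertex (~50 mm²) minimum; the
threshold is configurable as millimetres or a percentile, and the
filter is by exact vertex count (area is reported for reference, since
mm²-per-vertex depends on mesh resolution). A percentile threshold
that resolves to ≤ 0 (e.g. p95 of an all-zero FAD map) yields an empty
cluster table. Whether a percentile is taken jointly or per hemisphere
is a caller choice; the pipeline computes it over the left-referenced
FAD map.

The temporal-SNR asymmetry check pairs each right vertex with its
anatomical partner on the left, computes tSNR = temporal mean /
temporal SD per subject, and applies the Wilcoxon signed-rank test
across subjects (exact null for ≤ 25 subjects, normal approximation
above; uncorrected p < 0.01 reference level, no multiplicity
correction by design).

## Synthetic scenes

The generator favors exact ground truth over anatomical realism: the
left hemisphere is an icosphere scaled to ~80 mm with a smooth random
radial deformation (amplitude 4 mm — enough to break spherical
symmetry while keeping the tessellation well-conditioned), and the
right hemisphere is its x-negated mirror plus an independent radial
perturbation of configurable amplitude. The homotopic map is therefore
known exactly. The method under test assumes only mesh geometry, never
folding, so a folded cortex is not required for validity; what the
synthetic tests consequently do *not* probe is the behavior of the
landmark coordinate system under realistic gyral variability, partial
inter-subject misregistration, or hemispheric meshes of genuinely
different topology.

Parcellations are geodesic Voronoi tessellations of
farthest-point-sampled seeds (re-seeded if any region comes out
smaller than 4 vertices or disconnected), mirrored across hemispheres
so region j pairs with region j.

Time series follow a low-rank latent model: each network has one
latent Gaussian time course shared identically across hemispheres, and
each vertex pair has a private pair latent. Loadings satisfy
corr(x_v, x_mirror(v)) = ρ exactly, with the network latent carrying a
fixed fraction (default 0.25) of the shared variance — the pair latent
absorbs the remainder, which is what makes the mirror partner the
unique argmax rather than any same-network vertex. An optional
Gaussian spatial falloff attenuates the network loading with geodesic
distance from the network center (the pair latent compensating to keep
ρ exact). The reference study scale is 10 subjects × 140 timepoints at
ρ = 0.6 with unit noise; networks partition the surface by assigning
parcellation regions round-robin to 6 networks. BOLD realism
(hemodynamics, autocorrelated noise, physiological spectra) is a
non-goal; consequences for interpretation: recovery rates measured
here are upper bounds on real-data behavior, where noise is
structured and coupling varies continuously.

An injected asymmetry (patch of left vertices, displacement D mm)
re-routes each patch pair's latent on the right hemisphere: a vertex
~D mm away along the surface (all patch vertices walk shortest paths
toward a common distant anchor, so the field is locally coherent)
receives the latent at 0.9 of the symmetric loading while the true
mirror location keeps a 0.3 echo. Patch vertices drop their network
loading so the displaced copy is the unambiguous argmax for left
seeds, while right seeds at both the mirror and the displaced location
still map back to the left patch. This realizes a one-sided
displacement in the correlation structure itself — left-seed FCs move
by ≈ D while right-seed FCs stay symmetric — so AFCD and FAD both
recover ≈ D over the patch and control vertices are untouched, up to
the ≤ 1 edge discretization of the displacement walk.

## Problem sizes and determinism

Reference-scale checks run at icosphere subdivision 4 (2,562 vertices
per hemisphere) with 74 regions; unit tests use subdivisions 1–3 and
hand-built chains whose distances are known in closed form. These sizes
keep every all-pairs geodesic matrix dense and exactly checkable while
exercising the same code paths the 36k-vertex standardized meshes
would; the correlation and argmax machinery is blockwise precisely so
that vertex counts at that scale need no dense matrix. All generators
take explicit integer seeds and are bitwise deterministic given
(parameters, seed); tabular outputs use fixed 9-significant-digit
formatting so identical runs are byte-identical.

## Known limitations

- Edge-graph geodesics overestimate true surface distance; absolute
  mm values are metric-specific (see above).
- The FWHM estimator assumes near-regular tessellation and Gaussian
  autocorrelation shape.
- Anatomical correspondence quality on real data depends entirely on
  the upstream parcellation's cross-hemisphere consistency; the
  synthetic mirror-identity results quantify the method's intrinsic
  floor, not atlas error.
- `map_similarity` loops over seeds (O(n²) correlations); it is meant
  for region-of-interest follow-up, not whole-surface sweeps at high
  resolution.
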