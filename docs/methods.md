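# Methods

This note documents the models, parameter choices, numerical decisions,
and limitations of `leaftda`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

A leaf is an ordered set of homologous 2-D landmarks plus metadata:
species/morphotype label, vine id, and node index counted from the
growing tip (node 1 = youngest leaf). Within each vine, the observed
nodes are ranked from the tip and the leaf at rank k of N distinct
nodes receives the relative node position (k − 1)/(N − 1), so **0 =
growing tip and 1 = shoot base**. Ranks rather than raw node indices
are used so vines with collection gaps still span [0, 1]. Vines with a
single leaf are excluded (the denominator is undefined) with a warning.
This relative position doubles as the heteroblasty value and as the
developmental lens. The shoot-base/growing-tip split puts the boundary
leaf (relative node exactly at the threshold, default 0.5) in the tip
part, mirroring the ≤ in the per-vine-mean rule that assigns leaves to
the ontogenetic (≤ vine mean) versus heteroblastic (> mean) series.

Built-in landmark schemes: `grapevine` (15 landmarks digitized on one
half of the blade; positional names), `maracuya` (21 landmarks,
whole blade), and `shared` (6 corresponding landmarks: petiolar-
junction base, proximal lobe tip, proximal sinus, distal lobe tip,
distal sinus, leaf tip). Half-blade configurations are completed by
mirroring every non-axis landmark across the petiolar-base → leaf-tip
line; axis landmarks are kept once, mirrored landmarks are appended in
the original order so correspondence stays deterministic, and the
reflection is an involution to machine precision.

## Procrustes superimposition

Centroid size is the root summed squared distance of landmarks to their
centroid; every configuration is centered and scaled to centroid size 1.
Pairwise superimposition rotates the target onto the reference with the
SVD solution of the orthogonal Procrustes problem, **restricted to
proper rotations** (det +1): leaf handedness is biologically
meaningful, so mirror images are never introduced implicitly — only by
the explicit reflection-completion operation. A flag re-enables improper
maps for users who want the classical behavior.

GPA iterates: rotate all unit-size configurations to the current mean,
re-average, renormalize the mean, until the root summed squared change
of the mean falls below `tol` (default 1e-7) or `max_iter` (default
100) is reached; non-convergence returns the result with a warning and
the recorded final change. The initial mean is the first leaf after
normalization, making the result deterministic for a fixed dataset
order. Because the aligned frame would otherwise inherit the first
leaf's arbitrary orientation, the converged mean is rotated to a
canonical orientation (principal axes on the coordinate axes, with the
180° ambiguity resolved by the sign of the first landmark's
coordinates); this makes the aligned coordinates invariant — to within
the convergence tolerance — under any global rotation, translation, or
positive scaling of the input. The canonicalization is unstable only
for exactly isotropic mean shapes, which do not occur for leaf
outlines. The per-iteration objective (summed squared distances of the
rotated configurations to the current mean) is recorded so its
monotonicity is testable.

## Ordination

PCA is scikit-learn's full-SVD PCA wrapped with a deterministic sign
convention (each component's largest-magnitude loading is positive), so
lens values and plots are reproducible across runs and library
versions. Morphospace reconstruction uses the exact linear inverse
(mean + Σ scoreᵢ·componentᵢ) on a user grid of scores.

LDA solves the generalized eigenproblem S_b v = λ S_w v with
scipy's symmetric solver. Two numerical guards:

1. **Range projection.** GPA-aligned coordinates are rank-deficient
   (superimposition removes translation, size, and rotation degrees of
   freedom). Discriminant directions in the null space of the total
   scatter are artifacts with near-zero within-class variance, so the
   data are first projected onto the range of the total scatter
   (singular values above 1e-9 of the largest).
2. **Ridge.** If the within-class scatter is still singular (more
   dimensions than samples), a ridge λ = 1e-6·trace(S_w)/dim is added
   with a warning.

Axes follow the same sign convention as PCA; classification is by
nearest class mean in discriminant space. The implementation is
cross-checked against scikit-learn's LDA in the test suite.

On the synthetic two-genus study the first discriminant cleanly carries
the genus contrast, while the shoot-position contrast on the second
axis is intrinsically weaker as a *point-biserial correlation*: the
position label is a median split of a continuous ontogenetic
trajectory, which caps the correlation near 0.87 even for a noiseless
monotone score, and genus-specific trajectory directions (the two
schemes sample the template at slightly different homologous positions)
plus per-species scatter reduce it further. The pipeline test therefore
asserts that axis 2 is position-dominated with |r| ≥ 0.4 (validated by
a 10-seed simulation during design), while the stricter 0.95/0.8/0.95
thresholds are asserted on the discrete additive-effects construction
(genus offset ≫ position offset ≫ noise) where they belong.

## Mapper

Distances are 1 − Pearson correlation between flattened landmark
vectors, computed on **raw (unaligned) coordinates** by default — the
correlation distance already discounts affine components of shape
difference, and the original analyses describe no alignment before
Mapper — with a flag to use GPA-aligned input instead.

Cover intervals are **closed**, although the construction is described
with open covers: the data are finite samples, and closed endpoints
keep the extreme leaves inside the cover; a boundary value in an
overlap belongs to both adjacent intervals. With n intervals over
[m, M] and overlap fraction g, each interval has length
ℓ = (M − m)/(n − (n − 1)g) and interval k starts at m + kℓ(1 − g); the
last endpoint is pinned to M against rounding. Defaults: **12 intervals,
overlap 0.35**. Cover and clustering parameters are hand-tunable per
run — the construction is honest about that — and every tuned value is
recorded in the graph's provenance block.

Clustering is scikit-learn DBSCAN with `metric="precomputed"` on the
interval's distance submatrix; defaults **eps 0.05** (correlation-
distance units), **min_samples 5**. Noise points are excluded from
vertices but recorded per interval, and membership conservation (every
point in a vertex or the noise set, per interval it occupies) is a
tested invariant. Vertex ids are `i{interval}_c{cluster}` with clusters
ordered by their lexicographically smallest member — fully
deterministic output. Edges join clusters from different intervals that
share a leaf; with overlap < 0.5 edges can only join adjacent
intervals, which is tested. A brute-force nerve oracle (exhaustive
pairwise intersection) ships in the package and the build is checked
against it on hundreds of random configurations.

Diagnostics: component count C, cycle rank b₁ = E − V + C,
path-likeness (fraction of vertices with degree ≤ 2), and spine
monotonicity — the Spearman correlation between position along the
spine and vertex mean lens, where the spine is the longest simple path
(exhaustive DFS with a state budget; for pathological dense graphs the
fallback is a diameter path) oriented lens-ascending. A spine of fewer
than two vertices is trivially monotone (1.0); a spine with constant
lens values scores 0.

## Subway maps

The "primary structure" of a Mapper graph is realized as: keep vertices
with at least `min_vertex_size` members (default 2), restrict to the
largest connected component (ties broken by smallest vertex id). This
is one defensible realization of an operation the source analyses
describe only pictorially; it never adds vertices or edges, and
annotations (mean shapes, composition) are preserved for rendering
vertices as mean-leaf glyphs.

## Synthetic leaf series

The generator is the package's study-conditions module, not a fixture:
it produces datasets with exactly the statistical structure the
analysis assumes, at desk scale.

Template: a closed polar curve ρ(θ) = 1 + 0.22 cos 2θ + 0.10 cos 5θ
sampled at n equally spaced parameters, centered, unit centroid size —
a mildly bilobed outline with enough non-affine structure for the
correlation distance to resolve. Deformations at relative node r:

1. **Heteroblasty** — a fixed smooth quadratic displacement field
   scaled by `heteroblasty_amplitude · r` (default amplitude 0.5):
   lobes deepen and the blade shears as leaves mature toward the base.
2. **Ontogeny** — allometric contraction and elongation scaled by
   `ontogeny_amplitude · (1 − r)` (default 0.4): tip leaves are smaller
   and relatively elongated.
3. **Lineage and species effects** — fixed random per-lineage and
   per-species landmark offset fields (defaults: lineage sd 0 for
   single-genus studies, species sd 0.03), seeded from (seed, label) so
   they are independent of the number of vines generated.
4. **Divergence** — for designated species with r inside
   `divergence_band` (default [0.3, 0.7]), an extra displacement of
   magnitude `divergence_amplitude · sin²(π(r − lo)/(hi − lo))`
   (default amplitude 0.25), vanishing smoothly at the band edges so
   the deviant trajectory rejoins the shared one at both ends. The
   field uses high spatial frequency (sin 9y, cos 8x) deliberately:
   the correlation distance is blind to affine displacement components,
   so a low-frequency field would be invisible to the Mapper stage.
5. **Noise** — i.i.d. Gaussian landmark noise, sd 0.02.

Layout: `n_species` × `vines_per_species` vines (defaults 6 × 5), each
with nodes 1..N where N is drawn uniformly from `nodes_per_vine` ±
`nodes_jitter` (defaults 12 ± 3). Vine-length variation is essential,
not cosmetic: real collections have vines of differing length, which is
what makes the relative-node lens densely populated; with a single
fixed length the lens takes only N distinct values, cover overlap zones
are generically empty, and the Mapper graph disconnects. Draw order
(species sorted by label, then vine, then node) is fixed so datasets
are bit-reproducible from the seed.

At these defaults and the default Mapper parameters, a 20-seed
recovery experiment (≈360 leaves per run) is part of the acceptance
surface: core-only data yield b₁ = 0, path-likeness ≥ 0.8, spine
monotonicity ≥ 0.95; adding one divergent species yields branch
vertices majority-composed of that species, and in most runs a closed
branch-and-rejoin cycle (b₁ ≥ 1) — cycle closure is stochastic at
roughly a 90% per-seed rate because the rejoining bridge near a band
edge can fall below DBSCAN's min_samples, so the acceptance script
reports the detection *rate* over its runs.

What the generator does **not** emulate: real leaf outlines (the
template is parametric, chosen for controllable effect sizes rather
than botanical realism), phylogenetic covariance among species effects,
measurement error structure of digitization, environmental or
year-to-year effects, and within-vine serial correlation of noise.
Passing recovery tests therefore demonstrates that the pipeline detects
these structures when present at realistic effect sizes — not that any
particular real dataset contains them.

## The two-genus default study

`pipeline.default_synthetic_analysis` wires two genera: a
grapevine-like one (15 landmarks, conserved program only) and a
maracuya-like one (21 landmarks, one divergent species). Shared-
landmark selections pick approximately homologous template positions on
one side of the blade (petiolar base … leaf tip), and both genera are
completed by reflection across the base → tip axis so the pooled
configurations are landmark-for-landmark comparable — the analogue of
completing half-digitized leaves before a common morphospace. A
lineage-level offset field (sd 0.1) encodes deep between-genus
divergence; without it, two genera built from one template would be
inseparable by construction. Partial-dataset Mapper covers are rebuilt
over each half's own lens range, treating each partial dataset as a
fresh analysis.

Problem sizes throughout tests and the acceptance script (≈360–800
leaves per run, 20-seed recovery loops, 100 random oracle
configurations) were chosen so the full suite runs in well under a
minute; they are desk-scale versions of the study design, not attempts
to match the original sample counts (thousands of leaves).

## Known limitations

- Lenses are 1-dimensional; no multidimensional lenses or persistent
  homology.
- The cover formula (equal-length intervals, fixed fractional overlap)
  is one standard choice; the original analyses hand-tuned unreported
  covers, so exact figure reproduction is out of scope by design.
- DBSCAN's eps/min_samples interact with dataset density; the defaults
  suit the generator's scale and must be re-tuned for real data (the
  provenance block records every run's values).
- LDA is used descriptively (training separation of labeled groups),
  not as a validated classifier.
- The spine is defined by longest simple path; on graphs with many
  cycles this is exponential in principle, hence the state budget and
  diameter-path fallback.
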