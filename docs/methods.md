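# Methods

## Model

A spatial preprocessing transform is represented as a *pending operation*:
either a homogeneous (N+1)×(N+1) matrix over the N ∈ {2, 3} spatial
dimensions, or a grid of per-voxel sampling targets, together with input
and output shapes and dtypes, an interpolation mode (`linear` | `nearest`)
and a padding mode (`zeros` | `border` | `reflection`).  Images
(`MetaImage`) carry the ordered list of pending operations plus a trace of
operations already applied; transforms only append descriptions, and a
separate resampling step executes them.

### Conventions

These conventions are the package's own explicit choices (a reference
implementation need not share them); everything downstream depends on them:

* **Channel-first layout** `(C, *spatial)`; matrices act on spatial axes
  only.
* **Pull matrices**: a pending matrix maps *output* voxel coordinates to
  *input* voxel coordinates.  Resampling iterates output voxels, and
  composition reads left-to-right in pipeline order under
  right-multiplication: applying A then B composes as `M_A @ M_B`.
* **Centred voxel coordinates**: index *i* ↦ *i* − (extent − 1)/2, so
  rotations and zooms act about the array centre and a same-shape flip is
  the diagonal −1 matrix with no translation.
* **Index map**: for a group with matrix `[S | t]`, input index
  `i = S (o − c_out) + t + c_in` with `c = (extent − 1)/2` per axis.
* **Interpolation defaults**: linear for float images, nearest for integer
  labels (overridable per call).  Supported dtypes: float32/float64/uint8/
  int16/int32/int64; labels must be integer.
* **Extent rounding** for zoom/spacing/resize: round-half-away-from-zero of
  `extent × factor`, minimum 1 — a fixed rule so shape chains are
  deterministic (6/5 then 5/6 on 64 gives 64 → 77 → 64).
* The **world affine** (voxel → mm) is updated by each applied matrix group
  and the voxel spacing re-derived from its column norms; it plays no part
  in composition decisions, which live entirely in voxel space.

## Composition and dispatch

`build_groups` walks the pending list left to right and merges consecutive
matrix operations into one group while interpolation mode, padding mode and
output dtype are unchanged; any change — or any vector-grid operation —
closes the group.  This is deliberately the conservative reading of
"incompatible parameters": mode, padding or dtype changes, and grids never
merging.

Each group is classified on its *index-space* map (matrix plus the
half-integer centre terms, which is what makes quarter-turns between
odd/even extents and parity-changing crops classify correctly):

* `exact_op` — spatial block is a signed permutation and the index
  translation is integral (both within an absolute tolerance of 1e−5, wide
  enough that float parameter round trips such as 6/5 × 5/6 still snap to
  exact): executed by axis permutation, reversal, integer slicing and
  padding — a pure gather, bit-exact, no arithmetic on values.
* `axis_interp` — axis-aligned (one non-zero per row and column) but with
  non-integer scale or shift: interpolation is unavoidable.  It is executed
  through the general resampler; a separable fast path would change cost,
  not output, so correctness-first routing was chosen.
* `full_resample` — anything rotated or sheared.

The general resampler samples input coordinates per output voxel: linear
interpolation through `scipy.ndimage.map_coordinates` (order 1, no
prefilter, computation in float64 regardless of payload dtype), nearest as
an explicit integer gather with half-way ties resolved toward the lower
index — a fixed, platform-independent rule.  Padding modes map to constant
zeros, edge clamp, and mirror-without-edge-repeat respectively.  Nearest
mode is a pure gather, so output values are always a subset of input values
(plus the padding constant).  Composition arithmetic is float64 throughout,
which keeps the six-transform identity chain inside 1e−6 of the identity.

## Pipeline compilation

The compiler turns a user transform list into an executable stage sequence:
an `ApplyPending` stage is inserted before any stage that cannot run lazily,
after any lazy-capable stage whose own `lazy` flag is False, and at the end
of the pipeline.  A multi-sample transform (patch sampler) and everything
downstream of it are wrapped in a `MultiSampler` that executes depth-first,
one sample at a time — instrumentation confirms at most one sample's
intermediates are ever alive.  Compilation happens eagerly and is
idempotent; nesting multi-samplers beyond depth one is rejected.

Randomised transforms draw from dedicated streams seeded by
`(master_seed, position in the original transform list, sample index)`.
Two consequences: editing one transform does not shift any other
transform's draws, and a lazy and a traditional compilation of the same
list see *identical* random parameters — the precondition for every
lazy-vs-traditional comparison in this package.  Parameters are drawn
before the lazy/eager branch for the same reason.

### Inversion

Each `ApplyPending` leaves one trace record per executed group, containing
the *composed* operation as applied.  Inversion inverts each record's
matrix (shapes and dtypes swap, interpolation and padding modes are
preserved) and replays them in reverse order, compiled lazily by default —
so the inverse pass costs exactly as many resamples as the forward pass.
Vector grids and singular matrices raise `NotInvertibleError`.  A crop's
inverse is the enlarged-output inverse translation; voxels that left the
field of view during the forward *apply* are genuinely gone and come back
as padding.  The non-lazy noise stage is excluded from the trace: it is
neither spatial nor invertible.

## Synthetic data

The generator produces two families of inputs:

* **Checkerboards** (cells of 1, 2 and 4 px on 64×64 by default): periodic
  binary texture that maximises visible aliasing under incommensurate
  rescaling (6/5 then 5/6).
* **Labelled phantoms**: per class, axis-aligned ellipsoidal blobs with
  randomised anisotropy and non-overlapping placement by rejection
  sampling, at per-class foreground volume fractions drawn from a stated
  range; plus an intensity image = smooth background (Gaussian-filtered
  noise, σ = 6 voxels) + per-class offset + per-voxel uniform texture.
  Default spacing is (1, 1, 1.25) mm so the spacing stage genuinely
  resamples.  Everything is reproducible from the `PhantomSpec` seed.

Two foreground-fraction presets mirror public volumetric MRI segmentation
tasks: 0.0816–3.57 % per class (brain-tumour-like, 3 classes) and
3.76–7.48 % (hippocampus-like, 2 classes).  The entropy experiments use the
brain-tumour-like preset; the label round-trip experiments use the
hippocampus-like preset, because at the scaled-down 64³ phantom size the
smallest brain-tumour-like blobs shrink to ~200 voxels and their round-trip
Dice is dominated by discretisation noise rather than the resampling
behaviour being measured.

The uniform high-frequency texture is load-bearing for the entropy
experiment: a near-uniform marginal intensity distribution starts near the
maximal 8 bits at 256 bins, and every linear resample (a convex combination
of neighbours) strictly concentrates it, so entropy loss grows with the
number of resamples.  What passing tests show is therefore the *direction*
and *mechanism* of information loss — more resamples, more loss — not the
absolute entropy numbers of any real MRI dataset; real data have structured
backgrounds, air, and acquisition noise the phantoms do not emulate.

## Experiment sizes and defaults

Chosen as the package's own desk-scale study conditions:

| experiment | default size |
|---|---|
| identity chain | 64×64, 6 transforms |
| moire round trip | 64×64 checkerboards, cells 1/2/4, factor 6/5 |
| oracle equivalence (tests) | 200 random chains, length ≤ 5, volumes ≤ 32³ |
| forward entropy | 50 phantoms, 48³, 256 bins |
| label round trip | 20 runs over 10 phantoms, 64³ |
| multi-sampler | 8 patches of 16³ from 32³ |

The whole-volume reference pipeline is Spacing → Flip → Rotate90 → Zoom →
Rotate; its randomised form uses rotation ±15°, isotropic zoom 0.9–1.1 and
per-axis flip probability 0.5.  These ranges are package defaults, exposed
as configuration — not values taken from any dataset protocol.  In lazy
mode the five stages merge into one interpolation; traditionally spacing,
zoom and rotate each interpolate (flip and rotate90 are exact), giving the
1-vs-3 forward and 2-vs-6 round-trip interpolation counts the audits
assert.

## Known limitations

* Only linear and nearest interpolation; no B-spline/cubic and no
  anti-aliasing prefilter on downsampling.
* Grid (deformation-field) operations execute but never merge with
  neighbours, and are not invertible here.
* No DICOM I/O and no RAS/LPS orientation harmonisation beyond carrying the
  affine.
* The multi-sampler supports depth-1 nesting only; per-sample shape-changing
  non-lazy downstream transforms execute independently per sample.
* Round-trip exactness claims concern content that stays inside the field
  of view; translations and crops destroy out-of-view voxels at apply time
  by design.
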