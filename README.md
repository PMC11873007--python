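# lazyresample

Lazy composition of spatial preprocessing transforms for medical images:
describe, compose, resample **once**.

## The problem

Deep-learning pipelines for volumetric medical images chain many spatial
transforms — resampling to a target spacing, flips, 90° rotations, zooms,
free rotations, patch crops.  Executed traditionally, *every* lossy stage
interpolates the voxels it receives from the previous stage:

* each linear resample averages neighbours, eroding the fine, low-contrast
  detail that matters in MRI;
* each nearest-neighbour resample of a segmentation label nudges thin
  structures, and the damage compounds — catastrophically so when labels are
  pushed forward through a pipeline and back through its inverse;
* crops and translations destroy data that a later rotation would still
  have needed, forcing pipeline designers to pad defensively.

`lazyresample` instead treats every spatial transform as a *description*: a
homogeneous (N+1)×(N+1) matrix **M** in voxel space (pull convention —
output voxel coordinates map through **M** to input coordinates), plus the
interpolation mode, padding mode, shapes and dtypes needed to run it later.
Descriptions accumulate on the image; runs of compatible descriptions are
collapsed by matrix product, `M = M₁ M₂ ⋯ Mₖ`, and executed as a **single**
resample — or, when the composed matrix is a signed permutation with integer
translation, as an exact, bit-lossless array manipulation with no arithmetic
on the values at all.

The package provides:

* `core` — `MetaImage` (channel-first array + world affine + pending ops +
  applied trace), `PendingOp`, `AffineMatrix`, `VectorGrid`, NIfTI-1 I/O;
* `transforms` — rotate, rotate90, flip, zoom, translate, spacing,
  crop_patch, resize, their seeded randomised variants, a deliberately
  non-lazy noise stage, and per-record inversion;
* `pipeline` — a pipeline *compiler* that inserts `ApplyPending` stages at
  lazy/non-lazy boundaries, wraps multi-sample patch transforms in a
  constant-memory `MultiSampler`, executes with instrumentation, and inverts
  applied traces;
* `resampler` — greedy grouping of compatible descriptions and the
  universal dispatcher (`exact_op` / `axis_interp` / `full_resample`);
* `metrics` — 256-bin Shannon entropy, per-class Dice, L1 histogram
  divergence, interpolation-event counting;
* `synthetic` — checkerboards and labelled 3D phantoms (smooth background,
  ellipsoidal label blobs at realistic foreground fractions, high-frequency
  texture), so no data download is needed;
* `experiments` + a thin `lazyresample` CLI for the desk-scale comparisons.

## Worked example

```bash
python examples/01_identity_chain.py
```

```
max |composed - identity| : 1.21e-16
dispatch class            : exact_op
output bit-equal to input : True
interpolation events      : 0
```

Rotate(45°) → Zoom(1.25) → Rotate(22°) → Rotate(−22°) → Zoom(0.8) →
Rotate(−45°) would interpolate six times traditionally; composed lazily the
matrix product is the identity up to round-off, the dispatcher classifies it
as an exact operation, and the image passes through bit-for-bit.

The other examples tell the same story on different axes
(`python examples/04_entropy_forward.py`):

```
lazy       : entropy loss 0.641 ± 0.085 bits, 1 interpolations/sample
traditional: entropy loss 0.804 ± 0.106 bits, 3 interpolations/sample
paired sign test (traditional loses more): p = 9.54e-07
```

Identical random augmentations, identical inputs; the only difference is
*where* resampling happens — once (lazy) or at every lossy stage
(traditional) — and the traditional pipeline loses measurably more
information.  `examples/05_label_roundtrip.py` shows the label analogue
(round-trip Dice 0.993 lazy vs 0.985 traditional at 2 vs 6 nearest-neighbour
resamples), and `examples/02_moire_checkerboard.py` and
`examples/03_patch_viewport.py` demonstrate moire artifacts and
non-destructive cropping.

## Command-line interface

```bash
lazyresample fixtures generate --out fixtures/ --n 5 --shape 64,64,64
lazyresample run forward   --n-samples 20 --out reports/forward
lazyresample run roundtrip --n-runs 10 --out reports/roundtrip
lazyresample run moire     --out reports/moire     # writes a PNG image grid
```

Pipelines can also be given declaratively (YAML/JSON) via
`lazyresample.config`; see that module's docstring for the schema.

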