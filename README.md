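# svmpsf

Spatially variant PSF modeling and deconvolution for multimode-fiber
micro-endoscopy (and any 2-D imaging system whose point spread function
varies across the field of view).

Scanning micro-endoscopes built on step-index multimode fibers (MMFs) form
their focus by wavefront control; the effective numerical aperture decays
from the fiber-core center outward, so foci at the edge of the field of
view (FOV) are broader and radially elongated. A single-PSF deconvolution
cannot undo that blur. `svmpsf` implements the modal workaround:

1. **Model** — crop a square patch around each recorded calibration focus,
   eigendecompose the patches' second-moment matrix, and expand the local
   PSF on the resulting orthonormal *eigen-PSFs*:

   `P(u, v, x, y) = Σᵢ aᵢ(u, v) pᵢ(x, y)`

   where the coefficient maps `aᵢ` (projected at the grid points,
   bicubically interpolated in between) carry all the spatial variability.
2. **Deconvolve** — a modified Richardson-Lucy iteration with l1
   total-variation regularization in which both the forward blur and the
   correction use the modal model:

   `S_{k+1} = TV_k · F⁻¹{ Σᵢ F{p̂ᵢ}·F{aᵢ·R_k} } · S_k`,
   `R_k = I / F⁻¹{ Σᵢ F{pᵢ}·F{aᵢ·S_k} }`

   which deblurs *and* spatially regularizes the point response,
   effectively enlarging the usable FOV.

A synthetic-data module generates focus-grid calibration stacks and bead
phantoms with a controllable ground-truth variant PSF, so the whole chain
is testable without an optical setup. See `docs/methods.md` for the model,
its assumptions, and numerical choices.

## Worked example

Simulate a 13×13 focus grid on a 120×120-px FOV (0.435 µm/px, foci ≈1.9×
elongated at the edge), build the model, and deconvolve the grid image:

```sh
svmpsf simulate --grid 13 --frame 120 --seed 1 \
    --out-stack foci.tif --out-positions foci.csv
# wrote 169 frames to foci.tif

svmpsf build-model --stack foci.tif --positions foci.csv --crop 15 --out model.h5
# model: 225 eigen-PSFs of 15x15 px from 169 foci -> model.h5

svmpsf deconvolve --image raw.tif --model model.h5 \
    --iterations 500 --modes 30 --lambda-tv 0.002 --post-sigma 0.667 \
    --out deconv.tif --diagnostics diag.csv
# deconvolved 120x120 image (500 iterations, 30 modes) -> deconv.tif

svmpsf report --stack foci.tif --positions foci.csv --model model.h5 \
    --mode-counts 1,3,10,30,225 --out rms.csv
```

The report table (normalized RMS reconstruction error per radial bin, in
px from the FOV center) shows why ~30 modes suffice: with a single mode
(the average PSF) the error grows with radius, while 30 modes hold it flat
across the whole FOV:

| modes | r 0–16 | r 16–33 | r 33–49 | r 49–66 |
|------:|-------:|--------:|--------:|--------:|
|     1 | 0.196  | 0.209   | 0.287   | 0.353   |
|     3 | 0.172  | 0.086   | 0.081   | 0.131   |
|    10 | 0.021  | 0.011   | 0.011   | 0.014   |
|    30 | 0.0003 | 0.0003  | 0.0003  | 0.0003  |
|   225 | 0.0000 | 0.0000  | 0.0000  | 0.0000  |

On the same study, the edge-to-center ratio of radial 1/e² point-response
radii is 1.97 before deconvolution, 1.29 after 500 iterations with 30
modes (still decreasing toward 1), and 3.37 with a single mode — using too
few modes makes the spatial non-uniformity *worse*, not better.

The same in Python:

```python
from svmpsf import (SyntheticSceneSpec, generate_focus_grid,
                    build_eigen_psf_model, deconvolve, DeconvConfig)

spec = SyntheticSceneSpec()                      # 120x120, 13x13 grid
grid = generate_focus_grid(spec)
model = build_eigen_psf_model(grid, crop_size=15)
print(model.coeff_samples[0].mean())             # mode-1 coefficient ~0.96
result = deconvolve(grid.frames.sum(axis=0), model,
                    DeconvConfig(iterations=500, n_modes=30))
```

## Data formats

Images travel as multi-page float32 grayscale TIFF; grid positions as CSV
(`index,row,col`, 0-based pixel centers, row/col order documented in the
header); models as a single HDF5 container (`eigen_psfs`, `eigenvalues`,
`coeff_samples`, `coeff_maps`, `positions` + JSON metadata); every CLI run
writes a `*.provenance.json` record sufficient to reproduce it.
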