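# noseforge

Semi-automated design of nasal prostheses and their two-part 3D-printable
molds, driven by statistical shape modeling.

After a total rhinectomy, a patient's prosthesis is traditionally sculpted
and fitted by hand — a slow process whose result depends heavily on the
anaplastologist's skill, and for the nose there is no contralateral template
to copy. `noseforge` replaces the sculpting with statistics: a morphable
face model (MFM) — a PCA model over a database of face surfaces in
vertex-wise correspondence — is fitted to the patient's defect-masked face
scan, producing a complete face that is statistically consistent with the
intact facial remainder. Cropping the fitted surface to the nasal area
gives the nose model (NM); subtracting the patient's face model (FM) gives
a prosthesis model (PM) that seats seamlessly on the skin,

```
PM = NM − FM,
```

and a geometric protocol converts the PM into a two-part mold (anterior and
posterior shells, flat flanges with a 0.3 mm closure offset, 4 mm walls)
ready for stereolithography printing and conventional silicone casting.

The fit is shape-model ICP: closest-point correspondences from the model to
a dense sampling of the scan — rejecting pairs that are too distant, have
incompatible normals, or touch the defect boundary — alternate with a rigid
refinement and a ridge-regularized solve for the standardized coefficients
`c` of the shape `x = x̄ + B(c ⊙ σ)`. Model flexibility beyond the training
span comes from appended smooth squared-exponential deformation modes (the
Gaussian-process morphable model construction).

Because public morphable-model datasets are license-gated, the package
ships a first-class synthetic face generator (shared-topology height-field
faces with parametric, population-correlated noses, simulated rhinectomy
defects, and a CT voxelization route) so the entire workflow is testable
and reproducible offline. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

Build a model from a synthetic population, simulate a patient, and run the
full pipeline:

```sh
noseforge build-model --n 40 --seed 42 --out model.npz
noseforge synth face --seed 123 --out face.ply \
    --landmarks-out landmarks.json --nose-mask-out nose_mask.json
noseforge synth defect --face face.ply --nose-mask nose_mask.json \
    --out scan.ply --seed 1
noseforge run --scan scan.ply --landmarks landmarks.json \
    --model model.npz --out results/
```

which prints

```
model: rank 76, 9216 vertices -> model.npz
face: 9216 vertices -> face.ply
defected face: 8342 vertices -> scan.ply
pipeline complete; manifest at results/manifest.json
```

The model has 26 PCA modes from the 40-face population plus 50 smooth
deformation modes (rank 76). The "patient" scan lost 874 vertices to the
simulated rhinectomy. `results/` then contains the fitted face, the cropped
nose (`nm.ply`), the watertight prosthesis (`pm.ply`), the two printable
mold parts (`mold_anterior.stl`, `mold_posterior.stl`) and a manifest with
input/output hashes and per-stage timings. `results/fit_log.json` records
the fit: final residual 0.02 mm RMS over 7354 accepted correspondences.
The whole run takes under three minutes on one CPU; the design stage
(thickening, face subtraction, mold generation on a 0.4 mm signed-distance
grid) dominates.

The same stages are available individually (`noseforge fit`,
`noseforge design`, `noseforge synth ct`, ...) and as library functions
(`noseforge.fit_model`, `noseforge.build_prosthesis_solid`,
`noseforge.generate_mold`, ...).

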