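# Methods

`noseforge` implements a digital workflow for nasal prosthesis design: a
statistical (morphable) face model is fitted to a surface scan of a face with
a nasal defect, the missing nose is reconstructed from the intact facial
remainder, and the reconstruction is converted into a prosthesis solid and a
two-part, 3D-printable mold. This note records the models, the numerical
choices and the limits of what the synthetic validation shows. All lengths
are millimetres; this is fixed, not configurable, because every protocol
parameter (wall thicknesses, offsets, print resolutions) is metric.

## Shape model

The morphable face model is a point-distribution model: `n` training
surfaces in vertex-wise correspondence are rigidly aligned by generalized
Procrustes analysis (no scale normalization by default — prosthesis design
is metric, and a face's absolute size matters), stacked as 3N-vectors and
decomposed by PCA. A shape is `mean + B (c ⊙ σ)` with orthonormal basis `B`,
per-mode standard deviations `σ`, and standardized coefficients `c` (units
of SDs), so an isotropic ridge penalty `λ‖c‖²` is exactly a Gaussian shape
prior.

Modes with σ below `min_mode_sd` (default 0.01 mm) are discarded at build
time. PCA of a finite sample always produces trailing modes whose variance
is numerical residue; a direction whose total surface effect is a hundredth
of a scanner's 0.3 mm resolution carries no anatomy, and its standardized
coefficient is unidentifiable from any surface data. `min_mode_sd=0`
restores the complete decomposition (used where exact training-data
reconstruction is the point).

**Flexibility augmentation.** To let the fit reach shapes outside the
training span, low-rank eigenmodes of a smooth squared-exponential
deformation covariance (variance 1 mm², length scale 30 mm, 50 modes by
default) are appended, the Gaussian-process morphable model construction.
The scalar kernel is eigendecomposed by Nyström approximation on a
deterministic vertex subsample (≤ 700 points) with out-of-sample extension;
each scalar mode yields three axis-aligned vector modes. New modes are
orthogonalized against the kept PCA basis, so every base-model shape remains
exactly representable and the rank grows by exactly the requested count.
The defaults add sub-centimetre, face-scale-smooth variability — enough to
absorb individual detail the exemplar database cannot express, small enough
not to swamp the learned statistics.

**Conditioning.** `posterior_model` performs exact Gaussian conditioning of
the coefficient distribution on noisy point observations; the posterior
covariance `S C S` is re-eigendecomposed so the returned object is again a
valid model (orthonormal modes, non-increasing spreads, every posterior
variance bounded by the prior's).

## Fitting

Fitting is deterministic iterative closest point in coefficient space.
Landmarks give the initial similarity transform (closed-form Kabsch; scale
off by default). Each iteration:

1. correspondences from every model vertex to the nearest point of a dense
   sampling of the target (spacing 1.2 mm), rejecting pairs farther than
   5 mm, with normals differing by more than 60°, or whose target point lies
   within 2.5 mm of the defect boundary — the erased region can therefore
   never influence the solution;
2. a rigid refinement (Kabsch on the accepted pairs), then a ridge solve for
   the coefficients (weight 0.1, clipped to ±3 SD).

Iteration stops when the data RMS changes by under 0.01 mm (at most 50
iterations). The data term is non-increasing across iterations by the usual
ICP argument. All fitting hyperparameters live in `FitConfig`; none are
taken from literature — they are package defaults, exposed for adjustment.
For the self-consistency check (fitting a complete, noise-free model
instance) the ridge weight is set to zero: with complete data the prior is
unnecessary and only biases low-variance modes; that check exercises the
correspondence and solver machinery, not the prior.

## Geometric kernel

Closest-point queries, generalized winding numbers (van Oosterom–Strackee
solid angles), Möller–Trumbore ray casting, and signed-distance resampling
are implemented in-package on numpy/scipy/scikit-image; `trimesh` provides
the mesh container, file I/O and topology utilities.

**Booleans** are regularized SDF booleans: both operands are sampled on a
common jittered grid (per-axis irrational offsets, so grid points never sit
on mesh vertices, edges or 45° symmetry planes), combined with min/max, and
the zero set extracted by marching cubes. Inside/outside is exact for
watertight input (even–odd parity of vertical ray crossings, rasterized per
triangle); the magnitude near the surface uses a tangent-plane correction so
the zero crossing lands on the true surface well below the grid spacing.
Far-field magnitudes saturate at six cells — only the near band shapes the
level set, and capping the KD-tree search keeps the cost near-band bound.
Operands are cropped in x/y to the grid footprint (sign-safe: removed
triangles cannot cross a grid column, and far distances can only be
overestimated, which no min/max combination can flip). Disjoint operands
short-circuit without resampling. Default spacing targets ~1.5 M cells,
clamped to [0.2, 0.6] mm.

**Shell thickening** (`solidify_shell`) is constructive rather than
SDF-resampled: vertices are displaced along a smoothed vertex-normal field
and the rim is stitched with a triangle band, giving exact metric thickness
and analytic volumes on smooth surfaces (hemisphere shell volume within
0.2% of closed form). Rim normals are frozen during the normal smoothing —
averaging them toward the interior tilts the offset direction at an open
boundary (measured 0.27 mm rim dip on the toy case before the fix). Callers
may supply an explicit offset-direction field for sheets whose
winding-propagated normals are unreliable. Self-intersecting results
(surfaces too concave for the requested thickness) are detected via the
watertightness check and rejected.

## Design protocol

The eleven-step protocol is automated end to end; the two case-specific
steps of the clinical workflow (border definition, nostril sculpting) are
parameterized operations whose inputs can be replaced by externally edited
meshes. Parameters, with the three protocol-fixed values and the package's
own defaults:

| parameter | default | origin |
|---|---|---|
| prosthesis wall | 6 mm | protocol |
| mold closure gap | 0.3 mm | protocol |
| mold shell wall | 4 mm | protocol |
| blend width / depth | 3 / 0.5 mm | package default |
| densify target edge | 0.5 mm | package default |
| smoothing iterations | 10 | package default |
| flange width | 10 mm | package default |
| face backing depth | 30 mm | package default |
| boolean grid spacing | 0.4 mm | package default |

Pipeline: densify the nose surface; blend its border `blend_depth` below
the face surface over a cosine band (`blend_width`), guaranteeing a thin
feathered edge after subtraction; thicken inward by the prosthesis wall;
smooth the inner sheet; close the face surface into a solid (30 mm backing)
and subtract it — the connecting surface then lies on the skin by
construction; smooth the connecting surface; optionally subtract capped
nostril cylinders (1 mm proud of the entry point, exactly `depth` deep).

**Mold.** The prosthesis surface is split along its edge curve into the
anterior (visible) and posterior (skin-facing) sheets using provenance
labels (each vertex assigned to whichever reference surface — blended outer
nose, inner offset sheet, face — it is nearest). The binary face labelling
is regularized by majority filtering plus island absorption so the
interface is a simple curve. Both sheets receive a flat flange annulus in
the fitted parting plane, the anterior one lifted by the closure gap so the
flanges are parallel and exactly 0.3 mm apart while the halves still pinch
the prosthesis edge (that pinch seals the cavity, so the closure gap is
measured on the flange annuli excluding a 1.5 mm collar around the pinch
line). Each composite sheet is thickened away from the cavity by the shell
wall; the offset directions are the prosthesis's own outward normals on the
sheets, the parting normal on the flanges, faded into the parting normal
over a 3 mm collar around the pinch line (where the split slices the
feathered wedge and winding-propagated normals are meaningless).

**Casting simulation.** The cavity is the space inside the parting prism
occupied by neither shell, restricted to connected components that overlap
the prosthesis (enclosed pockets elsewhere — e.g. under the posterior dome
— are not reachable by silicone); the flange ring is excluded from the
tolerance, matching the protocol's intent. On the toy case the cast replica
matches the prosthesis to 0.04 mm at the 95th percentile.

**Measurement protocols** (fixed so the numbers are well-defined): wall
thickness is the median of ≥ 800 inward ray casts from the relevant sheet,
excluding two blend widths around the rim; closure gap is the minimum exact
point-to-mesh distance from anterior flange samples to the posterior shell.

## Synthetic data

The generator emulates a face-scan database: smooth height-field faces on a
shared (u, v) grid (96×96 over 170×210 mm by default), so all faces are in
exact correspondence. The nose is an additive analytic bump (two Gaussian
ridge lobes for tip and bridge, lateral Gaussian profile, gated nostril
indentations) controlled by eight parameters with documented normal
marginals (e.g. nose length 50 ± 4 mm, tip projection 18 ± 2.5 mm).

Parameters are **not** sampled independently: they load on three latent
factors (overall size, profile prominence, transverse width) with
per-parameter residuals scaled so the marginals are unchanged. This is
deliberate: in real faces nasal morphology covaries with the rest of the
face, and that covariation is precisely what a morphable model exploits when
it reconstructs a missing nose from the intact remainder — under parameter
independence the Bayes-optimal reconstruction would be the population mean
and no method could beat the prior SD. Brow prominence and cheek fullness
were included as observable correlates so the latent factors are
identifiable from a defect-masked face.

Rhinectomy simulation erases the nose patch dilated by a resection margin
(default 5 mm) and roughens a 4 mm collar around the crater rim with
Gaussian normal-displacement noise (default SD 0.1 mm, a scar-tissue and
scan-noise stand-in below the 0.3 mm optical scan resolution). The crop
region stored with a model extends 9 mm past the nose patch (resection
margin plus a 4 mm seating band) so the prosthesis border lands on intact
skin. The CT route closes the face into a solid, samples its occupancy on an
anisotropic voxel grid (default 0.46 × 0.46 × 1.0 mm, typical head-CT pixel
spacing and slice thickness) and re-extracts the isosurface.

What passing on this generator does **not** show: real scans have
texture-correlated noise, holes, hair and expression; real face-nose
covariation is richer (and weaker per-feature) than a three-factor model;
and real defect margins are irregular scar tissue, not dilated analytic
masks. The synthetic results validate the machinery and the protocol
geometry, not clinical accuracy.

## Reference figures computed by the test suite

On the hemisphere-on-plane toy case the achieved geometry reproduces the
protocol settings (median prosthesis wall 6.01 mm, closure gap 0.300 mm,
shell walls 4.00 mm, cavity error 0.04 mm p95). On the default synthetic
study (population 40, grid 96×96): full-surface coefficient recovery to
~0.01 SD and 10⁻⁴ mm RMS; nose reconstruction on the default fixture
~0.07 mm RMS; over 20 seeded cases mean ~0.4 mm RMS against a nose-region
population SD of ~1.4 mm. The full pipeline (population → model → defect →
fit → design → mold export) runs in under two minutes on one CPU.

## Known limitations

- The split into mold halves relies on provenance labels; prostheses whose
  edge curve is highly non-planar would produce warped flanges (the flange
  is flattened into the fitted parting plane).
- Nostril cylinders deeper than the prosthesis wall would pierce the inner
  sheet; the operation guards against shell separation but not against
  through-holes, which would add boundary loops the mold split does not yet
  handle.
- `solidify_shell` rejects, rather than repairs, self-intersecting output on
  strongly concave surfaces with large thickness.
- The parity voxelization assumes watertight operands; it is exact there but
  has no defined semantics on meshes with holes (open face scans are closed
  by the backing solidification first).
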