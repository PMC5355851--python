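# Methods

This note records the models, conventions and numerical choices behind
`vertexrec`, and what the synthetic experiments do and do not demonstrate.

## Conventions

**Orientations.** A pose is an intrinsic ZYZ Euler triplet
(`rot`, `tilt`, `psi`, degrees) with in-plane origin shifts (`dx`, `dy`,
pixels). The matrix `R = Rz(psi) @ Ry(tilt) @ Rz(rot)` maps reference-map
coordinates to the particle-image frame; an image is the line integral of
the rotated map along the image z axis, translated by the shifts. This is
the dominant single-particle metadata convention, and STAR columns use the
conventional names (`rlnAngleRot/Tilt/Psi`, `rlnOriginX/Y`). At
gimbal-degenerate tilts (0°, 180°) the triplet is canonicalized with
`rot = 0` and `psi` absorbing the full in-plane angle.

**Icosahedral frame.** The group `I` (order 60) is built in the 222
setting: two-fold axes on the coordinate axes, five-fold axes the
normalized cyclic permutations of (0, ±1, ±φ). The generator set (two
orthogonal two-folds plus one five-fold) is closed numerically and the
order asserted. Each vertex's *canonical frame* is the minimal rotation
taking +z to the vertex axis; antipodal vertices are distinct subparticles
facing opposite directions.

**Symmetry expansion.** For vertex k with axis a, the five particle poses
`R @ Rot(a, 72°j)` are equivalent views of that vertex. One is chosen per
subparticle by a seeded uniform draw, so the set of subparticle orientations
is not biased toward any stabilizer member. Since
`Rot(a,72°j)·V_k = V_k·Rz(72°j)`, the true apparent turret azimuth of a
subparticle is `(azimuth_k − 72°j) mod 60°`, which the simulator records as
ground truth.

## Caspar–Klug lattice (T = 13)

The facet triangle with corners (0,0), h·a1+k·a2 and its 60° rotation is
laid over the unit triangular lattice; the centroids of the small up/down
triangles are trimer positions (3 chains each). For T=13 no centroid falls
on a facet edge (`t(k−h) ≡ 0 mod 3` has no solution with t ∈ {1,2}), so
strict inclusion enumerates exactly 13 centroids per facet and 260 per
capsid with no boundary double counting. Centroids map to the sphere
barycentrically through each face's vertex triple (positively oriented, so
handedness is preserved); `laevo` is (h,k) = (1,3) in a right-handed frame
viewed from outside, `dextro` swaps h and k — the two layouts are exact
mirror images (verified to 1e-9).

Typing is by ranked angular proximity with tie-break order T→P→Q→S→R: the
20 trimers on three-fold axes are T; of the rest, the 60 nearest five-fold
axes are P and the next 60 are Q; of the remainder the 60 nearest two-fold
axes are S; the last 60 are R. The ranking gaps are wide (no tolerance
sensitivity), and typing is invariant under any icosahedral rotation of the
whole lattice. P trimers are removed from the returned outer-shell layout
(turrets occupy the vertices), leaving 200 trimers = 600 chains, i.e. 10
chains per asymmetric unit with the on-axis T trimers contributing one
chain each. Conformation labels: within each Q trimer the chain angularly
nearest its five-fold axis is *closed* (the position sterically blocked by
the vertex turret), all others *open* — 60 closed, 540 open.

## Phantom

A desk-scale double-shelled particle in a 96-voxel box at 1.35 Å/pixel
(half-width 64.8 Å). Default geometry, chosen once so that every component
fits the box with margin for subparticle cropping at the particle edge:

| component | default | rationale |
|---|---|---|
| inner shell | r = 22 Å, 4 Å thick | smooth sphere, cosine edges |
| outer shell | r = 30 Å, 4 Å thick | with 24° half-angle openings at the 12 vertices (no trimers under the turrets) |
| RNA layers | 1 layer, 30 Å spacing | concentric shells ~3 nm apart under the inner shell; one fits at this scale |
| turret | center 42 Å out, 6 Gaussian arms on an 11 Å ring, σ = 2 Å, amplitude 1.6 | C6 about its own axis; arm spacing 5.5σ gives strong azimuthal contrast |

Arm geometry matters: the correlation between a turret and its
azimuth-average (what icosahedral symmetrization produces) is ≈ 0.64 at
this spacing, leaving clear headroom between a correct localized
reconstruction (> 0.9) and the blurred global map. All components are
additive, so `full = hexamer_map(k) + all_but_one_map(k)` holds voxelwise
exactly for every vertex — subtraction tests are exact, not approximate.
Each vertex gets an independent azimuth in [0°, 60°); this is the symmetry
mismatch. Arms are evaluated on 4σ subboxes; integer placement of that
window can shift by one voxel when an arm center sits exactly on a grid
line, bounding mod-60 reproducibility at ~1e-4 of the peak rather than
machine precision.

## Image formation

Projection is real-space: trilinear (optionally cubic) resampling of the
rotated map, summed along z and scaled by the voxel size (flux conserving
to 0.1%). Trilinear interpolation is the accuracy floor quoted by the
equality tests. A `FourierProjector` (central-slice gather from a 2×
zero-padded 3D FFT) provides fast repeated projections for grid searches
and agrees with the real-space projector to > 0.999 correlation.

CTF: weak-phase model `−√(1−A²)·sin χ − A·cos χ`,
`χ(f) = πλΔz f² − (π/2)Cs λ³f⁴`, astigmatism as direction-dependent Δz,
no envelope. Defaults 300 kV, Cs 2 mm, amplitude contrast 0.1, defocus
uniform in 0.3–3.0 µm. Noise is additive white Gaussian after the CTF; the
pipeline's "moderate noise" is σ = 0.5 × the clean projection RMS
(per-pixel SNR ≈ 4). Real micrographs are far noisier per pixel but
average over ~10² more subparticles; this level was chosen once so that a
normal 200-particle run exercises noise robustness without requiring the
full-size dataset, and is not adjusted per experiment.

## Subtraction

The all-but-one reference for vertex k is `full × (1 − m)` with m a soft
cylindrical-cap mask along the vertex axis (axial start 35 Å, radius 21 Å,
3-voxel raised-cosine edges) — the turret sits above the outer shell, and
the shell openings at the vertices mean the cap contains turret density
only. Subtraction acts on the full particle image before cropping:
`image − s·CTF(proj(reference))`, with s = 1 or a least-squares amplitude
fit over a background annulus (25–48% of the box radius). The
`SubtractionEngine` avoids re-projecting the full box per vertex by reusing
one full-map projection per particle and projecting the kept turret from a
small crop pasted at its projected position (agrees with direct
subtraction to < 0.1% of image RMS).

## Azimuth assignment and reconstruction

Azimuths are assigned by a deterministic grid search (default step 2°, a
stand-in for maximum-likelihood classification): normalized
cross-correlation between the subtracted image and projections of the C6
reference at `R_sub · Rz(φ)`. Two points matter at high defocus, where the
CTF point spread delocalizes signal tens of pixels:

1. matching uses the **full subtracted parent frame**, not the small crop,
   so delocalized turret signal contributes;
2. the reference projection is pasted at the subparticle's parent
   coordinates and CTF-modulated **on the parent grid**, so its point
   spread (including wrap-around) matches the data's exactly.

With this, noise-free recovery is ≥ 95% within one grid step across the
full 0.3–3.0 µm defocus range. Exact side views of the planar, achiral arm
ring cannot distinguish azimuth +φ from −φ (a measure-zero degeneracy in
practice); top views degrade gracefully and are excluded by the 40°
side-view filter anyway.

Backprojection is direct Fourier inversion: each image's 2D FFT is
inserted as a central slice (trilinear spreading, samples beyond the cube
dropped) at every pose of the symmetry expansion `R·G`; origin shifts are
applied as phase ramps. Normalization is Wiener-style,
`ΣCTF·F / (ΣCTF² + ε)` with `ε = 1e-3 × mean(CTF²)` over filled voxels,
followed by division by the real-space sinc² envelope of the trilinear
kernel. The C6 localized reconstruction backprojects the full-frame
subtracted images (shifts recenter the turret) for the same
CTF-consistency reason as above, then crops the central region. Half-maps
split by even/odd **parent particle id** (never by subparticle) in a single
accumulation pass, so the gold-standard half-sets share no particle. The
icosahedral comparison map is a C1 reconstruction of the particle images
averaged over the 60 group rotations in real space (equivalent to, and
much cheaper than, 60-fold pose expansion).

FSC is the shell-wise normalized real part of `ΣF₁F₂*`; resolution is the
linear interpolation of the first downward crossing of the threshold
(default 0.143), or Nyquist if no crossing. Sharpening multiplies
amplitudes by `exp(−B·s²/4)` (B = −600 Å² boosts 1/9.1 Å⁻¹ by ≈ 6.12); the
low-pass is a raised cosine ending exactly at the cutoff frequency.

## Conformational analysis

Superposition is Kabsch SVD on C-alpha coordinates paired by the
intersection of author residue numbers, with the determinant correction
forcing a proper rotation in reflection-optimal cases. The two-domain
chain model uses peripheral domain 1–83, linker 84–93 (ending in the
helix-breaking proline), core domain 94–149. The hinge is operationalized
as: superpose CD→CD, then the transform carrying the CD-aligned PD onto
the target PD; its rotation angle and the PD centroid displacement are the
reported hinge descriptors (symmetric in the two chains). Interface-angle
change between expansion states conjugates the state-2 chain-to-chain
rotation into state 1's frame via a chain-A pre-alignment before composing
with the inverse of state 1's rotation — without the pre-alignment the
measure would depend on the arbitrary deposition frames. Constructed
motions (a 71° PD hinge, a 57° re-hinged dimer) are recovered exactly;
applying measurements to deposited models requires only local PDB/mmCIF
files (read through gemmi, author numbering).

## Problem sizes

The test-scale experiment is 200 particles in a 96-voxel box (≈ 1,540
side-view subparticles, 32-voxel crops, 2° azimuth grid), which runs in a
few minutes on one CPU; the noise-free azimuth control uses 40 particles.
These sizes are the package's validation conditions, not estimates of a
real dataset's; a full-size study (512-voxel boxes, ~10⁴ particles) uses
the same code paths at proportionally higher cost.

## What the synthetic experiments do not show

The phantom has exact additive components, no structural noise, no
solvent, no inter-particle background, no beam-induced motion, no dose
damage, and per-particle poses/CTFs known exactly (no alignment errors).
Passing the pipeline's tests therefore demonstrates the correctness of the
geometry, bookkeeping, subtraction, assignment and reconstruction
machinery — not that real micrographs of comparable size would reach the
same turret fidelity, which additionally depends on refinement quality and
classification of heterogeneity, both out of scope here. The FSC of the
desk-scale reconstruction reflects the phantom's band limit and noise, not
any resolution claim about real data.
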