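# Methods

## Model

The segmenter is a region-based active contour. The contour C is the zero
crossing of a level-set function ϕ (ϕ > 0 inside, ϕ < 0 outside) evolving on
the pixel grid with unit spacing. Its energy has three parts.

**Joint local binary fitting (LBF) data term.** For each pixel x the local
inside/outside fitting values of an intensity channel I are Gaussian-weighted
averages gated by the smoothed Heaviside H_ε(ϕ),

    f1 = K_σ∗(I·H_ε(ϕ)) / K_σ∗H_ε(ϕ),
    f2 = K_σ∗(I·(1−H_ε(ϕ))) / K_σ∗(1−H_ε(ϕ)),

with K_σ a Gaussian kernel (σ = 1.5 px, truncated at 4σ, unit sum).  Fitting
locally rather than globally is what makes LBF robust to smooth intensity
inhomogeneity.  Two channels are fitted: the CT gray values (range 0–255) and
the SUV map min–max rescaled to [0, 255] over the ROI so the channel weights
Λ₁ = Λ₂ = 1 act on commensurable scales.  The pointwise residuals are

    e1(x) = F1(x)·[Λ₁(I_ct − f1_ct)² + Λ₂(I_suv − f1_suv)²],
    e2(x) = F2(x)·[Λ₁(I_ct − f2_ct)² + Λ₂(I_suv − f2_suv)²].

**SUV information-entropy edge guide.** F1/F2 weight the residuals by how
homogeneous the tracer uptake is on each side of the contour.  Around a
contour point x a disk R(x) of radius r = 15 px is split by the sign of ϕ
into an inside part Ω₃ and an outside part Ω₄.  The SUV values of a part are
modelled as approximately Gaussian; evaluating that density at each pixel of
the part and normalising gives a discrete distribution whose Shannon entropy
H (bits) is maximal, log₂ n, when the part is homogeneous.  The guide weight
is F_i = exp(−H_i): smallest where uptake is homogeneous (the contour should
stop), larger where the neighbourhood mixes nodule and vessel/background
uptake (the contour should keep moving).  This is what lets the contour
detach a vessel whose CT gray equals the nodule's.  The guide is recomputed
every iteration, but only within a band |ϕ| ≤ 3 px of the contour (elsewhere
the smoothed Dirac factor makes the data force negligible and F ≡ 1); a very
large `band_px` recovers full-field evaluation.

**Regularisers.**  A length penalty ν·∫δ_ε(ϕ)|∇ϕ| (ν = 0.001·255², matching
the squared-residual scale of 8-bit images) keeps the contour smooth and
shrinks thin spurs such as detached vessel segments, and a distance penalty
μ·∫½(|∇ϕ|−1)² (μ = 1) nudges ϕ toward a signed distance function in place of
explicit reinitialisation.

**Gradient flow.**  The energy is minimised by the explicit descent

    ∂ϕ/∂t = −δ_ε(ϕ)(λ₁e1 − λ₂e2) + ν·δ_ε(ϕ)·div(∇ϕ/|∇ϕ|) + μ·(∇²ϕ − div(∇ϕ/|∇ϕ|)),

with H_ε(x) = ½(1 + (2/π)arctan(x/ε)), δ_ε its derivative, ε = 1, and
λ₁ = λ₂ = 1.  ϕ is initialised as the signed Euclidean distance to the
initial contour (a flat initialisation is degenerate — the gradient flow
cannot start from ϕ ≡ 0).  The run stops when the energy is stable,
|F_k − F_{k−1}| ≤ χ = 10⁻³, or after K_max = 300 iterations.

## Pipeline

* **ROI**: Otsu threshold on CT, border-touching components discarded, a
  disk closing (radius 3 px) seals vessel bands that would otherwise split
  the lung field or connect the nodule to the lung boundary, holes filled,
  disk opening (radius 2 px), largest one or two components kept.  The
  maximum-SUV pixel O inside the lung mask (row-major tie-break) is the
  nodule marker; the ROI is the disk of radius R = 30 mm around O (mm → px
  rounded to the nearest integer), chosen to cover nodules up to 30 mm
  diameter.
* **Initial contour**: threshold iteration with T₀ = (G_max+G_min)/2 and
  T ← (α_b+α_n)/2 until |ΔT| ≤ λ = 0.1 (an emptied class keeps the previous
  threshold as its mean, which terminates the iteration); binarisation at
  I ≥ T; 8-connected components; the boundary of the largest (hole-filled)
  component, traced at the 0.5 level (sub-pixel, closed).
* **Evolution** on the ROI bounding box padded by r; the final mask is
  {ϕ ≥ 0} clipped to the ROI disk.
* **Output extraction**: while a vessel is carved away the zero level set
  legitimately splits into several closed curves; the tool returns the
  component containing the seed O (fallback: the largest).  The classic-LBF
  baseline applies the identical rule, so method comparisons are unaffected
  by it.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `lambda_tol` | 0.1 | threshold-iteration stopping tolerance (gray levels) |
| `R_mm` | 30 | ROI template radius (mm) |
| `r_px` | 15 | entropy neighbourhood radius (px) |
| `sigma_g` | 1.5 | LBF Gaussian kernel std (px) |
| `nu` | 0.001·255² | length-penalty coefficient |
| `mu` | 1 | distance-regulariser coefficient |
| `chi` | 1e-3 | energy-stability stopping tolerance |
| `k_max` | 300 | iteration cap |
| `epsilon` | 1 | Heaviside/Dirac smoothing width |
| `lambda1, lambda2, Lambda1, Lambda2` | 1 | region / channel weights |
| `dt` | 0.01 | descent time step (see below) |
| `band_px` | 3 | guide evaluation band around the contour (px) |
| `sigma_floor` | 1e-3 | minimum SUV std in the entropy model |
| `open_radius_px` | 2 | lung-mask opening radius (px) |

## Numerical choices

* **Time step.** The explicit scheme must respect the stability bound of the
  dominant length term, ν·dt·max δ_ε ≤ ~0.25, i.e. dt ≲ 0.012 for
  ν = 0.001·255²; the default is dt = 0.01.  At dt ≥ 0.05 the data force
  steepens ϕ near the interface faster than μ can relax it, the distance
  penalty grows and the zero crossing effectively stalls.
* **Step-size control.** The fitting values and guide weights are
  re-estimated from ϕ every iteration, so the total energy is not monotone
  across iterations by construction (alternating estimation).  Descent is
  therefore enforced per step against the energy of the *frozen* current
  fields: a step that raises that energy by more than 10⁻⁶·F₀ is rejected
  and dt halved, up to 6 times.  `evolve.descend_fixed` exposes the strict
  fixed-field descent loop separately.
* **Discretisation.** Central differences (`np.gradient`) for ∇ϕ and the
  curvature div(∇ϕ/|∇ϕ|) with |∇ϕ| floored at 1e-10; 5-point Laplacian;
  reflecting boundary for the Gaussian convolutions; fit denominators
  floored at 1e-12.
* **Entropy model.** The continuous entropy integral is discretised as a sum
  over the region's pixels of normalised Gaussian densities, which bounds
  the entropy by log₂ n and makes a constant region exactly maximal.  The
  density prefactor cancels under normalisation, so only z-scores are
  evaluated; σ is floored at `sigma_floor` for constant regions.  A contour
  point whose neighbourhood lies entirely on one side gets neutral weights
  (1, 1).  Ties ϕ = 0 count as inside.
* **Degenerate inputs.** Constant rasters raise a degenerate-input error;
  empty masks, empty regions, a vanished zero level set and non-finite
  energies raise typed errors carrying the pipeline stage.

## Phantom

The generator emulates the clinical setting the method targets: one
transaxial slice with a solid, roughly circular nodule (default radius 7 mm;
cohorts jitter it uniformly over 3–12 mm) attached to a straight vessel band
(width 2–4 mm, random orientation) whose inner edge overlaps the nodule rim
by one pixel, inside a dark lung field (gray 40) surrounded by a bright
thorax ring (gray 210).  Nodule and vessel CT grays are nearly identical
(150 vs 145) — the configuration that defeats gray-value-only segmentation —
while the SUV levels are ordered nodule (6.0) > vessel (1.8) > parenchyma
(0.4), the contrast the entropy guide exploits.  CT is multiplied by a
low-order cosine bias field (amplitude 0.1, the smooth inhomogeneity LBF is
designed for) and both channels receive additive Gaussian noise
(σ_ct = 5 gray levels, σ_suv = 0.15).  The truth mask is the exact
pixel-centre rasterisation of the nodule disk, vessel excluded.

What the phantom does **not** model: 3-D partial-volume effects, the PET
point-spread function and the 128→512 resampling blur (an optional
block-average/upsample emulation exists but is off by default),
non-circular or part-solid nodules, vessel curvature and branching, and
registration error between the channels.  Passing the phantom tests shows
the algorithm separates attached vessels under noise and inhomogeneity at
realistic geometry and contrast; it does not certify clinical accuracy.

## Known limitations

* The published parameter scales leave μ = 1 far weaker than the data and
  length terms, so ϕ drifts from a signed distance function near the
  interface during hard runs (the distance penalty grows); the evolution
  still behaves because the guide band uses |ϕ| only locally.  The
  regulariser is verified in isolation (pure-μ descent restores |∇ϕ| → 1).
* Runs on the phantom typically use the full K_max = 300 iterations; the
  energy-stability criterion χ rarely triggers first at these energy scales.
* The entropy weights are small in absolute terms (≈ exp(−log₂ n)), so the
  guided data force is gentle and vessel carving is driven jointly by the
  guide asymmetry and the length term; very long attached structures may
  need more iterations than K_max at the default dt.
* Single 2-D slices only; no airway/vessel-tree removal; no SUV computation
  from raw DICOM counts (inputs are assumed already co-registered and in
  SUV units).
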