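# suvseg

Automatic segmentation of **juxta-vascular pulmonary nodules** in
co-registered PET-CT slices.

Nodules that grow attached to a blood vessel are hard to segment on CT
alone: nodule and vessel have nearly identical gray values, so
intensity-driven active contours leak along the vessel and oversegment.
PET adds the missing information — the standardized uptake value (SUV) of a
metabolically active nodule is markedly higher than that of blood vessels.
`suvseg` exploits this in a fully automatic pipeline for a pair of 2-D
rasters (a CT slice and a co-registered SUV map on the same pixel grid):

1. **ROI extraction** — the lung field is segmented from CT (Otsu threshold
   + morphology); the maximum-SUV pixel *O* inside it marks the nodule and a
   circular template of radius *R* = 30 mm around *O* bounds all further
   computation.
2. **Initial contour** — an automatic threshold iteration
   (T ← (α_b + α_n)/2 until |ΔT| ≤ λ) binarises the ROI; the boundary of the
   largest component is the initial contour.
3. **Level-set evolution** — a local binary fitting (LBF) active contour on
   the joint CT/SUV intensity vector, with each data residual weighted by an
   **SUV information-entropy edge guide**

   F_i(x) = exp(−H_i(x)),   H_i = −Σ p log₂ p,

   where the probabilities are normalised Gaussian densities of the SUV
   values in the inside/outside halves of a radius-*r* disk around the
   contour point x. Where the SUV distribution is homogeneous the entropy is
   maximal and the guide weight smallest, so the contour stops; where the
   neighbourhood mixes nodule and vessel uptake the contour keeps moving.
   The energy

   F = E′ + ν·L(ϕ) + μ·P(ϕ)

   adds a contour-length penalty L and a distance-regularising term
   P = ∫½(|∇ϕ|−1)², and is minimised by explicit gradient descent on the
   level-set function ϕ (positive inside) until the energy is stable
   (|ΔF| ≤ χ) or K_max iterations.
4. **Evaluation** — Dice similarity coefficient (DSC, %), symmetric
   Hausdorff distance of the boundary pixel sets (HD, mm) and false-positive
   fraction (FP, % of the truth area).

Because clinical PET-CT with expert annotations cannot ship with the code,
the package includes a seeded **phantom generator**: a disk nodule attached
to an elongated vessel band with near-identical CT gray but lower SUV,
embedded in a lung field inside a thorax ring, with Gaussian noise and a
smooth intensity-inhomogeneity field. A classic single-channel LBF
evolution is included as the reference baseline the guided model is
measured against.

## Worked example

```python
from suvseg import PhantomSpec, PetCtSlice, RunConfig, generate_phantom, run_segmentation

sample = generate_phantom(PhantomSpec(seed=3))          # 128x128, nodule r=7 mm
sl = PetCtSlice(ct=sample.ct, suv=sample.suv, pixel_spacing_mm=1.0)
record = run_segmentation(sl, RunConfig(), truth_mask=sample.truth_mask)
print(f"threshold T      : {record.threshold_T:.2f}")
print(f"stop             : {record.stop_reason} after {record.n_iter} iterations")
r = record.report
print(f"DSC              : {r.dsc_percent:.2f} %")
print(f"Hausdorff        : {r.hd_mm:.2f} mm ({r.hd_px:.2f} px)")
print(f"false positive   : {r.fp_percent:.2f} %")
```

prints

```
threshold T      : 94.02
stop             : max_iterations after 300 iterations
DSC              : 98.03 %
Hausdorff        : 1.00 mm (1.00 px)
false positive   : 4.03 %
```

The threshold ~94 sits between the parenchyma (~40) and nodule/vessel
(~150) gray levels, so the initial contour wraps the nodule *and* the
attached vessel (DSC ≈ 64 at that point); the entropy-guided evolution
carves the vessel away and stops at the nodule boundary within one pixel.

The same pipeline is available from the shell:

```sh
suvseg phantom --out ph --seed 3
suvseg segment --ct ph/sample_000_ct.npy --suv ph/sample_000_suv.npy \
               --truth ph/sample_000_truth.png --out seg
suvseg evaluate --truth ph/sample_000_truth.png --pred seg/mask.png
suvseg cohort --n 20 --seed 1 --out cohort
```

## Layout

| module | contents |
| --- | --- |
| `suvseg.phantom` | seeded CT/SUV phantom generator with ground truth |
| `suvseg.preprocess` | lung-field segmentation, max-SUV ROI template |
| `suvseg.initcontour` | threshold iteration, binarisation, contour selection |
| `suvseg.entropy` | SUV information entropy and the edge-guide field |
| `suvseg.evolve` | joint-vector LBF level set + classic LBF baseline |
| `suvseg.metrics` | DSC, Hausdorff, false-positive evaluation |
| `suvseg.pipeline` / `suvseg.cli` | orchestration, batch cohorts, CLI |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
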