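# rnflseg

Segmentation and thickness measurement of the **retinal nerve fiber layer
(RNFL)** in peripapillary OCT B-scans.

The RNFL is the hyperreflective innermost retinal layer; its thickness is the
standard structural readout for glaucoma (thinning) and optic disc edema
(thickening).  Clinical OCT devices export B-scans only as screenshots with
the device segmentation color-coded on top, and retinal vessels cast dark
vertical shadows that disrupt the posterior boundary.  This package implements
the full measurement chain:

1. **Overlay removal** — the color-coded boundary polylines are detected by
   their hue/saturation, recorded as ground truth, and removed by inpainting
   that solves the biharmonic equation, so filled regions blend seamlessly.
2. **Vessel-shadow removal** — shadows are near-vertical dark bands starting
   at the inner limiting membrane (ILM).  A truncated-SVD reconstruction
   amplifies column-coherent structure; after ILM masking, negation, mirror
   padding and gamma correction (γ = 2.2), the Radon transform concentrates
   vertical lines in its 0° projection, which is reinforced by squaring while
   other angles are attenuated by exp(−|θ|/τ).  The back-projected, detrended
   column-sum profile is thresholded at its 85th percentile to flag shadow
   columns, which are then inpainted.
3. **RNFL-Net** — a customized U-Net (encoder widths 32→256, bottleneck 512,
   3×3 kernels, batch norm, dropout 0.1, sigmoid 3-channel output) trained
   with a soft Dice loss, `L = 1 − mean_k (2Σpₖtₖ+ε)/(Σpₖ+Σtₖ+ε)`, and Adam
   (lr 10⁻⁴ decaying to 10⁻⁶).  It segments the scan into the three
   categories *above-background / RNFL / below-background*.
4. **Evaluation** — RNFL-class Dice/IoU and confusion metrics, per-boundary
   mean unsigned error (MUE), per-scan mean thickness with MAE/MAPE, and the
   nonparametric group workflow (Shapiro–Wilk, Kruskal–Wallis,
   Bonferroni-corrected Mann–Whitney U).

Because clinical scans are not redistributable, the package ships a
**phantom generator** producing OCT-like B-scans with exact ground-truth
boundaries, vessel masks and subject structure, on which every stage is
tested end-to-end.  The network runs on a self-contained numpy backend
(`rnflseg.nn`) with hand-derived backpropagation, gradient-checked against
finite differences.

## Worked example

```python
import numpy as np
from rnflseg.phantom import PhantomSpec, generate_phantom
from rnflseg.vessel import remove_vessels
from rnflseg.metrics import mean_thickness

rec = generate_phantom(PhantomSpec(seed=4, n_vessels=3, vessel_contrast=0.5))
cleaned, mask = remove_vessels(rec.image)

truth = rec.vessel_mask.any(axis=0)
flagged = mask.any(axis=0)
recall = (truth & flagged).sum() / truth.sum()
print(f"shadow columns flagged: {flagged.sum()}, recall: {recall:.2f}")
print(f"ground-truth mean thickness: {mean_thickness(rec.boundaries):.1f} px")
```

prints

```
shadow columns flagged: 23, recall: 1.00
ground-truth mean thickness: 24.0 px
```

i.e. every planted shadow column was detected (23 columns flagged,
including the shadow edges) and the phantom's band is
24 px thick on average (axial scale 1 µm/px on phantoms, so pixel and µm
values coincide).  The `rnflseg` command exposes the same stages
(`phantom`, `preprocess`, `remove-vessels`, `train`, `predict`, `evaluate`,
`run`) with a single YAML config and per-stage seeds derived from one global
seed; `rnflseg run` writes a manifest with a content hash of every output.

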