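"""Synthetic OCT-like B-scan phantoms with known ground truth.

A phantom emulates the gross appearance of a peripapillary circle scan:
a hyperreflective RNFL band between a wavy ILM surface and a posterior
boundary, darker backgrounds above (vitreous) and below (deeper retina),
near-vertical blood-vessel shadows that darken whole column intervals
from the ILM downward, and multiplicative speckle.  Every phantom comes
bundled with its exact boundary set and vessel mask so the downstream
stages (overlay removal, vessel detection, segmentation, thickness
evaluation) can be tested against known truth.

The generator is a geometric stand-in, not an optical model: speckle is
multiplicative Gaussian rather than Rayleigh, layers other than the RNFL
are flat textures, and vessel shadows are ideal column bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from rnflseg.types import BoundarySet, round_half_up

CLASS_LABELS = ("normal", "glaucoma", "edema")

#: Multiplier applied to the mean band thickness per diagnostic class.
#: Glaucoma thins the RNFL, optic disc edema thickens it; the ordering
#: (glaucoma < normal < edema) mirrors the clinical one.  These are
#: configuration values for phantoms, not clinical ground truth.
DEFAULT_CLASS_SCALES = {"normal": 1.0, "glaucoma": 0.65, "edema": 1.9}


@dataclass
class PhantomSpec:
    """Parameters of a single synthetic B-scan.

    Geometry is specified in pixels; intensities in [0, 1].  The RNFL
    band must be the brightest structure (hyperreflective, as in real
    B-scans), which is enforced at validation time.
    """

    image_height: int = 128
    image_width: int = 128
    ilm_baseline: int = 30
    ilm_waviness_amplitude: float = 4.0
    ilm_waviness_cycles: float = 2.0
    rnfl_thickness_mean: float = 24.0
    rnfl_thickness_profile: np.ndarray | None = None
    class_label: str = "normal"
    class_thickness_scale: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SCALES)
    )
    n_vessels: int = 3
    vessel_width_range: tuple[int, int] = (4, 8)
    vessel_contrast: float = 0.6
    speckle_sigma: float = 0.05
    edge_softness: int = 0
    background_intensity_above: float = 0.08
    background_intensity_below: float = 0.35
    rnfl_intensity: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image_height and image_width must be >= 32")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        if not (
            self.rnfl_intensity > self.background_intensity_above
            and self.rnfl_intensity > self.background_intensity_below
        ):
            raise ValueError(
                "rnfl_intensity must exceed both background intensities "
                "(the RNFL band is the brightest structure)"
            )
        if not 0 < self.vessel_contrast <= 1:
            raise ValueError("vessel_contrast must lie in (0, 1]")
        lo, hi = self.vessel_width_range
        if not (1 <= lo <= hi):
            raise ValueError("vessel_width_range must satisfy 1 <= lo <= hi")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be nonnegative")
        if self.edge_softness < 0:
            raise ValueError("edge_softness must be nonnegative")
        scale = self.class_thickness_scale[self.class_label]
        max_thick = self.rnfl_thickness_mean * scale
        if self.rnfl_thickness_profile is not None:
            prof = np.asarray(self.rnfl_thickness_profile, dtype=float)
            if prof.shape != (self.image_width,):
                raise ValueError("rnfl_thickness_profile must have one value per column")
            max_thick *= prof.max()
        max_row = self.ilm_baseline + self.ilm_waviness_amplitude + max_thick
        if max_row >= self.image_height:
            raise ValueError(
                "band geometry exceeds image height "
                f"(deepest boundary ~{max_row:.0f} >= {self.image_height})"
            )
        if self.ilm_baseline - self.ilm_waviness_amplitude < 0:
            raise ValueError("ILM wave rises above row 0")


@dataclass
class PhantomRecord:
    """A phantom image with its full ground truth."""

    image: np.ndarray
    boundaries: BoundarySet
    vessel_mask: np.ndarray
    subject_id: str
    class_label: str
    spec: PhantomSpec | None = None


def _band_geometry(spec: PhantomSpec) -> BoundarySet:
    cols = np.arange(spec.image_width)
    wave = spec.ilm_waviness_amplitude * np.sin(
        2 * np.pi * spec.ilm_waviness_cycles * cols / spec.image_width
    )
    upper = round_half_up(spec.ilm_baseline + wave)
    scale = spec.class_thickness_scale[spec.class_label]
    thickness = np.full(spec.image_width, spec.rnfl_thickness_mean * scale)
    if spec.rnfl_thickness_profile is not None:
        thickness = thickness * np.asarray(spec.rnfl_thickness_profile, dtype=float)
    lower = upper + np.maximum(round_half_up(thickness), 1)
    return BoundarySet(upper=upper, lower=lower)


def _place_vessels(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Non-overlapping (start, width) column intervals, >=2 px apart."""
    if spec.n_vessels == 0:
        return []
    lo, hi = spec.vessel_width_range
    intervals: list[tuple[int, int]] = []
    for _ in range(200):
        width = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, spec.image_width - width + 1))
        if all(
            start + width + 2 <= s or s + w + 2 <= start for s, w in intervals
        ):
            intervals.append((start, width))
            if len(intervals) == spec.n_vessels:
                break
    else:
        raise ValueError(
            f"could not place {spec.n_vessels} non-overlapping vessels of width "
            f"{spec.vessel_width_range} in {spec.image_width} columns"
        )
    return sorted(intervals)


def generate_phantom(spec: PhantomSpec, subject_id: str = "S0") -> PhantomRecord:
    """Render one synthetic B-scan from its spec.

    The noise-free image takes exactly the three configured intensities in
    the three bands; vessel columns are then darkened by ``vessel_contrast``
    from the ILM row to the bottom edge (a shadow column retains fraction
    ``1 - vessel_contrast`` of its intensity), and multiplicative Gaussian
    speckle ``x * (1 + N(0, sigma^2))`` is applied last, clipped to [0, 1].
    Identical spec and seed give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    boundaries = _band_geometry(spec)
    h, w = spec.image_height, spec.image_width

    rows = np.arange(h)[:, None]
    img = np.where(
        rows < boundaries.upper[None, :],
        spec.background_intensity_above,
        np.where(
            rows < boundaries.lower[None, :],
            spec.rnfl_intensity,
            spec.background_intensity_below,
        ),
    ).astype(np.float64)

    if spec.edge_softness > 0:
        # Vertical box smoothing turns the band steps into linear ramps,
        # emulating the gradual reflectivity transitions of real scans
        # (a hard step is an idealization; see the methods note).
        k = 2 * spec.edge_softness + 1
        kernel = np.ones(k) / k
        padded = np.pad(img, ((spec.edge_softness,) * 2, (0, 0)), mode="edge")
        img = np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="valid"), 0, padded
        )

    vessel_mask = np.zeros((h, w), dtype=bool)
    for start, width in _place_vessels(spec, rng):
        for c in range(start, start + width):
            vessel_mask[boundaries.upper[c]:, c] = True
    img = np.where(vessel_mask, img * (1.0 - spec.vessel_contrast), img)

    if spec.speckle_sigma > 0:
        img = img * (1.0 + rng.normal(0.0, spec.speckle_sigma, size=img.shape))
    img = np.clip(img, 0.0, 1.0)

    return PhantomRecord(
        image=img,
        boundaries=boundaries,
        vessel_mask=vessel_mask,
        subject_id=subject_id,
        class_label=spec.class_label,
        spec=spec,
    )


def render_overlay(
    record: PhantomRecord,
    upper_color: tuple[float, float, float] = (0.0, 1.0, 1.0),
    lower_color: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> np.ndarray:
    """Paint 1-px boundary polylines on the grayscale scan, as device
    software does when it color-codes its segmentation on a screenshot.

    Default colors are cyan (anterior/ILM) and red (posterior), the usual
    device palette.  Colors must be chromatic (not all channels equal), or
    they could not be told apart from the grayscale content.
    """
    for name, color in (("upper", upper_color), ("lower", lower_color)):
        r, g, b = color
        if r == g == b:
            raise ValueError(f"{name}_color is achromatic and would not be detectable")
    img = record.image
    rgb = np.repeat(img[:, :, None], 3, axis=2).astype(np.float64)
    cols = np.arange(img.shape[1])
    rgb[record.boundaries.upper, cols] = upper_color
    lower = np.minimum(record.boundaries.lower, img.shape[0] - 1)
    rgb[lower, cols] = lower_color
    return rgb


def generate_dataset(
    spec_template: PhantomSpec,
    n_subjects: int,
    scans_per_subject: int,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> list[PhantomRecord]:
    """Generate a cohort of phantoms with subject structure.

    Class counts follow largest-remainder allocation of ``class_mix`` over
    subjects (floors first, remainders by largest fractional part, ties in
    the listed class order).  All scans of one subject share its class and
    a jittered copy of the template geometry; scan-level seeds differ so
    speckle and vessel placement vary within a subject.
    """
    if n_subjects < 1 or scans_per_subject < 1:
        raise ValueError("n_subjects and scans_per_subject must be >= 1")
    if class_mix is None:
        class_mix = {"normal": 1.0}
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix proportions must sum to 1, got {total}")

    labels = list(class_mix)
    floors = {k: int(np.floor(class_mix[k] * n_subjects)) for k in labels}
    remainder = n_subjects - sum(floors.values())
    by_frac = sorted(
        labels, key=lambda k: (-(class_mix[k] * n_subjects - floors[k]), labels.index(k))
    )
    for k in by_frac[:remainder]:
        floors[k] += 1

    rng = np.random.default_rng(seed)
    subject_labels = [k for k in labels for _ in range(floors[k])]
    records: list[PhantomRecord] = []
    for s, label in enumerate(subject_labels):
        subject_id = f"subj{s:03d}"
        jitter_base = rng.normal(0.0, 1.0)
        baseline = spec_template.ilm_baseline + int(round(2 * jitter_base))
        thickness = spec_template.rnfl_thickness_mean * float(
            np.clip(1.0 + 0.05 * rng.normal(), 0.8, 1.2)
        )
        for scan in range(scans_per_subject):
            spec = replace(
                spec_template,
                class_label=label,
                ilm_baseline=baseline,
                rnfl_thickness_mean=thickness,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            records.append(generate_phantom(spec, subject_id=subject_id))
    return records
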