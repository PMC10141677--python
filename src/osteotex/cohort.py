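"""Synthetic wrist-MRI-like cohorts with a controlled age→texture effect.

Real pediatric wrist scans are not distributable, so every pipeline stage is
exercised on generated 512×512 scans that mimic the relevant statistics of
coronal wrist MRI of adolescent boys:

* a smooth "bone marrow" background of low-frequency Gaussian noise;
* a rectangular "trabecular bone" patch of correlated noise whose
  correlation length and contrast shrink monotonically with age (younger
  bone: coarser, less calcified pattern);
* a horizontal bright "growth band" whose width and brightness shrink with
  age (younger growth plate: wider, more fluid, brighter);
* a T2 rendition with the band/marrow contrast inverted relative to T1;
* a 12-bit master plus an 8-bit rendition obtained by per-image min-max
  scaling to 0–255, mirroring how clinical PNG exports are produced.

Because the feature path applies ±3σ normalization (which removes intensity
location and scale), the age signal is deliberately carried by *structure*:
the bright-band area fraction inside the growth ROI and the correlation
length of the trabecular field, not by raw brightness alone.

``effect_strength`` scales every age dependency; at 0 all generator
parameters are age-independent and texture is statistically independent of
age.  All randomness flows from the single seed in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import FeatureConfig, DEFAULT_CONFIG, extract_all, feature_names
from .io import Region, RoiSpec, ScanImage, extract_region, write_gray_png

#: age weights 9..17 shaped like the study population (mean ≈ 12.4, median 12)
DEFAULT_AGE_WEIGHTS = (2, 4, 5, 6, 4, 3, 3, 2, 1)

SCAN_SHAPE = (512, 512)
BONE_RECT = (150, 350, 120, 280)  # rows 150:350, cols 120:280
BAND_CENTER_ROW = 400
BAND_COLS = (120, 400)

#: default ROIs, in pixels, placed inside the synthetic anatomy
BONE_ROI = RoiSpec(region_kind="bone", anchor=(200, 150), height=48, width=48)
GROWTH_ROI = RoiSpec(region_kind="growth", anchor=(384, 200), height=32, width=48)


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; the defaults emulate the study's cohort shape."""

    n_patients: int = 30
    total_images: int = 55
    images_per_patient: Tuple[int, int] = (1, 3)
    age_range: Tuple[int, int] = (9, 17)
    age_weights: Tuple[float, ...] = DEFAULT_AGE_WEIGHTS
    effect_strength: float = 1.0
    pixel_spacings: Tuple[float, ...] = (0.2539, 0.293, 0.3516)
    spacing_weights: Tuple[float, ...] = (0.2, 0.6, 0.2)
    modalities: Tuple[str, ...] = ("T1", "T2")
    bit_depths: Tuple[int, ...] = (8, 12)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 4:
            raise ValueError("need at least 4 patients")
        if not (0.0 <= self.effect_strength <= 1.0):
            raise ValueError("effect_strength must lie in [0, 1]")
        lo, hi = self.images_per_patient
        if not (1 <= lo <= hi <= 3):
            raise ValueError("images_per_patient bounds must satisfy 1 <= lo <= hi <= 3")
        if not (self.n_patients * lo <= self.total_images <= self.n_patients * hi):
            raise ValueError("total_images unreachable with the per-patient bounds")
        if len(self.age_weights) != self.age_range[1] - self.age_range[0] + 1:
            raise ValueError("one age weight per year of the age range")


@dataclass(frozen=True)
class SyntheticScan:
    """A 12-bit master scan plus the ground-truth parameters that built it."""

    scan: ScanImage  # 12-bit master
    image_index: int  # 0-based within the patient
    band_width: float  # growth-band width [px]
    band_brightness: float  # band plateau level in the T1 master [12-bit units]
    trabecular_corr_length: float  # Gaussian correlation length [px]
    noise_level: float  # additive white-noise σ [12-bit units]

    def rendition(self, bit_depth: int) -> ScanImage:
        """The stored representation: 12-bit master or derived 8-bit export."""
        if bit_depth == 12:
            return self.scan
        if bit_depth == 8:
            px = self.scan.pixels.astype(np.float64)
            lo, hi = px.min(), px.max()
            scaled = (px - lo) * (255.0 / (hi - lo)) if hi > lo else np.zeros_like(px)
            return ScanImage(
                pixels=np.floor(scaled + 0.5).astype(np.int64),
                bit_depth=8,
                pixel_spacing=self.scan.pixel_spacing,
                modality=self.scan.modality,
                source_format="PNG",
                patient_id=self.scan.patient_id,
                age_years=self.scan.age_years,
            )
        raise ValueError(f"unsupported bit depth {bit_depth}")


@dataclass
class Cohort:
    """All generated scans plus the ROI definitions that apply to them."""

    spec: CohortSpec
    scans: List[SyntheticScan]
    bone_roi: RoiSpec = BONE_ROI
    growth_roi: RoiSpec = GROWTH_ROI

    def select(self, modality: str, first_image_only: bool = False) -> List[SyntheticScan]:
        chosen = [s for s in self.scans if s.scan.modality == modality]
        if first_image_only:
            chosen = [s for s in chosen if s.image_index == 0]
        return chosen


def _patient_image_counts(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Per-patient image counts within bounds, summing exactly to total_images."""
    lo, hi = spec.images_per_patient
    counts = rng.integers(lo, hi + 1, size=spec.n_patients)
    # deterministic adjustment toward the requested total
    idx = 0
    while counts.sum() != spec.total_images:
        if counts.sum() > spec.total_images and counts[idx % spec.n_patients] > lo:
            counts[idx % spec.n_patients] -= 1
        elif counts.sum() < spec.total_images and counts[idx % spec.n_patients] < hi:
            counts[idx % spec.n_patients] += 1
        idx += 1
    return counts


def _build_master(
    rng: np.random.Generator,
    modality: str,
    band_width: float,
    band_brightness: float,
    corr_length: float,
    band_center: float,
    noise_level: float,
) -> np.ndarray:
    """Compose one 512×512 12-bit scan."""
    rows, cols = SCAN_SHAPE
    if modality == "T1":
        marrow_level, bone_level = 2300.0, 1500.0
        band_level = band_brightness
    else:
        # inverted band/marrow contrast: the band is darker than marrow by
        # the same margin by which the T1 band is brighter
        marrow_level, bone_level = 3000.0, 2100.0
        band_level = marrow_level - (band_brightness - 2300.0)

    image = marrow_level + ndimage.gaussian_filter(rng.standard_normal(SCAN_SHAPE), 2.0) * 150.0

    r0, r1, c0, c1 = BONE_RECT
    white = rng.standard_normal((r1 - r0, c1 - c0))
    fieldv = ndimage.gaussian_filter(white, corr_length)
    fieldv /= fieldv.std()
    contrast = 240.0 + 60.0 * (corr_length - 1.7)  # coarser (younger) = higher contrast
    image[r0:r1, c0:c1] = bone_level + fieldv * contrast

    rr = np.arange(rows, dtype=np.float64)[:, None]
    # logistic band profile: soft ~1 px edge
    profile = 1.0 / (1.0 + np.exp((np.abs(rr - band_center) - band_width / 2.0) / 1.0))
    mask = np.zeros(SCAN_SHAPE)
    mask[:, BAND_COLS[0] : BAND_COLS[1]] = profile
    image = image * (1.0 - mask) + band_level * mask

    image += rng.standard_normal(SCAN_SHAPE) * noise_level
    return np.clip(np.floor(image + 0.5), 0, 4095).astype(np.int64)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort, bit-reproducible from ``spec.seed``.

    Patient-level texture parameters (band width/brightness jitter,
    correlation-length jitter) are shared across a patient's images; pixel
    noise is drawn independently per image.  With ``effect_strength = 1``
    the band width shrinks from ≈20 px at age 9 to ≈5.6 px at age 17 and the
    trabecular correlation length from ≈2.5 px to ≈0.9 px.
    """
    rng = np.random.default_rng(int(spec.seed) % (2**31))
    ages_pool = np.arange(spec.age_range[0], spec.age_range[1] + 1)
    weights = np.asarray(spec.age_weights, dtype=np.float64)
    weights = weights / weights.sum()
    eff = spec.effect_strength

    counts = _patient_image_counts(rng, spec)
    spacing_p = np.asarray(spec.spacing_weights, dtype=np.float64)
    spacing_p /= spacing_p.sum()

    scans: List[SyntheticScan] = []
    for p in range(spec.n_patients):
        patient_id = f"SYN{p:03d}"
        age = int(rng.choice(ages_pool, p=weights))
        dy = age - spec.age_range[0]
        band_width = max(2.0, 20.0 - eff * 1.8 * dy + rng.normal(0.0, 0.5))
        band_brightness = 3400.0 - eff * 95.0 * dy + rng.normal(0.0, 20.0)
        corr_length = max(0.4, 2.5 - eff * 0.2 * dy + rng.normal(0.0, 0.05))
        for image_index in range(int(counts[p])):
            spacing = float(rng.choice(spec.pixel_spacings, p=spacing_p))
            band_center = BAND_CENTER_ROW + rng.normal(0.0, 1.0)
            noise_level = 45.0
            for modality in spec.modalities:
                master = _build_master(
                    rng,
                    modality,
                    band_width,
                    band_brightness,
                    corr_length,
                    band_center,
                    noise_level,
                )
                scan = ScanImage(
                    pixels=master,
                    bit_depth=12,
                    pixel_spacing=spacing,
                    modality=modality,
                    source_format="DICOM",
                    patient_id=patient_id,
                    age_years=age,
                )
                scans.append(
                    SyntheticScan(
                        scan=scan,
                        image_index=image_index,
                        band_width=band_width,
                        band_brightness=band_brightness,
                        trabecular_corr_length=corr_length,
                        noise_level=noise_level,
                    )
                )
    return Cohort(spec=spec, scans=scans)


def cohort_to_feature_table(
    cohort: Cohort,
    roi_kind: str = "bone",
    modality: str = "T1",
    bit_depth: int = 12,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Extract the full descriptor for one (ROI, modality, encoding) dataset.

    The bone analysis uses every image; the growth analysis keeps one image
    per patient, mirroring the study's 55-sample and 30-sample designs.
    """
    roi = cohort.bone_roi if roi_kind == "bone" else cohort.growth_roi
    rows = []
    for synth in cohort.select(modality, first_image_only=(roi_kind == "growth")):
        scan = synth.rendition(bit_depth)
        region = extract_region(scan, roi)
        values = extract_all(region, config)
        values.update(
            patient_id=scan.patient_id,
            region_kind=roi_kind,
            modality=modality,
            source_format=scan.source_format,
            age_years=scan.age_years,
        )
        rows.append(values)
    columns = feature_names(config) + [
        "patient_id",
        "region_kind",
        "modality",
        "source_format",
        "age_years",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_cohort(cohort: Cohort, outdir) -> pd.DataFrame:
    """Write PNG renditions, a manifest CSV and an ROI config to a directory.

    Each scan produces a 16-bit PNG carrying the 12-bit master and an 8-bit
    PNG export.  The manifest lists path, patient_id, age_years, modality,
    pixel_spacing and bit_depth per file; the ROI config is a small JSON of
    the two ROI rectangles.  Returns the manifest frame.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for synth in cohort.scans:
        stem = f"{synth.scan.patient_id}_im{synth.image_index}_{synth.scan.modality}"
        for depth, suffix in ((12, "_12bit.png"), (8, "_8bit.png")):
            scan = synth.rendition(depth)
            path = outdir / (stem + suffix)
            write_gray_png(scan.pixels, path, depth)
            records.append(
                {
                    "path": str(path),
                    "patient_id": scan.patient_id,
                    "age_years": scan.age_years,
                    "modality": scan.modality,
                    "pixel_spacing": scan.pixel_spacing,
                    "bit_depth": depth,
                }
            )
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    roi_config = {
        kind: {
            "region_kind": roi.region_kind,
            "anchor": list(roi.anchor),
            "height": roi.height,
            "width": roi.width,
            "size_mode": roi.size_mode,
        }
        for kind, roi in (("bone", cohort.bone_roi), ("growth", cohort.growth_roi))
    }
    with open(outdir / "roi_config.json", "w") as fh:
        json.dump(roi_config, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
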