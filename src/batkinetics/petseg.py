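"""BARCIST-1.0 brown-adipose-tissue segmentation on PET-CT volumes.

A voxel is classified as BAT when (i) its CT radiodensity lies within the
fat range (−190 to −10 HU, endpoints inclusive) and (ii) its lean-body-mass
normalised standardized uptake value exceeds 1.2 g/mL scaled by
(lean body mass / total body mass) — i.e. SUV_LBM > 1.2 / (LBM/TBM),
strictly greater-than.

SUV_LBM is the PET activity concentration (Bq/mL) divided by the injected
dose per gram of lean body mass (Bq/g), yielding g/mL.  The LBM
normalisation constant uses grams; this convention is isolated in
:func:`suv_lbm`.

Volumes are accepted as NIfTI-1 files (via nibabel) or as a dependency-free
JSON-header + little-endian raw-array pair; see :func:`load_volume_pair`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "HU_FAT_LO",
    "HU_FAT_HI",
    "SUV_BASE_THRESHOLD",
    "F18_HALF_LIFE_MIN",
    "PetCtVolume",
    "BatMetrics",
    "suv_lbm",
    "bat_mask",
    "bat_metrics",
    "roi_summary",
    "decay_correct",
    "load_volume_pair",
    "save_mask",
]

HU_FAT_LO = -190.0
HU_FAT_HI = -10.0
SUV_BASE_THRESHOLD = 1.2  # g/mL, before the LBM/TBM scaling
F18_HALF_LIFE_MIN = 109.77


@dataclass
class PetCtVolume:
    """Co-registered CT (HU) and PET (Bq/mL) voxel grids with metadata.

    ``voxel_size`` is (dx, dy, dz) in mm; ``injected_dose`` is in Bq and
    assumed already decay-corrected to scan time (see :func:`decay_correct`
    for the helper).
    """

    hu: np.ndarray
    activity: np.ndarray
    voxel_size: tuple[float, float, float]
    injected_dose: float
    body_mass: float
    lean_body_mass: float

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.hu.shape != self.activity.shape:
            raise ValueError("hu and activity grids must have the same shape")
        if self.hu.ndim != 3:
            raise ValueError("volumes must be 3-D")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.injected_dose <= 0:
            raise ValueError("injected_dose must be positive")
        if not (0 < self.lean_body_mass < self.body_mass):
            raise ValueError("require 0 < lean_body_mass < body_mass")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (mm³ / 1000)."""
        return float(np.prod(self.voxel_size)) / 1000.0


@dataclass
class BatMetrics:
    """Summary of a segmented BAT region.

    ``suv_mean``/``suv_max``/``radiodensity_mean`` are ``None`` for an
    empty mask (volume 0): undefined, not zero.
    """

    volume: float  # mL
    suv_mean: float | None  # g/mL
    suv_max: float | None  # g/mL
    activity: float | None  # mL × SUV_mean
    radiodensity_mean: float | None  # HU
    voxel_count: int

    def to_dict(self) -> dict:
        return {
            "volume_ml": self.volume,
            "suv_mean": self.suv_mean,
            "suv_max": self.suv_max,
            "activity": self.activity,
            "radiodensity_mean": self.radiodensity_mean,
            "voxel_count": self.voxel_count,
        }


def suv_lbm(
    activity_voxel: np.ndarray | float, injected_dose: float, lbm_kg: float
) -> np.ndarray | float:
    """Lean-body-mass normalised SUV (g/mL).

    SUV_LBM = activity / (dose / (LBM in grams)); works elementwise on
    arrays.  The normalisation constant uses grams of LBM.
    """
    if injected_dose <= 0:
        raise ValueError("injected_dose must be positive")
    if lbm_kg <= 0:
        raise ValueError("lean body mass must be positive")
    return activity_voxel * (lbm_kg * 1000.0) / injected_dose


def decay_correct(dose: float, elapsed_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Decay-correct an injected dose to ``elapsed_min`` after assay.

    Provided as a helper; not applied automatically — doses are assumed
    corrected upstream.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    return dose * 2.0 ** (-elapsed_min / half_life_min)


def bat_mask(
    vol: PetCtVolume,
    hu_lo: float = HU_FAT_LO,
    hu_hi: float = HU_FAT_HI,
    suv_base: float = SUV_BASE_THRESHOLD,
    z_range: tuple[int, int] | None = None,
    min_cluster: int = 0,
) -> np.ndarray:
    """Boolean BAT mask per the BARCIST criteria.

    A voxel is BAT iff hu_lo ≤ HU ≤ hu_hi (inclusive) and
    SUV_LBM > suv_base / (LBM / body mass) (strict).  ``z_range`` optionally
    restricts segmentation to an axial slab [z0, z1) along the last axis
    (the anatomic skull-base-to-knee bounds are supplied externally this
    way).  ``min_cluster`` > 0 additionally removes 26-connected components
    smaller than that many voxels (off by default).
    """
    suv = suv_lbm(vol.activity, vol.injected_dose, vol.lean_body_mass)
    threshold = suv_base / (vol.lean_body_mass / vol.body_mass)
    mask = (vol.hu >= hu_lo) & (vol.hu <= hu_hi) & (suv > threshold)
    if z_range is not None:
        z0, z1 = z_range
        slab = np.zeros_like(mask)
        slab[:, :, z0:z1] = True
        mask &= slab
    if min_cluster > 0:
        from skimage import measure

        labels = measure.label(mask, connectivity=3)
        keep = np.zeros_like(mask)
        for region in measure.regionprops(labels):
            if region.num_pixels >= min_cluster:
                keep[labels == region.label] = True
        mask = keep
    return mask


def bat_metrics(mask: np.ndarray, vol: PetCtVolume) -> BatMetrics:
    """Quantify a BAT mask: volume, SUV_mean/max, activity, radiodensity.

    activity = volume × SUV_mean (mL × SUV); an empty mask yields volume 0
    with the intensive metrics undefined (``None``).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.hu.shape:
        raise ValueError("mask shape must match the volume")
    count = int(mask.sum())
    volume = count * vol.voxel_volume_ml
    if count == 0:
        return BatMetrics(
            volume=0.0,
            suv_mean=None,
            suv_max=None,
            activity=None,
            radiodensity_mean=None,
            voxel_count=0,
        )
    suv = suv_lbm(vol.activity[mask], vol.injected_dose, vol.lean_body_mass)
    suv_mean = float(np.mean(suv))
    return BatMetrics(
        volume=volume,
        suv_mean=suv_mean,
        suv_max=float(np.max(suv)),
        activity=volume * suv_mean,
        radiodensity_mean=float(np.mean(vol.hu[mask])),
        voxel_count=count,
    )


def roi_summary(vol: PetCtVolume, roi_mask: np.ndarray) -> dict:
    """Mean SUV_LBM and mean HU within an externally supplied ROI."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != vol.hu.shape:
        raise ValueError("roi_mask shape must match the volume")
    if not roi_mask.any():
        raise ValueError("roi_mask must be non-empty")
    suv = suv_lbm(vol.activity[roi_mask], vol.injected_dose, vol.lean_body_mass)
    return {
        "suv_mean": float(np.mean(suv)),
        "radiodensity_mean": float(np.mean(vol.hu[roi_mask])),
    }


# ---------------------------------------------------------------------------
# I/O: NIfTI-1 via nibabel, plus a JSON-header + raw little-endian fallback


def _load_grid(path: Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    path = Path(path)
    if path.suffix == ".json":
        header = json.loads(path.read_text())
        raw = path.with_suffix(".raw")
        dtype = np.dtype(header["dtype"]).newbyteorder("<")
        arr = np.fromfile(raw, dtype=dtype).reshape(header["shape"]).astype(float)
        vs = tuple(header["voxel_size"]) if "voxel_size" in header else None
        return arr, vs
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), tuple(
        float(z) for z in img.header.get_zooms()[:3]
    )


def load_volume_pair(
    hu_path: str | Path,
    activity_path: str | Path,
    injected_dose: float,
    body_mass: float,
    lean_body_mass: float,
) -> PetCtVolume:
    """Load co-registered CT and PET grids from NIfTI-1 or JSON+raw files.

    The JSON fallback is ``{"shape": [...], "voxel_size": [...],
    "dtype": "<f4"}`` next to a ``.raw`` little-endian array.
    """
    hu, vs1 = _load_grid(Path(hu_path))
    activity, vs2 = _load_grid(Path(activity_path))
    vs = vs1 or vs2
    if vs is None:
        raise ValueError("voxel size missing from both volume headers")
    return PetCtVolume(
        hu=hu,
        activity=activity,
        voxel_size=vs,
        injected_dose=injected_dose,
        body_mass=body_mass,
        lean_body_mass=lean_body_mass,
    )


def save_mask(mask: np.ndarray, path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a boolean mask as NIfTI-1 uint8."""
    import nibabel as nib

    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))
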