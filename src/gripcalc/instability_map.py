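"""Simplified abdominal-wall instability maps from 2-D displacement fields.

The input is a planar displacement field of the abdominal wall between rest
and a Valsalva maneuver (producing such fields by image registration is out
of scope — fields are inputs or synthesized). From it the module computes the
per-pixel displacement magnitude, segments the unstable region (shift
> 15 mm), and reports the maximum distension (cm) and the unstable area
(cm^2). The 15 mm shift threshold and the 1.5 cm tissue-stability limit are
the same quantity in different units, so a field whose maximum magnitude is
at most 15 mm is always classified stable. A strain (elasticity) map with
the companion > 20% criterion is computed separately; the two criteria are
reported side by side, not combined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from .biomech_scores import classify_stability
from .errors import DataError, DomainError

SHIFT_THRESHOLD_MM = 15.0
STRAIN_THRESHOLD = 0.20


@dataclass(frozen=True)
class DisplacementField:
    """Rest-to-Valsalva displacement vectors on a regular 2-D grid.

    ``dx``/``dy`` are in mm, ``spacing_mm`` is the isotropic pixel spacing;
    ``mask`` restricts analysis to the abdominal wall (None = whole grid).
    """

    dx: np.ndarray
    dy: np.ndarray
    spacing_mm: float
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        dx = np.asarray(self.dx, dtype=float)
        dy = np.asarray(self.dy, dtype=float)
        object.__setattr__(self, "dx", dx)
        object.__setattr__(self, "dy", dy)
        if dx.ndim != 2 or dx.shape != dy.shape:
            raise DataError("dx and dy must be 2-D arrays of identical shape")
        if not (np.all(np.isfinite(dx)) and np.all(np.isfinite(dy))):
            raise DataError("displacement field contains non-finite values")
        if not self.spacing_mm > 0:
            raise DataError("pixel spacing must be positive")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != dx.shape:
                raise DataError("mask shape must match the field")
            object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class InstabilityReport:
    """Summary of one field: peak distension, unstable area, stability verdict."""

    max_distension_cm: float
    unstable_area_cm2: float
    unstable_fraction: float
    stable: bool


def magnitude_map(field: DisplacementField) -> np.ndarray:
    """Per-pixel Euclidean displacement magnitude in mm (non-negative)."""
    return np.hypot(field.dx, field.dy)


def unstable_region(
    magnitudes: np.ndarray,
    spacing_mm: float,
    shift_threshold_mm: float = SHIFT_THRESHOLD_MM,
    mask: Optional[np.ndarray] = None,
) -> InstabilityReport:
    """Segment pixels with shift strictly above the threshold and measure them.

    Area is pixel count x spacing^2, converted to cm^2; the maximum distension
    is the peak magnitude converted to cm and classified against the 1.5 cm
    stability limit.
    """
    mag = np.asarray(magnitudes, dtype=float)
    if not np.all(np.isfinite(mag)):
        raise DataError("magnitude grid contains non-finite values")
    if np.any(mag < 0):
        raise DomainError("magnitudes must be >= 0")
    if not spacing_mm > 0:
        raise DataError("pixel spacing must be positive")
    if mask is None:
        mask = np.ones(mag.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != mag.shape:
            raise DataError("mask shape must match the magnitude grid")
    n_masked = int(mask.sum())
    if n_masked == 0:
        return InstabilityReport(0.0, 0.0, 0.0, True)
    unstable = mask & (mag > shift_threshold_mm)
    n_unstable = int(unstable.sum())
    area_cm2 = n_unstable * spacing_mm**2 / 100.0
    max_cm = float(mag[mask].max()) / 10.0
    return InstabilityReport(
        max_distension_cm=max_cm,
        unstable_area_cm2=area_cm2,
        unstable_fraction=n_unstable / n_masked,
        stable=classify_stability(max_cm) == "stable",
    )


@dataclass(frozen=True)
class ElasticityResult:
    strain: np.ndarray
    flagged: np.ndarray


def elasticity_map(
    rest_lengths: np.ndarray,
    stretched_lengths: np.ndarray,
    strain_threshold: float = STRAIN_THRESHOLD,
) -> ElasticityResult:
    """Engineering strain ``(stretched - rest) / rest`` with > 20% flagging."""
    rest = np.asarray(rest_lengths, dtype=float)
    stretched = np.asarray(stretched_lengths, dtype=float)
    if rest.shape != stretched.shape:
        raise DataError("rest and stretched grids must share a shape")
    if not (np.all(np.isfinite(rest)) and np.all(np.isfinite(stretched))):
        raise DataError("strain inputs contain non-finite values")
    if np.any(rest <= 0):
        raise DomainError("rest lengths must be strictly positive")
    strain = (stretched - rest) / rest
    return ElasticityResult(strain=strain, flagged=strain > strain_threshold)


# ---------------------------------------------------------------------------
# synthetic fields

Scenario = Literal["stable", "focal_laxity", "diffuse_laxity"]


def synth_field(
    scenario: Scenario,
    size: int = 128,
    amplitude_mm: float = 20.0,
    spacing_mm: float = 2.0,
    sigma_mm: float = 25.0,
    seed: int = 0,
) -> DisplacementField:
    """Seeded synthetic displacement fields emulating three wall phenotypes.

    ``stable``: smooth low-amplitude background whose peak magnitude equals
    ``amplitude_mm`` (choose < 15 for a genuinely stable wall).
    ``focal_laxity``: an isotropic Gaussian bump of peak ``amplitude_mm`` and
    width ``sigma_mm`` centred mid-grid (offset half a pixel to avoid
    symmetric boundary ties), on a faint background — its analytic
    level-set area is :func:`gaussian_levelset_area_cm2`.
    ``diffuse_laxity``: a broad plateau above threshold covering roughly the
    central half of the grid.
    """
    if amplitude_mm < 0:
        raise DomainError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(
        np.arange(size) * spacing_mm, np.arange(size) * spacing_mm, indexing="ij"
    )
    cx = cy = (size / 2 - 0.25) * spacing_mm
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    theta = rng.uniform(0, 2 * np.pi)
    if scenario == "stable":
        mag = _smooth_noise(rng, size, amplitude_mm)
    elif scenario == "focal_laxity":
        bump = amplitude_mm * np.exp(-r2 / (2.0 * sigma_mm**2))
        mag = bump + _smooth_noise(rng, size, min(1.0, 0.02 * amplitude_mm))
    elif scenario == "diffuse_laxity":
        plateau = amplitude_mm / (1.0 + np.exp((np.sqrt(r2) - size * spacing_mm / 4) / sigma_mm))
        mag = plateau + _smooth_noise(rng, size, min(1.0, 0.02 * amplitude_mm))
    else:
        raise DomainError(f"unknown scenario {scenario!r}")
    return DisplacementField(
        dx=mag * np.cos(theta), dy=mag * np.sin(theta), spacing_mm=spacing_mm
    )


def _smooth_noise(rng: np.random.Generator, size: int, peak: float) -> np.ndarray:
    """Low-frequency random field rescaled to [0, peak]."""
    coarse = rng.normal(size=(8, 8))
    fine = np.kron(coarse, np.ones((size // 8 + 1, size // 8 + 1)))[:size, :size]
    lo, hi = fine.min(), fine.max()
    if hi == lo:
        return np.zeros((size, size))
    return peak * (fine - lo) / (hi - lo)


def gaussian_levelset_area_cm2(
    amplitude_mm: float, sigma_mm: float, threshold_mm: float = SHIFT_THRESHOLD_MM
) -> float:
    """Analytic area (cm^2) where an isotropic Gaussian bump exceeds a threshold.

    ``A * exp(-r^2 / 2 sigma^2) > T`` holds inside radius
    ``r = sigma * sqrt(2 ln(A/T))``, giving area ``2 pi sigma^2 ln(A/T)``.
    Zero when the peak does not reach the threshold.
    """
    if amplitude_mm <= threshold_mm:
        return 0.0
    return float(2.0 * np.pi * sigma_mm**2 * np.log(amplitude_mm / threshold_mm) / 100.0)


# ---------------------------------------------------------------------------
# field I/O: two delimited grids + JSON sidecar


def read_field(
    dx_path: str | Path, dy_path: str | Path, meta_path: str | Path
) -> DisplacementField:
    """Load a field from dx/dy CSV grids plus a JSON sidecar.

    The sidecar carries ``spacing_mm`` and optionally ``mask`` (a path,
    relative to the sidecar, of a 0/1 CSV grid).
    """
    dx = np.loadtxt(dx_path, delimiter=",", ndmin=2)
    dy = np.loadtxt(dy_path, delimiter=",", ndmin=2)
    meta_path = Path(meta_path)
    meta = json.loads(meta_path.read_text(encoding="utf-8"))
    mask = None
    if meta.get("mask"):
        mask = np.loadtxt(meta_path.parent / meta["mask"], delimiter=",", ndmin=2) > 0.5
    return DisplacementField(dx=dx, dy=dy, spacing_mm=float(meta["spacing_mm"]), mask=mask)


def write_field(
    field: DisplacementField,
    dx_path: str | Path,
    dy_path: str | Path,
    meta_path: str | Path,
) -> None:
    np.savetxt(dx_path, field.dx, delimiter=",", fmt="%.6g")
    np.savetxt(dy_path, field.dy, delimiter=",", fmt="%.6g")
    meta: dict = {"spacing_mm": field.spacing_mm}
    meta_path = Path(meta_path)
    if field.mask is not None:
        mask_path = meta_path.with_suffix(".mask.csv")
        np.savetxt(mask_path, field.mask.astype(int), delimiter=",", fmt="%d")
        meta["mask"] = mask_path.name
    meta_path.write_text(json.dumps(meta), encoding="utf-8")
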