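"""Absorbed-dose maps: kernel convolution, PET local deposition, time scaling.

Two dosimetry routes produce :class:`DoseMap` objects:

* microCT route — microsphere locations are binned to a fine grid as total
  decays per voxel and convolved with the single-decay dose-point kernel
  (zero-padded FFT, i.e. linear convolution with no wrap-around);
* PET route — the local deposition method (LDM): each voxel's dose is
  proportional to its measured activity, with no transport between voxels.

Doses are "extended" (infinite-time, permanent implantation) unless scaled
to a truncation time with :func:`scale_dose_to_time`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .grid import Volume, VoxelGrid
from .kernel import DoseKernel
from .nuclide import MEV_TO_J, RadionuclideSpec, Y90, cumulative_dose_fraction
from .spheres import SphereTable

MICROCT_SOURCE = "microct-convolution"
PET_SOURCE = "pet-ldm"


@dataclass
class DoseMap:
    """A 3-D absorbed-dose array (Gy) with its delivery and source tags."""

    volume: Volume
    delivery: str = "extended"            # "extended" | "actual"
    source: str = MICROCT_SOURCE
    truncation_h: float | None = None

    def __post_init__(self):
        if self.volume.unit != "gy":
            raise ValueError("dose maps must carry the 'gy' unit tag")
        if np.any(self.volume.data < 0):
            raise ValueError("doses must be >= 0")
        if self.delivery not in ("extended", "actual"):
            raise ValueError("delivery must be 'extended' or 'actual'")
        if self.delivery == "actual" and self.truncation_h is None:
            raise ValueError("an 'actual' dose map requires a truncation time")
        if self.delivery == "extended" and self.truncation_h is not None:
            raise ValueError("an 'extended' dose map must not carry a truncation time")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def grid(self) -> VoxelGrid:
        return self.volume.grid


def bin_spheres_to_grid(table: SphereTable, grid: VoxelGrid,
                        spec: RadionuclideSpec = Y90) -> Volume:
    """Total (infinite-time) decays per voxel from a sphere table.

    Each sphere contributes activity / lambda decays to the voxel owning its
    center; at 36 μm a 27.5 μm sphere is sub-voxel, so no spreading is done.
    """
    decays = np.zeros(grid.shape)
    if len(table) > 0:
        inside = grid.contains(table.positions_mm)
        if not np.all(inside):
            bad = np.nonzero(~inside)[0]
            raise ValueError(
                f"{len(bad)} sphere(s) outside the grid, first offenders (row indices): "
                f"{bad[:10].tolist()}")
        idx = grid.voxel_of(table.positions_mm)
        flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), grid.shape)
        per_sphere_decays = table.activities_bq / spec.decay_constant_per_s
        decays = np.bincount(flat, weights=per_sphere_decays,
                             minlength=int(np.prod(grid.shape))).reshape(grid.shape)
    return Volume(grid, decays, "decays",
                  provenance={"n_spheres": len(table),
                              "total_activity_bq": table.total_activity_bq})


def convolve_dose(decay_map: Volume, kernel: DoseKernel,
                  density_g_per_ml: float = 1.03) -> DoseMap:
    """Fine-grid extended dose map: decays-per-voxel ⊛ kernel, energy → Gy.

    Linear (zero-padded) convolution in the frequency domain; same-size
    output. Energy per voxel is divided by the voxel mass.
    """
    if decay_map.unit != "decays":
        raise ValueError("decay map must carry the 'decays' unit tag")
    g = decay_map.grid
    if not g.isotropic or abs(g.spacing[0] - kernel.spacing_mm) > 1e-9:
        raise ValueError(
            f"decay map spacing {g.spacing} does not match kernel spacing "
            f"{kernel.spacing_mm} mm (isotropic required)")
    if density_g_per_ml <= 0:
        raise ValueError("density must be positive")
    energy_mev = fftconvolve(decay_map.data, kernel.data, mode="same")
    np.maximum(energy_mev, 0.0, out=energy_mev)  # clip FFT ringing at ~1e-16 level
    dose = energy_mev * MEV_TO_J / g.voxel_mass_kg(density_g_per_ml)
    vol = Volume(g, dose, "gy", provenance={
        **decay_map.provenance,
        "kernel": dict(kernel.metadata),
        "density_g_per_ml": density_g_per_ml,
    })
    return DoseMap(vol, delivery="extended", source=MICROCT_SOURCE)


def convolve_dose_direct(decay_map: Volume, kernel: DoseKernel,
                         density_g_per_ml: float = 1.03) -> DoseMap:
    """Brute-force shifted-kernel summation; oracle twin of :func:`convolve_dose`.

    O(sources × kernel volume); only for small grids and sparse sources.
    """
    if decay_map.unit != "decays":
        raise ValueError("decay map must carry the 'decays' unit tag")
    g = decay_map.grid
    out = np.zeros(g.shape)
    kh = kernel.data.shape[0] // 2
    src = np.argwhere(decay_map.data > 0)
    for (i, j, k) in src:
        w = decay_map.data[i, j, k]
        lo = np.array([i, j, k]) - kh
        hi = lo + kernel.data.shape[0]
        slo = np.maximum(lo, 0)
        shi = np.minimum(hi, g.shape)
        klo = slo - lo
        khi = klo + (shi - slo)
        out[slo[0]:shi[0], slo[1]:shi[1], slo[2]:shi[2]] += w * kernel.data[
            klo[0]:khi[0], klo[1]:khi[1], klo[2]:khi[2]]
    dose = out * MEV_TO_J / g.voxel_mass_kg(density_g_per_ml)
    vol = Volume(g, dose, "gy", provenance=dict(decay_map.provenance))
    return DoseMap(vol, delivery="extended", source=MICROCT_SOURCE)


def ldm_dose(pet_activity: Volume, density_g_per_ml: float = 1.03,
             spec: RadionuclideSpec = Y90) -> DoseMap:
    """Local deposition method: per-voxel dose = Delta × activity / voxel mass."""
    if pet_activity.unit != "gbq":
        raise ValueError("PET activity volume must carry the 'gbq' unit tag")
    if density_g_per_ml <= 0:
        raise ValueError("density must be positive")
    mass = pet_activity.grid.voxel_mass_kg(density_g_per_ml)
    dose = spec.dose_constant_j_per_gbq * pet_activity.data / mass
    vol = Volume(pet_activity.grid, dose, "gy", provenance={
        **pet_activity.provenance, "density_g_per_ml": density_g_per_ml})
    return DoseMap(vol, delivery="extended", source=PET_SOURCE)


def scale_dose_to_time(dose_map: DoseMap, spec: RadionuclideSpec = Y90,
                       truncation_h: float = 0.0) -> DoseMap:
    """Extended → actual: scale by the cumulative dose fraction at truncation."""
    if dose_map.delivery != "extended":
        raise ValueError("can only truncate an extended dose map")
    frac = cumulative_dose_fraction(spec, truncation_h)
    vol = dose_map.volume.copy_with(dose_map.data * frac, truncation_h=truncation_h)
    return DoseMap(vol, delivery="actual", source=dose_map.source,
                   truncation_h=truncation_h)
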