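"""Synthetic phantoms with known ground truth for the full pipeline.

No imaging data from the canine study is deposited anywhere, so every
downstream stage is exercised on phantoms that emulate its relevant
features: a treated-hemisphere ellipsoid containing a spherical tumor mass,
a deep-gray (thalamus/basal-ganglia surrogate) ellipsoid and, optionally, a
necrotic tumor core; an inhomogeneous microsphere placement process with a
controllable tumor:normal density ratio (the study reports dose T:N between
1.93 and 3.02); a microCT-like rendering of the spheres as bright
PSF-blurred blobs at 8.74 μm; and a PET-like activity volume at 2–4 mm
voxels with a 5 mm Gaussian reconstruction PSF.

Full-hemisphere grids at 8.74 μm are far beyond desk scale, so the default
geometry is dual-resolution: a millimeter-scale tile at microCT resolution
for detection work, and a ~40 mm field at 36–150 μm for dosimetry. All
sizes are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import Volume, VoxelGrid, make_grid
from .spheres import SphereTable, assign_sphere_activity

LABELS = {"background": 0, "cortex": 1, "deep_gray": 2, "tumor": 3, "necrotic_core": 4}
#: labels that count as tissue available for sphere lodging
PLACEABLE = ("cortex", "deep_gray", "tumor")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the dosimetry phantom (all lengths mm, world coordinates).

    Defaults describe a scaled-down treated hemisphere in a 40 mm field at
    150 μm: hemisphere semi-axes (17, 15, 13) mm, an 8 mm tumor offset
    anteriorly, a small deep-gray ellipsoid near the center.
    """

    shape: tuple[int, int, int] = (267, 267, 267)
    spacing_mm: float = 0.15
    hemisphere_center: tuple[float, float, float] = (20.0, 20.0, 20.0)
    hemisphere_semi_axes: tuple[float, float, float] = (17.0, 15.0, 13.0)
    tumor_center: tuple[float, float, float] = (26.0, 20.0, 20.0)
    tumor_radius: float = 8.0
    deep_gray_center: tuple[float, float, float] = (13.0, 20.0, 20.0)
    deep_gray_semi_axes: tuple[float, float, float] = (4.0, 3.5, 3.0)
    necrotic_core_radius: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.tumor_radius < 0 or self.necrotic_core_radius < 0:
            raise ValueError("radii must be >= 0")
        if self.necrotic_core_radius > self.tumor_radius:
            raise ValueError("necrotic core must be contained in the tumor")
        # containment: tumor and deep gray inside the hemisphere ellipsoid,
        # checked on a dense deterministic sample of the inner surface
        golden = np.pi * (3.0 - np.sqrt(5.0))
        i = np.arange(2048)
        z = 1.0 - 2.0 * (i + 0.5) / len(i)
        r = np.sqrt(1.0 - z ** 2)
        dirs = np.column_stack([r * np.cos(golden * i), r * np.sin(golden * i), z])
        for center, extent, name in (
                (self.tumor_center, (self.tumor_radius,) * 3, "tumor"),
                (self.deep_gray_center, self.deep_gray_semi_axes, "deep_gray")):
            if extent[0] == 0:
                continue
            c = np.asarray(center) - np.asarray(self.hemisphere_center)
            surface = c + dirs * np.asarray(extent)
            if np.any(np.sum((surface / np.asarray(self.hemisphere_semi_axes)) ** 2,
                             axis=1) > 1.0):
                raise ValueError(f"{name} region is not contained in the hemisphere")

    @property
    def grid(self) -> VoxelGrid:
        return make_grid(self.shape, self.spacing_mm)


@dataclass
class GroundTruth:
    """Known sphere placements plus the region labels they were drawn on."""

    spheres: SphereTable
    labels: Volume
    achieved_tumor_to_normal: float
    spec: PhantomSpec | None = None


def _ellipsoid_mask(grid: VoxelGrid, center, semi_axes) -> np.ndarray:
    axes = [grid.axis_coords(a) - center[a] for a in range(3)]
    sa = semi_axes
    return (axes[0][:, None, None] ** 2 / sa[0] ** 2
            + axes[1][None, :, None] ** 2 / sa[1] ** 2
            + axes[2][None, None, :] ** 2 / sa[2] ** 2) <= 1.0


def make_phantom(spec: PhantomSpec) -> Volume:
    """Integer label volume; cortex is the hemisphere exclusive of the tumor
    mass and deep gray (matching the study's cortex-exclusive-of-mass
    reporting convention)."""
    grid = spec.grid
    hemi = _ellipsoid_mask(grid, spec.hemisphere_center, spec.hemisphere_semi_axes)
    labels = np.where(hemi, LABELS["cortex"], LABELS["background"]).astype(np.int16)
    if spec.deep_gray_semi_axes[0] > 0:
        dg = _ellipsoid_mask(grid, spec.deep_gray_center, spec.deep_gray_semi_axes)
        labels[dg & hemi] = LABELS["deep_gray"]
    if spec.tumor_radius > 0:
        tum = _ellipsoid_mask(grid, spec.tumor_center, (spec.tumor_radius,) * 3)
        labels[tum & hemi] = LABELS["tumor"]
        if spec.necrotic_core_radius > 0:
            core = _ellipsoid_mask(grid, spec.tumor_center,
                                   (spec.necrotic_core_radius,) * 3)
            labels[core & hemi] = LABELS["necrotic_core"]
    return Volume(grid, labels, "label", provenance={"phantom_spec": asdict(spec)})


def sample_sphere_positions(labels: Volume, n_spheres: int,
                            tumor_to_normal_ratio: float = 3.0,
                            clustering: float = 1.0,
                            seed: int = 0,
                            total_activity_gbq: float = 0.0) -> GroundTruth:
    """Draw sphere positions from an inhomogeneous point process.

    Per-voxel placement density is 1 in normal tissue (cortex, deep gray),
    ``tumor_to_normal_ratio`` in viable tumor and 0 in the necrotic core and
    background. ``clustering`` > 1 places that many spheres (on average)
    along short randomly oriented line segments, a crude surrogate for
    microspheres queuing in a single vessel; 1 disables it.
    """
    if labels.unit != "label":
        raise ValueError("labels volume required")
    if n_spheres < 0:
        raise ValueError("n_spheres must be >= 0")
    if tumor_to_normal_ratio <= 0:
        raise ValueError("tumor:normal ratio must be positive")
    rng = np.random.default_rng(seed)
    grid = labels.grid
    lab = labels.data

    weights = np.zeros(lab.shape)
    normal = (lab == LABELS["cortex"]) | (lab == LABELS["deep_gray"])
    weights[normal] = 1.0
    weights[lab == LABELS["tumor"]] = tumor_to_normal_ratio

    if n_spheres == 0:
        truth = GroundTruth(SphereTable(np.empty((0, 3)), np.empty(0)),
                            labels, float("nan"))
        return truth
    total_w = weights.sum()
    if total_w == 0:
        raise ValueError("no placeable voxels in the label volume")

    flat_w = weights.ravel() / total_w
    nz = np.nonzero(flat_w)[0]
    p = flat_w[nz]

    def draw(n):
        chosen = rng.choice(nz, size=n, p=p)
        ijk = np.column_stack(np.unravel_index(chosen, lab.shape)).astype(float)
        jitter = rng.random((n, 3)) - 0.5  # uniform within the owning voxel
        return grid.index_to_world(ijk + jitter)

    if clustering <= 1.0:
        pos = draw(n_spheres)
    else:
        seg_len_mm = 0.15  # short arteriole surrogate
        n_seg = max(1, int(round(n_spheres / clustering)))
        seeds = draw(n_seg)
        counts = rng.poisson(clustering, size=n_seg)
        # adjust to hit n_spheres exactly
        while counts.sum() < n_spheres:
            counts[rng.integers(0, n_seg)] += 1
        overshoot = counts.sum() - n_spheres
        while overshoot > 0:
            i = rng.integers(0, n_seg)
            if counts[i] > 0:
                counts[i] -= 1
                overshoot -= 1
        dirs = rng.normal(size=(n_seg, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        offs = []
        for s, c, d in zip(seeds, counts, dirs):
            if c == 0:
                continue
            t = rng.random(c) * seg_len_mm
            offs.append(s[None, :] + t[:, None] * d[None, :])
        pos = np.concatenate(offs, axis=0)
        # segments may poke out of tissue; clamp those spheres back to their seed
        v = grid.voxel_of(pos)
        np.clip(v, 0, np.asarray(grid.shape) - 1, out=v)
        bad = weights[v[:, 0], v[:, 1], v[:, 2]] == 0
        if np.any(bad):
            pos[bad] = draw(int(bad.sum()))

    table = SphereTable(pos, np.zeros(len(pos)), provenance={
        "process": "inhomogeneous-poisson",
        "tumor_to_normal_ratio": tumor_to_normal_ratio,
        "clustering": clustering, "seed": seed})
    if total_activity_gbq > 0:
        table = assign_sphere_activity(table, total_activity_gbq)

    v = grid.voxel_of(pos)
    in_tumor = lab[v[:, 0], v[:, 1], v[:, 2]] == LABELS["tumor"]
    n_tumor_vox = int((lab == LABELS["tumor"]).sum())
    n_normal_vox = int(normal.sum())
    if n_tumor_vox and n_normal_vox and (~in_tumor).sum() > 0:
        achieved = ((in_tumor.sum() / n_tumor_vox)
                    / ((~in_tumor).sum() / n_normal_vox))
    else:
        achieved = float("nan")
    return GroundTruth(table, labels, float(achieved))


# -- renderers -----------------------------------------------------------

MICROCT_BACKGROUND = 100.0
MICROCT_SPHERE_AMPLITUDE = 900.0
SPHERE_DIAMETER_UM = 27.5


def single_sphere_integral(spacing_mm: float,
                           amplitude: float = MICROCT_SPHERE_AMPLITUDE,
                           diameter_um: float = SPHERE_DIAMETER_UM) -> float:
    """Documented integrated above-background intensity of one sphere.

    The rendered footprint is the sphere indicator times the amplitude,
    resampled then blurred (blur preserves the integral), so the integral is
    amplitude × sphere volume / voxel volume.
    """
    r_mm = diameter_um / 2000.0
    return amplitude * (4.0 / 3.0) * np.pi * r_mm ** 3 / spacing_mm ** 3


def render_microct(truth: GroundTruth | SphereTable, grid: VoxelGrid,
                   psf_sigma_mm: float = 0.006, noise_sd: float = 15.0,
                   seed: int = 0, *, amplitude: float = MICROCT_SPHERE_AMPLITUDE,
                   background: float = MICROCT_BACKGROUND,
                   diameter_um: float = SPHERE_DIAMETER_UM,
                   supersample: int = 5) -> Volume:
    """Phenomenological microCT tile: bright quasi-point spheres on a flat
    tissue background, Gaussian PSF blur, additive Gaussian noise.

    Spheres outside the grid are silently ignored (the tile is a window into
    a larger object).
    """
    table = truth.spheres if isinstance(truth, GroundTruth) else truth
    if not grid.isotropic:
        raise ValueError("microCT rendering requires an isotropic grid")
    spacing = grid.spacing[0]
    r_mm = diameter_um / 2000.0
    prov = {"psf_sigma_mm": psf_sigma_mm, "noise_sd": noise_sd,
            "amplitude": amplitude, "background": background,
            "single_sphere_integral": single_sphere_integral(spacing, amplitude, diameter_um)}
    if spacing > r_mm:
        prov["warning"] = (f"spacing {spacing} mm coarser than the sphere radius "
                           f"{r_mm} mm; spheres are unresolvable")

    img = np.zeros(grid.shape)
    half = int(np.ceil(r_mm / spacing)) + 1
    # midpoint supersampling offsets within one voxel, in voxel units
    ss = (np.arange(supersample) + 0.5) / supersample - 0.5
    sub = np.stack(np.meshgrid(ss, ss, ss, indexing="ij"), axis=-1).reshape(-1, 3)
    win = np.arange(-half, half + 1)
    wijk = np.stack(np.meshgrid(win, win, win, indexing="ij"), axis=-1).reshape(-1, 3)

    for pos in table.positions_mm:
        cidx = grid.world_to_index(pos)
        base = np.floor(cidx + 0.5).astype(int)
        vox = base[None, :] + wijk                       # (W, 3)
        pts = (vox[:, None, :] + sub[None, :, :] - cidx[None, None, :]) * spacing
        frac = (np.sum(pts ** 2, axis=-1) <= r_mm ** 2).mean(axis=1)
        ok = np.all((vox >= 0) & (vox < np.asarray(grid.shape)), axis=1)
        np.add.at(img, (vox[ok, 0], vox[ok, 1], vox[ok, 2]), amplitude * frac[ok])

    if psf_sigma_mm > 0:
        img = gaussian_filter(img, psf_sigma_mm / spacing, mode="constant")
    img += background
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return Volume(grid, img, "intensity", provenance=prov)


def render_pet_activity(truth: GroundTruth | SphereTable, grid: VoxelGrid,
                        psf_fwhm_mm: float = 5.0, seed: int = 0) -> Volume:
    """PET-like activity volume (GBq per voxel): bin sphere activities to the
    coarse grid and blur with the reconstruction PSF, conserving total
    activity (the blur kernel is normalized and edge losses renormalized)."""
    table = truth.spheres if isinstance(truth, GroundTruth) else truth
    act = np.zeros(grid.shape)
    if len(table) > 0:
        idx = grid.voxel_of(table.positions_mm)
        inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        flat = np.ravel_multi_index((idx[inside, 0], idx[inside, 1], idx[inside, 2]),
                                    grid.shape)
        act = np.bincount(flat, weights=table.activities_bq[inside] * 1e-9,
                          minlength=int(np.prod(grid.shape))).reshape(grid.shape)
    total = act.sum()
    if psf_fwhm_mm > 0 and total > 0:
        sigma = psf_fwhm_mm / 2.354820045 / np.asarray(grid.spacing)
        act = gaussian_filter(act, sigma, mode="constant")
        act *= total / act.sum()
    return Volume(grid, act, "gbq", provenance={
        "psf_fwhm_mm": psf_fwhm_mm, "total_activity_gbq": float(total)})
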