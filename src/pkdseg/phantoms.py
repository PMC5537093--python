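"""Synthetic ADPKD-like phantom volumes.

Real polycystic-kidney T2-weighted MR shows two enlarged, irregularly shaped
kidneys whose fluid-filled cysts are markedly brighter than parenchyma, with
variable border contrast, smooth coil-shading (bias) across the field of
view, noise, and — in patients with polycystic liver disease — a liver full
of equally bright cysts that a kidney segmentation must ignore.  The phantom
generator reproduces exactly those structural features on a small grid so
the full segmentation pipeline (training, voting, post-processing,
volumetry) can be exercised end to end without patient data:

* each kidney is an ellipsoid with a low-order smooth radial perturbation
  (irregular but compact shapes, few parameters);
* cysts are bright spheres strictly contained in a kidney;
* an optional liver-like confounder region with its own cysts overlaps no
  kidney and contributes nothing to the reference mask;
* intensity = piecewise-constant tissue values, modulated by a low-order
  polynomial bias field, plus additive Gaussian noise.

Additive Gaussian noise (rather than Rician) and a polynomial bias field are
deliberate simplifications; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import VoxelGrid3D, BinaryMask3D

__all__ = ["PhantomSpec", "PhantomGenerationError", "sample_phantom", "generate_dataset"]

# amplitude of the smooth radial perturbation applied to kidney ellipsoids
_SHAPE_PERTURB_AMP = 0.15
# cyst centres are drawn within this fraction of the kidney radius so blobs
# stay strictly interior even after the radial perturbation
_CYST_CENTER_FRAC = 0.55
_PLACEMENT_RETRIES = 50


class PhantomGenerationError(RuntimeError):
    """Raised when kidney regions cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative recipe for one synthetic ADPKD-like volume.

    Intensities are arbitrary MR-like units ordered
    ``cyst_intensity > kidney_intensity > background_intensity`` (T2-bright
    fluid).  All lengths are millimetres.
    """

    grid_shape: tuple = (64, 64, 8)
    in_plane_spacing_mm: float = 1.5
    slice_thickness_mm: float = 3.0
    kidney_count: int = 2
    kidney_axis_range_mm: tuple = (9.0, 16.0)
    kidney_intensity: float = 60.0
    cyst_count_range: tuple = (2, 6)
    cyst_radius_range_mm: tuple = (1.5, 4.0)
    cyst_intensity: float = 100.0
    background_intensity: float = 20.0
    border_contrast_jitter: float = 0.2
    liver_confounder_prob: float = 0.5
    noise_sd: float = 4.0
    bias_field_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.in_plane_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("voxel spacings must be positive")
        if self.kidney_count < 0:
            raise ValueError("kidney_count must be >= 0")
        if not (self.cyst_intensity > self.kidney_intensity > self.background_intensity):
            raise ValueError("require cyst_intensity > kidney_intensity > background_intensity")
        for name in ("kidney_axis_range_mm", "cyst_count_range", "cyst_radius_range_mm"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has min > max: ({lo}, {hi})")
        if not (0 <= self.border_contrast_jitter < 1):
            raise ValueError("border_contrast_jitter must lie in [0, 1)")
        if not (0 <= self.liver_confounder_prob <= 1):
            raise ValueError("liver_confounder_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.bias_field_amplitude < 1):
            raise ValueError("bias_field_amplitude must lie in [0, 1)")
        if self.kidney_axis_range_mm[0] <= 0 or self.cyst_radius_range_mm[0] <= 0:
            raise ValueError("axis lengths and radii must be positive")

    @property
    def spacing_mm(self):
        return (self.in_plane_spacing_mm, self.in_plane_spacing_mm, self.slice_thickness_mm)

    @property
    def fov_mm(self):
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing_mm))


def _voxel_centers_mm(spec: PhantomSpec):
    """Physical coordinates of voxel centres, one (X,Y,Z) array per axis."""
    axes = [
        (np.arange(n) + 0.5) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _perturbed_ellipsoid(coords, center, semi_axes, coeffs):
    """Rasterize an ellipsoid whose radius is modulated by a smooth low-order
    function of direction: r(d) = 1 + amp * sum_k c_k * h_k(d)."""
    u = [(c - ctr) / ax for c, ctr, ax in zip(coords, center, semi_axes)]
    r = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = [np.where(r > 0, ui / r, 0.0) for ui in u]
    harmonics = (
        d[0] * d[1],
        d[1] * d[2],
        d[0] * d[2],
        d[0] ** 2 - d[1] ** 2,
        d[1] ** 2 - d[2] ** 2,
    )
    # normalize by each term's sup so |perturbation| <= amp everywhere,
    # keeping the shape between the (1-amp) and (1+amp) ellipsoids
    sup = 0.5 * (abs(coeffs[0]) + abs(coeffs[1]) + abs(coeffs[2])) + abs(coeffs[3]) + abs(coeffs[4])
    scale = _SHAPE_PERTURB_AMP / max(sup, 1e-12)
    boundary = 1.0 + scale * sum(c * h for c, h in zip(coeffs, harmonics))
    return r <= boundary


def _sphere(coords, center, radius):
    sq = sum((c - ctr) ** 2 for c, ctr in zip(coords, center))
    return sq <= radius**2


def _bias_field(spec: PhantomSpec, rng):
    """Low-order polynomial shading over normalized [-1,1]^3 coordinates,
    scaled so max |field| = 1, applied multiplicatively."""
    norm = [
        2.0 * (np.arange(n) + 0.5) / n - 1.0 for n in spec.grid_shape
    ]
    x, y, z = np.meshgrid(*norm, indexing="ij")
    c = rng.uniform(-1.0, 1.0, size=9)
    poly = (
        c[0] * x + c[1] * y + c[2] * z
        + c[3] * x * y + c[4] * x * z + c[5] * y * z
        + c[6] * x**2 + c[7] * y**2 + c[8] * z**2
    )
    peak = np.max(np.abs(poly))
    if peak > 0:
        poly /= peak
    return poly


def _place_kidneys(spec: PhantomSpec, coords, rng):
    """Sample kidney centres/axes and rasterize, retrying on overlap."""
    fx, fy, fz = spec.fov_mm
    lo, hi = spec.kidney_axis_range_mm
    kidneys = []
    occupied = np.zeros(spec.grid_shape, dtype=bool)
    # lateral anchor positions: two kidneys sit left/right of the spine
    anchors = [((i + 0.5) / spec.kidney_count) * fx for i in range(spec.kidney_count)]
    for k in range(spec.kidney_count):
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            cz = min(rng.uniform(lo, hi), 0.45 * fz)
            # keep the whole perturbed ellipsoid inside the field of view
            amax = (1 + _SHAPE_PERTURB_AMP)
            cx = np.clip(anchors[k] + rng.uniform(-0.05, 0.05) * fx, a * amax, fx - a * amax)
            cyc = np.clip(0.5 * fy + rng.uniform(-0.08, 0.08) * fy, b * amax, fy - b * amax)
            czc = 0.5 * fz + rng.uniform(-0.05, 0.05) * fz
            coeffs = rng.uniform(-1.0, 1.0, size=5)
            region = _perturbed_ellipsoid(coords, (cx, cyc, czc), (a, b, cz), coeffs)
            if not region.any():
                continue
            if not (region & occupied).any():
                occupied |= region
                kidneys.append(
                    dict(center=(cx, cyc, czc), semi_axes=(a, b, cz),
                         coeffs=coeffs, region=region)
                )
                placed = True
                break
        if not placed:
            raise PhantomGenerationError(
                f"could not place kidney {k} without overlap after "
                f"{_PLACEMENT_RETRIES} attempts (grid {spec.grid_shape}, "
                f"axes {spec.kidney_axis_range_mm})"
            )
    return kidneys


def _place_liver(spec: PhantomSpec, coords, kidney_union, rng):
    """Optional liver-like confounder; skipped if it cannot avoid kidneys."""
    fx, fy, fz = spec.fov_mm
    lo, hi = spec.kidney_axis_range_mm
    for _ in range(_PLACEMENT_RETRIES):
        a = rng.uniform(lo, hi) * 1.2
        b = rng.uniform(lo, hi) * 0.9
        cz = min(rng.uniform(lo, hi), 0.35 * fz)
        center = (
            rng.uniform(0.12, 0.3) * fx,
            rng.uniform(0.12, 0.28) * fy,
            0.5 * fz + rng.uniform(-0.1, 0.1) * fz,
        )
        coeffs = rng.uniform(-1.0, 1.0, size=5)
        region = _perturbed_ellipsoid(coords, center, (a, b, cz), coeffs)
        if region.any() and not (region & kidney_union).any():
            return dict(center=center, semi_axes=(a, b, cz), coeffs=coeffs, region=region)
    return None


def _draw_cysts(spec: PhantomSpec, coords, parent, rng):
    """Bright spherical cysts, centres well inside the parent region."""
    n_cysts = int(rng.integers(spec.cyst_count_range[0], spec.cyst_count_range[1] + 1))
    cyst_mask = np.zeros(spec.grid_shape, dtype=bool)
    cysts = []
    for _ in range(n_cysts):
        # direction * radius fraction inside the (unperturbed) ellipsoid
        v = rng.normal(size=3)
        v /= max(np.linalg.norm(v), 1e-12)
        frac = _CYST_CENTER_FRAC * rng.uniform() ** (1 / 3)
        center = tuple(
            c + f * ax * vi
            for c, ax, vi, f in zip(parent["center"], parent["semi_axes"], v, [frac] * 3)
        )
        radius = rng.uniform(*spec.cyst_radius_range_mm)
        region = _sphere(coords, center, radius) & parent["region"]
        cyst_mask |= region
        cysts.append(dict(center=center, radius=radius))
    return cyst_mask, cysts


def sample_phantom(spec: PhantomSpec, seed: int, return_geometry: bool = False):
    """Generate one image/mask pair.

    Parameters
    ----------
    spec : PhantomSpec
    seed : int
        Overrides ``spec.seed``; identical ``(spec, seed)`` pairs produce
        bit-identical outputs.
    return_geometry : bool
        Also return the sampled geometric primitives (kidney/cyst/liver
        centres, axes, perturbation coefficients) for independent
        re-rasterization in tests.

    Returns
    -------
    (VoxelGrid3D, BinaryMask3D) or (VoxelGrid3D, BinaryMask3D, dict)
    """
    rng = np.random.default_rng(seed)
    coords = _voxel_centers_mm(spec)

    kidneys = _place_kidneys(spec, coords, rng)
    mask = np.zeros(spec.grid_shape, dtype=np.uint8)
    image = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float64)

    for kid in kidneys:
        jitter = rng.uniform(-spec.border_contrast_jitter, spec.border_contrast_jitter)
        kid["intensity"] = spec.kidney_intensity * (1.0 + jitter)
        image[kid["region"]] = kid["intensity"]
        mask[kid["region"]] = 1
        cyst_mask, kid["cysts"] = _draw_cysts(spec, coords, kid, rng)
        image[cyst_mask] = spec.cyst_intensity
        kid["cyst_mask"] = cyst_mask

    kidney_union = mask.astype(bool)
    liver = None
    if rng.uniform() < spec.liver_confounder_prob:
        liver = _place_liver(spec, coords, kidney_union, rng)
        if liver is not None:
            liver_intensity = 0.5 * (spec.background_intensity + spec.kidney_intensity)
            image[liver["region"]] = liver_intensity
            liver_cysts, liver["cysts"] = _draw_cysts(spec, coords, liver, rng)
            image[liver_cysts] = spec.cyst_intensity
            liver["cyst_mask"] = liver_cysts

    if spec.bias_field_amplitude > 0:
        image *= 1.0 + spec.bias_field_amplitude * _bias_field(spec, rng)
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    grid = VoxelGrid3D(image.astype(np.float32), spec.spacing_mm)
    out_mask = BinaryMask3D(mask, spec.spacing_mm)
    if return_geometry:
        geometry = dict(kidneys=kidneys, liver=liver)
        return grid, out_mask, geometry
    return grid, out_mask


def generate_dataset(n: int, spec: PhantomSpec, seed: int, out_dir) -> pd.DataFrame:
    """Write ``n`` phantom image/mask NIfTI pairs plus a CSV manifest.

    Per-case seeds are drawn deterministically from the master ``seed``, so
    equal ``(n, spec, seed)`` yield file-content-identical datasets.

    Returns the manifest as a DataFrame with columns
    ``case_id, image_path, mask_path, seed``; the same table is written to
    ``out_dir/manifest.csv``.
    """
    from .imaging_io import write_pair  # deferred: imaging_io imports grids only

    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n)

    rows = []
    for i, case_seed in enumerate(case_seeds):
        case_id = f"case_{i:03d}"
        grid, mask = sample_phantom(spec, int(case_seed))
        image_path = out_dir / f"{case_id}_img.nii.gz"
        mask_path = out_dir / f"{case_id}_msk.nii.gz"
        write_pair(grid, mask, image_path, mask_path)
        # paths relative to the manifest, so datasets are relocatable and
        # identical (spec, seed) runs are file-content-identical
        rows.append(
            dict(case_id=case_id, image_path=image_path.name,
                 mask_path=mask_path.name, seed=int(case_seed))
        )
    manifest = pd.DataFrame(rows, columns=["case_id", "image_path", "mask_path", "seed"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    for key in ("grid_shape", "kidney_axis_range_mm", "cyst_count_range", "cyst_radius_range_mm"):
        d[key] = list(d[key])
    return d
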