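"""Seeded, ground-truthed synthetic phantoms of cerebellar cortex.

The generator emulates the statistical structure a phase-contrast tomogram
of amyloid-bearing cerebellum exhibits, so that every downstream stage of
the pipeline can be exercised against known ground truth:

* three cortical layers stacked along the dorso-ventral axis — white matter
  (darkest), granular layer (brightest background) and molecular layer —
  with a sinusoidal displacement of the interfaces standing in for folia;
* bright prolate-ellipsoid plaques (a dense core inside a fainter corona)
  confined to the molecular layer, with log-normally distributed volumes
  and a region-dependent preferred axis: by default the left half of the
  grid ("hemisphere") prefers the dorso-ventral axis with an isotropic 30
  degree spread, the right half ("vermis") prefers the medio-lateral axis
  with an anisotropic spread (60 degrees in the transverse plane, 30 out);
* bright spheres of 15-25 um diameter centred on the granular-molecular
  interface (Purkinje-like somata);
* bright capsule-shaped vessels running in the coronal plane;
* additive Gaussian noise.

Placement uses rejection sampling (bounded retries) against an occupancy
grid so objects never overlap — silent overlap would corrupt the ground
truth.  Vessels and somata additionally keep a guard distance from plaques
so that a cylindrical VOI drawn around a plaque contains no other bright
object, mirroring the reported observation that stray bright structures do
not contaminate intensity-based plaque segmentation.

Everything is driven by one integer seed; identical spec + seed give
voxel-identical volumes and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import BoundsError, ConfigurationError, PlacementError
from .volume_io import (
    DEFAULT_VOXEL_SIZE_UM,
    LabelMap,
    SeedROI,
    Volume,
)

_MAX_RETRIES = 200


# ---------------------------------------------------------------------------
# Spec dataclasses
# ---------------------------------------------------------------------------

@dataclass
class LayerModel:
    """Gray means and thicknesses of the three cortical layers.

    Layers stack along axis 0 (dorso-ventral): white matter at low indices,
    then the granular layer, then the molecular layer filling the rest.
    Contrast ordering is strict: granular > molecular > white matter.
    """

    white_gray: float = 80.0
    granular_gray: float = 140.0
    molecular_gray: float = 100.0
    white_thickness_um: float = 60.0
    granular_thickness_um: float = 60.0

    def validate(self) -> None:
        if not (self.granular_gray > self.molecular_gray > self.white_gray):
            raise ConfigurationError(
                "layer grays must satisfy granular > molecular > white, got "
                f"{self.granular_gray}, {self.molecular_gray}, {self.white_gray}"
            )
        if self.white_thickness_um <= 0 or self.granular_thickness_um <= 0:
            raise ConfigurationError("layer thicknesses must be > 0")


@dataclass
class RegionSpec:
    """A named anatomical region: an ML-extent slab with a preferred axis.

    ``spread_deg`` is the cone semi-angle of the axis distribution.  If
    ``spread2_deg`` is set the spread is anisotropic: ``spread_deg`` applies
    within the transverse plane and ``spread2_deg`` out of it.
    """

    name: str
    ml_range: tuple[float, float]          # fraction of the axis-1 extent
    preferred_axis: tuple[float, float, float]
    spread_deg: float = 30.0
    spread2_deg: float | None = None

    def validate(self) -> None:
        lo, hi = self.ml_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigurationError(f"region {self.name}: bad ml_range {self.ml_range}")
        for s in (self.spread_deg, self.spread2_deg):
            if s is not None and not (0.0 <= s <= 90.0):
                raise ConfigurationError(
                    f"region {self.name}: angular spread {s} outside [0, 90]"
                )
        if np.linalg.norm(self.preferred_axis) == 0:
            raise ConfigurationError(f"region {self.name}: zero preferred axis")


@dataclass
class PlaqueModel:
    """Prolate-ellipsoid plaques with log-normal volumes.

    Volumes are drawn log-normally (median and log-std as parameters); the
    aspect ratio of the prolate shape is uniform over ``aspect_ratio_range``.
    Each plaque has a concentric core at ``core_volume_fraction`` of its
    volume, brighter than the corona, which is brighter than the molecular
    background.
    """

    count: int = 110
    volume_median_um3: float = 1000.0
    volume_log_std: float = 1.256   # puts ~90% of volumes below 5000 um^3
    #: redraw volumes above this cap (None disables); matches the largest
    #: plaque volumes such tissue shows (~2e4 um^3) and keeps rare giant
    #: draws from exceeding the molecular layer's thickness
    volume_max_um3: float | None = 20000.0
    aspect_ratio_range: tuple[float, float] = (1.5, 3.5)
    corona_gray_offset: float = 60.0
    core_gray_offset: float = 100.0
    core_volume_fraction: float = 0.15

    def validate(self) -> None:
        if self.count < 0:
            raise ConfigurationError("plaque count must be >= 0")
        lo, hi = self.aspect_ratio_range
        if lo < 1.0 or hi < lo:
            raise ConfigurationError("aspect ratios must be >= 1 and ordered")
        if not (0.0 < self.core_volume_fraction < 1.0):
            raise ConfigurationError("core_volume_fraction must be in (0, 1)")
        if self.core_gray_offset <= self.corona_gray_offset:
            raise ConfigurationError("core must be brighter than corona")
        if self.corona_gray_offset <= 0:
            raise ConfigurationError("corona must be brighter than background")


@dataclass
class PurkinjeModel:
    """Bright spheres centred on the granular-molecular interface."""

    count: int = 25
    diameter_range_um: tuple[float, float] = (15.0, 25.0)
    gray_offset: float = 90.0       # above molecular background
    at_interface: bool = True

    def validate(self) -> None:
        if self.count < 0:
            raise ConfigurationError("purkinje count must be >= 0")
        lo, hi = self.diameter_range_um
        if lo <= 0 or hi < lo:
            raise ConfigurationError("diameter range must be positive and ordered")


@dataclass
class VesselModel:
    """Bright capsules (cylinders with hemispherical caps) in the coronal plane."""

    count: int = 12
    radius_range_um: tuple[float, float] = (2.0, 4.0)
    length_um: float = 80.0
    gray_offset: float = 70.0
    orientation: str = "coronal-plane"   # random direction within the coronal plane

    def validate(self) -> None:
        if self.count < 0:
            raise ConfigurationError("vessel count must be >= 0")
        lo, hi = self.radius_range_um
        if lo <= 0 or hi < lo:
            raise ConfigurationError("radius range must be positive and ordered")
        if self.orientation not in ("coronal-plane", "random"):
            raise ConfigurationError(f"unknown vessel orientation {self.orientation!r}")


def _default_regions() -> list[RegionSpec]:
    return [
        RegionSpec("hemisphere", (0.0, 0.5), (1.0, 0.0, 0.0), spread_deg=30.0),
        RegionSpec("vermis", (0.5, 1.0), (0.0, 1.0, 0.0), spread_deg=60.0,
                   spread2_deg=30.0),
    ]


@dataclass
class PhantomSpec:
    """Full specification of one synthetic volume."""

    grid_shape: tuple[int, int, int] = (192, 192, 192)
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    layer_model: LayerModel = field(default_factory=LayerModel)
    fold_amplitude_um: float = 15.0
    fold_period_um: float = 200.0
    region_map: list[RegionSpec] = field(default_factory=_default_regions)
    plaque_model: PlaqueModel = field(default_factory=PlaqueModel)
    purkinje_model: PurkinjeModel = field(default_factory=PurkinjeModel)
    vessel_model: VesselModel = field(default_factory=VesselModel)
    noise_sigma: float = 4.0
    #: clearance (um) added around each plaque's future VOI cylinder; other
    #: bright objects (somata, vessels) keep out of that guard so the VOI
    #: contains no foreign object
    plaque_guard_um: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.voxel_size_um <= 0:
            raise ConfigurationError("voxel_size_um must be > 0")
        if min(self.grid_shape) < 8:
            raise ConfigurationError(f"grid {self.grid_shape} too small")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        self.layer_model.validate()
        self.plaque_model.validate()
        self.purkinje_model.validate()
        self.vessel_model.validate()
        for r in self.region_map:
            r.validate()
        lm = self.layer_model
        depth_um = self.grid_shape[0] * self.voxel_size_um
        needed = (lm.white_thickness_um + lm.granular_thickness_um
                  + 2.0 * self.fold_amplitude_um)
        if needed >= depth_um:
            raise ConfigurationError(
                f"grid depth {depth_um:.0f} um cannot contain white+granular "
                f"layers plus folding ({needed:.0f} um); enlarge axis 0"
            )

    def region_of(self, j: float) -> RegionSpec | None:
        frac = j / self.grid_shape[1]
        for r in self.region_map:
            lo, hi = r.ml_range
            if lo <= frac < hi or (hi == 1.0 and frac == 1.0):
                return r
        return None


@dataclass
class PhantomObject:
    """Ground-truth parameters of one rendered object."""

    object_id: int
    object_class: str            # plaque | purkinje | vessel
    region: str
    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    axis: tuple[float, float, float]
    volume_um3: float            # analytic, not voxel-counted


@dataclass
class PhantomGroundTruth:
    """True label maps, per-object records and layer masks."""

    plaque_labels: LabelMap
    purkinje_labels: LabelMap
    vessel_labels: LabelMap
    objects: list[PhantomObject]
    layer_masks: dict[str, np.ndarray]

    def objects_of(self, object_class: str) -> list[PhantomObject]:
        return [o for o in self.objects if o.object_class == object_class]

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.objects:
            rows.append({
                "id": o.object_id,
                "class": o.object_class,
                "region": o.region,
                "cx_um": o.center_um[0], "cy_um": o.center_um[1],
                "cz_um": o.center_um[2],
                "a_um": o.semi_axes_um[0], "b_um": o.semi_axes_um[1],
                "c_um": o.semi_axes_um[2],
                "ax": o.axis[0], "ay": o.axis[1], "az": o.axis[2],
                "volume_um3": o.volume_um3,
            })
        return pd.DataFrame(rows, columns=[
            "id", "class", "region", "cx_um", "cy_um", "cz_um",
            "a_um", "b_um", "c_um", "ax", "ay", "az", "volume_um3",
        ])


# ---------------------------------------------------------------------------
# Axis sampling
# ---------------------------------------------------------------------------

def _orthonormal_pair(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(p @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(p, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(p, e1)
    return e1, e2


def sample_axis(rng: np.random.Generator, region: RegionSpec) -> np.ndarray:
    """Draw a unit axis around a region's preferred axis.

    Isotropic spread: uniform over the spherical cap of the given semi-angle.
    Anisotropic spread (``spread2_deg`` set): independent uniform tilt angles
    toward the in-transverse-plane and out-of-plane tangents.
    """
    p = np.asarray(region.preferred_axis, dtype=np.float64)
    p = p / np.linalg.norm(p)
    if region.spread2_deg is None:
        alpha = math.radians(region.spread_deg)
        c = rng.uniform(math.cos(alpha), 1.0)
        s = math.sqrt(max(0.0, 1.0 - c * c))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        e1, e2 = _orthonormal_pair(p)
        return c * p + s * (math.cos(phi) * e1 + math.sin(phi) * e2)
    # anisotropic: e1 = tangent within the transverse plane (normal = DV axis)
    dv = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(dv, p)
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        raise ConfigurationError(
            f"region {region.name}: anisotropic spread undefined for a "
            "preferred axis parallel to the dorso-ventral axis"
        )
    e1 /= n1
    e2 = np.cross(p, e1)
    t1 = math.tan(math.radians(rng.uniform(-region.spread_deg, region.spread_deg)))
    t2 = math.tan(math.radians(rng.uniform(-float(region.spread2_deg),
                                           float(region.spread2_deg))))
    v = p + t1 * e1 + t2 * e2
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Geometry rendering helpers
# ---------------------------------------------------------------------------

def _bbox_indices(center_vox: np.ndarray, half_vox: float, shape) -> tuple | None:
    lo = np.floor(center_vox - half_vox).astype(int)
    hi = np.ceil(center_vox + half_vox).astype(int) + 1
    if (lo < 0).any() or (hi > np.asarray(shape)).any():
        return None
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _clipped_bbox(center_vox: np.ndarray, half_vox: float, shape) -> tuple:
    lo = np.maximum(np.floor(center_vox - half_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + half_vox).astype(int) + 1, np.asarray(shape))
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _ellipsoid_mask(sl, center_um, axis, a_um, b_um, voxel_size):
    grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij")
    coords = (np.stack(grids, axis=-1) + 0.5) * voxel_size - np.asarray(center_um)
    along = coords @ axis
    perp2 = np.sum(coords**2, axis=-1) - along**2
    return along**2 / a_um**2 + perp2 / b_um**2 <= 1.0


def _cylinder_mask(sl, center_um, radius_um, z_half_um, voxel_size):
    """Axis-2-aligned cylinder: in-plane disc radius x coronal slab."""
    grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij")
    coords = (np.stack(grids, axis=-1) + 0.5) * voxel_size - np.asarray(center_um)
    inplane = coords[..., 0] ** 2 + coords[..., 1] ** 2 <= radius_um**2
    return inplane & (np.abs(coords[..., 2]) <= z_half_um)


def _capsule_mask(sl, center_um, axis, half_len_um, radius_um, voxel_size):
    grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij")
    coords = (np.stack(grids, axis=-1) + 0.5) * voxel_size - np.asarray(center_um)
    along = np.clip(coords @ axis, -half_len_um, half_len_um)
    closest = along[..., None] * axis
    return np.sum((coords - closest) ** 2, axis=-1) <= radius_um**2


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _layer_fields(spec: PhantomSpec):
    n0, n1, _ = spec.grid_shape
    vs = spec.voxel_size_um
    lm = spec.layer_model
    jj = np.arange(n1)
    fold_vox = (spec.fold_amplitude_um / vs) * np.sin(
        2.0 * math.pi * jj * vs / spec.fold_period_um
    )
    ii = np.arange(n0)[:, None]
    depth = ii + fold_vox[None, :]                    # (n0, n1) warped depth
    t_w = lm.white_thickness_um / vs
    t_wg = t_w + lm.granular_thickness_um / vs
    white2d = depth < t_w
    gran2d = (depth >= t_w) & (depth < t_wg)
    mol2d = depth >= t_wg
    interface_i = t_wg - fold_vox                     # i of gran-mol interface per j
    return white2d, gran2d, mol2d, interface_i, t_wg


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomGroundTruth]:
    """Render a phantom volume and its ground truth from a spec.

    Deterministic for a fixed ``spec.seed``.  Raises
    :class:`ConfigurationError` for infeasible layer geometry and
    :class:`PlacementError` (naming the object class) if objects cannot be
    placed without overlap within bounded retries.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    vs = spec.voxel_size_um
    lm = spec.layer_model

    white2d, gran2d, mol2d, interface_i, t_wg_vox = _layer_fields(spec)
    n2 = shape[2]
    vol = np.empty(shape, dtype=np.float32)
    layer2d = np.full(white2d.shape, lm.molecular_gray, dtype=np.float32)
    layer2d[white2d] = lm.white_gray
    layer2d[gran2d] = lm.granular_gray
    vol[:] = layer2d[:, :, None]

    mol_mask = np.broadcast_to(mol2d[:, :, None], shape).copy()
    layer_masks = {
        "white": np.broadcast_to(white2d[:, :, None], shape).copy(),
        "granular": np.broadcast_to(gran2d[:, :, None], shape).copy(),
        "molecular": mol_mask,
    }

    # Placement bookkeeping.  `occupied` holds every rendered object inflated
    # by a small margin and enforces hard non-overlap.  `foreign` holds the
    # non-plaque bright objects (somata): a plaque keeps its guard sphere —
    # sized to circumscribe the VOI cylinder later drawn around it — clear of
    # them, and `plaque_guard` stores those spheres so vessels placed last
    # stay out of every future VOI.  Plaque-plaque proximity is allowed (two
    # nearby plaques segment as two components); only foreign bright objects
    # inside a plaque VOI would corrupt intensity-based segmentation.
    occupied = np.zeros(shape, dtype=bool)
    foreign = np.zeros(shape, dtype=bool)
    plaque_guard = np.zeros(shape, dtype=bool)
    margin_um = 5.0

    plaque_lab = np.zeros(shape, dtype=np.int32)
    purkinje_lab = np.zeros(shape, dtype=np.int32)
    vessel_lab = np.zeros(shape, dtype=np.int32)
    objects: list[PhantomObject] = []
    sphere_axis = np.array([1.0, 0.0, 0.0])

    km = spec.purkinje_model
    for cid in range(1, km.count + 1):
        d = float(rng.uniform(*km.diameter_range_um))
        r = d / 2.0
        placed = False
        for _ in range(_MAX_RETRIES):
            j = rng.uniform(0, shape[1])
            k = rng.uniform(0, shape[2])
            if km.at_interface:
                i = float(np.interp(j, np.arange(shape[1]), interface_i))
            else:
                i = rng.uniform(0, shape[0])
            center_vox = np.array([i, j, k])
            center_um = (center_vox + 0.5) * vs
            sl = _bbox_indices(center_vox, r / vs + 1.0, shape)
            gsl = _bbox_indices(center_vox, (r + margin_um) / vs + 1.0, shape)
            if sl is None or gsl is None:
                continue
            mask = _ellipsoid_mask(sl, center_um, sphere_axis, r, r, vs)
            if not mask.any():
                continue
            infl = _ellipsoid_mask(gsl, center_um, sphere_axis,
                                   r + margin_um, r + margin_um, vs)
            if occupied[gsl][infl].any():
                continue
            vol[sl][mask] = lm.molecular_gray + km.gray_offset
            purkinje_lab[sl][mask] = cid
            occupied[gsl][infl] = True
            foreign[gsl][infl] = True
            region = spec.region_of(j)
            objects.append(PhantomObject(
                cid, "purkinje", region.name if region else "",
                tuple(center_um), (r, r, r), (1.0, 0.0, 0.0),
                4.0 / 3.0 * math.pi * r**3,
            ))
            placed = True
            break
        if not placed:
            raise PlacementError("purkinje", cid - 1, km.count)

    vm = spec.vessel_model
    for vid in range(1, vm.count + 1):
        r = float(rng.uniform(*vm.radius_range_um))
        half_len = vm.length_um / 2.0
        placed = False
        for _ in range(_MAX_RETRIES):
            if vm.orientation == "coronal-plane":
                theta = rng.uniform(0.0, 2.0 * math.pi)
                d_axis = np.array([math.cos(theta), math.sin(theta), 0.0])
            else:
                d_axis = rng.standard_normal(3)
                d_axis /= np.linalg.norm(d_axis)
            # per-axis half extent of the padded capsule bounding box
            ext = (np.abs(d_axis) * half_len + r + margin_um) / vs + 1.0
            if np.any(ext >= np.asarray(shape) - ext):
                continue
            j = rng.uniform(ext[1], shape[1] - ext[1])
            k = rng.uniform(ext[2], shape[2] - ext[2])
            i_min = t_wg_vox - (spec.fold_amplitude_um / vs) * math.sin(
                2.0 * math.pi * j * vs / spec.fold_period_um
            )
            i_lo = max(i_min, ext[0])
            i_hi = shape[0] - ext[0]
            if i_lo >= i_hi:
                continue
            i = rng.uniform(i_lo, i_hi)
            center_vox = np.array([i, j, k])
            center_um = (center_vox + 0.5) * vs
            sl = _bbox_indices(center_vox, float(ext.max()), shape)
            if sl is None:
                continue
            mask = _capsule_mask(sl, center_um, d_axis, half_len, r, vs)
            if not mask.any():
                continue
            infl = _capsule_mask(sl, center_um, d_axis, half_len, r + margin_um, vs)
            if occupied[sl][infl].any():
                continue
            vol[sl][mask] = lm.molecular_gray + vm.gray_offset
            vessel_lab[sl][mask] = vid
            occupied[sl][infl] = True
            foreign[sl][infl] = True
            region = spec.region_of(j)
            objects.append(PhantomObject(
                vid, "vessel", region.name if region else "",
                tuple(center_um), (half_len, r, r), tuple(d_axis),
                math.pi * r**2 * vm.length_um + 4.0 / 3.0 * math.pi * r**3,
            ))
            placed = True
            break
        if not placed:
            raise PlacementError("vessel", vid - 1, vm.count)
    pm = spec.plaque_model
    mu_log = math.log(pm.volume_median_um3)
    core_scale = pm.core_volume_fraction ** (1.0 / 3.0)
    for pid in range(1, pm.count + 1):
        v_true = float(rng.lognormal(mean=mu_log, sigma=pm.volume_log_std))
        while pm.volume_max_um3 is not None and v_true > pm.volume_max_um3:
            v_true = float(rng.lognormal(mean=mu_log, sigma=pm.volume_log_std))
        ar = float(rng.uniform(*pm.aspect_ratio_range))
        b = (3.0 * v_true / (4.0 * math.pi * ar)) ** (1.0 / 3.0)
        a = ar * b
        half_vox = (a + margin_um) / vs + 1.0
        placed = False
        for _ in range(_MAX_RETRIES):
            # sample the centre inside the window where the padded bounding
            # box fits the grid, to spend retries on real collisions only
            if half_vox >= shape[1] - half_vox or half_vox >= shape[2] - half_vox:
                continue
            j = rng.uniform(half_vox, shape[1] - half_vox)
            k = rng.uniform(half_vox, shape[2] - half_vox)
            region = spec.region_of(j)
            if region is None:
                continue
            i_min = t_wg_vox - (spec.fold_amplitude_um / vs) * math.sin(
                2.0 * math.pi * j * vs / spec.fold_period_um
            )
            i_lo = max(i_min, half_vox)
            i_hi = shape[0] - half_vox
            if i_lo >= i_hi:
                continue
            i = rng.uniform(i_lo, i_hi)
            axis = sample_axis(rng, region)
            center_vox = np.array([i, j, k])
            center_um = (center_vox + 0.5) * vs
            sl = _bbox_indices(center_vox, a / vs + 1.0, shape)
            msl = _bbox_indices(center_vox, (a + margin_um) / vs + 1.0, shape)
            if sl is None or msl is None:
                continue
            mask = _ellipsoid_mask(sl, center_um, axis, a, b, vs)
            if not mask.any():
                continue
            if not mol_mask[sl][mask].all():
                continue  # plaques live only in the molecular layer
            infl = _ellipsoid_mask(msl, center_um, axis,
                                   a + margin_um, b + margin_um, vs)
            if occupied[msl][infl].any():
                continue
            # guard: the VOI cylinder later drawn around this plaque (its
            # in-plane footprint + seed margin + clearance, over its coronal
            # extent + clearance) must stay free of foreign bright objects
            u_xy2 = axis[0] ** 2 + axis[1] ** 2
            e_xy = math.sqrt(a * a * u_xy2 + b * b * (1.0 - u_xy2))
            e_z = math.sqrt(a * a * axis[2] ** 2 + b * b * (1.0 - axis[2] ** 2))
            g_r = e_xy + spec.plaque_guard_um
            g_z = e_z + spec.plaque_guard_um
            gsl = _clipped_bbox(center_vox, max(g_r, g_z) / vs + 1.0, shape)
            gm = _cylinder_mask(gsl, center_um, g_r, g_z, vs)
            if foreign[gsl][gm].any():
                continue  # a soma would fall inside this plaque's VOI
            vol[sl][mask] = lm.molecular_gray + pm.corona_gray_offset
            core = _ellipsoid_mask(sl, center_um, axis,
                                   core_scale * a, core_scale * b, vs)
            vol[sl][core & mask] = lm.molecular_gray + pm.core_gray_offset
            plaque_lab[sl][mask] = pid
            occupied[msl][infl] = True
            plaque_guard[gsl][gm] = True
            objects.append(PhantomObject(
                pid, "plaque", region.name, tuple(center_um),
                (a, b, b), tuple(axis), v_true,
            ))
            placed = True
            break
        if not placed:
            raise PlacementError("plaque", pid - 1, pm.count)


    if spec.noise_sigma > 0:
        vol += spec.noise_sigma * rng.standard_normal(shape, dtype=np.float32)

    gt = PhantomGroundTruth(
        plaque_labels=LabelMap(plaque_lab, vs),
        purkinje_labels=LabelMap(purkinje_lab, vs),
        vessel_labels=LabelMap(vessel_lab, vs),
        objects=objects,
        layer_masks=layer_masks,
    )
    return Volume(voxels=vol, voxel_size_um=vs), gt


# ---------------------------------------------------------------------------
# Seeds from ground truth, MIP rendering
# ---------------------------------------------------------------------------

def ground_truth_seeds(
    gt: PhantomGroundTruth, margin_um: float = 3.0
) -> list[SeedROI]:
    """One cylindrical seed per true plaque, from its label-mask extent.

    The circular ROI circumscribes the plaque's in-plane footprint with a
    small margin; the slice range spans its coronal extent.
    """
    seeds: list[SeedROI] = []
    lab = gt.plaque_labels.labels
    vs = gt.plaque_labels.voxel_size_um
    for obj in gt.objects_of("plaque"):
        where = np.nonzero(lab == obj.object_id)
        if where[0].size == 0:
            continue
        cx = obj.center_um[0] / vs - 0.5
        cy = obj.center_um[1] / vs - 0.5
        d_inplane = np.sqrt((where[0] - cx) ** 2 + (where[1] - cy) ** 2) * vs
        radius = float(d_inplane.max()) + margin_um
        seeds.append(SeedROI(
            center=(cx, cy),
            radius_um=radius,
            slice_range=(int(where[2].min()), int(where[2].max())),
            region_tag=obj.region,
        ))
    return seeds


_PLANE_AXIS = {"transverse": 0, "sagittal": 1, "coronal": 2}


def render_mip(
    volume: Volume,
    plane: str | int = "coronal",
    thickness_um: float = 25.0,
    start_um: float = 0.0,
) -> np.ndarray:
    """Maximum intensity projection across a physical slab.

    ``plane`` names the projection plane (projection runs along its normal:
    coronal -> axis 2, sagittal -> axis 1, transverse -> axis 0) or gives the
    axis directly.  The slab covers ``floor(thickness_um / voxel_size_um)``
    slices (minimum 1) starting at ``floor(start_um / voxel_size_um)``; a
    slab extending past the grid raises :class:`BoundsError`.
    """
    axis = _PLANE_AXIS[plane] if isinstance(plane, str) else int(plane)
    if axis not in (0, 1, 2):
        raise ConfigurationError(f"bad projection axis {plane!r}")
    vs = volume.voxel_size_um
    if thickness_um < vs:
        raise ConfigurationError(
            f"thickness {thickness_um} um is below one voxel ({vs} um)"
        )
    n = max(1, int(math.floor(thickness_um / vs)))
    i0 = int(math.floor(start_um / vs))
    extent = volume.shape[axis]
    if i0 < 0 or i0 + n > extent:
        raise BoundsError(
            f"slab [{i0}, {i0 + n}) outside axis-{axis} extent {extent}"
        )
    slab = np.take(volume.voxels, np.arange(i0, i0 + n), axis=axis)
    return slab.max(axis=axis)
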