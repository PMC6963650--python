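"""Digital phantoms: activity/attenuation maps and volumes of interest.

Phantoms are built from geometric primitives (z-aligned cylinders, spheres,
ellipsoids), each carrying per-isotope activity concentration (µCi/mL) and an
attenuation medium (water or air).  Primitives form a strict hierarchy: a
later primitive placed inside an earlier one *overrides* it (a cold chamber
carved into a hot cylinder).  Partial overlap is not supported.

Imaging here is two-dimensional (single direct transaxial slice, matching the
slice-wise filtered back-projection used downstream): activity maps are the
z = 0 cross-section of the phantom, and the activity bookkeeping is areal
(µCi per mm of axial extent through that slice).

Includes the caliper tumor-volume formula ``width² × length × 0.4`` used for
subcutaneous xenografts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.transform import radon

from .acquisition import ScannerModel, Sinogram, _MU_WATER_511_PER_MM

__all__ = [
    "Primitive", "Cylinder", "Sphere", "Ellipsoid", "PhantomSpec", "VOISpec",
    "nema_nu4_iq_phantom", "mouse_tumor_phantom", "tumor_volume",
    "voxelize", "voxelize_mu", "forward_project",
]

_MEDIA = ("water", "air")


@dataclass(frozen=True)
class Primitive:
    """Base geometric primitive with uniform activity and medium."""

    center_mm: tuple[float, float, float]
    activity_conc_uci_per_ml: Mapping[str, float] = field(default_factory=dict)
    medium: str = "water"

    def __post_init__(self) -> None:
        if self.medium not in _MEDIA:
            raise ValueError(f"medium must be one of {_MEDIA}")
        for iso, c in self.activity_conc_uci_per_ml.items():
            if c < 0:
                raise ValueError(f"negative concentration for {iso}")
        if self.medium == "air" and any(
                c > 0 for c in self.activity_conc_uci_per_ml.values()):
            raise ValueError("air compartments must carry zero activity")

    # subclasses implement
    def volume_mm3(self) -> float:
        raise NotImplementedError

    def cross_section_mm2(self) -> float:
        """Area of the z = 0 cross-section (0 if the slice misses it)."""
        raise NotImplementedError

    def contains(self, x, y, z=0.0) -> np.ndarray:
        raise NotImplementedError

    def radial_extent_mm(self) -> float:
        """Max distance of the solid from the z-axis (FOV check)."""
        raise NotImplementedError

    def _line_quadratic(self, o: np.ndarray, d: np.ndarray):
        raise NotImplementedError

    def ray_length_mm(self, origin: np.ndarray, direction: np.ndarray
                      ) -> np.ndarray:
        """Chord length of the forward ray (t ≥ 0) inside the solid."""
        t0, t1 = self._line_quadratic(np.atleast_2d(origin),
                                      np.atleast_2d(direction))
        lo = np.maximum(t0, 0.0)
        return np.maximum(t1 - lo, 0.0)


def _solve_quad(a, b, c):
    """Entry/exit parameters of a x² + b x + c ≤ 0; empty → (inf, inf)."""
    disc = b * b - a * c           # a t² + 2 b t + c form
    ok = (disc > 0) & (a > 0)
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = np.where(ok, (-b - sq) / a, np.inf)
        t1 = np.where(ok, (-b + sq) / a, np.inf)
    return t0, t1


@dataclass(frozen=True)
class Sphere(Primitive):
    radius_mm: float = 1.0

    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_mm**3

    def cross_section_mm2(self) -> float:
        cz = self.center_mm[2]
        if abs(cz) >= self.radius_mm:
            return 0.0
        return math.pi * (self.radius_mm**2 - cz**2)

    def contains(self, x, y, z=0.0) -> np.ndarray:
        cx, cy, cz = self.center_mm
        return ((np.asarray(x) - cx)**2 + (np.asarray(y) - cy)**2
                + (np.asarray(z) - cz)**2) <= self.radius_mm**2

    def radial_extent_mm(self) -> float:
        cx, cy, _ = self.center_mm
        return math.hypot(cx, cy) + self.radius_mm

    def _line_quadratic(self, o, d):
        p = o - np.asarray(self.center_mm)
        a = np.sum(d * d, axis=1)
        b = np.sum(p * d, axis=1)
        c = np.sum(p * p, axis=1) - self.radius_mm**2
        return _solve_quad(a, b, c)

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = self.radius_mm * rng.random(n) ** (1.0 / 3.0)
        return np.asarray(self.center_mm) + u * r[:, None]


@dataclass(frozen=True)
class Ellipsoid(Primitive):
    semi_axes_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c

    def cross_section_mm2(self) -> float:
        a, b, c = self.semi_axes_mm
        cz = self.center_mm[2]
        if abs(cz) >= c:
            return 0.0
        scale = 1.0 - (cz / c)**2
        return math.pi * a * b * scale

    def contains(self, x, y, z=0.0) -> np.ndarray:
        cx, cy, cz = self.center_mm
        a, b, c = self.semi_axes_mm
        return (((np.asarray(x) - cx) / a)**2 + ((np.asarray(y) - cy) / b)**2
                + ((np.asarray(z) - cz) / c)**2) <= 1.0

    def radial_extent_mm(self) -> float:
        cx, cy, _ = self.center_mm
        return math.hypot(cx, cy) + max(self.semi_axes_mm[:2])

    def _line_quadratic(self, o, d):
        s = np.asarray(self.semi_axes_mm)
        p = (o - np.asarray(self.center_mm)) / s
        q = d / s
        a = np.sum(q * q, axis=1)
        b = np.sum(p * q, axis=1)
        c = np.sum(p * p, axis=1) - 1.0
        return _solve_quad(a, b, c)

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = rng.random(n) ** (1.0 / 3.0)
        return (np.asarray(self.center_mm)
                + u * r[:, None] * np.asarray(self.semi_axes_mm))


@dataclass(frozen=True)
class Cylinder(Primitive):
    """z-aligned circular cylinder."""

    radius_mm: float = 1.0
    length_mm: float = 1.0

    def volume_mm3(self) -> float:
        return math.pi * self.radius_mm**2 * self.length_mm

    def cross_section_mm2(self) -> float:
        cz = self.center_mm[2]
        if abs(cz) > self.length_mm / 2.0:
            return 0.0
        return math.pi * self.radius_mm**2

    def contains(self, x, y, z=0.0) -> np.ndarray:
        cx, cy, cz = self.center_mm
        inside_r = ((np.asarray(x) - cx)**2
                    + (np.asarray(y) - cy)**2) <= self.radius_mm**2
        inside_z = np.abs(np.asarray(z) - cz) <= self.length_mm / 2.0
        return inside_r & inside_z

    def radial_extent_mm(self) -> float:
        cx, cy, _ = self.center_mm
        return math.hypot(cx, cy) + self.radius_mm

    def _line_quadratic(self, o, d):
        cx, cy, cz = self.center_mm
        px = o[:, 0] - cx
        py = o[:, 1] - cy
        a = d[:, 0]**2 + d[:, 1]**2
        b = px * d[:, 0] + py * d[:, 1]
        c = px * px + py * py - self.radius_mm**2
        t0, t1 = _solve_quad(a, b, c)
        # intersect with the z-slab
        zh = self.length_mm / 2.0
        dz = o[:, 2] - cz
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = np.where(d[:, 2] != 0, (-zh - dz) / d[:, 2], np.where(
                np.abs(dz) <= zh, -np.inf, np.inf))
            tb = np.where(d[:, 2] != 0, (zh - dz) / d[:, 2], np.where(
                np.abs(dz) <= zh, np.inf, -np.inf))
        z0, z1 = np.minimum(ta, tb), np.maximum(ta, tb)
        lo = np.maximum(t0, z0)
        hi = np.minimum(t1, z1)
        return lo, np.maximum(hi, lo)

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = self.radius_mm * np.sqrt(rng.random(n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        z = rng.uniform(-self.length_mm / 2.0, self.length_mm / 2.0, n)
        return np.asarray(self.center_mm) + np.column_stack(
            [r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class VOISpec:
    """Volume of interest for quantification.

    A voxel belongs to the VOI iff its *centre* lies inside the solid (no
    partial-volume weighting)."""

    shape: str                      # "cylinder" | "sphere"
    center_mm: tuple[float, float, float]
    dimensions_mm: tuple[float, ...]  # cylinder: (diameter, length); sphere: (diameter,)
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "sphere"):
            raise ValueError("shape must be cylinder or sphere")
        if any(d <= 0 for d in self.dimensions_mm):
            raise ValueError("dimensions must be positive")

    def mask(self, x: np.ndarray, y: np.ndarray, z=0.0) -> np.ndarray:
        cx, cy, cz = self.center_mm
        r = self.dimensions_mm[0] / 2.0
        in_xy = (np.asarray(x) - cx)**2 + (np.asarray(y) - cy)**2 <= r * r
        if self.shape == "sphere":
            return ((np.asarray(x) - cx)**2 + (np.asarray(y) - cy)**2
                    + (np.asarray(z) - cz)**2) <= r * r
        half = self.dimensions_mm[1] / 2.0
        return in_xy & (np.abs(np.asarray(z) - cz) <= half)


class PhantomSpec:
    """An ordered hierarchy of primitives; later primitives override earlier
    ones where they overlap (and must lie fully inside them)."""

    def __init__(self, primitives: Sequence[Primitive], name: str = "phantom"):
        if not primitives:
            raise ValueError("phantom needs at least one primitive")
        self.primitives = list(primitives)
        self.name = name
        self._parents = self._resolve_hierarchy()

    def _resolve_hierarchy(self) -> list[int | None]:
        """parent index of each primitive (innermost enclosing earlier one)."""
        parents: list[int | None] = []
        for j, child in enumerate(self.primitives):
            parent = None
            for i in range(j - 1, -1, -1):
                if self._inside(child, self.primitives[i]):
                    parent = i
                    break
            parents.append(parent)
        return parents

    @staticmethod
    def _inside(child: Primitive, parent: Primitive) -> bool:
        """Containment check via deterministic boundary probing."""
        pts = child.sample_points(256, np.random.default_rng(0))
        return bool(np.all(parent.contains(pts[:, 0], pts[:, 1], pts[:, 2])))

    # -- bookkeeping --------------------------------------------------------

    def isotopes(self) -> list[str]:
        names: list[str] = []
        for p in self.primitives:
            for iso in p.activity_conc_uci_per_ml:
                if iso not in names:
                    names.append(iso)
        return names

    def _conc(self, prim: Primitive, isotope: str) -> float:
        return float(prim.activity_conc_uci_per_ml.get(isotope, 0.0))

    def total_activity_uci(self, isotope: str) -> float:
        """Analytic total activity honoring the override hierarchy."""
        total = 0.0
        for j, p in enumerate(self.primitives):
            total += self._conc(p, isotope) * p.volume_mm3() / 1000.0
            if self._parents[j] is not None:
                parent = self.primitives[self._parents[j]]
                total -= self._conc(parent, isotope) * p.volume_mm3() / 1000.0
        return total

    def areal_activity_uci_per_mm(self, isotope: str) -> float:
        """Activity per mm of axial extent in the z = 0 slice (2-D mode)."""
        total = 0.0
        for j, p in enumerate(self.primitives):
            area = p.cross_section_mm2()
            total += self._conc(p, isotope) * area / 1000.0
            if self._parents[j] is not None:
                parent = self.primitives[self._parents[j]]
                total -= self._conc(parent, isotope) * area / 1000.0
        return total

    def check_fov(self, scanner: ScannerModel) -> None:
        for p in self.primitives:
            if p.radial_extent_mm() > scanner.fov_mm / 2.0:
                raise ValueError(
                    f"primitive at {p.center_mm} exceeds the scanner FOV")

    # -- queries used by the simulator --------------------------------------

    def _owner_index(self, x, y, z) -> np.ndarray:
        """Index of the (last, i.e. overriding) primitive containing each
        point; -1 outside."""
        x, y, z = np.broadcast_arrays(np.asarray(x, float),
                                      np.asarray(y, float),
                                      np.asarray(z, float))
        owner = np.full(x.shape, -1, dtype=int)
        for i, p in enumerate(self.primitives):
            owner[p.contains(x, y, z)] = i
        return owner

    def concentration_at(self, isotope: str, x, y, z=0.0) -> np.ndarray:
        owner = self._owner_index(x, y, z)
        concs = np.array([self._conc(p, isotope) for p in self.primitives])
        out = np.zeros(owner.shape)
        inside = owner >= 0
        out[inside] = concs[owner[inside]]
        return out

    def sample_activity_points(self, isotope: str, n: int,
                               rng: np.random.Generator) -> np.ndarray:
        """Sample emission points ∝ local activity concentration."""
        weights = []
        for j, p in enumerate(self.primitives):
            w = self._conc(p, isotope) * p.volume_mm3()
            weights.append(max(w, 0.0))
        weights = np.asarray(weights)
        if weights.sum() <= 0:
            raise ValueError(f"phantom holds no {isotope} activity")
        out = np.empty((n, 3))
        counts = rng.multinomial(n, weights / weights.sum())
        pos = 0
        for j, (p, k) in enumerate(zip(self.primitives, counts)):
            taken = 0
            while taken < k:  # rejection: child regions override the parent
                pts = p.sample_points(k - taken, rng)
                keep = self._owner_index(pts[:, 0], pts[:, 1], pts[:, 2]) == j
                kept = pts[keep]
                out[pos + taken:pos + taken + kept.shape[0]] = kept
                taken += kept.shape[0]
            pos += k
        return out

    def water_path_mm(self, origin: np.ndarray, direction: np.ndarray
                      ) -> np.ndarray:
        """Water path length along forward rays, honoring air carve-outs."""
        origin = np.atleast_2d(origin)
        direction = np.atleast_2d(direction)
        path = np.zeros(origin.shape[0])
        for j, p in enumerate(self.primitives):
            L = p.ray_length_mm(origin, direction)
            parent = self._parents[j]
            if p.medium == "water" and (parent is None or
                                        self.primitives[parent].medium != "water"):
                path += L
            elif p.medium == "air" and (parent is not None and
                                        self.primitives[parent].medium == "water"):
                path -= L
        return np.maximum(path, 0.0)

    def scatter_fraction_estimate(self) -> float:
        """Coarse pair-level scatter fraction from the mean chord (4V/S) of
        the largest water primitive."""
        water = [p for j, p in enumerate(self.primitives)
                 if p.medium == "water" and self._parents[j] is None]
        if not water:
            return 0.0
        body = max(water, key=lambda p: p.volume_mm3())
        if isinstance(body, Cylinder):
            surf = (2 * math.pi * body.radius_mm * body.length_mm
                    + 2 * math.pi * body.radius_mm**2)
        elif isinstance(body, Sphere):
            surf = 4 * math.pi * body.radius_mm**2
        else:  # ellipsoid: Thomsen approximation
            a, b, c = body.semi_axes_mm
            pex = 1.6075
            surf = 4 * math.pi * (((a * b)**pex + (a * c)**pex
                                   + (b * c)**pex) / 3.0) ** (1.0 / pex)
        chord = 4.0 * body.volume_mm3() / surf
        p1 = 1.0 - math.exp(-_MU_WATER_511_PER_MM * chord)
        return 1.0 - (1.0 - p1) ** 2


    # -- text-config serialization ------------------------------------------

    def to_config(self) -> str:
        """Structured text (YAML) description; inverse of
        :meth:`from_config`.  Schema: ``name`` plus a ``primitives`` list of
        mappings with ``shape`` (cylinder/sphere/ellipsoid), ``center_mm``,
        shape dimensions, ``medium`` and ``activity_uci_per_ml``."""
        import yaml

        prims = []
        for p in self.primitives:
            d: dict = {"shape": type(p).__name__.lower(),
                       "center_mm": list(p.center_mm),
                       "medium": p.medium,
                       "activity_uci_per_ml":
                           dict(p.activity_conc_uci_per_ml)}
            if isinstance(p, Cylinder):
                d.update(radius_mm=p.radius_mm, length_mm=p.length_mm)
            elif isinstance(p, Sphere):
                d.update(radius_mm=p.radius_mm)
            else:
                d.update(semi_axes_mm=list(p.semi_axes_mm))
            prims.append(d)
        return yaml.safe_dump({"name": self.name, "primitives": prims},
                              sort_keys=False)

    @classmethod
    def from_config(cls, text: str) -> "PhantomSpec":
        import yaml

        cfg = yaml.safe_load(text)
        shapes = {"cylinder": Cylinder, "sphere": Sphere,
                  "ellipsoid": Ellipsoid}
        prims = []
        for d in cfg["primitives"]:
            kind = shapes[d["shape"]]
            kwargs = {"center_mm": tuple(d["center_mm"]),
                      "medium": d.get("medium", "water"),
                      "activity_conc_uci_per_ml":
                          d.get("activity_uci_per_ml", {})}
            if kind is Ellipsoid:
                kwargs["semi_axes_mm"] = tuple(d["semi_axes_mm"])
            else:
                kwargs["radius_mm"] = d["radius_mm"]
                if kind is Cylinder:
                    kwargs["length_mm"] = d["length_mm"]
            prims.append(kind(**kwargs))
        return cls(prims, name=cfg.get("name", "phantom"))


# -- standard phantoms -------------------------------------------------------

def tumor_volume(width_mm: float, length_mm: float) -> float:
    """Caliper tumor volume in mm³: width² × length × 0.4."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("width and length must be positive")
    return width_mm**2 * length_mm * 0.4


def nema_nu4_iq_phantom(f18, i131=0.0,
                        ) -> tuple[PhantomSpec, dict[str, VOISpec]]:
    """NEMA NU4-2008 image-quality phantom, cold-chamber section.

    A uniform 30 mm-diameter hot cylinder (standard NU4 body; the uniform
    region is 15 mm long) with two cold chambers (length 15 mm, inner
    diameter 8 mm): one air-filled, one filled with non-radioactive water.
    Returns the phantom and the standard VOI set: one 7.5 mm × 4 mm-diameter
    cylinder centred in each cold chamber (diameter 50 % of the chamber's
    8 mm bore, within the ≤75 % rule) plus a uniform-region VOI.

    ``f18``/``i131`` are total activities in µCi (or :class:`Activity`).
    """
    f18 = float(f18)
    i131 = float(i131)
    if f18 < 0 or i131 < 0:
        raise ValueError("activities must be non-negative")
    body_r, body_len = 15.0, 15.0
    cham_r, cham_len = 4.0, 15.0
    net_volume_ml = (math.pi * body_r**2 * body_len
                     - 2 * math.pi * cham_r**2 * cham_len) / 1000.0
    conc = {}
    if f18 > 0:
        conc["F-18"] = f18 / net_volume_ml
    if i131 > 0:
        conc["I-131"] = i131 / net_volume_ml
    body = Cylinder(center_mm=(0.0, 0.0, 0.0), radius_mm=body_r,
                    length_mm=body_len, activity_conc_uci_per_ml=conc)
    water_chamber = Cylinder(center_mm=(-7.0, 0.0, 0.0), radius_mm=cham_r,
                             length_mm=cham_len, medium="water")
    air_chamber = Cylinder(center_mm=(7.0, 0.0, 0.0), radius_mm=cham_r,
                           length_mm=cham_len, medium="air")
    phantom = PhantomSpec([body, water_chamber, air_chamber], name="nema-nu4-iq")
    vois = {
        "cold-water": VOISpec("cylinder", (-7.0, 0.0, 0.0), (4.0, 7.5),
                              label="cold-water"),
        "cold-air": VOISpec("cylinder", (7.0, 0.0, 0.0), (4.0, 7.5),
                            label="cold-air"),
        "uniform": VOISpec("cylinder", (0.0, -8.5, 0.0), (6.0, 7.5),
                           label="uniform"),
    }
    return phantom, vois


def mouse_tumor_phantom(f18, i131=0.0, tumor_volume_mm3: float = 300.0,
                        *, shell_uptake_ratio: float = 3.0,
                        core_uptake_ratio: float = 0.0,
                        ) -> tuple[PhantomSpec, dict[str, VOISpec]]:
    """Stylized mouse with a subcutaneous tumor (hot shell, necrotic core).

    An ellipsoid body with uniform background uptake carries a spherical
    tumor of the requested volume whose outer shell takes up
    ``shell_uptake_ratio`` × background and whose core (half the radius)
    takes ``core_uptake_ratio`` × background (0 = fully necrotic).
    I-131 (the circulating therapy nuclide) is distributed uniformly over
    the body.  Not an anatomical atlas.
    """
    f18 = float(f18)
    i131 = float(i131)
    if tumor_volume_mm3 <= 0:
        raise ValueError("tumor volume must be positive")
    body_axes = (12.5, 12.5, 35.0)
    body_vol = 4.0 / 3.0 * math.pi * body_axes[0] * body_axes[1] * body_axes[2]
    r_tumor = (3.0 * tumor_volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    if tumor_volume_mm3 >= body_vol:
        raise ValueError("tumor larger than the body")
    r_core = r_tumor / 2.0
    center_t = (body_axes[0] - r_tumor * 0.9, 0.0, 0.0)  # subcutaneous bulge

    # background concentration from total activity over the body volume
    c_bg_f = f18 / (body_vol / 1000.0) if f18 > 0 else 0.0
    c_bg_i = i131 / (body_vol / 1000.0) if i131 > 0 else 0.0

    def conc(scale_f): return {
        k: v for k, v in (("F-18", c_bg_f * scale_f), ("I-131", c_bg_i)) if v > 0}

    body = Ellipsoid(center_mm=(0.0, 0.0, 0.0), semi_axes_mm=body_axes,
                     activity_conc_uci_per_ml=conc(1.0))
    shell = Sphere(center_mm=center_t, radius_mm=r_tumor,
                   activity_conc_uci_per_ml=conc(shell_uptake_ratio))
    core = Sphere(center_mm=center_t, radius_mm=r_core,
                  activity_conc_uci_per_ml=conc(core_uptake_ratio))
    phantom = PhantomSpec([body, shell, core], name="mouse-tumor")
    vois = {
        "tumor": VOISpec("sphere", center_t, (2.0 * r_tumor,), label="tumor"),
        "core": VOISpec("sphere", center_t, (2.0 * r_core,), label="core"),
        "background": VOISpec("sphere", (-8.0, 0.0, 0.0), (6.0,),
                              label="background"),
    }
    return phantom, vois


# -- voxelization and forward projection -------------------------------------

def _grid(scanner: ScannerModel, voxel_mm: float):
    n = int(round(scanner.fov_mm / voxel_mm))
    coords = (np.arange(n) - (n - 1) / 2.0) * voxel_mm
    return n, coords


def voxelize(phantom: PhantomSpec, scanner: ScannerModel,
             isotope: str | None = None, voxel_mm: float = 0.4,
             supersample: int = 4) -> np.ndarray:
    """Activity-concentration map (µCi/mL) of the z = 0 slice.

    Anti-aliased by ``supersample × supersample`` sub-voxel averaging, which
    keeps the voxelized total consistent with the analytic areal activity.
    If ``isotope`` is None, all isotopes are summed.
    """
    isotopes = [isotope] if isotope else phantom.isotopes()
    n, coords = _grid(scanner, voxel_mm)
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    out = np.zeros((n, n))
    for dy in sub:
        for dx in sub:
            xs = coords + dx * voxel_mm
            ys = coords + dy * voxel_mm
            xx, yy = np.meshgrid(xs, ys)
            for iso in isotopes:
                out += phantom.concentration_at(iso, xx, yy, 0.0)
    return out / supersample**2


def voxelize_mu(phantom: PhantomSpec, scanner: ScannerModel,
                voxel_mm: float = 0.4, supersample: int = 4) -> np.ndarray:
    """511 keV linear-attenuation map (1/mm) of the z = 0 slice."""
    n, coords = _grid(scanner, voxel_mm)
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    out = np.zeros((n, n))
    water = np.array([1.0 if p.medium == "water" else 0.0
                      for p in phantom.primitives])
    for dy in sub:
        for dx in sub:
            xs = coords + dx * voxel_mm
            ys = coords + dy * voxel_mm
            xx, yy = np.meshgrid(xs, ys)
            owner = phantom._owner_index(xx, yy, 0.0)
            inside = owner >= 0
            frame = np.zeros((n, n))
            frame[inside] = water[owner[inside]]
            out += frame
    return out * _MU_WATER_511_PER_MM / supersample**2


def forward_project(obj, scanner: ScannerModel, voxel_mm: float = 0.4,
                    isotope: str | None = None, **meta) -> Sinogram:
    """Noise-free parallel-beam line integrals on the scanner (φ, s) grid.

    ``obj`` is a :class:`PhantomSpec` (voxelized first) or a 2-D map on the
    matching grid.  Output values are line integrals in (map units)·mm;
    linear in the input.
    """
    if isinstance(obj, PhantomSpec):
        obj.check_fov(scanner)
        img = voxelize(obj, scanner, isotope=isotope, voxel_mm=voxel_mm)
    else:
        img = np.asarray(obj, dtype=float)
    n, _ = _grid(scanner, voxel_mm)
    if img.shape != (n, n):
        raise ValueError(f"image must be {(n, n)} for voxel {voxel_mm} mm")
    theta = np.arange(scanner.n_angles) * 180.0 / scanner.n_angles
    sino = radon(img, theta=theta, circle=True) * voxel_mm  # (n_s, n_theta)
    # resample the radon radial axis (spacing voxel_mm) onto the scanner bins
    s_in = (np.arange(sino.shape[0]) - (sino.shape[0] - 1) / 2.0) * voxel_mm
    s_out = (np.arange(scanner.n_radial_bins)
             - (scanner.n_radial_bins - 1) / 2.0) * scanner.radial_bin_mm
    out = np.empty((scanner.n_angles, scanner.n_radial_bins))
    for k in range(scanner.n_angles):
        out[k] = np.interp(s_out, s_in, sino[:, k], left=0.0, right=0.0)
    return Sinogram(np.maximum(out, 0.0),
                    {"bin_mm": scanner.radial_bin_mm, "kind": "line-integral",
                     **meta})
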