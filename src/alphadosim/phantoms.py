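"""Cell-nucleus phantom sets for the scoring region at the well bottom.

Two phantom families mirror the study design:

* **Elliptical cylinders** — major axes drawn from a truncated logistic
  distribution fitted to DAPI-segmented nuclei (mean 15.3 um, SD
  4.1 um); the minor axis is exactly 2/3 of the major and the height is
  8 um for every nucleus.  The printed mean phantom volume (930 um^3)
  is not attainable with the printed mean axis (a point mass at
  15.3 um already gives 981 um^3), so the sampler calibrates the
  logistic *location* so the expected phantom volume matches the
  requested target; the scale is kept at the fitted SD.
* **Closed triangle meshes** — loaded from STL (stand-ins for segmented
  DAPI z-stacks), validated for watertightness and orientation, and
  tiled across the region the way the study repeated its segmented
  image volume 95 times.

All phantoms sit at a common depth (tops 2.5 um below the water
surface), so overlap is tested on the 2-D footprints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import optimize, stats

__all__ = [
    "EllipticalCylinderNucleus",
    "MeshNucleus",
    "PhantomSet",
    "sample_elliptical_phantoms",
    "place_without_overlap",
    "load_mesh",
    "validate_mesh",
    "tile_mesh_set",
    "chord_length",
    "ellipses_overlap",
    "mesh_volume_um3",
]

HEIGHT_UM = 8.0
MINOR_OVER_MAJOR = 2.0 / 3.0


class PackingError(RuntimeError):
    pass


class MeshValidationError(ValueError):
    pass


@dataclass
class EllipticalCylinderNucleus:
    """Elliptical-cylinder nucleus: fixed 8-um height, minor = 2/3 major."""

    center_x_mm: float
    center_y_mm: float
    major_um: float
    azimuth_rad: float

    @property
    def minor_um(self) -> float:
        return self.major_um * MINOR_OVER_MAJOR

    @property
    def height_um(self) -> float:
        return HEIGHT_UM

    @property
    def volume_um3(self) -> float:
        return math.pi * (self.major_um / 2) * (self.minor_um / 2) * HEIGHT_UM

    @property
    def footprint_um2(self) -> float:
        return math.pi * (self.major_um / 2) * (self.minor_um / 2)


@dataclass
class MeshNucleus:
    """Watertight closed-surface nucleus; coordinates in um, with an
    (x, y) placement offset in mm."""

    mesh: trimesh.Trimesh
    center_x_mm: float = 0.0
    center_y_mm: float = 0.0
    validated: bool = False

    @property
    def volume_um3(self) -> float:
        return float(abs(self.mesh.volume))

    @property
    def footprint_radius_um(self) -> float:
        v = self.mesh.vertices
        c = v[:, :2].mean(axis=0)
        return float(np.max(np.hypot(v[:, 0] - c[0], v[:, 1] - c[1])))


@dataclass
class PhantomSet:
    """A set of placed nucleus phantoms inside the central scoring square."""

    kind: str                       # "ellipse" | "mesh"
    region_side_mm: float = 4.0
    depth_um: float = 2.5           # top surface below the water surface
    ellipses: list = field(default_factory=list)
    meshes: list = field(default_factory=list)

    def __len__(self):
        return len(self.ellipses) if self.kind == "ellipse" else len(self.meshes)

    @property
    def volumes_um3(self) -> np.ndarray:
        items = self.ellipses if self.kind == "ellipse" else self.meshes
        return np.array([p.volume_um3 for p in items])

    def to_frame(self) -> pd.DataFrame:
        if self.kind == "ellipse":
            return pd.DataFrame([{
                "id": i, "type": "ellipse",
                "center_x_mm": p.center_x_mm, "center_y_mm": p.center_y_mm,
                "major_um": p.major_um, "minor_um": p.minor_um,
                "height_um": p.height_um, "azimuth_rad": p.azimuth_rad,
                "volume_um3": p.volume_um3,
            } for i, p in enumerate(self.ellipses)])
        return pd.DataFrame([{
            "id": i, "type": "mesh",
            "center_x_mm": p.center_x_mm, "center_y_mm": p.center_y_mm,
            "volume_um3": p.volume_um3,
        } for i, p in enumerate(self.meshes)])


# ---------------------------------------------------------------------------
# elliptical phantoms

def _truncated_logistic(loc, scale, lo, hi):
    if scale <= 0:
        raise ValueError("scale must be positive")
    dist = stats.logistic(loc=loc, scale=scale)
    plo, phi = dist.cdf(lo), dist.cdf(hi)
    if phi - plo <= 1e-12:
        raise ValueError("truncation bounds exclude all probability mass")
    return dist, plo, phi

def _trunc_moment2(loc, scale, lo, hi, n_grid=4001):
    dist, plo, phi = _truncated_logistic(loc, scale, lo, hi)
    x = np.linspace(lo, hi, n_grid)
    pdf = dist.pdf(x) / (phi - plo)
    return float(np.trapezoid(x * x * pdf, x))


def sample_elliptical_phantoms(
    n: int,
    axis_mean_um: float = 15.3,
    axis_sd_um: float = 4.1,
    truncation_um: tuple[float, float] = (4.0, 40.0),
    target_mean_volume_um3: float | None = 930.0,
    seed: int = 0,
    region_side_mm: float = 4.0,
) -> PhantomSet:
    """Draw ``n`` elliptical-cylinder nuclei (not yet placed).

    Major axes follow a logistic distribution (scale from ``axis_sd_um``)
    truncated to ``truncation_um``.  If ``target_mean_volume_um3`` is
    given, the location parameter is calibrated so that the expected
    phantom volume matches the target; otherwise the location is
    ``axis_mean_um``.  Azimuths are uniform.
    """
    scale = axis_sd_um * math.sqrt(3.0) / math.pi
    lo, hi = truncation_um
    if target_mean_volume_um3 is not None:
        target_m2 = target_mean_volume_um3 / (
            math.pi * HEIGHT_UM * MINOR_OVER_MAJOR / 4.0)

        def f(loc):
            return _trunc_moment2(loc, scale, lo, hi) - target_m2

        loc = optimize.brentq(f, lo, hi, xtol=1e-6)
    else:
        loc = axis_mean_um
    dist, plo, phi = _truncated_logistic(loc, scale, lo, hi)
    rng = np.random.default_rng(seed)
    major = dist.ppf(plo + rng.random(n) * (phi - plo))
    azim = rng.random(n) * 2 * math.pi
    ells = [EllipticalCylinderNucleus(np.nan, np.nan, m, a)
            for m, a in zip(major, azim)]
    ps = PhantomSet(kind="ellipse", region_side_mm=region_side_mm, ellipses=ells)
    ps.axis_loc_um = float(loc)
    return ps


def _ellipse_boundary(cx, cy, a, b, az, n=256):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    ca, sa = math.cos(az), math.sin(az)
    return cx + x * ca - y * sa, cy + x * sa + y * ca


def _point_in_ellipse(px, py, cx, cy, a, b, az):
    ca, sa = math.cos(az), math.sin(az)
    dx, dy = px - cx, py - cy
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def ellipses_overlap(e1, e2, n_boundary: int = 256) -> bool:
    """Footprint-overlap test for two ellipses given as
    (cx, cy, semi_major, semi_minor, azimuth) tuples, all in one unit.

    Two ellipses overlap iff one centre lies inside the other or their
    boundaries cross; boundary crossing is detected by testing a dense
    set of boundary points of each ellipse for membership in the other.
    """
    c1 = (e1[0], e1[1])
    c2 = (e2[0], e2[1])
    # cheap reject: bounding circles
    if math.hypot(c1[0] - c2[0], c1[1] - c2[1]) > e1[2] + e2[2]:
        return False
    if _point_in_ellipse(c2[0], c2[1], *e1) or _point_in_ellipse(c1[0], c1[1], *e2):
        return True
    bx, by = _ellipse_boundary(*e2, n=n_boundary)
    if np.any(_point_in_ellipse_vec(bx, by, *e1)):
        return True
    bx, by = _ellipse_boundary(*e1, n=n_boundary)
    return bool(np.any(_point_in_ellipse_vec(bx, by, *e2)))


def _point_in_ellipse_vec(px, py, cx, cy, a, b, az):
    ca, sa = math.cos(az), math.sin(az)
    dx, dy = px - cx, py - cy
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def place_without_overlap(
    phantoms: PhantomSet,
    region_side_mm: float | None = None,
    seed: int = 0,
    max_attempts: int = 200,
) -> PhantomSet:
    """Rejection-sample non-overlapping centres inside the scoring square.

    Footprints (including the full ellipse) must stay inside the region.
    Neighbour candidates are found on a uniform grid hash; exact overlap
    uses :func:`ellipses_overlap`.  Raises :class:`PackingError` naming
    the failing nucleus when ``max_attempts`` placements all collide.
    """
    if phantoms.kind != "ellipse":
        raise ValueError("placement operates on elliptical phantom sets")
    if region_side_mm is None:
        region_side_mm = phantoms.region_side_mm
    side_um = region_side_mm * 1e3
    ells = phantoms.ellipses
    if not ells:
        return phantoms
    total_area = sum(p.footprint_um2 for p in ells)
    if total_area >= 0.5 * side_um**2:
        raise PackingError(
            f"footprint area {total_area:.0f} um^2 exceeds half the region")
    rng = np.random.default_rng(seed)
    max_r = max(p.major_um / 2 for p in ells)
    cell = 2 * max_r
    grid: dict[tuple[int, int], list[int]] = {}
    placed = []  # (cx, cy, a, b, az) in um, region-centred coords

    for i, p in enumerate(ells):
        a, b = p.major_um / 2, p.minor_um / 2
        for _ in range(max_attempts):
            cx = rng.uniform(a, side_um - a) - side_um / 2
            cy = rng.uniform(a, side_um - a) - side_um / 2
            gx, gy = int(cx // cell), int(cy // cell)
            cand = (e1 for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                    for e1 in grid.get((gx + dx, gy + dy), ()))
            me = (cx, cy, a, b, p.azimuth_rad)
            if not any(ellipses_overlap(me, placed[j]) for j in cand):
                placed.append(me)
                grid.setdefault((gx, gy), []).append(i)
                p.center_x_mm = cx * 1e-3
                p.center_y_mm = cy * 1e-3
                break
        else:
            raise PackingError(
                f"could not place nucleus {i} (major {p.major_um:.1f} um) "
                f"after {max_attempts} attempts")
    phantoms.region_side_mm = region_side_mm
    return phantoms


# ---------------------------------------------------------------------------
# mesh phantoms

def mesh_volume_um3(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume by the divergence theorem (sum of signed
    tetrahedra against the origin)."""
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)


def validate_mesh(mesh: trimesh.Trimesh) -> dict:
    """Watertightness / orientation / volume report for a candidate
    nucleus mesh."""
    vol = mesh_volume_um3(mesh.vertices.view(np.ndarray),
                          mesh.faces.view(np.ndarray))
    return {
        "watertight": bool(mesh.is_watertight),
        "winding_consistent": bool(mesh.is_winding_consistent),
        "volume_um3": abs(vol),
        "outward_oriented": vol > 0,
        "n_faces": len(mesh.faces),
    }


def load_mesh(path, require_valid: bool = True) -> MeshNucleus:
    """Load an STL nucleus mesh (ASCII or binary) and validate it."""
    mesh = trimesh.load_mesh(path, process=True)  # merge duplicated STL vertices
    report = validate_mesh(mesh)
    if require_valid and not (report["watertight"] and report["winding_consistent"]):
        raise MeshValidationError(f"mesh {path} failed validation: {report}")
    return MeshNucleus(mesh=mesh, validated=report["watertight"])


def tile_mesh_set(unit_cell: list[MeshNucleus], n_tiles: int,
                  region_side_mm: float = 4.0,
                  pitch_mm: float | None = None) -> PhantomSet:
    """Replicate a unit cell of mesh nuclei ``n_tiles`` times on a
    square grid inside the scoring region (the study repeated its
    segmented image volume 95 times to reach 9975 phantoms).
    """
    if not unit_cell:
        raise ValueError("empty unit cell")
    if pitch_mm is None:
        # unit-cell xy extent (um) from mesh bounds + offsets
        xs, ys = [], []
        for m in unit_cell:
            v = m.mesh.vertices
            xs += [v[:, 0].min() + m.center_x_mm * 1e3,
                   v[:, 0].max() + m.center_x_mm * 1e3]
            ys += [v[:, 1].min() + m.center_y_mm * 1e3,
                   v[:, 1].max() + m.center_y_mm * 1e3]
        pitch_mm = max(max(xs) - min(xs), max(ys) - min(ys)) * 1e-3
    ncols = max(1, int(region_side_mm // pitch_mm))
    nrows = math.ceil(n_tiles / ncols)
    if nrows * pitch_mm > region_side_mm + 1e-9:
        raise PackingError(
            f"{n_tiles} tiles of pitch {pitch_mm:.3f} mm do not fit in "
            f"{region_side_mm} mm region")
    out = []
    x0 = -ncols * pitch_mm / 2 + pitch_mm / 2
    y0 = -nrows * pitch_mm / 2 + pitch_mm / 2
    for t in range(n_tiles):
        r, c = divmod(t, ncols)
        ox, oy = x0 + c * pitch_mm, y0 + r * pitch_mm
        for m in unit_cell:
            out.append(MeshNucleus(
                mesh=m.mesh,  # shared geometry; offset carries the tile
                center_x_mm=m.center_x_mm + ox,
                center_y_mm=m.center_y_mm + oy,
                validated=m.validated,
            ))
    return PhantomSet(kind="mesh", region_side_mm=region_side_mm, meshes=out)


# ---------------------------------------------------------------------------
# chords

def chord_length(origin_um, direction, nucleus, depth_um: float = 2.5) -> float:
    """In-volume path length (um) of a straight ray through one nucleus.

    ``origin_um`` is the point where the ray crosses the water surface,
    in um, in the nucleus-local frame where (0, 0) is the nucleus centre
    and z increases downward from the water surface.  ``direction`` is
    the unit direction with positive z (downward).
    """
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    if isinstance(nucleus, EllipticalCylinderNucleus):
        s = _ellcyl_chords(
            np.asarray([origin_um[0]]), np.asarray([origin_um[1]]),
            np.asarray([d[0]]), np.asarray([d[1]]), np.asarray([d[2]]),
            nucleus.major_um / 2, nucleus.minor_um / 2, nucleus.azimuth_rad,
            depth_um, depth_um + nucleus.height_um)
        return float(s[0][0])
    if isinstance(nucleus, MeshNucleus):
        if not nucleus.validated:
            raise MeshValidationError("refusing chords through unvalidated mesh")
        chord, _ = mesh_ray_chords(
            nucleus.mesh,
            np.asarray([[origin_um[0], origin_um[1], 0.0]]),
            np.asarray([d]))
        return float(chord[0])
    raise TypeError(f"unsupported nucleus type {type(nucleus)!r}")


def _ellcyl_chords(x0, y0, ux, uy, uz, a, b, az, z_top, z_bot):
    """Vectorised ray / elliptical-cylinder intersection.

    Rays start at z=0 going downward (uz > 0 in this frame); the
    cylinder axis is vertical through the origin with the ellipse
    rotated by ``az``.  Returns (chord_lengths, entry_path_lengths);
    both are 0 where the ray misses.
    """
    ca, sa = math.cos(az), math.sin(az)
    # rotate into ellipse frame
    rx0 = x0 * ca + y0 * sa
    ry0 = -x0 * sa + y0 * ca
    rux = ux * ca + uy * sa
    ruy = -ux * sa + uy * ca
    # (rx0 + s rux)^2/a^2 + (ry0 + s ruy)^2/b^2 = 1
    A = (rux / a) ** 2 + (ruy / b) ** 2
    B = 2 * (rx0 * rux / a**2 + ry0 * ruy / b**2)
    C = (rx0 / a) ** 2 + (ry0 / b) ** 2 - 1.0
    axial = A < 1e-16          # ray (near-)parallel to the cylinder axis
    disc = B * B - 4 * A * C
    hit = (disc > 0) & ~axial | (axial & (C < 0))
    sq = np.sqrt(np.where(disc > 0, disc, 0.0))
    big = 1e12
    with np.errstate(divide="ignore", invalid="ignore"):
        s1 = np.where(axial, -big, (-B - sq) / np.where(axial, 1.0, 2 * A))
        s2 = np.where(axial, big, (-B + sq) / np.where(axial, 1.0, 2 * A))
        s1, s2 = np.where(hit, s1, 0.0), np.where(hit, s2, 0.0)
        # slab interval in path length
        t1 = z_top / uz
        t2 = z_bot / uz
    lo = np.maximum(np.maximum(s1, t1), 0.0)
    hi = np.minimum(s2, t2)
    chord = np.where(hit, np.clip(hi - lo, 0.0, None), 0.0)
    return chord, lo


def mesh_ray_chords(mesh: trimesh.Trimesh, origins_um: np.ndarray,
                    directions: np.ndarray):
    """Total in-volume chord per ray through a closed mesh, by
    Moller-Trumbore ray/triangle intersection with entry/exit pairing.

    Returns (chords, entry_path_lengths); rays that miss get 0.
    """
    v = mesh.vertices.view(np.ndarray)
    f = mesh.faces.view(np.ndarray)
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    e1, e2 = p1 - p0, p2 - p0
    n_rays = len(origins_um)
    chords = np.zeros(n_rays)
    entries = np.zeros(n_rays)
    for i in range(n_rays):
        o, d = origins_um[i], directions[i]
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o - p0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        vv = np.einsum("j,ij->i", d, qvec) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        hit = ok & (u >= 0) & (vv >= 0) & (u + vv <= 1) & (t > 1e-9)
        ts = np.sort(t[hit])
        if len(ts) >= 2:
            # entry/exit pairing; drop an unpaired grazing hit if odd
            ts = ts[: len(ts) - (len(ts) % 2)]
            chords[i] = float(np.sum(ts[1::2] - ts[0::2]))
            entries[i] = float(ts[0])
    return chords, entries
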