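"""Per-nucleus scoring of alpha-particle hits, energy imparted and
specific energy.

A *hit* is an alpha track entering the nucleus volume (positive chord,
positive residual energy at entry) — no energy threshold is applied.
Nuclei are transparent to tracks: each track is scored independently
against every nucleus it crosses (packing is <1%, so shadowing is
negligible).  Energy imparted per hit is

    eps_s = E_entry - degrade(E_entry, chord, water)

with E_entry the arrival energy degraded through the water overburden
above the nucleus; a particle stopping inside deposits everything.
Specific energy converts MeV in a um^3 water volume to Gy:
z = eps * 1.602e-13 J/MeV / (V * 1e-15 kg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .phantoms import PhantomSet, _ellcyl_chords, mesh_ray_chords
from .stopping_power import get_table

__all__ = [
    "MEV_TO_GY_PER_UM3",
    "ScoreResult",
    "DistributionSummary",
    "score_irradiation",
    "specific_energy",
    "build_distributions",
    "summarize",
]

#: z[Gy] = eps[MeV] / V[um^3] * this constant
MEV_TO_GY_PER_UM3 = 1.602176634e-13 / 1e-15


def specific_energy(eps_mev, volume_um3):
    """Specific energy z (Gy) from energy imparted (MeV) and nucleus
    volume (um^3), assuming unit-density water."""
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    out = np.asarray(eps_mev, dtype=float) / v * MEV_TO_GY_PER_UM3
    return float(out) if np.isscalar(eps_mev) and np.isscalar(volume_um3) else out


@dataclass
class ScoreResult:
    """Scores for one irradiation of one phantom set.

    ``per_nucleus`` has one row per nucleus (nucleus_id, n_hits,
    energy_MeV, z_Gy, volume_um3); ``per_hit`` one row per hit
    (nucleus_id, entry_energy_MeV, eps_s_MeV, chord_um).
    """

    per_nucleus: pd.DataFrame
    per_hit: pd.DataFrame
    n_arrivals: int
    n_outside_region: int = 0

    @property
    def hits(self) -> np.ndarray:
        return self.per_nucleus["n_hits"].to_numpy()

    @property
    def mean_hits(self) -> float:
        return float(self.per_nucleus["n_hits"].mean())


def score_irradiation(arrivals: pd.DataFrame, phantoms: PhantomSet) -> ScoreResult:
    """Score arrival tracks against every nucleus in a placed phantom set.

    Arrivals are taken at the water surface; tracks continue in a
    straight line through the 2.5-um overburden and the phantom slab.
    Arrivals outside the scoring square are ignored (counted in
    ``n_outside_region``).
    """
    water = get_table("water")
    half = phantoms.region_side_mm / 2.0
    ax = arrivals["x_mm"].to_numpy()
    ay = arrivals["y_mm"].to_numpy()
    inside = (np.abs(ax) <= half) & (np.abs(ay) <= half)
    n_outside = int((~inside).sum())
    arr = arrivals.loc[inside]
    ax, ay = ax[inside], ay[inside]
    dx = arr["ux"].to_numpy()
    dy = arr["uy"].to_numpy()
    dz = -arr["uz"].to_numpy()          # downward-positive frame
    e_arr = arr["energy_MeV"].to_numpy()
    depth = phantoms.depth_um

    n = len(phantoms)
    nuc_rows = []
    hit_rows = []
    if n and len(arr):
        tree = cKDTree(np.column_stack([ax, ay]))
        tan_max = float(np.max(np.hypot(dx, dy) / dz)) if len(arr) else 0.0
        items = phantoms.ellipses if phantoms.kind == "ellipse" else phantoms.meshes
        for nid, p in enumerate(items):
            if phantoms.kind == "ellipse":
                reach_um = p.major_um / 2 + tan_max * (depth + p.height_um)
            else:
                v = p.mesh.vertices.view(np.ndarray)
                reach_um = p.footprint_radius_um + tan_max * float(v[:, 2].max())
            cand = tree.query_ball_point(
                [p.center_x_mm, p.center_y_mm], reach_um * 1e-3 + 1e-6)
            if not cand:
                nuc_rows.append((nid, 0, 0.0, 0.0, p.volume_um3))
                continue
            cand = np.asarray(cand)
            x0 = (ax[cand] - p.center_x_mm) * 1e3
            y0 = (ay[cand] - p.center_y_mm) * 1e3
            if phantoms.kind == "ellipse":
                chord, s_entry = _ellcyl_chords(
                    x0, y0, dx[cand], dy[cand], dz[cand],
                    p.major_um / 2, p.minor_um / 2, p.azimuth_rad,
                    depth, depth + p.height_um)
            else:
                origins = np.column_stack([x0, y0, np.zeros(len(cand))])
                dirs = np.column_stack([dx[cand], dy[cand], dz[cand]])
                chord, s_entry = mesh_ray_chords(p.mesh, origins, dirs)
            hit = chord > 0
            if not np.any(hit):
                nuc_rows.append((nid, 0, 0.0, 0.0, p.volume_um3))
                continue
            idx = cand[hit]
            e_entry = water.degrade(e_arr[idx], s_entry[hit])
            live = e_entry > 0
            idx, ch = idx[live], chord[hit][live]
            e_entry = np.atleast_1d(e_entry)[live]
            eps = e_entry - water.degrade(e_entry, ch)
            nuc_rows.append((nid, int(live.sum()), float(eps.sum()),
                             specific_energy(float(eps.sum()), p.volume_um3),
                             p.volume_um3))
            for k in range(len(idx)):
                hit_rows.append((nid, e_entry[k], eps[k], ch[k]))
    else:
        items = phantoms.ellipses if phantoms.kind == "ellipse" else phantoms.meshes
        nuc_rows = [(nid, 0, 0.0, 0.0, p.volume_um3)
                    for nid, p in enumerate(items)]

    per_nucleus = pd.DataFrame(
        nuc_rows, columns=["nucleus_id", "n_hits", "energy_MeV", "z_Gy",
                           "volume_um3"])
    per_hit = pd.DataFrame(
        hit_rows, columns=["nucleus_id", "entry_energy_MeV", "eps_s_MeV",
                           "chord_um"])
    return ScoreResult(per_nucleus, per_hit, len(arr), n_outside)


# ---------------------------------------------------------------------------
# distributions and summaries

def build_distributions(result: ScoreResult, n_bins: int = 60) -> dict[str, pd.DataFrame]:
    """Normalized distributions of the scored quantities.

    Returns PMF/PDF tables: ``f_hits`` (PMF, sums to 1), ``f_eps`` and
    ``f_z`` (densities, sum x binwidth = 1), plus the pooled single-hit
    energy-imparted spectrum ``f_eps_s`` and entry-energy spectrum.
    """
    if len(result.per_nucleus) == 0:
        raise ValueError("no scores to histogram")
    out = {}
    hits = result.hits
    kmax = int(hits.max()) if len(hits) else 0
    pmf = np.bincount(hits, minlength=kmax + 1) / len(hits)
    out["f_hits"] = pd.DataFrame({"k": np.arange(kmax + 1), "probability": pmf})
    for key, vals in (
        ("f_eps", result.per_nucleus["energy_MeV"].to_numpy()),
        ("f_z", result.per_nucleus["z_Gy"].to_numpy()),
        ("f_eps_s", result.per_hit["eps_s_MeV"].to_numpy()),
        ("f_entry_energy", result.per_hit["entry_energy_MeV"].to_numpy()),
    ):
        if len(vals) == 0:
            out[key] = pd.DataFrame(columns=["bin_center", "density"])
            continue
        dens, edges = np.histogram(vals, bins=n_bins, density=True)
        out[key] = pd.DataFrame({
            "bin_center": 0.5 * (edges[1:] + edges[:-1]), "density": dens})
    return out


@dataclass
class DistributionSummary:
    """Mean / median / mode / variance / SD / CV summary row."""

    mean: float
    median: float
    mode: float
    variance: float
    sd: float
    cv: float

    def to_dict(self) -> dict:
        return {"Mean": self.mean, "Median": self.median, "Mode": self.mode,
                "Variance": self.variance, "SD": self.sd, "CV": self.cv}


def summarize(values, count_data: bool | None = None,
              population: bool = True) -> DistributionSummary:
    """Summary statistics in the comparison-table format.

    For count data the mode is the smallest most-frequent integer; for
    continuous data it is the densest histogram bin centre.  Variance is
    population variance by default.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if count_data is None:
        count_data = np.allclose(v, np.round(v))
    if count_data:
        counts = np.bincount(v.astype(int))
        mode = float(np.argmax(counts))  # argmax -> smallest most-frequent
    else:
        dens, edges = np.histogram(v, bins="auto", density=True)
        mode = float(0.5 * (edges[np.argmax(dens)] + edges[np.argmax(dens) + 1]))
    mean = float(v.mean())
    var = float(v.var(ddof=0 if population else 1))
    sd = math.sqrt(var)
    return DistributionSummary(
        mean=mean, median=float(np.median(v)), mode=mode,
        variance=var, sd=sd, cv=sd / mean if mean > 0 else math.nan)
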