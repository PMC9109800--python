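"""Cardiac-frame fiber angles, disarray index and layer quantification.

Conventions (fixed package-wide, stated in every TSV header written here):

* Local frame: circumferential ``c``, longitudinal ``l`` (toward the base),
  transmural ``t``; right-handed orthonormal triad per voxel.
* Transmural coordinate ``rho``: 0 on the LV endocardium, 1 on the opposite
  (RV endocardial) surface.
* Helix angle HA: signed angle between the projection of the primary
  eigenvector onto the wall-tangent (c-l) plane and ``c``, positive toward
  ``+l`` (right-handed helix toward the base). Transverse angle TA:
  projection onto the c-t plane. Sheetlet elevation SE: elevation of the
  tertiary eigenvector out of the tangent plane; sheetlet azimuth SA: its
  azimuth in the c-t plane. All four are insensitive to eigenvector sign
  and folded into [-90, 90] degrees.
* MDI: mean absolute dot product of the primary eigenvector with its
  in-mask neighbors in an odd cubic window (center excluded); 1 = perfectly
  uniform, lower = disarray. This absolute-dot-product mean is this
  package's operational definition of the disarray index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LocalFrame",
    "TransmuralProfile",
    "LayerReportRow",
    "build_local_frames",
    "frames_from_sidecar",
    "compute_angle_maps",
    "compute_mdi",
    "transmural_profile",
    "detect_layer_discontinuity",
    "summarize_specimens",
    "layer_report_table",
    "write_layer_report_tsv",
    "write_profile_tsv",
]

_TSV_HEADER = (
    "# septumkit fiber-architecture report\n"
    "# rho origin: LV endocardium (rho=0) -> RV endocardium (rho=1)\n"
    "# helix angle sign: positive toward the base (+l), right-handed helix\n"
)


@dataclass
class LocalFrame:
    """Per-voxel orthonormal cardiac triad and transmural coordinate."""

    c_hat: np.ndarray  # (..., 3) circumferential
    l_hat: np.ndarray  # (..., 3) longitudinal
    t_hat: np.ndarray  # (..., 3) transmural
    rho: np.ndarray  # (...,) in [0, 1]
    mask: np.ndarray  # (...,) bool

    def orthonormality_defect(self) -> float:
        """Max deviation from unit-norm/orthogonality over in-mask voxels."""
        m = self.mask
        defects = []
        for a in (self.c_hat, self.l_hat, self.t_hat):
            defects.append(np.abs(np.linalg.norm(a[m], axis=-1) - 1.0))
        for a, b in ((self.c_hat, self.l_hat), (self.c_hat, self.t_hat), (self.l_hat, self.t_hat)):
            defects.append(np.abs(np.einsum("...i,...i", a[m], b[m])))
        return float(max(d.max(initial=0.0) for d in defects))


def frames_from_sidecar(volume) -> LocalFrame:
    """Local frames of a slab phantom, read from its ground-truth sidecar."""
    gt = volume.ground_truth
    if gt is None:
        raise ValueError("volume has no ground-truth sidecar")
    shape = volume.shape
    fr = gt["frame"]
    def full(vec):
        return np.broadcast_to(np.asarray(vec, dtype=float), shape + (3,)).copy()

    return LocalFrame(
        c_hat=full(fr["circumferential"]),
        l_hat=full(fr["longitudinal"]),
        t_hat=full(fr["transmural"]),
        rho=np.asarray(gt["rho"], dtype=float).copy(),
        mask=volume.mask.copy(),
    )


def build_local_frames(
    mask: np.ndarray,
    voxel_size,
    long_axis=(0.0, 0.0, 1.0),
    chamber_center=None,
) -> LocalFrame:
    """Cylindrical cardiac frames for an annular mask around a chamber axis.

    The transmural axis is the outward radial direction from the chamber
    axis, the longitudinal axis is the (unit) ``long_axis``, and the
    circumferential direction completes the right-handed triad
    ``c = l x t``. ``rho`` is the radial position normalized between the
    innermost and outermost in-mask radius. Voxels on the axis, where the
    radial direction is undefined, are excluded from the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    voxel_size = np.asarray(voxel_size, dtype=float)
    l = np.asarray(long_axis, dtype=float)
    l = l / np.linalg.norm(l)

    idx = np.indices(mask.shape).astype(float)
    coords = np.moveaxis(idx, 0, -1) * voxel_size  # (..., 3) mm
    if chamber_center is None:
        chamber_center = coords[mask].mean(axis=0)
    rel = coords - np.asarray(chamber_center, dtype=float)
    radial = rel - np.einsum("...i,i->...", rel, l)[..., None] * l
    r = np.linalg.norm(radial, axis=-1)

    ok = mask & (r > 1e-8)
    t_hat = np.zeros(mask.shape + (3,))
    t_hat[ok] = radial[ok] / r[ok, None]
    l_hat = np.broadcast_to(l, mask.shape + (3,)).copy()
    c_hat = np.cross(l_hat, t_hat)

    rho = np.zeros(mask.shape)
    if ok.any():
        r_in, r_out = r[ok].min(), r[ok].max()
        span = max(r_out - r_in, 1e-12)
        rho[ok] = (r[ok] - r_in) / span
    return LocalFrame(c_hat=c_hat, l_hat=l_hat, t_hat=t_hat, rho=rho, mask=ok)


def _fold_angle(a_comp: np.ndarray, b_comp: np.ndarray) -> np.ndarray:
    """Signed angle atan2(b, a) after folding the axial vector so a >= 0.

    The fold makes the result independent of the eigenvector's sign and maps
    it into [-90, 90]; the a == 0 boundary resolves to +90 by convention.
    """
    flip = (a_comp < 0) | ((a_comp == 0) & (b_comp < 0))
    sgn = np.where(flip, -1.0, 1.0)
    return np.degrees(np.arctan2(sgn * b_comp, sgn * a_comp))


def compute_angle_maps(
    v1: np.ndarray,
    v2: np.ndarray | None,
    v3: np.ndarray | None,
    frames: LocalFrame,
    proj_tol: float = 1e-8,
) -> dict:
    """HA/TA (from v1) and SE/SA (from v3) maps in degrees.

    Voxels whose primary eigenvector is parallel to the transmural axis
    (tangent-plane projection below ``proj_tol``) have no defined helix
    angle; they are flagged in the returned ``valid`` mask and set to NaN.
    """
    def comps(v):
        return (
            np.einsum("...i,...i", v, frames.c_hat),
            np.einsum("...i,...i", v, frames.l_hat),
            np.einsum("...i,...i", v, frames.t_hat),
        )

    c1, l1, t1 = comps(np.asarray(v1, dtype=float))
    ha = _fold_angle(c1, l1)
    ta = _fold_angle(c1, t1)
    degenerate = np.hypot(c1, l1) < proj_tol
    valid = frames.mask & ~degenerate
    ha = np.where(valid, ha, np.nan)
    ta = np.where(frames.mask, ta, np.nan)

    out = {"HA": ha, "TA": ta, "valid": valid}
    if v3 is not None:
        c3, l3, t3 = comps(np.asarray(v3, dtype=float))
        # elevation out of the tangent plane, signed after folding the axial
        # vector so its circumferential component is non-negative
        flip = (c3 < 0) | ((c3 == 0) & (l3 < 0))
        se = np.degrees(
            np.arctan2(np.where(flip, -t3, t3), np.hypot(c3, l3))
        )
        sa = _fold_angle(c3, t3)
        out["SE"] = np.where(frames.mask, se, np.nan)
        out["SA"] = np.where(frames.mask, sa, np.nan)
    return out


def compute_mdi(v1: np.ndarray, mask: np.ndarray, window: int = 3) -> np.ndarray:
    """Myoarchitectural disarray index over an odd cubic neighborhood.

    MDI(voxel) = mean over in-mask neighbors j (center excluded) of
    ``|v1(voxel) . v1(j)|``; NaN where a voxel has no in-mask neighbor.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    v1 = np.asarray(v1, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    r = window // 2
    acc = np.zeros(mask.shape)
    cnt = np.zeros(mask.shape)

    def shifted(arr, off, fill=0.0):
        out = np.full_like(arr, fill)
        src = [slice(max(-o, 0), arr.shape[d] - max(o, 0)) for d, o in enumerate(off)]
        dst = [slice(max(o, 0), arr.shape[d] - max(-o, 0)) for d, o in enumerate(off)]
        out[tuple(dst)] = arr[tuple(src)]
        return out

    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                if dx == dy == dz == 0:
                    continue
                off = (dx, dy, dz)
                nb_mask = shifted(mask.astype(float), off) > 0.5
                nb_v = np.stack(
                    [shifted(v1[..., k], off) for k in range(3)], axis=-1
                )
                dot = np.abs(np.einsum("...i,...i", v1, nb_v))
                acc += np.where(nb_mask, dot, 0.0)
                cnt += nb_mask
    with np.errstate(invalid="ignore", divide="ignore"):
        mdi = acc / cnt
    mdi[~mask | (cnt == 0)] = np.nan
    return mdi


def quadrant_masks(
    frames: LocalFrame,
    coords_mm: np.ndarray,
    chamber_center,
    long_axis=(0.0, 0.0, 1.0),
    septum_azimuth_deg: float = 0.0,
) -> dict:
    """Regional masks on an annular geometry: 4 sectors x 4 levels.

    Sectors (septal / anterior / lateral / posterior) split the azimuth
    around the long axis into 90-degree quadrants centered on the septal
    direction; levels (apical / mid-low / mid-high / basal) split the
    longitudinal coordinate into quartiles of the in-mask extent. Returns
    ``{"sector_level": bool mask, ...}`` for use as the region mask of
    :func:`transmural_profile`.
    """
    l = np.asarray(long_axis, dtype=float)
    l = l / np.linalg.norm(l)
    rel = np.asarray(coords_mm, dtype=float) - np.asarray(chamber_center, dtype=float)
    axial = np.einsum("...i,i->...", rel, l)
    radial = rel - axial[..., None] * l
    # azimuth in a fixed transverse basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ l) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ l) * l
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(l, e1)
    az = np.degrees(
        np.arctan2(np.einsum("...i,i->...", radial, e2),
                   np.einsum("...i,i->...", radial, e1))
    ) - septum_azimuth_deg

    sectors = {
        "septal": (-45.0, 45.0),
        "anterior": (45.0, 135.0),
        "lateral": (135.0, 225.0),
        "posterior": (225.0, 315.0),
    }
    m = frames.mask
    lo, hi = axial[m].min(), axial[m].max()
    q = np.clip((axial - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    levels = {
        "apical": (0.0, 0.25),
        "mid_low": (0.25, 0.5),
        "mid_high": (0.5, 0.75),
        "basal": (0.75, 1.0001),
    }
    out = {}
    azm = (az + 45.0) % 360.0 - 45.0  # fold into [-45, 315)
    for s_name, (a0, a1) in sectors.items():
        s_mask = (azm >= a0) & (azm < a1)
        for l_name, (q0, q1) in levels.items():
            out[f"{s_name}_{l_name}"] = m & s_mask & (q >= q0) & (q < q1)
    return out


@dataclass
class TransmuralProfile:
    """Binned transmural statistics of an angle map."""

    bin_edges: np.ndarray  # (n_bins + 1,)
    median: np.ndarray  # (n_bins,) NaN where the bin is empty
    q25: np.ndarray
    q75: np.ndarray
    count: np.ndarray
    hist2d: np.ndarray | None = field(default=None, repr=False)  # (n_bins, n_angle_bins)
    angle_edges: np.ndarray | None = field(default=None, repr=False)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return self.median.size


def _axial_quantiles(values: np.ndarray, qs=(50.0, 25.0, 75.0)) -> tuple:
    """Quantiles of axial (180-degree-periodic) angle data.

    Fiber angles are orientations, not directions: -88 and +88 degrees are 4
    degrees apart, not 176. Values are unwrapped into a half-turn window
    centered on the axial mean direction (via the doubled-angle resultant)
    before ordinary quantiles are taken, which removes the wrap bias that a
    naive median suffers near +/-90 degrees.
    """
    v = np.asarray(values, dtype=float)
    two = np.deg2rad(2.0 * v)
    mean_axis = 0.5 * np.degrees(np.arctan2(np.sin(two).mean(), np.cos(two).mean()))
    dev = (v - mean_axis + 90.0) % 180.0 - 90.0
    out = []
    for q in qs:
        ang = mean_axis + np.percentile(dev, q)
        out.append((ang + 90.0) % 180.0 - 90.0)  # fold back into [-90, 90)
    return tuple(out)


def transmural_profile(
    angle_map: np.ndarray,
    rho: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 50,
    angle_bins: int = 36,
) -> TransmuralProfile:
    """Median/IQR of an angle map binned by transmural depth.

    Bin statistics are axial (180-degree-periodic) quantiles, so profiles of
    steep fiber fields near +/-90 degrees are unbiased. Also returns the 2-D
    histogram of angle vs rho. Empty bins are recorded as missing (NaN),
    never interpolated.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    sel = np.asarray(mask, dtype=bool) & np.isfinite(angle_map)
    vals = np.asarray(angle_map, dtype=float)[sel]
    r = np.asarray(rho, dtype=float)[sel]

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    median = np.full(n_bins, np.nan)
    q25 = np.full(n_bins, np.nan)
    q75 = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        v = vals[which == b]
        count[b] = v.size
        if v.size:
            median[b], q25[b], q75[b] = _axial_quantiles(v)
    angle_edges = np.linspace(-90.0, 90.0, angle_bins + 1)
    hist2d, _, _ = np.histogram2d(r, vals, bins=[edges, angle_edges])
    return TransmuralProfile(
        bin_edges=edges,
        median=median,
        q25=q25,
        q75=q75,
        count=count,
        hist2d=hist2d,
        angle_edges=angle_edges,
    )


@dataclass
class LayerReportRow:
    """One specimen row of the dual-layer quantification."""

    specimen: str
    has_discontinuity: bool
    rho_star: float | None
    lv_layer_percent: float | None
    rv_layer_percent: float | None
    orientation_lv_endo: float
    orientation_rv_endo: float
    jump_deg: float


def detect_layer_discontinuity(
    profile: TransmuralProfile,
    jump_threshold_deg: float = 30.0,
    specimen: str = "phantom",
) -> LayerReportRow:
    """Single change-point detection on the binned median helix angle.

    The change point is the bin boundary maximizing the absolute jump in
    median HA between adjacent (non-empty) bins, accepted only if the jump
    reaches ``jump_threshold_deg``. The LV/RV layer split is reported as a
    percentage of the wall; endocardial orientations come from the first and
    last populated bins.
    """
    if profile.n_bins < 20:
        raise ValueError("profile must have >= 20 bins")
    med = profile.median
    filled = np.flatnonzero(np.isfinite(med))
    if filled.size < 2:
        raise ValueError("profile has fewer than 2 populated bins")

    jumps = np.diff(med[filled])
    jumps = (jumps + 90.0) % 180.0 - 90.0  # axial difference between bins
    k = int(np.argmax(np.abs(jumps)))
    jump = float(abs(jumps[k]))
    # boundary between the two populated bins straddling the jump
    rho_star = float(
        0.5 * (profile.bin_edges[filled[k] + 1] + profile.bin_edges[filled[k + 1]])
    )
    lv_endo = float(med[filled[0]])
    rv_endo = float(med[filled[-1]])

    if jump >= jump_threshold_deg:
        return LayerReportRow(
            specimen=specimen,
            has_discontinuity=True,
            rho_star=rho_star,
            lv_layer_percent=100.0 * rho_star,
            rv_layer_percent=100.0 * (1.0 - rho_star),
            orientation_lv_endo=lv_endo,
            orientation_rv_endo=rv_endo,
            jump_deg=jump,
        )
    return LayerReportRow(
        specimen=specimen,
        has_discontinuity=False,
        rho_star=None,
        lv_layer_percent=None,
        rv_layer_percent=None,
        orientation_lv_endo=lv_endo,
        orientation_rv_endo=rv_endo,
        jump_deg=jump,
    )


def summarize_specimens(rows: list[LayerReportRow]) -> dict:
    """Arithmetic mean over specimen rows, rounded as conventionally printed.

    Layer percentages are rounded to one decimal, the averaged endocardial
    orientations to the nearest degree. A single row is returned unchanged
    (up to the same rounding).
    """
    if not rows:
        raise ValueError("need at least one specimen row")
    with_layer = [r for r in rows if r.has_discontinuity]
    out = {
        "n_specimens": len(rows),
        "orientation_lv_endo": int(round(float(np.mean([r.orientation_lv_endo for r in rows])))),
        "orientation_rv_endo": int(round(float(np.mean([r.orientation_rv_endo for r in rows])))),
    }
    if with_layer:
        out["lv_layer_percent"] = round(
            float(np.mean([r.lv_layer_percent for r in with_layer])), 1
        )
        out["rv_layer_percent"] = round(
            float(np.mean([r.rv_layer_percent for r in with_layer])), 1
        )
    else:
        out["lv_layer_percent"] = out["rv_layer_percent"] = None
    return out


def layer_report_table(rows: list[LayerReportRow]) -> pd.DataFrame:
    """Specimen rows plus an 'Average' row, as a DataFrame."""
    recs = [
        {
            "specimen": r.specimen,
            "lv_layer_percent": r.lv_layer_percent,
            "rv_layer_percent": r.rv_layer_percent,
            "orientation_lv_endo": r.orientation_lv_endo,
            "orientation_rv_endo": r.orientation_rv_endo,
            "discontinuity": r.has_discontinuity,
        }
        for r in rows
    ]
    avg = summarize_specimens(rows)
    recs.append(
        {
            "specimen": "Average",
            "lv_layer_percent": avg["lv_layer_percent"],
            "rv_layer_percent": avg["rv_layer_percent"],
            "orientation_lv_endo": avg["orientation_lv_endo"],
            "orientation_rv_endo": avg["orientation_rv_endo"],
            "discontinuity": all(r.has_discontinuity for r in rows),
        }
    )
    return pd.DataFrame.from_records(recs)


def write_layer_report_tsv(rows: list[LayerReportRow], path) -> None:
    df = layer_report_table(rows)
    with open(Path(path), "w") as fh:
        fh.write(_TSV_HEADER)
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def write_profile_tsv(profile: TransmuralProfile, path, angle_name: str = "HA") -> None:
    df = pd.DataFrame(
        {
            "rho_center": profile.bin_centers,
            f"{angle_name}_median_deg": profile.median,
            f"{angle_name}_q25_deg": profile.q25,
            f"{angle_name}_q75_deg": profile.q75,
            "count": profile.count,
        }
    )
    with open(Path(path), "w") as fh:
        fh.write(_TSV_HEADER)
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")
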