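"""Per-degree radial fluorescence profiling and Ld-domain calling.

For each vesicle, 360 radial profiles (one per degree) are drawn from the
center outward; on every ray the membrane/actin peak is located and its
mean intensity above background recorded.  Per-channel profiles are then
normalized to [0, 1] (1 = the channel's per-vesicle maximum, 0 = the
background).  Liquid-disordered (Ld) domains are defined as contiguous
angular runs where the normalized lipid signal exceeds 0.2; the mean
normalized actin fluorescence over those runs quantifies how much actin
decorates the Ld domains.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphometry import GuvContour, _ray_samples
from .synth import ImageLapse

__all__ = [
    "RadialProfileSet",
    "DomainSet",
    "estimate_center",
    "estimate_background",
    "radial_profiles",
    "normalize_profiles",
    "segment_ld_domains",
    "actin_on_ld",
    "min_width_from_radius",
    "profile_guv",
]


@dataclass
class RadialProfileSet:
    """360 per-degree peak intensities for the lipid and actin channels."""

    center_px: tuple[float, float]
    angles_deg: np.ndarray
    lipid_peak_mean: np.ndarray       # background-subtracted, >= 0
    actin_peak_mean: np.ndarray
    background: np.ndarray            # per-channel scalar background
    lipid_norm: np.ndarray | None = None
    actin_norm: np.ndarray | None = None
    truncated_rays: np.ndarray | None = None
    flags: list[str] = dataclasses.field(default_factory=list)

    def to_dataframe(self):
        """360-row table of raw and normalized per-degree values."""
        import pandas as pd

        cols = {"angle_deg": self.angles_deg,
                "lipid_peak_mean": self.lipid_peak_mean,
                "actin_peak_mean": self.actin_peak_mean}
        if self.lipid_norm is not None:
            cols["lipid_norm"] = self.lipid_norm
        if self.actin_norm is not None:
            cols["actin_norm"] = self.actin_norm
        return pd.DataFrame(cols)


@dataclass
class DomainSet:
    """Ld domains as half-open angular intervals [a, b) modulo 360."""

    intervals_deg: list[tuple[float, float]]
    threshold: float
    min_width_deg: float

    @property
    def n_d(self) -> int:
        return len(self.intervals_deg)

    def to_dict(self) -> dict:
        return {"intervals_deg": [[float(a), float(b)] for a, b in self.intervals_deg],
                "n_d": self.n_d, "threshold": self.threshold,
                "min_width_deg": self.min_width_deg}

    def member_mask(self, angles_deg: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(angles_deg), dtype=bool)
        for a, b in self.intervals_deg:
            t = (angles_deg - a) % 360.0
            mask |= t < (b - a)
        return mask


def estimate_center(contour: GuvContour) -> tuple[float, float]:
    """Area centroid of the enclosed contour polygon, in pixels."""
    return contour.centroid_px()


def estimate_background(
    frame: np.ndarray,
    contour: GuvContour,
    center: tuple[float, float] | None = None,
    factor: float = 1.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel background median and robust sigma outside the vesicle.

    Uses all pixels farther than ``factor`` times the maximum contour radius
    from the center; robust sigma is 1.4826 * MAD.  Raises when the frame is
    too tight around the vesicle to contain any such pixel.
    """
    if center is None:
        center = contour.centroid_px()
    h, w = frame.shape[1:]
    y, x = np.mgrid[0:h, 0:w]
    r = np.hypot(x - center[0], y - center[1])
    far = r > factor * contour.max_radius_px()
    if not far.any():
        raise ValueError("frame too tight: no pixels beyond the background radius")
    med = np.array([float(np.median(frame[c][far])) for c in range(frame.shape[0])])
    mad = np.array(
        [float(np.median(np.abs(frame[c][far] - med[c]))) for c in range(frame.shape[0])]
    )
    return med, 1.4826 * mad


def _peak_mean(radii: np.ndarray, vals: np.ndarray, bg: float) -> float:
    """Mean background-subtracted intensity over the half-max run of the peak."""
    v = vals - bg
    m = float(np.max(v))
    if m <= 1e-9 * (1.0 + abs(bg)):   # flat channel up to interpolation round-off
        return 0.0
    i0 = int(np.argmax(v))
    half = m / 2.0
    lo = i0
    while lo > 0 and v[lo - 1] >= half:
        lo -= 1
    hi = i0
    while hi < len(v) - 1 and v[hi + 1] >= half:
        hi += 1
    return max(float(np.mean(v[lo:hi + 1])), 0.0)


def radial_profiles(
    frame: np.ndarray,
    center: tuple[float, float],
    n_angles: int = 360,
    r_max_px: float | None = None,
    guv_radius_px: float | None = None,
    background: np.ndarray | None = None,
    step_px: float = 0.5,
    lipid_channel: int = ImageLapse.CH_LIPID,
    actin_channel: int = ImageLapse.CH_ACTIN,
) -> RadialProfileSet:
    """Un-normalized per-degree peak intensities around ``center``.

    Rays extend to 1.5x the vesicle radius (or ``r_max_px``); rays that
    leave the frame earlier are truncated and flagged.  On each ray the
    reported value is the mean background-subtracted intensity over the
    contiguous half-maximum run around the ray's global peak.
    """
    h, w = frame.shape[1:]
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("center outside frame")
    if r_max_px is None:
        if guv_radius_px is None:
            raise ValueError("provide r_max_px or guv_radius_px")
        r_max_px = 1.5 * guv_radius_px
    if background is None:
        background = np.zeros(frame.shape[0])
    r_frame = min(cx, cy, w - 1 - cx, h - 1 - cy)
    r_used = min(r_max_px, r_frame)
    truncated = np.full(n_angles, r_used < r_max_px)

    angles = np.arange(n_angles) * (360.0 / n_angles)
    radii, lipid = _ray_samples(frame[lipid_channel], center, angles, r_used, step_px)
    _, actin = _ray_samples(frame[actin_channel], center, angles, r_used, step_px)
    lipid_peak = np.array([_peak_mean(radii, lipid[i], background[lipid_channel])
                           for i in range(n_angles)])
    actin_peak = np.array([_peak_mean(radii, actin[i], background[actin_channel])
                           for i in range(n_angles)])
    return RadialProfileSet(
        center_px=(cx, cy),
        angles_deg=angles,
        lipid_peak_mean=lipid_peak,
        actin_peak_mean=actin_peak,
        background=np.asarray(background, dtype=float),
        truncated_rays=truncated,
        flags=["truncated_rays"] if truncated.any() else [],
    )


def normalize_profiles(profiles: RadialProfileSet) -> RadialProfileSet:
    """Scale each channel by its own per-vesicle maximum (0 = background).

    An all-zero channel stays all-zero and is flagged.
    """
    if np.any(profiles.lipid_peak_mean < 0) or np.any(profiles.actin_peak_mean < 0):
        raise ValueError("profiles must be background-subtracted and non-negative")
    out = dataclasses.replace(profiles)
    out.flags = list(profiles.flags)
    for name in ("lipid", "actin"):
        raw = getattr(profiles, f"{name}_peak_mean")
        m = float(np.max(raw))
        if m <= 0:
            setattr(out, f"{name}_norm", np.zeros_like(raw))
            out.flags.append(f"{name}_all_zero")
        else:
            setattr(out, f"{name}_norm", raw / m)
    return out


def min_width_from_radius(guv_radius_um: float, min_arc_um: float = 1.0) -> float:
    """Angle (deg) subtended by the smallest optically resolvable arc (~1 um)."""
    if guv_radius_um <= 0:
        raise ValueError("radius must be positive")
    return float(np.degrees(min_arc_um / guv_radius_um))


def segment_ld_domains(
    profiles: RadialProfileSet,
    threshold: float = 0.2,
    min_width_deg: float = 0.0,
) -> DomainSet:
    """Ld domains: angular runs where normalized lipid exceeds ``threshold``.

    Runs touching across the 0/360 wrap are merged; runs narrower than
    ``min_width_deg`` are discarded (sub-resolution).  Strict inequality.
    """
    if profiles.lipid_norm is None:
        raise ValueError("normalize_profiles must be applied first")
    mask = profiles.lipid_norm > threshold
    n = len(mask)
    step = 360.0 / n
    if not mask.any():
        return DomainSet([], threshold, min_width_deg)
    if mask.all():
        return DomainSet([(0.0, 360.0)], threshold, min_width_deg)
    # rotate so index 0 is outside a run, then find contiguous runs
    start0 = int(np.argmin(mask))
    rolled = np.roll(mask, -start0)
    edges = np.diff(np.concatenate([[0], rolled.astype(int), [0]]))
    starts = np.where(edges == 1)[0]
    ends = np.where(edges == -1)[0]
    intervals = []
    for s, e in zip(starts, ends):
        width = (e - s) * step
        if width < min_width_deg:
            continue
        a = ((s + start0) % n) * step
        intervals.append((a, a + width))
    intervals.sort()
    return DomainSet(intervals, threshold, min_width_deg)


def actin_on_ld(profiles: RadialProfileSet, domains: DomainSet) -> float:
    """Mean normalized actin over Ld angles, scaled to the Ld maximum.

    1 means the actin signal is uniform at its own maximum over all Ld
    angles; 0 means no domains or no actin on them.
    """
    if profiles.actin_norm is None:
        raise ValueError("normalize_profiles must be applied first")
    if domains.n_d == 0:
        return 0.0
    vals = profiles.actin_norm[domains.member_mask(profiles.angles_deg)]
    if len(vals) == 0:
        return 0.0
    m = float(np.max(vals))
    if m <= 0:
        return 0.0
    return float(np.mean(vals) / m)


def profile_guv(
    frame: np.ndarray,
    contour: GuvContour,
    threshold: float = 0.2,
    min_width_deg: float | None = None,
) -> tuple[RadialProfileSet, DomainSet, float]:
    """Convenience pipeline: center, background, profiles, domains, actin score."""
    center = estimate_center(contour)
    bg, _ = estimate_background(frame, contour, center=center)
    from .morphometry import guv_diameter

    r_um = guv_diameter(contour) / 2.0
    r_px = r_um / contour.pixel_size_um
    ps = radial_profiles(frame, center, guv_radius_px=r_px, background=bg)
    ps = normalize_profiles(ps)
    if min_width_deg is None:
        min_width_deg = min_width_from_radius(r_um)
    domains = segment_ld_domains(ps, threshold=threshold, min_width_deg=min_width_deg)
    return ps, domains, actin_on_ld(ps, domains)
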