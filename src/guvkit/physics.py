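"""Saffman–Delbrück mobility and stochastic domain coalescence on a vesicle.

Liquid-disordered (Ld) lipid domains embedded in a liquid-ordered (Lo)
membrane diffuse laterally and coarsen by coalescence.  The lateral mobility
of a membrane inclusion of radius ``r`` follows the Saffman–Delbrück law

    D(r) = kBT / (4 pi eta_m) * ln(eta_m / (eta_f * r))

where ``eta_m`` is the membrane surface viscosity (Pa m s) and ``eta_f`` the
bulk fluid viscosity (Pa s).  The time for a domain to meet its nearest
neighbor a distance ``R`` away is estimated as ``tau = R^2 / (4 D)``.

When a branched actin network polymerizes on an Ld domain it also grows
laterally, forming a corona that overhangs the domain edge by
``v_gel * t``.  Once that overhang exceeds the actin mesh size ``xi``
(~100 nm) the corona sterically blocks coalescence: two domains may touch
but can no longer fuse.  :func:`simulate_domains` implements this picture as
Brownian dynamics of disk-shaped domains on the surface of a sphere, with
pairwise merging and optional corona blocking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PhysicalParams",
    "SimTrace",
    "saffman_delbruck_D",
    "contact_time",
    "corona_overhang",
    "is_coalescence_blocked",
    "simulate_domains",
    "equatorial_arcs",
]

SIM_MODES = ("bare", "spvca", "actin")


@dataclass
class PhysicalParams:
    """Physical constants of the membrane/actin system (SI units).

    Defaults correspond to an Lo membrane in water at room temperature with
    a branched Arp2/3 actin network growing at 0.15 um/min.
    """

    kBT: float = 4.1e-21              # J, thermal energy at ~298 K
    eta_m: float = 1.0e-8             # Pa m s, membrane surface viscosity (Lo phase)
    eta_f: float = 1.0e-3             # Pa s, water viscosity
    xi_mesh: float = 100e-9           # m, branched-actin mesh size
    v_gel: float = 2.5e-9             # m/s, lateral corona growth rate (0.15 um/min)
    R_spacing: float = 5e-6           # m, typical inter-domain distance
    f_spvca: float = 0.3              # dimensionless slow-down of D under spVCA coating

    def __post_init__(self) -> None:
        for name in ("kBT", "eta_m", "eta_f", "xi_mesh", "v_gel", "R_spacing", "f_spvca"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")


def saffman_delbruck_D(r: float, params: PhysicalParams | None = None) -> float:
    """Saffman–Delbrück lateral diffusion coefficient of a domain of radius ``r``.

    Parameters
    ----------
    r : float
        Domain radius in meters.  Must satisfy ``r < eta_m / eta_f`` (the
        Saffman–Delbrück length), otherwise the hydrodynamic model does not
        apply and a ``ValueError`` is raised.

    Returns
    -------
    float
        Diffusion coefficient in m^2 s^-1.
    """
    p = params or PhysicalParams()
    if r <= 0:
        raise ValueError("domain radius must be positive")
    l_sd = p.eta_m / p.eta_f
    if r > l_sd:
        raise ValueError(
            f"radius {r:.3g} m exceeds the Saffman–Delbrück length "
            f"eta_m/eta_f = {l_sd:.3g} m; model not valid"
        )
    return p.kBT / (4.0 * np.pi * p.eta_m) * np.log(l_sd / r)


def contact_time(R: float, D: float) -> float:
    """Diffusive time ``tau = R^2 / (4 D)`` to reach a neighbor a distance R away.

    ``R`` in meters, ``D`` in m^2/s; returns seconds.
    """
    if R <= 0 or D <= 0:
        raise ValueError("R and D must be positive")
    return R * R / (4.0 * D)


def corona_overhang(v_gel: float, t: float) -> float:
    """Lateral overhang ``v_gel * t`` of an actin corona past its domain edge."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if v_gel < 0:
        raise ValueError("growth rate must be non-negative")
    return v_gel * t


def is_coalescence_blocked(overhang: float, params: PhysicalParams | None = None) -> bool:
    """Whether a corona overhang sterically blocks domain fusion.

    Blocked iff ``overhang > xi_mesh`` (strict: an overhang of exactly one
    mesh size does not yet block).
    """
    if overhang < 0:
        raise ValueError("overhang must be non-negative")
    p = params or PhysicalParams()
    return overhang > p.xi_mesh


# ---------------------------------------------------------------------------
# Brownian diffusion–coalescence simulator on the sphere
# ---------------------------------------------------------------------------


@dataclass
class SimTrace:
    """Record of one diffusion–coalescence run.

    ``times_s`` are the requested sample times; ``counts_total`` the number
    of domains on the whole sphere at each sample, ``counts_equatorial`` the
    number of distinct arcs the domains cut on the equatorial great circle
    (what an equatorial focal plane would show).  ``states`` stores, per
    sample, ``(positions, radii_um, corona_radii_um)`` with positions as
    unit vectors.  ``events`` logs every merge.
    """

    mode: str
    n0: int
    R_guv_um: float
    seed: int
    times_s: np.ndarray
    counts_total: np.ndarray
    counts_equatorial: np.ndarray
    states: list = field(default_factory=list)
    events: list = field(default_factory=list)
    params: PhysicalParams = field(default_factory=PhysicalParams)

    def total_area_um2(self, i: int) -> float:
        _, radii, _ = self.states[i]
        return float(np.sum(np.pi * np.asarray(radii) ** 2))

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode,
            "n0": self.n0,
            "R_guv_um": self.R_guv_um,
            "seed": self.seed,
            "times_s": self.times_s.tolist(),
            "counts_total": self.counts_total.tolist(),
            "counts_equatorial": self.counts_equatorial.tolist(),
            "events": self.events,
            "params": asdict(self.params),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _random_nonoverlapping_positions(n, ang_radii, rng, max_tries=20000):
    """Uniform random unit vectors with pairwise angular separation > sum of radii."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        i = len(pts)
        ok = all(
            np.arccos(np.clip(np.dot(v, p), -1, 1)) > ang_radii[i] + ang_radii[j]
            for j, p in enumerate(pts)
        )
        if ok:
            pts.append(v)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping domains of these sizes on the sphere"
            )
    return np.array(pts)


def _tangent_basis(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent vectors at each unit vector p (n,3)."""
    ref = np.zeros_like(p)
    ref[:, 2] = 1.0
    near_pole = np.abs(p[:, 2]) > 0.9
    ref[near_pole] = [1.0, 0.0, 0.0]
    e1 = np.cross(p, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(p, e1)
    return e1, e2


def equatorial_arcs(positions: np.ndarray, radii_um: np.ndarray, R_guv_um: float):
    """Project spherical cap domains onto the equatorial great circle.

    A domain is a spherical cap of angular radius ``alpha = r / R_guv``
    centered at latitude ``lam``.  It intersects the equator iff
    ``|lam| < alpha``; the intersection is a longitude arc of half-width
    ``dphi = arccos(cos(alpha) / cos(lam))``.

    Returns a list of merged, disjoint arcs ``(start_deg, end_deg)`` with
    start in [0, 360) and end possibly > 360 for wrap-around arcs.
    """
    radii_um = np.asarray(radii_um, dtype=float)
    alpha = radii_um / R_guv_um
    lam = np.arcsin(np.clip(positions[:, 2], -1, 1))
    lon = np.degrees(np.arctan2(positions[:, 1], positions[:, 0])) % 360.0
    arcs = []
    for a, la, lo in zip(alpha, lam, lon):
        if a <= np.abs(la):
            continue
        ca, cl = np.cos(a), np.cos(la)
        dphi = np.degrees(np.arccos(np.clip(ca / cl, -1, 1)))
        if dphi <= 0:
            continue
        arcs.append((lo - dphi, lo + dphi))
    if not arcs:
        return []
    # normalize to start in [0,360) and merge overlaps on the circle
    arcs = sorted(((s % 360.0, (s % 360.0) + (e - s)) for s, e in arcs))
    merged = [list(arcs[0])]
    for s, e in arcs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    # wrap: last arc running past 360 may absorb the first
    if len(merged) > 1 and merged[-1][1] >= 360.0 and merged[-1][1] - 360.0 >= merged[0][0]:
        merged[-1][1] = max(merged[-1][1], merged[0][1] + 360.0)
        merged.pop(0)
    return [tuple(a) for a in merged]


def simulate_domains(
    n0: int,
    R_guv_um: float = 10.0,
    params: PhysicalParams | None = None,
    mode: str = "bare",
    t_end_s: float = 3600.0,
    dt_s: float = 0.05,
    seed: int = 0,
    sample_times_s: np.ndarray | None = None,
    initial_radius_um: float = 1.0,
    record_states: bool = True,
) -> SimTrace:
    """Brownian diffusion–coalescence of Ld domains on a spherical vesicle.

    Each domain takes isotropic Brownian steps on the sphere surface with its
    own Saffman–Delbrück ``D(r_i)``; in ``spvca`` mode every D is multiplied
    by ``params.f_spvca`` (the NPF coat slows domain diffusion); in ``actin``
    mode corona radii grow as ``c_i = r_i + v_gel * t`` and merging is
    sterically blocked once the overhang exceeds the mesh size.  Two domains
    merge when their caps overlap: the product is placed at the area-weighted
    centroid with radius ``sqrt(r_i^2 + r_j^2)`` (membrane area conserved).
    No fission, no Ostwald ripening: coarsening is coalescence-only.
    """
    if mode not in SIM_MODES:
        raise ValueError(f"mode must be one of {SIM_MODES}")
    if n0 < 2:
        raise ValueError("need at least two domains")
    p = params or PhysicalParams()
    rng = np.random.default_rng(seed)

    R_m = R_guv_um * 1e-6
    radii = np.full(n0, float(initial_radius_um))  # um
    ang = radii / R_guv_um
    pos = _random_nonoverlapping_positions(n0, ang, rng)

    # stability guard: rms step must stay well below the domain radius
    D0 = saffman_delbruck_D(initial_radius_um * 1e-6, p)
    if np.sqrt(4.0 * D0 * dt_s) > initial_radius_um * 1e-6:
        raise ValueError(
            f"dt={dt_s} s gives Brownian steps larger than the domain radius; "
            "reduce dt_s"
        )

    if sample_times_s is None:
        sample_times_s = np.arange(0.0, t_end_s + 1e-9, max(t_end_s / 60.0, dt_s))
    sample_times_s = np.asarray(sample_times_s, dtype=float)

    counts_tot, counts_eq, states = [], [], []
    events: list[dict] = []

    def snapshot(t):
        counts_tot.append(len(radii))
        counts_eq.append(len(equatorial_arcs(pos, radii, R_guv_um)))
        if record_states:
            corona = radii + (p.v_gel * t * 1e6 if mode == "actin" else 0.0)
            states.append((pos.copy(), radii.copy(), corona))

    n_steps = int(np.ceil(t_end_s / dt_s))
    sample_idx = np.clip(np.round(sample_times_s / dt_s).astype(int), 0, n_steps)
    sample_set = {}
    for k, si in enumerate(sample_idx):
        sample_set.setdefault(si, []).append(k)

    def merge_pass(t):
        nonlocal pos, radii
        merged_any = True
        while merged_any and len(radii) > 1:
            merged_any = False
            if mode == "actin" and is_coalescence_blocked(corona_overhang(p.v_gel, t), p):
                return
            a = radii / R_guv_um
            dots = np.clip(pos @ pos.T, -1, 1)
            gamma = np.arccos(dots)
            contact = gamma < (a[:, None] + a[None, :])
            np.fill_diagonal(contact, False)
            ii, jj = np.where(np.triu(contact, 1))
            if len(ii) == 0:
                return
            # deepest overlap first
            order = np.argsort(gamma[ii, jj] - (a[ii] + a[jj]))
            i, j = int(ii[order[0]]), int(jj[order[0]])
            Ai, Aj = radii[i] ** 2, radii[j] ** 2
            new_pos = Ai * pos[i] + Aj * pos[j]
            new_pos /= np.linalg.norm(new_pos)
            new_r = float(np.sqrt(Ai + Aj))
            events.append(
                {"time_s": float(t), "i": i, "j": j,
                 "r_i_um": float(radii[i]), "r_j_um": float(radii[j]),
                 "r_new_um": new_r, "n_after": len(radii) - 1}
            )
            keep = np.ones(len(radii), dtype=bool)
            keep[[i, j]] = False
            pos = np.vstack([pos[keep], new_pos])
            radii = np.concatenate([radii[keep], [new_r]])
            merged_any = True

    l_sd_um = p.eta_m / p.eta_f * 1e6

    def diffusivities():
        D = p.kBT / (4.0 * np.pi * p.eta_m) * np.log(l_sd_um / radii)
        if mode == "spvca":
            D = D * p.f_spvca
        return np.maximum(D, 0.0)

    t = 0.0
    n_before = len(radii)
    merge_pass(t)
    if 0 in sample_set:
        for _ in sample_set[0]:
            snapshot(0.0)
    D = diffusivities()

    for step in range(1, n_steps + 1):
        t = step * dt_s
        if len(radii) > 1:
            sigma_ang = np.sqrt(2.0 * D * dt_s) / R_m
            e1, e2 = _tangent_basis(pos)
            g = rng.normal(size=(len(radii), 2))
            pos = pos + sigma_ang[:, None] * (g[:, :1] * e1 + g[:, 1:] * e2)
            pos /= np.linalg.norm(pos, axis=1, keepdims=True)
            n_before = len(radii)
            merge_pass(t)
            if len(radii) != n_before:
                D = diffusivities()
        if step in sample_set:
            for _ in sample_set[step]:
                snapshot(t)

    return SimTrace(
        mode=mode,
        n0=n0,
        R_guv_um=R_guv_um,
        seed=seed,
        times_s=sample_times_s,
        counts_total=np.asarray(counts_tot),
        counts_equatorial=np.asarray(counts_eq),
        states=states,
        events=events,
        params=p,
    )
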