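"""Monodomain propagation on tetrahedral meshes.

Solves ``beta Cm dV/dt = div(sigma_m grad V) - beta I_ion + beta I_stim``
with the per-axis monodomain conductivity taken as the harmonic mean of the
intracellular and extracellular conductivities, rotated into the local
fiber frame per element. Spatial discretization is P1 finite elements with
a lumped mass matrix (on structured slabs built by the wedge mesher this is
the fast path; the same assembly covers arbitrary tet meshes). Time
integration is operator splitting: explicit diffusion plus the ionic-model
update, both at the reaction time step.

Units: mm / ms / mV / kPa-free. Conductivities are given in S/m, which
equals mS/mm; the diffusion tensor is sigma_m / (beta Cm) in mm^2/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..geometry import FiberField, TetMesh, assemble_stiffness, build_wedge_mesh, lumped_mass
from .tentusscher import IonicModelConfig, ionic_initial_state, ionic_step

__all__ = [
    "MonodomainParams",
    "StimulusProtocol",
    "MonodomainResult",
    "monodomain_simulate",
    "build_strand_mesh",
    "measure_cv",
    "tune_conductivities",
    "conductivity_tensors",
]


@dataclass
class MonodomainParams:
    """Tissue-level parameters.

    The printed intra/extracellular conductivities (S/m) are the starting
    point of the conduction-velocity tuning; ``scale_l``/``scale_t`` are the
    tuned multipliers on the longitudinal/transverse monodomain
    conductivity. ``beta`` (surface-to-volume, 1/cm) and ``C_m`` (uF/cm^2)
    are framework defaults; the CV tuning makes the targets insensitive to
    their exact values.
    """

    g_il: float = 0.2390  # S/m, intracellular longitudinal
    g_el: float = 0.8585  # S/m, extracellular longitudinal
    g_it: float = 0.0382  # S/m, intracellular transverse
    g_et: float = 0.1374  # S/m, extracellular transverse
    beta: float = 1400.0  # 1/cm
    C_m: float = 1.0  # uF/cm^2
    dt: float = 0.02  # ms
    output_interval: float = 1.0  # ms
    duration: float = 250.0  # ms
    stim_strength: float = 100.0  # uA/cm^2 transmembrane
    stim_duration: float = 2.0  # ms
    activation_threshold: float = -20.0  # mV on the upstroke
    scale_l: float = 1.0
    scale_t: float = 1.0

    def __post_init__(self) -> None:
        if min(self.g_il, self.g_el, self.g_it, self.g_et) <= 0:
            raise ValueError("conductivities must be positive")
        if self.dt > 0.025:
            raise ValueError("dt must be <= 25 us")

    @property
    def sigma_l(self) -> float:
        """Longitudinal monodomain conductivity (mS/mm), harmonic mean."""
        return self.scale_l * self.g_il * self.g_el / (self.g_il + self.g_el)

    @property
    def sigma_t(self) -> float:
        return self.scale_t * self.g_it * self.g_et / (self.g_it + self.g_et)

    @property
    def beta_cm(self) -> float:
        """beta * Cm in uF/mm^3."""
        return (self.beta / 10.0) * (self.C_m / 100.0)


def conductivity_tensors(fibers: FiberField, sigma_l: float, sigma_t: float) -> np.ndarray:
    """(m, 3, 3) monodomain conductivity tensors in the element fiber frames."""
    f = fibers.f
    eye = np.eye(3)
    ff = np.einsum("mi,mj->mij", f, f)
    return sigma_t * eye[None, :, :] + (sigma_l - sigma_t) * ff


@dataclass
class StimulusProtocol:
    """Either a region pulse or per-node timed pulses (reaction-eikonal foot).

    ``nodes`` with a scalar ``start`` delivers one pulse to a region;
    ``node_times`` (ms per node, inf = never) delivers the per-node foot
    current used by the hybrid reaction-eikonal scheme.
    """

    nodes: np.ndarray | None = None
    start: float = 0.0
    duration: float | None = None  # defaults to params.stim_duration
    strength: float | None = None  # uA/cm^2; defaults to params.stim_strength
    node_times: np.ndarray | None = None


@dataclass
class MonodomainResult:
    times: np.ndarray  # output sample times (ms)
    activation: np.ndarray  # per-node first crossing of the threshold (ms; NaN = never)
    snapshots: np.ndarray | None  # (n_out, n_nodes) V if requested
    probe_traces: np.ndarray | None  # (n_out, n_probes)
    probe_nodes: np.ndarray | None


def monodomain_simulate(
    mesh: TetMesh,
    fibers: FiberField,
    params: MonodomainParams,
    ionic: IonicModelConfig | None = None,
    stimulus: StimulusProtocol | None = None,
    save_snapshots: bool = False,
    probe_nodes=None,
    nonconducting_elements: np.ndarray | None = None,
) -> MonodomainResult:
    """Run monodomain propagation and record the activation map.

    ``nonconducting_elements`` zeroes the conductivity of selected elements
    (e.g. a nonconducting base). Aborts with a diagnostic if the membrane
    potential leaves [-100, +80] mV away from freshly stimulated nodes
    (instability guard).
    """
    ionic = ionic or IonicModelConfig()
    stimulus = stimulus or StimulusProtocol(nodes=np.array([0]))

    sigma = conductivity_tensors(fibers, params.sigma_l, params.sigma_t)
    if nonconducting_elements is not None:
        sigma = sigma.copy()
        sigma[nonconducting_elements] = 0.0
    K = assemble_stiffness(mesh, sigma / params.beta_cm)  # mm^2/ms weighting
    mass = lumped_mass(mesh)
    Kdiv = K.multiply(1.0 / mass[:, None]).tocsr()

    n = mesh.n_nodes
    Y = ionic_initial_state(n)
    dt = params.dt
    n_steps = int(round(params.duration / dt))
    out_every = max(1, int(round(params.output_interval / dt)))

    stim_amp = (
        stimulus.strength if stimulus.strength is not None else params.stim_strength
    ) / params.C_m  # pA/pF
    stim_dur = stimulus.duration if stimulus.duration is not None else params.stim_duration

    activation = np.full(n, np.nan)
    thr = params.activation_threshold
    # stability guard excludes nodes for a short grace period after their own
    # stimulus: a strong transmembrane pulse legitimately overshoots there.
    last_stim_end = np.full(n, -np.inf)
    if stimulus.node_times is not None:
        last_stim_end = np.asarray(stimulus.node_times, dtype=float) + stim_dur
    elif stimulus.nodes is not None:
        last_stim_end[stimulus.nodes] = stimulus.start + stim_dur
    times_out = []
    snaps = [] if save_snapshots else None
    probe_nodes = None if probe_nodes is None else np.asarray(probe_nodes, dtype=int)
    traces = [] if probe_nodes is not None else None

    istim = np.zeros(n)
    cell_code = ionic.cell_code
    for step in range(n_steps):
        t = step * dt
        V_prev = Y[:, 0].copy()

        istim[:] = 0.0
        if stimulus.node_times is not None:
            active = (t >= stimulus.node_times) & (t < stimulus.node_times + stim_dur)
            istim[active] = stim_amp
        elif stimulus.nodes is not None and stimulus.start <= t < stimulus.start + stim_dur:
            istim[stimulus.nodes] = stim_amp

        Y[:, 0] -= dt * (Kdiv @ Y[:, 0])
        ionic_step(Y, dt, istim, ionic.g_kr_scale, ionic.g_ks_scale, cell_code)

        V = Y[:, 0]
        crossed = np.isnan(activation) & (V_prev < thr) & (V >= thr)
        if crossed.any():
            frac = (thr - V_prev[crossed]) / (V[crossed] - V_prev[crossed])
            activation[crossed] = t + frac * dt

        if (step + 1) % out_every == 0:
            times_out.append(t + dt)
            if snaps is not None:
                snaps.append(V.copy())
            if traces is not None:
                traces.append(V[probe_nodes].copy())
            guard = t + dt > last_stim_end + 2.0
            if guard.any():
                vg = V[guard]
                if vg.max() > 80.0 or vg.min() < -100.0 or not np.all(np.isfinite(vg)):
                    raise FloatingPointError(
                        f"monodomain unstable at t={t + dt:.2f} ms "
                        f"(V range {vg.min():.1f}..{vg.max():.1f} mV)"
                    )

    return MonodomainResult(
        times=np.asarray(times_out),
        activation=activation,
        snapshots=None if snaps is None else np.asarray(snaps),
        probe_traces=None if traces is None else np.asarray(traces),
        probe_nodes=probe_nodes,
    )


def build_strand_mesh(
    length_mm: float = 20.0, width_mm: float = 0.9, spacing_mm: float = 0.3
) -> TetMesh:
    """Thin strand along z for conduction-velocity measurements."""
    return build_wedge_mesh((width_mm, width_mm, length_mm), spacing_mm)


def strand_fibers(mesh: TetMesh, along_axis: bool = True) -> FiberField:
    """Fibers along the strand axis (z) or perpendicular to it (x)."""
    m = mesh.n_tets
    if along_axis:
        f = np.tile([0.0, 0.0, 1.0], (m, 1))
        s = np.tile([1.0, 0.0, 0.0], (m, 1))
    else:
        f = np.tile([1.0, 0.0, 0.0], (m, 1))
        s = np.tile([0.0, 0.0, 1.0], (m, 1))
    return FiberField(f=f, s=s, n=np.cross(f, s))


def measure_cv(
    activation: np.ndarray, probe_a: int, probe_b: int, points: np.ndarray
) -> float:
    """Conduction velocity between two activated probes, in cm/s."""
    ta, tb = activation[probe_a], activation[probe_b]
    if not (np.isfinite(ta) and np.isfinite(tb)) or ta == tb:
        raise ValueError("both probes must be activated at distinct times")
    dist = np.linalg.norm(points[probe_a] - points[probe_b])  # mm
    return float(abs(dist / (tb - ta)) * 100.0)  # mm/ms -> cm/s


def _strand_probes(mesh: TetMesh, z_a: float, z_b: float) -> tuple[int, int]:
    """Centerline nodes nearest two axial stations."""
    p = mesh.points
    center = p[:, :2].mean(axis=0)
    on_axis = np.flatnonzero(np.linalg.norm(p[:, :2] - center, axis=1) < 1e-6)
    if on_axis.size == 0:  # even cell count: no exact centerline, take nearest
        d = np.linalg.norm(p[:, :2] - center, axis=1)
        on_axis = np.flatnonzero(d <= d.min() + 1e-9)
    za = on_axis[np.argmin(np.abs(p[on_axis, 2] - z_a))]
    zb = on_axis[np.argmin(np.abs(p[on_axis, 2] - z_b))]
    return int(za), int(zb)


def _strand_cv_once(
    params: MonodomainParams,
    ionic: IonicModelConfig,
    mesh: TetMesh,
    fibers: FiberField,
    probe_gap_mm: float = 5.0,
) -> float:
    length = mesh.points[:, 2].max()
    stim_nodes = np.flatnonzero(mesh.points[:, 2] < 0.6 + 1e-9)
    pa, pb = _strand_probes(
        mesh, length / 2.0 - probe_gap_mm / 2.0, length / 2.0 + probe_gap_mm / 2.0
    )
    res = monodomain_simulate(
        mesh,
        fibers,
        replace(params, duration=min(params.duration, 80.0)),
        ionic,
        StimulusProtocol(nodes=stim_nodes, start=0.0),
    )
    return measure_cv(res.activation, pa, pb, mesh.points)


def tune_conductivities(
    target_cv_l: float = 75.0,
    target_cv_t: float = 30.0,
    params: MonodomainParams | None = None,
    ionic: IonicModelConfig | None = None,
    spacing_mm: float = 0.3,
    rel_tol: float = 0.01,
    max_iter: int = 30,
) -> tuple[MonodomainParams, dict]:
    """Per-axis bisection of a conductivity scale factor to hit target CVs.

    Starting from the printed intra/extracellular conductivities, each axis
    runs a planar-wave strand simulation; the scale on the monodomain
    conductivity is bisected until the measured CV is within ``rel_tol`` of
    the target (CV grows monotonically, ~ as sqrt(sigma)). Returns the tuned
    parameters and a report with the verification CVs.
    """
    params = params or MonodomainParams()
    ionic = ionic or IonicModelConfig()
    mesh = build_strand_mesh(spacing_mm=spacing_mm)
    report = {}

    # two sweeps: the off-axis conductivity contributes a little lateral
    # coupling on the strand, so each axis is refined once more after the
    # other has been tuned.
    for axis, target in (
        ("l", target_cv_l),
        ("t", target_cv_t),
        ("l", target_cv_l),
        ("t", target_cv_t),
    ):
        fibers = strand_fibers(mesh, along_axis=(axis == "l"))

        def cv_at(scale: float) -> float:
            p = replace(params, **{f"scale_{axis}": scale})
            try:
                return _strand_cv_once(p, ionic, mesh, fibers)
            except ValueError:
                return 0.0  # conduction block at this conductivity

        base_scale = getattr(params, f"scale_{axis}")
        cv0 = cv_at(base_scale)
        scale = base_scale * 4.0 if cv0 == 0.0 else base_scale * (target / cv0) ** 2
        lo, hi = scale / 2.0, scale * 2.0
        # ensure the bracket actually straddles the target
        cv_lo, cv_hi = cv_at(lo), cv_at(hi)
        it = 2
        while cv_lo > target and it < max_iter:
            lo /= 2.0
            cv_lo = cv_at(lo)
            it += 1
        while cv_hi < target and it < max_iter:
            hi *= 2.0
            cv_hi = cv_at(hi)
            it += 1
        if not (cv_lo <= target <= cv_hi):
            raise RuntimeError(f"CV tuning failed to bracket target on axis {axis}")

        cv_mid = cv0
        for _ in range(it, max_iter):
            mid = np.sqrt(lo * hi)
            cv_mid = cv_at(mid)
            if abs(cv_mid - target) <= rel_tol * target:
                scale = mid
                break
            if cv_mid < target:
                lo = mid
            else:
                hi = mid
            scale = mid
        else:
            raise RuntimeError(
                f"CV tuning did not converge on axis {axis} (last {cv_mid:.2f} cm/s)"
            )
        params = replace(params, **{f"scale_{axis}": float(scale)})
        report[axis] = {"scale": float(scale), "cv_initial": cv0}

    # verification runs at the tuned parameters
    report["cv_l"] = _strand_cv_once(params, ionic, mesh, strand_fibers(mesh, True))
    report["cv_t"] = _strand_cv_once(params, ionic, mesh, strand_fibers(mesh, False))
    return params, report


def save_snapshots_flat(result: MonodomainResult, path) -> None:
    """Write V(t) snapshots as flat little-endian float32 + JSON header.

    The binary file holds ``n_out x n_nodes`` float32 values in C order; the
    sidecar ``<path>.json`` records shape, units and the sample times so the
    series can be memory-mapped without guessing.
    """
    from pathlib import Path
    import json

    if result.snapshots is None:
        raise ValueError("simulation was run without save_snapshots")
    path = Path(path)
    result.snapshots.astype("<f4").tofile(path)
    header = {
        "dtype": "<f4",
        "shape": list(result.snapshots.shape),
        "order": "C",
        "units": "mV",
        "times_ms": result.times.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))


def load_snapshots_flat(path):
    """Load a snapshot series written by :func:`save_snapshots_flat`."""
    from pathlib import Path
    import json

    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=header["dtype"]).reshape(header["shape"])
    return data, np.asarray(header["times_ms"])
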