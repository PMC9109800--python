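"""Material-point myocardial mechanics.

Passive response: orthotropic Fung-type strain energy in the local
fiber/sheet/normal (f/s/n) frame,

    Psi(E) = C/2 (exp(Q) - 1) + k/2 ln^2(J),
    Q = bff Eff^2 + 2 bfs Efs^2 + 2 bfn Efn^2 + bss Ess^2 + bnn Enn^2
        + 2 bsn Esn^2,

with the Green-Lagrange strain E expressed in f/s/n components, plus a
stiffer neo-Hookean material Psi = c (I1 - 3) + k/2 ln^2(J) for the basal
tissue. C is in kPa (inferred from the incompressibility penalty k = 650 kPa
entering the same energy); the exponent coefficients are unitless and read
from a versioned parameter file.

Active response: the six-ODE length- and velocity-dependent crossbridge
contraction model of Land et al. (human parameter set), producing the
tension

    T_a(lambda, dlambda/dt) = h(lambda) (T_ref / r_s) [(zeta_s + 1) S
                              + zeta_w W],

with overrides T_ref = 100 kPa and Ca50 = 0.9 uM. The tension acts along
the fiber with a 40% transverse fraction applied equally to the sheet and
sheet-normal directions. Calcium is supplied in uM (the ventricular ionic
model exports mM; couple with a factor 1000).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "PassiveParams",
    "LandParams",
    "LandState",
    "DeformationState",
    "psi_orthotropic",
    "pk2_stress",
    "psi_neohookean",
    "land_step",
    "land_initial_state",
    "active_stress_tensor",
    "fsn_summary",
]


def _load_b_coefficients() -> dict:
    with resources.files("septumkit.data").joinpath("passive_orthotropic.json").open() as fh:
        return json.load(fh)


@dataclass
class PassiveParams:
    """Passive material constants (kPa where dimensional)."""

    C: float = 1.6  # kPa, exponential scaling
    k: float = 650.0  # kPa, incompressibility penalty
    c_base: float = 1000.0  # kPa, neo-Hookean base stiffness (1 MPa)
    b: dict = field(default_factory=_load_b_coefficients)

    def __post_init__(self) -> None:
        if min(self.C, self.k, self.c_base) <= 0:
            raise ValueError("material constants must be positive")
        for key in ("b_ff", "b_fs", "b_fn", "b_ss", "b_sn", "b_nn"):
            if self.b[key] <= 0:
                raise ValueError(f"{key} must be positive")

    @property
    def b_matrix(self) -> np.ndarray:
        """Full 3x3 coefficient matrix W with W_ab E_ab^2 summed over all a, b
        equal to Q (off-diagonal terms appear twice, giving the printed 2x)."""
        b = self.b
        return np.array(
            [
                [b["b_ff"], b["b_fs"], b["b_fn"]],
                [b["b_fs"], b["b_ss"], b["b_sn"]],
                [b["b_fn"], b["b_sn"], b["b_nn"]],
            ]
        )


@dataclass
class DeformationState:
    """Kinematics of a material point in the f/s/n frame.

    ``F`` is the deformation gradient in laboratory coordinates; ``triad``
    stacks the unit fiber/sheet/normal vectors as rows. ``E_fsn`` is the
    Green-Lagrange strain rotated into the f/s/n frame; ``stretch`` is the
    fiber stretch |F f|.
    """

    F: np.ndarray
    triad: np.ndarray  # rows f, s, n

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.triad = np.asarray(self.triad, dtype=float)
        if np.linalg.det(self.F) <= 0:
            raise ValueError("deformation gradient must have positive determinant")

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def E_lab(self) -> np.ndarray:
        return 0.5 * (self.F.T @ self.F - np.eye(3))

    @property
    def E_fsn(self) -> np.ndarray:
        Q = self.triad
        return Q @ self.E_lab @ Q.T

    @property
    def stretch(self) -> float:
        return float(np.linalg.norm(self.F @ self.triad[0]))


def psi_orthotropic(E_fsn: np.ndarray, J: float, params: PassiveParams | None = None) -> float:
    """Orthotropic strain energy (kPa) at a material point."""
    params = params or PassiveParams()
    if J <= 0:
        raise ValueError("J must be positive")
    E = np.asarray(E_fsn, dtype=float)
    Q = float(np.sum(params.b_matrix * E * E))
    return 0.5 * params.C * (np.exp(Q) - 1.0) + 0.5 * params.k * np.log(J) ** 2


def pk2_stress(E_fsn: np.ndarray, J: float, params: PassiveParams | None = None) -> np.ndarray:
    """Analytic second Piola-Kirchhoff stress S = dPsi/dE (kPa, f/s/n frame).

    The exponential term differentiates to ``C exp(Q) (W o E)`` with W the
    full coefficient matrix (off-diagonals carrying the printed factor 2
    through their double appearance); the volumetric term contributes
    ``k ln(J) C_right^{-1}`` with C_right = 2E + I via dJ/dE.
    """
    params = params or PassiveParams()
    if J <= 0:
        raise ValueError("J must be positive")
    E = np.asarray(E_fsn, dtype=float)
    W = params.b_matrix
    Q = float(np.sum(W * E * E))
    S = params.C * np.exp(Q) * (W * E)
    C_right = 2.0 * E + np.eye(3)
    S += params.k * np.log(J) * np.linalg.inv(C_right)
    return S


def psi_neohookean(I1: float, J: float, c: float = 1000.0, k: float = 650.0) -> float:
    """Neo-Hookean base material Psi = c (I1 - 3) + k/2 ln^2 J (kPa)."""
    if J <= 0:
        raise ValueError("J must be positive")
    return c * (I1 - 3.0) + 0.5 * k * np.log(J) ** 2


# ---------------------------------------------------------------------------
# Land active-contraction model (six ODEs; human parameter set)
# ---------------------------------------------------------------------------


@dataclass
class LandParams:
    """Rate constants in 1/ms, calcium in uM, tension in kPa.

    ``T_ref`` and ``ca50_ref`` default to the overrides used for the septal
    models (published reference values are 120 kPa and 0.805 uM).
    """

    T_ref: float = 100.0  # kPa
    ca50_ref: float = 0.9  # uM
    k_trpn: float = 0.1  # 1/ms
    n_trpn: float = 2.0
    k_u: float = 0.04  # 1/ms, tropomyosin unblocking
    n_tm: float = 2.4
    trpn50: float = 0.35
    k_uw: float = 0.182  # 1/ms
    k_ws: float = 0.012  # 1/ms
    r_s: float = 0.25  # steady-state duty ratio
    r_w: float = 0.5
    gamma_s: float = 0.0085
    gamma_w: float = 0.615
    phi: float = 2.23
    A_eff: float = 25.0
    beta_0: float = 2.3
    beta_1: float = -2.4

    @property
    def k_wu(self) -> float:
        return self.k_uw * (1.0 / self.r_w - 1.0) - self.k_ws

    @property
    def k_su(self) -> float:
        return self.k_ws * self.r_w * (1.0 / self.r_s - 1.0)

    @property
    def k_b(self) -> float:
        return self.k_u * self.trpn50 ** self.n_tm / (
            1.0 - self.r_s - (1.0 - self.r_s) * self.r_w
        )

    @property
    def A(self) -> float:
        return self.A_eff * self.r_s / ((1.0 - self.r_s) * self.r_w + self.r_s)


@dataclass
class LandState:
    """Six state variables of the contraction model."""

    S: float = 0.0  # post-powerstroke (force-generating) crossbridge fraction
    W: float = 0.0  # pre-powerstroke crossbridge fraction
    CaTRPN: float = 1e-8  # calcium-bound troponin fraction
    B: float = 1.0  # blocked tropomyosin fraction
    zeta_s: float = 0.0  # distortion of the S state
    zeta_w: float = 0.0  # distortion of the W state

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.W, self.CaTRPN, self.B, self.zeta_s, self.zeta_w])


def land_initial_state(cai_rest_uM: float = 0.126, params: LandParams | None = None) -> LandState:
    """Resting state with troponin equilibrated to the resting calcium."""
    params = params or LandParams()
    x = (cai_rest_uM / params.ca50_ref) ** params.n_trpn
    return LandState(CaTRPN=max(x / (1.0 + x), 1e-8))


def _h_of_lambda(lam: float, beta_0: float) -> float:
    lam = min(lam, 1.2)
    return max(0.0, 1.0 + beta_0 * (lam + min(lam, 0.87) - 1.87))


def land_tension(state: LandState, lam: float, params: LandParams | None = None) -> float:
    """Active tension T_a = h(lambda) (T_ref/r_s) [(zeta_s+1) S + zeta_w W]."""
    params = params or LandParams()
    h = _h_of_lambda(lam, params.beta_0)
    return h * (params.T_ref / params.r_s) * (
        (state.zeta_s + 1.0) * state.S + state.zeta_w * state.W
    )


def land_step(
    state: LandState,
    cai_uM: float,
    lam: float,
    dlam_dt: float,
    dt: float,
    params: LandParams | None = None,
    max_substep: float = 0.1,
) -> tuple[LandState, float]:
    """Advance the six ODEs by ``dt`` (ms) and return (state', T_a in kPa).

    Forward Euler with internal substepping at <= ``max_substep`` ms;
    ``dlam_dt`` is in 1/s to match the physiological stretch-rate convention
    (converted to 1/ms internally). Aborts on non-finite state.
    """
    params = params or LandParams()
    if dt > 1.0 + 1e-9:
        raise ValueError("dt must be <= 1 ms; substepping is internal")
    n_sub = max(1, int(np.ceil(dt / max_substep)))
    h = dt / n_sub
    dlam_ms = dlam_dt / 1000.0

    S, W, catrpn, B, zs, zw = state.as_array()
    lam12 = min(lam, 1.2)
    ca50 = params.ca50_ref * (1.0 + params.beta_1 * (lam12 - 1.0))
    ca50 = max(ca50, 1e-6)
    cw = params.phi * params.k_uw * ((1 - params.r_s) * (1 - params.r_w)) / (
        (1 - params.r_s) * params.r_w
    )
    cs = params.phi * params.k_ws * ((1 - params.r_s) * params.r_w) / params.r_s

    for _ in range(n_sub):
        U = 1.0 - B - S - W
        gamma_su = params.gamma_s * max(zs if zs > 0 else 0.0, -zs - 1.0 if zs < -1.0 else 0.0)
        gamma_wu = params.gamma_w * abs(zw)
        dS = params.k_ws * W - params.k_su * S - gamma_su * S
        dW = params.k_uw * U - params.k_wu * W - params.k_ws * W - gamma_wu * W
        dCaT = params.k_trpn * (
            (cai_uM / ca50) ** params.n_trpn * (1.0 - catrpn) - catrpn
        )
        cat = max(catrpn, 1e-8)
        dB = params.k_b * min(cat ** (-params.n_tm / 2.0), 100.0) * U - params.k_u * (
            cat ** (params.n_tm / 2.0)
        ) * B
        dzs = params.A * dlam_ms - cs * zs
        dzw = params.A * dlam_ms - cw * zw
        S += h * dS
        W += h * dW
        catrpn += h * dCaT
        B += h * dB
        zs += h * dzs
        zw += h * dzw

    out = LandState(S=S, W=W, CaTRPN=catrpn, B=B, zeta_s=zs, zeta_w=zw)
    if not np.all(np.isfinite(out.as_array())):
        raise FloatingPointError("Land model state became non-finite")
    return out, land_tension(out, lam, params)


def active_stress_tensor(
    T_a: float, triad: np.ndarray, transverse_fraction: float = 0.4
) -> np.ndarray:
    """Active stress T_a f(x)f + q T_a (s(x)s + n(x)n), q the transverse fraction.

    The transverse share is split equally between the sheet and sheet-normal
    directions.
    """
    f, s, n = np.asarray(triad, dtype=float)
    return T_a * (
        np.outer(f, f) + transverse_fraction * (np.outer(s, s) + np.outer(n, n))
    )


FSN_COMPONENTS = ["ff", "ss", "nn", "fs", "fn", "sn"]
_COMP_INDEX = {"ff": (0, 0), "ss": (1, 1), "nn": (2, 2), "fs": (0, 1), "fn": (0, 2), "sn": (1, 2)}


def fsn_summary(series: np.ndarray) -> dict:
    """Mean and interquartile band of f/s/n tensor components over a region.

    ``series`` is (n_time, n_samples, 3, 3) symmetric tensors (strain or
    stress) already expressed in the f/s/n frame. Returns per component
    ``mean``, ``q25`` and ``q75`` time series; the interquartile band is the
    outlier-robust spread summary.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 4 or arr.shape[2:] != (3, 3):
        raise ValueError("series must be (n_time, n_samples, 3, 3)")
    if arr.shape[1] == 0:
        raise ValueError("region is empty")
    out = {}
    for name, (i, j) in _COMP_INDEX.items():
        comp = arr[:, :, i, j]
        out[name] = {
            "mean": comp.mean(axis=1),
            "q25": np.percentile(comp, 25, axis=1),
            "q75": np.percentile(comp, 75, axis=1),
        }
    return out
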