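"""Human ventricular myocyte ionic model (ten Tusscher-Noble-Noble-Panfilov).

The 17-variable 2004 formulation: membrane potential, 12 gating variables
(including the calcium-dependent L-type inactivation gate fCa and the
release gate g), intracellular Na+/K+ and the two-compartment calcium
subsystem (cytosol + sarcoplasmic reticulum with rapid buffering). The
rapid and slow delayed-rectifier conductances carry scale factors;
reducing both by 20% lengthens the epicardial action potential from its
published ~276 ms to the ~300 ms plateau duration characteristic of sheep
ventricle.

Integration: Rush-Larsen exponential updates for the voltage-gated
variables, the model's conditional Euler update for fCa and g (they may
not increase during depolarization above -60 mV), forward Euler for
Na+/K+, and the analytic rapid-buffering update for the calcium
compartments. The hot loop is compiled with numba; a plain-NumPy
right-hand side (`ionic_rhs`) of the same model in ODE form is provided
for cross-checks with generic ODE integrators.

State vector layout (index, variable, units):
0 V (mV), 1 m, 2 h, 3 j, 4 d, 5 f, 6 fCa, 7 r, 8 s, 9 xr1, 10 xr2,
11 xs, 12 g, 13 Nai (mM), 14 Ki (mM), 15 Cai (mM), 16 CaSR (mM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "IonicModelConfig",
    "ionic_initial_state",
    "ionic_step",
    "ionic_rhs",
    "N_STATES",
    "CELL_TYPES",
]

CELL_TYPES = {"epi": 0, "endo": 1, "mcell": 2}
N_STATES = 17

# physical constants and fixed model parameters
R_GAS = 8314.472
TEMP = 310.0
FARADAY = 96485.3415
RTONF = R_GAS * TEMP / FARADAY
KO, NAO, CAO = 5.4, 140.0, 2.0
CAPACITANCE = 0.185
VC, VSR = 0.016404, 0.001094
G_NA, G_K1 = 14.838, 5.405
G_KR_BASE = 0.096
G_CAL = 1.75e-4
G_BNA, G_BCA = 0.00029, 0.000592
G_PCA, KP_CA, G_PK = 0.825, 0.0005, 0.0146
P_KNA = 0.03
P_NAK, KM_K, KM_NA = 1.362, 1.0, 40.0
K_NACA, KM_NAI, KM_CA, KSAT, N_GAMMA, ALPHA_NACA = 1000.0, 87.5, 1.38, 0.1, 0.35, 2.5
A_REL, B_REL, C_REL = 0.016464, 0.25, 0.008232
V_LEAK = 8e-5
VMAX_UP, K_UP = 0.000425, 0.00025
BUF_C, K_BUF_C = 0.15, 0.001
BUF_SR, K_BUF_SR = 10.0, 0.3


@dataclass
class IonicModelConfig:
    """Conductance scaling and cell-type variant of the ionic model."""

    g_kr_scale: float = 0.8
    g_ks_scale: float = 0.8
    cell_type: str = "epi"

    def __post_init__(self) -> None:
        if self.g_kr_scale <= 0 or self.g_ks_scale <= 0:
            raise ValueError("conductance scale factors must be positive")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {sorted(CELL_TYPES)}")

    @property
    def cell_code(self) -> int:
        return CELL_TYPES[self.cell_type]


# published resting state
_Y0 = np.array(
    [
        -86.2, 0.0, 0.75, 0.75, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0,
        11.6, 138.3, 0.0002, 0.2,
    ]
)


def ionic_initial_state(n_cells: int = 1) -> np.ndarray:
    """(n, 17) state array at the published resting values."""
    return np.tile(_Y0, (n_cells, 1))


@njit(cache=True, fastmath=True)
def _gto_gks(cell_code):
    if cell_code == 0:  # epi
        return 0.294, 0.245
    elif cell_code == 1:  # endo
        return 0.073, 0.245
    else:  # mid-myocardial
        return 0.294, 0.062


@njit(cache=True, fastmath=True)
def ionic_step(Y, dt, istim, g_kr_scale, g_ks_scale, cell_code):
    """Advance all cells by dt (ms) in place; istim in pA/pF (depolarizing > 0)."""
    g_to, g_ks0 = _gto_gks(cell_code)
    g_kr = G_KR_BASE * g_kr_scale
    g_ks = g_ks0 * g_ks_scale
    for i in range(Y.shape[0]):
        V = Y[i, 0]
        m, h, j = Y[i, 1], Y[i, 2], Y[i, 3]
        d, f, fca = Y[i, 4], Y[i, 5], Y[i, 6]
        r, s = Y[i, 7], Y[i, 8]
        xr1, xr2, xs = Y[i, 9], Y[i, 10], Y[i, 11]
        g = Y[i, 12]
        nai, ki = Y[i, 13], Y[i, 14]
        cai, casr = Y[i, 15], Y[i, 16]

        ek = RTONF * math.log(KO / ki)
        ena = RTONF * math.log(NAO / nai)
        eks = RTONF * math.log((KO + P_KNA * NAO) / (ki + P_KNA * nai))
        eca = 0.5 * RTONF * math.log(CAO / cai)

        ina = G_NA * m ** 3 * h * j * (V - ena)
        vf = V / RTONF
        if abs(V) < 1e-6:
            vf = 1e-6 / RTONF
        expv = math.exp(2.0 * vf)
        ical = (
            G_CAL * d * f * fca * 4.0 * vf * FARADAY
            * (cai * expv - 0.341 * CAO) / (expv - 1.0)
        )
        ito = g_to * r * s * (V - ek)
        ikr = g_kr * math.sqrt(KO / 5.4) * xr1 * xr2 * (V - ek)
        iks = g_ks * xs * xs * (V - eks)
        ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - ek - 200.0)))
        bk1 = (
            3.0 * math.exp(0.0002 * (V - ek + 100.0)) + math.exp(0.1 * (V - ek - 10.0))
        ) / (1.0 + math.exp(-0.5 * (V - ek)))
        ik1 = G_K1 * math.sqrt(KO / 5.4) * ak1 / (ak1 + bk1) * (V - ek)
        inaca = (
            K_NACA
            / ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO)
               * (1.0 + KSAT * math.exp((N_GAMMA - 1.0) * V / RTONF)))
            * (
                math.exp(N_GAMMA * V / RTONF) * nai ** 3 * CAO
                - math.exp((N_GAMMA - 1.0) * V / RTONF) * NAO ** 3 * cai * ALPHA_NACA
            )
        )
        inak = (
            P_NAK
            * (KO / (KO + KM_K))
            * (nai / (nai + KM_NA))
            / (1.0 + 0.1245 * math.exp(-0.1 * V / RTONF) + 0.0353 * math.exp(-V / RTONF))
        )
        ipca = G_PCA * cai / (KP_CA + cai)
        ipk = G_PK * (V - ek) / (1.0 + math.exp((25.0 - V) / 5.98))
        ibna = G_BNA * (V - ena)
        ibca = G_BCA * (V - eca)

        itot = ina + ik1 + ito + ikr + iks + ical + inaca + inak + ipca + ipk + ibna + ibca

        # --- calcium dynamics (analytic rapid-buffering update) ---
        irel = (A_REL * casr * casr / (B_REL * B_REL + casr * casr) + C_REL) * d * g
        ileak = V_LEAK * (casr - cai)
        iup = VMAX_UP / (1.0 + (K_UP / cai) ** 2)

        casrbuf = BUF_SR * casr / (casr + K_BUF_SR)
        dcasr = dt * (VC / VSR) * (iup - irel - ileak)
        bjsr = BUF_SR - casrbuf - dcasr - casr + K_BUF_SR
        cjsr = K_BUF_SR * (casrbuf + dcasr + casr)
        casr = (math.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

        ca_current = -(ical + ibca + ipca - 2.0 * inaca) * CAPACITANCE / (2.0 * VC * FARADAY)
        cabuf = BUF_C * cai / (cai + K_BUF_C)
        dcai = dt * (ca_current - (iup - irel - ileak))
        bc = BUF_C - cabuf - dcai - cai + K_BUF_C
        cc = K_BUF_C * (cabuf + dcai + cai)
        cai = (math.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

        nai += dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca) * CAPACITANCE / (VC * FARADAY))
        ki += dt * (
            -(ik1 + ito + ikr + iks - 2.0 * inak + ipk - istim[i])
            * CAPACITANCE
            / (VC * FARADAY)
        )

        # --- voltage-gated variables, Rush-Larsen ---
        m_inf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
        am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
        bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) + 0.1 / (
            1.0 + math.exp((V - 50.0) / 200.0)
        )
        tau_m = am * bm

        h_inf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
        if V >= -40.0:
            ah = 0.0
            bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        else:
            ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
            bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
        tau_h = 1.0 / (ah + bh)

        j_inf = h_inf
        if V >= -40.0:
            aj = 0.0
            bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
        else:
            aj = (
                (-2.5428e4 * math.exp(0.2444 * V) - 6.948e-6 * math.exp(-0.04391 * V))
                * (V + 37.78)
                / (1.0 + math.exp(0.311 * (V + 79.23)))
            )
            bj = 0.02424 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
        tau_j = 1.0 / (aj + bj)

        d_inf = 1.0 / (1.0 + math.exp((-5.0 - V) / 7.5))
        ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
        bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
        gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
        tau_d = ad * bd + gd

        f_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
        tau_f = (
            1125.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
            + 80.0
            + 165.0 / (1.0 + math.exp((25.0 - V) / 10.0))
        )

        if cell_code == 1:  # endocardial transient-outward kinetics
            s_inf = 1.0 / (1.0 + math.exp((V + 28.0) / 5.0))
            tau_s = 1000.0 * math.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
        else:
            s_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
            tau_s = (
                85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
                + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0))
                + 3.0
            )
        r_inf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
        tau_r = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8

        xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
        axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
        bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
        tau_xr1 = axr1 * bxr1
        xr2_inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
        axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
        bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
        tau_xr2 = axr2 * bxr2
        xs_inf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
        axs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - V) / 6.0))
        bxs = 1.0 / (1.0 + math.exp((V - 60.0) / 20.0))
        tau_xs = axs * bxs

        # --- calcium-dependent gates: conditional Euler updates ---
        afca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
        bfca = 0.1 / (1.0 + math.exp((cai - 0.0005) / 0.0001))
        gfca = 0.2 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
        fca_inf = (afca + bfca + gfca + 0.23) / 1.46
        fca_new = fca + dt * (fca_inf - fca) / 2.0
        if not (fca_inf > fca and V > -60.0):
            fca = fca_new

        if cai < 0.00035:
            g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
        else:
            g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 16)
        g_new = g + dt * (g_inf - g) / 2.0
        if not (g_inf > g and V > -60.0):
            g = g_new

        Y[i, 1] = m_inf - (m_inf - m) * math.exp(-dt / tau_m)
        Y[i, 2] = h_inf - (h_inf - h) * math.exp(-dt / tau_h)
        Y[i, 3] = j_inf - (j_inf - j) * math.exp(-dt / tau_j)
        Y[i, 4] = d_inf - (d_inf - d) * math.exp(-dt / tau_d)
        Y[i, 5] = f_inf - (f_inf - f) * math.exp(-dt / tau_f)
        Y[i, 6] = fca
        Y[i, 7] = r_inf - (r_inf - r) * math.exp(-dt / tau_r)
        Y[i, 8] = s_inf - (s_inf - s) * math.exp(-dt / tau_s)
        Y[i, 9] = xr1_inf - (xr1_inf - xr1) * math.exp(-dt / tau_xr1)
        Y[i, 10] = xr2_inf - (xr2_inf - xr2) * math.exp(-dt / tau_xr2)
        Y[i, 11] = xs_inf - (xs_inf - xs) * math.exp(-dt / tau_xs)
        Y[i, 12] = g
        Y[i, 13] = nai
        Y[i, 14] = ki
        Y[i, 15] = cai
        Y[i, 16] = casr
        Y[i, 0] = V + dt * (-itot + istim[i])


def ionic_rhs(t, y, config: IonicModelConfig | None = None, istim=0.0):
    """Plain-NumPy right-hand side of the same model in ODE form (one cell).

    For use with generic ODE integrators as an independent integration route
    (rapid buffering enters as multiplicative factors; the fCa/g gates keep
    their conditional freeze). Not used by the simulation code path.
    """
    config = config or IonicModelConfig()
    (V, m, h, j, d, f, fca, r, s, xr1, xr2, xs, g,
     nai, ki, cai, casr) = y

    g_to, g_ks0 = (0.294, 0.245)
    if config.cell_type == "endo":
        g_to = 0.073
    elif config.cell_type == "mcell":
        g_ks0 = 0.062
    g_kr = G_KR_BASE * config.g_kr_scale
    g_ks = g_ks0 * config.g_ks_scale

    ek = RTONF * np.log(KO / ki)
    ena = RTONF * np.log(NAO / nai)
    eks = RTONF * np.log((KO + P_KNA * NAO) / (ki + P_KNA * nai))
    eca = 0.5 * RTONF * np.log(CAO / cai)

    ina = G_NA * m ** 3 * h * j * (V - ena)
    vf = V / RTONF if abs(V) > 1e-6 else 1e-6 / RTONF
    expv = np.exp(2.0 * vf)
    ical = G_CAL * d * f * fca * 4.0 * vf * FARADAY * (cai * expv - 0.341 * CAO) / (expv - 1.0)
    ito = g_to * r * s * (V - ek)
    ikr = g_kr * np.sqrt(KO / 5.4) * xr1 * xr2 * (V - ek)
    iks = g_ks * xs ** 2 * (V - eks)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (V - ek + 100.0)) + np.exp(0.1 * (V - ek - 10.0))) / (
        1.0 + np.exp(-0.5 * (V - ek)))
    ik1 = G_K1 * np.sqrt(KO / 5.4) * ak1 / (ak1 + bk1) * (V - ek)
    inaca = (K_NACA / ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO)
             * (1.0 + KSAT * np.exp((N_GAMMA - 1.0) * V / RTONF)))
             * (np.exp(N_GAMMA * V / RTONF) * nai ** 3 * CAO
                - np.exp((N_GAMMA - 1.0) * V / RTONF) * NAO ** 3 * cai * ALPHA_NACA))
    inak = (P_NAK * (KO / (KO + KM_K)) * (nai / (nai + KM_NA))
            / (1.0 + 0.1245 * np.exp(-0.1 * V / RTONF) + 0.0353 * np.exp(-V / RTONF)))
    ipca = G_PCA * cai / (KP_CA + cai)
    ipk = G_PK * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    ibna = G_BNA * (V - ena)
    ibca = G_BCA * (V - eca)
    itot = ina + ik1 + ito + ikr + iks + ical + inaca + inak + ipca + ipk + ibna + ibca

    irel = (A_REL * casr ** 2 / (B_REL ** 2 + casr ** 2) + C_REL) * d * g
    ileak = V_LEAK * (casr - cai)
    iup = VMAX_UP / (1.0 + (K_UP / cai) ** 2)
    buf_i = 1.0 / (1.0 + BUF_C * K_BUF_C / (cai + K_BUF_C) ** 2)
    buf_sr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (casr + K_BUF_SR) ** 2)
    ca_current = -(ical + ibca + ipca - 2.0 * inaca) * CAPACITANCE / (2.0 * VC * FARADAY)
    dcai = buf_i * (ca_current - (iup - irel - ileak))
    dcasr = buf_sr * (VC / VSR) * (iup - irel - ileak)
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * CAPACITANCE / (VC * FARADAY)
    dki = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk - istim) * CAPACITANCE / (VC * FARADAY)

    def gate(val, inf, tau):
        return (inf - val) / tau

    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    tau_m = (1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))) * (
        0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0)))
    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah, bh = 0.0, 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    tau_h = 1.0 / (ah + bh)
    j_inf = h_inf
    if V >= -40.0:
        aj, bj = 0.0, 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    tau_j = 1.0 / (aj + bj)
    d_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 7.5))
    tau_d = (1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25) * (
        1.4 / (1.0 + np.exp((V + 5.0) / 5.0))) + 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (1125.0 * np.exp(-((V + 27.0) ** 2) / 240.0) + 80.0
             + 165.0 / (1.0 + np.exp((25.0 - V) / 10.0)))
    if config.cell_type == "endo":
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau_s = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau_s = (85.0 * np.exp(-((V + 45.0) ** 2) / 320.0)
                 + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)
    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    tau_xr1 = (450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))) * (
        6.0 / (1.0 + np.exp((V + 30.0) / 11.5)))
    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    tau_xr2 = (3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))) * (
        1.12 / (1.0 + np.exp((V - 60.0) / 20.0)))
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    tau_xs = (1100.0 / np.sqrt(1.0 + np.exp((-10.0 - V) / 6.0))) * (
        1.0 / (1.0 + np.exp((V - 60.0) / 20.0)))

    afca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + np.exp((cai - 0.0005) / 0.0001))
    gfca = 0.2 / (1.0 + np.exp((cai - 0.00075) / 0.0008))
    fca_inf = (afca + bfca + gfca + 0.23) / 1.46
    dfca = 0.0 if (fca_inf > fca and V > -60.0) else (fca_inf - fca) / 2.0
    if cai < 0.00035:
        g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 16)
    dg = 0.0 if (g_inf > g and V > -60.0) else (g_inf - g) / 2.0

    return np.array([
        -itot + istim,
        gate(m, m_inf, tau_m), gate(h, h_inf, tau_h), gate(j, j_inf, tau_j),
        gate(d, d_inf, tau_d), gate(f, f_inf, tau_f), dfca,
        gate(r, r_inf, tau_r), gate(s, s_inf, tau_s),
        gate(xr1, xr1_inf, tau_xr1), gate(xr2, xr2_inf, tau_xr2), gate(xs, xs_inf, tau_xs),
        dg, dnai, dki, dcai, dcasr,
    ])
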