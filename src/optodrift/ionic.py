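"""Single-node electrophysiology of an optogenetically modified mouse ventricular cell.

The ionic membrane model is the 40-variable adult mouse ventricular
cardiomyocyte model of Bondarenko and co-workers (apex parameter set),
carrying Markov-chain descriptions of the fast Na+ and L-type Ca2+ channels
and of the rapid delayed rectifier, Hodgkin-Huxley gates for the remaining
K+ currents, and a four-compartment Ca2+ handling system (myoplasm, subspace,
junctional and network SR).  Fifteen sarcolemmal currents sum to the total
ionic current

    Iion = INa + ICaL + IpCa + IKto_f + IKto_s + IKr + IKur + IKss
         + IK1 + IKs + INaCa + INaK + ICl_Ca + ICab + INab

and the membrane voltage obeys  dV/dt = -(Iion + IChR2 - Istim)/Cm.

Light sensitivity enters through a four-state channelrhodopsin-2 (ChR2)
photocycle appended to the state vector (see :mod:`optodrift.chr2`), giving
45 dynamical variables per node in total (40 ionic + V is included in the 40
by the usual counting convention of the source model + 4 ChR2 + the ChR2
activation handled algebraically).

Units: time ms, voltage mV, concentrations uM, current densities pA/pF
(numerically equal to uA/cm^2 at Cm = 1 uF/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chr2 import ChR2Params, chr2_derivatives, chr2_conductance_factor

__all__ = [
    "IonicParams",
    "STATE_NAMES",
    "N_STATE",
    "initial_state",
    "compute_currents",
    "derivatives",
    "pack_gate_indices",
]

# ---------------------------------------------------------------------------
# State vector layout (index constants used throughout the package,
# including the compiled tissue kernel).
# ---------------------------------------------------------------------------
I_V = 0
I_CAI = 1
I_CASS = 2
I_CAJSR = 3
I_CANSR = 4
I_PRYR = 5
I_LTRPN = 6
I_HTRPN = 7
I_PO1 = 8
I_PO2 = 9
I_PC2 = 10
I_OCAL = 11
I_C2 = 12
I_C3 = 13
I_C4 = 14
I_I1 = 15
I_I2 = 16
I_I3 = 17
I_NAI = 18
I_CNA2 = 19
I_CNA1 = 20
I_ONA = 21
I_IFNA = 22
I_I1NA = 23
I_I2NA = 24
I_ICNA2 = 25
I_ICNA3 = 26
I_KI = 27
I_ATOF = 28
I_ITOF = 29
I_ATOS = 30
I_ITOS = 31
I_NKS = 32
I_AUR = 33
I_IUR = 34
I_AKSS = 35
I_IKSS = 36
I_CK1 = 37
I_CK2 = 38
I_OK = 39
I_IK = 40
# ChR2 photocycle occupancies (C1 + O1 + O2 + C2 = 1)
I_CH_C1 = 41
I_CH_O1 = 42
I_CH_O2 = 43
I_CH_C2 = 44

N_STATE = 45

STATE_NAMES = [
    "V", "Cai", "Cass", "CaJSR", "CaNSR", "P_RyR", "LTRPN_Ca", "HTRPN_Ca",
    "P_O1", "P_O2", "P_C2",
    "O_CaL", "C2_CaL", "C3_CaL", "C4_CaL", "I1_CaL", "I2_CaL", "I3_CaL",
    "Nai",
    "C_Na2", "C_Na1", "O_Na", "IF_Na", "I1_Na", "I2_Na", "IC_Na2", "IC_Na3",
    "Ki",
    "ato_f", "ito_f", "ato_s", "ito_s", "nKs", "aur", "iur", "aKss", "iKss",
    "C_K1", "C_K2", "O_K", "I_K",
    "chr2_C1", "chr2_O1", "chr2_O2", "chr2_C2",
]

# Hodgkin-Huxley gates, advanced with exact exponential (Rush-Larsen) updates
# in the operator-split integrator.
GATE_INDICES = (I_ATOF, I_ITOF, I_ATOS, I_ITOS, I_NKS, I_AUR, I_IUR, I_AKSS)

# Concentration-like variables (must stay strictly positive).
CONC_INDICES = (I_CAI, I_CASS, I_CAJSR, I_CANSR, I_NAI, I_KI)


def pack_gate_indices() -> np.ndarray:
    return np.array(GATE_INDICES, dtype=np.int64)


@dataclass(frozen=True)
class IonicParams:
    """Parameter set of the mouse ventricular ionic model.

    The defaults are the apex variant of the published model, tagged in
    ``variant``.  All conductances in mS/uF, permeabilities/pump rates in
    pA/pF, concentrations in uM, volumes in uL.
    """

    variant: str = "bondarenko2004-apex+fast-recovery"

    # Physical constants / geometry
    Cm: float = 1.0              # uF/cm^2
    F: float = 96.5              # C/mmol
    T: float = 298.0             # K
    R: float = 8.314             # J mol^-1 K^-1
    Acap: float = 1.534e-4       # cm^2
    Vmyo: float = 25.84e-6       # uL
    VJSR: float = 0.12e-6        # uL
    VNSR: float = 2.098e-6       # uL
    Vss: float = 1.485e-9        # uL

    # Extracellular concentrations (uM)
    Ko: float = 5400.0
    Nao: float = 140000.0
    Cao: float = 1800.0

    # Ca2+ buffering
    LTRPN_tot: float = 70.0
    HTRPN_tot: float = 140.0
    k_plus_htrpn: float = 0.00237
    k_minus_htrpn: float = 3.2e-5
    k_plus_ltrpn: float = 0.0327
    k_minus_ltrpn: float = 0.0196
    CMDN_tot: float = 50.0
    CSQN_tot: float = 15000.0
    Km_CMDN: float = 0.238
    Km_CSQN: float = 800.0

    # SR fluxes
    v1: float = 4.5              # ms^-1, RyR release
    v2: float = 1.74e-5          # ms^-1, NSR->myoplasm leak
    v3: float = 0.45             # uM/ms, SERCA uptake
    Km_up: float = 0.5
    tau_tr: float = 20.0         # ms
    tau_xfer: float = 8.0        # ms

    # RyR gating
    k_plus_a: float = 0.006075   # uM^-4 ms^-1
    k_minus_a: float = 0.07125
    k_plus_b: float = 0.00405    # uM^-3 ms^-1
    k_minus_b: float = 0.965
    k_plus_c: float = 0.009
    k_minus_c: float = 0.0008

    # L-type Ca2+ channel
    GCaL: float = 0.1729
    ECaL: float = 63.0
    Kpcb: float = 0.0005
    Kpc_max: float = 0.23324
    Kpc_half: float = 20.0
    ICaL_max: float = 7.0        # pA/pF, normalization in the P_RyR drive

    # Fast Na+
    GNa: float = 13.0
    # Scaling of the recovery-from-inactivation rate of the Na+ channel
    # Markov chain.  The published chain recovers with tau ~ 100 ms at
    # diastolic voltages, which pins the spiral rotation period; the scale
    # is calibrated so the dark spiral rotates at the reference ~15 Hz
    # (see docs/methods.md).
    na_recovery_scale: float = 3.0
    # Negative shift (mV) of the steady-state Na+ availability midpoint,
    # implemented as bNa3 *= exp(shift/7.7).  Together with the recovery
    # scaling this is the tagged "variant" adjustment calibrated against
    # the tissue-level references (docs/methods.md).
    na_avail_shift_mv: float = 4.0

    # K+ currents
    Gtof: float = 0.4067
    Gtos: float = 0.0            # apex: slow transient outward absent
    GKs: float = 0.00575
    GKur: float = 0.16
    GKss: float = 0.05
    GKr: float = 0.078
    kf_Kr: float = 0.023761
    kb_Kr: float = 0.036778
    GK1: float = 0.2938

    # Pumps / exchangers / backgrounds
    INaK_max: float = 0.88
    Km_Nai: float = 21000.0
    Km_Ko: float = 1500.0
    kNaCa: float = 292.8
    Km_Na: float = 87500.0
    Km_Ca: float = 1380.0
    ksat: float = 0.1
    eta: float = 0.35
    IpCa_max: float = 1.0
    Km_pCa: float = 0.5
    GCab: float = 0.000367
    GNab: float = 0.0026
    GClCa: float = 10.0
    Km_Cl: float = 10.0
    ECl: float = -40.0

    chr2: ChR2Params = field(default_factory=ChR2Params)

    @property
    def RT_over_F(self) -> float:
        return self.R * self.T / self.F

    def with_chr2(self, **kwargs) -> "IonicParams":
        return replace(self, chr2=replace(self.chr2, **kwargs))


# Published initial conditions of the apex model (dark-adapted ChR2 appended).
_Y0 = {
    "V": -82.4202,
    "Cai": 0.115001,
    "Cass": 0.115001,
    "CaJSR": 1299.5,
    "CaNSR": 1299.5,
    "P_RyR": 0.0,
    "LTRPN_Ca": 11.2684,
    "HTRPN_Ca": 125.29,
    "P_O1": 0.0000149102,
    "P_O2": 9.51726e-11,
    "P_C2": 0.0000167401,
    "O_CaL": 9.30308e-19,
    "C2_CaL": 0.000124216,
    "C3_CaL": 5.78679e-9,
    "C4_CaL": 1.19547e-13,
    "I1_CaL": 4.97923e-19,
    "I2_CaL": 3.45847e-14,
    "I3_CaL": 1.85106e-14,
    "Nai": 14237.1,
    "C_Na2": 0.020752,
    "C_Na1": 0.000279132,
    "O_Na": 7.13483e-7,
    "IF_Na": 0.000153176,
    "I1_Na": 0.000673345,
    "I2_Na": 1.55787e-9,
    "IC_Na2": 0.0113879,
    "IC_Na3": 0.34278,
    "Ki": 143720.0,
    "ato_f": 0.00265563,
    "ito_f": 0.999977,
    "ato_s": 0.000417069,
    "ito_s": 0.998543,
    "nKs": 0.000262753,
    "aur": 0.000417069,
    "iur": 0.998543,
    "aKss": 0.000417069,
    "iKss": 1.0,
    "C_K1": 0.000992513,
    "C_K2": 0.000641229,
    "O_K": 0.000175298,
    "I_K": 0.0000319129,
    "chr2_C1": 1.0,
    "chr2_O1": 0.0,
    "chr2_O2": 0.0,
    "chr2_C2": 0.0,
}


def initial_state() -> np.ndarray:
    """Published initial conditions (dark-adapted), as a packed state vector."""
    return np.array([_Y0[name] for name in STATE_NAMES], dtype=np.float64)


# ---------------------------------------------------------------------------
# Voltage-dependent transition rates.  Grouped in one routine so the lookup-
# table builder used by the tissue kernel can tabulate exactly the same
# expressions (see optodrift.tables).
# ---------------------------------------------------------------------------

def sodium_rates(V, recovery_scale: float = 1.0, avail_shift_mv: float = 0.0):
    """Markov transition rates of the fast Na+ channel.

    ``recovery_scale`` multiplies both directions of the closed <->
    closed-inactivated exchange (aNa3 and bNa3), accelerating recovery from
    inactivation while leaving the steady-state availability curve and the
    detailed-balance rate bNa2 (which depends only on their ratio) exactly
    as published.  ``avail_shift_mv`` > 0 additionally moves the
    availability midpoint toward more negative potentials by that many mV
    (bNa3 gains a factor exp(shift/7.7), the slope constant of aNa3).
    """
    aNa11 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 17.0) + 0.20 * np.exp(-(V + 2.5) / 150.0))
    aNa12 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 15.0) + 0.23 * np.exp(-(V + 2.5) / 150.0))
    aNa13 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 12.0) + 0.25 * np.exp(-(V + 2.5) / 150.0))
    bNa11 = 0.1917 * np.exp(-(V + 2.5) / 20.3)
    bNa12 = 0.20 * np.exp(-(V - 2.5) / 20.3)
    bNa13 = 0.22 * np.exp(-(V - 7.5) / 20.3)
    aNa3 = recovery_scale * 7.0e-7 * np.exp(-(V + 7.0) / 7.7)
    bNa3 = (recovery_scale * np.exp(avail_shift_mv / 7.7)
            * (0.0084 + 0.00002 * (V + 7.0)))
    aNa2 = 1.0 / (0.188495 * np.exp(-(V + 7.0) / 16.6) + 0.393956)
    bNa2 = aNa13 * aNa2 * aNa3 / (bNa13 * bNa3)
    return aNa11, aNa12, aNa13, bNa11, bNa12, bNa13, aNa3, bNa3, aNa2, bNa2


def calcium_channel_rates(V):
    """Voltage-dependent rates of the L-type Ca2+ channel Markov chain."""
    e_fast = np.exp((V + 12.0) / 10.0)
    alpha = (0.4 * e_fast
             * (1.0 + 0.7 * np.exp(-((V + 40.0) ** 2) / 10.0)
                - 0.75 * np.exp(-((V + 20.0) ** 2) / 400.0))
             / (1.0 + 0.12 * e_fast))
    beta = 0.05 * np.exp(-(V + 12.0) / 13.0)
    Kpcf = 13.0 * (1.0 - np.exp(-((V + 14.5) ** 2) / 100.0))
    return alpha, beta, Kpcf


def kr_rates(V):
    aa0 = 0.022348 * np.exp(0.01176 * V)
    ba0 = 0.047002 * np.exp(-0.0631 * V)
    aa1 = 0.013733 * np.exp(0.038198 * V)
    ba1 = 0.0000689 * np.exp(-0.04178 * V)
    ai = 0.090821 * np.exp(0.023391 * (V + 5.0))
    bi = 0.006497 * np.exp(-0.03268 * (V + 5.0))
    return aa0, ba0, aa1, ba1, ai, bi


def gate_rates(V):
    """(alpha, beta) or (inf, tau) kinetics of the eight HH gates.

    Returns two arrays (x_inf, tau_x) ordered as GATE_INDICES.
    """
    V = np.asarray(V, dtype=np.float64)
    ass = 1.0 / (1.0 + np.exp(-(V + 22.5) / 7.7))
    iss = 1.0 / (1.0 + np.exp((V + 45.2) / 5.7))

    a_atof = 0.18064 * np.exp(0.03577 * (V + 30.0))
    b_atof = 0.3956 * np.exp(-0.06237 * (V + 30.0))
    a_itof = (0.000152 * np.exp(-(V + 13.5) / 7.0)
              / (0.0067083 * np.exp(-(V + 33.5) / 7.0) + 1.0))
    b_itof = (0.00095 * np.exp((V + 33.5) / 7.0)
              / (0.051335 * np.exp((V + 33.5) / 7.0) + 1.0))

    tau_tas = 0.493 * np.exp(-0.0629 * V) + 2.058
    tau_tis = 270.0 + 1050.0 / (1.0 + np.exp((V + 45.2) / 5.7))

    a_n = 4.81333e-6 * (V + 26.5) / (1.0 - np.exp(-0.128 * (V + 26.5)))
    b_n = 9.53333e-5 * np.exp(-0.038 * (V + 26.5))

    tau_aur = tau_tas
    tau_iur = 1200.0 - 170.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    tau_Kss = 39.3 * np.exp(-0.0862 * V) + 13.17

    inf = np.array([
        a_atof / (a_atof + b_atof),
        a_itof / (a_itof + b_itof),
        ass, iss,
        a_n / (a_n + b_n),
        ass, iss,
        ass,
    ])
    tau = np.array([
        1.0 / (a_atof + b_atof),
        1.0 / (a_itof + b_itof),
        tau_tas, tau_tis,
        1.0 / (a_n + b_n),
        tau_aur, tau_iur,
        tau_Kss,
    ])
    return inf, tau


# ---------------------------------------------------------------------------
# Currents and full right-hand side
# ---------------------------------------------------------------------------

def _check_finite(y: np.ndarray) -> None:
    if not np.all(np.isfinite(y)):
        bad = int(np.argmax(~np.isfinite(np.asarray(y))))
        raise ValueError(f"non-finite state component: {STATE_NAMES[bad]}")


def compute_currents(y: np.ndarray, p: IonicParams, LI: float = 0.0) -> dict:
    """All fifteen membrane currents, their sum Iion, and the ChR2 photocurrent.

    Pure function of the state vector and parameters; ``LI`` only matters for
    bookkeeping (the photocurrent depends on state, not on LI directly).
    Returns a dict with keys INa .. INab, Iion, IChR2 in pA/pF.
    """
    _check_finite(y)
    V = y[I_V]
    RTF = p.RT_over_F

    Cai, Cass = y[I_CAI], y[I_CASS]
    Nai, Ki = y[I_NAI], y[I_KI]

    EK = RTF * np.log(p.Ko / Ki)
    ENa = RTF * np.log((0.9 * p.Nao + 0.1 * p.Ko) / (0.9 * Nai + 0.1 * Ki))
    EKr = RTF * np.log((0.98 * p.Ko + 0.02 * p.Nao) / (0.98 * Ki + 0.02 * Nai))
    ECaN = 0.5 * RTF * np.log(p.Cao / Cai)

    INa = p.GNa * y[I_ONA] * (V - ENa)
    ICaL = p.GCaL * y[I_OCAL] * (V - p.ECaL)

    IpCa = p.IpCa_max * Cai ** 2 / (p.Km_pCa ** 2 + Cai ** 2)

    IKto_f = p.Gtof * y[I_ATOF] ** 3 * y[I_ITOF] * (V - EK)
    IKto_s = p.Gtos * y[I_ATOS] * y[I_ITOS] * (V - EK)
    IKr = p.GKr * y[I_OK] * (V - EKr)
    IKur = p.GKur * y[I_AUR] * y[I_IUR] * (V - EK)
    IKss = p.GKss * y[I_AKSS] * y[I_IKSS] * (V - EK)
    IK1 = (p.GK1 * (p.Ko / (p.Ko + 210.0)) * (V - EK)
           / (1.0 + np.exp(0.0896 * (V - EK))))
    IKs = p.GKs * y[I_NKS] ** 2 * (V - EK)

    VFRT = V / RTF
    e_eta = np.exp(p.eta * VFRT)
    e_etam = np.exp((p.eta - 1.0) * VFRT)
    INaCa = (p.kNaCa
             / (p.Km_Na ** 3 + p.Nao ** 3) / (p.Km_Ca + p.Cao)
             / (1.0 + p.ksat * e_etam)
             * (e_eta * Nai ** 3 * p.Cao - e_etam * p.Nao ** 3 * Cai))

    sigma = (np.exp(p.Nao / 67300.0) - 1.0) / 7.0
    fNaK = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * VFRT) + 0.0365 * sigma * np.exp(-VFRT))
    INaK = (p.INaK_max * fNaK * (p.Ko / (p.Ko + p.Km_Ko))
            / (1.0 + (p.Km_Nai / Nai) ** 1.5))

    O_ClCa = 0.2 / (1.0 + np.exp(-(V - 46.7) / 7.8))
    ICl_Ca = p.GClCa * O_ClCa * (Cai / (Cai + p.Km_Cl)) * (V - p.ECl)

    ICab = p.GCab * (V - ECaN)
    INab = p.GNab * (V - ENa)

    Iion = (INa + ICaL + IpCa + IKto_f + IKto_s + IKr + IKur + IKss
            + IK1 + IKs + INaCa + INaK + ICl_Ca + ICab + INab)

    IChR2 = p.chr2.current(V, y[I_CH_O1], y[I_CH_O2])

    return {
        "INa": INa, "ICaL": ICaL, "IpCa": IpCa, "IKto_f": IKto_f,
        "IKto_s": IKto_s, "IKr": IKr, "IKur": IKur, "IKss": IKss,
        "IK1": IK1, "IKs": IKs, "INaCa": INaCa, "INaK": INaK,
        "ICl_Ca": ICl_Ca, "ICab": ICab, "INab": INab,
        "Iion": Iion, "IChR2": IChR2,
    }


def derivatives(t: float, y: np.ndarray, p: IonicParams,
                Istim: float = 0.0, LI: float = 0.0) -> np.ndarray:
    """Full right-hand side dy/dt of the 45-variable cell model.

    ``Istim`` > 0 is a depolarizing stimulus current density (pA/pF);
    ``LI`` is the local irradiance in mW/mm^2 driving the ChR2 photocycle.
    """
    cur = compute_currents(y, p, LI)
    V = y[I_V]
    dy = np.empty_like(y)

    dy[I_V] = -(cur["Iion"] + cur["IChR2"] - Istim) / p.Cm

    # --- HH gates -----------------------------------------------------------
    inf, tau = gate_rates(V)
    for k, idx in enumerate(GATE_INDICES):
        dy[idx] = (inf[k] - y[idx]) / tau[k]
    dy[I_IKSS] = 0.0  # non-inactivating

    # --- L-type Ca2+ Markov chain ------------------------------------------
    alpha, beta, Kpcf = calcium_channel_rates(V)
    gamma_ca = p.Kpc_max * y[I_CASS] / (p.Kpc_half + y[I_CASS])
    O, C2, C3, C4 = y[I_OCAL], y[I_C2], y[I_C3], y[I_C4]
    I1, I2, I3 = y[I_I1], y[I_I2], y[I_I3]
    C1 = 1.0 - (O + C2 + C3 + C4 + I1 + I2 + I3)
    dy[I_OCAL] = (alpha * C4 - 4.0 * beta * O + p.Kpcb * I1 - gamma_ca * O
                  + 0.001 * (alpha * I2 - Kpcf * O))
    dy[I_C2] = 4.0 * alpha * C1 - beta * C2 + 2.0 * beta * C3 - 3.0 * alpha * C2
    dy[I_C3] = 3.0 * alpha * C2 - 2.0 * beta * C3 + 3.0 * beta * C4 - 2.0 * alpha * C3
    dy[I_C4] = (2.0 * alpha * C3 - 3.0 * beta * C4 + 4.0 * beta * O - alpha * C4
                + 0.01 * (4.0 * p.Kpcb * beta * I1 - alpha * gamma_ca * C4)
                + 0.002 * (4.0 * beta * I2 - Kpcf * C4)
                + 4.0 * beta * p.Kpcb * I3 - gamma_ca * Kpcf * C4)
    dy[I_I1] = (gamma_ca * O - p.Kpcb * I1
                + 0.001 * (alpha * I3 - Kpcf * I1)
                + 0.01 * (alpha * gamma_ca * C4 - 4.0 * beta * p.Kpcb * I1))
    dy[I_I2] = (0.001 * (Kpcf * O - alpha * I2) + p.Kpcb * I3 - gamma_ca * I2
                + 0.002 * (Kpcf * C4 - 4.0 * beta * I2))
    dy[I_I3] = (0.001 * (Kpcf * I1 - alpha * I3) + gamma_ca * I2 - p.Kpcb * I3
                + gamma_ca * Kpcf * C4 - 4.0 * beta * p.Kpcb * I3)

    # --- Fast Na+ Markov chain ---------------------------------------------
    (aNa11, aNa12, aNa13, bNa11, bNa12, bNa13,
     aNa3, bNa3, aNa2, bNa2) = sodium_rates(V, p.na_recovery_scale,
                                            p.na_avail_shift_mv)
    aNa4, bNa4 = aNa2 / 1000.0, aNa3
    aNa5, bNa5 = aNa2 / 95000.0, aNa3 / 50.0
    CNa2, CNa1, ONa = y[I_CNA2], y[I_CNA1], y[I_ONA]
    IFNa, I1Na, I2Na = y[I_IFNA], y[I_I1NA], y[I_I2NA]
    ICNa2, ICNa3 = y[I_ICNA2], y[I_ICNA3]
    CNa3 = 1.0 - (ONa + CNa1 + CNa2 + IFNa + I1Na + I2Na + ICNa2 + ICNa3)
    dy[I_CNA2] = (aNa11 * CNa3 - bNa11 * CNa2 + bNa12 * CNa1 - aNa12 * CNa2
                  + aNa3 * ICNa2 - bNa3 * CNa2)
    dy[I_CNA1] = (aNa12 * CNa2 - bNa12 * CNa1 + bNa13 * ONa - aNa13 * CNa1
                  + aNa3 * IFNa - bNa3 * CNa1)
    dy[I_ONA] = aNa13 * CNa1 - bNa13 * ONa + bNa2 * IFNa - aNa2 * ONa
    dy[I_IFNA] = (aNa2 * ONa - bNa2 * IFNa + bNa3 * CNa1 - aNa3 * IFNa
                  + bNa4 * I1Na - aNa4 * IFNa + aNa12 * ICNa2 - bNa12 * IFNa)
    dy[I_I1NA] = aNa4 * IFNa - bNa4 * I1Na + bNa5 * I2Na - aNa5 * I1Na
    dy[I_I2NA] = aNa5 * I1Na - bNa5 * I2Na
    dy[I_ICNA2] = (aNa11 * ICNa3 - bNa11 * ICNa2 + bNa12 * IFNa - aNa12 * ICNa2
                   + bNa3 * CNa2 - aNa3 * ICNa2)
    dy[I_ICNA3] = bNa11 * ICNa2 - aNa11 * ICNa3 + bNa3 * CNa3 - aNa3 * ICNa3

    # --- IKr Markov chain ---------------------------------------------------
    aa0, ba0, aa1, ba1, ai, bi = kr_rates(V)
    CK1, CK2, OK, IK = y[I_CK1], y[I_CK2], y[I_OK], y[I_IK]
    CK0 = 1.0 - (CK1 + CK2 + OK + IK)
    dy[I_CK1] = aa0 * CK0 - ba0 * CK1 + p.kb_Kr * CK2 - p.kf_Kr * CK1
    dy[I_CK2] = p.kf_Kr * CK1 - p.kb_Kr * CK2 + ba1 * OK - aa1 * CK2
    dy[I_OK] = aa1 * CK2 - ba1 * OK + bi * IK - ai * OK
    dy[I_IK] = ai * OK - bi * IK

    # --- RyR and Ca2+ handling ---------------------------------------------
    Cai, Cass = y[I_CAI], y[I_CASS]
    CaJSR, CaNSR = y[I_CAJSR], y[I_CANSR]
    PO1, PO2, PC2 = y[I_PO1], y[I_PO2], y[I_PC2]
    PC1 = 1.0 - (PC2 + PO1 + PO2)
    Cass2 = Cass * Cass
    Cass3 = Cass2 * Cass
    Cass4 = Cass2 * Cass2
    dy[I_PO1] = (p.k_plus_a * Cass4 * PC1 - p.k_minus_a * PO1
                 - p.k_plus_b * Cass3 * PO1 + p.k_minus_b * PO2
                 - p.k_plus_c * PO1 + p.k_minus_c * PC2)
    dy[I_PO2] = p.k_plus_b * Cass3 * PO1 - p.k_minus_b * PO2
    dy[I_PC2] = p.k_plus_c * PO1 - p.k_minus_c * PC2

    dy[I_PRYR] = (-0.04 * y[I_PRYR]
                  - 0.1 * (cur["ICaL"] / p.ICaL_max)
                  * np.exp(-((V - 5.0) ** 2) / 648.0))

    Jrel = p.v1 * (PO1 + PO2) * (CaJSR - Cass) * y[I_PRYR]
    Jtr = (CaNSR - CaJSR) / p.tau_tr
    Jxfer = (Cass - Cai) / p.tau_xfer
    Jleak = p.v2 * (CaNSR - Cai)
    Jup = p.v3 * Cai ** 2 / (p.Km_up ** 2 + Cai ** 2)
    Jtrpn = (p.k_plus_htrpn * Cai * (p.HTRPN_tot - y[I_HTRPN])
             - p.k_minus_htrpn * y[I_HTRPN]
             + p.k_plus_ltrpn * Cai * (p.LTRPN_tot - y[I_LTRPN])
             - p.k_minus_ltrpn * y[I_LTRPN])
    dy[I_LTRPN] = (p.k_plus_ltrpn * Cai * (p.LTRPN_tot - y[I_LTRPN])
                   - p.k_minus_ltrpn * y[I_LTRPN])
    dy[I_HTRPN] = (p.k_plus_htrpn * Cai * (p.HTRPN_tot - y[I_HTRPN])
                   - p.k_minus_htrpn * y[I_HTRPN])

    Bi = 1.0 / (1.0 + p.CMDN_tot * p.Km_CMDN / (p.Km_CMDN + Cai) ** 2)
    Bss = 1.0 / (1.0 + p.CMDN_tot * p.Km_CMDN / (p.Km_CMDN + Cass) ** 2)
    BJSR = 1.0 / (1.0 + p.CSQN_tot * p.Km_CSQN / (p.Km_CSQN + CaJSR) ** 2)

    conv = p.Acap * p.Cm / (2.0 * p.Vmyo * p.F)
    dy[I_CAI] = Bi * (Jleak + Jxfer - Jup - Jtrpn
                      - (cur["ICab"] - 2.0 * cur["INaCa"] + cur["IpCa"]) * conv)
    dy[I_CASS] = Bss * (Jrel * p.VJSR / p.Vss - Jxfer * p.Vmyo / p.Vss
                        - cur["ICaL"] * p.Acap * p.Cm / (2.0 * p.Vss * p.F))
    dy[I_CAJSR] = BJSR * (Jtr - Jrel)
    dy[I_CANSR] = ((Jup - Jleak) * p.Vmyo / p.VNSR - Jtr * p.VJSR / p.VNSR)

    # --- Na+/K+ bookkeeping --------------------------------------------------
    convV = p.Acap * p.Cm / (p.Vmyo * p.F)
    dy[I_NAI] = -(cur["INa"] + cur["INab"]
                  + 3.0 * cur["INaCa"] + 3.0 * cur["INaK"]) * convV
    dy[I_KI] = -(cur["IKto_f"] + cur["IKto_s"] + cur["IK1"] + cur["IKs"]
                 + cur["IKss"] + cur["IKur"] + cur["IKr"]
                 - 2.0 * cur["INaK"]) * convV

    # --- ChR2 photocycle ----------------------------------------------------
    dC1, dO1, dO2, dC2ch = chr2_derivatives(
        y[I_CH_C1], y[I_CH_O1], y[I_CH_O2], y[I_CH_C2], V, LI, p.chr2)
    dy[I_CH_C1] = dC1
    dy[I_CH_O1] = dO1
    dy[I_CH_O2] = dO2
    dy[I_CH_C2] = dC2ch

    return dy
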