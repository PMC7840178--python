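"""Voltage lookup tables and packed parameter vectors for the compiled solver.

All voltage-dependent transition rates and current factors of the cell model
are tabulated on a fine voltage axis (0.02 mV spacing) and linearly
interpolated inside the tissue kernel; the expressions tabulated here are
imported from :mod:`optodrift.ionic` / :mod:`optodrift.chr2` so the compiled
path and the reference right-hand side cannot drift apart.  The axis also
covers the driving-force variable u = V - EK used by the inward rectifier.

Tables embed the Rush-Larsen gate decay factors exp(-dt (alpha+beta)) and are
therefore built per time step; builders are memoized per (params, dt).
"""

from __future__ import annotations

import functools

import numpy as np

from . import ionic
from .chr2 import ChR2Params
from .ionic import IonicParams

__all__ = ["build_tables", "pack_params", "light_rate_arrays",
           "VMIN", "VMAX", "DV"]

VMIN = -140.0
VMAX = 160.0
DV = 0.02

# ---------------------------------------------------------------------------
# Table column layout
# ---------------------------------------------------------------------------
C_GINF0 = 0            # 8 gate steady states
C_GEXP0 = 8            # 8 gate decay factors exp(-dt/tau)
C_CAL_ALPHA = 16
C_CAL_BETA = 17
C_CAL_KPCF = 18
C_NA0 = 19             # 10 Na rates: aNa11..bNa2 (order of ionic.sodium_rates)
C_KR0 = 29             # 6 Kr rates: aa0, ba0, aa1, ba1, ai, bi
C_EETA = 35            # exp(eta V F/RT)
C_EETAM = 36           # exp((eta-1) V F/RT)
C_FNAK = 37
C_OCLCA = 38
C_IK1F = 39            # u/(1+exp(0.0896 u)), indexed by u = V-EK
C_CHW = 40             # ChR2 G(V)*(V-E)
C_CHGD1 = 41
C_CHGR = 42
C_PRYRG = 43           # exp(-(V-5)^2/648)
N_COLS = 44


@functools.lru_cache(maxsize=8)
def _tables_cached(params: IonicParams, dt: float) -> np.ndarray:
    V = np.arange(VMIN, VMAX + DV / 2, DV)
    n = V.size
    tab = np.zeros((n, N_COLS), dtype=np.float64)

    inf, tau = ionic.gate_rates(V)          # shapes (8, n)
    tab[:, C_GINF0:C_GINF0 + 8] = inf.T
    tab[:, C_GEXP0:C_GEXP0 + 8] = np.exp(-dt / tau).T

    a, b, kpcf = ionic.calcium_channel_rates(V)
    tab[:, C_CAL_ALPHA] = a
    tab[:, C_CAL_BETA] = b
    tab[:, C_CAL_KPCF] = kpcf

    na = ionic.sodium_rates(V, params.na_recovery_scale,
                            params.na_avail_shift_mv)
    for k in range(10):
        tab[:, C_NA0 + k] = na[k]

    kr = ionic.kr_rates(V)
    for k in range(6):
        tab[:, C_KR0 + k] = kr[k]

    RTF = params.RT_over_F
    tab[:, C_EETA] = np.exp(params.eta * V / RTF)
    tab[:, C_EETAM] = np.exp((params.eta - 1.0) * V / RTF)
    sigma = (np.exp(params.Nao / 67300.0) - 1.0) / 7.0
    tab[:, C_FNAK] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RTF)
                            + 0.0365 * sigma * np.exp(-V / RTF))
    tab[:, C_OCLCA] = 0.2 / (1.0 + np.exp(-(V - 46.7) / 7.8))
    # inward-rectifier factor, valid when indexed by u = V - EK
    u = V
    tab[:, C_IK1F] = u / (1.0 + np.exp(np.clip(0.0896 * u, -500, 500)))

    ch = params.chr2
    tab[:, C_CHW] = ch.rectification(V) * (V - ch.E_chr2)
    tab[:, C_CHGD1] = ch.gd1_base + ch.gd1_amp * np.tanh(-(V + 20.0) / 20.0)
    tab[:, C_CHGR] = ch.gr_base * np.exp(-ch.gr_vdep * V)
    tab[:, C_PRYRG] = np.exp(-((V - 5.0) ** 2) / 648.0)

    tab.setflags(write=False)
    return tab


def build_tables(params: IonicParams | None = None, dt: float = 0.01):
    """Rate/current lookup table for the given parameter set and time step."""
    p = params or IonicParams()
    return _tables_cached(p, float(dt))


# ---------------------------------------------------------------------------
# Packed scalar parameters for the kernel
# ---------------------------------------------------------------------------
_PARAM_NAMES = [
    "Cm", "RTF", "Ko", "Nao", "Cao",
    "GCaL", "ECaL", "Kpcb", "Kpc_max", "Kpc_half", "ICaL_max",
    "GNa", "Gtof", "Gtos", "GKs", "GKur", "GKss", "GKr", "kf_Kr", "kb_Kr",
    "GK1", "INaK_max", "Km_Nai", "Km_Ko",
    "kNaCa_pref", "IpCa_max", "Km_pCa", "GCab", "GNab",
    "GClCa", "Km_Cl", "ECl",
    "LTRPN_tot", "HTRPN_tot", "k_plus_htrpn", "k_minus_htrpn",
    "k_plus_ltrpn", "k_minus_ltrpn",
    "CMDN_tot", "CSQN_tot", "Km_CMDN", "Km_CSQN",
    "v1", "v2", "v3", "Km_up", "tau_tr", "tau_xfer",
    "k_plus_a", "k_minus_a", "k_plus_b", "k_minus_b", "k_plus_c", "k_minus_c",
    "conv_cai", "conv_cass", "conv_v", "VJSR_Vss", "Vmyo_Vss",
    "Vmyo_VNSR", "VJSR_VNSR", "ksat",
    "g_chr2", "gamma_chr2", "chr2_gd2",
]
P = {name: i for i, name in enumerate(_PARAM_NAMES)}


def pack_params(params: IonicParams | None = None) -> np.ndarray:
    p = params or IonicParams()
    v = np.zeros(len(_PARAM_NAMES))

    def s(name, val):
        v[P[name]] = val

    s("Cm", p.Cm); s("RTF", p.RT_over_F)
    s("Ko", p.Ko); s("Nao", p.Nao); s("Cao", p.Cao)
    s("GCaL", p.GCaL); s("ECaL", p.ECaL); s("Kpcb", p.Kpcb)
    s("Kpc_max", p.Kpc_max); s("Kpc_half", p.Kpc_half)
    s("ICaL_max", p.ICaL_max)
    s("GNa", p.GNa); s("Gtof", p.Gtof); s("Gtos", p.Gtos)
    s("GKs", p.GKs); s("GKur", p.GKur); s("GKss", p.GKss)
    s("GKr", p.GKr); s("kf_Kr", p.kf_Kr); s("kb_Kr", p.kb_Kr)
    s("GK1", p.GK1 * p.Ko / (p.Ko + 210.0))
    s("INaK_max", p.INaK_max); s("Km_Nai", p.Km_Nai); s("Km_Ko", p.Km_Ko)
    s("kNaCa_pref", p.kNaCa / (p.Km_Na ** 3 + p.Nao ** 3) / (p.Km_Ca + p.Cao))
    s("IpCa_max", p.IpCa_max); s("Km_pCa", p.Km_pCa)
    s("GCab", p.GCab); s("GNab", p.GNab)
    s("GClCa", p.GClCa); s("Km_Cl", p.Km_Cl); s("ECl", p.ECl)
    s("LTRPN_tot", p.LTRPN_tot); s("HTRPN_tot", p.HTRPN_tot)
    s("k_plus_htrpn", p.k_plus_htrpn); s("k_minus_htrpn", p.k_minus_htrpn)
    s("k_plus_ltrpn", p.k_plus_ltrpn); s("k_minus_ltrpn", p.k_minus_ltrpn)
    s("CMDN_tot", p.CMDN_tot); s("CSQN_tot", p.CSQN_tot)
    s("Km_CMDN", p.Km_CMDN); s("Km_CSQN", p.Km_CSQN)
    s("v1", p.v1); s("v2", p.v2); s("v3", p.v3); s("Km_up", p.Km_up)
    s("tau_tr", p.tau_tr); s("tau_xfer", p.tau_xfer)
    s("k_plus_a", p.k_plus_a); s("k_minus_a", p.k_minus_a)
    s("k_plus_b", p.k_plus_b); s("k_minus_b", p.k_minus_b)
    s("k_plus_c", p.k_plus_c); s("k_minus_c", p.k_minus_c)
    s("conv_cai", p.Acap * p.Cm / (2.0 * p.Vmyo * p.F))
    s("conv_cass", p.Acap * p.Cm / (2.0 * p.Vss * p.F))
    s("conv_v", p.Acap * p.Cm / (p.Vmyo * p.F))
    s("VJSR_Vss", p.VJSR / p.Vss); s("Vmyo_Vss", p.Vmyo / p.Vss)
    s("Vmyo_VNSR", p.Vmyo / p.VNSR); s("VJSR_VNSR", p.VJSR / p.VNSR)
    s("ksat", p.ksat)
    s("g_chr2", p.chr2.g_chr2); s("gamma_chr2", p.chr2.gamma)
    s("chr2_gd2", p.chr2.gd2)
    v.setflags(write=False)
    return v


def light_rate_arrays(LI: np.ndarray, chr2: ChR2Params):
    """Per-node light-driven photocycle rates (k1, k2, e12, e21) in ms^-1.

    Light patterns in this package are piecewise constant in time, so these
    are recomputed only when the pattern switches.
    """
    LI = np.asarray(LI, dtype=np.float64)
    if np.any(LI < 0):
        raise ValueError("irradiance must be non-negative")
    F = chr2.flux_coeff * LI
    act = chr2.activation(LI)
    k1 = chr2.eps1 * F * act
    k2 = chr2.eps2 * F * act
    ratio = LI / chr2.e_irr_half
    e12 = chr2.e12_dark + chr2.e12_amp * np.log10(1.0 + ratio)
    e21 = chr2.e21_dark + chr2.e21_amp * np.log10(1.0 + ratio)
    return (np.ascontiguousarray(k1.ravel()), np.ascontiguousarray(k2.ravel()),
            np.ascontiguousarray(e12.ravel()), np.ascontiguousarray(e21.ravel()))
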