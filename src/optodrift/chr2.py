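"""Four-state channelrhodopsin-2 (ChR2) photocycle and photocurrent.

The photocycle has two closed states (C1 dark-adapted, C2 light-adapted) and
two open states (O1 high-conductance, O2 low-conductance):

        k1(LI)          e12(LI)
    C1 --------> O1 <----------> O2
     ^            |    e21(LI)    |
     | Gr(V)      | Gd1(V)        | Gd2
     |            v               v
    C2 <------------------------- .
          k2(LI) (C2 -> O2)

Light enters through the photon-absorption rates k1 = eps1*Fphi*p and
k2 = eps2*Fphi*p, where Fphi is the photon-absorption frequency per channel
(retinal cross-section x photon flux / loss factor) and p is a sigmoidal
light-activation function treated here as its algebraic steady state: its
~1 ms relaxation is far below every protocol timescale in this package.

The photocurrent is

    IChR2 = g_ChR2 * G(V) * (O1 + gamma * O2) * (V - E_ChR2),

with an empirical inward-rectifying G(V) and reversal near 0 mV, so the
current is inward (depolarizing) at diastolic voltages.

Units: ms, mV, mW/mm^2; current densities pA/pF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChR2Params", "chr2_rates", "chr2_derivatives", "chr2_step",
           "chr2_current", "dark_state"]

_H = 6.62607015e-34   # J s
_C = 2.99792458e8     # m/s


def _photon_flux_coeff(wavelength_nm: float, sigma_retinal_um2: float,
                       w_loss: float) -> float:
    """Absorption rate (ms^-1) per unit irradiance (mW/mm^2).

    irradiance -> photon flux via the photon energy h*c/lambda, then scaled
    by the retinal absorption cross-section and a protein loss factor.
    """
    e_photon = _H * _C / (wavelength_nm * 1e-9)            # J
    # 1 mW/mm^2 = 1e-3 J s^-1 mm^-2 = 1e-12 J ms^-1 um^-2
    flux_per_um2_ms = 1e-12 / e_photon                     # photons um^-2 ms^-1
    return sigma_retinal_um2 * flux_per_um2_ms / w_loss


@dataclass(frozen=True)
class ChR2Params:
    """Constants of the ChR2(H134R) photocycle and conductance.

    ``g_chr2`` sets the expression level; it is the one constant not fixed by
    the photocycle literature and is calibrated at tissue level so that
    0.02 mW/mm^2 sits in the sub-threshold regime with the documented CV/DF
    effects (see docs/methods.md).
    """

    g_chr2: float = 2.9          # mS/cm^2, maximal conductance (calibrated)
    gamma: float = 0.1           # O2/O1 conductance ratio
    E_chr2: float = 0.0          # mV

    # empirical rectification G(V) = (rect_a - rect_b*exp(-V/rect_v0))/V
    rect_a: float = 10.6408
    rect_b: float = 14.6408
    rect_v0: float = 42.7671     # mV

    wavelength_nm: float = 470.0
    sigma_retinal_um2: float = 1.2e-8
    w_loss: float = 1.3
    eps1: float = 0.8535         # quantum efficiency, C1 -> O1
    eps2: float = 0.14           # quantum efficiency, C2 -> O2

    # open-state closures and recovery
    gd1_base: float = 0.075      # ms^-1
    gd1_amp: float = 0.043
    gd2: float = 0.05            # ms^-1
    gr_base: float = 4.34e-5     # ms^-1
    gr_vdep: float = 0.0211539274

    # inter-open-state transitions, log-saturating in irradiance
    e12_dark: float = 0.011
    e12_amp: float = 0.005
    e21_dark: float = 0.008
    e21_amp: float = 0.004
    e_irr_half: float = 0.024    # mW/mm^2

    # light-activation function p = 0.5*(1 + tanh(sharp*(scale*LI - mid)))
    act_scale: float = 100.0     # 1/(mW/mm^2)
    act_sharp: float = 120.0
    act_mid: float = 0.1

    @property
    def flux_coeff(self) -> float:
        return _photon_flux_coeff(self.wavelength_nm, self.sigma_retinal_um2,
                                  self.w_loss)

    def activation(self, LI: float):
        theta = self.act_scale * LI
        return 0.5 * (1.0 + np.tanh(self.act_sharp * (theta - self.act_mid)))

    def rectification(self, V):
        """G(V); finite and positive over the physiological range."""
        Vs = np.where(np.abs(V) < 1e-6, 1e-6, V)
        return (self.rect_a - self.rect_b * np.exp(-Vs / self.rect_v0)) / Vs

    def current(self, V, O1, O2):
        """Photocurrent density (pA/pF); inward for V < E_chr2."""
        return (self.g_chr2 * self.rectification(V)
                * (O1 + self.gamma * O2) * (V - self.E_chr2))


def dark_state() -> np.ndarray:
    """Dark-adapted photocycle occupancies (C1, O1, O2, C2)."""
    return np.array([1.0, 0.0, 0.0, 0.0])


def chr2_rates(V, LI, p: ChR2Params):
    """All six transition rates (k1, k2, e12, e21, Gd1, Gd2, Gr) in ms^-1."""
    if np.any(np.asarray(LI) < 0):
        raise ValueError("irradiance must be non-negative")
    F = p.flux_coeff * LI
    act = p.activation(LI)
    k1 = p.eps1 * F * act
    k2 = p.eps2 * F * act
    ratio = LI / p.e_irr_half
    e12 = p.e12_dark + p.e12_amp * np.log10(1.0 + ratio)
    e21 = p.e21_dark + p.e21_amp * np.log10(1.0 + ratio)
    gd1 = p.gd1_base + p.gd1_amp * np.tanh(-(V + 20.0) / 20.0)
    gr = p.gr_base * np.exp(-p.gr_vdep * V)
    return k1, k2, e12, e21, gd1, p.gd2, gr


def chr2_derivatives(C1, O1, O2, C2, V, LI, p: ChR2Params):
    """Time derivatives of the photocycle occupancies (closed system)."""
    k1, k2, e12, e21, gd1, gd2, gr = chr2_rates(V, LI, p)
    dC1 = gr * C2 - k1 * C1 + gd1 * O1
    dO1 = k1 * C1 - (gd1 + e12) * O1 + e21 * O2
    dO2 = e12 * O1 - (e21 + gd2) * O2 + k2 * C2
    dC2 = gd2 * O2 - (k2 + gr) * C2
    return dC1, dO1, dO2, dC2


def chr2_step(chr2_state: np.ndarray, V: float, LI: float, dt: float,
              p: ChR2Params | None = None) -> np.ndarray:
    """Advance the photocycle one explicit step of length ``dt`` (ms).

    Probability is moved between states, so C1+O1+O2+C2 is conserved exactly.
    Raises if ``dt`` exceeds the explicit stability bound of the kinetics.
    """
    if p is None:
        p = ChR2Params()
    if dt <= 0:
        raise ValueError("dt must be positive")
    k1, k2, e12, e21, gd1, gd2, gr = chr2_rates(V, LI, p)
    max_exit = max(k1, gd1 + e12, e21 + gd2, k2 + gr)
    if dt * max_exit > 1.0:
        raise ValueError(
            f"dt = {dt} ms exceeds the stability bound "
            f"{1.0 / max_exit:.3g} ms for the ChR2 kinetics")
    C1, O1, O2, C2 = chr2_state
    d = chr2_derivatives(C1, O1, O2, C2, V, LI, p)
    return np.array([C1 + dt * d[0], O1 + dt * d[1],
                     O2 + dt * d[2], C2 + dt * d[3]])


def chr2_current(V: float, chr2_state: np.ndarray,
                 p: ChR2Params | None = None) -> float:
    """Photocurrent density for a given voltage and photocycle state."""
    if p is None:
        p = ChR2Params()
    state = np.asarray(chr2_state, dtype=float)
    if not np.all(np.isfinite(state)) or not np.isfinite(V):
        raise ValueError("non-finite input")
    _, O1, O2, _ = state
    return float(p.current(V, O1, O2))


def chr2_conductance_factor(V, p: ChR2Params):
    return p.rectification(V)
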