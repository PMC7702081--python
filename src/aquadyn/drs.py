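"""GHz-THz dielectric relaxation analysis.

The measured complex permittivity of an aqueous electrolyte over
~0.01-110 GHz is modelled by the two-mode Debye form

    eps(nu) = S1/(1 + i omega tau1) + S2/(1 + i omega tau2) + eps_inf,

with the slow (~20 GHz) reorientation mode (S1, tau1), the fast (~1 THz)
mode (S2, tau2) and the high-frequency permittivity eps_inf (fixed at 3.52
for salt solutions unless overridden).  Loss spectra are stored with the
dielectric loss eps'' positive; the Ohmic ion-conductivity term
sigma/(omega eps0) is removed before fitting.

The loss of total dielectric strength S = S1 + S2 relative to pure water is
decomposed into kinetic depolarization (ion drift dragging solvent
rotation; perfect-slip boundary condition) and static depolarization
(irrotationally bound slow waters); the static part, combined with the
dilution of the water concentration, yields the DRS hydration number N_hyd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "EPS0_SI",
    "DielectricSpectrum",
    "DebyeFit",
    "DepolarizationResult",
    "ProbeCalibration",
    "calibrate_probe",
    "remove_conductivity",
    "add_conductivity",
    "double_debye_eps",
    "fit_double_debye",
    "static_depolarization",
    "drs_hydration_number",
]

#: vacuum permittivity, F/m
EPS0_SI = 8.8541878128e-12


@dataclass
class DielectricSpectrum:
    """Complex permittivity vs frequency (GHz); eps_imag is the positive
    dielectric loss."""

    freq_GHz: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    conductivity: float = 0.0  # S/m
    concentration: float = 0.0  # mol/kg solute
    water_concentration: float = 55.35  # mol/L

    def __post_init__(self) -> None:
        self.freq_GHz = np.asarray(self.freq_GHz, dtype=float)
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        if np.any(np.diff(self.freq_GHz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def omega(self) -> np.ndarray:
        """Angular frequency in rad/s."""
        return 2.0 * np.pi * self.freq_GHz * 1e9


@dataclass
class DebyeFit:
    """Two-mode Debye decomposition (tau in ps; tau1 > tau2 enforced)."""

    S1: float
    S2: float
    tau1: float
    tau2: float
    eps_inf: float = 3.52
    residual: float = 0.0

    @property
    def strength(self) -> float:
        """Total dielectric strength S = S1 + S2."""
        return self.S1 + self.S2

    @property
    def static_permittivity(self) -> float:
        """Zero-frequency limit S1 + S2 + eps_inf."""
        return self.S1 + self.S2 + self.eps_inf


@dataclass
class DepolarizationResult:
    """Depolarization decomposition (positive-magnitude convention:
    dS_total = S(0) - S(c) >= 0 for a depolarized solution)."""

    dS_total: float
    dS_kinetic: float
    dS_static: float
    N_hyd: float | None = None
    negative_N_flagged: bool = False
    inputs: dict = field(default_factory=dict)


@dataclass
class ProbeCalibration:
    """Bilinear open-ended coaxial probe model eps = (A rho + C)/(1 + B rho)."""

    A: complex
    B: complex
    C: complex

    def apply(self, rho) -> np.ndarray:
        rho = np.asarray(rho)
        return (self.A * rho + self.C) / (1.0 + self.B * rho)

    def reflection(self, eps) -> np.ndarray:
        """Inverse map: reflection coefficient for a known permittivity."""
        eps = np.asarray(eps)
        return (eps - self.C) / (self.A - self.B * eps)


def calibrate_probe(standards: list[tuple[complex, complex]]) -> ProbeCalibration:
    """Solve the bilinear probe model from three (eps, rho) standards.

    eps (1 + B rho) = A rho + C is linear in (A, B, C); three distinct
    standards determine it exactly.
    """
    if len(standards) != 3:
        raise ValueError("exactly three calibration standards are required")
    M = np.zeros((3, 3), dtype=complex)
    rhs = np.zeros(3, dtype=complex)
    for k, (eps, rho) in enumerate(standards):
        M[k] = [rho, -eps * rho, 1.0]
        rhs[k] = eps
    if abs(np.linalg.det(M)) < 1e-12 * max(1.0, float(np.abs(M).max()) ** 3):
        raise ValueError("calibration standards are degenerate (singular system)")
    A, B, C = np.linalg.solve(M, rhs)
    return ProbeCalibration(A=A, B=B, C=C)


def remove_conductivity(spec: DielectricSpectrum) -> DielectricSpectrum:
    """Subtract the Ohmic loss sigma/(omega eps0) from the loss spectrum."""
    if spec.conductivity < 0:
        raise ValueError("conductivity must be non-negative")
    ohmic = spec.conductivity / (spec.omega * EPS0_SI)
    return DielectricSpectrum(
        freq_GHz=spec.freq_GHz.copy(),
        eps_real=spec.eps_real.copy(),
        eps_imag=spec.eps_imag - ohmic,
        conductivity=0.0,
        concentration=spec.concentration,
        water_concentration=spec.water_concentration,
    )


def add_conductivity(spec: DielectricSpectrum, sigma: float) -> DielectricSpectrum:
    """Inverse of :func:`remove_conductivity` (adds an Ohmic loss term)."""
    if sigma < 0:
        raise ValueError("conductivity must be non-negative")
    ohmic = sigma / (spec.omega * EPS0_SI)
    return DielectricSpectrum(
        freq_GHz=spec.freq_GHz.copy(),
        eps_real=spec.eps_real.copy(),
        eps_imag=spec.eps_imag + ohmic,
        conductivity=sigma,
        concentration=spec.concentration,
        water_concentration=spec.water_concentration,
    )


def double_debye_eps(
    freq_GHz, S1: float, S2: float, tau1_ps: float, tau2_ps: float, eps_inf: float
) -> tuple[np.ndarray, np.ndarray]:
    """(eps_real, eps_loss) of the two-mode Debye model on a GHz grid."""
    omega_tau1 = 2 * np.pi * np.asarray(freq_GHz, float) * 1e9 * tau1_ps * 1e-12
    omega_tau2 = 2 * np.pi * np.asarray(freq_GHz, float) * 1e9 * tau2_ps * 1e-12
    real = S1 / (1 + omega_tau1**2) + S2 / (1 + omega_tau2**2) + eps_inf
    loss = S1 * omega_tau1 / (1 + omega_tau1**2) + S2 * omega_tau2 / (1 + omega_tau2**2)
    return real, loss


def fit_double_debye(
    spec: DielectricSpectrum,
    eps_inf: float = 3.52,
    n_starts: int = 4,
) -> DebyeFit:
    """Joint least-squares fit of the real and loss parts to the Debye model.

    Equal absolute weights on both parts; S >= 0 and tau > 0 enforced;
    initial relaxation times at the ~20 GHz and ~1 THz mode centres with a
    few spread-out restarts; the slower mode is reported as mode 1.
    The spectrum must already be conductivity-corrected.
    """
    y = np.concatenate([spec.eps_real, spec.eps_imag])
    f = spec.freq_GHz
    s_total0 = max(float(spec.eps_real[0] - eps_inf), 1.0)

    def resid(p):
        real, loss = double_debye_eps(f, p[0], p[1], p[2], p[3], eps_inf)
        return np.concatenate([real, loss]) - y

    tau1_0 = 1e12 / (2 * np.pi * 20e9)   # ~7.96 ps (20 GHz mode)
    tau2_0 = 1e12 / (2 * np.pi * 1e12)   # ~0.159 ps (1 THz mode)
    best = None
    for scale in np.logspace(-0.3, 0.3, n_starts):
        x0 = [0.95 * s_total0, 0.05 * s_total0, tau1_0 * scale, tau2_0 / scale]
        try:
            sol = least_squares(
                resid, x0,
                bounds=([0, 0, 1e-4, 1e-4], [np.inf, np.inf, 1e4, 1e4]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("double-Debye fit failed to converge from any start")
    S1, S2, tau1, tau2 = best.x
    if tau1 < tau2:  # keep mode 1 the slower one
        S1, S2, tau1, tau2 = S2, S1, tau2, tau1
    return DebyeFit(
        S1=float(S1), S2=float(S2), tau1=float(tau1), tau2=float(tau2),
        eps_inf=eps_inf,
        residual=float(np.sqrt(2 * best.cost / y.size)),
    )


def static_depolarization(
    fit_c: DebyeFit,
    fit_0: DebyeFit,
    sigma_c: float,
    eps_s0: float | None = None,
    eps_inf_c: float | None = None,
    kinetic_numerator: str = "static0_minus_inf",
) -> DepolarizationResult:
    """Split the strength loss S(0) - S(c) into kinetic and static parts.

    Kinetic depolarization (perfect-slip boundary condition), fully in SI:

        dS_kin = (2/3) sigma(c) tau1(0) / eps0 * (eps_s(0) - eps_inf(c)) / eps_s(0)

    where tau1(0) is the slow-mode relaxation time of pure water and
    eps_s(0) its static permittivity.  ``kinetic_numerator`` switches the
    permittivity difference to ``(eps_s(c) - eps_inf(c))`` ("staticc_minus_inf")
    for sensitivity checks against the alternative reading of the formula.
    """
    if fit_0 is None:
        raise ValueError("a pure-water reference fit is required")
    if sigma_c < 0:
        raise ValueError("conductivity must be non-negative")
    if eps_s0 is None:
        eps_s0 = fit_0.static_permittivity
    if eps_inf_c is None:
        eps_inf_c = fit_c.eps_inf
    dS_total = fit_0.strength - fit_c.strength
    tau1_s = fit_0.tau1 * 1e-12
    if kinetic_numerator == "static0_minus_inf":
        num = eps_s0 - eps_inf_c
    elif kinetic_numerator == "staticc_minus_inf":
        num = fit_c.static_permittivity - eps_inf_c
    else:
        raise ValueError("unknown kinetic_numerator option")
    dS_kin = (2.0 / 3.0) * sigma_c * tau1_s / EPS0_SI * num / eps_s0
    return DepolarizationResult(
        dS_total=float(dS_total),
        dS_kinetic=float(dS_kin),
        dS_static=float(dS_total - dS_kin),
        inputs={
            "sigma_c_S_per_m": sigma_c,
            "tau1_0_ps": fit_0.tau1,
            "eps_s0": eps_s0,
            "eps_inf_c": eps_inf_c,
            "eps0_F_per_m": EPS0_SI,
        },
    )


def drs_hydration_number(
    dep: DepolarizationResult,
    c: float,
    cH2O_c: float,
    cH2O_0: float,
    S0: float,
) -> DepolarizationResult:
    """DRS hydration number: slow waters per dissolved salt unit.

        N_hyd = [cH2O(c) - (S(0) - dS_static)/S(0) * cH2O(0)] / c

    (S(0) - dS_static) is the bulk-like strength remaining in the solution
    after removing the kinetic contribution, so the bracket is the
    difference between the actual water concentration and the bulk-like
    water concentration inferred from the spectrum.  For a pure dilution
    (no slow waters) the two cancel and N_hyd = 0.  Negative values are
    reported and flagged rather than clipped.
    """
    if c <= 0:
        raise ValueError("solute concentration must be positive")
    if S0 <= 0:
        raise ValueError("S(0) must be positive")
    n_hyd = (cH2O_c - (S0 - dep.dS_static) / S0 * cH2O_0) / c
    dep.N_hyd = float(n_hyd)
    dep.negative_N_flagged = n_hyd < 0
    dep.inputs.update(
        {"c_mol_per_kg": c, "cH2O_c": cH2O_c, "cH2O_0": cH2O_0, "S0": S0}
    )
    return dep
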