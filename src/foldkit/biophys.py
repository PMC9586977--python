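"""Binding and oligomer biophysics: 1:1 ITC fitting and SEC-MALS.

Two independent experiments support the domain analysis:

* Isothermal titration calorimetry of the module construct titrated
  into its binding partner, fit with the exact single-site (1:1)
  mass-action isotherm.  Per injection, the bound-complex concentration
  in the cell follows the quadratic root of the mass balance

      [MX] = ((Mt + Xt + KD) - sqrt((Mt + Xt + KD)^2 - 4 Mt Xt)) / 2,

  where Mt = n·[cell species] and Xt are post-dilution totals.  The
  thermodynamic decomposition uses ΔG = −RT ln(1/K_D) and
  TΔS = ΔH − ΔG with R = 1.99 cal/(mol·K); these identities are
  enforced, never fitted.

* SEC-MALS molecular weights from Debye plots: per 1-s elution slice a
  straight line is fit to KC/Rθ against sin²(θ/2); the molecular weight
  is the reciprocal intercept, and a peak's weight is the
  concentration-weighted average over its slices.  In the dilute limit
  used here the second virial coefficient is neglected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "R_CAL",
    "ITCProtocol",
    "ITCExperiment",
    "BindingFit",
    "MALSSlice",
    "DebyeFit",
    "BiophysicsError",
    "predict_isotherm",
    "titration_state",
    "fit_itc",
    "debye_molecular_weight",
    "oligomeric_state",
]

#: Gas constant in cal/(mol·K), the value used for the ΔG identity.
R_CAL = 1.99


class BiophysicsError(ValueError):
    """Raised on non-physical parameters or malformed experiments."""


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ITCProtocol:
    """Instrument geometry of a titration.

    Defaults reproduce the reference experiment: 2 µL injections of
    1.6 mM titrant into a 350 µL cell holding 70 µM of the binding-site
    species, at 4 °C.
    """

    cell_conc: float = 70e-6          # M, species in the cell
    syringe_conc: float = 1.6e-3      # M, titrant
    cell_volume: float = 350e-6       # L
    injection_volumes: tuple[float, ...] = (2e-6,) * 20  # L each
    temperature: float = 277.15       # K

    def __post_init__(self) -> None:
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise BiophysicsError("concentrations must be positive")
        if self.cell_volume <= 0 or self.temperature <= 0:
            raise BiophysicsError("cell volume and temperature must be positive")
        if not self.injection_volumes or any(v <= 0 for v in self.injection_volumes):
            raise BiophysicsError("injection volumes must be positive")


@dataclass(frozen=True)
class ITCExperiment:
    """A baseline-corrected titration: protocol plus per-injection heats (µcal)."""

    protocol: ITCProtocol
    heats: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.heats) != len(self.protocol.injection_volumes):
            raise BiophysicsError(
                "need one heat per injection "
                f"({len(self.heats)} heats, {len(self.protocol.injection_volumes)} injections)"
            )


@dataclass(frozen=True)
class BindingFit:
    """Fitted 1:1 binding parameters with the derived thermodynamics.

    ΔG and TΔS are computed from the enforced identities at the
    experiment temperature; they carry no independent uncertainty.
    """

    n: float                   # stoichiometry (sites per cell species)
    k_d: float                 # M
    dh: float                  # kcal/mol
    dg: float                  # kcal/mol, = -RT ln(1/K_D)
    tds: float                 # kcal/mol, = ΔH - ΔG
    n_stderr: Optional[float] = None
    k_d_stderr: Optional[float] = None
    dh_stderr: Optional[float] = None
    converged: bool = True
    offset: float = 0.0        # µcal heat-of-dilution offset, if fitted


def _equilibrium_complex(m_tot: float, x_tot: float, k_d: float) -> float:
    """Bound-complex concentration from the 1:1 mass-action quadratic."""
    b = m_tot + x_tot + k_d
    disc = b * b - 4.0 * m_tot * x_tot
    mx = (b - math.sqrt(max(disc, 0.0))) / 2.0
    # guard rounding at the tight-binding limit
    return min(mx, m_tot, x_tot)


def titration_state(
    n: float, k_d: float, protocol: ITCProtocol
) -> pd.DataFrame:
    """Per-injection bookkeeping of the titration.

    Models each injection as instantaneous mixing at constant cell
    volume: the injected volume dV enters, the solution mixes, and dV
    of the mixed solution overflows.  Returns a table with, after every
    injection, the total cell concentrations, the equilibrium complex
    concentration, and the cumulative injected / displaced titrant
    moles (which balance exactly — this is the conservation law the
    model is built on).
    """
    if n <= 0 or k_d <= 0:
        raise BiophysicsError("n and K_D must be positive")
    v0 = protocol.cell_volume
    m = protocol.cell_conc       # total cell species, M
    x = 0.0                      # total titrant in cell, M
    displaced = 0.0              # mol titrant carried out by overflow
    injected = 0.0               # mol titrant delivered
    rows = []
    for i, dv in enumerate(protocol.injection_volumes, start=1):
        f = v0 / (v0 + dv)
        m = m * f
        x = (x * v0 + protocol.syringe_conc * dv) / (v0 + dv)
        injected += protocol.syringe_conc * dv
        displaced += x * dv
        mx = _equilibrium_complex(n * m, x, k_d)
        rows.append(
            {
                "injection": i,
                "volume_L": dv,
                "m_total_M": m,
                "x_total_M": x,
                "complex_M": mx,
                "injected_mol": injected,
                "cell_x_mol": x * v0,
                "displaced_mol": displaced,
            }
        )
    return pd.DataFrame(rows)


def predict_isotherm(
    n: float,
    k_d: float,
    dh: float,
    protocol: ITCProtocol,
    offset: float = 0.0,
) -> np.ndarray:
    """Per-injection heats (µcal) of an ideal 1:1 titration.

    ``dh`` is the molar binding enthalpy in kcal/mol.  The incremental
    heat of injection i is the change in cell-complex heat content with
    the standard displacement correction for the complex carried out in
    the overflow volume:

        q_i = Q_i − Q_{i−1} + (dV_i / V0)·(Q_i + Q_{i−1})/2,

    with Q_i = ΔH·V0·[MX]_i.  ``offset`` adds a constant
    heat-of-dilution term per injection (µcal, default 0).
    """
    if n <= 0 or k_d <= 0:
        raise BiophysicsError("n and K_D must be positive")
    state = titration_state(n, k_d, protocol)
    v0 = protocol.cell_volume
    dh_cal = dh * 1000.0  # kcal/mol -> cal/mol
    q_prev = 0.0
    heats = []
    for dv, mx in zip(protocol.injection_volumes, state["complex_M"]):
        q = dh_cal * v0 * mx  # cal
        dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
        heats.append(dq * 1e6 + offset)  # µcal
        q_prev = q
    return np.array(heats)


def thermodynamics(k_d: float, dh: float, temperature: float) -> tuple[float, float]:
    """ΔG and TΔS (kcal/mol) from ΔG = −RT ln(1/K_D), TΔS = ΔH − ΔG."""
    if k_d <= 0:
        raise BiophysicsError("K_D must be positive")
    dg = -R_CAL * temperature * math.log(1.0 / k_d) / 1000.0
    return dg, dh - dg


_KD_STARTS = tuple(10.0 ** e for e in (-8, -7, -6, -5, -4, -3))
_N_STARTS = (1.0, 0.5, 2.0)


def fit_itc(
    experiment: ITCExperiment,
    fit_offset: bool = False,
) -> BindingFit:
    """Nonlinear least-squares single-site fit of a titration.

    Fits (n, K_D, ΔH) — and optionally a constant heat-of-dilution
    offset — by Levenberg–Marquardt from a grid of starts (n ∈
    {0.5, 1, 2}, K_D log-spaced over 1e-8–1e-3 M, ΔH seeded from the
    first-injection heat), keeping the best-χ² solution.  K_D is fit in
    log10 space to keep it positive and well-scaled.  If no start
    converges the least-bad parameters are returned with
    ``converged=False``.
    """
    heats = np.asarray(experiment.heats, float)
    if len(heats) < 8:
        raise BiophysicsError("need at least 8 injections for a stable fit")
    protocol = experiment.protocol

    # ΔH guess from the first injection: q1 ≈ ΔH * moles injected
    mol_1 = protocol.syringe_conc * protocol.injection_volumes[0]
    dh_guess = (heats[0] * 1e-6) / mol_1 / 1000.0  # kcal/mol
    if not np.isfinite(dh_guess) or dh_guess == 0:
        dh_guess = -10.0

    def residuals(params: lmfit.Parameters) -> np.ndarray:
        model = predict_isotherm(
            params["n"].value,
            10.0 ** params["log10_kd"].value,
            params["dh"].value,
            protocol,
            offset=params["offset"].value if fit_offset else 0.0,
        )
        return model - heats

    best = None
    for n0 in _N_STARTS:
        for kd0 in _KD_STARTS:
            params = lmfit.Parameters()
            params.add("n", value=n0, min=1e-3, max=20.0)
            params.add("log10_kd", value=math.log10(kd0), min=-12.0, max=0.0)
            params.add("dh", value=dh_guess)
            if fit_offset:
                params.add("offset", value=0.0)
            else:
                params.add("offset", value=0.0, vary=False)
            try:
                res = lmfit.minimize(residuals, params, method="leastsq")
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res

    if best is None:
        raise BiophysicsError("all fit starts failed")

    p = best.params
    k_d = 10.0 ** p["log10_kd"].value
    dg, tds = thermodynamics(k_d, p["dh"].value, protocol.temperature)
    kd_stderr = None
    if p["log10_kd"].stderr is not None:
        # delta method: d(KD)/d(log10 KD) = KD ln 10
        kd_stderr = p["log10_kd"].stderr * k_d * math.log(10.0)
    return BindingFit(
        n=p["n"].value,
        k_d=k_d,
        dh=p["dh"].value,
        dg=dg,
        tds=tds,
        n_stderr=p["n"].stderr,
        k_d_stderr=kd_stderr,
        dh_stderr=p["dh"].stderr,
        converged=bool(best.success),
        offset=p["offset"].value,
    )


# ---------------------------------------------------------------------------
# SEC-MALS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MALSSlice:
    """One elution-time slice of a MALS trace.

    ``angles`` are detector angles in degrees with matching excess
    Rayleigh ratios ``r_theta``; ``k_optical`` is the instrument
    optical constant (with dn/dc folded in) such that, for an ideal
    monodisperse dilute solution with no angular dependence,
    K·C/Rθ = 1/MW.
    """

    time: float                    # s
    concentration: float           # g/mL
    angles: tuple[float, ...]      # degrees
    r_theta: tuple[float, ...]
    k_optical: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise BiophysicsError("concentration must be >= 0")
        if len(set(self.angles)) < 2:
            raise BiophysicsError("a Debye fit needs >= 2 distinct angles")
        if len(self.angles) != len(self.r_theta):
            raise BiophysicsError("angles and r_theta must align")


@dataclass(frozen=True)
class DebyeFit:
    """Per-slice and peak-averaged molecular weights (g/mol)."""

    slices: pd.DataFrame           # time, concentration, mw, valid
    peak_mw: dict[str, float]      # weight-average MW per peak window


def _slice_mw(s: MALSSlice) -> Optional[float]:
    x = np.sin(np.radians(np.asarray(s.angles, float)) / 2.0) ** 2
    y = s.k_optical * s.concentration / np.asarray(s.r_theta, float)
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0:
        return None
    return 1.0 / intercept


def debye_molecular_weight(
    slices: Sequence[MALSSlice],
    peaks: Optional[dict[str, tuple[float, float]]] = None,
) -> DebyeFit:
    """Molecular weight from Debye plots across an elution trace.

    Per slice, fits KC/Rθ against sin²(θ/2); the molecular weight is
    the reciprocal intercept.  Slices with a non-positive intercept or
    zero concentration are flagged invalid and excluded from averages.
    The peak value is the concentration-weighted (weight-average)
    molecular weight over the valid slices of each window; with no
    ``peaks`` a single window spanning the whole trace is used.
    """
    if not slices:
        raise BiophysicsError("no slices supplied")
    rows = []
    for s in slices:
        mw = _slice_mw(s) if s.concentration > 0 else None
        rows.append(
            {
                "time": s.time,
                "concentration": s.concentration,
                "mw": mw if mw is not None else np.nan,
                "valid": mw is not None,
            }
        )
    df = pd.DataFrame(rows).sort_values("time", ignore_index=True)

    if peaks is None:
        peaks = {"peak": (float(df["time"].min()), float(df["time"].max()))}
    peak_mw: dict[str, float] = {}
    for name, (t0, t1) in peaks.items():
        sel = df[(df["time"] >= t0) & (df["time"] <= t1) & df["valid"]]
        wsum = sel["concentration"].sum()
        if len(sel) == 0 or wsum <= 0:
            raise BiophysicsError(f"peak {name!r} contains no valid slices")
        peak_mw[name] = float((sel["concentration"] * sel["mw"]).sum() / wsum)
    return DebyeFit(slices=df, peak_mw=peak_mw)


def oligomeric_state(
    measured_mw: float,
    monomer_mw: float,
    tolerance: float = 0.15,
) -> Optional[int]:
    """Nearest integer oligomer of ``measured_mw`` over ``monomer_mw``.

    Returns the integer when the measured/monomer ratio lies within
    ``tolerance`` (relative, default 15%) of it, otherwise ``None``
    (ambiguous).  E.g. an ~80 kDa species of a 41 kDa monomer is a
    dimer.
    """
    if measured_mw <= 0 or monomer_mw <= 0:
        raise BiophysicsError("molecular weights must be positive")
    ratio = measured_mw / monomer_mw
    k = max(1, round(ratio))
    if abs(ratio / k - 1.0) <= tolerance:
        return int(k)
    return None
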