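"""CPMG relaxation dispersion: R2eff transforms, the Carver-Richards closed
form, and an explicit echo-train numerical oracle.

A constant-time CPMG experiment measures peak intensities after a fixed
relaxation period T_CPMG filled with refocusing pulses at varying pulsing
frequency nu_CPMG = 1/(4 tau_cp).  Chemical exchange broadening is
progressively refocused as nu_CPMG grows, producing a dispersion of the
effective transverse relaxation rate

    R2eff(nu) = -(1/T_CPMG) * ln(I_nu / I0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import InvalidInputError, InvalidParameterError
from .exchange import (
    ExchangeModelSpec,
    ExchangeTopology,
    FieldContext,
    build_rate_matrix,
    ppm_to_angular,
)

__all__ = [
    "CpmgProfile",
    "r2eff_from_intensity",
    "r2eff_sigma",
    "carver_richards_r2eff",
    "simulate_cpmg_numeric",
    "estimate_delta_i",
]


def r2eff_from_intensity(intensity, i0, t_cpmg_s):
    """R2eff = -(1/T_CPMG) ln(I/I0); monotone decreasing in I.

    Non-positive intensities signal a peak-picking failure and raise.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0) or i0 <= 0 or t_cpmg_s <= 0:
        raise InvalidInputError(
            "intensities, I0 and T_CPMG must all be > 0 "
            "(non-positive intensity indicates a peak-picking failure)"
        )
    return -np.log(intensity / i0) / t_cpmg_s


def r2eff_sigma(delta_i, intensity, t_cpmg_s):
    """R2eff uncertainty (1/T_CPMG)(dI/I) from the repeat-measurement intensity
    standard deviation ``delta_i``."""
    intensity = np.asarray(intensity, dtype=float)
    delta_i = np.asarray(delta_i, dtype=float)
    if np.any(intensity <= 0) or t_cpmg_s <= 0 or np.any(delta_i < 0):
        raise InvalidInputError("need intensity > 0, T_CPMG > 0 and delta_i >= 0")
    return (delta_i / intensity) / t_cpmg_s


@dataclass
class CpmgProfile:
    """One residue's CPMG intensities at one static field.

    ``is_repeat`` flags duplicate nu_CPMG measurements (kept as independent
    observations; they also feed the intensity-uncertainty estimate).
    ``delta_i`` may be set to a dataset-wide average intensity standard
    deviation; otherwise the profile's own repeats are used.
    """

    residue_id: str
    nu_cpmg_hz: np.ndarray
    intensities: np.ndarray
    i0: float
    t_cpmg_s: float
    field: FieldContext
    is_repeat: np.ndarray | None = None
    delta_i: float | None = None

    def __post_init__(self) -> None:
        self.nu_cpmg_hz = np.asarray(self.nu_cpmg_hz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n = self.nu_cpmg_hz.size
        if self.intensities.shape != (n,):
            raise InvalidInputError(
                f"residue {self.residue_id}: nu and intensity lengths differ"
            )
        if self.is_repeat is None:
            # mark second and later occurrences of a nu value
            seen: set[float] = set()
            rep = np.zeros(n, dtype=bool)
            for k, nu in enumerate(self.nu_cpmg_hz):
                rep[k] = nu in seen
                seen.add(float(nu))
            self.is_repeat = rep
        else:
            self.is_repeat = np.asarray(self.is_repeat, dtype=bool)
        if np.any(self.nu_cpmg_hz <= 0):
            raise InvalidInputError("nu_CPMG values must be > 0")
        if np.any(self.intensities <= 0) or self.i0 <= 0 or self.t_cpmg_s <= 0:
            raise InvalidInputError("intensities, I0 and T_CPMG must be > 0")

    @property
    def tau_cp_s(self) -> np.ndarray:
        """Delay between refocusing pulses: tau_cp = 1/(4 nu_CPMG)."""
        return 1.0 / (4.0 * self.nu_cpmg_hz)

    def r2eff(self) -> np.ndarray:
        return r2eff_from_intensity(self.intensities, self.i0, self.t_cpmg_s)

    def repeat_std(self) -> float:
        """Mean intensity standard deviation over duplicated nu values (nan if none)."""
        stds = []
        for nu in np.unique(self.nu_cpmg_hz):
            vals = self.intensities[self.nu_cpmg_hz == nu]
            if vals.size > 1:
                stds.append(np.std(vals, ddof=1))
        return float(np.mean(stds)) if stds else float("nan")

    def r2eff_sigma(self) -> np.ndarray:
        di = self.delta_i if self.delta_i is not None else self.repeat_std()
        if not np.isfinite(di):
            raise InvalidInputError(
                f"residue {self.residue_id}: no repeats and no delta_i given; "
                "cannot estimate R2eff uncertainties"
            )
        return r2eff_sigma(di, self.intensities, self.t_cpmg_s)


def estimate_delta_i(profiles) -> float:
    """Average repeat-measurement intensity std over a set of profiles."""
    stds = [p.repeat_std() for p in profiles]
    stds = [s for s in stds if np.isfinite(s)]
    if not stds:
        raise InvalidInputError("no duplicated nu_CPMG points in any profile")
    return float(np.mean(stds))


def _cr72(kex: float, p_e: float, dw_rad: float, r2_0, nu_hz) -> np.ndarray:
    """Carver-Richards R2eff for a two-state exchange, all regimes.

    Shared intrinsic R2 for both states.  Evaluated through a log-scaled
    branch for large arguments, so it never overflows for physical inputs.
    """
    nu = np.atleast_1d(np.asarray(nu_hz, dtype=float))
    r2_0 = np.broadcast_to(np.asarray(r2_0, dtype=float), nu.shape)
    if p_e <= 0.0 or dw_rad == 0.0 or kex <= 0.0:
        return r2_0.copy()
    p_g = 1.0 - p_e
    psi = kex * kex - dw_rad * dw_rad
    zeta = -2.0 * dw_rad * kex * (p_g - p_e)
    root = math.hypot(psi, zeta)
    if root == 0.0:  # pathological kex == |dw| with p_g == p_e
        root = 1e-12
    dplus = 0.5 * (1.0 + (psi + 2.0 * dw_rad * dw_rad) / root)
    dminus = 0.5 * (-1.0 + (psi + 2.0 * dw_rad * dw_rad) / root)
    etap = np.sqrt(max(root + psi, 0.0)) / (2.0 * math.sqrt(2.0) * nu)
    etam = np.sqrt(max(root - psi, 0.0)) / (2.0 * math.sqrt(2.0) * nu)

    small = etap < 20.0
    acosh_term = np.empty_like(nu)
    if np.any(small):
        x = dplus * np.cosh(etap[small]) - dminus * np.cos(etam[small])
        acosh_term[small] = np.arccosh(np.maximum(x, 1.0))
    if np.any(~small):
        ep = etap[~small]
        inner = dplus * (1.0 + np.exp(-2.0 * ep)) - 2.0 * dminus * np.cos(
            etam[~small]
        ) * np.exp(-ep)
        acosh_term[~small] = ep + np.log(np.maximum(inner, 1e-300))
    return r2_0 + 0.5 * kex - nu * acosh_term


def carver_richards_r2eff(
    spec: ExchangeModelSpec,
    nu_cpmg_hz,
    field: FieldContext,
    r2_0,
) -> np.ndarray:
    """Closed-form R2eff(nu_CPMG) for a two-state exchanging 15N spin.

    ``r2_0`` is the intrinsic transverse relaxation rate (s^-1), shared by
    ground and excited state; it may be a scalar or per-point array.  Reduces
    to ``r2_0`` when p_E = 0 or delta-omega = 0.
    """
    if spec.topology is not ExchangeTopology.TWO_STATE:
        raise InvalidParameterError(
            "Carver-Richards closed form applies to two-state exchange only"
        )
    nu = np.atleast_1d(np.asarray(nu_cpmg_hz, dtype=float))
    if np.any(nu <= 0):
        raise InvalidParameterError("nu_CPMG must be > 0")
    dw = spec.delta_omega_rad(field)
    return _cr72(spec.kex_edges[0], float(spec.populations[1]), dw, r2_0, nu)


def simulate_cpmg_numeric(
    spec: ExchangeModelSpec,
    nu_cpmg_hz,
    t_cpmg_s: float,
    field: FieldContext,
    r2_0: float,
) -> np.ndarray:
    """Explicit echo-train propagation oracle for R2eff(nu_CPMG).

    Transverse magnetization of all states is propagated through
    ``n = T_CPMG * nu_CPMG`` blocks of (tau - 180 - 2 tau - 180 - tau) with
    tau = 1/(4 nu), using free-precession-plus-exchange matrix exponentials
    and ideal refocusing pulses (complex conjugation).  The surviving
    ground-state coherence is converted to R2eff via
    :func:`r2eff_from_intensity`.  Supports any number of states.
    """
    nu = np.atleast_1d(np.asarray(nu_cpmg_hz, dtype=float))
    K = build_rate_matrix(spec)
    omega = ppm_to_angular(spec.shifts_ppm - spec.shifts_ppm[0], field)
    A = K + np.diag(1j * omega - r2_0)
    p = spec.populations.astype(complex)
    out = np.empty(nu.shape)
    for k, v in enumerate(nu):
        n_blocks = t_cpmg_s * v
        if abs(n_blocks - round(n_blocks)) > 1e-6 or round(n_blocks) < 1:
            raise InvalidInputError(
                f"T_CPMG * nu_CPMG = {n_blocks} is not a positive integer "
                "number of echo blocks"
            )
        n_blocks = int(round(n_blocks))
        tau = 1.0 / (4.0 * v)
        e1 = scipy.linalg.expm(A * tau)
        e2 = scipy.linalg.expm(A * 2.0 * tau)
        cycle = e1 @ np.conj(e2) @ e1
        m = np.linalg.matrix_power(cycle, n_blocks) @ p
        out[k] = r2eff_from_intensity(abs(m[0]), spec.populations[0], t_cpmg_s)
    return out
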