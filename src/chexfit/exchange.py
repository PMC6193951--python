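"""Kinetic models of chemical exchange between protein conformational states.

This module is the single home of the exchange bookkeeping used throughout
the package: state topologies (two-state and the three linear three-state
schemes), populations, chemical shifts, apparent exchange rates, and the
first-order rate matrices they imply.

Conventions
-----------
* States are ordered ground first: ``("G", "E")`` or ``("G", "E1", "E2")``.
* Each allowed edge carries one *apparent* exchange rate
  ``k_ex = k_forward + k_backward`` (s^-1); the directional rates follow from
  detailed balance across that edge, e.g. for the two-state scheme
  ``k_GE = k_ex * p_E`` and ``k_EG = k_ex * p_G``.
* Chemical shifts are absolute ppm on the 15N scale; conversion to angular
  frequency uses the gyromagnetic-ratio magnitude below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "GAMMA_RATIO_15N_1H",
    "ExchangeTopology",
    "FieldContext",
    "ExchangeModelSpec",
    "rates_from_kex_p",
    "kex_p_from_rates",
    "build_rate_matrix",
    "ppm_to_angular",
]

#: Magnitude of gamma(15N)/gamma(1H) = 0.101329118 (unitless).  The 15N
#: gyromagnetic ratio is negative; only the magnitude enters any quantity
#: computed here (|Delta omega|, nutation frequencies), so the sign is
#: dropped by convention and documented once, here.
GAMMA_RATIO_15N_1H = 0.101329118


class ExchangeTopology(Enum):
    """Supported exchange schemes between a ground state G and excited states.

    The three-state schemes are linear: exactly two edges and no direct
    exchange between the two terminal states.
    """

    TWO_STATE = "G<=>E"
    THREE_G_E1_E2 = "G<=>E1<=>E2"
    THREE_G_E2_E1 = "G<=>E2<=>E1"
    THREE_E1_G_E2 = "E1<=>G<=>E2"

    @property
    def states(self) -> tuple[str, ...]:
        if self is ExchangeTopology.TWO_STATE:
            return ("G", "E")
        return ("G", "E1", "E2")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        """Allowed exchange edges as ordered (i, j) state-index pairs.

        The pair order defines which apparent rate in
        :attr:`ExchangeModelSpec.kex_edges` belongs to which edge.
        """
        if self is ExchangeTopology.TWO_STATE:
            return ((0, 1),)
        if self is ExchangeTopology.THREE_G_E1_E2:
            return ((0, 1), (1, 2))  # G-E1, E1-E2
        if self is ExchangeTopology.THREE_G_E2_E1:
            return ((0, 2), (2, 1))  # G-E2, E2-E1
        return ((0, 1), (0, 2))  # E1-G, G-E2


@dataclass(frozen=True)
class FieldContext:
    """Static-field context of a spectrometer, stated as the 1H frequency.

    The 15N frequency is derived from the documented gyromagnetic-ratio
    magnitude: a 600-MHz spectrometer observes 15N at ~60.8 MHz.
    """

    proton_mhz: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.proton_mhz) and self.proton_mhz > 0):
            raise InvalidParameterError(
                f"proton frequency must be positive and finite, got {self.proton_mhz}"
            )

    @property
    def nitrogen_mhz(self) -> float:
        return self.proton_mhz * GAMMA_RATIO_15N_1H

    def __repr__(self) -> str:  # compact, used in log lines
        return f"FieldContext({self.proton_mhz:g} MHz 1H)"


def ppm_to_angular(delta_ppm, field: FieldContext):
    """Convert a 15N chemical-shift value or difference from ppm to rad/s.

    ppm times the 15N Larmor frequency in MHz gives Hz; times 2*pi gives
    rad/s.  Linear in ``delta_ppm``; accepts scalars or arrays.
    """
    return 2.0 * math.pi * np.asarray(delta_ppm, dtype=float) * field.nitrogen_mhz


def rates_from_kex_p(k_ex: float, p_G: float, p_E: float) -> tuple[float, float]:
    """Decompose an apparent two-state exchange rate into directional rates.

    ``k_GE = k_ex * p_E`` (ground -> excited) and ``k_EG = k_ex * p_G``, so
    that ``k_GE + k_EG = k_ex`` and the stationary flux balance
    ``p_G * k_GE = p_E * k_EG`` holds exactly.
    """
    if not np.isfinite(k_ex) or k_ex < 0:
        raise InvalidParameterError(f"k_ex must be >= 0, got {k_ex}")
    for name, p in (("p_G", p_G), ("p_E", p_E)):
        if not np.isfinite(p) or p < 0 or p > 1:
            raise InvalidParameterError(f"{name} must lie in [0, 1], got {p}")
    if abs(p_G + p_E - 1.0) > 1e-6:
        raise InvalidParameterError(f"p_G + p_E must equal 1, got {p_G + p_E}")
    return k_ex * p_E, k_ex * p_G


def kex_p_from_rates(k_GE: float, k_EG: float) -> tuple[float, float]:
    """Inverse of :func:`rates_from_kex_p`: ``(k_GE, k_EG) -> (k_ex, p_E)``."""
    if k_GE < 0 or k_EG < 0:
        raise InvalidParameterError("directional rates must be >= 0")
    k_ex = k_GE + k_EG
    if k_ex == 0.0:
        return 0.0, 0.0
    return k_ex, k_GE / k_ex


def _edge_rates(k_ex: float, p_i: float, p_j: float) -> tuple[float, float]:
    """Directional rates across one edge from its apparent rate.

    Flux balance across the edge, ``p_i * k_ij = p_j * k_ji``, together with
    ``k_ij + k_ji = k_ex`` gives ``k_ij = k_ex * p_j / (p_i + p_j)``.  For a
    two-state system (p_i + p_j = 1) this reduces to ``k_GE = k_ex * p_E``.
    """
    tot = p_i + p_j
    if tot <= 0:
        return 0.0, 0.0
    return k_ex * p_j / tot, k_ex * p_i / tot


@dataclass
class ExchangeModelSpec:
    """Full parameterization of one exchange model.

    Parameters
    ----------
    topology : ExchangeTopology
    populations : sequence of float
        Per-state fractional populations, ground first.  Must be
        non-negative and sum to 1 (renormalized if within 1e-6).
    shifts_ppm : sequence of float
        Per-state absolute 15N chemical shifts (ppm).
    kex_edges : sequence of float
        Apparent exchange rate (s^-1, forward + backward) per topology edge,
        in :attr:`ExchangeTopology.edges` order.
    r1 : float
        Longitudinal relaxation rate (s^-1), shared by all states.
    r2 : float or sequence of float
        Transverse relaxation rate (s^-1); a scalar is shared by all states,
        a sequence gives one value per state.
    """

    topology: ExchangeTopology
    populations: np.ndarray
    shifts_ppm: np.ndarray
    kex_edges: tuple[float, ...]
    r1: float = 1.2
    r2: float | Sequence[float] = 10.0

    def __post_init__(self) -> None:
        n = self.topology.n_states
        self.populations = np.asarray(self.populations, dtype=float)
        self.shifts_ppm = np.asarray(self.shifts_ppm, dtype=float)
        self.kex_edges = tuple(float(k) for k in np.atleast_1d(self.kex_edges))
        if self.populations.shape != (n,) or self.shifts_ppm.shape != (n,):
            raise InvalidParameterError(
                f"{self.topology.name} needs {n} populations and shifts"
            )
        if len(self.kex_edges) != len(self.topology.edges):
            raise InvalidParameterError(
                f"{self.topology.name} needs {len(self.topology.edges)} edge rates"
            )
        if np.any(self.populations < 0) or not np.all(np.isfinite(self.populations)):
            raise InvalidParameterError("populations must be finite and >= 0")
        s = self.populations.sum()
        if abs(s - 1.0) > 1e-6:
            raise InvalidParameterError(f"populations must sum to 1, got {s}")
        self.populations = self.populations / s
        if not np.all(np.isfinite(self.shifts_ppm)):
            raise InvalidParameterError("shifts must be finite")
        if any(k < 0 or not np.isfinite(k) for k in self.kex_edges):
            raise InvalidParameterError("edge k_ex values must be finite and >= 0")
        if not (np.isfinite(self.r1) and self.r1 >= 0):
            raise InvalidParameterError(f"r1 must be >= 0, got {self.r1}")
        r2 = np.broadcast_to(np.asarray(self.r2, dtype=float), (n,)).copy()
        if np.any(r2 < 0) or not np.all(np.isfinite(r2)):
            raise InvalidParameterError("r2 must be finite and >= 0")
        self._r2_states = r2

    # -- derived quantities -------------------------------------------------

    @property
    def n_states(self) -> int:
        return self.topology.n_states

    @property
    def r2_states(self) -> np.ndarray:
        """Per-state transverse relaxation rates (s^-1)."""
        return self._r2_states

    def edge_rates(self, edge_index: int = 0) -> tuple[float, float]:
        """Directional (forward, backward) rates for one topology edge."""
        i, j = self.topology.edges[edge_index]
        return _edge_rates(
            self.kex_edges[edge_index], self.populations[i], self.populations[j]
        )

    @property
    def k_GE(self) -> float:
        """Ground -> excited rate of the first edge (two-state convenience)."""
        return self.edge_rates(0)[0]

    @property
    def k_EG(self) -> float:
        return self.edge_rates(0)[1]

    def delta_omega_ppm(self, state: int = 1, reference: int = 0) -> float:
        """Signed shift difference delta(state) - delta(reference) in ppm."""
        return float(self.shifts_ppm[state] - self.shifts_ppm[reference])

    def delta_omega_rad(self, field: FieldContext, state: int = 1, reference: int = 0) -> float:
        return float(ppm_to_angular(self.delta_omega_ppm(state, reference), field))

    # -- constructors --------------------------------------------------------

    @classmethod
    def two_state(
        cls,
        k_ex: float,
        p_E: float,
        delta_G_ppm: float = 0.0,
        delta_E_ppm: float | None = None,
        dw_ppm: float | None = None,
        r1: float = 1.2,
        r2: float | Sequence[float] = 10.0,
    ) -> "ExchangeModelSpec":
        """Two-state spec from (k_ex, p_E); give either delta_E_ppm or dw_ppm."""
        if (delta_E_ppm is None) == (dw_ppm is None):
            raise InvalidParameterError("give exactly one of delta_E_ppm or dw_ppm")
        if delta_E_ppm is None:
            delta_E_ppm = delta_G_ppm + dw_ppm
        return cls(
            ExchangeTopology.TWO_STATE,
            np.array([1.0 - p_E, p_E]),
            np.array([delta_G_ppm, delta_E_ppm]),
            (k_ex,),
            r1=r1,
            r2=r2,
        )

    @classmethod
    def three_state(
        cls,
        topology: ExchangeTopology,
        p_E1: float,
        p_E2: float,
        kex_1: float,
        kex_2: float,
        shifts_ppm: Sequence[float],
        r1: float = 1.2,
        r2: float | Sequence[float] = 10.0,
    ) -> "ExchangeModelSpec":
        """Three-state spec; edge rates follow :attr:`ExchangeTopology.edges` order."""
        if topology is ExchangeTopology.TWO_STATE:
            raise InvalidParameterError("use two_state() for the two-state topology")
        return cls(
            topology,
            np.array([1.0 - p_E1 - p_E2, p_E1, p_E2]),
            np.asarray(shifts_ppm, dtype=float),
            (kex_1, kex_2),
            r1=r1,
            r2=r2,
        )


def build_rate_matrix(spec: ExchangeModelSpec) -> np.ndarray:
    """First-order exchange rate matrix K (s^-1) with dp/dt = K p.

    Off-diagonal element ``K[i, j]`` is the rate j -> i for allowed edges and
    0 otherwise; diagonal elements make every column sum to zero (population
    conservation).  By the detailed-balance construction of the directional
    rates, the stationary vector of K equals ``spec.populations``.
    """
    n = spec.n_states
    K = np.zeros((n, n))
    for e, (i, j) in enumerate(spec.topology.edges):
        k_ij, k_ji = spec.edge_rates(e)  # i->j, j->i
        K[j, i] += k_ij
        K[i, j] += k_ji
    K[np.diag_indices(n)] -= K.sum(axis=0)
    return K
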