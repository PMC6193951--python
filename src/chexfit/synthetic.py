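"""Synthetic CEST, CPMG and titration datasets at the published acquisition
settings and truth parameters, so every pipeline stage is testable without
any experimental download.

Acquisition presets (immutable, see :data:`PRESETS`):

``paper_cest_600``
    191 carrier offsets from 100 to 138 ppm at 0.2 ppm spacing, B1 = 8.4 and
    13.5 Hz (each +/- 0.2 Hz), T_EX = 800 ms, 600 MHz.
``paper_cpmg_arsc`` / ``paper_cpmg_trx`` / ``paper_cpmg_complex``
    nu_CPMG ladder 50, 100 (x2), 150, 200, 250, 300, 350, 400, 450, 500,
    600, 750 Hz (13 measurements, one duplicate) at 600 and 800 MHz, with
    T_CPMG = 60, 80 and 40 ms respectively.

Truth scenarios encode the published group-level kinetic parameters of the
arsenate-reductase system (see :data:`PUBLISHED_GROUPS`).  Quantities the source
tables do not pin per residue -- |dw|, absolute shifts, intrinsic R1/R2 --
are drawn once per scenario from documented physically typical ranges.

Noise model: CPMG intensities carry multiplicative Gaussian noise
(sigma_rel, default 2%); CEST ratios carry additive Gaussian noise of
standard deviation sigma_rel (default 1%) on the I/I0 scale, i.e. intensity
noise relative to the reference intensity.  Every generator is a pure
function of (scenario, preset, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

from .binding import TitrationSeries
from .cest import CestProfile, simulate_cest
from .cpmg import CpmgProfile, carver_richards_r2eff
from .errors import InvalidParameterError
from .exchange import ExchangeModelSpec, ExchangeTopology, FieldContext

__all__ = [
    "AcquisitionPreset",
    "TruthScenario",
    "PRESETS",
    "PUBLISHED_GROUPS",
    "cpmg_group_scenario",
    "cest_two_state_scenario",
    "cest_three_state_scenario",
    "generate_cpmg_dataset",
    "generate_cest_dataset",
    "generate_titration",
]


@dataclass(frozen=True)
class AcquisitionPreset:
    """Immutable description of one acquisition scheme.

    CEST-only presets leave the CPMG fields None and vice versa.
    """

    name: str
    fields: tuple[FieldContext, ...]
    cest_offsets_ppm: tuple[float, ...] | None = None
    cest_b1_hz: tuple[float, ...] | None = None
    cest_b1_sigma_hz: float = 0.0
    cest_t_ex_s: float | None = None
    cpmg_nu_hz: tuple[float, ...] | None = None  # repeats appear twice
    cpmg_t_cpmg_s: float | None = None


_CEST_OFFSETS = tuple(np.round(np.linspace(100.0, 138.0, 191), 10))
_CPMG_NU = (50.0, 100.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0, 450.0, 500.0, 600.0, 750.0)

PRESETS: Mapping[str, AcquisitionPreset] = MappingProxyType(
    {
        "paper_cest_600": AcquisitionPreset(
            name="paper_cest_600",
            fields=(FieldContext(600.0),),
            cest_offsets_ppm=_CEST_OFFSETS,
            cest_b1_hz=(8.4, 13.5),
            cest_b1_sigma_hz=0.2,
            cest_t_ex_s=0.8,
        ),
        "paper_cpmg_arsc": AcquisitionPreset(
            name="paper_cpmg_arsc",
            fields=(FieldContext(600.0), FieldContext(800.0)),
            cpmg_nu_hz=_CPMG_NU,
            cpmg_t_cpmg_s=0.06,
        ),
        "paper_cpmg_trx": AcquisitionPreset(
            name="paper_cpmg_trx",
            fields=(FieldContext(600.0), FieldContext(800.0)),
            cpmg_nu_hz=_CPMG_NU,
            cpmg_t_cpmg_s=0.08,
        ),
        "paper_cpmg_complex": AcquisitionPreset(
            name="paper_cpmg_complex",
            fields=(FieldContext(600.0), FieldContext(800.0)),
            cpmg_nu_hz=_CPMG_NU,
            cpmg_t_cpmg_s=0.04,
        ),
    }
)

#: Published group-level CPMG kinetic parameters: residues, k_ex (s^-1), p_E.
PUBLISHED_GROUPS: Mapping[str, dict] = MappingProxyType(
    {
        "A": {
            "residues": (11, 12, 13, 15, 16, 17, 38, 39, 40, 65, 66, 67),
            "k_ex": 870.0,
            "p_E": 0.0052,
            "state": "re-ArsC.sulfate",
        },
        "K": {
            "residues": (18, 34, 36, 43, 45, 63),
            "k_ex": 328.0,
            "p_E": 0.0128,
            "state": "re-ArsC.sulfate",
        },
        "R": {
            "residues": (81, 88),
            "k_ex": 40.0,
            "p_E": 0.066,
            "state": "re-ArsC.sulfate",
        },
        "70": {
            "residues": (68, 70, 72, 73, 74, 78),
            "k_ex": 269.0,
            "p_E": 0.019,
            "state": "re-ArsC.sulfate",
        },
        "int_conf1": {
            "residues": (
                "7", "8", "9", "20", "22", "24", "34", "35", "50", "62",
                "68-1", "73", "74", "78", "79-1", "85", "96", "98-1", "102", "104",
            ),
            "k_ex": 685.0,
            "p_E": 0.049,
            "state": "int-ArsC",
        },
        "int_conf2": {
            "residues": (
                "7", "8", "9", "20", "22", "24", "34", "35", "50", "62",
                "68-2", "73", "74", "78", "79-2", "85", "96", "98-2", "99-2", "102", "104",
            ),
            "k_ex": 681.0,
            "p_E": 0.049,
            "state": "int-ArsC",
        },
        "c": {
            "residues": (
                10, 12, 13, 15, 16, 17, 18, 20, 36, 39, 45, 65, 67, 80,
                82, 83, 87, 88, 89, 95, 96, 97, 100, 101, 102,
            ),
            "k_ex": 443.0,
            "p_E": 0.028,
            "state": "c-ArsC",
        },
    }
)


@dataclass(frozen=True)
class TruthScenario:
    """Per-residue truth models plus a noise level and a seed.

    ``specs`` maps residue id to its :class:`ExchangeModelSpec`; ``r2_0``
    maps residue id to a per-field intrinsic R2 (CPMG nuisance truth).
    """

    name: str
    specs: Mapping[str, ExchangeModelSpec]
    r2_0: Mapping[str, Mapping[float, float]]
    sigma_rel_cpmg: float = 0.02
    sigma_rel_cest: float = 0.01
    seed: int = 0


# physically typical draws for quantities the source tables do not pin
_DW_CPMG_PPM = (1.0, 4.0)      # |dw| range, uniform
_R2_0_RANGE = (10.0, 20.0)     # intrinsic 15N R2 at these fields, s^-1
_SHIFT_RANGE = (106.0, 132.0)  # backbone 15N shifts, ppm
_R1_DEFAULT = 1.2              # s^-1
_R2_CEST_DEFAULT = 11.0        # s^-1


def cpmg_group_scenario(
    group: str = "A",
    seed: int = 0,
    sigma_rel: float = 0.02,
    fields: Sequence[float] = (600.0, 800.0),
) -> TruthScenario:
    """Truth scenario for one published CPMG group.

    Each member residue gets the group's shared (k_ex, p_E), its own |dw|
    drawn uniformly from 1-4 ppm, and its own per-field intrinsic R2_0 drawn
    uniformly from 10-20 s^-1 (all from ``seed``).
    """
    if group not in PUBLISHED_GROUPS:
        raise InvalidParameterError(
            f"unknown group {group!r}; choose from {sorted(PUBLISHED_GROUPS)}"
        )
    info = PUBLISHED_GROUPS[group]
    rng = np.random.default_rng(seed)
    specs: dict[str, ExchangeModelSpec] = {}
    r2_0: dict[str, dict[float, float]] = {}
    for res in info["residues"]:
        res = str(res)
        dw = rng.uniform(*_DW_CPMG_PPM)
        delta_g = rng.uniform(*_SHIFT_RANGE)
        specs[res] = ExchangeModelSpec.two_state(
            k_ex=info["k_ex"], p_E=info["p_E"],
            delta_G_ppm=delta_g, dw_ppm=dw,
            r1=_R1_DEFAULT, r2=_R2_CEST_DEFAULT,
        )
        r2_0[res] = {f: rng.uniform(*_R2_0_RANGE) for f in fields}
    return TruthScenario(
        name=f"cpmg_group_{group}",
        specs=specs,
        r2_0=r2_0,
        sigma_rel_cpmg=sigma_rel,
        seed=seed,
    )


def cest_two_state_scenario(
    seed: int = 0,
    n_residues: int = 1,
    k_ex: float = 300.0,
    p_E: float = 0.02,
    sigma_rel: float = 0.01,
) -> TruthScenario:
    """Two-state CEST truth: a slow conformational exchange with a visible
    minor dip (defaults k_ex = 300 s^-1, p_E = 2%)."""
    rng = np.random.default_rng(seed)
    specs, r2_0 = {}, {}
    for i in range(n_residues):
        res = f"R{i + 1}"
        delta_g = rng.uniform(112.0, 126.0)
        dw = rng.uniform(1.5, 3.0) * rng.choice([-1.0, 1.0])
        specs[res] = ExchangeModelSpec.two_state(
            k_ex=k_ex, p_E=p_E, delta_G_ppm=delta_g, dw_ppm=float(dw),
            r1=_R1_DEFAULT, r2=_R2_CEST_DEFAULT,
        )
        r2_0[res] = {}
    return TruthScenario(
        name="cest_two_state", specs=specs, r2_0=r2_0,
        sigma_rel_cest=sigma_rel, seed=seed,
    )


def cest_three_state_scenario(
    seed: int = 0,
    n_residues: int = 1,
    kex_1: float = 120.0,
    kex_2: float = 300.0,
    p_E1: float = 0.048,
    p_E2: float = 0.015,
    sigma_rel: float = 0.01,
) -> TruthScenario:
    """Linear G<=>E1<=>E2 CEST truth in the published regime.

    Defaults: the ligand-binding edge at k_ex ~ 120 s^-1 with the free-form
    population p_E1 = 4.8% (a 20 mM ligand at K_d ~ 1 mM), and a
    conformational edge at k_ex ~ 300 s^-1 with p_E2 = 1.5% (the smaller
    third dip).
    """
    rng = np.random.default_rng(seed)
    specs, r2_0 = {}, {}
    for i in range(n_residues):
        res = f"R{i + 1}"
        delta_g = rng.uniform(112.0, 126.0)
        dw1 = rng.uniform(1.5, 3.0) * rng.choice([-1.0, 1.0])
        dw2 = rng.uniform(1.5, 3.0) * rng.choice([-1.0, 1.0])
        if abs(dw1 - dw2) < 1.0:  # keep the two minor dips resolvable
            dw2 = -dw2
        specs[res] = ExchangeModelSpec.three_state(
            ExchangeTopology.THREE_G_E1_E2,
            p_E1=p_E1, p_E2=p_E2, kex_1=kex_1, kex_2=kex_2,
            shifts_ppm=[delta_g, delta_g + float(dw1), delta_g + float(dw2)],
            r1=_R1_DEFAULT, r2=_R2_CEST_DEFAULT,
        )
        r2_0[res] = {}
    return TruthScenario(
        name="cest_three_state", specs=specs, r2_0=r2_0,
        sigma_rel_cest=sigma_rel, seed=seed,
    )


def generate_cpmg_dataset(
    scenario: TruthScenario,
    preset: AcquisitionPreset,
    seed: int | None = None,
    i0: float = 1.0e5,
) -> dict[str, list[CpmgProfile]]:
    """Simulate CPMG intensity ladders for every residue of a scenario.

    intensity = I0 * exp(-R2eff_model * T_CPMG) * (1 + eps) with
    eps ~ N(0, sigma_rel); duplicate nu points get independent noise.
    Returns one profile per (residue, static field).
    """
    if preset.cpmg_nu_hz is None:
        raise InvalidParameterError(f"preset {preset.name} has no CPMG settings")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    nu = np.asarray(preset.cpmg_nu_hz, dtype=float)
    out: dict[str, list[CpmgProfile]] = {}
    for res in sorted(scenario.specs):
        spec = scenario.specs[res]
        profiles = []
        for fctx in preset.fields:
            r2_0 = scenario.r2_0[res].get(fctx.proton_mhz, 12.0)
            r2eff = carver_richards_r2eff(spec, nu, fctx, r2_0)
            clean = i0 * np.exp(-r2eff * preset.cpmg_t_cpmg_s)
            noisy = clean * (1.0 + rng.normal(0.0, scenario.sigma_rel_cpmg, nu.size))
            profiles.append(
                CpmgProfile(
                    residue_id=res,
                    nu_cpmg_hz=nu.copy(),
                    intensities=noisy,
                    i0=i0,
                    t_cpmg_s=preset.cpmg_t_cpmg_s,
                    field=fctx,
                )
            )
        out[res] = profiles
    return out


def generate_cest_dataset(
    scenario: TruthScenario,
    preset: AcquisitionPreset,
    seed: int | None = None,
) -> dict[str, list[CestProfile]]:
    """Simulate CEST I/I0 profiles for every residue at every preset B1.

    Additive Gaussian noise of standard deviation sigma_rel on the ratio;
    the per-point sigma column records that value.
    """
    if preset.cest_offsets_ppm is None:
        raise InvalidParameterError(f"preset {preset.name} has no CEST settings")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    offsets = np.asarray(preset.cest_offsets_ppm, dtype=float)
    fctx = preset.fields[0]
    out: dict[str, list[CestProfile]] = {}
    for res in sorted(scenario.specs):
        spec = scenario.specs[res]
        profiles = []
        for b1 in preset.cest_b1_hz:
            clean = simulate_cest(spec, b1, preset.cest_t_ex_s, offsets, fctx)
            noisy = clean + rng.normal(0.0, scenario.sigma_rel_cest, offsets.size)
            noisy = np.clip(noisy, -0.2, 1.2)
            sig = scenario.sigma_rel_cest if scenario.sigma_rel_cest > 0 else 1e-6
            profiles.append(
                CestProfile(
                    residue_id=res,
                    offsets_ppm=offsets.copy(),
                    ratios=noisy,
                    sigmas=np.full(offsets.size, sig),
                    b1_hz=b1,
                    b1_sigma_hz=preset.cest_b1_sigma_hz,
                    t_ex_s=preset.cest_t_ex_s,
                    field=fctx,
                )
            )
        out[res] = profiles
    return out


def generate_titration(
    kd_mM: float,
    concentrations_mM: Sequence[float],
    sigma_rel: float = 0.1,
    seed: int = 0,
    protein_mM: float = 0.05,
    bound_is_ground: bool = True,
) -> TitrationSeries:
    """Synthetic titration of the minor-state population against ligand.

    p_minor = K_d/(K_d + [L]) (ground = bound form) with multiplicative
    Gaussian noise; sigmas record sigma_rel times the noise-free population.
    """
    if kd_mM <= 0:
        raise InvalidParameterError("K_d must be > 0")
    rng = np.random.default_rng(seed)
    L = np.asarray(concentrations_mM, dtype=float)
    p = kd_mM / (kd_mM + L) if bound_is_ground else L / (kd_mM + L)
    noisy = np.clip(p * (1.0 + rng.normal(0.0, sigma_rel, L.size)), 0.0, 1.0)
    sig = sigma_rel * p if sigma_rel > 0 else np.full(L.size, 1e-6)
    return TitrationSeries(
        ligand_mM=L, p_minor=noisy, sigmas=sig, protein_mM=protein_mM
    )
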