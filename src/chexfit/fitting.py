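"""Least-squares estimation of exchange parameters from CEST and CPMG data.

Individual and grouped/global fits, three-state model selection, uncertainty
estimation (covariance, unscaled-Jacobian and Monte-Carlo), and cross-method
comparison of excited-state chemical shifts.

All optimizations run through :mod:`lmfit` (trust-region least squares) from
a deterministic multi-start grid, so identical inputs always produce
identical results.  Default bounds are wide enough to contain every exchange
process the package targets: k_ex in [1, 10000] s^-1, p_E in [1e-4, 0.5],
R2_0 in [1, 100] s^-1.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from .cest import CestProfile, find_dips, simulate_cest
from .cpmg import CpmgProfile, _cr72
from .errors import (
    DegenerateFitError,
    InsufficientOverlapError,
    InvalidInputError,
    InvalidParameterError,
)
from .exchange import ExchangeModelSpec, ExchangeTopology, FieldContext, ppm_to_angular

__all__ = [
    "FitResult",
    "ResidueGroup",
    "ModelRank",
    "fit_cpmg_individual",
    "fit_cpmg_global",
    "group_residues",
    "fit_cest",
    "select_three_state_model",
    "estimate_uncertainties",
    "compare_shift_sets",
    "ShiftComparison",
]

# documented multi-start grid (shared with the CEST fits)
KEX_STARTS = (100.0, 300.0, 1000.0, 3000.0)
PE_STARTS = (0.005, 0.02, 0.08)
DW_START_PPM = 2.0

KEX_BOUNDS = (1.0, 1.0e4)
PE_BOUNDS = (1.0e-4, 0.5)
R2_0_BOUNDS = (1.0, 100.0)


def _sanitize(name: str) -> str:
    return re.sub(r"\W", "_", str(name))


def _diverse(positions, k: int, min_sep: float = 1.2) -> list[float]:
    """First k entries of a ranked position list at pairwise >= min_sep ppm."""
    out: list[float] = []
    for x in positions:
        if all(abs(x - y) >= min_sep for y in out):
            out.append(x)
        if len(out) == k:
            break
    return out


@dataclass
class FitResult:
    """Point estimates, uncertainties and goodness of fit of one model.

    ``estimates``/``sigmas`` are keyed by parameter name with units embedded
    (``k_ex`` s^-1, ``p_E`` fraction, ``dw_ppm`` ppm, ``r2_0_<field>`` s^-1).
    ``covariance`` rows/columns follow ``free_names`` and are scaled by the
    reduced chi-square (the covariance-matrix method).
    """

    model: str
    estimates: dict[str, float]
    sigmas: dict[str, float]
    chi2: float
    n_points: int
    n_free: int
    free_names: tuple[str, ...] = ()
    covariance: np.ndarray | None = None
    flags: tuple[str, ...] = ()
    per_residue: dict[str, dict[str, float]] | None = None
    residue_id: str | None = None
    _residual: Callable[[np.ndarray], np.ndarray] | None = dataclass_field(
        default=None, repr=False, compare=False
    )
    _refit: Callable[[int], np.ndarray] | None = dataclass_field(
        default=None, repr=False, compare=False
    )

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / max(self.n_points - self.n_free, 1)

    @property
    def aicc(self) -> float:
        """Small-sample-corrected Akaike criterion on the weighted chi2."""
        n, k = self.n_points, self.n_free
        aic = n * math.log(max(self.chi2, 1e-300) / n) + 2 * k
        if n - k - 1 > 0:
            aic += 2.0 * k * (k + 1) / (n - k - 1)
        else:
            aic = math.inf
        return aic

    @property
    def bic(self) -> float:
        """Bayesian information criterion on the weighted chi2.

        Primary model-selection criterion here: a freely scanned
        excited-state position can harvest ~2 ln(n_offsets) of chi2 from
        noise alone (look-elsewhere effect), which the Akaike 2k penalty
        does not cover; the ln(n) k penalty does.
        """
        n, k = self.n_points, self.n_free
        return n * math.log(max(self.chi2, 1e-300) / n) + math.log(n) * k

    @property
    def best_values(self) -> np.ndarray:
        return np.array([self.estimates[k] for k in self.free_names])

    def to_dict(self) -> dict:
        """JSON-serializable summary (deterministic key order)."""
        out = {
            "model": self.model,
            "residue_id": self.residue_id,
            "estimates": {k: self.estimates[k] for k in sorted(self.estimates)},
            "sigmas": {k: self.sigmas.get(k) for k in sorted(self.estimates)},
            "chi2": self.chi2,
            "n_points": self.n_points,
            "n_free": self.n_free,
            "reduced_chi2": self.reduced_chi2,
            "flags": list(self.flags),
        }
        if self.per_residue is not None:
            out["per_residue"] = {
                r: {k: v for k, v in sorted(d.items())}
                for r, d in sorted(self.per_residue.items())
            }
        return out


@dataclass
class ResidueGroup:
    """Residues sharing one exchange process (k_ex, p_E) in a global fit."""

    members: tuple[str, ...]
    rationale: dict[str, dict[str, float]]
    region: str | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise InvalidParameterError("a residue group needs at least one member")


# ---------------------------------------------------------------------------
# CPMG fitting
# ---------------------------------------------------------------------------


def _cpmg_data_table(profiles_by_residue: Mapping[str, Sequence[CpmgProfile]]):
    """Flatten profiles into (residue, field, nu, r2eff, sigma) rows.

    Profiles without an explicit ``delta_i`` use a dataset-wide
    repeat-measurement noise estimate at their static field: a single
    duplicate pair per profile is far too noisy an estimator on its own.
    Peak-intensity noise scales with the intensity, so the pooled quantity
    is the *relative* repeat std (std/mean); the per-point intensity
    uncertainty is then ``delta_i = rel_std * I`` and the R2eff uncertainty
    follows the usual (1/T_CPMG)(delta_i/I) form.
    """
    from .cpmg import r2eff_sigma as _r2eff_sigma

    all_profiles = [
        p for res in profiles_by_residue for p in profiles_by_residue[res]
    ]
    rel_by_field: dict[float, float] = {}
    for f in {p.field.proton_mhz for p in all_profiles}:
        rels = []
        for p in all_profiles:
            if p.field.proton_mhz != f:
                continue
            for nu in np.unique(p.nu_cpmg_hz):
                vals = p.intensities[p.nu_cpmg_hz == nu]
                if vals.size > 1:
                    rels.append(np.std(vals, ddof=1) / np.mean(vals))
        if rels:
            # floor keeps noiseless synthetic data finite-weighted
            rel_by_field[f] = max(float(np.mean(rels)), 1e-8)

    rows = []
    for res in sorted(profiles_by_residue, key=_sanitize):
        for prof in sorted(
            profiles_by_residue[res], key=lambda p: p.field.proton_mhz
        ):
            if prof.delta_i is not None:
                sigma = prof.r2eff_sigma()
            else:
                rel = rel_by_field.get(prof.field.proton_mhz)
                if rel is None:
                    sigma = prof.r2eff_sigma()  # raises with a clear message
                else:
                    sigma = _r2eff_sigma(rel * prof.intensities, prof.intensities, prof.t_cpmg_s)
            rows.append(
                (str(res), prof.field, prof.nu_cpmg_hz.copy(), prof.r2eff(), sigma)
            )
    return rows


def _run_minimize(params: lmfit.Parameters, residual, max_nfev=None) -> lmfit.minimizer.MinimizerResult:
    return lmfit.minimize(
        residual, params, method="least_squares", max_nfev=max_nfev, nan_policy="raise"
    )


def _multistart(params: lmfit.Parameters, residual, starts, max_nfev=None):
    """Minimize from each start (dict of param values); return the best result."""
    best = None
    for start in starts:
        p = params.copy()
        for k, v in start.items():
            p[k].set(value=v)
        try:
            res = _run_minimize(p, residual, max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise DegenerateFitError("all optimization starts failed")
    return best


def _result_from_lmfit(
    model: str,
    mres: lmfit.minimizer.MinimizerResult,
    residual,
    n_points: int,
    flags: tuple[str, ...] = (),
    residue_id: str | None = None,
) -> FitResult:
    free = tuple(n for n in mres.params if mres.params[n].vary)
    estimates = {n: float(mres.params[n].value) for n in mres.params}
    sigmas = {}
    for n in mres.params:
        err = mres.params[n].stderr
        sigmas[n] = float(err) if err is not None and np.isfinite(err) else float("inf")
    cov = mres.covar if mres.covar is not None else None
    if cov is None and "degenerate_covariance" not in flags:
        flags = flags + ("degenerate_covariance",)

    params_template = mres.params

    def residual_vec(x: np.ndarray) -> np.ndarray:
        p = params_template.copy()
        for name, val in zip(free, x):
            p[name].set(value=float(val))
        return np.asarray(residual(p), dtype=float)

    return FitResult(
        model=model,
        estimates=estimates,
        sigmas=sigmas,
        chi2=float(mres.chisqr),
        n_points=n_points,
        n_free=len(free),
        free_names=free,
        covariance=cov,
        flags=flags,
        residue_id=residue_id,
        _residual=residual_vec,
    )


def _fit_cpmg(
    profiles_by_residue: Mapping[str, Sequence[CpmgProfile]],
    starts: Sequence[dict] | None = None,
) -> FitResult:
    """Shared engine for individual (one residue) and global CPMG fits.

    Free parameters: shared (k_ex, p_E); per residue one |dw| in ppm shared
    across static fields, and one intrinsic R2_0 per static field.
    """
    data = _cpmg_data_table(profiles_by_residue)
    if not data:
        raise InvalidInputError("no CPMG profiles given")
    residues = sorted({row[0] for row in data}, key=_sanitize)
    fields_per_res = {
        r: sorted({row[1].proton_mhz for row in data if row[0] == r}) for r in residues
    }
    all_fields = sorted({f for fl in fields_per_res.values() for f in fl})
    for r, fl in fields_per_res.items():
        if len(fl) < 2:
            raise InvalidInputError(
                f"residue {r}: need profiles at >= 2 static fields to separate "
                "dw from k_ex (got " + ", ".join(f"{f:g}" for f in fl) + " MHz)"
            )

    # no-exchange detection: exchange always raises R2eff at low nu, so
    # compare the low-nu and high-nu ends of each dispersion; a contrast
    # below 2 sigma in every profile flags the residue set as flat
    def _contrast_is_flat(row) -> bool:
        nu, y, s = row[2], row[3], row[4]
        order = np.argsort(nu)
        k = max(min(4, y.size // 3), 1)
        contrast = float(np.mean(y[order[:k]]) - np.mean(y[order[-k:]]))
        sigma_c = float(np.median(s)) * math.sqrt(2.0 / k)
        return contrast < 2.0 * sigma_c

    flat = all(_contrast_is_flat(row) for row in data)
    if flat:
        est: dict[str, float] = {"k_ex": 0.0, "p_E": 0.0}
        chi2 = 0.0
        n_pts = 0
        for res, fctx, nu, y, s in data:
            mean = float(np.average(y, weights=1.0 / s**2))
            est[f"r2_0_{_sanitize(res)}_{fctx.proton_mhz:g}"] = mean
            chi2 += float(np.sum(((y - mean) / s) ** 2))
            n_pts += y.size
        return FitResult(
            model="two_state_cpmg",
            estimates=est,
            sigmas={k: float("nan") for k in est},
            chi2=chi2,
            n_points=n_pts,
            n_free=len(est) - 2,
            flags=("no_exchange",),
            residue_id=residues[0] if len(residues) == 1 else None,
        )

    params = lmfit.Parameters()
    params.add("k_ex", value=300.0, min=KEX_BOUNDS[0], max=KEX_BOUNDS[1])
    params.add("p_E", value=0.02, min=PE_BOUNDS[0], max=PE_BOUNDS[1])
    for res in residues:
        tag = _sanitize(res)
        params.add(f"dw_{tag}_ppm", value=DW_START_PPM, min=1e-3, max=10.0)
        for res2, fctx, nu, y, s in data:
            if res2 != res:
                continue
            # intrinsic rate starts at the high-nu plateau of the dispersion
            r2_init = float(np.mean(np.sort(y)[:3]))
            params.add(
                f"r2_0_{tag}_{fctx.proton_mhz:g}",
                value=np.clip(r2_init, *R2_0_BOUNDS),
                min=R2_0_BOUNDS[0],
                max=R2_0_BOUNDS[1],
            )

    nitrogen = {f: FieldContext(f) for f in all_fields}

    def residual(p: lmfit.Parameters) -> np.ndarray:
        kex = p["k_ex"].value
        pe = p["p_E"].value
        out = []
        for res, fctx, nu, y, s in data:
            tag = _sanitize(res)
            dw = ppm_to_angular(p[f"dw_{tag}_ppm"].value, fctx)
            r2_0 = p[f"r2_0_{tag}_{fctx.proton_mhz:g}"].value
            model = _cr72(kex, pe, float(dw), r2_0, nu)
            out.append((y - model) / s)
        return np.concatenate(out)

    if starts is None:
        starts = [
            {"k_ex": k, "p_E": pe}
            for k, pe in itertools.product(KEX_STARTS, PE_STARTS)
        ]
    best = _multistart(params, residual, starts)
    n_pts = sum(row[3].size for row in data)
    result = _result_from_lmfit(
        "two_state_cpmg",
        best,
        residual,
        n_pts,
        residue_id=residues[0] if len(residues) == 1 else None,
    )
    result.per_residue = {
        res: {
            "dw_ppm": result.estimates[f"dw_{_sanitize(res)}_ppm"],
            **{
                f"r2_0_{f:g}": result.estimates[f"r2_0_{_sanitize(res)}_{f:g}"]
                for f in fields_per_res[res]
            },
        }
        for res in residues
    }

    # Monte-Carlo refit closure: resample R2eff per its sigma and refit from
    # the optimum (single start).
    best_vals = {n: best.params[n].value for n in best.params}
    model_rows = []
    for res, fctx, nu, y, s in data:
        tag = _sanitize(res)
        dw = float(ppm_to_angular(best_vals[f"dw_{tag}_ppm"], fctx))
        r2_0 = best_vals[f"r2_0_{tag}_{fctx.proton_mhz:g}"]
        model_rows.append(_cr72(best_vals["k_ex"], best_vals["p_E"], dw, r2_0, nu))

    def refit(seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        noisy = [m + rng.normal(0.0, row[4]) for m, row in zip(model_rows, data)]

        def res_noisy(p: lmfit.Parameters) -> np.ndarray:
            kex = p["k_ex"].value
            pe = p["p_E"].value
            out = []
            for (res, fctx, nu, y, s), yn in zip(data, noisy):
                tag = _sanitize(res)
                dw = ppm_to_angular(p[f"dw_{tag}_ppm"].value, fctx)
                r2_0 = p[f"r2_0_{tag}_{fctx.proton_mhz:g}"].value
                out.append((yn - _cr72(kex, pe, float(dw), r2_0, nu)) / s)
            return np.concatenate(out)

        p0 = best.params.copy()
        mres = _run_minimize(p0, res_noisy)
        return np.array([mres.params[n].value for n in result.free_names])

    result._refit = refit
    return result


def fit_cpmg_individual(profiles: Sequence[CpmgProfile]) -> FitResult:
    """Two-state Carver-Richards fit of one residue's dispersion profiles.

    Requires profiles at two or more static fields (|dw| in ppm is shared
    across fields; a single field leaves dw/k_ex degenerate).  A profile set
    whose total dispersion is below twice the point uncertainty is returned
    flagged ``no_exchange`` instead of being force-fitted.
    """
    ids = {p.residue_id for p in profiles}
    if len(ids) != 1:
        raise InvalidInputError(f"expected one residue, got {sorted(ids)}")
    return _fit_cpmg({ids.pop(): list(profiles)})


def fit_cpmg_global(
    profiles_by_residue: Mapping[str, Sequence[CpmgProfile]],
) -> FitResult:
    """Grouped fit sharing (k_ex, p_E) across residues.

    Per-residue parameters (|dw|, one R2_0 per field) stay free; the group
    reduced chi-square is reported.  With a single member this reduces
    exactly to :func:`fit_cpmg_individual`.
    """
    return _fit_cpmg(profiles_by_residue)


def group_residues(
    individual: Mapping[str, FitResult],
    structure_tags: Mapping[str, str] | None = None,
    tol_log_kex: float = 0.4,
    tol_logit_pe: float = 0.6,
) -> list[ResidueGroup]:
    """Cluster residues by their individually fitted (k_ex, p_E).

    Greedy, deterministic agglomeration in (log k_ex, logit p_E) space:
    residues are visited in residue-number order and join the first existing
    group whose running mean lies within both tolerances; otherwise they
    found a new group.  Structure-region tags, when given, can only split
    clusters (residues with different tags never share a group), never merge
    them.
    """

    def sort_key(r: str):
        m = re.match(r"(\d+)", str(r))
        return (int(m.group(1)) if m else 10**9, str(r))

    groups: list[dict] = []
    for res in sorted(individual, key=sort_key):
        fit = individual[res]
        kex = fit.estimates.get("k_ex", float("nan"))
        pe = fit.estimates.get("p_E", float("nan"))
        if not (np.isfinite(kex) and kex > 0 and 0 < pe < 1):
            raise InvalidInputError(
                f"residue {res}: grouping requires finite positive k_ex and p_E"
            )
        x = math.log(kex)
        y = math.log(pe / (1.0 - pe))
        tag = structure_tags.get(res) if structure_tags else None
        placed = False
        for g in groups:
            if g["tag"] != tag:
                continue
            if (
                abs(x - np.mean(g["x"])) <= tol_log_kex
                and abs(y - np.mean(g["y"])) <= tol_logit_pe
            ):
                g["members"].append(res)
                g["x"].append(x)
                g["y"].append(y)
                g["rationale"][res] = {"k_ex": kex, "p_E": pe}
                placed = True
                break
        if not placed:
            groups.append(
                {
                    "members": [res],
                    "x": [x],
                    "y": [y],
                    "tag": tag,
                    "rationale": {res: {"k_ex": kex, "p_E": pe}},
                }
            )
    return [
        ResidueGroup(tuple(g["members"]), g["rationale"], region=g["tag"])
        for g in groups
    ]


# ---------------------------------------------------------------------------
# CEST fitting
# ---------------------------------------------------------------------------


def _cest_spec_from_params(p, topology: ExchangeTopology) -> ExchangeModelSpec:
    if topology is ExchangeTopology.TWO_STATE:
        return ExchangeModelSpec.two_state(
            k_ex=p["k_ex_1"].value,
            p_E=p["p_E1"].value,
            delta_G_ppm=p["delta_G_ppm"].value,
            delta_E_ppm=p["delta_E1_ppm"].value,
            r1=p["r1"].value,
            r2=p["r2"].value,
        )
    return ExchangeModelSpec.three_state(
        topology,
        p_E1=p["p_E1"].value,
        p_E2=p["p_E1"].value * p["f_E2"].value,
        kex_1=p["k_ex_1"].value,
        kex_2=p["k_ex_2"].value,
        shifts_ppm=[
            p["delta_G_ppm"].value,
            p["delta_E1_ppm"].value,
            p["delta_E2_ppm"].value,
        ],
        r1=p["r1"].value,
        r2=p["r2"].value,
    )


def fit_cest(
    profiles: Sequence[CestProfile],
    topology: ExchangeTopology = ExchangeTopology.TWO_STATE,
    two_state_start: FitResult | None = None,
    n_optimize: int = 3,
    max_nfev: int = 600,
) -> FitResult:
    """Fit one residue's CEST profiles (one per B1 field) to an exchange model.

    Chemical-shift starts come from dip detection; (k_ex, p) starts from the
    documented grid, chi2-screened so only the ``n_optimize`` most promising
    start points are fully optimized.  For three-state topologies an
    additional start embeds a previously fitted two-state solution with the
    extra state at its population lower bound, which guarantees the nested
    model never ends above the two-state chi-square.

    Returns signed shift differences (CEST resolves the sign of dw, unlike
    CPMG): estimates carry absolute per-state shifts plus ``dw_E1_ppm`` (and
    ``dw_E2_ppm``) relative to the ground state.
    """
    ids = {p.residue_id for p in profiles}
    if len(ids) != 1:
        raise InvalidInputError(f"expected one residue, got {sorted(ids)}")
    residue = ids.pop()
    profiles = sorted(profiles, key=lambda p: p.b1_hz)
    b1s = {p.b1_hz for p in profiles}
    if topology is ExchangeTopology.TWO_STATE and len(b1s) < 2:
        raise InvalidInputError(
            "two-state CEST fitting requires profiles at >= 2 B1 fields"
        )

    n_minor = topology.n_states - 1
    flags: tuple[str, ...] = ()
    # dip-informed shift starts (strongest-B1 profile gives the widest dips)
    dips = None
    for prof in sorted(profiles, key=lambda p: -p.b1_hz):
        try:
            d = find_dips(prof, min_depth=0.02)
        except InvalidInputError:
            continue
        if dips is None or len(d) > len(dips):
            dips = d
        if dips is not None and len(dips) >= n_minor + 1:
            break
    positions = list(dips.positions_ppm) if dips is not None else []
    if len(positions) < n_minor + 1:
        flags += ("insufficient_dips",)
    lo = min(p.offsets_ppm.min() for p in profiles)
    hi = max(p.offsets_ppm.max() for p in profiles)
    center = positions[0] if positions else 0.5 * (lo + hi)
    while len(positions) < n_minor + 1:
        positions.append(center + 1.5 * (len(positions) - 0.5))

    plateau = float(np.mean(np.sort(profiles[0].ratios)[-max(profiles[0].ratios.size // 10, 3):]))
    t_ex = profiles[0].t_ex_s
    r1_init = float(np.clip(-math.log(max(plateau, 1e-3)) / max(t_ex, 1e-6), 0.1, 5.0))

    params = lmfit.Parameters()
    params.add("delta_G_ppm", value=positions[0], min=lo - 2.0, max=hi + 2.0)
    params.add("delta_E1_ppm", value=positions[1], min=lo - 5.0, max=hi + 5.0)
    params.add("k_ex_1", value=300.0, min=KEX_BOUNDS[0], max=KEX_BOUNDS[1])
    params.add("p_E1", value=0.02, min=PE_BOUNDS[0], max=PE_BOUNDS[1])
    if topology is not ExchangeTopology.TWO_STATE:
        params.add("delta_E2_ppm", value=positions[2], min=lo - 5.0, max=hi + 5.0)
        params.add("k_ex_2", value=300.0, min=KEX_BOUNDS[0], max=KEX_BOUNDS[1])
        # E1 is by definition the larger minor dip: p_E2 = p_E1 * f_E2 <= p_E1
        params.add("f_E2", value=0.3, min=1e-3, max=1.0)
    params.add("r1", value=r1_init, min=0.05, max=10.0)
    params.add("r2", value=10.0, min=0.5, max=200.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        spec = _cest_spec_from_params(p, topology)
        out = []
        for prof in profiles:
            sim = simulate_cest(spec, prof.b1_hz, prof.t_ex_s, prof.offsets_ppm, prof.field)
            out.append((prof.ratios - sim) / prof.sigmas)
        return np.concatenate(out)

    def chi2_at(start: dict) -> float:
        p = params.copy()
        for k, v in start.items():
            p[k].set(value=v)
        try:
            return float(np.sum(residual(p) ** 2))
        except Exception:
            return float("inf")

    # Candidate excited-state positions: detected dips plus a coarse scan of
    # the offset range (minor dips at these exchange rates are often
    # shoulders without a local minimum, so a model-based position screen is
    # more robust than dip picking alone).
    scan = [
        x
        for x in np.arange(lo + 0.5, hi - 0.5 + 1e-9, 0.8)
        if abs(x - positions[0]) > 0.7
    ]
    pos_candidates = [p for p in positions[1:] if abs(p - positions[0]) > 0.3] + scan

    # start grid, chi2-screened (documented k_ex/p grid x position candidates)
    if topology is ExchangeTopology.TWO_STATE:
        pos_scored = sorted(
            pos_candidates,
            key=lambda x: chi2_at({"delta_E1_ppm": x, "k_ex_1": 300.0, "p_E1": 0.02}),
        )
        grid = [
            {"delta_E1_ppm": pos, "k_ex_1": k, "p_E1": pe}
            for pos, (k, pe) in itertools.product(
                _diverse(pos_scored, 2), itertools.product(KEX_STARTS, PE_STARTS)
            )
        ]
    else:
        if two_state_start is None:
            two_state_start = fit_cest(
                profiles, ExchangeTopology.TWO_STATE,
                n_optimize=n_optimize, max_nfev=max_nfev,
            )
        est2 = two_state_start.estimates
        base = {
            "delta_G_ppm": est2["delta_G_ppm"],
            "delta_E1_ppm": est2["delta_E1_ppm"],
            "k_ex_1": est2["k_ex_1"],
            "p_E1": est2["p_E1"],
            "r1": est2["r1"],
            "r2": est2["r2"],
        }
        # screen the second excited-state position given the two-state stage
        pos2 = sorted(
            (x for x in pos_candidates if abs(x - est2["delta_E1_ppm"]) > 0.7),
            key=lambda x: chi2_at(
                {**base, "delta_E2_ppm": x, "k_ex_2": 300.0, "f_E2": 0.2}
            ),
        )
        pos2_pick = _diverse(pos2, 2)
        grid = [
            {**base, "delta_E2_ppm": pos, "k_ex_2": k2, "f_E2": f2}
            for pos, k2, f2 in itertools.product(
                pos2_pick, KEX_STARTS[:3], (0.1, 0.4)
            )
        ]
        # swapped assignment: the two-state stage may have locked onto the
        # wrong minor state, so place E1 at the scanned position with E2 at
        # the two-state solution.  A chi2 screen cannot rank these fairly
        # (nuisance mismatches in delta_G and R2 dominate), so the best
        # swapped start is always optimized alongside the screened ones.
        swap_entries = [
            {
                **base,
                "delta_E1_ppm": pos,
                "delta_E2_ppm": est2["delta_E1_ppm"],
                "k_ex_1": k1,
                "k_ex_2": k2,
                "f_E2": 0.4,
            }
            for pos, k1, k2 in itertools.product(
                pos2_pick, KEX_STARTS[:2], KEX_STARTS[:3]
            )
        ]
        # stage-free starts: the two-state solution can be pathological when
        # the two minor features overlap the ground dip, so also screen
        # position pairs with default relaxation rates
        probe = {
            "delta_G_ppm": positions[0], "k_ex_1": 300.0, "p_E1": 0.02,
            "f_E2": 1e-3, "delta_E2_ppm": lo - 5.0, "k_ex_2": 300.0,
            "r1": r1_init, "r2": 10.0,
        }
        pos_free = _diverse(
            sorted(
                pos_candidates, key=lambda x: chi2_at({**probe, "delta_E1_ppm": x})
            ),
            3,
        )
        grid += [
            {
                "delta_G_ppm": positions[0], "r1": r1_init, "r2": 10.0,
                "delta_E1_ppm": pa, "delta_E2_ppm": pb,
                "k_ex_1": k1, "k_ex_2": 300.0, "p_E1": 0.04, "f_E2": 0.4,
            }
            for pa, pb in itertools.permutations(pos_free, 2)
            for k1 in KEX_STARTS[:2]
            if abs(pa - pb) > 0.7
        ]

    scored = sorted(grid, key=chi2_at)
    starts = scored[:n_optimize]
    if topology is not ExchangeTopology.TWO_STATE and swap_entries:
        starts = starts + [min(swap_entries, key=chi2_at)]
    if two_state_start is not None and topology is not ExchangeTopology.TWO_STATE:
        est = two_state_start.estimates
        embed = {
            "delta_G_ppm": est["delta_G_ppm"],
            "r1": est["r1"],
            "r2": est["r2"],
        }
        if topology is ExchangeTopology.THREE_G_E2_E1:
            # the state adjacent to G is E2, which the p_E1 >= p_E2 labeling
            # caps at p_E1; start both at the two-state population with the
            # terminal E1 decoupled as far as the bounds allow
            embed.update(
                delta_E2_ppm=est["delta_E1_ppm"],
                delta_E1_ppm=lo - 5.0,
                k_ex_1=est["k_ex_1"],
                p_E1=est["p_E1"],
                f_E2=1.0,
                k_ex_2=KEX_BOUNDS[0],
            )
        else:
            # E1 adjacent to G: the two-state solution embeds exactly with
            # the extra state at a vanishing population
            embed.update(
                delta_E1_ppm=est["delta_E1_ppm"],
                delta_E2_ppm=est["delta_G_ppm"] - 1.5,
                k_ex_1=est["k_ex_1"],
                p_E1=est["p_E1"],
                f_E2=1e-3,
                k_ex_2=300.0,
            )
        starts = starts + [embed]

    best = _multistart(params, residual, starts, max_nfev=max_nfev)
    n_pts = sum(p.offsets_ppm.size for p in profiles)
    result = _result_from_lmfit(
        f"cest_{topology.name.lower()}", best, residual, n_pts,
        flags=flags, residue_id=str(residue),
    )
    result.estimates["dw_E1_ppm"] = (
        result.estimates["delta_E1_ppm"] - result.estimates["delta_G_ppm"]
    )
    if topology is not ExchangeTopology.TWO_STATE:
        result.estimates["dw_E2_ppm"] = (
            result.estimates["delta_E2_ppm"] - result.estimates["delta_G_ppm"]
        )
        # derived second-state population (p_E2 = p_E1 * f_E2)
        p1, f2 = result.estimates["p_E1"], result.estimates["f_E2"]
        result.estimates["p_E2"] = p1 * f2
        s1, sf = result.sigmas.get("p_E1", np.inf), result.sigmas.get("f_E2", np.inf)
        if np.isfinite(s1) and np.isfinite(sf):
            result.sigmas["p_E2"] = p1 * f2 * math.hypot(
                s1 / max(p1, 1e-12), sf / max(f2, 1e-12)
            )
        else:
            result.sigmas["p_E2"] = float("inf")

    best_params = best.params

    def refit(seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        spec = _cest_spec_from_params(best_params, topology)
        noisy = []
        for prof in profiles:
            sim = simulate_cest(spec, prof.b1_hz, prof.t_ex_s, prof.offsets_ppm, prof.field)
            noisy.append(sim + rng.normal(0.0, prof.sigmas))

        def res_noisy(p: lmfit.Parameters) -> np.ndarray:
            s = _cest_spec_from_params(p, topology)
            out = []
            for prof, yn in zip(profiles, noisy):
                sim = simulate_cest(s, prof.b1_hz, prof.t_ex_s, prof.offsets_ppm, prof.field)
                out.append((yn - sim) / prof.sigmas)
            return np.concatenate(out)

        mres = _run_minimize(best_params.copy(), res_noisy, max_nfev=max_nfev)
        return np.array([mres.params[n].value for n in result.free_names])

    result._refit = refit
    return result


@dataclass
class ModelRank:
    """One entry of a model-selection ranking (ranked by BIC)."""

    topology: ExchangeTopology
    fit: FitResult | None
    bic: float
    aicc: float
    reduced_chi2: float
    failure: str | None = None


_DEFAULT_CANDIDATES = (
    ExchangeTopology.TWO_STATE,
    ExchangeTopology.THREE_G_E1_E2,
    ExchangeTopology.THREE_G_E2_E1,
    ExchangeTopology.THREE_E1_G_E2,
)


def select_three_state_model(
    profiles: Sequence[CestProfile],
    candidates: Sequence[ExchangeTopology] = _DEFAULT_CANDIDATES,
    force: bool = False,
    n_optimize: int = 2,
    max_nfev: int = 600,
) -> list[ModelRank]:
    """Fit candidate exchange topologies and rank them.

    Primary criterion is the Bayesian information criterion on the weighted
    chi-square (see :attr:`FitResult.bic` for why the Akaike penalty is too
    weak here); AICc and reduced chi-square are reported per model.  The two-state topology is included among the default candidates
    as the parsimony reference, so truly two-state data rank it first.
    Requires at least two minor dips unless ``force`` is set.  A candidate
    whose fit raises is ranked last with the failure reason recorded.
    """
    if not force:
        n_dips = 0
        for prof in profiles:
            try:
                n_dips = max(n_dips, len(find_dips(prof, min_depth=0.02)))
            except InvalidInputError:
                pass
        if n_dips < 3 and any(
            t is not ExchangeTopology.TWO_STATE for t in candidates
        ):
            raise InvalidInputError(
                f"only {max(n_dips - 1, 0)} minor dip(s) detected; three-state "
                "model selection needs >= 2 (pass force=True to override)"
            )

    two_state = None
    ranks: list[ModelRank] = []
    if any(t is not ExchangeTopology.TWO_STATE for t in candidates):
        try:
            two_state = fit_cest(
                profiles, ExchangeTopology.TWO_STATE,
                n_optimize=n_optimize, max_nfev=max_nfev,
            )
        except Exception:
            two_state = None
    for topo in candidates:
        try:
            if topo is ExchangeTopology.TWO_STATE and two_state is not None:
                fit = two_state
            else:
                fit = fit_cest(
                    profiles, topo, two_state_start=two_state,
                    n_optimize=n_optimize, max_nfev=max_nfev,
                )
            ranks.append(ModelRank(topo, fit, fit.bic, fit.aicc, fit.reduced_chi2))
        except Exception as exc:  # ranked last with the reason
            ranks.append(
                ModelRank(
                    topo, None, math.inf, math.inf, math.inf,
                    failure=f"{type(exc).__name__}: {exc}",
                )
            )
    ranks.sort(key=lambda r: (r.bic, r.topology.name))
    return ranks


# ---------------------------------------------------------------------------
# Uncertainties
# ---------------------------------------------------------------------------


def _numeric_jacobian(residual, x0: np.ndarray) -> np.ndarray:
    r0 = residual(x0)
    J = np.empty((r0.size, x0.size))
    for j in range(x0.size):
        h = 1e-6 * max(abs(x0[j]), 1e-6)
        xp = x0.copy()
        xp[j] += h
        J[:, j] = (residual(xp) - r0) / h
    return J


def estimate_uncertainties(
    fit: FitResult,
    method: str = "covariance",
    n_mc: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Parameter uncertainties of a converged fit.

    ``covariance``
        Scaled inverse of J'J at the optimum (J the weighted-residual
        Jacobian), multiplied by the reduced chi-square.
    ``jacobian``
        Unscaled inverse of J'J -- appropriate when the per-point sigmas are
        trusted absolutely.
    ``monte_carlo``
        Standard deviation over >= ``n_mc`` synthetic-noise refits; a
        cross-check, not the primary estimate.

    Rank-deficient Jacobian columns are flagged with infinite sigma.
    """
    if method == "monte_carlo":
        if fit._refit is None:
            raise InvalidInputError("this FitResult does not support Monte-Carlo refits")
        rng = np.random.default_rng(seed)
        samples = np.array(
            [fit._refit(int(rng.integers(0, 2**31 - 1))) for _ in range(n_mc)]
        )
        return dict(zip(fit.free_names, np.std(samples, axis=0, ddof=1)))

    if fit._residual is None:
        raise InvalidInputError("this FitResult carries no residual function")
    x0 = fit.best_values
    J = _numeric_jacobian(fit._residual, x0)
    JtJ = J.T @ J
    col_norm = np.linalg.norm(J, axis=0)
    dead = col_norm < 1e-12 * max(col_norm.max(), 1.0)
    sigmas = dict.fromkeys(fit.free_names, float("inf"))
    keep = ~dead
    if keep.any():
        sub = JtJ[np.ix_(keep, keep)]
        try:
            cov = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            u, s, vt = np.linalg.svd(sub)
            cov = (vt.T * np.where(s > s.max() * 1e-12, 1.0 / s, np.inf)) @ u.T
        if method == "covariance":
            dof = max(fit.n_points - fit.n_free, 1)
            cov = cov * fit.chi2 / dof
        elif method != "jacobian":
            raise InvalidParameterError(f"unknown method {method!r}")
        diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for name, s_val in zip(np.array(fit.free_names)[keep], diag):
            sigmas[str(name)] = float(s_val)
    return sigmas


# ---------------------------------------------------------------------------
# Shift-set comparison
# ---------------------------------------------------------------------------


@dataclass
class ShiftComparison:
    """Paired chemical-shift comparison between two methods or states."""

    table: pd.DataFrame  # residue, value_a, value_b, difference
    rms: float
    correlation: float


def compare_shift_sets(
    set_a: Mapping[str, float],
    set_b: Mapping[str, float],
    absolute: bool = False,
) -> ShiftComparison:
    """Inner-join two residue -> shift (or dw) mappings and compare them.

    ``absolute`` compares magnitudes, for pairing signed CEST dw values with
    CPMG-derived |dw|.  Fewer than 3 common residues raises.
    """
    common = sorted(set(set_a) & set(set_b), key=_sanitize)
    if len(common) < 3:
        raise InsufficientOverlapError(
            f"only {len(common)} common residues; need >= 3"
        )
    a = np.array([set_a[r] for r in common], dtype=float)
    b = np.array([set_b[r] for r in common], dtype=float)
    if absolute:
        a, b = np.abs(a), np.abs(b)
    diff = a - b
    table = pd.DataFrame(
        {"residue": common, "value_a": a, "value_b": b, "difference": diff}
    )
    rms = float(np.sqrt(np.mean(diff**2)))
    corr = float(np.corrcoef(a, b)[0, 1]) if np.std(a) > 0 and np.std(b) > 0 else 1.0
    return ShiftComparison(table, rms, corr)
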