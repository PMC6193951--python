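"""TSV and JSON input/output for profiles, titrations and fit results.

All data files are tab-separated text with '#'-prefixed ``key = value``
metadata header lines, numeric columns written at full precision (``%.17g``)
so write/read round trips are lossless.  Units are embedded in the column
names: ppm for shifts and offsets, Hz for B1 and nu_CPMG, seconds for times.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import TitrationSeries
from .cest import CestProfile
from .cpmg import CpmgProfile
from .errors import InvalidInputError, ParseError
from .exchange import FieldContext, rates_from_kex_p
from .fitting import FitResult

__all__ = [
    "read_cest_tsv",
    "write_cest_tsv",
    "read_cpmg_tsv",
    "write_cpmg_tsv",
    "write_r2eff_tsv",
    "read_titration_tsv",
    "write_titration_tsv",
    "write_results",
    "RunConfig",
]

_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FMT % x


def _read_tsv(path) -> tuple[dict[str, float | str], pd.DataFrame]:
    """Read metadata header + table; raise ParseError naming the problem."""
    path = Path(path)
    meta: dict[str, float | str] = {}
    header_lines = 0
    try:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                header_lines += 1
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    try:
                        meta[key] = float(val)
                    except ValueError:
                        meta[key] = val
    except OSError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        df = pd.read_csv(
            path, sep="\t", skiprows=header_lines, float_precision="round_trip"
        )
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse table: {exc}") from exc
    return meta, df


def _require_columns(path, df: pd.DataFrame, columns: Sequence[str]) -> None:
    for col in columns:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")


def _numeric(path, df: pd.DataFrame, col: str) -> np.ndarray:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
            f"'{col}', data row {row + 1}"
        )
    if out.isna().any():
        row = int(np.nonzero(out.isna().to_numpy())[0][0])
        raise ParseError(f"{path}: empty cell in column '{col}', data row {row + 1}")
    return out.to_numpy(dtype=float)


def _require_meta(path, meta: Mapping, keys: Sequence[str]) -> None:
    for key in keys:
        if key not in meta:
            raise ParseError(f"{path}: missing metadata header line '# {key} = ...'")


# ---------------------------------------------------------------------------
# CEST
# ---------------------------------------------------------------------------

_CEST_COLUMNS = ("residue", "offset_ppm", "ratio", "sigma")


def write_cest_tsv(profiles: Sequence[CestProfile], path) -> None:
    """Write profiles sharing one (B1, T_EX, field) setting to one file."""
    if not profiles:
        raise InvalidInputError("no profiles to write")
    first = profiles[0]
    for p in profiles:
        if (
            p.b1_hz != first.b1_hz
            or p.t_ex_s != first.t_ex_s
            or p.field.proton_mhz != first.field.proton_mhz
        ):
            raise InvalidInputError(
                "all profiles in one CEST file must share B1, T_EX and field"
            )
    with open(path, "w") as fh:
        fh.write(f"# b1_hz = {_fmt(first.b1_hz)}\n")
        fh.write(f"# b1_sigma_hz = {_fmt(first.b1_sigma_hz)}\n")
        fh.write(f"# t_ex_s = {_fmt(first.t_ex_s)}\n")
        fh.write(f"# proton_mhz = {_fmt(first.field.proton_mhz)}\n")
        fh.write("\t".join(_CEST_COLUMNS) + "\n")
        for p in profiles:
            for o, r, s in zip(p.offsets_ppm, p.ratios, p.sigmas):
                fh.write(f"{p.residue_id}\t{_fmt(o)}\t{_fmt(r)}\t{_fmt(s)}\n")


def read_cest_tsv(path) -> list[CestProfile]:
    meta, df = _read_tsv(path)
    _require_meta(path, meta, ("b1_hz", "t_ex_s", "proton_mhz"))
    _require_columns(path, df, _CEST_COLUMNS)
    offsets = _numeric(path, df, "offset_ppm")
    ratios = _numeric(path, df, "ratio")
    sigmas = _numeric(path, df, "sigma")
    fctx = FieldContext(float(meta["proton_mhz"]))
    out = []
    for res in df["residue"].astype(str).unique():
        m = (df["residue"].astype(str) == res).to_numpy()
        out.append(
            CestProfile(
                residue_id=res,
                offsets_ppm=offsets[m],
                ratios=ratios[m],
                sigmas=sigmas[m],
                b1_hz=float(meta["b1_hz"]),
                b1_sigma_hz=float(meta.get("b1_sigma_hz", 0.0)),
                t_ex_s=float(meta["t_ex_s"]),
                field=fctx,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CPMG
# ---------------------------------------------------------------------------

_CPMG_COLUMNS = ("residue", "nu_cpmg_hz", "intensity", "is_repeat")


def write_cpmg_tsv(profiles: Sequence[CpmgProfile], path) -> None:
    """Write profiles sharing one (I0, T_CPMG, field) setting to one file."""
    if not profiles:
        raise InvalidInputError("no profiles to write")
    first = profiles[0]
    for p in profiles:
        if (
            p.i0 != first.i0
            or p.t_cpmg_s != first.t_cpmg_s
            or p.field.proton_mhz != first.field.proton_mhz
        ):
            raise InvalidInputError(
                "all profiles in one CPMG file must share I0, T_CPMG and field"
            )
    with open(path, "w") as fh:
        fh.write(f"# i0 = {_fmt(first.i0)}\n")
        fh.write(f"# t_cpmg_s = {_fmt(first.t_cpmg_s)}\n")
        fh.write(f"# proton_mhz = {_fmt(first.field.proton_mhz)}\n")
        fh.write("\t".join(_CPMG_COLUMNS) + "\n")
        for p in profiles:
            for nu, i, rep in zip(p.nu_cpmg_hz, p.intensities, p.is_repeat):
                fh.write(f"{p.residue_id}\t{_fmt(nu)}\t{_fmt(i)}\t{int(rep)}\n")


def read_cpmg_tsv(path) -> list[CpmgProfile]:
    meta, df = _read_tsv(path)
    _require_meta(path, meta, ("i0", "t_cpmg_s", "proton_mhz"))
    _require_columns(path, df, _CPMG_COLUMNS)
    nu = _numeric(path, df, "nu_cpmg_hz")
    inten = _numeric(path, df, "intensity")
    rep = _numeric(path, df, "is_repeat").astype(bool)
    fctx = FieldContext(float(meta["proton_mhz"]))
    out = []
    for res in df["residue"].astype(str).unique():
        m = (df["residue"].astype(str) == res).to_numpy()
        out.append(
            CpmgProfile(
                residue_id=res,
                nu_cpmg_hz=nu[m],
                intensities=inten[m],
                i0=float(meta["i0"]),
                t_cpmg_s=float(meta["t_cpmg_s"]),
                field=fctx,
                is_repeat=rep[m],
            )
        )
    return out


def write_r2eff_tsv(profiles: Sequence[CpmgProfile], path) -> None:
    """Write the derived R2eff table (residue, nu, R2eff, sigma)."""
    with open(path, "w") as fh:
        fh.write("residue\tnu_cpmg_hz\tr2eff\tr2eff_sigma\n")
        for p in profiles:
            r2 = p.r2eff()
            sig = p.r2eff_sigma()
            for nu, y, s in zip(p.nu_cpmg_hz, r2, sig):
                fh.write(f"{p.residue_id}\t{_fmt(nu)}\t{_fmt(y)}\t{_fmt(s)}\n")


# ---------------------------------------------------------------------------
# Titration
# ---------------------------------------------------------------------------

_TITRATION_COLUMNS = ("ligand_mM", "p_minor", "sigma")


def write_titration_tsv(series: TitrationSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# protein_mM = {_fmt(series.protein_mM)}\n")
        fh.write("\t".join(_TITRATION_COLUMNS) + "\n")
        for L, p, s in zip(series.ligand_mM, series.p_minor, series.sigmas):
            fh.write(f"{_fmt(L)}\t{_fmt(p)}\t{_fmt(s)}\n")


def read_titration_tsv(path) -> TitrationSeries:
    meta, df = _read_tsv(path)
    _require_columns(path, df, _TITRATION_COLUMNS)
    return TitrationSeries(
        ligand_mM=_numeric(path, df, "ligand_mM"),
        p_minor=_numeric(path, df, "p_minor"),
        sigmas=_numeric(path, df, "sigma"),
        protein_mM=float(meta.get("protein_mM", 0.0)),
    )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def write_results(
    fits: Mapping[str, FitResult],
    prefix,
    provenance: Mapping | None = None,
) -> tuple[Path, Path]:
    """Serialize fits keyed by group/residue name.

    Writes ``<prefix>.json`` (full structured results plus a provenance
    block) and ``<prefix>_table.tsv``, a kinetic summary table with the
    derived k_GE/k_EG columns and error-propagated sigmas.
    """
    prefix = Path(prefix)
    json_path = prefix.with_suffix(".json")
    tsv_path = prefix.parent / (prefix.name + "_table.tsv")

    payload = {
        "provenance": {
            "package": "chexfit",
            "version": __version__,
            **(dict(provenance) if provenance else {}),
        },
        "fits": {name: fits[name].to_dict() for name in sorted(fits)},
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    cols = (
        "group\tresidues\tk_ex\tk_ex_sigma\tp_E\tp_E_sigma"
        "\tk_GE\tk_GE_sigma\tk_EG\tk_EG_sigma\treduced_chi2\n"
    )
    with open(tsv_path, "w") as fh:
        fh.write(cols)
        for name in sorted(fits):
            fit = fits[name]
            kex = fit.estimates.get("k_ex", fit.estimates.get("k_ex_1"))
            pe = fit.estimates.get("p_E", fit.estimates.get("p_E1"))
            if kex is None or pe is None:
                continue
            skex = fit.sigmas.get("k_ex", fit.sigmas.get("k_ex_1", float("nan")))
            spe = fit.sigmas.get("p_E", fit.sigmas.get("p_E1", float("nan")))
            k_ge, k_eg = rates_from_kex_p(kex, 1.0 - pe, pe)
            # linear propagation through k_GE = k_ex p_E, k_EG = k_ex (1-p_E)
            cov_term = 0.0
            if (
                fit.covariance is not None
                and "k_ex" in fit.free_names
                and "p_E" in fit.free_names
            ):
                i = fit.free_names.index("k_ex")
                j = fit.free_names.index("p_E")
                cov_term = float(fit.covariance[i, j])
            s_ge = math.sqrt(
                max((pe * skex) ** 2 + (kex * spe) ** 2 + 2 * pe * kex * cov_term, 0.0)
            ) if np.isfinite(skex) and np.isfinite(spe) else float("nan")
            s_eg = math.sqrt(
                max(
                    ((1 - pe) * skex) ** 2
                    + (kex * spe) ** 2
                    - 2 * (1 - pe) * kex * cov_term,
                    0.0,
                )
            ) if np.isfinite(skex) and np.isfinite(spe) else float("nan")
            residues = (
                ",".join(sorted(fit.per_residue)) if fit.per_residue else
                (fit.residue_id or "")
            )
            fh.write(
                f"{name}\t{residues}\t{_fmt(kex)}\t{_fmt(skex)}\t{_fmt(pe)}"
                f"\t{_fmt(spe)}\t{_fmt(k_ge)}\t{_fmt(s_ge)}\t{_fmt(k_eg)}"
                f"\t{_fmt(s_eg)}\t{_fmt(fit.reduced_chi2)}\n"
            )
    return json_path, tsv_path


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "inputs",
    "preset",
    "topology",
    "seed",
    "output_dir",
    "verbosity",
    "tol_log_kex",
    "tol_logit_pe",
    "bound_is_ground",
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected.

    Every run writes a provenance block (config echo, package version and
    seed) into its JSON output.
    """

    inputs: tuple[str, ...] = ()
    preset: str = "paper_cpmg_arsc"
    topology: str = "TWO_STATE"
    seed: int = 0
    output_dir: str = "."
    verbosity: str = "info"
    tol_log_kex: float = 0.4
    tol_logit_pe: float = 0.6
    bound_is_ground: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: config must be a mapping")
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        if "inputs" in raw:
            raw["inputs"] = tuple(raw["inputs"])
        return cls(**raw)

    def provenance(self) -> dict:
        return {
            "config": {
                "inputs": list(self.inputs),
                "preset": self.preset,
                "topology": self.topology,
                "seed": self.seed,
                "output_dir": self.output_dir,
            },
            "seed": self.seed,
        }
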