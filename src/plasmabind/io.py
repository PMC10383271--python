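"""Delimited-text readers/writers for titration, displacement, and CD data.

All tables are plain CSV with a one-line header naming columns and
units.  Titration tables use the long format

    temperature_K,Q_molar,F_obs,A_ex,A_em[,lambda_max_nm]

(the temperature column may be omitted for a single-temperature file,
in which case the temperature must be passed explicitly).  Displacement
tables carry ``marker,ratio,F`` and CD tables ``ratio,wavelength_nm,
ellipticity_mdeg``.  Generated fixture directories receive a JSON
sidecar recording the design and ground truth for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cd import CDSpectrum
from .displacement import DisplacementSeries
from .errors import ValidationError
from .quenching import TitrationPoint, TitrationSeries

TITRATION_COLUMNS = ["temperature_K", "Q_molar", "F_obs", "A_ex", "A_em"]


def write_titration(series_list: Sequence[TitrationSeries], path) -> None:
    rows = []
    for s in series_list:
        for p in s.points:
            row = {
                "temperature_K": s.temperature,
                "Q_molar": p.q,
                "F_obs": p.f_obs,
                "A_ex": p.a_ex,
                "A_em": p.a_em,
            }
            if p.lambda_max is not None:
                row["lambda_max_nm"] = p.lambda_max
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_titration(path, temperature: float | None = None) -> list[TitrationSeries]:
    """Read a titration table, returning one series per temperature."""
    df = _read_csv(path)
    if "temperature_K" not in df.columns:
        if temperature is None:
            raise ValidationError(
                f"{path}: no temperature_K column and no temperature given"
            )
        df = df.assign(temperature_K=temperature)
    for col in ("Q_molar", "F_obs"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if "A_ex" not in df.columns:
        df = df.assign(A_ex=0.0)
    if "A_em" not in df.columns:
        df = df.assign(A_em=0.0)
    series = []
    for t, group in df.groupby("temperature_K", sort=True):
        group = group.sort_values("Q_molar")
        points = tuple(
            TitrationPoint(
                q=row.Q_molar,
                f_obs=row.F_obs,
                a_ex=row.A_ex,
                a_em=row.A_em,
                lambda_max=getattr(row, "lambda_max_nm", None),
            )
            for row in group.itertuples()
        )
        series.append(TitrationSeries(points=points, temperature=float(t)))
    return series


def write_displacement(series_list: Sequence[DisplacementSeries], path) -> None:
    rows = [
        {"marker": s.marker, "ratio": r, "F": f}
        for s in series_list
        for r, f in zip(s.ratios, s.f)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_displacement(path) -> list[DisplacementSeries]:
    df = _read_csv(path)
    for col in ("marker", "ratio", "F"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    out = []
    for marker, group in df.groupby("marker", sort=True):
        group = group.sort_values("ratio")
        out.append(
            DisplacementSeries(
                marker=str(marker),
                ratios=tuple(group["ratio"]),
                f=tuple(group["F"]),
            )
        )
    return out


def write_cd(spectra_by_ratio: Mapping[float, CDSpectrum], path) -> None:
    rows = [
        {"ratio": ratio, "wavelength_nm": wl, "ellipticity_mdeg": el}
        for ratio, spec in sorted(spectra_by_ratio.items())
        for wl, el in zip(spec.wavelengths, spec.ellipticity)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cd(path) -> dict[float, CDSpectrum]:
    df = _read_csv(path)
    if "ratio" not in df.columns:
        df = df.assign(ratio=0.0)
    for col in ("wavelength_nm", "ellipticity_mdeg"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    out = {}
    for ratio, group in df.groupby("ratio", sort=True):
        group = group.sort_values("wavelength_nm")
        out[float(ratio)] = CDSpectrum(
            wavelengths=group["wavelength_nm"].to_numpy(),
            ellipticity=group["ellipticity_mdeg"].to_numpy(),
        )
    return out


def read_descriptors(path) -> pd.DataFrame:
    """Read a descriptor table (one row per compound)."""
    df = _read_csv(path)
    if "compound_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'compound_id'")
    return df


def write_sidecar(payload: dict, path) -> None:
    """Write a JSON provenance sidecar next to a generated fixture."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot parse table {path}: {exc}") from exc
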