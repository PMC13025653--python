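"""Delimited-table and FASTA readers/writers plus declarative configuration.

Comma is the default delimiter and tab is auto-detected; all files are
UTF-8 and numbers are locale-independent (decimal point, no thousands
separators).  Readers validate against the consuming type's invariants
and fail with errors naming the offending column, row or record; there
is no silent coercion.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .assays import KineticTrace
from .errors import ConfigError, DataError
from .pepscreen import FunnelReport, PeptideRecord, ScreenConfig
from .rsm import AnovaReport, DesignTable, FactorSpec, code_point

__all__ = [
    "read_table",
    "read_design_table",
    "read_kinetic_trace",
    "read_peptide_table",
    "read_fasta",
    "write_anova",
    "write_funnel",
    "read_factor_specs",
    "PipelineConfig",
]

_PEPTIDE_COLUMNS = {
    # table column -> PeptideRecord field / score key
    "sequence": "sequence",
    "mass": "observed_mass",
    "alc": "alc",
    "rt": "retention_time",
    "area": "peak_area",
    "ranker": "bioactivity",
    "toxin": "toxicity",
    "solubility": "solubility",
}


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table, auto-detecting comma vs tab."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise DataError(f"{path}: file is empty")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    return pd.read_csv(path, sep=sep)


def _numeric(frame: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(frame[column], errors="coerce")
    bad = vals.isna() & frame[column].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise DataError(
            f"{path}: non-numeric value {frame[column][row]!r} in column {column!r}, row {row + 2}"
        )
    return vals.to_numpy(float)


def read_design_table(
    path: str | Path,
    factors: Sequence[FactorSpec],
    strict_design: bool = False,
) -> DesignTable:
    """Read a run table with factor columns in actual units plus responses.

    The header must contain the three factor names; every remaining
    numeric column becomes a response.  With ``strict_design`` the
    Box-Behnken structure of the runs is verified.
    """
    path = Path(path)
    frame = read_table(path)
    for f in factors:
        if f.name not in frame.columns:
            raise DataError(f"{path}: missing factor column {f.name!r}")
    actual = np.column_stack([_numeric(frame, f.name, path) for f in factors])
    coded = np.array([code_point(factors, row) for row in actual])
    response_cols = [c for c in frame.columns if c not in {f.name for f in factors}]
    responses = {c: _numeric(frame, c, path) for c in response_cols}
    design = DesignTable(tuple(factors), coded, actual, responses)
    if strict_design:
        design.validate_bbd()
    return design


def read_kinetic_trace(path: str | Path, time_unit: str = "s") -> KineticTrace:
    """Read a two-column (time, absorbance) trace; time unit declared by the caller."""
    path = Path(path)
    frame = read_table(path)
    if frame.shape[1] < 2:
        raise DataError(f"{path}: a kinetic trace needs two columns (time, absorbance)")
    t = _numeric(frame, frame.columns[0], path)
    a = _numeric(frame, frame.columns[1], path)
    return KineticTrace(t, a, time_unit=time_unit)


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide ID table (columns ``sequence, mass, alc, rt, area, ranker,
    toxin, solubility``; all but ``sequence`` optional, extras ignored)."""
    path = Path(path)
    frame = read_table(path)
    if "sequence" not in frame.columns:
        raise DataError(f"{path}: missing required column 'sequence'")
    records = []
    for i, row in frame.iterrows():
        fields: dict = {"external_scores": {}}
        for col, target in _PEPTIDE_COLUMNS.items():
            if col not in frame.columns or pd.isna(row[col]):
                continue
            if target in ("bioactivity",):
                fields["external_scores"][target] = float(row[col])
            elif target in ("toxicity", "solubility"):
                fields["external_scores"][target] = str(row[col])
            elif target == "sequence":
                fields["sequence"] = str(row[col])
            else:
                fields[target] = float(row[col])
        try:
            records.append(PeptideRecord(**fields))
        except Exception as exc:
            raise DataError(f"{path}: row {i + 2}: {exc}") from exc
    if not records:
        raise DataError(f"{path}: no peptide records")
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read peptide sequences from FASTA; headers kept as identifiers,
    sequences normalised to uppercase."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise DataError(f"{path}: no FASTA records found")
    return out


def write_anova(report: AnovaReport, path: str | Path) -> None:
    """Write an ANOVA report as a delimited table (Source, SS, Df, MS, F, p)
    followed by the fit statistics."""
    path = Path(path)
    table = report.table.copy()
    table["SS"] = table["SS"].map(lambda v: f"{v:.6g}")
    table["MS"] = table["MS"].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    table["F"] = table["F"].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    table["p"] = table["p"].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    lines = [",".join(table.columns)]
    lines += [",".join(str(v) for v in row) for row in table.itertuples(index=False)]
    lines.append(f"R2,{report.r2:.6g}")
    lines.append(f"R2_adj,{report.r2_adj:.6g}")
    lines.append(f"CV_percent,{report.cv_percent:.6g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_funnel(report: FunnelReport, path: str | Path) -> None:
    """Write the per-stage funnel attrition as a delimited table."""
    path = Path(path)
    lines = ["stage,entering,surviving,survivor_ids"]
    for row in report.to_rows():
        lines.append(f"{row['stage']},{row['entering']},{row['surviving']},{row['survivor_ids']}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_factor_specs(path: str | Path) -> tuple[FactorSpec, ...]:
    """Read factor specs from YAML: a list of {name, low, center, high}."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such file: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    entries = raw.get("factors", raw) if isinstance(raw, dict) else raw
    if not isinstance(entries, list) or not entries:
        raise ConfigError(f"{path}: expected a list of factor specs")
    specs = []
    for entry in entries:
        unknown = set(entry) - {"name", "low", "center", "high"}
        if unknown:
            raise ConfigError(f"{path}: unknown factor keys {sorted(unknown)}")
        try:
            specs.append(FactorSpec(str(entry["name"]), float(entry["low"]),
                                    float(entry["center"]), float(entry["high"])))
        except KeyError as exc:
            raise ConfigError(f"{path}: factor spec missing key {exc}") from exc
    return tuple(specs)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration for a whole run, parsed from one YAML file.

    Unknown keys are rejected by name so typos never pass silently.
    """

    factors: tuple[FactorSpec, ...] = ()
    pka_variant: str = "standard"
    curve_family: str = "quadratic"
    time_unit: str = "s"
    screen: ScreenConfig = ScreenConfig()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"no such file: {path}")
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        known = {"factors", "pka_variant", "curve_family", "time_unit", "screen", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        kwargs: dict = {}
        if "factors" in raw:
            kwargs["factors"] = tuple(
                FactorSpec(e["name"], float(e["low"]), float(e["center"]), float(e["high"]))
                for e in raw["factors"]
            )
        for key in ("pka_variant", "curve_family", "time_unit", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "screen" in raw:
            valid = {f.name for f in dataclasses.fields(ScreenConfig)}
            unknown = set(raw["screen"]) - valid
            if unknown:
                raise ConfigError(f"{path}: unknown screen keys {sorted(unknown)}")
            kwargs["screen"] = ScreenConfig(**raw["screen"])
        return cls(**kwargs)
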