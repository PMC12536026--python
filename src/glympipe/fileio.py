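"""File-format contracts: subject tables, per-subject signal TSVs,
manifests, NIfTI phantoms, and schema validation.

All tables are plain CSV/TSV with documented headers; results are JSON.
Percentages are stored as percent (a CPV fraction of 0.09% is written as
0.09), volumes in ml, diffusivities in 1e-3 mm^2/s, durations in months.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import TimeSeries

SUBJECT_COLUMNS = [
    "subject_id", "group", "age", "sex", "bmi", "education", "alsfrs_r",
    "duration_months", "onset", "progression_rate", "coupling_index",
    "alps_index", "cpv_ml", "tiv_ml", "cpv_fraction_pct",
]


class SchemaError(ValueError):
    """A table violates its declared schema (missing column, bad range)."""


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def write_signal_tsv(path, gbold: TimeSeries, csf: TimeSeries) -> None:
    """Two-signal TSV with a comment header carrying tr and t0."""
    if len(gbold) != len(csf) or not np.isclose(gbold.tr, csf.tr):
        raise ValueError("gbold and csf must share length and tr")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# tr={gbold.tr:g} t0={gbold.t0:g}\n")
        fh.write("time_s\tgbold\tcsf\n")
        for t, g, c in zip(gbold.times, gbold.values, csf.values):
            fh.write(f"{t:.6g}\t{g:.10g}\t{c:.10g}\n")


def read_signal_tsv(path) -> tuple[TimeSeries, TimeSeries]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise SchemaError(f"{path}: missing '# tr=...' header line")
    meta = dict(item.split("=") for item in header[1:].split())
    tr = float(meta["tr"])
    t0 = float(meta.get("t0", 0.0))
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gbold", "csf"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    return (TimeSeries(df["gbold"].to_numpy(float), tr, t0),
            TimeSeries(df["csf"].to_numpy(float), tr, t0))


def write_subject_table(path, table: pd.DataFrame) -> None:
    missing = [c for c in SUBJECT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"subject table missing columns: {missing}")
    table.to_csv(path, index=False, float_format="%.10g")


def read_subject_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    report = validate_subject_table(table)
    if not report.ok:
        raise SchemaError("; ".join(report.errors))
    return table


def read_manifest(path) -> pd.DataFrame:
    """Manifest CSV listing per-subject signal files.

    Columns: ``subject_id, signal_path`` (paths relative to the manifest's
    directory or absolute).
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("subject_id", "signal_path"):
        if col not in df.columns:
            raise SchemaError(f"{path}: manifest missing required column '{col}'")
    df["signal_path"] = [
        str(p) if Path(p).is_absolute() else str(path.parent / p)
        for p in df["signal_path"]
    ]
    return df


def validate_subject_table(table: pd.DataFrame) -> ValidationReport:
    """Range, uniqueness, and internal-consistency checks."""
    rep = ValidationReport()
    missing = [c for c in SUBJECT_COLUMNS if c not in table.columns]
    if missing:
        rep.errors.append(f"missing columns: {missing}")
        return rep

    if table["subject_id"].duplicated().any():
        rep.errors.append("duplicate subject_id values")
    bad_group = set(table["group"].dropna().unique()) - {"ALS", "HC"}
    if bad_group:
        rep.errors.append(f"unknown group labels: {sorted(bad_group)}")

    def check_range(col, lo=None, hi=None, strict_lo=False):
        v = table[col].dropna()
        if lo is not None:
            bad = v <= lo if strict_lo else v < lo
            if bad.any():
                rep.errors.append(f"{col}: {int(bad.sum())} values out of range (min {lo})")
        if hi is not None and (v > hi).any():
            rep.errors.append(f"{col}: {int((v > hi).sum())} values out of range (max {hi})")

    check_range("alsfrs_r", 0, 48)
    check_range("duration_months", 0, strict_lo=True)
    check_range("cpv_ml", 0, strict_lo=True)
    check_range("tiv_ml", 0, strict_lo=True)
    check_range("cpv_fraction_pct", 0, 100, strict_lo=True)

    complete = table.dropna(subset=["cpv_ml", "tiv_ml", "cpv_fraction_pct"])
    if len(complete):
        if (complete["cpv_ml"] >= complete["tiv_ml"]).any():
            rep.errors.append("cpv_ml >= tiv_ml for some subjects")
        expected = 100.0 * complete["cpv_ml"] / complete["tiv_ml"]
        if (np.abs(expected - complete["cpv_fraction_pct"]) > 1e-6).any():
            rep.errors.append("cpv_fraction_pct inconsistent with 100*cpv/tiv (> 1e-6)")

    clin = table.dropna(subset=["alsfrs_r", "duration_months", "progression_rate"])
    if len(clin):
        expected = (48.0 - clin["alsfrs_r"]) / clin["duration_months"]
        if (np.abs(expected - clin["progression_rate"]) > 1e-6).any():
            rep.errors.append("progression_rate inconsistent with (48-alsfrs_r)/duration")

    als = table[table["group"] == "ALS"]
    if als["alsfrs_r"].isna().any():
        rep.warnings.append("ALS rows with missing alsfrs_r")
    return rep


def validate_table(path, schema: str = "subject") -> ValidationReport:
    """Validate a file on disk against a named schema."""
    path = Path(path)
    if not path.exists():
        rep = ValidationReport()
        rep.errors.append(f"file not found: {path}")
        return rep
    if schema == "subject":
        try:
            table = pd.read_csv(path)
        except (pd.errors.ParserError, UnicodeDecodeError) as exc:
            rep = ValidationReport()
            rep.errors.append(f"{path}: not a readable CSV ({exc})")
            return rep
        return validate_subject_table(table)
    if schema == "signal":
        rep = ValidationReport()
        try:
            read_signal_tsv(path)
        except (SchemaError, KeyError, ValueError) as exc:
            rep.errors.append(str(exc))
        return rep
    raise ValueError(f"unknown schema {schema!r}")


def write_json(path, payload: dict) -> None:
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")


def write_phantom_nifti(prefix, image4d: np.ndarray, gm_mask: np.ndarray,
                        csf_mask: np.ndarray, tr: float) -> list[Path]:
    """Write the toy phantom and its masks as NIfTI (optional path)."""
    import nibabel as nib

    prefix = Path(prefix)
    affine = np.eye(4)
    paths = []
    for suffix, data in (("bold", image4d.astype(np.float32)),
                         ("gm_mask", gm_mask.astype(np.uint8)),
                         ("csf_mask", csf_mask.astype(np.uint8))):
        img = nib.Nifti1Image(data, affine)
        if suffix == "bold":
            img.header["pixdim"][4] = tr
        out = prefix.with_name(prefix.name + f"_{suffix}.nii")
        nib.save(img, out)
        paths.append(out)
    return paths
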