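"""Tabular glymphatic markers: DTI-ALPS index, CPV fraction, progression rate.

These are pure functions of upstream-derived tables (directional
diffusivities from tensor fitting, FreeSurfer volumetry, clinical scores);
no image processing happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HemisphereDiffusivities:
    """Directional diffusivities (1e-3 mm^2/s) for one hemisphere.

    x is the left-right axis (perpendicular to both fiber systems at the
    level of the lateral ventricle body), y anterior-posterior along the
    projection fibers, z inferior-superior along the association fibers.
    """

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float

    def __post_init__(self) -> None:
        for name in ("dxx_proj", "dxx_assoc", "dyy_proj", "dzz_assoc"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")

    def ratio(self) -> float:
        return (self.dxx_proj + self.dxx_assoc) / (self.dyy_proj + self.dzz_assoc)


@dataclass(frozen=True)
class AlpsInputs:
    left: HemisphereDiffusivities
    right: HemisphereDiffusivities


def alps_index(d: AlpsInputs, mode: str = "per_hemisphere_mean") -> float:
    """Diffusivity-along-the-perivascular-space index.

    The ratio ``(Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)`` of
    diffusivity perpendicular to the dominant fiber directions (the
    perivascular orientation) over diffusivity along them; values near 1
    indicate no preferential perivascular diffusion, higher values more.

    ``per_hemisphere_mean`` (default) computes the ratio per hemisphere
    and averages; ``pooled`` averages the four diffusivities across
    hemispheres first and takes a single ratio.  The two agree exactly
    when hemispheres are identical.
    """
    if mode == "per_hemisphere_mean":
        return 0.5 * (d.left.ratio() + d.right.ratio())
    if mode == "pooled":
        num = 0.5 * (d.left.dxx_proj + d.right.dxx_proj) + \
            0.5 * (d.left.dxx_assoc + d.right.dxx_assoc)
        den = 0.5 * (d.left.dyy_proj + d.right.dyy_proj) + \
            0.5 * (d.left.dzz_assoc + d.right.dzz_assoc)
        return num / den
    raise ValueError(f"unknown mode {mode!r}")


def alps_from_table(diffusivities: pd.DataFrame,
                    mode: str = "per_hemisphere_mean") -> pd.Series:
    """ALPS index per subject from a long-format diffusivity table.

    Expects columns ``subject_id, hemisphere, dxx_proj, dxx_assoc,
    dyy_proj, dzz_assoc`` with one row per hemisphere.
    """
    required = {"subject_id", "hemisphere", "dxx_proj", "dxx_assoc",
                "dyy_proj", "dzz_assoc"}
    missing = required - set(diffusivities.columns)
    if missing:
        raise ValueError(f"diffusivity table missing columns: {sorted(missing)}")

    def per_subject(sub: pd.DataFrame) -> float:
        hemis = {}
        for _, row in sub.iterrows():
            hemis[row["hemisphere"]] = HemisphereDiffusivities(
                row["dxx_proj"], row["dxx_assoc"], row["dyy_proj"], row["dzz_assoc"]
            )
        if set(hemis) != {"left", "right"}:
            raise ValueError(
                f"subject {sub['subject_id'].iloc[0]!r} must have exactly "
                "left and right hemisphere rows"
            )
        return alps_index(AlpsInputs(hemis["left"], hemis["right"]), mode=mode)

    grouped = diffusivities.groupby("subject_id", sort=False)
    return grouped[list(required)].apply(per_subject)


def cpv_fraction(cpv: float, tiv: float) -> float:
    """Choroid-plexus volume as a percentage of total intracranial volume."""
    if not (cpv > 0):
        raise ValueError("cpv must be positive")
    if not (tiv > 0):
        raise ValueError("tiv must be positive")
    if cpv >= tiv:
        raise ValueError("cpv must be smaller than tiv")
    return 100.0 * cpv / tiv


def progression_rate(alsfrs_r: float, duration_months: float) -> float:
    """Disease progression rate in ALSFRS-R points lost per month.

    ``(48 - ALSFRS-R) / disease duration``, where 48 is the maximum
    (fully functional) score.
    """
    if not (0.0 <= alsfrs_r <= 48.0):
        raise ValueError("alsfrs_r must lie in [0, 48]")
    if not (duration_months > 0):
        raise ValueError("duration must be positive")
    return (48.0 - alsfrs_r) / duration_months
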