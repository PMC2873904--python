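"""FRET ratio <-> normalized activity conversion and tabular I/O.

The FRET signal is the CFP/YFP intensity ratio R of the CheZ-CFP /
CheY-P-YFP pair.  The number of interacting FRET pairs — which proxies
kinase activity — follows from the two-channel intensity bookkeeping:
energy transfer moves intensity Delta from the donor to the acceptor
channel scaled by the fluorescence efficiency ratio alpha, so the pair
count is proportional to (R - R_sat)/(R + alpha), where R_sat is the
ratio at a saturating attractant dose (kinase fully off, zero FRET).
Normalizing by the adapted pre-stimulus ratio R_0 gives

    A_norm(R) = (R - R_sat) (R_0 + alpha) / ((R_0 - R_sat) (R + alpha)),

which maps R_0 -> 1 and R_sat -> 0 and is strictly monotone between.
A plain linear normalization (R - R_sat)/(R_0 - R_sat) is available as
an alternative mode.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FretCalibration",
    "ratio_to_activity",
    "activity_to_ratio",
    "read_timecourse",
    "write_timecourse",
]


@dataclasses.dataclass(frozen=True)
class FretCalibration:
    """Per-experiment FRET calibration."""

    R_sat: float  # ratio at saturating attractant (zero FRET)
    R_0: float  # adapted pre-stimulus ratio
    alpha: float = 0.43  # fluorescence efficiency ratio of the setup
    dt_sample: float = 0.2  # sampling resolution [s]

    def __post_init__(self) -> None:
        if self.R_sat == self.R_0:
            raise ValueError("R_sat and R_0 must differ")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be positive")


def ratio_to_activity(R, calib: FretCalibration, mode: str = "ratiometric"):
    """Normalized activity from the FRET ratio; R_0 -> 1, R_sat -> 0.

    Ratios outside [min(R_sat, R_0_side extrapolation)] are clamped to
    the physical branch with a warning (the transform stays monotone on
    the clamped range).
    """
    R = np.asarray(R, dtype=float)
    lo, hi = min(calib.R_sat, calib.R_0), max(calib.R_sat, calib.R_0)
    # activities above the adapted value are physical (R beyond R_0); only
    # the zero-FRET side is a hard bound
    if calib.R_0 > calib.R_sat:
        bad = R < lo
        R_cl = np.maximum(R, lo)
    else:
        bad = R > hi
        R_cl = np.minimum(R, hi)
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} ratio value(s) beyond the zero-FRET bound "
            f"were clamped", stacklevel=2,
        )
    if mode == "ratiometric":
        out = ((R_cl - calib.R_sat) * (calib.R_0 + calib.alpha)
               / ((calib.R_0 - calib.R_sat) * (R_cl + calib.alpha)))
    elif mode == "linear":
        out = (R_cl - calib.R_sat) / (calib.R_0 - calib.R_sat)
    else:
        raise ValueError("mode must be 'ratiometric' or 'linear'")
    return out if out.ndim else float(out)


def activity_to_ratio(A_norm, calib: FretCalibration, mode: str = "ratiometric"):
    """Exact inverse of :func:`ratio_to_activity` (used by the synthetic generator)."""
    A_norm = np.asarray(A_norm, dtype=float)
    if mode == "ratiometric":
        c = A_norm * (calib.R_0 - calib.R_sat) / (calib.R_0 + calib.alpha)
        if np.any(c >= 1):
            raise ValueError("activity too large to invert: implied infinite ratio")
        out = (calib.R_sat + c * calib.alpha) / (1.0 - c)
    elif mode == "linear":
        out = calib.R_sat + A_norm * (calib.R_0 - calib.R_sat)
    else:
        raise ValueError("mode must be 'ratiometric' or 'linear'")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# delimited-text tables

def write_timecourse(path: str | Path, table: pd.DataFrame,
                     header_lines: list[str] | None = None,
                     sep: str = ",") -> None:
    """Write a table as delimited text; '#' provenance lines before the header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False, sep=sep)


def read_timecourse(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a delimited text table (comma or tab), resolving columns by header.

    Malformed numeric rows are reported with their line numbers; an
    empty file raises an explicit error.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    body = [(i + 1, ln) for i, ln in enumerate(raw_lines)
            if ln.strip() and not ln.lstrip().startswith("#")]
    if not body:
        raise ValueError(f"{path}: empty table (no header or data rows)")
    text = "\n".join(ln for _, ln in body)
    sep = "\t" if "\t" in body[0][1] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: table has a header but no data rows")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    bad_rows = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.all():
            continue  # genuinely non-numeric column (labels etc.)
        if bad.any():
            for i in df.index[bad]:
                bad_rows.append((body[i + 1][0], col, df.at[i, col]))
        df[col] = coerced
    if bad_rows:
        detail = "; ".join(f"line {ln}: column {c!r} value {v!r}"
                           for ln, c, v in bad_rows[:5])
        raise ValueError(f"{path}: malformed numeric values ({detail})")
    return df
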