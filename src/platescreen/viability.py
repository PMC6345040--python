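"""Raw fluorescence to percent cell viability.

In a resazurin (alamarBlue-type) assay, metabolically active cells reduce
resazurin to fluorescent resorufin, so after subtracting the background
fluorescence of medium-only (blank) wells the signal is proportional to the
number of viable cells. Percent viability of a well is then its
blank-corrected signal divided by the blank-corrected mean of the control
wells on the same plate, times 100. The control is the DMSO (vehicle) wells
for single-agent data, or the fixed-concentration single-agent wells for
combination series; the caller selects which via ``control_role``.

Blanks are per plate: plate-to-plate gain differences make a shared blank
inappropriate. Negative blank-corrected values (signal below background)
are kept as-is and flagged, not clamped — the record stays faithful to the
raw data; any flooring happens only at the log step of screen scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ControlError


def blank_correct(readings, blank_readings) -> np.ndarray:
    """Subtract the mean blank fluorescence from raw readings.

    Parameters
    ----------
    readings : array-like
        Raw fluorescence intensities.
    blank_readings : array-like
        Readings of the plate's medium-only wells; must be non-empty.

    Returns
    -------
    numpy.ndarray
        ``readings - mean(blank_readings)``; values may be negative.
    """
    blanks = np.asarray(blank_readings, dtype=float)
    if blanks.size == 0:
        raise ControlError("blank correction requires at least one blank well")
    return np.asarray(readings, dtype=float) - blanks.mean()


def percent_viability(corrected, control_mean_corrected: float):
    """Express blank-corrected signal as percent of the control mean.

    ``control_mean_corrected`` must be positive; the result may exceed 100
    (wells healthier than control) or be negative (signal below background).
    """
    if not control_mean_corrected > 0:
        raise ControlError(
            f"control mean must be positive, got {control_mean_corrected!r}"
        )
    return 100.0 * np.asarray(corrected, dtype=float) / control_mean_corrected

def add_viability(table: pd.DataFrame, control_role: str = "dmso") -> pd.DataFrame:
    """Append blank-corrected and percent-viability columns to a long table.

    Per plate: subtract the mean blank reading, then divide non-blank wells
    by the mean corrected signal of that plate's ``control_role`` wells.
    Adds three columns: ``corrected``, ``percent_viability`` (NaN for blank
    wells) and ``flag_negative`` (corrected signal below zero on a
    non-blank well).

    Raises
    ------
    ControlError
        If any plate lacks blank wells or ``control_role`` wells, or a
        plate's corrected control mean is not positive.
    """
    df = table.copy()
    plate_ids = df["plate_id"].unique()

    is_blank = df["role"].to_numpy() == "blank"
    blank_means = df.loc[is_blank].groupby("plate_id")["reading"].mean()
    missing = [p for p in plate_ids if p not in blank_means.index]
    if missing:
        raise ControlError(f"no blank wells on plate(s): {', '.join(map(str, missing))}")
    df["corrected"] = df["reading"] - df["plate_id"].map(blank_means).to_numpy()

    is_ctrl = df["role"].to_numpy() == control_role
    ctrl_means = df.loc[is_ctrl].groupby("plate_id")["corrected"].mean()
    missing = [p for p in plate_ids if p not in ctrl_means.index]
    if missing:
        raise ControlError(
            f"no {control_role!r} control wells on plate(s): "
            + ", ".join(map(str, missing))
        )
    bad = ctrl_means[ctrl_means <= 0]
    if len(bad):
        raise ControlError(
            "non-positive corrected control mean on plate(s): "
            + ", ".join(f"{p} ({v:.3g})" for p, v in bad.items())
        )
    df["percent_viability"] = (
        100.0 * df["corrected"] / df["plate_id"].map(ctrl_means).to_numpy()
    )
    df.loc[is_blank, "percent_viability"] = np.nan
    df["flag_negative"] = (df["corrected"] < 0) & ~is_blank
    return df
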