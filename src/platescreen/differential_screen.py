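"""Differential Z-score scoring of a two-condition viability screen.

The scoring chain for a compound library screened under two conditions
(e.g. a cell line with and without a fixed dose of a modulator, or two
cell lines):

1. per plate, express every compound well as percent of that plate's
   DMSO-control mean (after blank subtraction);
2. average a compound's wells across duplicate plates and independent
   runs (4 wells per condition in the canonical 2 runs x duplicate design);
3. divide each compound's mean viability by the screen-wide mean viability
   of its condition, so both conditions sit on a common unitless scale;
4. for each compound take the log ratio of the two conditions,
   L_i = ln(norm_ref_i / norm_test_i), and standardize by the screen-wide
   spread: Z_i = (L_i - mean(L)) / SD(L), sample SD (n-1) over all
   compounds pooled across plates;
5. call hits at |Z| >= 2 (inclusive): Z >= 2 means the compound is
   selectively cytotoxic in the *test* condition (lower viability there),
   Z <= -2 selectively cytotoxic in the *reference* condition.

Z-scores are invariant to the log base (any base rescales L and SD(L)
alike), so natural log is used throughout. Normalized viabilities at or
below zero — possible after blank correction of total-kill wells — are
floored at a small positive value before the log and flagged, keeping L
finite without discarding the compound.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import viability
from .errors import ControlError, DegenerateScreenError, MismatchedCompoundsError

#: Default floor applied to normalized viabilities before taking logs.
DEFAULT_LOG_FLOOR = 1e-3
#: Default |Z| hit threshold, boundaries inclusive.
DEFAULT_THRESHOLD = 2.0

HIT_CLASSES = ("selective_in_test", "selective_in_reference", "none")


def normalize_to_plate_dmso(table: pd.DataFrame) -> pd.DataFrame:
    """Express each well as percent of its own plate's DMSO-control mean.

    Thin wrapper over :func:`platescreen.viability.add_viability` with the
    DMSO wells as control; raises :class:`ControlError` naming the plate if
    DMSO wells are missing or their corrected mean is not positive.
    """
    return viability.add_viability(table, control_role="dmso")


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average each compound's percent viability over all wells and runs.

    Takes a long table carrying ``percent_viability`` and returns one row
    per (compound_id, condition) with columns ``mean_percent_viability``
    and ``n_wells``. The mean is unweighted over wells, which equals the
    mean of run means under balanced replication (the canonical design:
    2 runs x duplicate plates = 4 wells). Compounds left with a single
    well only trigger a warning, not an error.
    """
    cmp_rows = table[table["role"] == "compound"]
    if cmp_rows.empty:
        raise MismatchedCompoundsError("no compound wells in table")
    grouped = cmp_rows.groupby(["compound_id", "condition"], sort=True)
    out = grouped["percent_viability"].agg(
        mean_percent_viability="mean", n_wells="size"
    ).reset_index()
    singles = out.loc[out["n_wells"] == 1, "compound_id"]
    if len(singles):
        warnings.warn(
            "single-well compounds (no replication): "
            + ", ".join(singles.astype(str).tolist()[:10]),
            stacklevel=2,
        )
    return out


def normalize_to_screen_mean(compound_viability: pd.DataFrame) -> pd.DataFrame:
    """Divide each compound's mean viability by its condition's screen mean.

    Adds a ``norm_viability`` column; within each condition the mean of
    ``norm_viability`` over compounds is exactly 1.
    """
    df = compound_viability.copy()
    for cond, idx in df.groupby("condition").groups.items():
        sub = df.loc[idx, "mean_percent_viability"]
        if len(sub) < 2:
            raise DegenerateScreenError(
                f"condition {cond!r}: screen-mean normalization needs >= 2 compounds"
            )
        mean = sub.mean()
        if not mean > 0:
            raise ControlError(
                f"condition {cond!r}: screen mean viability is not positive ({mean:.3g})"
            )
        df.loc[idx, "norm_viability"] = sub / mean
    return df


def differential_zscore(
    reference: pd.DataFrame,
    test: pd.DataFrame,
    floor: float = DEFAULT_LOG_FLOOR,
) -> pd.DataFrame:
    """Per-compound log viability ratio between conditions, standardized.

    Parameters
    ----------
    reference, test : DataFrame
        Screen-mean-normalized compound viabilities (one row per compound,
        with ``norm_viability``) of the two conditions; the compound sets
        must match.
    floor : float
        Positive floor applied to normalized viabilities before the log.

    Returns
    -------
    DataFrame with columns ``compound_id, mean_viab_ref, mean_viab_test,
    norm_ref, norm_test, log_ratio, zscore, flag_floored``; mean(zscore)=0
    and SD(zscore)=1 (n-1) by construction.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    ref = reference.set_index("compound_id").sort_index()
    tst = test.set_index("compound_id").sort_index()
    only_ref = ref.index.difference(tst.index)
    only_tst = tst.index.difference(ref.index)
    if len(only_ref) or len(only_tst):
        raise MismatchedCompoundsError(
            "compound sets differ between conditions; "
            f"only in reference: {list(only_ref[:5])}, "
            f"only in test: {list(only_tst[:5])}"
        )
    if len(ref) < 3:
        raise DegenerateScreenError(
            "differential Z-score needs >= 3 compounds to estimate the screen SD"
        )
    norm_ref = ref["norm_viability"].to_numpy(dtype=float)
    norm_tst = tst["norm_viability"].to_numpy(dtype=float)
    floored = (norm_ref < floor) | (norm_tst < floor)
    log_ratio = np.log(np.maximum(norm_ref, floor) / np.maximum(norm_tst, floor))
    sd = log_ratio.std(ddof=1)
    if sd == 0:
        raise DegenerateScreenError(
            "screen is degenerate: all log viability ratios identical (SD = 0)"
        )
    zscore = (log_ratio - log_ratio.mean()) / sd
    return pd.DataFrame(
        {
            "compound_id": ref.index.to_numpy(),
            "mean_viab_ref": ref["mean_percent_viability"].to_numpy(),
            "mean_viab_test": tst["mean_percent_viability"].to_numpy(),
            "norm_ref": norm_ref,
            "norm_test": norm_tst,
            "log_ratio": log_ratio,
            "zscore": zscore,
            "flag_floored": floored,
        }
    )


def call_hits(
    scores: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Three-way hit classification at an inclusive |Z| threshold.

    Returns the score table ranked by Z descending with a ``hit_call``
    column: ``selective_in_test`` for Z >= threshold (the compound kills
    more in the test condition), ``selective_in_reference`` for
    Z <= -threshold, ``none`` otherwise.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    df = scores.copy()
    z = df["zscore"].to_numpy(dtype=float)
    df["hit_call"] = np.select(
        [z >= threshold, z <= -threshold],
        ["selective_in_test", "selective_in_reference"],
        default="none",
    )
    return df.sort_values(
        ["zscore", "compound_id"], ascending=[False, True]
    ).reset_index(drop=True)


def score_screen(
    table: pd.DataFrame,
    reference: str,
    test: str,
    threshold: float = DEFAULT_THRESHOLD,
    floor: float = DEFAULT_LOG_FLOOR,
) -> tuple[pd.DataFrame, dict]:
    """Run the full scoring chain on a raw long table.

    Plate-DMSO normalization -> replicate averaging -> screen-mean
    normalization -> differential Z -> hit calls. ``reference`` and
    ``test`` are the two condition labels; positive Z means selectively
    cytotoxic in ``test``.

    Returns the ranked score table and a summary dict (compound count,
    per-class hit counts, screen means and log-ratio spread).
    """
    present = set(table["condition"].unique())
    for cond in (reference, test):
        if cond not in present:
            raise MismatchedCompoundsError(
                f"condition {cond!r} absent from table (found {sorted(present)})"
            )
    sub = table[table["condition"].isin([reference, test])]
    normalized = normalize_to_plate_dmso(sub)
    averaged = average_replicates(normalized)
    averaged = normalize_to_screen_mean(averaged)
    ref_rows = averaged[averaged["condition"] == reference]
    tst_rows = averaged[averaged["condition"] == test]
    scores = differential_zscore(ref_rows, tst_rows, floor=floor)
    scores = call_hits(scores, threshold=threshold)
    counts = scores["hit_call"].value_counts().to_dict()
    summary = {
        "n_compounds": int(len(scores)),
        "reference": reference,
        "test": test,
        "threshold": float(threshold),
        "floor": float(floor),
        "hit_counts": {c: int(counts.get(c, 0)) for c in HIT_CLASSES},
        "screen_mean_viab_ref": float(scores["mean_viab_ref"].mean()),
        "screen_mean_viab_test": float(scores["mean_viab_test"].mean()),
        "log_ratio_mean": float(scores["log_ratio"].mean()),
        "log_ratio_sd": float(scores["log_ratio"].std(ddof=1)),
        "n_floored": int(scores["flag_floored"].sum()),
    }
    return scores, summary
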