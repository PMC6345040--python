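"""Reading, validating and reshaping 96-well plate data.

A screen run produces one raw fluorescence grid per physical plate plus a
plate map that assigns each well coordinate a role (blank, DMSO control,
fixed-dose control, compound, unused), a compound identifier and a
concentration. This module parses both, enforces layout invariants, and
flattens sets of plates into the tidy long-format table that every
downstream stage (viability conversion, screen scoring, dose-response
fitting) consumes.

Conventions
-----------
* Wells are letter-row (A-H) + 1-based column (1-12), stored as strings
  such as ``"B3"``; no zero-based indexing is exposed.
* Concentrations are always nanomolar in files and in memory.
* Unused or contaminated wells are declared in the map, never inferred.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, PlateMapError, PlateParseError

ROW_LABELS = "ABCDEFGH"
N_ROWS = 8
N_COLS = 12
#: All 96 well coordinates in row-major (reading) order.
WELLS: tuple[str, ...] = tuple(
    f"{r}{c}" for r in ROW_LABELS for c in range(1, N_COLS + 1)
)
_WELL_TO_FLAT = {w: i for i, w in enumerate(WELLS)}

ROLES = frozenset({"blank", "dmso", "fixed_dose_control", "compound", "unused"})

#: Column order of the tidy long table.
LONG_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "compound_id",
    "concentration_nM",
    "condition",
    "run",
    "replicate",
    "reading",
]

_MISSING_TOKENS = {"", "na", "nan", "n/a"}


def well_index(well: str) -> tuple[int, int]:
    """Return the (row, column) 0-based grid position of a well coordinate.

    Raises :class:`PlateMapError` for coordinates outside A1..H12.
    """
    if well not in _WELL_TO_FLAT:
        raise PlateMapError(f"invalid well coordinate {well!r} (expected A1..H12)")
    flat = _WELL_TO_FLAT[well]
    return flat // N_COLS, flat % N_COLS


@dataclass(eq=False)
class RawPlate:
    """One physical 96-well plate of raw fluorescence readings.

    ``readings`` is an 8x12 array in row-major well order (A1..A12, B1..);
    NaN marks a missing cell, which is only legal for wells the plate map
    declares unused (checked in :func:`to_long_table`).
    """

    plate_id: str
    condition: str
    run: int
    replicate: int
    readings: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.readings, dtype=float)
        if arr.shape != (N_ROWS, N_COLS):
            raise PlateParseError(
                f"plate {self.plate_id!r}: readings must be {N_ROWS}x{N_COLS}, "
                f"got {arr.shape}"
            )
        if np.any(arr[np.isfinite(arr)] < 0):
            bad = np.argwhere(np.nan_to_num(arr, nan=0.0) < 0)[0]
            well = WELLS[bad[0] * N_COLS + bad[1]]
            raise PlateParseError(
                f"plate {self.plate_id!r}: negative reading at {well}"
            )
        if self.run < 1 or self.replicate < 1:
            raise PlateParseError(
                f"plate {self.plate_id!r}: run and replicate must be >= 1"
            )
        self.readings = arr

    def reading_at(self, well: str) -> float:
        r, c = well_index(well)
        return float(self.readings[r, c])


@dataclass(frozen=True)
class WellAnnotation:
    """Layout semantics of one well: role, compound, concentration, condition.

    ``condition`` may be empty, in which case the plate-level condition
    applies; a non-empty value overrides it (mixed-condition plates).
    """

    well: str
    role: str
    compound_id: str = ""
    concentration_nM: float = math.nan
    condition: str = ""


@dataclass(eq=False)
class PlateMap:
    """Validated per-plate well annotations."""

    entries: list[WellAnnotation]
    _frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        n_blank = n_dmso = 0
        for e in self.entries:
            well_index(e.well)  # validates the coordinate
            if e.well in seen:
                raise PlateMapError(f"duplicate well {e.well} in plate map")
            seen.add(e.well)
            if e.role not in ROLES:
                raise PlateMapError(
                    f"unknown role {e.role!r} at well {e.well} "
                    f"(expected one of {sorted(ROLES)})"
                )
            if e.role == "compound" and not e.compound_id:
                raise PlateMapError(
                    f"well {e.well}: role 'compound' requires a compound_id"
                )
            n_blank += e.role == "blank"
            n_dmso += e.role == "dmso"
        if n_blank == 0:
            raise PlateMapError("plate map contains no blank (medium-only) well")
        if n_dmso == 0:
            raise PlateMapError("plate map contains no DMSO control well")

    @property
    def wells(self) -> set[str]:
        return {e.well for e in self.entries}

    def annotation_frame(self) -> pd.DataFrame:
        """Annotations of non-unused wells, with flat grid indices, cached."""
        if self._frame is None:
            rows = [
                (e.well, _WELL_TO_FLAT[e.well], e.role, e.compound_id,
                 e.concentration_nM, e.condition)
                for e in self.entries
                if e.role != "unused"
            ]
            self._frame = pd.DataFrame(
                rows,
                columns=["well", "flat", "role", "compound_id",
                         "concentration_nM", "condition"],
            )
        return self._frame


def _parse_cell(token: str, well: str, path: str) -> float:
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        value = float(token)
    except ValueError:
        raise PlateParseError(
            f"{path}: non-numeric reading {token!r} at well {well}"
        ) from None
    return value


def read_plate_grid(
    path: str,
    plate_id: str,
    condition: str = "",
    run: int = 1,
    replicate: int = 1,
) -> RawPlate:
    """Read a raw plate grid CSV into a validated :class:`RawPlate`.

    The expected layout is a header row ``plate,1,2,...,12`` followed by
    eight rows labelled A-H. Row order in the file is irrelevant; rows are
    keyed by their label. Empty or ``NA`` cells become NaN and are accepted
    only for wells the map later declares unused.
    """
    path = str(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(t.strip() for t in r)]
    if not rows:
        raise PlateParseError(f"{path}: empty plate grid")
    header = [t.strip() for t in rows[0]]
    if len(header) != N_COLS + 1 or header[1:] != [str(c) for c in range(1, N_COLS + 1)]:
        raise PlateParseError(
            f"{path}: header must be '<label>,1,2,...,12', got {','.join(header)!r}"
        )
    body = rows[1:]
    if len(body) != N_ROWS:
        raise PlateParseError(f"{path}: expected {N_ROWS} rows, got {len(body)}")
    grid = np.full((N_ROWS, N_COLS), math.nan)
    seen_labels: set[str] = set()
    for row in body:
        label = row[0].strip().upper()
        if label not in ROW_LABELS:
            raise PlateParseError(f"{path}: unexpected row label {row[0]!r}")
        if label in seen_labels:
            raise PlateParseError(f"{path}: duplicate row label {label!r}")
        seen_labels.add(label)
        if len(row) != N_COLS + 1:
            raise PlateParseError(
                f"{path}: row {label} has {len(row) - 1} cells, expected {N_COLS}"
            )
        r = ROW_LABELS.index(label)
        for c, token in enumerate(row[1:]):
            grid[r, c] = _parse_cell(token, f"{label}{c + 1}", path)
    return RawPlate(
        plate_id=plate_id,
        condition=condition,
        run=run,
        replicate=replicate,
        readings=grid,
    )


def read_plate_map(path: str) -> PlateMap:
    """Read a long-format plate-map CSV into a validated :class:`PlateMap`.

    Required columns: ``well, role, compound_id, concentration_nM, condition``.
    """
    path = str(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["well", "role", "compound_id", "concentration_nM", "condition"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateMapError(f"{path}: missing plate-map columns {missing}")
    entries = []
    for rec in df.itertuples(index=False):
        conc_token = str(rec.concentration_nM).strip()
        if conc_token.lower() in _MISSING_TOKENS:
            conc = math.nan
        else:
            try:
                conc = float(conc_token)
            except ValueError:
                raise PlateMapError(
                    f"{path}: non-numeric concentration {conc_token!r} "
                    f"at well {rec.well}"
                ) from None
            if conc < 0:
                raise PlateMapError(
                    f"{path}: negative concentration at well {rec.well}"
                )
        entries.append(
            WellAnnotation(
                well=str(rec.well).strip(),
                role=str(rec.role).strip(),
                compound_id=str(rec.compound_id).strip(),
                concentration_nM=conc,
                condition=str(rec.condition).strip(),
            )
        )
    return PlateMap(entries=entries)


def write_plate_map(plate_map: PlateMap, path: str) -> None:
    """Write a plate map back to its CSV format (lossless round trip)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["well", "role", "compound_id", "concentration_nM", "condition"])
        for e in plate_map.entries:
            conc = "" if math.isnan(e.concentration_nM) else repr(e.concentration_nM)
            w.writerow([e.well, e.role, e.compound_id, conc, e.condition])


def to_long_table(plates, plate_map: PlateMap) -> pd.DataFrame:
    """Flatten plates sharing one map into the tidy long table.

    One row per annotated (non-unused) well per plate. Every plate well must
    be covered by the map, and a missing reading is accepted only on a well
    the map declares unused.
    """
    if isinstance(plates, RawPlate):
        plates = [plates]
    plates = list(plates)
    uncovered = sorted(set(WELLS) - plate_map.wells,
                       key=lambda w: _WELL_TO_FLAT[w])
    if uncovered:
        raise CoverageError(
            "plate wells not covered by the plate map: " + ", ".join(uncovered)
        )
    ann = plate_map.annotation_frame()
    flat_idx = ann["flat"].to_numpy()
    n = len(ann)
    chunks = []
    for plate in plates:
        readings = plate.readings.ravel()[flat_idx]
        bad = np.isnan(readings)
        if bad.any():
            wells = ", ".join(ann["well"].to_numpy()[bad])
            raise CoverageError(
                f"plate {plate.plate_id!r}: missing readings at wells not "
                f"marked unused: {wells}"
            )
        cond = ann["condition"].to_numpy(dtype=object).copy()
        cond[cond == ""] = plate.condition
        chunks.append(
            pd.DataFrame(
                {
                    "plate_id": np.repeat(plate.plate_id, n),
                    "well": ann["well"].to_numpy(),
                    "role": ann["role"].to_numpy(),
                    "compound_id": ann["compound_id"].to_numpy(),
                    "concentration_nM": ann["concentration_nM"].to_numpy(),
                    "condition": cond,
                    "run": np.repeat(plate.run, n),
                    "replicate": np.repeat(plate.replicate, n),
                    "reading": readings,
                }
            )
        )
    out = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(
        columns=LONG_COLUMNS
    )
    return out[LONG_COLUMNS]


def write_long_table(table: pd.DataFrame, path: str) -> None:
    """Write a long table CSV with the canonical column order."""
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise PlateParseError(f"long table missing columns {missing}")
    table[LONG_COLUMNS].to_csv(path, index=False)


def read_long_table(path: str) -> pd.DataFrame:
    """Read a long table CSV written by :func:`write_long_table`."""
    df = pd.read_csv(
        path,
        dtype={
            "plate_id": str, "well": str, "role": str, "compound_id": str,
            "condition": str, "run": int, "replicate": int,
        },
        keep_default_na=True,
    )
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise PlateParseError(f"{path}: long table missing columns {missing}")
    df["compound_id"] = df["compound_id"].fillna("")
    df["condition"] = df["condition"].fillna("")
    return df[LONG_COLUMNS]
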