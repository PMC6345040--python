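"""Shared fixtures and test-side oracles."""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd
import pytest

from platescreen.plate_io import ROW_LABELS, WELLS, PlateMap, WellAnnotation


def write_grid_csv(path, values, row_labels=ROW_LABELS, header_label="plate"):
    """Write a plate-grid CSV; ``values`` is an 8x12 nested list (strings kept)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([header_label] + [str(c) for c in range(1, 13)])
        for label, row in zip(row_labels, values):
            w.writerow([label] + list(row))


def make_full_map(n_blank=2, n_dmso=2, n_compounds=None, screen_dose=1000.0):
    """A map covering all 96 wells: blanks, DMSO, compounds, rest unused."""
    entries = []
    cursor = 0
    for _ in range(n_blank):
        entries.append(WellAnnotation(well=WELLS[cursor], role="blank"))
        cursor += 1
    for _ in range(n_dmso):
        entries.append(WellAnnotation(well=WELLS[cursor], role="dmso"))
        cursor += 1
    if n_compounds is None:
        n_compounds = 96 - cursor
    for i in range(n_compounds):
        entries.append(
            WellAnnotation(
                well=WELLS[cursor], role="compound",
                compound_id=f"c{i + 1:03d}", concentration_nM=screen_dose,
            )
        )
        cursor += 1
    for pos in range(cursor, 96):
        entries.append(WellAnnotation(well=WELLS[pos], role="unused"))
    return PlateMap(entries=entries)


def make_viability_table(plate_specs):
    """Build a minimal long table from per-plate well specs.

    ``plate_specs`` is a list of dicts with keys plate_id, condition, run,
    replicate and wells, where wells is a list of
    (well, role, compound_id, reading).
    """
    rows = []
    for spec in plate_specs:
        for well, role, cid, reading in spec["wells"]:
            rows.append(
                {
                    "plate_id": spec["plate_id"],
                    "well": well,
                    "role": role,
                    "compound_id": cid,
                    "concentration_nM": 1000.0 if role == "compound" else np.nan,
                    "condition": spec["condition"],
                    "run": spec.get("run", 1),
                    "replicate": spec.get("replicate", 1),
                    "reading": float(reading),
                }
            )
    return pd.DataFrame(rows)


def grid_search_4pl_rss(conc, viab, hill_bounds=(0.1, 5.0),
                        logec50_bounds=(-1.0, 3.0), top_bounds=(80.0, 120.0),
                        bottom_bounds=(-10.0, 30.0), n=15, n_refine=5):
    """Brute-force oracle: best 4PL residual sum of squares on a refined grid.

    Pure grid search with iterative local refinement around the incumbent;
    evaluates the sigmoid independently of the package implementation.
    """
    conc = np.asarray(conc, dtype=float)
    viab = np.asarray(viab, dtype=float)
    logc = np.log10(conc)
    limits = [top_bounds, bottom_bounds, hill_bounds, logec50_bounds]
    bounds = [list(b) for b in limits]
    best_rss, best = np.inf, None
    for _ in range(n_refine):
        axes = [np.linspace(lo, hi, n) for lo, hi in bounds]
        top, bottom, hill, logec50 = np.meshgrid(*axes, indexing="ij", sparse=True)
        rss = np.zeros((n, n, n, n))
        for x, y in zip(logc, viab):
            pred = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - logec50)))
            rss += (pred - y) ** 2
        idx = np.unravel_index(np.argmin(rss), rss.shape)
        if rss[idx] < best_rss:
            best_rss = float(rss[idx])
            best = [axes[d][idx[d]] for d in range(4)]
        new_bounds = []
        for d in range(4):
            step = (bounds[d][1] - bounds[d][0]) / (n - 1)
            lo = max(limits[d][0], best[d] - step)
            hi = min(limits[d][1], best[d] + step)
            new_bounds.append([lo, hi])
        bounds = new_bounds
    return best_rss


@pytest.fixture
def small_screen_table():
    """Two-condition, two-plate-per-condition table with 4 compounds."""
    def plate(pid, cond, run, readings):
        wells = [("A1", "blank", "", 100.0), ("A2", "blank", "", 100.0),
                 ("A3", "dmso", "", 1100.0), ("A4", "dmso", "", 1100.0)]
        for i, r in enumerate(readings):
            wells.append((f"B{i + 1}", "compound", f"c{i + 1:03d}", r))
        return {"plate_id": pid, "condition": cond, "run": run,
                "replicate": 1, "wells": wells}

    return make_viability_table(
        [
            plate("ref_r1", "ref", 1, [600.0, 1100.0, 850.0, 350.0]),
            plate("ref_r2", "ref", 2, [620.0, 1080.0, 830.0, 370.0]),
            plate("tst_r1", "tst", 1, [600.0, 1100.0, 350.0, 850.0]),
            plate("tst_r2", "tst", 2, [580.0, 1120.0, 330.0, 870.0]),
        ]
    )
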