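"""Synthetic resazurin plate data with known ground truth.

Two generators provide the raw inputs the analysis consumes, with the
statistical structure a fluorescence viability assay produces:

* :func:`simulate_screen` builds a whole two-condition compound screen —
  a library spread over four 96-well plates, each plate run in duplicate
  and the whole screen repeated across independent runs, with DMSO-control
  and medium-only blank wells on every plate. The fluorescence of a
  cell-bearing well is ``blank_level + baseline * viability * noise`` with
  multiplicative lognormal well noise (sigma = sqrt(ln(1 + cv^2))), since
  resorufin fluorescence scales with viable-cell number; blank wells get
  independent additive Gaussian noise (SD 2% of the blank level; fully
  noiseless when noise_cv = 0). Condition-selective cytotoxic compounds
  are planted through per-condition viability multipliers and recorded in
  a ground-truth table.

* :func:`simulate_dose_response` draws percent-viability observations
  around a four-parameter logistic curve for serial-dilution dose series,
  in independent experiments with triplicate wells, optionally with a
  second arm whose absolute IC50 is shifted by a fold factor (fold > 1
  means the modulator sensitizes).

All randomness flows from one integer seed. Each plate (and each
dose-response arm/experiment) draws from its own deterministic substream,
so enlarging the design never changes the data of earlier units.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plate_io
from .dose_response import four_pl
from .errors import SimulationConfigError
from .plate_io import N_COLS, N_ROWS, WELLS, PlateMap, RawPlate, WellAnnotation

#: Additive blank-well noise, as a fraction of the blank level.
BLANK_NOISE_FRAC = 0.02


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth condition-selective effect for one library compound.

    ``viability_multiplier`` scales the compound's viability in
    ``condition`` only: 0.25 means a 4-fold kill there.
    """

    compound_id: str
    condition: str
    viability_multiplier: float

    def __post_init__(self) -> None:
        if not self.viability_multiplier > 0:
            raise SimulationConfigError("viability_multiplier must be positive")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Design of a simulated two-condition library screen.

    Defaults mirror the canonical design this package targets: a
    328-entry library on 4 plates, each plate in duplicate, the screen
    performed in 2 independent runs, compounds at a single 1 uM dose,
    with 10% multiplicative well noise.
    """

    n_compounds: int = 328
    n_plates: int = 4
    wells_dmso_per_plate: int = 8
    wells_blank_per_plate: int = 4
    conditions: tuple[str, str] = ("reference", "test")
    runs: int = 2
    duplicates: int = 2
    noise_cv: float = 0.10
    baseline_fluorescence: float = 5000.0
    blank_level: float = 200.0
    screen_dose_nM: float = 1000.0
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_plates < 1:
            raise SimulationConfigError("need >= 1 compound and >= 1 plate")
        if self.wells_dmso_per_plate < 1 or self.wells_blank_per_plate < 1:
            raise SimulationConfigError("each plate needs >= 1 DMSO and >= 1 blank well")
        if self.noise_cv < 0:
            raise SimulationConfigError("noise_cv must be >= 0")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise SimulationConfigError("conditions must be two distinct labels")
        capacity = N_ROWS * N_COLS - self.wells_dmso_per_plate - self.wells_blank_per_plate
        per_plate = math.ceil(self.n_compounds / self.n_plates)
        if per_plate > capacity:
            raise SimulationConfigError(
                f"{self.n_compounds} compounds on {self.n_plates} plates need "
                f"{per_plate}/plate but only {capacity} wells are free of controls"
            )

    @property
    def compound_ids(self) -> list[str]:
        width = len(str(self.n_compounds))
        return [f"c{i + 1:0{width}d}" for i in range(self.n_compounds)]


@dataclass(eq=False)
class SimulatedScreen:
    """Plates, per-layout maps and ground truth of one simulated screen."""

    config: ScreenSimConfig
    plates: list[RawPlate]
    maps: dict[int, PlateMap]
    plate_layout: dict[str, int]  # plate_id -> layout index
    truth: pd.DataFrame

    def long_table(self) -> pd.DataFrame:
        """Tidy long table of every plate, via the plate_io contract."""
        chunks = []
        for layout, pmap in self.maps.items():
            group = [p for p in self.plates if self.plate_layout[p.plate_id] == layout]
            chunks.append(plate_io.to_long_table(group, pmap))
        return pd.concat(chunks, ignore_index=True)


def _build_layouts(config: ScreenSimConfig) -> dict[int, PlateMap]:
    """Fixed per-plate layouts: blanks, then DMSO controls, then compounds
    in row-major order; leftover wells declared unused."""
    chunks = np.array_split(np.asarray(config.compound_ids, dtype=object),
                            config.n_plates)
    maps: dict[int, PlateMap] = {}
    for layout, chunk in enumerate(chunks):
        entries = []
        cursor = 0
        for _ in range(config.wells_blank_per_plate):
            entries.append(WellAnnotation(well=WELLS[cursor], role="blank"))
            cursor += 1
        for _ in range(config.wells_dmso_per_plate):
            entries.append(WellAnnotation(well=WELLS[cursor], role="dmso"))
            cursor += 1
        for cid in chunk:
            entries.append(
                WellAnnotation(
                    well=WELLS[cursor], role="compound", compound_id=str(cid),
                    concentration_nM=config.screen_dose_nM,
                )
            )
            cursor += 1
        for pos in range(cursor, N_ROWS * N_COLS):
            entries.append(WellAnnotation(well=WELLS[pos], role="unused"))
        maps[layout] = PlateMap(entries=entries)
    return maps


def _truth_table(config: ScreenSimConfig) -> pd.DataFrame:
    mult = {
        (cid, cond): 1.0
        for cid in config.compound_ids
        for cond in config.conditions
    }
    for eff in config.planted_effects:
        if eff.compound_id not in config.compound_ids:
            raise SimulationConfigError(
                f"planted effect references unknown compound {eff.compound_id!r}"
            )
        if eff.condition not in config.conditions:
            raise SimulationConfigError(
                f"planted effect references unknown condition {eff.condition!r}"
            )
        mult[(eff.compound_id, eff.condition)] *= eff.viability_multiplier
    planted = {(e.compound_id, e.condition) for e in config.planted_effects}
    rows = [
        {
            "compound_id": cid,
            "condition": cond,
            "true_viability": mult[(cid, cond)],
            "planted": (cid, cond) in planted,
            "expected_reading": config.blank_level
            + config.baseline_fluorescence * mult[(cid, cond)],
        }
        for cid in config.compound_ids
        for cond in config.conditions
    ]
    return pd.DataFrame(rows)


def simulate_screen(config: ScreenSimConfig) -> SimulatedScreen:
    """Generate all raw plates of a two-condition screen plus ground truth.

    Deterministic under ``config.seed``: each plate's noise comes from a
    substream keyed by (condition, run, duplicate, layout).
    """
    maps = _build_layouts(config)
    truth = _truth_table(config)
    mult = {
        (r.compound_id, r.condition): r.true_viability
        for r in truth.itertuples(index=False)
    }
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    blank_sd = BLANK_NOISE_FRAC * config.blank_level if config.noise_cv > 0 else 0.0

    plates: list[RawPlate] = []
    plate_layout: dict[str, int] = {}
    for cond_idx, cond in enumerate(config.conditions):
        for run in range(1, config.runs + 1):
            for dup in range(1, config.duplicates + 1):
                for layout in range(config.n_plates):
                    rng = np.random.default_rng(
                        np.random.SeedSequence(
                            entropy=config.seed,
                            spawn_key=(cond_idx, run, dup, layout),
                        )
                    )
                    grid = np.full(N_ROWS * N_COLS, math.nan)
                    viab = np.full(N_ROWS * N_COLS, math.nan)
                    blank_mask = np.zeros(N_ROWS * N_COLS, dtype=bool)
                    for pos, entry in enumerate(maps[layout].entries):
                        if entry.role == "blank":
                            blank_mask[pos] = True
                        elif entry.role == "dmso":
                            viab[pos] = 1.0
                        elif entry.role == "compound":
                            viab[pos] = mult[(entry.compound_id, cond)]
                    cell_mask = np.isfinite(viab)
                    noise = (
                        rng.lognormal(0.0, sigma, size=int(cell_mask.sum()))
                        if sigma > 0
                        else np.ones(int(cell_mask.sum()))
                    )
                    grid[cell_mask] = (
                        config.blank_level
                        + config.baseline_fluorescence * viab[cell_mask] * noise
                    )
                    n_blank = int(blank_mask.sum())
                    blank_noise = (
                        rng.normal(0.0, blank_sd, size=n_blank)
                        if blank_sd > 0
                        else np.zeros(n_blank)
                    )
                    grid[blank_mask] = config.blank_level + blank_noise
                    np.clip(grid, 0.0, None, out=grid)
                    plate_id = f"{cond}_run{run}_dup{dup}_p{layout + 1}"
                    plates.append(
                        RawPlate(
                            plate_id=plate_id, condition=cond, run=run,
                            replicate=dup, readings=grid.reshape(N_ROWS, N_COLS),
                        )
                    )
                    plate_layout[plate_id] = layout
    return SimulatedScreen(
        config=config, plates=plates, maps=maps,
        plate_layout=plate_layout, truth=truth,
    )


def write_plate_grid(plate: RawPlate, path: str) -> None:
    """Write one plate in the grid CSV format plate_io reads."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plate"] + [str(c) for c in range(1, N_COLS + 1)])
        for r, label in enumerate(plate_io.ROW_LABELS):
            row = [
                "NA" if math.isnan(v) else repr(float(v))
                for v in plate.readings[r]
            ]
            w.writerow([label] + row)


def write_screen(sim: SimulatedScreen, outdir: str) -> dict[str, str]:
    """Write a simulated screen as the CSV artifacts plate_io consumes.

    Produces per-plate grid CSVs, per-layout map CSVs, a manifest tying
    plates to metadata and files, the ground-truth table, and the
    ready-to-score long table. Returns the paths written.
    """
    out = Path(outdir)
    (out / "plates").mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for plate in sim.plates:
        layout = sim.plate_layout[plate.plate_id]
        grid_path = out / "plates" / f"{plate.plate_id}.csv"
        write_plate_grid(plate, str(grid_path))
        manifest_rows.append(
            {
                "plate_id": plate.plate_id, "condition": plate.condition,
                "run": plate.run, "replicate": plate.replicate,
                "grid_file": f"plates/{plate.plate_id}.csv",
                "map_file": f"maps/map_p{layout + 1}.csv",
            }
        )
    for layout, pmap in sim.maps.items():
        plate_io.write_plate_map(pmap, str(out / "maps" / f"map_p{layout + 1}.csv"))
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    sim.truth.to_csv(out / "truth.csv", index=False)
    plate_io.write_long_table(sim.long_table(), str(out / "long_table.csv"))
    return {
        "manifest": str(out / "manifest.csv"),
        "truth": str(out / "truth.csv"),
        "long_table": str(out / "long_table.csv"),
    }


def read_screen(indir: str) -> pd.DataFrame:
    """Re-read a written screen directory into a long table via plate_io.

    Exercises the full parse path (grids + maps + manifest), unlike the
    shortcut of loading ``long_table.csv`` directly.
    """
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    by_map: dict[str, list[RawPlate]] = {}
    for rec in manifest.itertuples(index=False):
        plate = plate_io.read_plate_grid(
            str(indir / rec.grid_file), plate_id=rec.plate_id,
            condition=rec.condition, run=int(rec.run), replicate=int(rec.replicate),
        )
        by_map.setdefault(rec.map_file, []).append(plate)
    chunks = [
        plate_io.to_long_table(group, plate_io.read_plate_map(str(indir / map_file)))
        for map_file, group in by_map.items()
    ]
    return pd.concat(chunks, ignore_index=True)


@dataclass(frozen=True)
class DoseResponseSimConfig:
    """Design of simulated serial-dilution dose-response experiments.

    ``true_ic50_nM`` is the absolute IC50 (50%-of-control crossing) of the
    generating curve, from which the curve's inflection ec50 is derived;
    with top=100 and bottom=0 the two coincide. ``modulator_fold_shift``
    > 1 sensitizes the modulator arm: its absolute IC50 is
    ``true_ic50_nM / modulator_fold_shift``.
    """

    true_top: float = 100.0
    true_bottom: float = 0.0
    true_hill: float = 1.0
    true_ic50_nM: float = 10.0
    top_dose_nM: float = 1000.0
    dilution_factor: float = 3.0
    n_doses: int = 8
    wells_per_dose: int = 3
    n_experiments: int = 3
    noise_cv: float = 0.05
    modulator_fold_shift: float = 1.0
    with_modulator_arm: bool = True
    compound_id: str = "c001"
    condition_labels: tuple[str, str] = ("alone", "with_modulator")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_ic50_nM > 0:
            raise SimulationConfigError("true_ic50_nM must be positive")
        if not (min(self.true_top, self.true_bottom) < 50 < max(self.true_top, self.true_bottom)):
            raise SimulationConfigError(
                "generating curve must cross 50% of control for an absolute IC50"
            )
        if self.n_doses < 4:
            raise SimulationConfigError("need >= 4 doses for a 4-parameter fit")
        if self.dilution_factor <= 1:
            raise SimulationConfigError("dilution_factor must exceed 1")
        if not self.modulator_fold_shift > 0:
            raise SimulationConfigError("modulator_fold_shift must be positive")

    @property
    def doses_nM(self) -> np.ndarray:
        return self.top_dose_nM / self.dilution_factor ** np.arange(self.n_doses)

    def ec50_for_ic50(self, ic50: float) -> float:
        """Inflection ec50 whose curve has the given absolute IC50."""
        return ic50 / ((self.true_top - 50.0) / (50.0 - self.true_bottom)) ** (
            1.0 / self.true_hill
        )


def simulate_dose_response(config: DoseResponseSimConfig) -> pd.DataFrame:
    """Draw noisy viability observations around the true 4PL curve.

    Returns a long table with columns ``compound_id, condition, experiment,
    well, concentration_nM, percent_viability``; when the modulator arm is
    enabled the second condition label carries the fold-shifted curve.
    Warns if the dose series does not bracket the 50% crossing of an arm.
    """
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    doses = config.doses_nM
    arms = [(config.condition_labels[0], config.true_ic50_nM)]
    if config.with_modulator_arm:
        arms.append(
            (config.condition_labels[1],
             config.true_ic50_nM / config.modulator_fold_shift)
        )
    rows = []
    for arm_idx, (label, ic50) in enumerate(arms):
        ec50 = config.ec50_for_ic50(ic50)
        expected = four_pl(doses, config.true_top, config.true_bottom,
                           config.true_hill, ec50)
        if expected.min() > 50.0 or expected.max() < 50.0:
            warnings.warn(
                f"arm {label!r}: dose series does not bracket the 50% crossing; "
                "absolute IC50 may be undefined on some replicates",
                stacklevel=2,
            )
        for exp in range(1, config.n_experiments + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(arm_idx, exp))
            )
            for dose, mean_v in zip(doses, expected):
                noise = (
                    rng.lognormal(0.0, sigma, size=config.wells_per_dose)
                    if sigma > 0
                    else np.ones(config.wells_per_dose)
                )
                for w, v in enumerate(mean_v * noise, start=1):
                    rows.append(
                        {
                            "compound_id": config.compound_id,
                            "condition": label,
                            "experiment": exp,
                            "well": w,
                            "concentration_nM": float(dose),
                            "percent_viability": float(v),
                        }
                    )
    return pd.DataFrame(rows)
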