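"""384-well plate layouts: geometry, DMSO controls, TSV I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
DMSO = "DMSO"


def well_name(row: str, col: int) -> str:
    return f"{row}{col:02d}"


def well_key(plate: str, well: str) -> str:
    """Canonical well identifier used in count matrices and FASTQ filenames."""
    return f"{plate}_{well}"


@dataclass
class PlateLayout:
    """Assignment of treatments to wells of one or more 384-well plates.

    ``table`` columns: plate, well (e.g. ``A01``), treatment (compound id or
    ``DMSO``), dose_uM, time_h. Invariants: (plate, well) unique, wells lie
    on the 16x24 grid, and every plate carries at least two DMSO vehicle
    wells (the fold-change denominator).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        required = {"plate", "well", "treatment", "dose_uM", "time_h"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout table missing columns: {sorted(missing)}")
        dup = self.table.duplicated(subset=["plate", "well"])
        if dup.any():
            bad = self.table.loc[dup, ["plate", "well"]].iloc[0]
            raise ValueError(f"duplicate well {bad.plate}/{bad.well} in layout")
        for w in self.table["well"]:
            row, col = w[0], w[1:]
            if row not in ROWS or not col.isdigit() or not (1 <= int(col) <= N_COLS):
                raise ValueError(f"well {w!r} is off the 384-well grid")
        for plate, grp in self.table.groupby("plate"):
            n_dmso = int((grp["treatment"] == DMSO).sum())
            if n_dmso < 2:
                raise ValueError(
                    f"plate {plate} has {n_dmso} DMSO wells; at least 2 required"
                )

    # -- views -------------------------------------------------------------
    @property
    def plates(self) -> list[str]:
        return list(dict.fromkeys(self.table["plate"]))

    @property
    def compounds(self) -> list[str]:
        t = self.table["treatment"]
        return sorted(set(t[t != DMSO]))

    def well_keys(self) -> list[str]:
        return [well_key(p, w) for p, w in zip(self.table["plate"], self.table["well"])]

    def wells_of(self, treatment: str, plate: str | None = None) -> list[str]:
        sel = self.table["treatment"] == treatment
        if plate is not None:
            sel &= self.table["plate"] == plate
        sub = self.table[sel]
        return [well_key(p, w) for p, w in zip(sub["plate"], sub["well"])]

    def plates_of(self, treatment: str) -> list[str]:
        sub = self.table[self.table["treatment"] == treatment]
        return list(dict.fromkeys(sub["plate"]))

    def plate_of_well(self, key: str) -> str:
        # well keys are PLATE_ROWCOL with the well id after the last underscore
        return key.rsplit("_", 1)[0]

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PlateLayout":
        return cls(pd.read_csv(path, sep="\t", dtype={"plate": str, "well": str, "treatment": str}))


def build_layout(
    compounds: list[str],
    replicates: int = 2,
    dmso_per_plate: int = 16,
    dose_uM: float = 1.0,
    time_h: float = 24.0,
    plate_prefix: str = "PLATE",
) -> PlateLayout:
    """Lay compounds out on as many 384-well plates as needed.

    DMSO wells are spread evenly across each plate; a compound's replicate
    wells are kept on one plate. Deterministic.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if dmso_per_plate < 2:
        raise ValueError("each plate needs at least 2 DMSO wells")
    positions = [well_name(r, c) for r in ROWS for c in range(1, N_COLS + 1)]
    capacity = len(positions) - dmso_per_plate
    if capacity < replicates:
        raise ValueError("plate cannot host a single compound at this replicate count")
    step = max(1, len(positions) // dmso_per_plate)
    dmso_positions = positions[::step][:dmso_per_plate]
    open_positions = [p for p in positions if p not in dmso_positions]

    records = []
    plate_no, used = 0, capacity  # force first plate creation

    def new_plate():
        nonlocal plate_no, used
        plate_no += 1
        used = 0
        pid = f"{plate_prefix}{plate_no:02d}"
        for w in dmso_positions:
            records.append((pid, w, DMSO, 0.0, time_h))
        return pid

    pid = None
    for comp in compounds:
        if used + replicates > capacity:
            pid = new_plate()
        for _ in range(replicates):
            records.append((pid, open_positions[used], comp, dose_uM, time_h))
            used += 1
    if not records:  # DMSO-only layout is valid (all-control screen)
        pid = new_plate()
    return PlateLayout(
        pd.DataFrame(records, columns=["plate", "well", "treatment", "dose_uM", "time_h"])
    )
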