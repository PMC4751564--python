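"""Read, validate, and filter plate-structured duplex qPCR data.

One well of a duplex reaction carries two cycle-threshold (Ct) values: the
reporter channel (FAM) and the housekeeping channel (JOE). Lower Ct means
more transcript (one cycle per doubling). Wells whose amplification crossed
the fluorescence threshold only after the late-cycle cutoff, or not at all,
are treated as failed and dropped before any normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

ROWS = "ABCDEFGH"
N_COLS = 12
CONDITIONS = ("KCl", "mock", "rapamycin")
ROLES = ("library", "control_center_peak", "wild_type")

WELL_COLUMNS = ["plate_id", "well", "strain_id", "condition", "role", "ct_fam", "ct_joe"]


class PlateIOError(ValueError):
    """Raised when a plate file violates the well schema."""


def well_name(index: int) -> str:
    """Row-major well coordinate for a 0-based index on an 8x12 plate."""
    if not 0 <= index < len(ROWS) * N_COLS:
        raise ValueError(f"well index {index} outside 8x12 plate")
    return f"{ROWS[index // N_COLS]}{index % N_COLS + 1}"


def parse_well(well: str) -> tuple[int, int]:
    """Split a coordinate like ``B7`` into (row, column) indices, validating bounds."""
    if not well or well[0] not in ROWS:
        raise ValueError(f"bad well row in {well!r} (rows are {ROWS[0]}-{ROWS[-1]})")
    try:
        col = int(well[1:])
    except ValueError as exc:
        raise ValueError(f"bad well column in {well!r}") from exc
    if not 1 <= col <= N_COLS:
        raise ValueError(f"well column {col} outside 1-{N_COLS} in {well!r}")
    return ROWS.index(well[0]), col - 1


@dataclass(frozen=True)
class WellRecord:
    """One well's raw duplex qPCR measurement with identity metadata.

    ``ct_fam`` (reporter) and ``ct_joe`` (housekeeping) are in cycles and may
    be ``None`` when the channel never crossed its fluorescence threshold.
    """

    plate_id: str
    well: str
    strain_id: str
    condition: str
    role: str = "library"
    ct_fam: float | None = None
    ct_joe: float | None = None

    def validate(self) -> None:
        parse_well(self.well)
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not self.strain_id:
            raise ValueError("empty strain_id")
        for name, ct in (("ct_fam", self.ct_fam), ("ct_joe", self.ct_joe)):
            if ct is not None and not (0.0 < ct < float("inf")):
                raise ValueError(f"{name}={ct} is not positive finite")


@dataclass(frozen=True)
class FilterReport:
    """Tally of wells removed by the late-Ct / missing-channel filter."""

    n_input: int
    n_discarded_late_ct: int
    n_discarded_missing: int
    discarded_strains: tuple[str, ...]

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_discarded_late_ct - self.n_discarded_missing

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_discarded_late_ct": self.n_discarded_late_ct,
            "n_discarded_missing": self.n_discarded_missing,
            "discarded_strains": list(self.discarded_strains),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _parse_ct(raw, line: int, column: str, errors: list[str]) -> float | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return None
    try:
        return float(raw)
    except ValueError:
        errors.append(f"line {line}: non-numeric {column} {raw!r}")
        return None


def read_wells(path: str | Path) -> list[WellRecord]:
    """Load a well table from CSV, validating the schema row by row.

    Malformed rows are reported with their 1-based file line numbers; a
    duplicated (plate_id, well) pair or an unknown condition label raises.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in WELL_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise PlateIOError(f"{path}: header missing columns {missing_cols}")

    errors: list[str] = []
    seen: dict[tuple[str, str], int] = {}
    wells: list[WellRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header is line 1
        record = WellRecord(
            plate_id=row.plate_id,
            well=row.well,
            strain_id=row.strain_id,
            condition=row.condition,
            role=row.role or "library",
            ct_fam=_parse_ct(row.ct_fam, line, "ct_fam", errors),
            ct_joe=_parse_ct(row.ct_joe, line, "ct_joe", errors),
        )
        try:
            record.validate()
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        key = (record.plate_id, record.well)
        if key in seen:
            errors.append(
                f"line {line}: duplicate well {record.plate_id}/{record.well}"
                f" (first seen on line {seen[key]})"
            )
            continue
        seen[key] = line
        wells.append(record)
    if errors:
        raise PlateIOError(f"{path}: invalid rows\n" + "\n".join(errors))
    return wells


def wells_to_frame(wells: Iterable[WellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.plate_id, w.well, w.strain_id, w.condition, w.role, w.ct_fam, w.ct_joe)
            for w in wells
        ],
        columns=WELL_COLUMNS,
    )


def write_wells(wells: Iterable[WellRecord], path: str | Path) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


def filter_wells(
    wells: Sequence[WellRecord], ct_cutoff: float = 28.0
) -> tuple[list[WellRecord], FilterReport]:
    """Drop wells with a late or absent Ct on either channel.

    A channel crossing only after ``ct_cutoff`` cycles marks a failed
    amplification; the boundary itself (Ct exactly equal to the cutoff) is
    retained. Wells with a missing channel are discarded under their own
    tally. No record is altered; retained + discarded partitions the input.
    """
    retained: list[WellRecord] = []
    late = missing = 0
    dropped: set[str] = set()
    for w in wells:
        if w.ct_fam is None or w.ct_joe is None:
            missing += 1
            dropped.add(w.strain_id)
        elif w.ct_fam > ct_cutoff or w.ct_joe > ct_cutoff:
            late += 1
            dropped.add(w.strain_id)
        else:
            retained.append(w)
    report = FilterReport(
        n_input=len(wells),
        n_discarded_late_ct=late,
        n_discarded_missing=missing,
        discarded_strains=tuple(sorted(dropped)),
    )
    return retained, report
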