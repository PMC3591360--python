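"""Data model and I/O for co-culture screening plates.

The screen measures an 8-readout panel on stimulated B-cell/PBMC (BT)
co-cultures: B-cell proliferation and PBMC viability (both AlamarBlue
absorbance), secreted IgG, and the cytokines IL-17A, IL-17F, IL-2, IL-6
and TNFα.  Every plate carries its own controls — stimulated wells with
no drug, DMSO-treated non-stimulated wells, and colchicine control
stimulation wells — and agent-treated wells over a multi-dose series,
one well per readout per concentration.

Raw values are kept in original assay units (pg/ml, ng/ml, absorbance AU);
all normalisation to log10 ratios happens downstream in
:mod:`btscreen.profiling`.  A missing readout is represented explicitly
(absent from the well's value map) and propagates as "no call"; it is
never imputed or silently zeroed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Readout panel in the presentation order used throughout reports:
#: proliferation, viability (cytotoxicity probe), IgG, then cytokines.
PANEL: tuple[str, ...] = (
    "Proliferation",
    "Viability",
    "IgG",
    "IL17A",
    "IL17F",
    "IL2",
    "IL6",
    "TNFa",
)

#: The single readout used for cytotoxicity gating: AlamarBlue reduction
#: measured at 18–24 h, before drug effects on proliferation confound it.
CYTOTOX_PROBE = "Viability"

#: Readout kinds; exactly one panel member is the cytotoxicity probe.
READOUT_KINDS: dict[str, str] = {
    "Proliferation": "growth",
    "Viability": "cytotox_probe",
    "IgG": "secreted",
    "IL17A": "secreted",
    "IL17F": "secreted",
    "IL2": "secreted",
    "IL6": "secreted",
    "TNFa": "secreted",
}

COLCHICINE_AGENT_ID = "colchicine"
COLCHICINE_DOSE = 1.11
COLCHICINE_DOSE_UNIT = "uM"

_CSV_COLUMNS = [
    "plate_id",
    "donor_pool_id",
    "well_id",
    "role",
    "agent_id",
    "dose",
    "dose_unit",
    "readout",
    "value",
]


class PlateParseError(ValueError):
    """A plate file does not conform to the documented schema."""


class PlateValidationError(ValueError):
    """A structurally parseable plate violates a model invariant."""


class WellRole(str, Enum):
    AGENT_STIMULATED = "agent_stimulated"
    CONTROL_STIMULATED = "control_stimulated"
    DMSO_NONSTIMULATED = "dmso_nonstimulated"
    COLCHICINE_CONTROL = "colchicine_control"


#: Roles that carry an agent identity and a dose.
_DOSED_ROLES = frozenset({WellRole.AGENT_STIMULATED, WellRole.COLCHICINE_CONTROL})


@dataclass(frozen=True)
class Well:
    """One physical well: a role, an optional (agent, dose), raw readout values.

    ``values`` maps readout name to the raw measurement in assay units.
    Readouts not measured in this well are simply absent from the map.
    """

    plate_id: str
    well_id: str
    role: WellRole
    values: Mapping[str, float]
    agent_id: str | None = None
    dose: float | None = None
    dose_unit: str | None = None

    def __post_init__(self) -> None:
        role = WellRole(self.role)
        object.__setattr__(self, "role", role)
        if role in _DOSED_ROLES:
            if self.agent_id is None or self.dose is None:
                raise PlateValidationError(
                    f"well {self.well_id!r}: role {role.value} requires agent_id and dose"
                )
            if not (self.dose > 0 and math.isfinite(self.dose)):
                raise PlateValidationError(
                    f"well {self.well_id!r}: dose must be a positive finite number"
                )
            if not self.dose_unit:
                raise PlateValidationError(
                    f"well {self.well_id!r}: dosed wells need a dose_unit"
                )
        else:
            if self.agent_id is not None or self.dose is not None:
                raise PlateValidationError(
                    f"well {self.well_id!r}: role {role.value} must not carry agent_id/dose"
                )
        for readout, value in self.values.items():
            if readout not in PANEL:
                raise PlateValidationError(
                    f"well {self.well_id!r}: unknown readout {readout!r}"
                )
            if value is None or not math.isfinite(value) or value < 0:
                raise PlateValidationError(
                    f"well {self.well_id!r}, readout {readout}: raw values must be "
                    f"finite and >= 0, got {value!r}"
                )
        object.__setattr__(
            self, "values", {r: float(v) for r, v in self.values.items()}
        )


@dataclass
class Plate:
    """A validated screening plate: wells sharing one plate and donor pool."""

    plate_id: str
    wells: list[Well]
    donor_pool_id: str | None = None
    #: Lower bounds on control counts; defaults mirror the 6–12 DMSO wells
    #: and the presence of positive control stimulation wells on every plate.
    min_dmso: int = 6
    min_control: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.wells:
            raise PlateValidationError("plate has no wells (controls are required)")
        seen: set[str] = set()
        for well in self.wells:
            if well.plate_id != self.plate_id:
                raise PlateValidationError(
                    f"well {well.well_id!r} carries plate_id {well.plate_id!r}, "
                    f"expected {self.plate_id!r}"
                )
            if well.well_id in seen:
                raise PlateValidationError(f"duplicate well_id {well.well_id!r}")
            seen.add(well.well_id)
        n_ctrl = sum(1 for w in self.wells if w.role is WellRole.CONTROL_STIMULATED)
        n_dmso = sum(1 for w in self.wells if w.role is WellRole.DMSO_NONSTIMULATED)
        if n_ctrl < self.min_control:
            raise PlateValidationError(
                f"plate {self.plate_id!r}: {n_ctrl} control_stimulated wells, "
                f"need >= {self.min_control}"
            )
        if n_dmso < self.min_dmso:
            raise PlateValidationError(
                f"plate {self.plate_id!r}: {n_dmso} dmso_nonstimulated wells, "
                f"need >= {self.min_dmso}"
            )

    def wells_with_role(self, role: WellRole) -> list[Well]:
        return [w for w in self.wells if w.role is role]

    def agent_ids(self) -> list[str]:
        """Dosed agents on this plate, colchicine included, in sorted order."""
        return sorted({w.agent_id for w in self.wells if w.agent_id is not None})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Plate):
            return NotImplemented
        key = lambda w: w.well_id  # noqa: E731 - local sort key
        return (
            self.plate_id == other.plate_id
            and self.donor_pool_id == other.donor_pool_id
            and sorted(self.wells, key=key) == sorted(other.wells, key=key)
        )


@dataclass(frozen=True)
class DoseSeries:
    """An agent's dose series: strictly increasing positive doses, one unit.

    Units are opaque strings (the screen mixes µM, nM, ng/ml and U/ml);
    doses are only ever compared within one agent's series.
    """

    agent_id: str
    doses: tuple[float, ...]
    unit: str

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        if len(doses) < 1:
            raise PlateValidationError(f"{self.agent_id}: empty dose series")
        if any(not (d > 0 and math.isfinite(d)) for d in doses):
            raise PlateValidationError(f"{self.agent_id}: doses must be positive finite")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise PlateValidationError(
                f"{self.agent_id}: doses must be strictly increasing, got {doses}"
            )
        object.__setattr__(self, "doses", doses)


@dataclass
class HistoricalControlArchive:
    """Accumulated null log10 ratios from control wells on past plates.

    ``values`` maps readout name to a 1-D array of historical log10 ratios.
    These calibrate the significance envelope; a per-readout minimum count
    guards against bands estimated from too little history.
    """

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for readout, vals in self.values.items():
            if readout not in PANEL:
                raise PlateValidationError(f"unknown readout {readout!r} in archive")
            arr = np.asarray(vals, dtype=float).ravel()
            if arr.size and not np.all(np.isfinite(arr)):
                raise PlateValidationError(f"non-finite log10 ratio in archive[{readout}]")
            clean[readout] = arr
        self.values = clean

    def counts(self) -> dict[str, int]:
        return {r: int(v.size) for r, v in self.values.items()}


# ---------------------------------------------------------------------------
# I/O


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"csv", "json"}:
            raise ValueError(f"unsupported plate format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"csv", "json"}:
        return suffix
    raise ValueError(f"cannot infer plate format from {path.name!r}; pass format=")


def read_plate(path: str | Path, fmt: str | None = None, *,
               min_dmso: int = 6, min_control: int = 1) -> Plate:
    """Read and validate a plate from CSV or JSON.

    The CSV layout is one row per (well, readout) with columns
    ``plate_id, donor_pool_id, well_id, role, agent_id, dose, dose_unit,
    readout, value`` (``donor_pool_id`` optional); the JSON layout mirrors
    the object model with wells as records.  Row order never affects the
    resulting plate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _infer_format(path, fmt) == "json":
        return _plate_from_json(json.loads(path.read_text()),
                                min_dmso=min_dmso, min_control=min_control)
    return _plate_from_csv(path, min_dmso=min_dmso, min_control=min_control)


def _plate_from_csv(path: Path, *, min_dmso: int, min_control: int) -> Plate:
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PlateParseError(f"{path}: unreadable CSV ({exc})") from exc
    required = {"plate_id", "well_id", "role", "readout", "value"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise PlateParseError(f"{path}: missing columns {sorted(missing_cols)}")
    for optional in ("agent_id", "dose", "dose_unit", "donor_pool_id"):
        if optional not in table.columns:
            table[optional] = ""

    def cell(row: pd.Series, col: str) -> str | None:
        text = row[col].strip()
        return text or None

    groups: dict[str, dict] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for idx, row in table.iterrows():
        rownum = idx + 2  # 1-based, after the header line
        well_id = cell(row, "well_id")
        role = cell(row, "role")
        readout = cell(row, "readout")
        if well_id is None:
            raise PlateParseError(f"{path}: row {rownum}: missing well_id")
        if role is None:
            raise PlateParseError(f"{path}: row {rownum}: missing role for well {well_id!r}")
        if readout is None:
            raise PlateParseError(f"{path}: row {rownum}: missing readout for well {well_id!r}")
        try:
            role_enum = WellRole(role)
        except ValueError as exc:
            raise PlateParseError(f"{path}: row {rownum}: unknown role {role!r}") from exc
        dose_text = cell(row, "dose")
        try:
            dose = float(dose_text) if dose_text is not None else None
        except ValueError as exc:
            raise PlateParseError(f"{path}: row {rownum}: bad dose {dose_text!r}") from exc
        value_text = cell(row, "value")
        value: float | None
        if value_text is None:
            value = None  # explicit missing measurement
        else:
            try:
                value = float(value_text)
            except ValueError as exc:
                raise PlateParseError(
                    f"{path}: row {rownum}: bad value {value_text!r}"
                ) from exc
        meta = dict(
            plate_id=cell(row, "plate_id"),
            donor_pool_id=cell(row, "donor_pool_id"),
            role=role_enum,
            agent_id=cell(row, "agent_id"),
            dose=dose,
            dose_unit=cell(row, "dose_unit"),
        )
        entry = groups.setdefault(well_id, {"meta": meta, "values": {}})
        if entry["meta"] != meta:
            raise PlateParseError(
                f"{path}: row {rownum}: well {well_id!r} has inconsistent metadata"
            )
        if (well_id, readout) in seen_pairs:
            raise PlateParseError(
                f"{path}: row {rownum}: duplicate readout {readout!r} for well {well_id!r}"
            )
        seen_pairs.add((well_id, readout))
        if value is not None:
            entry["values"][readout] = value

    plate_ids = {entry["meta"]["plate_id"] for entry in groups.values()}
    if len(plate_ids) != 1:
        raise PlateParseError(f"{path}: expected exactly one plate_id, got {sorted(map(str, plate_ids))}")
    pools = {entry["meta"]["donor_pool_id"] for entry in groups.values()}
    if len(pools) != 1:
        raise PlateParseError(f"{path}: donor_pool_id must be constant on a plate")

    wells = [
        Well(
            plate_id=entry["meta"]["plate_id"],
            well_id=well_id,
            role=entry["meta"]["role"],
            agent_id=entry["meta"]["agent_id"],
            dose=entry["meta"]["dose"],
            dose_unit=entry["meta"]["dose_unit"],
            values=entry["values"],
        )
        for well_id, entry in groups.items()
    ]
    return Plate(
        plate_id=plate_ids.pop(),
        donor_pool_id=pools.pop(),
        wells=wells,
        min_dmso=min_dmso,
        min_control=min_control,
    )


def _plate_from_json(doc: dict, *, min_dmso: int, min_control: int) -> Plate:
    try:
        wells = [
            Well(
                plate_id=doc["plate_id"],
                well_id=rec["well_id"],
                role=WellRole(rec["role"]),
                agent_id=rec.get("agent_id"),
                dose=rec.get("dose"),
                dose_unit=rec.get("dose_unit"),
                values=rec.get("values", {}),
            )
            for rec in doc["wells"]
        ]
    except KeyError as exc:
        raise PlateParseError(f"plate JSON missing field {exc}") from exc
    return Plate(
        plate_id=doc["plate_id"],
        donor_pool_id=doc.get("donor_pool_id"),
        wells=wells,
        min_dmso=min_dmso,
        min_control=min_control,
    )


def write_plate(plate: Plate, path: str | Path, fmt: str | None = None) -> None:
    """Write a plate so that :func:`read_plate` reproduces it exactly.

    Floats are serialised via ``repr`` (shortest round-trip form), so raw
    values survive a write/read cycle bit-exactly in both formats.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    plate.validate()
    wells = sorted(plate.wells, key=lambda w: w.well_id)
    if fmt == "json":
        doc = {
            "plate_id": plate.plate_id,
            "donor_pool_id": plate.donor_pool_id,
            "wells": [
                {
                    "well_id": w.well_id,
                    "role": w.role.value,
                    "agent_id": w.agent_id,
                    "dose": w.dose,
                    "dose_unit": w.dose_unit,
                    "values": {r: w.values[r] for r in PANEL if r in w.values},
                }
                for w in wells
            ],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
        return
    lines = [",".join(_CSV_COLUMNS)]
    for w in wells:
        for readout in PANEL:
            if readout not in w.values:
                continue
            lines.append(
                ",".join(
                    [
                        w.plate_id,
                        plate.donor_pool_id or "",
                        w.well_id,
                        w.role.value,
                        w.agent_id or "",
                        repr(w.dose) if w.dose is not None else "",
                        w.dose_unit or "",
                        readout,
                        repr(w.values[readout]),
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")


def read_archive(path: str | Path) -> HistoricalControlArchive:
    """Read a historical-control archive CSV (columns readout, log10_ratio)."""
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    missing = {"readout", "log10_ratio"} - set(table.columns)
    if missing:
        raise PlateParseError(f"{path}: missing columns {sorted(missing)}")
    values = {
        str(readout): grp["log10_ratio"].to_numpy(dtype=float)
        for readout, grp in table.groupby("readout", sort=True)
    }
    return HistoricalControlArchive(values)


def write_archive(archive: HistoricalControlArchive, path: str | Path) -> None:
    lines = ["readout,log10_ratio"]
    for readout in sorted(archive.values):
        for v in archive.values[readout]:
            lines.append(f"{readout},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")
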