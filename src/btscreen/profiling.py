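"""Log10-ratio agent profiles, plate QC and significance envelopes.

The unit of all screening analysis is the log10 ratio of an agent-treated
stimulated well to the mean of the same plate's control stimulated wells,
computed per readout and per dose.  Plate quality is summarised by the
stimulation window — log10 of mean control-stimulated over mean DMSO
non-stimulated — and significance is conveyed by a per-readout 95% band
of null log10 ratios estimated from historical control wells, not from
per-dose replicates (the screen runs a single well per readout per
concentration).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_data import (
    PANEL,
    DoseSeries,
    HistoricalControlArchive,
    Plate,
    WellRole,
)


class ProfilingError(ValueError):
    """Raised when a plate cannot be converted into a profile."""


class EnvelopeError(ValueError):
    """Raised when an envelope cannot be estimated from the archive."""


@dataclass
class AgentProfile:
    """Per-agent log10-ratio matrix over (dose, readout).

    ``ratios`` is a DataFrame indexed by dose (ascending) with one column
    per panel readout; a cell is NaN when the treated measurement was
    missing.  ``floored`` marks cells where a zero raw value was floored
    at the detection limit before taking the log.
    """

    agent_id: str
    plate_id: str
    dose_series: DoseSeries
    ratios: pd.DataFrame
    floored: pd.DataFrame
    qc_pass: bool | None = None

    def ratio(self, dose: float, readout: str) -> float:
        return float(self.ratios.at[dose, readout])

    def readout_ratios(self, readout: str) -> dict[float, float]:
        """Dose -> log10 ratio for one readout (NaN preserved)."""
        return {float(d): float(v) for d, v in self.ratios[readout].items()}


@dataclass(frozen=True)
class PlateQC:
    """Stimulation windows per readout plus pass/fail against minimums."""

    windows: Mapping[str, float]
    minima: Mapping[str, float]
    per_readout_pass: Mapping[str, bool]
    qc_pass: bool


@dataclass(frozen=True)
class Envelope:
    """Per-readout significance band of null log10 ratios.

    ``bounds`` maps readout -> (lower, upper): the empirical
    (1-coverage)/2 and 1-(1-coverage)/2 quantiles of the historical
    control archive for that readout.
    """

    bounds: Mapping[str, tuple[float, float]]
    coverage: float
    n_source: Mapping[str, int]

    def __post_init__(self) -> None:
        for readout, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise EnvelopeError(f"{readout}: lower {lo} > upper {hi}")

    def contains(self, readout: str, value: float) -> bool:
        lo, hi = self.bounds[readout]
        return lo <= value <= hi

    def to_json(self, path: str | Path) -> None:
        doc = {
            r: {"lower": lo, "upper": hi, "coverage": self.coverage,
                "n": self.n_source[r]}
            for r, (lo, hi) in self.bounds.items()
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Envelope":
        doc = json.loads(Path(path).read_text())
        coverages = {rec["coverage"] for rec in doc.values()}
        if len(coverages) != 1:
            raise EnvelopeError("envelope JSON mixes coverage levels")
        return cls(
            bounds={r: (rec["lower"], rec["upper"]) for r, rec in doc.items()},
            coverage=coverages.pop(),
            n_source={r: rec["n"] for r, rec in doc.items()},
        )


def compute_log_ratio(treated_value: float, control_mean: float,
                      floor: float | None = None) -> float:
    """log10(treated / control), with an optional detection-limit floor.

    ``control_mean`` must be positive — a plate whose control wells
    average to zero is uninterpretable.  A treated value of exactly zero
    is below the assay's detection limit; it is floored at ``floor``
    (callers typically pass half the smallest positive value of that
    readout on the plate) so the profile stays finite.
    """
    if not (math.isfinite(control_mean) and control_mean > 0):
        raise ProfilingError(f"control mean must be positive, got {control_mean!r}")
    if not (math.isfinite(treated_value) and treated_value >= 0):
        raise ProfilingError(f"treated value must be >= 0, got {treated_value!r}")
    if treated_value == 0:
        if floor is None or floor <= 0:
            raise ProfilingError(
                "treated value is 0 and no positive detection-limit floor was given"
            )
        treated_value = floor
    return math.log10(treated_value / control_mean)


def _control_means(plate: Plate, stat: str) -> dict[str, float]:
    controls = plate.wells_with_role(WellRole.CONTROL_STIMULATED)
    if not controls:
        raise ProfilingError(f"plate {plate.plate_id!r} has no control_stimulated wells")
    means: dict[str, float] = {}
    for readout in PANEL:
        vals = [w.values[readout] for w in controls if readout in w.values]
        if not vals:
            continue
        if stat == "arithmetic":
            means[readout] = float(np.mean(vals))
        elif stat == "geometric":
            if any(v <= 0 for v in vals):
                raise ProfilingError(
                    f"geometric control mean undefined for non-positive {readout} values"
                )
            means[readout] = float(np.exp(np.mean(np.log(vals))))
        else:
            raise ValueError(f"unknown control statistic {stat!r}")
    return means


def _detection_floors(plate: Plate) -> dict[str, float]:
    # Half the smallest positive value of each readout anywhere on the plate.
    floors: dict[str, float] = {}
    for readout in PANEL:
        positives = [
            w.values[readout]
            for w in plate.wells
            if readout in w.values and w.values[readout] > 0
        ]
        if positives:
            floors[readout] = 0.5 * min(positives)
    return floors


def profile_agent(plate: Plate, agent_id: str, *,
                  control_stat: str = "arithmetic") -> AgentProfile:
    """Profile one agent on a plate: log10 ratios per (dose, readout).

    The denominator for every readout is the mean of the same plate's
    control stimulated wells (arithmetic by default; ``control_stat=
    "geometric"`` switches the averaging).  The viability readout is
    ratioed against the same stimulated-no-drug baseline as everything
    else.  Well identity and input row order never matter: doses are
    sorted ascending internally.
    """
    wells = [w for w in plate.wells if w.agent_id == agent_id]
    if not wells:
        raise ProfilingError(f"agent {agent_id!r} not on plate {plate.plate_id!r}")
    means = _control_means(plate, control_stat)
    if not means:
        raise ProfilingError(
            f"plate {plate.plate_id!r}: control wells carry no readout values"
        )
    floors = _detection_floors(plate)

    by_dose: dict[float, object] = {}
    units = {w.dose_unit for w in wells}
    if len(units) != 1:
        raise ProfilingError(f"agent {agent_id!r}: mixed dose units {sorted(units)}")
    for w in wells:
        if w.dose in by_dose:
            raise ProfilingError(
                f"agent {agent_id!r}: duplicate well for dose {w.dose} "
                "(the screen runs a single well per concentration)"
            )
        by_dose[float(w.dose)] = w

    doses = sorted(by_dose)
    series = DoseSeries(agent_id=agent_id, doses=tuple(doses), unit=units.pop())
    ratios = pd.DataFrame(np.nan, index=doses, columns=list(PANEL), dtype=float)
    floored = pd.DataFrame(False, index=doses, columns=list(PANEL), dtype=bool)
    for dose in doses:
        well = by_dose[dose]
        for readout in PANEL:
            if readout not in well.values or readout not in means:
                continue  # explicit missing -> NaN cell
            raw = well.values[readout]
            floor = floors.get(readout)
            ratios.at[dose, readout] = compute_log_ratio(raw, means[readout], floor)
            floored.at[dose, readout] = raw == 0
    return AgentProfile(
        agent_id=agent_id,
        plate_id=plate.plate_id,
        dose_series=series,
        ratios=ratios,
        floored=floored,
    )


def plate_qc(plate: Plate, min_windows: Mapping[str, float]) -> PlateQC:
    """Stimulation windows and pass/fail for the QC-relevant readouts.

    window(readout) = log10(mean control_stimulated / mean dmso_nonstimulated).
    The plate passes when every readout listed in ``min_windows`` meets its
    configured minimum window.
    """
    ctrl_means = _control_means(plate, "arithmetic")
    dmso = plate.wells_with_role(WellRole.DMSO_NONSTIMULATED)
    if not dmso:
        raise ProfilingError(f"plate {plate.plate_id!r} has no dmso_nonstimulated wells")
    windows: dict[str, float] = {}
    for readout in PANEL:
        vals = [w.values[readout] for w in dmso if readout in w.values]
        if not vals or readout not in ctrl_means:
            continue
        dmso_mean = float(np.mean(vals))
        if dmso_mean <= 0:
            raise ProfilingError(
                f"plate {plate.plate_id!r}: zero mean in DMSO wells for {readout}"
            )
        windows[readout] = math.log10(ctrl_means[readout] / dmso_mean)
    per_pass: dict[str, bool] = {}
    for readout, minimum in min_windows.items():
        if readout not in windows:
            raise ProfilingError(f"QC readout {readout!r} has no window on this plate")
        per_pass[readout] = windows[readout] >= minimum
    return PlateQC(
        windows=windows,
        minima=dict(min_windows),
        per_readout_pass=per_pass,
        qc_pass=all(per_pass.values()),
    )


def compute_envelope(archive: HistoricalControlArchive, coverage: float = 0.95,
                     *, min_n: int = 50) -> Envelope:
    """Empirical significance envelope from a historical-control archive.

    Per readout the band is the empirical ((1-coverage)/2,
    1-(1-coverage)/2) quantile pair of the archived null log10 ratios
    (linear/type-7 interpolation).  Raising coverage never narrows the
    band; coverage 1.0 returns the archive's (min, max).
    """
    if not (0 < coverage <= 1):
        raise EnvelopeError(f"coverage must be in (0, 1], got {coverage}")
    bounds: dict[str, tuple[float, float]] = {}
    n_source: dict[str, int] = {}
    for readout in sorted(archive.values):
        vals = archive.values[readout]
        if vals.size < min_n:
            raise EnvelopeError(
                f"insufficient history for {readout}: {vals.size} values, need >= {min_n}"
            )
        alpha = (1.0 - coverage) / 2.0
        lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
        bounds[readout] = (float(lo), float(hi))
        n_source[readout] = int(vals.size)
    return Envelope(bounds=bounds, coverage=coverage, n_source=n_source)


# ---------------------------------------------------------------------------
# Profile TSV interchange (agent_id, dose, dose_unit, readout, log10_ratio,
# missing_flag), used by the CLI to chain `profile` into `call`/`report`.


def write_profiles(profiles: Iterable[AgentProfile], path: str | Path) -> None:
    lines = ["plate_id\tagent_id\tdose\tdose_unit\treadout\tlog10_ratio\tmissing_flag"]
    for prof in profiles:
        for dose in prof.dose_series.doses:
            for readout in PANEL:
                v = prof.ratios.at[dose, readout]
                missing = isinstance(v, float) and math.isnan(v)
                lines.append(
                    "\t".join(
                        [
                            prof.plate_id,
                            prof.agent_id,
                            repr(float(dose)),
                            prof.dose_series.unit,
                            readout,
                            "" if missing else repr(float(v)),
                            "1" if missing else "0",
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_profiles(path: str | Path) -> list[AgentProfile]:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    profiles: list[AgentProfile] = []
    for (plate_id, agent_id), grp in table.groupby(["plate_id", "agent_id"], sort=True):
        unit = grp["dose_unit"].iloc[0]
        doses = sorted({float(d) for d in grp["dose"]})
        ratios = pd.DataFrame(np.nan, index=doses, columns=list(PANEL), dtype=float)
        for _, row in grp.iterrows():
            if row["missing_flag"] == "1" or row["log10_ratio"] == "":
                continue
            ratios.at[float(row["dose"]), row["readout"]] = float(row["log10_ratio"])
        profiles.append(
            AgentProfile(
                agent_id=str(agent_id),
                plate_id=str(plate_id),
                dose_series=DoseSeries(str(agent_id), tuple(doses), unit),
                ratios=ratios,
                floored=pd.DataFrame(False, index=doses, columns=list(PANEL)),
            )
        )
    return profiles
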