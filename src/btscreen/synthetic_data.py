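"""Synthetic plates, historical archives and paired expression data.

Every pipeline stage is exercisable without any deposited data: the
generator plants known multiplicative effects on a noise model calibrated
to the co-culture system and serialises the ground truth next to the
plate so recovery can be scored exactly.

Noise is multiplicative lognormal on raw values — assay readouts are
ratios of positive quantities — parameterised by a per-readout standard
deviation on the log10 scale.  Default baselines use the measured
stimulated supernatant levels where the study reports them (IL-17A
261 ± 73 pg/ml, IL-17F 1549 ± 206 pg/ml); the corresponding default log10
sds are calibrated so control coefficients of variation match those
reported mean ± sd pairs.  Generation is a pure function of
(truth, noise model, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_stats import PairedExpressionMatrix
from .plate_data import (
    COLCHICINE_AGENT_ID,
    COLCHICINE_DOSE,
    COLCHICINE_DOSE_UNIT,
    CYTOTOX_PROBE,
    PANEL,
    DoseSeries,
    HistoricalControlArchive,
    Plate,
    Well,
    WellRole,
)


def _sd_log10_from_cv(cv: float) -> float:
    # Lognormal: cv^2 = exp(sigma_ln^2) - 1; convert sigma to log10 units.
    return math.sqrt(math.log1p(cv * cv)) / math.log(10.0)


#: Stimulated baseline per readout, in assay units (pg/ml for cytokines,
#: ng/ml for IgG, absorbance AU for the AlamarBlue readouts).  IL-17A and
#: IL-17F use the reported supernatant concentrations; the rest are
#: plausible stimulated levels for this panel.
DEFAULT_BASELINES: dict[str, float] = {
    "Proliferation": 1.2,
    "Viability": 1.0,
    "IgG": 1800.0,
    "IL17A": 261.0,
    "IL17F": 1549.0,
    "IL2": 310.0,
    "IL6": 2400.0,
    "TNFa": 920.0,
}

#: Per-readout noise sd on the log10 scale.  IL-17A/IL-17F match the
#: reported control CVs (73/261 and 206/1549); AlamarBlue absorbance is
#: tight, the other ELISAs use a generic mid-range CV.
DEFAULT_SD_LOG10: dict[str, float] = {
    "Proliferation": 0.03,
    "Viability": 0.03,
    "IgG": 0.06,
    "IL17A": _sd_log10_from_cv(73.0 / 261.0),
    "IL17F": _sd_log10_from_cv(206.0 / 1549.0),
    "IL2": 0.06,
    "IL6": 0.06,
    "TNFa": 0.06,
}


class SimulationError(ValueError):
    """Raised on invalid generator configuration."""


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise: per-readout baseline and log10 sd.

    ``window`` is the log10 stimulation window used to place DMSO
    non-stimulated wells at baseline / 10**window.
    """

    baselines: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    sd_log10: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SD_LOG10))
    window: float = 1.0

    def __post_init__(self) -> None:
        for readout in PANEL:
            if readout not in self.baselines or self.baselines[readout] <= 0:
                raise SimulationError(f"baseline for {readout} must be positive")
            if self.sd_log10.get(readout, -1) < 0:
                raise SimulationError(f"sd_log10 for {readout} must be >= 0")

    def with_uniform_sd(self, sd: float) -> "NoiseModel":
        """Same baselines, one log10 sd for every readout."""
        return NoiseModel(
            baselines=dict(self.baselines),
            sd_log10={r: sd for r in PANEL},
            window=self.window,
        )


@dataclass(frozen=True)
class Effect:
    """Planted effect on one readout: type plus per-dose multipliers."""

    effect_type: str  # none | inhibit | stimulate
    multipliers: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.effect_type not in {"none", "inhibit", "stimulate"}:
            raise SimulationError(f"unknown effect type {self.effect_type!r}")
        for m in self.multipliers:
            if m <= 0:
                raise SimulationError("effect multipliers must be positive")
            if self.effect_type == "inhibit" and m > 1:
                raise SimulationError("inhibit multipliers must be <= 1")
            if self.effect_type == "stimulate" and m < 1:
                raise SimulationError("stimulate multipliers must be >= 1")


@dataclass(frozen=True)
class AgentTruth:
    """Ground truth for one simulated agent.

    ``effects`` maps readout -> planted :class:`Effect`; unlisted
    readouts are untouched (multiplier 1).  ``cytotoxic_from_dose`` is
    the index into the dose series from which viability is suppressed.
    """

    agent_id: str
    effects: Mapping[str, Effect] = field(default_factory=dict)
    cytotoxic_from_dose: int | None = None

    def multiplier(self, readout: str, dose_index: int) -> float:
        eff = self.effects.get(readout)
        return eff.multipliers[dose_index] if eff is not None else 1.0

    def to_record(self) -> dict:
        return {
            "agent_id": self.agent_id,
            "cytotoxic_from_dose": self.cytotoxic_from_dose,
            "effects": {
                r: {"type": e.effect_type, "multipliers": list(e.multipliers)}
                for r, e in self.effects.items()
            },
        }

    @classmethod
    def from_record(cls, rec: dict) -> "AgentTruth":
        return cls(
            agent_id=rec["agent_id"],
            cytotoxic_from_dose=rec.get("cytotoxic_from_dose"),
            effects={
                r: Effect(e["type"], tuple(e["multipliers"]))
                for r, e in rec["effects"].items()
            },
        )


# ---------------------------------------------------------------------------
# Truth factories for the qualitative patterns seen in the screen:
# dual inhibitors, dose-stratified IL-17A-selective (mTOR-like),
# IL-17F-selective, stimulators, divergent PGE2-like, cytotoxic top dose.


def _const(effect_type: str, mult: float, n_doses: int) -> Effect:
    return Effect(effect_type, (mult,) * n_doses)


def truth_null(agent_id: str, n_doses: int = 4,
               strength: float = 0.5) -> AgentTruth:
    del n_doses, strength
    return AgentTruth(agent_id=agent_id)


def truth_dual_inhibitor(agent_id: str, n_doses: int = 4,
                         strength: float = 0.5) -> AgentTruth:
    m = 10.0 ** -strength
    return AgentTruth(agent_id, {
        "IL17A": _const("inhibit", m, n_doses),
        "IL17F": _const("inhibit", m, n_doses),
    })


def truth_a_selective_stratified(agent_id: str, n_doses: int = 4,
                                 strength: float = 0.5) -> AgentTruth:
    """IL-17A inhibited at every dose, IL-17F only at the top two doses."""
    if n_doses < 4:
        raise SimulationError("stratified truth needs >= 4 doses")
    m = 10.0 ** -strength
    f_mults = (1.0,) * (n_doses - 2) + (m, m)
    return AgentTruth(agent_id, {
        "IL17A": _const("inhibit", m, n_doses),
        "IL17F": Effect("inhibit", f_mults),
    })


def truth_f_selective(agent_id: str, n_doses: int = 4,
                      strength: float = 0.5) -> AgentTruth:
    return AgentTruth(agent_id, {
        "IL17F": _const("inhibit", 10.0 ** -strength, n_doses),
    })


def truth_stimulator(agent_id: str, n_doses: int = 4,
                     strength: float = 0.5) -> AgentTruth:
    m = 10.0 ** strength
    return AgentTruth(agent_id, {
        "IL17A": _const("stimulate", m, n_doses),
        "IL17F": _const("stimulate", m, n_doses),
    })


def truth_divergent(agent_id: str, n_doses: int = 4,
                    strength: float = 0.5) -> AgentTruth:
    """PGE2-like: IL-17A up, IL-17F down."""
    return AgentTruth(agent_id, {
        "IL17A": _const("stimulate", 10.0 ** strength, n_doses),
        "IL17F": _const("inhibit", 10.0 ** -strength, n_doses),
    })


def truth_cytotoxic_top_dose(agent_id: str, n_doses: int = 4,
                             strength: float = 0.5) -> AgentTruth:
    """Dual inhibitor whose top dose kills cells (viability below the gate)."""
    m = 10.0 ** -strength
    viability = (1.0,) * (n_doses - 1) + (10.0 ** -0.5,)
    return AgentTruth(
        agent_id,
        {
            "IL17A": _const("inhibit", m, n_doses),
            "IL17F": _const("inhibit", m, n_doses),
            CYTOTOX_PROBE: Effect("inhibit", viability),
        },
        cytotoxic_from_dose=n_doses - 1,
    )


TRUTH_FACTORIES = (
    truth_dual_inhibitor,
    truth_a_selective_stratified,
    truth_f_selective,
    truth_stimulator,
    truth_divergent,
    truth_cytotoxic_top_dose,
    truth_null,
)


def standard_truth_mix(n_agents: int, n_doses: int = 4,
                       strength: float = 0.5) -> list[AgentTruth]:
    """Cycle through the seven canonical truth patterns."""
    width = len(str(max(n_agents, 1)))
    return [
        TRUTH_FACTORIES[i % len(TRUTH_FACTORIES)](f"agent{i + 1:0{width}d}", n_doses, strength)
        for i in range(n_agents)
    ]


def expected_hit_direction(truth: AgentTruth, readout: str,
                           theta_inhibit: float = -0.2,
                           theta_stimulate: float = 0.15,
                           min_active_doses: int = 2) -> str:
    """Noise-free direction call implied by a truth (the recovery oracle).

    Counts doses whose planted log10 effect clears the threshold and is
    not excluded by the planted cytotoxicity, mirroring the calling rule.
    """
    eff = truth.effects.get(readout)
    if eff is None:
        return "none"
    cut = truth.cytotoxic_from_dose
    n_active = 0
    for i, m in enumerate(eff.multipliers):
        if cut is not None and i >= cut:
            continue
        lg = math.log10(m)
        if eff.effect_type == "inhibit" and lg < theta_inhibit:
            n_active += 1
        elif eff.effect_type == "stimulate" and lg > theta_stimulate:
            n_active += 1
    if n_active < min_active_doses:
        return "none"
    return "inhibitor" if eff.effect_type == "inhibit" else "stimulator"


# ---------------------------------------------------------------------------
# Generators


def _draw(rng: np.random.Generator, base: float, sd: float) -> float:
    return base * 10.0 ** rng.normal(0.0, sd) if sd > 0 else base


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_plate(truths: Sequence[AgentTruth], noise: NoiseModel,
                   doses: DoseSeries, seed: int | np.random.Generator,
                   *, plate_id: str = "SIMPLATE", donor_pool_id: str = "pool1",
                   n_control: int = 2, n_dmso: int = 6,
                   n_colchicine: int = 1) -> tuple[Plate, list[dict]]:
    """Simulate one plate plus its serialisable truth record.

    Well values are baseline × planted multiplier × lognormal noise;
    DMSO non-stimulated wells sit a stimulation window below baseline;
    colchicine control stimulation wells (1.11 µM) get a fixed strong
    suppression of proliferation and cytokines.  The returned plate
    passes full validation; with sd = 0 the generator is exact.
    """
    if n_control < 2 or n_dmso < 6:
        raise SimulationError("plates need >= 2 control and >= 6 DMSO wells")
    for truth in truths:
        for eff in truth.effects.values():
            if len(eff.multipliers) != len(doses.doses):
                raise SimulationError(
                    f"{truth.agent_id}: effect length {len(eff.multipliers)} != "
                    f"{len(doses.doses)} doses"
                )
    rng = _rng(seed)
    wells: list[Well] = []

    def values(mult: Mapping[str, float] | None = None,
               scale: float = 1.0) -> dict[str, float]:
        out = {}
        for readout in PANEL:
            m = 1.0 if mult is None else mult.get(readout, 1.0)
            out[readout] = _draw(
                rng, noise.baselines[readout] * m * scale, noise.sd_log10[readout]
            )
        return out

    for i in range(n_control):
        wells.append(Well(plate_id, f"CTRL{i + 1:02d}",
                          WellRole.CONTROL_STIMULATED, values()))
    for i in range(n_dmso):
        wells.append(Well(plate_id, f"DMSO{i + 1:02d}",
                          WellRole.DMSO_NONSTIMULATED,
                          values(scale=10.0 ** -noise.window)))
    colchicine_mult = {r: 0.2 for r in PANEL if r != CYTOTOX_PROBE}
    colchicine_mult[CYTOTOX_PROBE] = 0.9
    for i in range(n_colchicine):
        wells.append(Well(plate_id, f"COLC{i + 1:02d}",
                          WellRole.COLCHICINE_CONTROL, values(colchicine_mult),
                          agent_id=COLCHICINE_AGENT_ID, dose=COLCHICINE_DOSE,
                          dose_unit=COLCHICINE_DOSE_UNIT))
    for truth in truths:
        for di, dose in enumerate(doses.doses):
            mult = {r: truth.multiplier(r, di) for r in PANEL}
            wells.append(Well(plate_id, f"{truth.agent_id}_d{di + 1}",
                              WellRole.AGENT_STIMULATED, values(mult),
                              agent_id=truth.agent_id, dose=float(dose),
                              dose_unit=doses.unit))
    plate = Plate(plate_id=plate_id, donor_pool_id=donor_pool_id, wells=wells)
    return plate, [t.to_record() for t in truths]


def simulate_historical_archive(noise: NoiseModel, n: int,
                                seed: int | np.random.Generator) -> HistoricalControlArchive:
    """n null log10 ratios per readout, drawn from the noise model."""
    if n < 1:
        raise SimulationError("archive size must be >= 1")
    rng = _rng(seed)
    values = {
        readout: rng.normal(0.0, noise.sd_log10[readout], size=n)
        if noise.sd_log10[readout] > 0 else np.zeros(n)
        for readout in PANEL
    }
    return HistoricalControlArchive(values)


def simulate_paired_expression(n_genes: int, n_pools: int = 3,
                               planted: Mapping[str, float] | None = None,
                               noise_sd: float = 0.1,
                               seed: int | np.random.Generator = 0,
                               *, baseline_log10_range: tuple[float, float] = (1.5, 3.5)
                               ) -> tuple[PairedExpressionMatrix, dict[str, float]]:
    """Paired stim/ctrl matrices with planted fold changes.

    Control values are lognormal around per-gene baselines; stimulated
    values are the *same pool's* control value times the planted fold
    times fresh noise, so pairing is preserved.  Genes named in
    ``planted`` come first; the rest are null (fold 1).  Returns the
    matrix and the full gene -> planted-fold map.
    """
    planted = dict(planted or {})
    if any(f <= 0 for f in planted.values()):
        raise SimulationError("planted folds must be positive")
    if len(planted) > n_genes:
        raise SimulationError("more planted genes than n_genes")
    rng = _rng(seed)
    genes = sorted(planted)
    width = len(str(max(n_genes, 1)))
    i = 0
    while len(genes) < n_genes:
        i += 1
        name = f"null{i:0{width}d}"
        if name not in planted:
            genes.append(name)
    folds = {g: planted.get(g, 1.0) for g in genes}
    pools = [f"pool{j + 1}" for j in range(n_pools)]
    lo, hi = baseline_log10_range
    base = 10.0 ** rng.uniform(lo, hi, size=n_genes)
    ctrl = base[:, None] * 10.0 ** rng.normal(0.0, noise_sd, size=(n_genes, n_pools))
    fold_vec = np.array([folds[g] for g in genes])
    stim = ctrl * fold_vec[:, None] * 10.0 ** rng.normal(0.0, noise_sd,
                                                         size=(n_genes, n_pools))
    matrix = PairedExpressionMatrix(
        stim=pd.DataFrame(stim, index=genes, columns=pools),
        ctrl=pd.DataFrame(ctrl, index=genes, columns=pools),
    )
    return matrix, folds


def write_truths(truths: Iterable[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(truths), indent=1) + "\n")


def read_truths(path: str | Path) -> list[AgentTruth]:
    return [AgentTruth.from_record(rec) for rec in json.loads(Path(path).read_text())]
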