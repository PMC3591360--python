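"""Cytotoxicity gating, multi-dose hit calling, IL-17 selectivity and
target-class aggregation.

The screen calls hits from thresholded log10 ratios, not fitted curves:

* a dose is overtly cytotoxic when its viability log10 ratio drops below
  −0.2 (strictly: a decrease *greater than* 0.2 log units), and every
  readout at that dose is excluded from analysis;
* an agent inhibits a readout when the ratio is < −0.2 at ≥ 2
  non-cytotoxic doses, and stimulates when the ratio is > +0.15 at ≥ 2
  non-cytotoxic doses (both inequalities strict — boundary values are
  inactive);
* IL-17A/IL-17F selectivity distinguishes agents active on one cytokine
  only, on both, or on one at low doses and both at higher doses
  (dose-stratified selectivity, e.g. mTOR inhibitors on IL-17A);
* a target class enters the summary table only when a strict majority of
  its agents had any IL-17A/IL-17F effect.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .plate_data import CYTOTOX_PROBE, PANEL
from .profiling import AgentProfile

#: Selectivity categories, in tie-break preference order (most inclusive
#: first) for the modal category of a class.
CATEGORIES = ("A_and_F", "A_over_F", "F_over_A", "A_only", "F_only", "none")

IL17A = "IL17A"
IL17F = "IL17F"


class HitCallingError(ValueError):
    """Raised on inconsistent inputs to the hit-calling rules."""


@dataclass(frozen=True)
class Thresholds:
    """Fixed log10-ratio thresholds of the hit-calling rules.

    theta_inhibit   ratio below which a readout counts as inhibited (−0.2)
    theta_stimulate ratio above which a readout counts as stimulated (+0.15)
    theta_cytotox   viability ratio below which a dose is cytotoxic (−0.2)
    min_active_doses  non-cytotoxic doses required for a call (2)
    """

    theta_inhibit: float = -0.2
    theta_stimulate: float = 0.15
    theta_cytotox: float = -0.2
    min_active_doses: int = 2

    def __post_init__(self) -> None:
        if not (self.theta_inhibit < 0 < self.theta_stimulate):
            raise HitCallingError(
                "need theta_inhibit < 0 < theta_stimulate, got "
                f"({self.theta_inhibit}, {self.theta_stimulate})"
            )
        if self.min_active_doses < 1:
            raise HitCallingError("min_active_doses must be >= 1")


@dataclass(frozen=True)
class DoseCall:
    """Per-(dose, readout) direction label."""

    dose: float
    readout: str
    direction: str  # inhibited | stimulated | inactive | excluded_cytotoxic | missing


@dataclass(frozen=True)
class HitCall:
    """Per-(agent, readout) call over the whole dose series."""

    agent_id: str
    readout: str
    direction: str  # inhibitor | stimulator | none
    active_doses: tuple[float, ...]
    n_noncytotoxic_doses: int


@dataclass(frozen=True)
class SelectivityCall:
    """IL-17A-versus-IL-17F selectivity category for one agent.

    ``dose_dependent`` is true only for the dose-stratified categories
    A_over_F / F_over_A; ``divergent`` marks agents with opposing
    directions on the two cytokines (the PGE2 pattern: IL-17A up,
    IL-17F down), which are reported as two independent hit calls
    rather than forced into a shared category.
    """

    agent_id: str
    category: str
    dose_dependent: bool = False
    divergent: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise HitCallingError(f"unknown selectivity category {self.category!r}")
        if self.dose_dependent and self.category not in {"A_over_F", "F_over_A"}:
            raise HitCallingError(
                "dose_dependent is only meaningful for A_over_F / F_over_A"
            )


@dataclass(frozen=True)
class ClassSummary:
    class_name: str
    agents_active: int
    agents_total: int
    included: bool
    modal_selectivity: str


def flag_cytotoxic_doses(profile: AgentProfile,
                         thresholds: Thresholds = Thresholds()) -> dict[float, bool]:
    """Map each dose to True when it must be excluded from analysis.

    A dose is flagged when its viability (18–24 h AlamarBlue) log10 ratio
    is strictly below ``theta_cytotox`` — a decrease greater than 0.2 log
    units; a ratio of exactly −0.2 is not cytotoxic.  A dose whose
    viability measurement is missing is non-evaluable and excluded the
    same way.
    """
    flags: dict[float, bool] = {}
    for dose, ratio in profile.readout_ratios(CYTOTOX_PROBE).items():
        flags[dose] = True if math.isnan(ratio) else ratio < thresholds.theta_cytotox
    return flags


def dose_calls(profile: AgentProfile, readout: str,
               thresholds: Thresholds = Thresholds(),
               cytotoxic: Mapping[float, bool] | None = None) -> list[DoseCall]:
    """Per-dose direction labels for one readout (exclusion-aware)."""
    if readout not in PANEL:
        raise HitCallingError(f"unknown readout {readout!r}")
    if cytotoxic is None:
        cytotoxic = flag_cytotoxic_doses(profile, thresholds)
    calls = []
    for dose, ratio in profile.readout_ratios(readout).items():
        if cytotoxic.get(dose, False):
            direction = "excluded_cytotoxic"
        elif math.isnan(ratio):
            direction = "missing"
        elif ratio < thresholds.theta_inhibit:
            direction = "inhibited"
        elif ratio > thresholds.theta_stimulate:
            direction = "stimulated"
        else:
            direction = "inactive"
        calls.append(DoseCall(dose=dose, readout=readout, direction=direction))
    return calls


def call_direction(profile: AgentProfile, readout: str,
                   thresholds: Thresholds = Thresholds(),
                   cytotoxic: Mapping[float, bool] | None = None) -> HitCall:
    """Call one readout inhibitor / stimulator / none over the dose series.

    Inhibitor: ratio < theta_inhibit at >= min_active_doses non-cytotoxic
    doses; stimulator: ratio > theta_stimulate likewise.  Should a
    non-monotone agent satisfy both patterns, the direction with more
    active doses wins; an exact tie is reported as none with a warning.
    Missing cells are never active.  Dose order in the input is
    irrelevant (the series is kept sorted).
    """
    per_dose = dose_calls(profile, readout, thresholds, cytotoxic)
    inhibited = tuple(c.dose for c in per_dose if c.direction == "inhibited")
    stimulated = tuple(c.dose for c in per_dose if c.direction == "stimulated")
    n_usable = sum(1 for c in per_dose if c.direction != "excluded_cytotoxic")
    m = thresholds.min_active_doses
    direction, active = "none", ()
    if len(inhibited) >= m and len(stimulated) >= m:
        if len(inhibited) == len(stimulated):
            warnings.warn(
                f"{profile.agent_id}/{readout}: inhibition and stimulation tie at "
                f"{len(inhibited)} doses each; calling none",
                stacklevel=2,
            )
        elif len(inhibited) > len(stimulated):
            direction, active = "inhibitor", inhibited
        else:
            direction, active = "stimulator", stimulated
    elif len(inhibited) >= m:
        direction, active = "inhibitor", inhibited
    elif len(stimulated) >= m:
        direction, active = "stimulator", stimulated
    return HitCall(
        agent_id=profile.agent_id,
        readout=readout,
        direction=direction,
        active_doses=tuple(sorted(active)),
        n_noncytotoxic_doses=n_usable,
    )


def _active_set(profile: AgentProfile, readout: str, direction: str,
                thresholds: Thresholds,
                cytotoxic: Mapping[float, bool]) -> set[float]:
    want = "inhibited" if direction == "inhibitor" else "stimulated"
    return {
        c.dose
        for c in dose_calls(profile, readout, thresholds, cytotoxic)
        if c.direction == want
    }


def _stratified(doses: Sequence[float], solo: set[float], both: set[float],
                m: int) -> bool:
    # Cut-point search: "relatively low doses" is operationalised as all
    # solo-active doses strictly below all dual-active doses at some cut.
    for k in range(1, len(doses)):
        low, high = doses[:k], doses[k:]
        n_solo_low = sum(1 for d in low if d in solo and d not in both)
        n_both_high = sum(1 for d in high if d in both)
        if n_solo_low >= m and n_both_high >= m:
            return True
    return False


def classify_selectivity(call_a: HitCall, call_f: HitCall,
                         profile: AgentProfile,
                         thresholds: Thresholds = Thresholds(),
                         cytotoxic: Mapping[float, bool] | None = None) -> SelectivityCall:
    """IL-17A-vs-IL-17F selectivity from the two cytokine hit calls.

    * both hits, same direction, dose-stratified (one cytokine active
      alone at >= min_active_doses low doses, both active at >=
      min_active_doses higher doses) -> A_over_F / F_over_A with
      dose_dependent=True;
    * both hits, same direction, not stratified -> A_and_F;
    * exactly one hit -> A_only / F_only;
    * opposing directions -> category none with divergent=True (the two
      hit calls stand on their own);
    * no hits -> none.
    """
    if call_a.agent_id != call_f.agent_id or call_a.agent_id != profile.agent_id:
        raise HitCallingError(
            f"selectivity needs calls from one agent, got {call_a.agent_id!r} / "
            f"{call_f.agent_id!r} on profile {profile.agent_id!r}"
        )
    if {call_a.readout, call_f.readout} != {IL17A, IL17F}:
        raise HitCallingError("selectivity requires one IL17A and one IL17F call")
    if call_a.readout != IL17A:
        call_a, call_f = call_f, call_a
    agent = profile.agent_id
    a_hit, f_hit = call_a.direction != "none", call_f.direction != "none"
    if not a_hit and not f_hit:
        return SelectivityCall(agent_id=agent, category="none")
    if a_hit and not f_hit:
        return SelectivityCall(agent_id=agent, category="A_only")
    if f_hit and not a_hit:
        return SelectivityCall(agent_id=agent, category="F_only")
    if call_a.direction != call_f.direction:
        return SelectivityCall(agent_id=agent, category="none", divergent=True)

    if cytotoxic is None:
        cytotoxic = flag_cytotoxic_doses(profile, thresholds)
    doses = list(profile.dose_series.doses)
    active_a = _active_set(profile, IL17A, call_a.direction, thresholds, cytotoxic)
    active_f = _active_set(profile, IL17F, call_f.direction, thresholds, cytotoxic)
    both = active_a & active_f
    m = thresholds.min_active_doses
    if _stratified(doses, active_a, both, m):
        return SelectivityCall(agent_id=agent, category="A_over_F", dose_dependent=True)
    if _stratified(doses, active_f, both, m):
        return SelectivityCall(agent_id=agent, category="F_over_A", dose_dependent=True)
    return SelectivityCall(agent_id=agent, category="A_and_F")


def call_agent(profile: AgentProfile,
               thresholds: Thresholds = Thresholds()) -> tuple[list[HitCall], SelectivityCall]:
    """Convenience: gate, call every panel readout, classify selectivity."""
    cytotoxic = flag_cytotoxic_doses(profile, thresholds)
    hits = [
        call_direction(profile, readout, thresholds, cytotoxic)
        for readout in PANEL
        if readout != CYTOTOX_PROBE
    ]
    by_readout = {h.readout: h for h in hits}
    selectivity = classify_selectivity(
        by_readout[IL17A], by_readout[IL17F], profile, thresholds, cytotoxic
    )
    return hits, selectivity


def summarize_class(selectivity_calls: Iterable[SelectivityCall],
                    hit_calls: Iterable[HitCall],
                    class_map: Mapping[str, str]) -> list[ClassSummary]:
    """Aggregate per-agent calls into target-class rows.

    An agent is *active* when it has any IL-17A or IL-17F hit (divergent
    agents qualify through their two opposing hits).  A class is included
    only when a strict majority of its agents are active; the modal
    selectivity is the most frequent category among active agents, with
    ties resolved toward the more inclusive category (A_and_F first).
    """
    sel_by_agent = {c.agent_id: c for c in selectivity_calls}
    hits_by_agent: dict[str, list[HitCall]] = {}
    for h in hit_calls:
        hits_by_agent.setdefault(h.agent_id, []).append(h)
    agents = sorted(set(sel_by_agent) | set(hits_by_agent))
    unmapped = [a for a in agents if a not in class_map]
    if unmapped:
        raise HitCallingError(f"agents missing from class map: {unmapped}")

    def is_active(agent: str) -> bool:
        return any(
            h.direction != "none" and h.readout in (IL17A, IL17F)
            for h in hits_by_agent.get(agent, [])
        )

    classes: dict[str, list[str]] = {}
    for agent in agents:
        classes.setdefault(class_map[agent], []).append(agent)
    summaries = []
    for class_name in sorted(classes):
        members = classes[class_name]
        active = [a for a in members if is_active(a)]
        counts = Counter(
            sel_by_agent[a].category for a in active if a in sel_by_agent
        )
        if counts:
            top = max(counts.values())
            modal = next(c for c in CATEGORIES if counts.get(c) == top)
        else:
            modal = "none"
        summaries.append(
            ClassSummary(
                class_name=class_name,
                agents_active=len(active),
                agents_total=len(members),
                included=len(active) / len(members) > 0.5,
                modal_selectivity=modal,
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# Tabular output


def write_hit_table(hits: Iterable[HitCall], path: str | Path) -> None:
    lines = ["agent_id\treadout\tdirection\tactive_doses\tn_noncytotoxic"]
    for h in sorted(hits, key=lambda h: (h.agent_id, PANEL.index(h.readout))):
        lines.append(
            "\t".join(
                [
                    h.agent_id,
                    h.readout,
                    h.direction,
                    ";".join(repr(d) for d in h.active_doses),
                    str(h.n_noncytotoxic_doses),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_selectivity_table(calls: Iterable[SelectivityCall], path: str | Path) -> None:
    lines = ["agent_id\tcategory\tdose_dependent\tdivergent"]
    for c in sorted(calls, key=lambda c: c.agent_id):
        lines.append(
            f"{c.agent_id}\t{c.category}\t{int(c.dose_dependent)}\t{int(c.divergent)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
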