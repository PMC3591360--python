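"""Hit-calling rules: gating, direction calls, selectivity, class summary."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from btscreen.hit_calling import (
    HitCall,
    HitCallingError,
    SelectivityCall,
    Thresholds,
    call_agent,
    call_direction,
    classify_selectivity,
    dose_calls,
    flag_cytotoxic_doses,
    summarize_class,
)
from btscreen.plate_data import PANEL, DoseSeries
from btscreen.profiling import AgentProfile

DOSES = (0.1, 0.3, 1.0, 3.0)


def make_profile(readout_ratios: dict[str, list[float]],
                 agent_id: str = "drugX",
                 doses: tuple[float, ...] = DOSES) -> AgentProfile:
    """Profile from per-readout ratio lists; unlisted readouts sit at 0."""
    ratios = pd.DataFrame(0.0, index=list(doses), columns=list(PANEL))
    for readout, vals in readout_ratios.items():
        ratios[readout] = vals
    return AgentProfile(
        agent_id=agent_id,
        plate_id="P1",
        dose_series=DoseSeries(agent_id, doses, "uM"),
        ratios=ratios,
        floored=pd.DataFrame(False, index=list(doses), columns=list(PANEL)),
    )


class TestThresholds:
    def test_invariants(self):
        with pytest.raises(HitCallingError):
            Thresholds(theta_inhibit=0.1)
        with pytest.raises(HitCallingError):
            Thresholds(min_active_doses=0)


class TestCytotoxGate:
    def test_rule_application(self):
        prof = make_profile({"Viability": [-0.25, -0.1, 0.0, 0.0]})
        flags = flag_cytotoxic_doses(prof)
        assert flags == {0.1: True, 0.3: False, 1.0: False, 3.0: False}

    def test_boundary_is_not_cytotoxic(self):
        # the rule is a decrease strictly greater than 0.2 log units
        prof = make_profile({"Viability": [-0.2, 0.0, 0.0, 0.0]})
        assert flag_cytotoxic_doses(prof)[0.1] is False

    def test_all_zero_viability_excludes_nothing(self):
        prof = make_profile({})
        assert not any(flag_cytotoxic_doses(prof).values())

    def test_missing_viability_is_excluded(self):
        prof = make_profile({"Viability": [math.nan, 0.0, 0.0, 0.0]})
        assert flag_cytotoxic_doses(prof)[0.1] is True

    def test_exclusion_applies_to_all_readouts_at_that_dose(self):
        prof = make_profile({"Viability": [-0.5, 0.0, 0.0, 0.0],
                             "IL17A": [-0.9, 0.0, 0.0, 0.0]})
        for readout in PANEL:
            calls = dose_calls(prof, readout)
            assert calls[0].direction == "excluded_cytotoxic"


class TestCallDirection:
    def test_inhibitor_example(self):
        prof = make_profile({"IL17A": [-0.3, -0.25, -0.1, 0.0]})
        call = call_direction(prof, "IL17A")
        assert call.direction == "inhibitor"
        assert call.active_doses == (0.1, 0.3)  # the two lowest-ratio doses
        assert call.n_noncytotoxic_doses == 4

    def test_cytotoxic_active_doses_void_the_call(self):
        prof = make_profile({"IL17F": [-0.3, -0.25, -0.1, 0.0],
                             "Viability": [-0.5, -0.5, 0.0, 0.0]})
        assert call_direction(prof, "IL17F").direction == "none"

    def test_stimulator_example(self):
        prof = make_profile({"IL17A": [0.2, 0.18, 0.05, 0.0]})
        call = call_direction(prof, "IL17A")
        assert call.direction == "stimulator"
        assert call.active_doses == (0.1, 0.3)

    def test_boundary_values_are_inactive(self):
        prof = make_profile({"IL17A": [-0.2, -0.2, 0.15, 0.15]})
        assert call_direction(prof, "IL17A").direction == "none"

    def test_single_active_dose_is_not_a_hit(self):
        prof = make_profile({"IL17A": [-0.9, 0.0, 0.0, 0.0]})
        assert call_direction(prof, "IL17A").direction == "none"

    def test_mixed_pattern_majority_wins(self):
        prof = make_profile({"IL17A": [0.3, 0.3, -0.5, -0.5]})
        with pytest.warns(UserWarning, match="tie"):
            assert call_direction(prof, "IL17A").direction == "none"
        # one stimulated dose is below the minimum; the inhibition stands
        prof2 = make_profile({"IL17A": [0.3, -0.5, -0.5, -0.5]})
        assert call_direction(prof2, "IL17A").direction == "inhibitor"
        # both patterns qualify on a 5-dose series: the majority wins
        prof3 = make_profile({"IL17A": [0.3, 0.3, -0.5, -0.5, -0.5]},
                             doses=(0.1, 0.3, 1.0, 3.0, 9.0))
        assert call_direction(prof3, "IL17A").direction == "inhibitor"

    def test_unknown_readout_errors(self):
        prof = make_profile({})
        with pytest.raises(HitCallingError, match="unknown readout"):
            call_direction(prof, "bogus")

    def test_invariant_to_dose_reordering(self):
        vals = [-0.3, -0.25, 0.0, -0.5]
        prof = make_profile({"IL17A": vals})
        # build the permuted profile through sorted reconstruction
        ratios = pd.DataFrame(0.0, index=sorted((1.0, 0.1, 3.0, 0.3)),
                              columns=list(PANEL))
        for d, v in zip((1.0, 0.1, 3.0, 0.3), [vals[2], vals[0], vals[3], vals[1]]):
            ratios.at[d, "IL17A"] = v
        permuted = AgentProfile("drugX", "P1",
                                DoseSeries("drugX", tuple(sorted(DOSES)), "uM"),
                                ratios,
                                pd.DataFrame(False, index=ratios.index,
                                             columns=list(PANEL)))
        assert call_direction(prof, "IL17A") == call_direction(permuted, "IL17A")


def brute_force_direction(ratios: list[float], cytotoxic: list[bool],
                          th: Thresholds = Thresholds()) -> str:
    """Literal enumeration of the footnote rules, independent of the code path."""
    usable = [r for r, c in zip(ratios, cytotoxic) if not c]
    n_inh = sum(1 for r in usable if r < th.theta_inhibit)
    n_stim = sum(1 for r in usable if r > th.theta_stimulate)
    if n_inh >= th.min_active_doses and n_stim >= th.min_active_doses:
        if n_inh == n_stim:
            return "none"
        return "inhibitor" if n_inh > n_stim else "stimulator"
    if n_inh >= th.min_active_doses:
        return "inhibitor"
    if n_stim >= th.min_active_doses:
        return "stimulator"
    return "none"


class TestOracleEquivalence:
    LEVELS = {"inhibit": -0.3, "neutral": 0.0, "stimulate": 0.2}

    def test_all_81_sign_patterns_match_brute_force(self):
        for pattern in itertools.product(self.LEVELS, repeat=4):
            ratios = [self.LEVELS[p] for p in pattern]
            prof = make_profile({"IL17A": ratios})
            got = call_direction(prof, "IL17A").direction
            want = brute_force_direction(ratios, [False] * 4)
            assert got == want, pattern

    def test_patterns_with_cytotoxic_top_dose_match_brute_force(self):
        for pattern in itertools.product(self.LEVELS, repeat=4):
            ratios = [self.LEVELS[p] for p in pattern]
            prof = make_profile({"IL17A": ratios,
                                 "Viability": [0.0, 0.0, 0.0, -0.4]})
            got = call_direction(prof, "IL17A").direction
            want = brute_force_direction(ratios, [False, False, False, True])
            assert got == want, pattern


class TestMonotonicityProperties:
    def test_more_extreme_ratio_never_deletes_a_hit(self, rng):
        for _ in range(100):
            ratios = rng.uniform(-0.6, 0.4, 4).tolist()
            prof = make_profile({"IL17A": ratios})
            call = call_direction(prof, "IL17A")
            if call.direction == "none":
                continue
            sign = -1.0 if call.direction == "inhibitor" else 1.0
            j = int(rng.integers(4))
            pushed = list(ratios)
            pushed[j] = sign * (abs(pushed[j]) + 1.0)
            call2 = call_direction(make_profile({"IL17A": pushed}), "IL17A")
            assert call2.direction == call.direction

    def test_flagging_one_more_dose_cytotoxic_never_adds_a_hit(self, rng):
        # restricted to unidirectional profiles: with opposing patterns the
        # majority tie rule can legitimately flip when a dose is excluded
        for _ in range(100):
            ratios = rng.uniform(-0.6, 0.1, 4).tolist()
            base_v = [0.0, 0.0, 0.0, 0.0]
            prof = make_profile({"IL17A": ratios, "Viability": base_v})
            before = call_direction(prof, "IL17A")
            j = int(rng.integers(4))
            v2 = list(base_v)
            v2[j] = -0.5
            after = call_direction(make_profile({"IL17A": ratios,
                                                 "Viability": v2}), "IL17A")
            if before.direction == "none":
                assert after.direction == "none"


class TestSelectivity:
    def test_torin1_like_pattern_is_a_over_f_dose_dependent(self):
        # IL-17A inhibited at all 4 doses, IL-17F only at the top 2
        prof = make_profile({"IL17A": [-0.5] * 4,
                             "IL17F": [0.0, 0.0, -0.5, -0.5]})
        hits, sel = call_agent(prof)
        assert sel.category == "A_over_F"
        assert sel.dose_dependent

    def test_same_doses_both_is_a_and_f(self):
        prof = make_profile({"IL17A": [0.0, -0.5, -0.5, -0.5],
                             "IL17F": [0.0, -0.5, -0.5, -0.5]})
        _, sel = call_agent(prof)
        assert sel.category == "A_and_F"
        assert not sel.dose_dependent

    def test_pge2_like_divergence(self):
        prof = make_profile({"IL17A": [0.5] * 4, "IL17F": [-0.5] * 4})
        hits, sel = call_agent(prof)
        assert sel.category == "none"
        assert sel.divergent
        by = {h.readout: h.direction for h in hits}
        assert by["IL17A"] == "stimulator" and by["IL17F"] == "inhibitor"

    def test_single_cytokine_hits(self):
        _, sel = call_agent(make_profile({"IL17A": [-0.5] * 4}))
        assert sel.category == "A_only" and not sel.dose_dependent
        _, sel = call_agent(make_profile({"IL17F": [-0.5] * 4}))
        assert sel.category == "F_only"

    def test_no_hits_is_none(self):
        _, sel = call_agent(make_profile({}))
        assert sel == SelectivityCall("drugX", "none")

    def test_f_over_a_symmetry(self):
        prof = make_profile({"IL17F": [-0.5] * 4,
                             "IL17A": [0.0, 0.0, -0.5, -0.5]})
        _, sel = call_agent(prof)
        assert sel.category == "F_over_A" and sel.dose_dependent

    def test_mismatched_agents_rejected(self):
        prof = make_profile({"IL17A": [-0.5] * 4, "IL17F": [-0.5] * 4})
        a = call_direction(prof, "IL17A")
        f = HitCall("other", "IL17F", "inhibitor", (0.1, 0.3), 4)
        with pytest.raises(HitCallingError, match="one agent"):
            classify_selectivity(a, f, prof)


class TestClassSummary:
    @staticmethod
    def _calls(spec: dict[str, str]):
        """spec: agent -> category ('inactive' for no effect)."""
        sels, hits = [], []
        for agent, cat in spec.items():
            if cat == "inactive":
                sels.append(SelectivityCall(agent, "none"))
                hits.append(HitCall(agent, "IL17A", "none", (), 4))
            else:
                sels.append(SelectivityCall(
                    agent, cat,
                    dose_dependent=cat in ("A_over_F", "F_over_A")))
                hits.append(HitCall(agent, "IL17A", "inhibitor", (0.1, 0.3), 4))
        return sels, hits

    def test_mek_like_four_of_five(self):
        sels, hits = self._calls({f"mek{i}": "A_and_F" for i in range(4)}
                                 | {"mek4": "inactive"})
        (summary,) = summarize_class(sels, hits, {a: "MEK" for a in
                                                  [f"mek{i}" for i in range(5)]})
        assert (summary.agents_active, summary.agents_total) == (4, 5)
        assert summary.included and summary.modal_selectivity == "A_and_F"

    def test_half_is_excluded(self):
        sels, hits = self._calls({"a1": "A_and_F", "a2": "inactive"})
        (summary,) = summarize_class(sels, hits, {"a1": "X", "a2": "X"})
        assert not summary.included  # 1/2 is not a strict majority

    def test_zero_active_excluded(self):
        sels, hits = self._calls({"a1": "inactive", "a2": "inactive"})
        (summary,) = summarize_class(sels, hits, {"a1": "X", "a2": "X"})
        assert not summary.included and summary.agents_active == 0

    def test_modal_tie_prefers_most_inclusive(self):
        sels, hits = self._calls({"a1": "A_over_F", "a2": "A_and_F",
                                  "a3": "F_only", "a4": "A_and_F",
                                  "a5": "A_over_F"})
        (summary,) = summarize_class(sels, hits, {a: "X" for a in
                                                  ["a1", "a2", "a3", "a4", "a5"]})
        assert summary.modal_selectivity == "A_and_F"

    def test_unmapped_agent_listed(self):
        sels, hits = self._calls({"a1": "A_and_F"})
        with pytest.raises(HitCallingError, match="a1"):
            summarize_class(sels, hits, {})
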