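"""Profile reports and summary tables in the screen's presentation style.

A profile report is the familiar bar chart: log10 ratios grouped by
readout along the x-axis in panel order (Proliferation, Viability/
Cytotoxicity, IgG, IL-17A, IL-17F, IL-2, IL-6, TNFα), one bar per dose,
with a gray band marking the 95% significance envelope per readout.
The numeric TSV twin is the canonical artifact — it contains exactly the
plotted numbers and is byte-stable across runs; images are a convenience
layer.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .hit_calling import (
    CATEGORIES,
    ClassSummary,
    HitCall,
    Thresholds,
    flag_cytotoxic_doses,
)
from .plate_data import PANEL
from .profiling import AgentProfile, Envelope


class ReportingError(ValueError):
    """Raised when a report cannot be rendered from its inputs."""


#: Presentation labels for selectivity categories (asterisk marks the
#: dose-stratified reading of "X over Y").
CATEGORY_LABELS = {
    "A_and_F": "IL-17A and IL-17F",
    "A_over_F": "IL-17A over IL-17F*",
    "F_over_A": "IL-17F over IL-17A*",
    "A_only": "IL-17A",
    "F_only": "IL-17F",
    "none": "",
}


def _check_panels(profile: AgentProfile, envelope: Envelope) -> None:
    with_data = {
        r for r in PANEL
        if not profile.ratios[r].isna().all()
    }
    missing = with_data - set(envelope.bounds)
    if missing:
        raise ReportingError(
            f"envelope lacks readouts present in the profile: {sorted(missing)}"
        )


def profile_table_lines(profile: AgentProfile, envelope: Envelope,
                        thresholds: Thresholds = Thresholds()) -> list[str]:
    """TSV lines of exactly the numbers a rendered profile shows."""
    _check_panels(profile, envelope)
    cytotoxic = flag_cytotoxic_doses(profile, thresholds)
    lines = [
        "agent_id\treadout\tdose\tdose_unit\tlog10_ratio\t"
        "env_lower\tenv_upper\toutside_envelope\tcytotoxic_dose"
    ]
    for readout in PANEL:
        if readout not in envelope.bounds:
            continue
        lo, hi = envelope.bounds[readout]
        for dose in profile.dose_series.doses:
            v = profile.ratios.at[dose, readout]
            missing = isinstance(v, float) and math.isnan(v)
            outside = "" if missing else str(int(not (lo <= v <= hi)))
            lines.append(
                "\t".join(
                    [
                        profile.agent_id,
                        readout,
                        repr(float(dose)),
                        profile.dose_series.unit,
                        "" if missing else repr(float(v)),
                        repr(float(lo)),
                        repr(float(hi)),
                        outside,
                        str(int(cytotoxic.get(dose, False))),
                    ]
                )
            )
    return lines


def render_profile(profile: AgentProfile, envelope: Envelope,
                   path: str | Path, fmt: str | None = None,
                   thresholds: Thresholds = Thresholds()) -> None:
    """Write a profile report as tsv, svg or png (inferred from suffix)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "tsv":
        path.write_text("\n".join(profile_table_lines(profile, envelope, thresholds)) + "\n")
        return
    if fmt not in {"svg", "png"}:
        raise ReportingError(f"unsupported report format {fmt!r}")
    _check_panels(profile, envelope)
    doses = list(profile.dose_series.doses)
    n_doses = len(doses)
    group_width = 0.8
    bar_width = group_width / n_doses
    fig, ax = plt.subplots(figsize=(10, 4))
    for gi, readout in enumerate(PANEL):
        if readout in envelope.bounds:
            lo, hi = envelope.bounds[readout]
            ax.fill_between([gi - 0.5, gi + 0.5], lo, hi,
                            color="0.85", zorder=0, linewidth=0)
        for di, dose in enumerate(doses):
            v = profile.ratios.at[dose, readout]
            if isinstance(v, float) and math.isnan(v):
                continue
            x = gi - group_width / 2 + (di + 0.5) * bar_width
            ax.bar(x, v, width=bar_width * 0.9,
                   color=plt.cm.viridis(di / max(n_doses - 1, 1)), zorder=2)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_xticks(range(len(PANEL)))
    ax.set_xticklabels(PANEL, rotation=45, ha="right")
    ax.set_ylabel("Log10 ratio (treated / control stimulated)")
    ax.set_title(f"{profile.agent_id} ({profile.dose_series.doses[0]}"
                 f"–{profile.dose_series.doses[-1]} {profile.dose_series.unit})")
    fig.tight_layout()
    fig.savefig(path, format=fmt)
    plt.close(fig)


def render_class_tables(summaries: Iterable[ClassSummary], path: str | Path,
                        *, included_only: bool = True) -> None:
    """Class summary TSV: class, "n_active (n_total)", selectivity label.

    Rows are ordered by class name; with ``included_only`` (default) only
    classes where a strict majority of agents were active appear, matching
    the published summary-table convention.
    """
    lines = ["class\tn_active (n_total)\tselectivity"]
    for s in sorted(summaries, key=lambda s: s.class_name):
        if included_only and not s.included:
            continue
        lines.append(
            f"{s.class_name}\t{s.agents_active} ({s.agents_total})\t"
            f"{CATEGORY_LABELS[s.modal_selectivity]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
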