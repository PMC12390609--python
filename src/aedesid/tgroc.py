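"""Two-graph ROC analysis for maximum-Ct cutoff selection.

For a verified tissue group, sensitivity and specificity are recomputed
while sweeping a maximum-Ct cutoff over a 0.5-cycle grid: at cutoff c a
channel is positive iff it amplified with Ct <= c, so sensitivity (the
fraction of specimens whose correct channel is positive) is non-decreasing
in c while specificity (the fraction whose wrong channel stays negative)
is non-increasing. Plotting both against c gives the two-graph ROC, and
the working cutoff is chosen where the curves meet:

* a crossing (sign change of sensitivity - specificity between adjacent
  grid points, or equality at an isolated grid point) selects that grid
  cutoff (``intersection``);
* curves that coincide over a run of grid points and then diverge select
  the last cutoff of the run (``last_equality``);
* otherwise — curves that never meet, or coincide through the end of the
  grid — the cutoff defaults to 40, the assay's final cycle
  (``default_40``).

The grid runs from 10.0 to 40.0 cycles in 0.5 steps; 10 is below every
plausible tissue Ct for this assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import SpeciesCall, call_record
from .qpcr_io import (
    Dataset,
    MAX_CYCLES,
    SpecimenRecord,
    channel_for_species,
)

GRID_START = 10.0
GRID_STEP = 0.5

#: Sensitivity and specificity are ratios of small integers; exact equality
#: is meaningful, with a tiny tolerance guarding float accumulation.
EQUALITY_TOL = 1e-12

INTERSECTION = "intersection"
LAST_EQUALITY = "last_equality"
DEFAULT_40 = "default_40"


@dataclass
class TgrocCurve:
    group_label: str
    cutoffs: np.ndarray
    se_at: np.ndarray
    sp_at: np.ndarray
    selected_cutoff: float
    selection_rule: str
    flags: list[str] = field(default_factory=list)


def _grid(step: float, start: float, max_cutoff: float) -> np.ndarray:
    n = int(round((max_cutoff - start) / step)) + 1
    return start + step * np.arange(n)


def _channel_min_cts(records: Sequence[SpecimenRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per specimen, min amplified Ct on the correct / wrong channel (inf if none)."""
    correct = np.full(len(records), np.inf)
    wrong = np.full(len(records), np.inf)
    for i, rec in enumerate(records):
        ch = channel_for_species(rec.verified_species)
        for r in rec.results:
            if not r.amplified or r.ct is None:
                continue
            if r.probe is ch:
                correct[i] = min(correct[i], r.ct)
            else:
                wrong[i] = min(wrong[i], r.ct)
    return correct, wrong


def compute_curves(
    records: Sequence[SpecimenRecord],
    group_label: str = "",
    step: float = GRID_STEP,
    start: float = GRID_START,
    max_cutoff: float = MAX_CYCLES,
) -> TgrocCurve:
    """Sensitivity/specificity versus maximum-Ct cutoff for one group."""
    if not records:
        raise ValueError("cannot compute TG-ROC curves for an empty group")
    grid = _grid(step, start, max_cutoff)
    correct, wrong = _channel_min_cts(records)
    se = (correct[:, None] <= grid[None, :]).mean(axis=0)
    sp = 1.0 - (wrong[:, None] <= grid[None, :]).mean(axis=0)
    curve = TgrocCurve(
        group_label=group_label or (records[0].group_label if records else ""),
        cutoffs=grid,
        se_at=se,
        sp_at=sp,
        selected_cutoff=float(max_cutoff),
        selection_rule=DEFAULT_40,
    )
    cutoff, rule = select_cutoff(curve)
    curve.selected_cutoff = cutoff
    curve.selection_rule = rule
    return curve


def select_cutoff(curve: TgrocCurve) -> tuple[float, str]:
    """Apply the intersection / last-equality / default-40 rules to a curve.

    Crossings take precedence; with several isolated crossings the lowest
    cutoff is returned and the curve flagged. An equality run of two or
    more grid points followed by divergence returns the run's last point.
    Coincidence through the end of the grid, or no meeting at all, falls
    back to the 40-cycle default.
    """
    d = curve.se_at - curve.sp_at
    eq = np.abs(d) < EQUALITY_TOL
    k = len(d)
    crossings: list[float] = []
    for i in range(k):
        if eq[i]:
            prev_eq = eq[i - 1] if i > 0 else False
            next_eq = eq[i + 1] if i < k - 1 else False
            if not prev_eq and not next_eq:
                crossings.append(float(curve.cutoffs[i]))
        elif i < k - 1 and not eq[i + 1] and d[i] * d[i + 1] < 0:
            # strict sign change between adjacent grid points: take the
            # lower point so the cutoff stays on the grid and is stricter
            crossings.append(float(curve.cutoffs[i]))
    if crossings:
        if len(crossings) > 1:
            curve.flags.append(f"multiple crossings at {crossings}")
        return min(crossings), INTERSECTION
    # equality runs (length >= 2) that later diverge
    i = 0
    while i < k:
        if eq[i]:
            j = i
            while j + 1 < k and eq[j + 1]:
                j += 1
            if j - i + 1 >= 2 and j < k - 1:
                return float(curve.cutoffs[j]), LAST_EQUALITY
            i = j + 1
        else:
            i += 1
    return float(curve.cutoffs[-1]), DEFAULT_40


def curves_by_group(
    dataset: Dataset,
    step: float = GRID_STEP,
    start: float = GRID_START,
    max_cutoff: float = MAX_CYCLES,
) -> dict[str, TgrocCurve]:
    """TG-ROC curves for every verified tissue group in the dataset."""
    groups: dict[str, list[SpecimenRecord]] = {}
    for rec in dataset.tissue_records():
        groups.setdefault(rec.group_label, []).append(rec)
    return {
        label: compute_curves(groups[label], label, step, start, max_cutoff)
        for label in sorted(groups)
    }


def apply_cutoffs(
    dataset: Dataset,
    cutoff_table: Mapping[str, tuple[float, float]],
) -> dict[str, SpeciesCall]:
    """Re-call tissue samples with per-group (sierr, aegypti) Ct cutoffs.

    Amplifications above a channel's cutoff are treated as negative. Every
    tissue group in the dataset must appear in the table.
    """
    calls: dict[str, SpeciesCall] = {}
    for rec in dataset.tissue_records():
        if rec.group_label not in cutoff_table:
            raise KeyError(f"no cutoffs for group {rec.group_label!r}")
        cut_sierr, cut_aegy = cutoff_table[rec.group_label]
        calls[rec.sample_id] = call_record(rec, cut_sierr, cut_aegy)
    return calls
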