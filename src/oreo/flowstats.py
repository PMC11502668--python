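"""Flow-cytometry gating and the reporter selectivity/efficiency statistics.

Gating follows the reporter-only-control convention: live events are those
with viability-dye intensity at or below a threshold taken as a quantile of
the control's viability channel; the GFP/mCherry quadrant thresholds are set
at a high quantile (default 0.999) of the control's live population per
channel, so essentially all reporter-only live events fall in the
double-negative quadrant Q4. Quadrants (x = eGFP, y = mCherry):

* Q1 — mCherry-positive only, Q2 — double positive,
* Q3 — eGFP-positive only,  Q4 — double negative.

Selectivity is the ratio of median mCherry to median eGFP intensity over the
NOT-Q4 population (Q1 ∪ Q2 ∪ Q3), normalized to a reference condition
(cytoplasmic enzyme, "NES"-like). Efficiency is the double-positive
percentage of live cells normalized by the iRFP-positive (transfection)
percentage of the reference. Medians use the linear-interpolation definition
on even counts (numpy's default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GatingError, UndefinedResultError

DEFAULT_VIABILITY_CUT = 0.85
DEFAULT_QUADRANT_QUANTILE = 0.999
#: iRFP intensity (generator units) above which an event counts as transfected.
DEFAULT_IRFP_THRESHOLD = 1000.0

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class GateThresholds:
    """Thresholds applied during gating (echoed to the JSON sidecar)."""

    viability: float
    gfp: float
    mcherry: float
    viability_cut: float
    quadrant_quantile: float


def _require_columns(events: pd.DataFrame, what: str) -> None:
    missing = {"gfp", "mcherry", "viability"} - set(events.columns)
    if missing:
        raise GatingError(f"{what} table missing columns: {sorted(missing)}")


def gate_events(
    events: pd.DataFrame,
    reporter_only: pd.DataFrame,
    viability_cut: float = DEFAULT_VIABILITY_CUT,
    quadrant_quantile: float = DEFAULT_QUADRANT_QUANTILE,
) -> tuple[pd.DataFrame, GateThresholds]:
    """Label live events and assign quadrants against a reporter-only control.

    The viability threshold is the ``viability_cut`` quantile of the control's
    viability channel (dye-high events are dead); quadrant thresholds are the
    ``quadrant_quantile`` quantiles of the control's live population per
    fluorescence channel. Returns a copy of ``events`` with ``live`` and
    ``quadrant`` columns (quadrants only for live singlets) plus the
    thresholds used.
    """
    if events.empty:
        raise GatingError("events table is empty")
    if reporter_only.empty:
        raise GatingError("reporter-only control table is empty")
    if not 0.0 < viability_cut < 1.0 or not 0.0 < quadrant_quantile < 1.0:
        raise GatingError(
            f"cut quantiles must be in (0, 1), got viability_cut={viability_cut}, "
            f"quadrant_quantile={quadrant_quantile}"
        )
    _require_columns(events, "events")
    _require_columns(reporter_only, "reporter-only control")

    via_thr = float(np.quantile(reporter_only["viability"], viability_cut))
    ctrl_singlet = (
        reporter_only["singlet"].to_numpy(dtype=bool)
        if "singlet" in reporter_only.columns
        else np.ones(len(reporter_only), dtype=bool)
    )
    ctrl_live = reporter_only[(reporter_only["viability"] <= via_thr) & ctrl_singlet]
    if ctrl_live.empty:
        raise GatingError("no live singlet events in the reporter-only control")
    # "higher" keeps each threshold at an observed control intensity, so at
    # least quadrant_quantile of control live events sit at/below it per
    # channel and the control's Q4 containment is >= 1 - 2*(1 - quantile)
    t_gfp = float(np.quantile(ctrl_live["gfp"], quadrant_quantile, method="higher"))
    t_mch = float(np.quantile(ctrl_live["mcherry"], quadrant_quantile, method="higher"))

    gated = events.copy()
    singlet = (
        gated["singlet"].to_numpy(dtype=bool)
        if "singlet" in gated.columns
        else np.ones(len(gated), dtype=bool)
    )
    live = (gated["viability"].to_numpy() <= via_thr) & singlet
    gated["live"] = live
    gfp_pos = gated["gfp"].to_numpy() > t_gfp
    mch_pos = gated["mcherry"].to_numpy() > t_mch
    quadrant = np.where(
        gfp_pos & mch_pos, "Q2", np.where(mch_pos, "Q1", np.where(gfp_pos, "Q3", "Q4"))
    )
    gated["quadrant"] = pd.Series(np.where(live, quadrant, None), dtype="object")
    thresholds = GateThresholds(
        viability=via_thr,
        gfp=t_gfp,
        mcherry=t_mch,
        viability_cut=viability_cut,
        quadrant_quantile=quadrant_quantile,
    )
    return gated, thresholds


def _live(gated: pd.DataFrame, what: str) -> pd.DataFrame:
    if "live" not in gated.columns or "quadrant" not in gated.columns:
        raise GatingError(f"{what} table is not gated (missing live/quadrant columns)")
    live = gated[gated["live"]]
    if live.empty:
        raise UndefinedResultError(f"no live events in {what}; statistic undefined")
    return live


@dataclass(frozen=True)
class EfficiencyResult:
    """Double-positive percentage of live cells, iRFP-normalized."""

    q2_pct: float
    irfp_pos_pct: float
    reference_irfp_pos_pct: float
    normalized_q2_pct: float


def efficiency(
    gated: pd.DataFrame,
    reference_gated: pd.DataFrame,
    irfp_threshold: float = DEFAULT_IRFP_THRESHOLD,
) -> EfficiencyResult:
    """Q2 percentage of live cells, normalized by relative transfection rates.

    ``normalized_q2_pct = q2_pct × irfp⁺%(reference) / irfp⁺%(sample)``; the
    reference condition therefore normalizes to its own raw Q2 percentage.
    """
    live = _live(gated, "sample")
    ref_live = _live(reference_gated, "reference")
    q2_pct = 100.0 * float((live["quadrant"] == "Q2").mean())
    irfp_pct = 100.0 * float((live["irfp"] > irfp_threshold).mean())
    ref_irfp_pct = 100.0 * float((ref_live["irfp"] > irfp_threshold).mean())
    if irfp_pct == 0:
        raise UndefinedResultError("no iRFP-positive live events in sample; efficiency undefined")
    return EfficiencyResult(
        q2_pct=q2_pct,
        irfp_pos_pct=irfp_pct,
        reference_irfp_pos_pct=ref_irfp_pct,
        normalized_q2_pct=q2_pct * ref_irfp_pct / irfp_pct,
    )


@dataclass(frozen=True)
class SelectivityResult:
    """Median-intensity ratio over the NOT-Q4 population, reference-normalized."""

    median_mcherry: float
    median_gfp: float
    ratio: float
    reference_ratio: float
    normalized_fold_change: float


def _not_q4_medians(gated: pd.DataFrame, what: str) -> tuple[float, float]:
    live = _live(gated, what)
    sel = live[live["quadrant"] != "Q4"]
    if sel.empty:
        raise UndefinedResultError(f"no live events outside Q4 in {what}; selectivity undefined")
    return float(np.median(sel["mcherry"])), float(np.median(sel["gfp"]))


def selectivity(gated: pd.DataFrame, reference_gated: pd.DataFrame) -> SelectivityResult:
    """Median mCherry / median eGFP over Q1∪Q2∪Q3, normalized to the reference."""
    med_mch, med_gfp = _not_q4_medians(gated, "sample")
    ref_mch, ref_gfp = _not_q4_medians(reference_gated, "reference")
    if med_gfp == 0 or ref_gfp == 0:
        raise UndefinedResultError("median eGFP intensity is 0; ratio undefined")
    ratio = med_mch / med_gfp
    ref_ratio = ref_mch / ref_gfp
    return SelectivityResult(
        median_mcherry=med_mch,
        median_gfp=med_gfp,
        ratio=ratio,
        reference_ratio=ref_ratio,
        normalized_fold_change=ratio / ref_ratio,
    )
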