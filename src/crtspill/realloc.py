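"""Cluster reallocation: the dilation diagnostic for spatial spillover.

One arm's cluster boundaries are buffered outward in increments (default
0–1000 m in 100 m steps); opposite-arm households captured by the buffer
are reassigned, and the main trial model is refitted at each step.  Under
no spillover, growing either arm dilutes the contrast and the intervention
estimate attenuates toward SMR 1.  Under a spillover from intervention to
control, dilating the intervention arm over the spillover's functional
range removes partially-protected controls from the control arm, and the
estimate strengthens (smaller SMR) before dilution takes over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialData
from .models import DegenerateArmError, FitError, ModelSpec, fit
from .spatial import apply_assignment, dilate_and_reassign

logger = logging.getLogger(__name__)

DEFAULT_BUFFERS = tuple(float(b) for b in range(0, 1001, 100))


@dataclass
class ReallocationCurve:
    """Per-step intervention estimates for both dilation sweeps."""

    table: pd.DataFrame
    # columns: dilated_arm, buffer_m, n_intervention, n_control,
    #          smr, lower95, upper95, degenerate
    buffers: tuple
    spec: ModelSpec

    def arm_sweep(self, dilated_arm: int) -> pd.DataFrame:
        return self.table[self.table["dilated_arm"] == dilated_arm].reset_index(drop=True)


def reallocation_sweep(trial: TrialData, spec: ModelSpec | None = None,
                       buffers=DEFAULT_BUFFERS) -> ReallocationCurve:
    """Dilate each arm over the buffer grid, reassign and refit.

    Degenerate steps (an arm shrunk below the model's minimum) are recorded
    with a flag and no estimate.  The buffer-0 rows equal the base fit.
    """
    spec = spec or ModelSpec(random_structure="iid")
    try:
        base = fit(trial, spec)
    except FitError as exc:
        raise FitError(f"base fit failed; sweep aborted: {exc}") from exc
    if not base.converged:
        raise FitError("base fit did not converge; sweep aborted")
    base_row = base.smr_table.loc["intervention"]

    rows = []
    for arm in (1, 0):
        for b in buffers:
            if b == 0:
                hh = trial.households
                rows.append(
                    {
                        "dilated_arm": arm,
                        "buffer_m": 0.0,
                        "n_intervention": int((hh["arm"] == 1).sum()),
                        "n_control": int((hh["arm"] == 0).sum()),
                        "smr": base_row["estimate"],
                        "lower95": base_row["lower95"],
                        "upper95": base_row["upper95"],
                        "degenerate": False,
                    }
                )
                continue
            assign = dilate_and_reassign(trial, dilated_arm=arm, buffer_m=b)
            realloc = apply_assignment(trial, assign)
            n1 = int((assign.arm_labels == 1).sum())
            n0 = int((assign.arm_labels == 0).sum())
            row = {
                "dilated_arm": arm,
                "buffer_m": float(b),
                "n_intervention": n1,
                "n_control": n0,
                "smr": np.nan,
                "lower95": np.nan,
                "upper95": np.nan,
                "degenerate": assign.degenerate,
            }
            if not assign.degenerate:
                try:
                    res = fit(realloc, spec)
                    t = res.smr_table.loc["intervention"]
                    row.update(smr=t["estimate"], lower95=t["lower95"], upper95=t["upper95"])
                except DegenerateArmError:
                    row["degenerate"] = True
                except FitError as exc:
                    logger.warning("refit failed at arm=%d buffer=%g: %s", arm, b, exc)
                    row["degenerate"] = True
            rows.append(row)
    return ReallocationCurve(pd.DataFrame(rows), tuple(buffers), spec)


def curve_summary(curve: ReallocationCurve) -> dict:
    """Per-arm mean/min/max of estimates over non-degenerate buffers > 0,
    plus the original (buffer-0) estimate — the reallocation block of the
    exploratory summary table."""
    t = curve.table
    ok = t[(~t["degenerate"]) & t["smr"].notna()]
    if ok.empty:
        raise FitError("all sweep steps degenerate; no summary")
    out = {"original_smr": float(t.loc[t["buffer_m"] == 0, "smr"].iloc[0])}
    for arm, name in ((0, "control_larger"), (1, "intervention_larger")):
        sub = ok[(ok["dilated_arm"] == arm) & (ok["buffer_m"] > 0)]
        if sub.empty:
            raise FitError(f"all non-zero steps degenerate for dilated_arm={arm}")
        out[name] = {
            "mean": float(sub["smr"].mean()),
            "min": float(sub["smr"].min()),
            "max": float(sub["smr"].max()),
            "n_steps": int(len(sub)),
        }
    return out
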