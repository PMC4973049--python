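"""Result tables and machine-readable outputs.

Builds per-arm summary tables mirroring the published layout (expected
benefit, expected cost, paired incremental benefit and cost versus usual
care, ICER or dominance flag, probability cost-effective at 30,000 and
50,000 GBP), plus CEAC curves and cost-effectiveness-plane coordinates, and
writes everything as delimited text with a JSON run log sufficient to
reproduce the run bit-for-bit (seed, draws, scenario, config hash).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import economics
from .psa import PSAResults

DEFAULT_THRESHOLDS = (30_000.0, 50_000.0)
DOMINATED_TOKEN = "Dominated"

MEASURES = {"cases-averted": "cea", "qalys": "cua"}


def summary_table(res: PSAResults, measure: str,
                  thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                  reference: str = "UC") -> pd.DataFrame:
    """Per-arm results table for one effect measure.

    The benefit column shows expected poison cases (cost-effectiveness
    analysis) or expected QALYs (cost-utility analysis); increments are
    paired per-draw differences versus the reference arm.  ICERs are ratios
    of mean increments against the reference for arms on the efficient
    frontier; dominated arms carry the literal ``Dominated`` token in the
    display column.
    """
    eff, cost = res.effects(measure), res.costs(measure)
    shown = res.cases if measure == "cases-averted" else res.qalys
    r = res.labels.index(reference)
    table = economics.incremental_analysis(res.arm_summaries(measure), reference,
                                           effect_label=measure)
    curve = economics.ceac(eff, cost, res.labels, thresholds)

    rows = []
    for j, lab in enumerate(res.labels):
        d_eff = eff[:, j] - eff[:, r]
        d_cost = cost[:, j] - cost[:, r]
        dom = table.dominance[lab]
        icer = table.icer_vs_reference[lab]
        if lab == reference:
            display = ""
        elif dom is not None:
            display = DOMINATED_TOKEN
        else:
            display = f"{icer:.0f}"
        row = {
            "arm": lab,
            "benefit_mean": shown[:, j].mean(),
            "benefit_lo": np.percentile(shown[:, j], 2.5),
            "benefit_hi": np.percentile(shown[:, j], 97.5),
            "cost_mean": cost[:, j].mean(),
            "cost_lo": np.percentile(cost[:, j], 2.5),
            "cost_hi": np.percentile(cost[:, j], 97.5),
            "incr_benefit_mean": np.nan if lab == reference else d_eff.mean(),
            "incr_benefit_lo": np.nan if lab == reference else np.percentile(d_eff, 2.5),
            "incr_benefit_hi": np.nan if lab == reference else np.percentile(d_eff, 97.5),
            "incr_cost_mean": np.nan if lab == reference else d_cost.mean(),
            "incr_cost_lo": np.nan if lab == reference else np.percentile(d_cost, 2.5),
            "incr_cost_hi": np.nan if lab == reference else np.percentile(d_cost, 97.5),
            "icer": np.nan if (lab == reference or dom is not None) else icer,
            "icer_display": display,
            "dominance": dom or "",
        }
        for lam in thresholds:
            t = int(np.flatnonzero(curve.thresholds == lam)[0])
            row[f"p_ce_{int(lam)}"] = round(float(curve.probability[t, j]), 3)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cea_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a results table as CSV (full precision; display columns are
    strings).  Round-trips exactly through :func:`read_cea_table`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_cea_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""],
                       float_precision="round_trip",
                       dtype={"icer_display": str, "dominance": str})


@dataclass
class ResultBundle:
    """Everything one run produces, with metadata to reproduce it."""

    results: PSAResults
    tables: dict[str, pd.DataFrame]
    ceac: dict[str, pd.DataFrame]
    plane: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_results(cls, res: PSAResults,
                     thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                     ceac_grid: Sequence[float] | None = None,
                     reference: str = "UC",
                     plane_draws: int | None = None) -> "ResultBundle":
        """``plane_draws`` caps the number of scatter points kept per arm
        (first draws; pairing preserved); None keeps every draw."""
        grid = (np.arange(0, 100_001, 2_500, dtype=float)
                if ceac_grid is None else np.asarray(list(ceac_grid), float))
        tables, ceacs, planes = {}, {}, {}
        for measure, tag in MEASURES.items():
            tables[tag] = summary_table(res, measure, thresholds, reference)
            curve = economics.ceac(res.effects(measure), res.costs(measure),
                                   res.labels, grid)
            ceacs[tag] = curve.to_frame()
            pl = economics.ce_plane(res.effects(measure), res.costs(measure),
                                    res.labels, reference)
            frames = []
            for lab, pts in pl.items():
                if plane_draws is not None:
                    pts = pts[:plane_draws]
                frames.append(pd.DataFrame({"arm": lab, "d_effect": pts[:, 0],
                                            "d_cost": pts[:, 1]}))
            planes[tag] = pd.concat(frames, ignore_index=True)
        meta = {
            "variant": res.variant, "scenario": res.scenario,
            "seed": res.seed, "n_draws": res.n_draws,
            "config_hash": res.config_hash, "reference": reference,
            "thresholds": list(thresholds),
            "threshold_note": ("cost-effectiveness analysis thresholds are per "
                               "poison case avoided; cost-utility per QALY"),
        }
        return cls(results=res, tables=tables, ceac=ceacs, plane=planes, metadata=meta)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = f"{self.results.variant}_{self.results.scenario}"
        for tag in self.tables:
            write_cea_table(self.tables[tag], out / f"{stem}_{tag}.csv")
            self.ceac[tag].to_csv(out / f"{stem}_ceac_{tag}.csv", index=False,
                                  float_format="%.12g")
            self.plane[tag].to_csv(out / f"{stem}_plane_{tag}.csv", index=False,
                                   float_format="%.12g")
        (out / f"{stem}_runlog.json").write_text(json.dumps(self.metadata, indent=2))
        return out
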