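#!/usr/bin/env python
"""Base-case analysis: safe storage of other household products.

Same pipeline as the medicines model with the household-products inputs.
The network meta-analysis places every arm's absolute safe-storage
probability below the high baseline prevalence (0.83), so active
interventions lower safe storage, add cases, and are dominated by usual
care in both analyses; education-vs-usual-care increments fall in the
north-west quadrant of the cost-effectiveness plane.
"""

from pathlib import Path

import numpy as np

from poisonprev import economics, psa
from poisonprev.reporting import ResultBundle, summary_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED, DRAWS = 1, 4000


def main() -> int:
    res = psa.run_variant("nonmedicinal", n_draws=DRAWS, seed=SEED)
    ResultBundle.from_results(res, plane_draws=150).write(OUT)

    cols = ["arm", "benefit_mean", "cost_mean", "incr_benefit_mean",
            "incr_cost_mean", "icer_display"]
    print("== cost-effectiveness (poison cases per 1,000 households) ==")
    print(summary_table(res, "cases-averted")[cols].to_string(index=False))
    print("\n== cost-utility (lifetime QALYs per 1,000 households) ==")
    print(summary_table(res, "qalys")[cols].to_string(index=False))

    pts = economics.ce_plane(res.effects("cases-averted"), res.cost_cea,
                             res.labels, "UC")["E"]
    nw = float(np.mean((pts[:, 0] < 0) & (pts[:, 1] > 0)))
    print(f"\neducation vs usual care: {nw:.0%} of simulated increments in the "
          f"north-west quadrant (more costly, fewer benefits)")
    print(f"tables written to {OUT}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
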