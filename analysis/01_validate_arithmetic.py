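#!/usr/bin/env python
"""Check the published derivation arithmetic before any simulation.

Recomputes every derived probability (ingestion, admission, severe, fatal),
the seven per-household offer costs and the three acute unit costs for both
model variants, and compares each against the value printed in the source
tables at printed precision.  Writes results/validation.csv.
"""

from pathlib import Path

import pandas as pd

from poisonprev.params import load_config, validate_config

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    rows = []
    for variant in ("medicinal", "nonmedicinal"):
        for name, printed, value, ok in validate_config(load_config(variant)):
            rows.append({"variant": variant, "quantity": name,
                         "printed": printed, "recomputed": value, "ok": ok})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "validation.csv", index=False)
    n_bad = int((~df["ok"]).sum())
    print(df.to_string(index=False))
    print(f"\n{len(df)} checks, {n_bad} failures -> results/validation.csv")
    return 1 if n_bad else 0


if __name__ == "__main__":
    raise SystemExit(main())
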