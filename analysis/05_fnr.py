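"""Estimate per-species false-negative rates from benchmark sites.

Uses the fully protected scenario (every functional window 100% identical
across species) with per-species detection sensitivities {0.9, 0.6, 0.3},
and compares each species' estimated FNR with the enumeration-based
conditional oracle that accounts for the >= 2-observations selection bias.
"""

from pathlib import Path

import pandas as pd

from phosite_evo.benchmarks import FNR_SENSITIVITIES, fnr_recovery

BASE = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    r = fnr_recovery(seed=seed, n_seeds=10)
    rows = []
    for sp, d in r["per_species"].items():
        rows.append({"species": sp, "sensitivity": d["sensitivity"],
                     "fnr_estimate": round(d["estimate"], 4),
                     "conditional_oracle": round(d["oracle"], 4),
                     "abs_error": round(d["abs_err"], 4)})
    df = pd.DataFrame(rows).sort_values("species")
    df.to_csv(BASE / "fnr.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\nbenchmark sites per replicate: {r['n_benchmark']}")
    print(f"max |estimate - oracle| = {r['max_abs_err']:.4f} "
          f"(10 replicates); monotone in sensitivity: "
          f"{r['monotone_in_sensitivity']}")


if __name__ == "__main__":
    main()
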