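"""Disease-variant proximity of conserved phosphosites.

Measures the fraction of phosphosites with a variant within 10 residues,
stratified by identity cutoff and acceptor status, and tests enrichment of
the high-identity stratum; then summarizes the power/type-I benchmark.
"""

from pathlib import Path

import pandas as pd

from phosite_evo.benchmarks import enrichment_power_and_type1
from phosite_evo.pipeline import run_synthetic_pipeline
from phosite_evo.synthetic_data import SimulationConfig

BASE = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    res = run_synthetic_pipeline(SimulationConfig(seed=seed, n_groups=60),
                                 train_propensity=False)
    rows = [{"identity_cutoff": p.identity_cutoff, "stratum": p.stratum,
             "n_sites": p.n_sites, "fraction_proximal": round(p.fraction, 3),
             "p_value_vs_below_cutoff": p.p_value}
            for p in res.proximity_results]
    df = pd.DataFrame(rows)
    df.to_csv(BASE / "disease_proximity.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    bench = enrichment_power_and_type1(seed=seed)
    print(f"\n2x planted enrichment, {bench['n_sites']} spaced sites: "
          f"detected at p < 0.05 in {bench['power']:.0%} of "
          f"{bench['n_power']} replicates")
    print(f"uniform-placement null: type-I error "
          f"{bench['type1_error']:.3f} over {bench['n_null']} replicates")


if __name__ == "__main__":
    main()
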