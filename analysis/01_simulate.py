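"""Generate the default synthetic six-species dataset.

Writes proteomes, gap-free truth alignments, the ortholog map, the
detection-limited multi-source site catalog, and the variant table to
scratch/dataset/, and prints the headline counts.
"""

from pathlib import Path

from phosite_evo import io as pio
from phosite_evo.synthetic_data import (SimulationConfig, simulate_detection,
                                        simulate_families, simulate_variants)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "dataset"


def main(seed: int = 1) -> None:
    cfg = SimulationConfig(seed=seed, n_groups=60)
    proteomes, groups, omap, truth = simulate_families(cfg)
    catalog = simulate_detection(truth, cfg, groups)
    variants = simulate_variants(truth, cfg)

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "alignments").mkdir(exist_ok=True)
    cfg.to_yaml(OUT / "config.yaml")
    for sp in cfg.species:
        pio.write_proteome_fasta(proteomes[sp], OUT / f"proteome_{sp}.fasta")
    for gid, group in groups.items():
        pio.write_alignment_fasta(group.alignment,
                                  OUT / "alignments" / f"{gid}.afa")
    pio.write_ortholog_map(omap, OUT / "ortholog_map.tsv")
    pio.write_site_table(catalog, OUT / "catalog.tsv")
    pio.write_variant_table(variants, OUT / "variants.tsv")

    n_sites = len(truth.all_sites())
    n_func = sum(len(g.functional_sites) for g in truth.groups.values())
    print(f"simulated {cfg.n_groups} ortholog families "
          f"({sum(len(p) for p in proteomes.values())} proteins)")
    print(f"planted {n_sites} true phosphosites "
          f"({n_func} functional, {n_sites - n_func} neutral)")
    print(f"detected {len(catalog.records)} site records "
          f"across {len(catalog.sources)} sources; "
          f"{len(variants)} disease variants")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
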