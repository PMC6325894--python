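"""Integrate the simulated multi-source catalog onto non-redundant proteomes.

Reads the dataset written by 01_simulate.py, consolidates each species'
proteome, remaps every peptide-anchored record, merges the per-source
catalogs, and writes the merged catalog plus the cross-source overlap
table (the multi-source integration summary).
"""

from pathlib import Path

from phosite_evo import io as pio
from phosite_evo.integrate import (consolidate_proteome, merge_catalogs,
                                   overlap_table, remap_catalog)

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "dataset"


def main() -> None:
    catalog = pio.read_site_table(DATA / "catalog.tsv")
    parts = []
    for fasta in sorted(DATA.glob("proteome_*.fasta")):
        records = pio.read_proteome_fasta(fasta)
        nr = consolidate_proteome(records)
        sub = catalog.subset(species=nr.species)
        remapped, n_unmapped = remap_catalog(sub, nr)
        parts.append(remapped)
        print(f"{nr.species}: {len(nr)} non-redundant proteins, "
              f"{len(remapped)} site keys remapped, {n_unmapped} unmapped")
    merged = merge_catalogs(parts)
    pio.write_site_table(merged, DATA / "catalog_merged.tsv")
    table = overlap_table(merged.subset(species="mel"))
    table.to_csv(BASE / "overlap_table.tsv", sep="\t", index=False)
    print(f"\nmerged catalog: {len(merged)} keys, "
          f"{len(merged.sources)} sources")
    print("\nreference-species source overlap:")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
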