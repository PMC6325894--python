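"""End-to-end orchestration of the synthetic analysis pipeline.

Stages run in dependency order: simulate -> integrate -> map-sites ->
conserve -> propensity -> fnr -> evostats -> disease. Results are kept in
memory (:class:`PipelineResult`) and optionally written to an output
directory together with a manifest of checksums and per-stage record
counts. Deterministic stages reproduce identical checksums when re-run
with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import io as pio
from .alignment_sites import index_catalog, select_aligned_acceptor_sites
from .conservation import extract_window, score_site_conservation
from .constants import ACCEPTORS, DEFAULT_FLANK, acceptor_class
from .disease_proximity import proximity_by_identity
from .evostats import (match_control_acceptors, ortholog_conservation_comparison,
                       site_conservation_comparison, default_site_identity_rule)
from .fnr import estimate_fnr, select_benchmark_sites
from .integrate import (SiteCatalog, acceptor_positions, consolidate_proteome,
                        merge_catalogs, overlap_table, remap_catalog)
from .propensity import (assemble_training_sets, default_bank,
                         predict_propensity, train_propensity_model)
from .synthetic_data import (SimulationConfig, simulate_detection,
                             simulate_families, simulate_variants)


def _log(stage: str, message: str, level: str = "INFO") -> None:
    print(f"{stage}\t{level}\t{message}", file=sys.stderr)


@dataclass
class PipelineResult:
    config: SimulationConfig
    proteomes: dict = field(default_factory=dict)
    nr_proteomes: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)
    ortholog_map: dict = field(default_factory=dict)
    truth: object = None
    catalog: Optional[SiteCatalog] = None
    overlap: object = None
    aligned_sites: list = field(default_factory=list)
    conservation_results: list = field(default_factory=list)
    propensity_model: object = None
    fnr_estimates: list = field(default_factory=list)
    ortholog_comparisons: list = field(default_factory=list)
    site_comparisons: list = field(default_factory=list)
    proximity_results: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)

    def group_sequences(self) -> dict:
        """{group_id: {species: ungapped sequence}} for window extraction."""
        out = {}
        for gid, group in self.groups.items():
            out[gid] = {sp: group.ungapped((sp, pid))
                        for sp, pid in group.members}
        return out


def run_synthetic_pipeline(config: SimulationConfig,
                           train_propensity: bool = True) -> PipelineResult:
    """Run every stage on a freshly simulated dataset."""
    res = PipelineResult(config=config)
    ref = config.reference_species

    _log("simulate", f"seed={config.seed} n_groups={config.n_groups}")
    res.proteomes, res.groups, res.ortholog_map, res.truth = \
        simulate_families(config)
    raw_catalog = simulate_detection(res.truth, config, res.groups)
    res.variants = simulate_variants(res.truth, config)
    res.stage_counts["simulate"] = {
        "n_groups": len(res.groups),
        "n_true_sites": len(res.truth.all_sites()),
        "n_detected_records": len(raw_catalog.records),
        "n_variants": len(res.variants),
    }

    _log("integrate", "consolidating proteomes and remapping peptides")
    per_species_catalogs = []
    for sp in config.species:
        nr = consolidate_proteome(res.proteomes[sp])
        res.nr_proteomes[sp] = nr
        sub = raw_catalog.subset(species=sp)
        remapped, n_unmapped = remap_catalog(sub, nr)
        if n_unmapped:
            _log("integrate", f"{sp}: {n_unmapped} unmapped records", "WARN")
        per_species_catalogs.append(remapped)
    res.catalog = merge_catalogs(per_species_catalogs)
    res.overlap = overlap_table(res.catalog.subset(species=ref))
    res.stage_counts["integrate"] = {
        "n_keys": len(res.catalog),
        "n_sources": len(res.catalog.sources),
    }

    _log("map_sites", "projecting sites onto alignments")
    cat_index = index_catalog(res.catalog)
    for gid in sorted(res.groups):
        res.aligned_sites.extend(select_aligned_acceptor_sites(
            res.groups[gid], cat_index))
    res.stage_counts["map_sites"] = {"n_aligned_sites": len(res.aligned_sites)}

    _log("conserve", "window similarity scoring")
    seqs = res.group_sequences()
    for site in res.aligned_sites:
        pos = site.positions.get(ref)
        if pos is None or site.residues[ref] not in ACCEPTORS:
            continue
        res.conservation_results.append(score_site_conservation(
            res.groups[site.group_id], site, ref, seqs[site.group_id],
            flank=config.flank))
    n_cons = sum(1 for r in res.conservation_results if r.conserved)
    res.stage_counts["conserve"] = {
        "n_scored": len(res.conservation_results), "n_conserved": n_cons}

    if train_propensity:
        _log("propensity", f"training ST model for {ref}")
        bank = default_bank()
        pos_w, neg_w = assemble_training_sets(
            res.catalog, res.nr_proteomes[ref], "ST", seed=config.seed)
        res.propensity_model = train_propensity_model(
            pos_w, neg_w, bank, species=ref, seed=config.seed)
        # fill per-species propensities on aligned ST sites
        n_scored = 0
        for site in res.aligned_sites:
            for sp, pos in site.positions.items():
                if pos is None or site.observed[sp]:
                    if site.observed[sp]:
                        site.propensity[sp] = 1.0
                    continue
                residue = site.residues[sp]
                if residue not in ("S", "T"):
                    continue
                w = extract_window(seqs[site.group_id][sp], pos, config.flank)
                site.propensity[sp] = predict_propensity(
                    res.propensity_model, w, bank, observed=False)
                n_scored += 1
        res.stage_counts["propensity"] = {
            "n_train_pos": len(pos_w), "n_train_neg": len(neg_w),
            "n_predicted": n_scored}

    _log("fnr", "benchmark selection and per-species estimates")
    benchmarks = select_benchmark_sites(
        res.groups, res.aligned_sites, seqs, flank=config.flank)
    if benchmarks:
        for sp in config.species:
            res.fnr_estimates.append(estimate_fnr(benchmarks, sp))
    res.stage_counts["fnr"] = {"n_benchmark": len(benchmarks)}

    _log("evostats", "protein- and site-level conservation contrasts")
    phospho_proteins = {r.protein_id for r in res.catalog.subset(species=ref)}
    all_ref = set(res.nr_proteomes[ref].sequences)
    control_proteins = all_ref - phospho_proteins
    retained = {}
    for gid, members in res.ortholog_map.items():
        pid = f"{ref}_{gid}"
        retained[pid] = {sp for sp, _, score in members if score >= 3}
    if phospho_proteins and control_proteins:
        for sp in config.species:
            if sp == ref:
                continue
            res.ortholog_comparisons.append(ortholog_conservation_comparison(
                phospho_proteins, control_proteins, retained, sp))
    res.site_comparisons = _site_level_comparisons(res, seqs)
    res.stage_counts["evostats"] = {
        "n_protein_comparisons": len(res.ortholog_comparisons),
        "n_site_comparisons": len(res.site_comparisons)}

    _log("disease", "variant proximity by identity stratum")
    sites = proximity_site_table(res)
    if sites and res.variants:
        res.proximity_results = proximity_by_identity(
            sites, res.variants, distance=config.variant_distance)
    res.stage_counts["disease"] = {
        "n_sites": len(sites), "n_results": len(res.proximity_results)}
    return res


def _site_level_comparisons(res: PipelineResult, seqs: dict) -> list:
    """Phospho vs matched non-phospho acceptors: conserved-fraction contrast."""
    config = res.config
    ref = config.reference_species
    cat_index = index_catalog(res.catalog)
    phospho, phospho_residues = [], []
    for gid in sorted(res.groups):
        pid = f"{ref}_{gid}"
        recs = [r for r in cat_index.get((ref, pid), ()) if not r.ambiguous]
        seq = seqs[gid].get(ref)
        if seq is None:
            continue
        observed_pos = {r.position for r in recs}
        for pos in sorted(observed_pos):
            phospho.append((gid, pos))
            phospho_residues.append(seq[pos - 1])
    candidates = []
    for gid in sorted(res.groups):
        seq = seqs[gid].get(ref)
        if seq is None:
            continue
        pid = f"{ref}_{gid}"
        if not any(True for _ in cat_index.get((ref, pid), ())):
            continue  # controls come from identified phosphoproteins
        observed_pos = {r.position for r in cat_index.get((ref, pid), ())}
        for pos in acceptor_positions(seq):
            if pos not in observed_pos:
                candidates.append((gid, pos))
    if not phospho or not candidates:
        return []
    rng = np.random.default_rng([config.seed, 4])
    controls = match_control_acceptors(
        phospho_residues, candidates,
        lambda gp: seqs[gp[0]][ref][gp[1] - 1], rng)
    comparisons = []
    for sp in config.species:
        if sp == ref:
            continue

        def outcome(gid_pos):
            gid, pos = gid_pos
            group = res.groups[gid]
            sp_seq = seqs[gid].get(sp)
            if sp_seq is None:
                return False
            member = group.member_of(ref)
            col = group.position_to_column(member, pos)
            tgt_pos = group.column_to_position(group.member_of(sp), col)
            if tgt_pos is None:
                return False
            ref_w = extract_window(seqs[gid][ref], pos, config.flank)
            tgt_w = extract_window(sp_seq, tgt_pos, config.flank)
            from .conservation import window_identity
            ident = window_identity(ref_w, tgt_w)
            acceptor_ok = (sp_seq[tgt_pos - 1] in ACCEPTORS
                           and sp_seq[tgt_pos - 1] in
                           _class_letters(seqs[gid][ref][pos - 1]))
            return default_site_identity_rule(acceptor_ok, ident)

        comparisons.append(site_conservation_comparison(
            [outcome(s) for s in phospho],
            [outcome(s) for s in controls], sp))
    return comparisons


def _class_letters(residue: str) -> tuple:
    return ("S", "T") if residue in ("S", "T") else ("Y",)


def proximity_site_table(res: PipelineResult) -> list:
    """Site dicts for :func:`proximity_by_identity` from conservation results.

    Identity is the site's average similarity; a site counts as
    acceptor-conserved when at least half of its non-gap orthologs retain
    an acceptor of the same class.
    """
    ref = res.config.reference_species
    sites = []
    for r in res.conservation_results:
        if r.average_similarity is None:
            continue
        pos = r.site.positions[ref]
        classes = [c for c in r.acceptor_class.values() if c != "gap"]
        kept = sum(1 for c in classes
                   if c.startswith("identical_acceptor")
                   or c == "acceptor_class_changed")
        sites.append({
            "protein_id": f"{ref}_{r.site.group_id}",
            "position": pos,
            "identity": r.average_similarity,
            "acceptor_conserved": bool(classes) and kept * 2 >= len(classes),
        })
    return sites


def write_outputs(res: PipelineResult, outdir) -> dict:
    """Write all stage outputs as TSV/FASTA/JSON and return the manifest."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(exist_ok=True)
    config_path = outdir / "config.yaml"
    res.config.to_yaml(config_path)
    for sp in res.config.species:
        pio.write_proteome_fasta(res.proteomes[sp], outdir / f"proteome_{sp}.fasta")
    for gid, group in res.groups.items():
        pio.write_alignment_fasta(group.alignment,
                                  outdir / "alignments" / f"{gid}.afa")
    pio.write_ortholog_map(res.ortholog_map, outdir / "ortholog_map.tsv")
    pio.write_site_table(res.catalog, outdir / "catalog.tsv")
    res.overlap.to_csv(outdir / "overlap_table.tsv", sep="\t", index=False)
    pio.write_variant_table(
        [v for v in res.variants], outdir / "variants.tsv")

    rows = []
    for r in res.conservation_results:
        ref = res.config.reference_species
        row = {"group_id": r.site.group_id,
               "protein_id": f"{ref}_{r.site.group_id}",
               "position": r.site.positions[ref],
               "column": r.site.column,
               "average_similarity": None if r.average_similarity is None
               else round(r.average_similarity, 3),
               "conserved": r.conserved}
        for sp, v in sorted(r.per_ortholog.items()):
            row[f"similarity_{sp}"] = round(v, 3)
            row[f"acceptor_class_{sp}"] = r.acceptor_class[sp]
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "conservation.tsv", sep="\t", index=False)

    pd.DataFrame([dataclasses.asdict(e) for e in res.fnr_estimates]).to_csv(
        outdir / "fnr.tsv", sep="\t", index=False)
    comp_rows = []
    for kind, comps in (("protein", res.ortholog_comparisons),
                        ("site", res.site_comparisons)):
        for c in comps:
            comp_rows.append({
                "kind": kind, "target_species": c.target_species,
                "a": c.table.a, "b": c.table.b, "c": c.table.c, "d": c.table.d,
                "phospho_proportion": c.phospho_proportion,
                "control_proportion": c.control_proportion,
                "odds_ratio": c.odds_ratio, "p_value": c.p_value})
    pd.DataFrame(comp_rows).to_csv(outdir / "evostats.tsv", sep="\t", index=False)
    prox_rows = [{
        "identity_cutoff": p.identity_cutoff, "stratum": p.stratum,
        "n_sites": p.n_sites, "n_proximal": p.n_proximal,
        "fraction": p.fraction, "odds_ratio": p.odds_ratio,
        "p_value": p.p_value} for p in res.proximity_results]
    pd.DataFrame(prox_rows).to_csv(outdir / "disease_proximity.tsv",
                                   sep="\t", index=False)
    if res.propensity_model is not None:
        res.propensity_model.to_json(outdir / "propensity_model.json")

    manifest = {
        "tool_version": _version(),
        "config_sha256": _sha256(config_path),
        "stage_counts": res.stage_counts,
        "stage_order": list(res.stage_counts),
        "outputs": {},
    }
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_pipeline(config: SimulationConfig, outdir) -> dict:
    """Simulate, analyze, write outputs; returns the manifest.

    On stage failure, completed outputs are kept and an error manifest
    naming the failing stage is written.
    """
    outdir = Path(outdir)
    try:
        res = run_synthetic_pipeline(config)
    except Exception as exc:  # noqa: BLE001 — error manifest by contract
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump({"error": str(exc)}, fh, indent=1)
        raise
    return write_outputs(res, outdir)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _version() -> str:
    from . import __version__

    return __version__
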