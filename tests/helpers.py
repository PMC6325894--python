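from phosite_evo.integrate import PTMSiteRecord


def make_site(species="mel", protein_id="P1", position=2, residue="S",
              ptm_type="phospho", source="src_a", **kwargs):
    return PTMSiteRecord(species=species, protein_id=protein_id,
                         position=position, residue=residue,
                         ptm_type=ptm_type, source=source, **kwargs)
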