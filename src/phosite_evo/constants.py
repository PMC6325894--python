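"""Shared alphabet and coordinate conventions.

All protein positions in this package are 1-based and inclusive, matching
the UniProt/PhosphoSitePlus convention. Alignment columns are likewise
1-based. The residue letter ``X`` (unknown) never matches any letter,
including another ``X``, in identity computations.
"""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: residues chemically able to accept a phosphate in metazoans
ACCEPTORS = frozenset("STY")

GAP = "-"
UNKNOWN = "X"

#: default half-window: site plus five residues up- and downstream (11-mer)
DEFAULT_FLANK = 5


def acceptor_class(residue: str) -> str:
    """Return ``"ST"`` or ``"Y"`` for a phospho-acceptor residue.

    Serine and threonine are pooled into one class (their kinases largely
    overlap); tyrosine is scored separately.
    """
    if residue in ("S", "T"):
        return "ST"
    if residue == "Y":
        return "Y"
    raise ValueError(f"not a phospho-acceptor residue: {residue!r}")
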