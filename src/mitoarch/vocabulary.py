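"""Controlled vocabulary for the 37 genes of the animal mitochondrial genome.

Animal mtDNA carries 13 protein-coding genes (PCGs), 22 tRNAs and the two
ribosomal subunit genes.  All modules in this package address genes by the
canonical symbols defined here; :mod:`mitoarch.annotation_io` maps the many
spellings found in GenBank records (COX1, NAD2, rrnL, tRNA-Val, ...) onto
them through an editable synonym table.
"""

from __future__ import annotations

from importlib import resources

PCG_GENES: tuple[str, ...] = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COI", "COII", "COIII", "ATP6", "ATP8", "Cytb",
)

#: The 22 tRNA genes; Leu and Ser each occur twice and are disambiguated the
#: standard way: trnL1 = Leu(CUN), trnL2 = Leu(UUR), trnS1 = Ser(AGN),
#: trnS2 = Ser(UCN).
TRNA_GENES: tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNA_GENES: tuple[str, ...] = ("lrRNA", "srRNA")

ALL_GENES: tuple[str, ...] = PCG_GENES + TRNA_GENES + RRNA_GENES

GENE_CLASS: dict[str, str] = {
    **{g: "PCG" for g in PCG_GENES},
    **{g: "tRNA" for g in TRNA_GENES},
    **{g: "rRNA" for g in RRNA_GENES},
}

#: Translation table of the invertebrate mitochondrial genetic code
#: (ATA=Met, TGA=Trp, AGA/AGG=Ser).
INVERTEBRATE_MITO_CODE = 5


def gene_class(name: str) -> str:
    """Return ``PCG``, ``tRNA`` or ``rRNA`` for a canonical gene symbol."""
    try:
        return GENE_CLASS[name]
    except KeyError:
        raise ValueError(f"unknown gene symbol: {name!r}") from None


def load_synonym_table(path=None) -> dict[str, str]:
    """Load an alias -> canonical-symbol map.

    The default table ships with the package and covers the common GenBank
    spellings (COX1/NAD4L/rrnS/CYTB/...) and ``tRNA-Xxx`` product names.
    Lookup is case-insensitive on the alias.
    """
    if path is None:
        source = resources.files("mitoarch.data").joinpath("gene_synonyms.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")
        if canonical not in GENE_CLASS:
            raise ValueError(f"synonym table maps {alias!r} to unknown symbol {canonical!r}")
        table[alias.strip().casefold()] = canonical
    return table


def normalize_gene_name(raw: str, synonyms: dict[str, str] | None = None) -> str | None:
    """Map a raw feature name onto the 37-symbol vocabulary.

    Returns ``None`` when the name cannot be mapped (the caller decides
    whether that is a skip-with-warning or an error).
    """
    if synonyms is None:
        synonyms = load_synonym_table()
    cleaned = raw.strip().replace("_", "").replace(" ", "")
    if cleaned in GENE_CLASS:
        return cleaned
    key = cleaned.casefold()
    for symbol in ALL_GENES:
        if symbol.casefold() == key:
            return symbol
    return synonyms.get(key)
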