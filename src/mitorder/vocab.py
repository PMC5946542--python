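"""Closed vocabulary for vertebrate mitochondrial gene-order tokens.

The 37 canonical genes (22 tRNAs, 2 rRNAs, 13 protein-coding genes) plus the
control region (CR), the light-strand replication origin (OL) and anonymous
non-coding blocks (NC).  tRNAs use single-letter amino-acid codes; the two
leucine and serine isoacceptors are disambiguated as L1 = Leu(CUN),
L2 = Leu(UUR), S1 = Ser(AGY), S2 = Ser(UCN).  A trailing ``*`` marks a
pseudogene copy (e.g. ``P*`` for pseudo-tRNA-Pro).
"""

from __future__ import annotations

TRNAS = frozenset(
    "F V L1 L2 I Q M W A N C Y S1 S2 D K G R H E T P".split()
)
RRNAS = frozenset({"12S", "16S"})
PCGS = frozenset(
    "ND1 ND2 COX1 COX2 ATP8 ATP6 COX3 ND3 ND4L ND4 ND5 ND6 CYTB".split()
)
GENES = TRNAS | RRNAS | PCGS          # the 37 genes
SPECIAL = frozenset({"CR", "OL", "NC"})
VOCABULARY = GENES | SPECIAL

#: genes encoded on the light (minus) strand in the typical vertebrate order
L_STRAND = frozenset({"Q", "A", "N", "C", "Y", "S2", "E", "P", "ND6"})

CATEGORY_TRNA = "tRNA"
CATEGORY_RRNA = "rRNA"
CATEGORY_PCG = "PCG"
CATEGORY_CR = "CR"
CATEGORY_OL = "OL"
CATEGORY_NC = "NC"
CATEGORY_PSEUDO = "pseudo"

#: plausible default feature lengths (bp) used by the record generator.
#: Only diagnostic lengths matter downstream; the rest merely need to be
#: realistic for a ~17 kb squamate mitogenome.
DEFAULT_LENGTHS = {
    "12S": 950,
    "16S": 1550,
    "ND1": 960,
    "ND2": 1040,
    "COX1": 1545,
    "COX2": 690,
    "ATP8": 165,
    "ATP6": 680,
    "COX3": 785,
    "ND3": 345,
    "ND4L": 295,
    "ND4": 1375,
    "ND5": 1800,
    "ND6": 520,
    "CYTB": 1120,
    "CR": 1100,
    "OL": 35,
}
DEFAULT_TRNA_LENGTH = 70
DEFAULT_PSEUDO_LENGTH = 50


def base_symbol(name: str) -> str:
    """Strip a pseudogene star: ``P*`` -> ``P``."""
    return name[:-1] if name.endswith("*") else name


def is_pseudo_name(name: str) -> bool:
    return name.endswith("*")


def category_of(name: str) -> str:
    """Category implied by a (possibly pseudo) token name.

    Raises ``ValueError`` for names outside the vocabulary.
    """
    if is_pseudo_name(name):
        base = base_symbol(name)
        if base not in GENES:
            raise ValueError(f"unknown pseudogene base symbol: {name!r}")
        return CATEGORY_PSEUDO
    if name in TRNAS:
        return CATEGORY_TRNA
    if name in RRNAS:
        return CATEGORY_RRNA
    if name in PCGS:
        return CATEGORY_PCG
    if name in SPECIAL:
        return name
    raise ValueError(f"unknown gene-order token name: {name!r}")


def default_strand(name: str) -> int:
    return -1 if base_symbol(name) in L_STRAND else 1


def default_length(name: str) -> int | None:
    base = base_symbol(name)
    if is_pseudo_name(name):
        return DEFAULT_PSEUDO_LENGTH
    if base in TRNAS:
        return DEFAULT_TRNA_LENGTH
    return DEFAULT_LENGTHS.get(base)


# --- GenBank qualifier synonym table -------------------------------------

_AA3 = {
    "Phe": "F", "Val": "V", "Ile": "I", "Gln": "Q", "Met": "M", "Trp": "W",
    "Ala": "A", "Asn": "N", "Cys": "C", "Tyr": "Y", "Asp": "D", "Lys": "K",
    "Gly": "G", "Arg": "R", "His": "H", "Glu": "E", "Thr": "T", "Pro": "P",
}

#: maps a normalised gene/product qualifier to a token name; the sentinel
#: values "L?"/"S?" mark leucine/serine tRNAs whose isoacceptor must be
#: inferred from position when the anticodon is not annotated.
SYNONYMS: dict[str, str] = {}
for _aa3, _code in _AA3.items():
    SYNONYMS[f"trna-{_aa3.lower()}"] = _code
    SYNONYMS[f"trn{_code.lower()}"] = _code
SYNONYMS.update({
    "trna-leu": "L?",
    "trna-ser": "S?",
    "trnl": "L?",
    "trns": "S?",
    "trna-leu(uur)": "L2",
    "trna-leu(cun)": "L1",
    "trna-ser(ucn)": "S2",
    "trna-ser(agy)": "S1",
    "trna-ser(agc)": "S1",
    "trnl1": "L1",
    "trnl2": "L2",
    "trns1": "S1",
    "trns2": "S2",
    # rRNAs
    "12s ribosomal rna": "12S",
    "12s rrna": "12S",
    "s-rrna": "12S",
    "small subunit ribosomal rna": "12S",
    "rrn12": "12S",
    "rrns": "12S",
    "16s ribosomal rna": "16S",
    "16s rrna": "16S",
    "l-rrna": "16S",
    "large subunit ribosomal rna": "16S",
    "rrn16": "16S",
    "rrnl": "16S",
    # protein-coding genes
    "nd1": "ND1", "nad1": "ND1", "nadh dehydrogenase subunit 1": "ND1",
    "nd2": "ND2", "nad2": "ND2", "nadh dehydrogenase subunit 2": "ND2",
    "nd3": "ND3", "nad3": "ND3", "nadh dehydrogenase subunit 3": "ND3",
    "nd4": "ND4", "nad4": "ND4", "nadh dehydrogenase subunit 4": "ND4",
    "nd4l": "ND4L", "nad4l": "ND4L",
    "nadh dehydrogenase subunit 4l": "ND4L",
    "nd5": "ND5", "nad5": "ND5", "nadh dehydrogenase subunit 5": "ND5",
    "nd6": "ND6", "nad6": "ND6", "nadh dehydrogenase subunit 6": "ND6",
    "cox1": "COX1", "coi": "COX1", "co1": "COX1",
    "cytochrome c oxidase subunit i": "COX1",
    "cytochrome c oxidase subunit 1": "COX1",
    "cox2": "COX2", "coii": "COX2", "co2": "COX2",
    "cytochrome c oxidase subunit ii": "COX2",
    "cytochrome c oxidase subunit 2": "COX2",
    "cox3": "COX3", "coiii": "COX3", "co3": "COX3",
    "cytochrome c oxidase subunit iii": "COX3",
    "cytochrome c oxidase subunit 3": "COX3",
    "atp6": "ATP6", "atpase6": "ATP6", "atpase 6": "ATP6",
    "atp synthase f0 subunit 6": "ATP6",
    "atp8": "ATP8", "atpase8": "ATP8", "atpase 8": "ATP8",
    "atp synthase f0 subunit 8": "ATP8",
    "cytb": "CYTB", "cob": "CYTB", "cytochrome b": "CYTB",
    # non-gene elements
    "d-loop": "CR", "control region": "CR", "cr": "CR",
    "putative control region": "CR",
    "ol": "OL", "origin of l-strand replication": "OL",
    "l-strand origin of replication": "OL",
    "light strand replication origin": "OL",
})


def normalise_qualifier(text: str) -> str:
    """Normalise a GenBank gene/product qualifier for synonym lookup."""
    t = text.strip().lower()
    t = t.replace(" (", "(").replace(") ", ")")
    return t


def lookup_symbol(text: str) -> str | None:
    """Resolve a qualifier to a token name, or None if unknown.

    Returns the sentinels ``L?``/``S?`` for anticodon-less Leu/Ser tRNAs.
    """
    return SYNONYMS.get(normalise_qualifier(text))
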