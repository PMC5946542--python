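"""Synthetic annotated mitogenome generator and single-event perturbation.

``generate_record`` realizes any registry arrangement type as a fully
annotated record: the token sequence is the type's reference order, gene
lengths come from a documented table of typical vertebrate sizes (with a
small seed-deterministic jitter on gene lengths; control-region and
non-coding diagnostic lengths are never jittered), and the record can be
emitted as a GenBank flat file.  ``perturb`` applies exactly one
rearrangement event to a record, which makes it the driver for
closure-property tests of the event-path inference.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
import io as _stdio

from . import vocab
from .classify import TypeRegistry, builtin_registry
from .model import (
    CR_ASYMMETRY,
    DUPLICATION,
    EventAnnotation,
    GeneOrder,
    GeneToken,
    INSERTION,
    LOSS,
    MitogenomeRecord,
    PSEUDOGENIZATION,
    TRANSLOCATION,
)

_AA1TO3 = {
    "F": "Phe", "V": "Val", "I": "Ile", "Q": "Gln", "M": "Met", "W": "Trp",
    "A": "Ala", "N": "Asn", "C": "Cys", "Y": "Tyr", "D": "Asp", "K": "Lys",
    "G": "Gly", "R": "Arg", "H": "His", "E": "Glu", "T": "Thr", "P": "Pro",
    "L1": "Leu(CUN)", "L2": "Leu(UUR)", "S1": "Ser(AGY)", "S2": "Ser(UCN)",
}


def trna_product(symbol: str) -> str:
    aa = _AA1TO3[symbol]
    return f"tRNA-{aa}"


@dataclass
class GenerationParams:
    """Parameters of one synthetic record."""

    type_label: str
    seed: int = 0
    length_overrides: dict[str, int] = field(default_factory=dict)
    emit_sequence: bool = False
    jitter: bool = True


def _jittered_length(tok: GeneToken, rng: random.Random) -> int | None:
    if tok.length_bp is None:
        return None
    if tok.category == vocab.CATEGORY_TRNA:
        return tok.length_bp + rng.randint(-4, 4)
    if tok.category == vocab.CATEGORY_RRNA:
        return tok.length_bp + rng.randint(-20, 20)
    if tok.category == vocab.CATEGORY_PCG:
        return tok.length_bp + rng.randint(-15, 15)
    # CR, OL, NC and pseudogene lengths stay exactly as specified: some
    # are diagnostic (asymmetry ratios, insertion sizes)
    return tok.length_bp


def generate_record(params: GenerationParams,
                    registry: TypeRegistry | None = None,
                    taxon_id: str | None = None,
                    species: str = "synthetic",
                    family: str = "synthetic") -> MitogenomeRecord:
    """Instantiate a registry arrangement type as an annotated record.

    Same parameters (including seed) produce byte-identical output.
    Length overrides are keyed by token name; the positional aliases
    ``CR1``/``CR2`` address the last/first control region of the
    F-anchored order (ancestral copy and IQM-cluster copy respectively).
    """
    if registry is None:
        registry = builtin_registry()
    try:
        atype = registry.get(params.type_label)
    except KeyError:
        raise ValueError(
            f"unknown arrangement type label {params.type_label!r}"
        ) from None
    rng = random.Random(("generate", params.type_label, params.seed)
                        .__repr__())
    tokens: list[GeneToken] = []
    cr_positions = [i for i, t in enumerate(atype.reference_order)
                    if t.category == vocab.CATEGORY_CR]
    for i, tok in enumerate(atype.reference_order):
        length = _jittered_length(tok, rng) if params.jitter \
            else tok.length_bp
        if tok.name in params.length_overrides:
            length = params.length_overrides[tok.name]
        if tok.category == vocab.CATEGORY_CR and cr_positions:
            # CR2 = first CR in the anchored reference, CR1 = last
            alias = "CR2" if i == cr_positions[0] else "CR1"
            if len(cr_positions) == 1:
                alias = "CR1"
            if alias in params.length_overrides:
                length = params.length_overrides[alias]
        tokens.append(replace(tok, length_bp=length))
    order = GeneOrder(tuple(tokens))
    return MitogenomeRecord(
        taxon_id=taxon_id or f"synthetic_{params.type_label}_{params.seed}",
        species=species,
        family=family,
        order=order,
        genome_length_bp=sum(t.length_bp or 0 for t in tokens),
        source="generated",
    )


def _feature_for(tok: GeneToken, start: int, end: int) -> SeqFeature:
    loc = FeatureLocation(start, end, strand=tok.strand)
    q: dict[str, list[str]] = {}
    if tok.category == vocab.CATEGORY_TRNA:
        ftype = "tRNA"
        q["gene"] = [f"trn{tok.name}"]
        q["product"] = [trna_product(tok.name)]
    elif tok.category == vocab.CATEGORY_RRNA:
        ftype = "rRNA"
        q["product"] = [f"{tok.name} ribosomal RNA"]
    elif tok.category == vocab.CATEGORY_PCG:
        ftype = "CDS"
        q["gene"] = [tok.name]
    elif tok.category == vocab.CATEGORY_CR:
        ftype = "D-loop"
        q["note"] = ["control region"]
    elif tok.category == vocab.CATEGORY_OL:
        ftype = "rep_origin"
        q["note"] = ["origin of L-strand replication"]
    elif tok.category == vocab.CATEGORY_NC:
        ftype = "misc_feature"
        q["note"] = ["non-coding region"]
    else:  # pseudogene
        base = vocab.base_symbol(tok.name)
        ftype = "misc_feature"
        q["gene"] = [f"trn{base}" if base in vocab.TRNAS else base]
        q["note"] = [f"pseudogene copy of {base}"]
    return SeqFeature(loc, type=ftype, qualifiers=q)


def record_to_genbank(record: MitogenomeRecord, seed: int = 0,
                      emit_sequence: bool = False) -> str:
    """Serialize a record as a GenBank flat file (circular mtDNA)."""
    total = sum(t.length_bp or 0 for t in record.order)
    if emit_sequence:
        rng = random.Random(("sequence", record.taxon_id, seed).__repr__())
        seq = "".join(rng.choice("ACGT") for _ in range(total))
    else:
        seq = "N" * total
    locus = record.taxon_id[:16].replace(" ", "_")
    sr = SeqRecord(
        Seq(seq),
        id=locus,
        name=locus,
        description=f"{record.species} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": record.species,
            "taxonomy": ["Squamata", "Serpentes", record.family],
        },
    )
    pos = 0
    for tok in record.order:
        end = pos + (tok.length_bp or 0)
        sr.features.append(_feature_for(tok, pos, end))
        pos = end
    out = _stdio.StringIO()
    SeqIO.write(sr, out, "genbank")
    return out.getvalue()


# --- single-event perturbation --------------------------------------------


def _find_occurrence(order: GeneOrder, name: str,
                     context: tuple[str, str] | None) -> int:
    idx = order.indices_of(name)
    if not idx:
        raise ValueError(f"perturb: subject {name!r} absent from order")
    if context is not None:
        for i in idx:
            left, right = order.neighbors(i)
            if (left.name, right.name) == tuple(context):
                return i
    return idx[0]


def _find_boundary(tokens: list[GeneToken], context: tuple[str, str]) -> int:
    """Index at which to insert so the new token sits between the named
    (5', 3') pair."""
    n = len(tokens)
    for i in range(n):
        if tokens[i].name == context[0] \
                and tokens[(i + 1) % n].name == context[1]:
            return (i + 1) % n
    raise ValueError(f"perturb: target context {context} not adjacent")


def perturb(record: MitogenomeRecord, event: EventAnnotation,
            seed: int = 0) -> MitogenomeRecord:
    """Apply exactly one rearrangement event to a record.

    Raises ``ValueError`` when the event is inapplicable (subject absent
    for losses/translocations, target context not adjacent for
    insertions/duplications).
    """
    rng = random.Random(("perturb", record.taxon_id, seed).__repr__())
    tokens = list(record.order.tokens)
    kind = event.kind
    if kind == LOSS:
        i = _find_occurrence(record.order, event.subject,
                             event.from_context)
        del tokens[i]
    elif kind == TRANSLOCATION:
        i = _find_occurrence(record.order, event.subject,
                             event.from_context)
        moved = tokens.pop(i)
        j = _find_boundary(tokens, event.to_context)
        tokens.insert(j, moved)
    elif kind == DUPLICATION:
        i = _find_occurrence(record.order, event.subject, None)
        j = _find_boundary(tokens, event.to_context)
        tokens.insert(j, tokens[i])
    elif kind == PSEUDOGENIZATION:
        name = event.subject if event.subject.endswith("*") \
            else event.subject + "*"
        tok = GeneToken(name, vocab.CATEGORY_PSEUDO,
                        vocab.default_strand(name),
                        vocab.DEFAULT_PSEUDO_LENGTH)
        j = _find_boundary(tokens, event.to_context)
        tokens.insert(j, tok)
    elif kind == INSERTION:
        length = event.length_bp or rng.randint(100, 6000)
        if event.subject == "NC":
            tok = GeneToken("NC", vocab.CATEGORY_NC, 1, length)
        else:
            tok = GeneToken(event.subject,
                            vocab.category_of(event.subject),
                            vocab.default_strand(event.subject),
                            vocab.default_length(event.subject))
        j = _find_boundary(tokens, event.to_context)
        tokens.insert(j, tok)
    elif kind == CR_ASYMMETRY:
        cr_idx = [i for i, t in enumerate(tokens)
                  if t.category == vocab.CATEGORY_CR
                  and t.length_bp is not None]
        if len(cr_idx) < 2:
            raise ValueError("perturb: CR asymmetry needs two measured CRs")
        lengths = [tokens[i].length_bp for i in cr_idx]
        target = cr_idx[lengths.index(max(lengths))]
        tokens[target] = replace(tokens[target],
                                 length_bp=2 * min(lengths))
    else:
        raise ValueError(f"perturb: unsupported event kind {kind!r}")
    rec = record.with_order(GeneOrder(tuple(tokens)))
    rec.genome_length_bp = sum(t.length_bp or 0 for t in rec.order)
    return rec


def random_event(order: GeneOrder, rng: random.Random) -> EventAnnotation:
    """Draw one recoverable rearrangement event applicable to ``order``.

    The draw is restricted to events whose path inference is unambiguous:
    insertions never land next to an existing copy of the same token,
    translocations move a single-copy gene to a boundary disjoint from its
    old neighbourhood, and anchors (tRNA-Phe, 12S) never move.
    """
    names = [t.name for t in order.tokens]
    n = len(names)
    counts = {x: names.count(x) for x in names}

    def boundaries(exclude: set[str]) -> list[tuple[str, str]]:
        out = []
        for i in range(n):
            a, b = names[i], names[(i + 1) % n]
            if a in exclude or b in exclude or a == b:
                continue
            out.append((a, b))
        return out

    single = [x for x in counts
              if counts[x] == 1 and x not in ("F", "12S", "NC")]
    for _ in range(200):
        kind = rng.choice(
            (LOSS, TRANSLOCATION, DUPLICATION, PSEUDOGENIZATION, INSERTION)
        )
        if kind == LOSS and single:
            g = rng.choice(sorted(single))
            i = order.indices_of(g)[0]
            left, right = order.neighbors(i)
            if left.name == right.name:
                continue
            return EventAnnotation(LOSS, g,
                                   from_context=(left.name, right.name))
        if kind == TRANSLOCATION and single:
            g = rng.choice(sorted(single))
            i = order.indices_of(g)[0]
            left, right = order.neighbors(i)
            cands = [bd for bd in boundaries({g, "NC"})
                     if not {*bd} & {left.name, right.name}]
            if not cands or left.name == right.name:
                continue
            to = rng.choice(cands)
            return EventAnnotation(TRANSLOCATION, g,
                                   from_context=(left.name, right.name),
                                   to_context=to)
        if kind == DUPLICATION and single:
            dup_ok = [x for x in single if not x.endswith("*")]
            if not dup_ok:
                continue
            g = rng.choice(sorted(dup_ok))
            cands = [bd for bd in boundaries({g, "NC"})]
            i = order.indices_of(g)[0]
            left, right = order.neighbors(i)
            cands = [bd for bd in cands if bd != (left.name, right.name)]
            if not cands:
                continue
            return EventAnnotation(DUPLICATION, g,
                                   to_context=rng.choice(cands))
        if kind == PSEUDOGENIZATION:
            free = sorted(
                t for t in vocab.TRNAS
                if f"{t}*" not in counts
            )
            cands = boundaries({"NC"})
            if not free or not cands:
                continue
            return EventAnnotation(PSEUDOGENIZATION,
                                   rng.choice(free) + "*",
                                   to_context=rng.choice(cands))
        if kind == INSERTION:
            cands = boundaries({"NC"})
            if not cands:
                continue
            return EventAnnotation(INSERTION, "NC",
                                   to_context=rng.choice(cands),
                                   length_bp=rng.randint(100, 6000))
    raise RuntimeError("no applicable random event found")


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed derived from arbitrary string parts."""
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF
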