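"""I/O: GenBank feature tables, the gene-order TSV dialect, and newick trees.

GenBank records are read with Biopython; only the feature table is
consumed — no de-novo annotation is performed.  Coordinates are kept
0-based half-open internally (Biopython's convention); the flat file's
1-based inclusive spans are converted at the boundary.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from pathlib import Path

import dendropy
from Bio import SeqIO

from . import vocab
from .model import (
    GeneOrder,
    GeneToken,
    MitogenomeRecord,
    order_from_string,
    order_to_string,
)

logger = logging.getLogger(__name__)

#: unannotated stretches at least this long become NC tokens; shorter
#: intergenic spacers are ignored (typical spacers are <30 bp, the smallest
#: diagnostic insertion scored here is 342 bp).
NC_THRESHOLD_BP = 50

_FEATURE_KEYS = ("tRNA", "rRNA", "CDS", "D-loop", "rep_origin", "misc_feature")


def _resolve_leu_ser(symbol: str, prev_name: str | None,
                     next_name: str | None) -> str:
    """Positional disambiguation for anticodon-less Leu/Ser tRNAs.

    Leu(CUN) sits in the H-strand run Ser(AGY)-Leu(CUN)-ND5 of the typical
    order, so a Leu neighbouring ND5/S1/H is called L1, anything else L2.
    Ser(UCN) immediately follows COX1; a Ser elsewhere is S1.
    """
    near = {prev_name, next_name}
    if symbol == "L?":
        out = "L1" if near & {"ND5", "S1", "H"} else "L2"
    else:
        out = "S2" if near & {"COX1"} else "S1"
    logger.info("anticodon absent: assigned %s by position (flanks %s/%s)",
                out, prev_name, next_name)
    return out


def parse_genbank_features(text: str,
                           nc_threshold_bp: int = NC_THRESHOLD_BP,
                           ) -> MitogenomeRecord:
    """Parse one GenBank flat file into a mitogenome record.

    Features are emitted in ascending start-coordinate order; gene/product
    qualifiers are mapped to the standard vocabulary through the synonym
    table in :mod:`mitorder.vocab`.  Unannotated gaps of at least
    ``nc_threshold_bp`` (including the circular wrap-around gap) become NC
    tokens.  Unknown gene names are a hard error naming the qualifier.
    """
    seqrec = SeqIO.read(_io.StringIO(text), "genbank")
    genome_len = len(seqrec.seq)

    feats = [f for f in seqrec.features if f.type in _FEATURE_KEYS]
    if not feats:
        raise ValueError(f"record {seqrec.id}: no usable features")
    feats.sort(key=lambda f: int(f.location.start))

    raw: list[tuple[str, int, int, int, bool]] = []  # name,start,end,strand
    prev_end = None
    for f in feats:
        start, end = int(f.location.start), int(f.location.end)
        strand = -1 if f.location.strand == -1 else 1
        quals = f.qualifiers
        note = " ".join(quals.get("note", [])).lower()
        pseudo = "pseudo" in quals or "pseudo" in note
        if f.type == "D-loop":
            name = "CR"
        elif f.type == "rep_origin":
            name = "OL"
        elif f.type == "misc_feature" and not pseudo:
            candidates = quals.get("gene", []) + quals.get("product", [])
            sym = next((vocab.lookup_symbol(c) for c in candidates
                        if vocab.lookup_symbol(c)), None)
            if sym is None:
                if end - start >= nc_threshold_bp:
                    raw.append(("NC", start, end, 1, False))
                continue
            name = sym
        else:
            candidates = quals.get("gene", []) + quals.get("product", [])
            name = None
            for cand in candidates:
                sym = vocab.lookup_symbol(cand)
                if sym is not None:
                    name = sym
                    break
            if name is None:
                offender = candidates[0] if candidates else f.type
                raise ValueError(
                    f"record {seqrec.id}: unknown gene name {offender!r} "
                    f"after synonym mapping"
                )
        if prev_end is not None and start < prev_end:
            logger.info("record %s: overlapping features at %d..%d",
                        seqrec.id, start, end)
        prev_end = max(prev_end or 0, end)
        raw.append((name, start, end, strand, pseudo))

    # insert NC tokens for unannotated gaps, including the wrap-around gap
    entries: list[tuple[str, int, int | None]] = []  # name, strand, length
    for i, (name, start, end, strand, pseudo) in enumerate(raw):
        if i > 0:
            gap = start - raw[i - 1][2]
            if gap >= nc_threshold_bp:
                entries.append(("NC", 1, gap))
        if pseudo and not name.endswith("*"):
            name = name + "*"
        entries.append((name, strand, end - start))
    wrap_gap = genome_len - raw[-1][2] + raw[0][1]
    if wrap_gap >= nc_threshold_bp:
        entries.append(("NC", 1, wrap_gap))

    # second pass: positional Leu/Ser isoacceptor assignment
    n = len(entries)
    resolved: list[GeneToken] = []
    for i, (name, strand, length) in enumerate(entries):
        if name in ("L?", "S?"):
            name = _resolve_leu_ser(
                name, entries[(i - 1) % n][0], entries[(i + 1) % n][0]
            )
        resolved.append(
            GeneToken(name, vocab.category_of(name), strand, length)
        )

    organism = seqrec.annotations.get("organism", seqrec.id)
    return MitogenomeRecord(
        taxon_id=seqrec.id,
        species=organism,
        family=seqrec.annotations.get("taxonomy", ["unknown"])[-1]
        if seqrec.annotations.get("taxonomy") else "unknown",
        order=GeneOrder(tuple(resolved)),
        genome_length_bp=genome_len,
        source="parsed",
    )


_TSV_COLUMNS = ["taxon_id", "species", "family", "order"]


def read_gene_order_tsv(path: str | Path) -> list[MitogenomeRecord]:
    """Read records from the gene-order TSV dialect.

    Columns: taxon_id, species, family, order — the last holding a
    comma-separated token string (``-`` prefix = L-strand, ``:len`` suffix =
    length in bp).  Malformed tokens and duplicate taxon_ids are errors.
    """
    records: list[MitogenomeRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")),
            delimiter="\t",
        )
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            tid = row["taxon_id"].strip()
            if tid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate taxon_id {tid!r}")
            seen.add(tid)
            try:
                order = order_from_string(row["order"])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(MitogenomeRecord(
                taxon_id=tid,
                species=row["species"].strip(),
                family=row["family"].strip(),
                order=order,
                source="parsed",
            ))
    return records


def write_gene_order_tsv(records: list[MitogenomeRecord],
                         path: str | Path) -> None:
    """Write records losslessly (names, strands, lengths round-trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.taxon_id, rec.species, rec.family,
                order_to_string(rec.order, with_lengths=True),
            ])


class PhyloTree:
    """Rooted phylogeny (possibly multifurcating) with unique tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("tree tip labels are not unique")
        self.tip_labels = set(labels)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(
                f"newick parse error (tip labels must be unique): {exc}"
            ) from exc
        tree.is_rooted = True
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def n_tips(self) -> int:
        return len(self.tip_labels)

    def validate_charmap(self, charmap: dict[str, str]) -> None:
        unknown = set(charmap) - self.tip_labels
        if unknown:
            raise ValueError(
                f"character map keys not on the tree: {sorted(unknown)}"
            )
        missing = self.tip_labels - set(charmap)
        if missing:
            raise ValueError(f"tips without a state: {sorted(missing)}")
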