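"""The bundled 65-taxon study panel: records, tree and prior registry.

The panel is a synthetic stand-in (see ``data/synthetic_fixture_taxa.tsv``)
for a real 65-species, 14-family snake mitogenome compilation: each taxon
row names an arrangement type, and ``build_fixture_set`` instantiates a
fully annotated record for it with the synthetic generator, so every
downstream count is recomputed from actual gene orders rather than read
off the table.  Integrity checks verify the panel shape (65 records, 14
families, tree/record agreement) and that classification of the generated
orders reproduces the tabulated labels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .classify import THE_ELEVEN, TypeRegistry, builtin_registry, \
    classify_record, prior_registry
from .io import PhyloTree
from .model import MitogenomeRecord
from .simulate import GenerationParams, generate_record, stable_seed


@dataclass
class FixtureSet:
    """Records + tree + tip states + the prior six-arrangement registry."""

    records: list[MitogenomeRecord]
    tree: PhyloTree
    tip_types: dict[str, str]
    registry: TypeRegistry
    prior: TypeRegistry

    def record(self, taxon_id: str) -> MitogenomeRecord:
        for r in self.records:
            if r.taxon_id == taxon_id:
                return r
        raise KeyError(taxon_id)

    def families(self) -> set[str]:
        return {r.family for r in self.records}


class FixtureIntegrityError(ValueError):
    pass


def _load_taxa() -> list[dict]:
    text = resources.files("mitorder.data").joinpath(
        "synthetic_fixture_taxa.tsv").read_text()
    lines = [ln for ln in text.splitlines()
             if ln and not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def build_fixture_set(seed: int = 0,
                      registry: TypeRegistry | None = None) -> FixtureSet:
    """Load the bundled panel, generating one annotated record per taxon.

    ``seed`` feeds the per-record length jitter (derived per taxon, so the
    panel is order-independent and reproducible); it never changes any
    token sequence.  Raises :class:`FixtureIntegrityError` on any shape or
    classification violation.
    """
    if registry is None:
        registry = builtin_registry()
    rows = _load_taxa()
    records: list[MitogenomeRecord] = []
    tip_types: dict[str, str] = {}
    for row in rows:
        label = row["type_label"]
        rec = generate_record(
            GenerationParams(
                type_label=label,
                seed=stable_seed(seed, row["taxon_id"]),
            ),
            registry=registry,
            taxon_id=row["taxon_id"],
            species=row["species"],
            family=row["family"],
        )
        rec.source = "fixture"
        records.append(rec)
        tip_types[row["taxon_id"]] = label

    tree_text = resources.files("mitorder.data").joinpath(
        "synthetic_fixture_tree.nwk").read_text()
    tree = PhyloTree.from_newick(tree_text)

    fixture = FixtureSet(
        records=records,
        tree=tree,
        tip_types=tip_types,
        registry=registry,
        prior=prior_registry(),
    )
    validate_fixture(fixture)
    return fixture


def validate_fixture(fixture: FixtureSet) -> None:
    records = fixture.records
    ids = [r.taxon_id for r in records]
    if len(ids) != len(set(ids)):
        raise FixtureIntegrityError("duplicate taxon_id in panel")
    if len(records) != 65:
        raise FixtureIntegrityError(
            f"panel must hold 65 records, found {len(records)}"
        )
    if len(fixture.families()) != 14:
        raise FixtureIntegrityError(
            f"panel must span 14 families, found {len(fixture.families())}"
        )
    if fixture.tree.tip_labels != set(ids):
        raise FixtureIntegrityError(
            "tree tip set differs from panel taxon_id set"
        )
    bad = set(fixture.tip_types.values()) - set(THE_ELEVEN)
    if bad:
        raise FixtureIntegrityError(f"unknown tip type labels: {bad}")
    for rec in records:
        got = classify_record(rec, fixture.registry)
        want = fixture.tip_types[rec.taxon_id]
        if got != want:
            raise FixtureIntegrityError(
                f"{rec.taxon_id}: generated order classifies as {got}, "
                f"panel says {want}"
            )
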