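"""Headline comparative counts recomputed end-to-end from the panel."""

from __future__ import annotations

from .classify import classify_record, novel_types, type_census
from .features import cr_flank_type_count, detect_ol, detect_pseudogenes
from .fixtures import FixtureSet
from .parsimony import DELTRAN, count_losses, count_origins


def binary_charmap(fixture: FixtureSet, predicate) -> dict[str, str]:
    """present/absent tip states from a per-record predicate."""
    return {
        r.taxon_id: "present" if predicate(r) else "absent"
        for r in fixture.records
    }


def pstar_present(record) -> bool:
    return any(sym == "P*" for sym, _ in detect_pseudogenes(record.order))


def ol_present(record) -> bool:
    present, _ = detect_ol(record.order)
    return present


def headline_counts(fixture: FixtureSet, mode: str = DELTRAN) -> dict:
    """Recompute every headline count of the comparative analysis.

    Each entry carries the value and the module that produced it.  All
    quantities are derived from the generated gene orders and the tree —
    none is read off the taxon table.
    """
    census, distinct = type_census(fixture.records, fixture.registry)
    labels = {
        r.taxon_id: classify_record(r, fixture.registry)
        for r in fixture.records
    }

    iii_c_map = {
        tid: "present" if lab == "III-C" else "absent"
        for tid, lab in labels.items()
    }
    pstar_map = binary_charmap(fixture, pstar_present)
    ol_map = binary_charmap(fixture, ol_present)

    return {
        "distinct_types": {
            "value": distinct, "module": "classify",
        },
        "species": {
            "value": int(census.sum()), "module": "classify",
        },
        "families": {
            "value": len(fixture.families()), "module": "synthetic_data",
        },
        "iii_c_origins": {
            "value": count_origins(fixture.tree, iii_c_map, "present",
                                   mode=mode),
            "module": "events_tree",
        },
        "pstar_origins": {
            "value": count_origins(fixture.tree, pstar_map, "present",
                                   mode=mode),
            "module": "events_tree",
        },
        "ol_losses": {
            # lizard outgroups carry a functional OL: the ancestral state
            # enters as a virtual root neighbour
            "value": count_losses(fixture.tree, ol_map, "present",
                                  outgroup_state="present", mode=mode),
            "module": "events_tree",
        },
        "cr_flank_types": {
            "value": cr_flank_type_count(fixture.registry),
            "module": "feature_detect",
        },
        "new_vs_prior": {
            "value": len(novel_types(fixture.registry, fixture.prior)),
            "module": "classify",
        },
        "census": {
            "value": {str(k): int(v) for k, v in census.items()},
            "module": "classify",
        },
    }
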