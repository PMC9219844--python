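"""EC-set derivation, overlap, reaction expansion, and iPath export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from duomics.integrate import (
    MappingTables,
    ecs_from_degs,
    ecs_from_metabolites,
    export_ipath,
    is_partial_ec,
    is_valid_ec,
    overlap_ecs,
    reactions_for_ecs,
)


@pytest.mark.parametrize(
    "ec, valid",
    [
        ("1.3.1.24", True),
        ("1.3.1.-", True),
        ("1.3.1.243", True),  # syntactically fine even if not a curated code
        ("1.3.1", False),
        ("a.b.c.d", False),
        ("1.3.1.24.5", False),
    ],
)
def test_ec_pattern(ec, valid):
    assert is_valid_ec(ec) is valid


def _toy_maps():
    return MappingTables(
        transcript_pfam={"g1": {"p1"}, "g2": {"p2"}, "g3": set()},
        pfam_ec={
            "p1": {("1.1.1.1", "gold"), ("2.2.2.2", "gold")},
            "p2": {("3.3.3.3", "silver")},
        },
        compound_ec={"68-94-0": {"1.17.1.4"}, "cmpB": {"2.2.2.2"}},
        ec_reaction={
            "1.1.1.1": {"r1", "r2"},
            "2.2.2.2": {"r2", "r3"},
            "1.17.1.4": {"r4"},
        },
        reaction_pathway={"r1": {"pwA"}, "r2": {"pwA"}, "r3": {"pwB"}, "r4": {"pwB"}},
    )


def _degs(rows):
    return pd.DataFrame(rows, columns=["gene", "q_value"])


def test_ecs_from_degs_gold_lookup():
    maps = _toy_maps()
    degs = _degs([("g1", 0.001), ("g3", 0.001), ("gX", 0.9)])
    assert ecs_from_degs(degs, maps) == {"1.1.1.1", "2.2.2.2"}


def test_ecs_from_degs_tier_filter():
    maps = _toy_maps()
    degs = _degs([("g2", 0.001)])
    assert ecs_from_degs(degs, maps, tier="gold") == set()
    assert ecs_from_degs(degs, maps, tier="silver") == {"3.3.3.3"}


def test_ecs_from_metabolites_cas_and_name_keys(registry):
    maps = _toy_maps()
    annotated = pd.DataFrame(
        {
            "id": ["f1", "f2", "f3"],
            "compound": ["hypoxanthine", "cmpB", "unannotated"],
            "p_value": [1e-5, 1e-5, 1e-9],
        }
    )
    # hypoxanthine resolves through its CAS number, cmpB through its name
    ecs = ecs_from_metabolites(annotated, maps, registry=registry)
    assert ecs == {"1.17.1.4", "2.2.2.2"}


def test_ecs_from_metabolites_threshold():
    maps = _toy_maps()
    annotated = pd.DataFrame(
        {"id": ["f1"], "compound": ["cmpB"], "p_value": [0.01]}
    )
    assert ecs_from_metabolites(annotated, maps) == set()


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ({"a.1.1.1"}, {"b.1.1.1"}, set()),
        ({"1.1.1.1", "2.2.2.2", "3.3.3.3"}, {"2.2.2.2", "3.3.3.3", "4.4.4.4"},
         {"2.2.2.2", "3.3.3.3"}),
    ],
)
def test_overlap_examples(a, b, expected):
    assert overlap_ecs(a, b) == expected


def test_overlap_excludes_partial_ecs():
    assert overlap_ecs({"1.3.1.-", "1.1.1.1"}, {"1.3.1.-", "1.1.1.1"}) == {"1.1.1.1"}


@given(
    st.sets(st.sampled_from([f"1.1.1.{i}" for i in range(20)])),
    st.sets(st.sampled_from([f"1.1.1.{i}" for i in range(20)])),
)
def test_overlap_is_a_subset_of_both_inputs(a, b):
    o = overlap_ecs(a, b)
    assert o <= a and o <= b
    assert len(o) <= min(len(a), len(b))
    assert overlap_ecs(a, a) == a  # idempotence (no partials in the pool)


def test_reactions_for_ecs_evidence_classes():
    maps = _toy_maps()
    records = reactions_for_ecs(
        ["1.1.1.1", "2.2.2.2"],
        maps,
        layer_sets=({"1.1.1.1", "2.2.2.2"}, {"2.2.2.2"}),
    )
    # two ECs over {r1,r2} and {r2,r3}: 3 distinct reactions, r2 shared
    assert [r.reaction for r in records] == ["r1", "r2", "r3"]
    by_rxn = {r.reaction: r for r in records}
    assert by_rxn["r1"].evidence == "transcript_only"
    assert by_rxn["r2"].evidence == "both"
    assert by_rxn["r3"].evidence == "both"  # supported by a dual-layer EC
    assert len({r.reaction for r in records}) == len(records)


def test_reactions_single_layer():
    maps = _toy_maps()
    records = reactions_for_ecs(["1.17.1.4"], maps, layer_sets=(set(), {"1.17.1.4"}))
    assert len(records) == 1 and records[0].evidence == "metabolite_only"
    assert records[0].pathways == frozenset({"pwB"})


def test_export_ipath_format(tmp_path):
    maps = _toy_maps()
    records = reactions_for_ecs(
        ["1.1.1.1", "2.2.2.2", "1.17.1.4"],
        maps,
        layer_sets=({"1.1.1.1", "2.2.2.2"}, {"2.2.2.2", "1.17.1.4"}),
    )
    out = tmp_path / "sel.txt"
    export_ipath(records, out)
    lines = out.read_text().strip().split("\n")
    assert lines == [
        "1.1.1.1 #00ff00 W10",
        "1.17.1.4 #0000ff W10",
        "2.2.2.2 #000000 W20",
    ]


def test_export_ipath_rejects_empty(tmp_path):
    with pytest.raises(ValueError):
        export_ipath([], tmp_path / "sel.txt")


def test_perfect_upstream_recovery_matches_truth(dataset):
    """Feeding the planted truth through the EC derivation reproduces the
    recorded per-layer EC sets and their intersection exactly."""
    ds = dataset
    degs = pd.DataFrame(
        {
            "gene": list(ds.counts.index),
            "q_value": [0.0 if g in ds.truth.de_genes else 1.0 for g in ds.counts.index],
        }
    )
    t_ecs = ecs_from_degs(degs, ds.maps)
    assert t_ecs == ds.truth.transcript_ecs

    rows = []
    for fid, info in ds.truth.feature_truth.items():
        differential = info["compound"] in ds.truth.differential_compounds
        rows.append(
            {"id": fid, "compound": info["compound"], "p_value": 0.0 if differential else 1.0}
        )
    annotated = pd.DataFrame(rows)
    m_ecs = ecs_from_metabolites(annotated, ds.maps, registry=ds.registry)
    assert m_ecs == ds.truth.metabolite_ecs
    assert overlap_ecs(t_ecs, m_ecs) == ds.truth.overlap_ecs


def test_mapping_tables_round_trip_from_dir(dataset, tmp_path):
    from duomics.simulate import write_fixture

    write_fixture(dataset, tmp_path)
    maps = MappingTables.from_dir(tmp_path)
    assert maps.pfam_ec == dataset.maps.pfam_ec
    assert maps.transcript_pfam == dataset.maps.transcript_pfam
    assert maps.compound_ec == dataset.maps.compound_ec
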