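"""Query semantics against fixture definitions and brute-force oracle scans."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from mirversions import query_engine as qe
from mirversions.core_model import DatabaseError, MatureProduct, PrecursorEntry, VersionLabel
from mirversions.mirbase_io import ReleaseData, build_database

import oracles
from conftest import make_history


# ---------------------------------------------------------------------------
# resolve
# ---------------------------------------------------------------------------

def test_resolve_empty_input_is_not_found(demo_db):
    assert qe.resolve(demo_db, "", "v16").status == qe.NOT_FOUND


def test_resolve_every_name_returns_its_own_accession(histories):
    """Exhaustive self-resolution: every name of every version maps back to
    the accession the raw release assigns it."""
    for releases, _events, db in histories[:3]:
        for release in releases:
            label = release.version.label
            for entry in release.entries:
                row = qe.resolve(db, entry.name, label, "precursor")
                assert (row.status, row.accession) == (qe.ALIVE, entry.accession)
                for product in entry.products:
                    row = qe.resolve(db, product.name, label, "mature")
                    assert row.status == qe.ALIVE
                    assert row.accession == product.accession


def test_resolve_case_folded_with_kind_filter(demo_db):
    row = qe.resolve(demo_db, "HSA-MIR-224", "v16", "precursor")
    assert (row.status, row.accession) == (qe.ALIVE, "MI0900010")


def test_resolve_case_folded_dual_hit_is_ambiguous(demo_db):
    row = qe.resolve(demo_db, "HSA-MIR-224", "v16", "any")
    assert row.status == qe.AMBIGUOUS
    assert set(row.extras["candidates"]) == {"MI0900010", "MIMAT0900010"}


# ---------------------------------------------------------------------------
# check_alive
# ---------------------------------------------------------------------------

def test_check_alive_demo_examples(demo_db):
    rows = qe.check_alive(demo_db, ["mmu-miR-1274a", "hsa-miR-224-5p"], "v22")
    assert [r.status for r in rows] == [qe.DEAD, qe.ALIVE]


def test_check_alive_matches_event_log(histories):
    """Every accession killed in the event log is dead at the final version;
    every survivor is alive."""
    for releases, events, db in histories:
        latest = releases[-1].version.label
        killed = {e.accession for e in events if e.kind == "kill"}
        born = {e.accession for e in events if e.kind == "birth"}
        for acc in sorted(born):
            row = qe.check_alive(db, [acc], latest)[0]
            expected = qe.DEAD if acc in killed else qe.ALIVE
            assert row.status == expected, acc


def test_check_alive_unknown_target_version_raises(demo_db):
    with pytest.raises(DatabaseError, match="v99"):
        qe.check_alive(demo_db, ["x"], "v99")


# ---------------------------------------------------------------------------
# check_version
# ---------------------------------------------------------------------------

def test_check_version_recovers_known_source_version(histories):
    rng = random.Random(0)
    releases, _events, db = histories[0]
    target = releases[1]
    pool = sorted(oracles.name_pool(target))
    sample = rng.sample(pool, min(20, len(pool)))
    result = qe.check_version(db, sample)
    assert result.proportions[target.version.label] == 1.0


def test_check_version_tie_breaks_to_latest(demo_db):
    result = qe.check_version(demo_db, ["hsa-mir-224"])  # present in all four
    assert all(p == 1.0 for p in result.proportions.values())
    assert result.best == "v22"


def test_check_version_mixed_list_splits_proportions(demo_db):
    # two v16-only names, two v22-only names: 0.5 each way, newest wins
    result = qe.check_version(
        demo_db,
        ["hsa-mir-103-1-as", "hsa-miR-224*", "hsa-miR-103b-3p", "hsa-miR-224-5p"],
    )
    assert result.proportions["v16"] == 0.5
    assert result.proportions["v22"] == 0.5
    assert result.best == "v22"
    assert result.n_matched_best == 2


def test_check_version_proportions_match_oracle(histories):
    rng = random.Random(1)
    for releases, _events, db in histories[:5]:
        pool = sorted(set().union(*(oracles.name_pool(r) for r in releases)))
        sample = rng.sample(pool, min(15, len(pool)))
        expected = oracles.version_proportions(releases, sample)
        assert qe.check_version(db, sample).proportions == expected


def test_check_version_rejects_empty_and_accession_only_input(demo_db):
    with pytest.raises(DatabaseError, match="no usable input"):
        qe.check_version(demo_db, ["", "  "])
    with pytest.raises(DatabaseError, match="no usable input"):
        qe.check_version(demo_db, ["MI0900001"])


# ---------------------------------------------------------------------------
# check_family
# ---------------------------------------------------------------------------

def test_check_family_demo_lookup(demo_db):
    rows = qe.check_family(demo_db, ["hsa-mir-103b-1"], "v22")
    assert len(rows) == 1
    assert rows[0].extras["family_accession"] == "MIPF0900001"
    assert rows[0].extras["family_name"] == "mir-103"


def test_check_family_mature_maps_through_parent(demo_db):
    rows = qe.check_family(demo_db, ["hsa-miR-103b-3p"], "v22")
    assert rows[0].extras["family_name"] == "mir-103"


def test_check_family_inputs_without_family_keep_status(demo_db):
    rows = qe.check_family(demo_db, ["mmu-mir-1274a", "garbage"], "v16")
    assert rows[0].status == qe.ALIVE and "family_name" not in rows[0].extras
    assert rows[1].status == qe.NOT_FOUND


def test_check_family_errors_without_family_data():
    releases, _events = make_history(3, include_mifam=False)
    db = build_database(releases)
    with pytest.raises(DatabaseError, match="no family data"):
        qe.check_family(db, ["anything"])


def test_check_family_agrees_with_mifam_scan(histories):
    for releases, _events, db in histories[:5]:
        for release in releases:
            label = release.version.label
            for entry in release.entries:
                rows = qe.check_family(db, [entry.name], label)
                got = {
                    (r.extras["family_accession"], r.extras["family_name"])
                    for r in rows
                    if "family_accession" in r.extras
                }
                assert got == oracles.families_of(release, entry.name)


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def test_name_to_accession_demo(demo_db):
    rows = qe.name_to_accession(demo_db, ["hsa-mir-103-1-as"], "v16")
    assert rows[0].extras["accession"] == "MI0900001"


def test_name_accession_round_trip_on_all_alive_entities(histories):
    releases, _events, db = histories[1]
    for release in releases:
        label = release.version.label
        names = sorted(oracles.name_pool(release))
        accession_rows = qe.name_to_accession(db, names, label)
        back = qe.accession_to_name(db, [r.accession for r in accession_rows], label)
        assert [r.name for r in back] == names


def test_name_to_accession_garbage_is_not_found_at_position(demo_db):
    rows = qe.name_to_accession(demo_db, ["hsa-mir-224", "xyz"], "v16")
    assert (rows[1].position, rows[1].status) == (1, qe.NOT_FOUND)


def test_accession_to_name_demo(demo_db):
    rows = qe.accession_to_name(demo_db, ["MI0900001", "MIMAT0900001"], "v22")
    assert (rows[0].status, rows[0].name) == (qe.ALIVE, "hsa-mir-103b-1")
    assert (rows[1].status, rows[1].name) == (qe.DEAD, None)


def test_accession_to_name_matches_release_scan(histories):
    for releases, _events, db in histories[:5]:
        accs = sorted(oracles.distinct_accessions(releases))
        accs = [a for a in accs if not a.startswith("MIPF")]
        for release in releases:
            rows = qe.accession_to_name(db, accs, release.version.label)
            for acc, row in zip(accs, rows):
                assert row.name == oracles.name_of_accession(release, acc)


def test_version_convert_demo_worked_example(demo_db):
    rows = qe.version_convert(demo_db, ["hsa-mir-103-1-as"], "v16", "v22")
    assert rows[0].extras["target_name"] == "hsa-mir-103b-1"
    assert rows[0].status == qe.ALIVE


def test_version_convert_is_identity_when_source_equals_target(histories):
    releases, _events, db = histories[2]
    release = releases[-1]
    label = release.version.label
    names = sorted(oracles.name_pool(release))
    rows = qe.version_convert(db, names, label, label)
    assert [r.extras["target_name"] for r in rows] == names


def test_version_convert_reproduces_every_logged_rename(histories):
    """For each precursor rename event, converting the old name from the
    preceding version to the rename version yields the new name."""
    checked = 0
    for releases, events, db in histories:
        labels = [r.version.label for r in releases]
        for ev in events:
            if ev.kind != "rename" or not ev.accession.startswith("MI0"):
                continue
            prev = labels[labels.index(ev.version) - 1]
            row = qe.version_convert(db, [ev.old_name], prev, ev.version)[0]
            assert row.extras["target_name"] == ev.new_name, ev
            checked += 1
    assert checked > 20


def test_version_convert_is_transitive(histories):
    releases, _events, db = histories[4]
    labels = [r.version.label for r in releases]
    u, v, w = labels[0], labels[1], labels[-1]
    alive_everywhere = sorted(
        set.intersection(*(
            {e.accession for e in oracles.release_by_label(releases, lab).entries}
            for lab in (u, v, w)
        ))
    )
    names_u = [
        oracles.name_of_accession(oracles.release_by_label(releases, u), acc)
        for acc in alive_everywhere
    ]
    direct = [r.extras["target_name"] for r in qe.version_convert(db, names_u, u, w)]
    via_v = [r.extras["target_name"] for r in qe.version_convert(db, names_u, u, v)]
    two_step = [r.extras["target_name"] for r in qe.version_convert(db, via_v, v, w)]
    assert direct == two_step


# ---------------------------------------------------------------------------
# precursor <-> mature
# ---------------------------------------------------------------------------

def test_precursor_to_mature_demo_v19(demo_db):
    rows = qe.precursor_to_mature(demo_db, ["hsa-mir-224"], "v19")
    assert [r.extras["mature_name"] for r in rows] == [
        "hsa-miR-224-5p", "hsa-miR-224-3p",
    ]
    assert [r.extras["arm"] for r in rows] == ["5p", "3p"]


def test_precursor_to_mature_flags_mature_input(demo_db):
    rows = qe.precursor_to_mature(demo_db, ["hsa-miR-224-5p"], "v19")
    assert rows[0].status == qe.AMBIGUOUS
    assert "note" in rows[0].extras


def test_precursor_mature_mapping_matches_feature_scan(histories):
    for releases, _events, db in histories[:5]:
        for release in releases:
            label = release.version.label
            for entry in release.entries:
                rows = qe.precursor_to_mature(db, [entry.accession], label)
                got = [
                    (r.extras["mature_accession"], r.extras["mature_name"])
                    for r in rows
                    if "mature_accession" in r.extras
                ]
                assert got == oracles.matures_of_precursor(release, entry.accession)
                assert len(got) <= 2


def test_mature_to_precursor_round_trip_containment(histories):
    releases, _events, db = histories[3]
    for release in releases:
        label = release.version.label
        for entry in release.entries:
            for product in entry.products:
                rows = qe.mature_to_precursor(db, [product.accession], label)
                parents = {r.extras["precursor_accession"] for r in rows}
                assert entry.accession in parents
                assert parents == oracles.precursors_of_mature(release, product.accession)


def test_mature_with_two_parents_yields_two_rows():
    shared = MatureProduct("MIMAT0900501", "hsa-miR-501-5p", qe.Arm.FIVE_PRIME, 2, 23)
    entries = [
        PrecursorEntry("MI0900501", "hsa-mir-501-1", "hsa", "", "ACGU" * 20, (shared,)),
        PrecursorEntry("MI0900502", "hsa-mir-501-2", "hsa", "", "AGGU" * 20, (shared,)),
    ]
    db = build_database([ReleaseData(version=VersionLabel(1, "v1"), entries=entries)])
    rows = qe.mature_to_precursor(db, ["hsa-miR-501-5p"], "v1")
    assert [r.extras["precursor_accession"] for r in rows] == ["MI0900501", "MI0900502"]


def test_mature_to_precursor_demo(demo_db):
    rows = qe.mature_to_precursor(demo_db, ["hsa-miR-224-5p"], "v22")
    assert rows[0].extras["precursor_name"] == "hsa-mir-224"


# ---------------------------------------------------------------------------
# retrieval
# ---------------------------------------------------------------------------

def test_get_history_demo_rename(demo_db):
    frame = qe.get_history(demo_db, ["MI0900001"])
    row = frame.iloc[0]
    assert row["v16"] == "hsa-mir-103-1-as"
    assert row["v17"] == row["v19"] == row["v22"] == "hsa-mir-103b-1"
    assert row["aliases"] == "hsa-mir-103-1-as;hsa-mir-103b-1"


def test_get_history_matches_oracle(histories):
    releases, _events, db = histories[5]
    labels = [r.version.label for r in releases]
    accs = sorted(
        a for a in oracles.distinct_accessions(releases) if not a.startswith("MIPF")
    )
    frame = qe.get_history(db, accs)
    for acc, (_, row) in zip(accs, frame.iterrows()):
        expected = oracles.history_of(releases, acc)
        assert {lab: row[lab] for lab in labels} == expected


def test_get_history_late_birth_has_absent_early_markers(histories):
    for releases, events, db in histories:
        latest = releases[-1].version.label
        late = [e.accession for e in events if e.kind == "birth" and e.version == latest]
        if not late:
            continue
        frame = qe.get_history(db, [late[0]])
        row = frame.iloc[0]
        for release in releases[:-1]:
            assert row[release.version.label] is None
        assert row[latest] is not None
        break
    else:
        pytest.skip("no history produced a latest-version birth")


def test_get_sequence_matches_fasta_exhaustively(histories):
    for releases, _events, db in histories[:5]:
        for release in releases:
            label = release.version.label
            accs = sorted(oracles.accession_pool(release))
            rows = qe.get_sequence(db, accs, label)
            for acc, row in zip(accs, rows):
                assert row.extras["sequence"] == oracles.sequence_of(release, acc)
                assert set(row.extras["sequence"]) <= set("ACGU")


def test_get_sequence_dead_entry_absent(demo_db):
    row = qe.get_sequence(demo_db, ["MIMAT0900001"], "v22")[0]
    assert row.status == qe.DEAD and row.extras["sequence"] is None


def test_get_table_counts_and_filter(demo_db):
    table = qe.get_table(demo_db, "v16", kind="precursor")
    assert len(table) == demo_db.version_info("v16").n_precursors
    hsa = qe.get_table(demo_db, "v16", species_filter="hsa", kind="joined")
    assert all(name.startswith("hsa-") for name in hsa["name"])
    with pytest.raises(DatabaseError, match="hsa"):
        qe.get_table(demo_db, "v16", species_filter="xxx")


def test_get_table_joined_orders_5p_before_3p(demo_db):
    table = qe.get_table(demo_db, "v19", kind="joined").set_index("name")
    row = table.loc["hsa-mir-224"]
    assert row["mature1_name"] == "hsa-miR-224-5p"
    assert row["mature2_name"] == "hsa-miR-224-3p"


def test_get_table_equals_rebuilt_release(histories):
    from mirversions.core_model import rebuild_release

    releases, _events, db = histories[6]
    label = releases[0].version.label
    table = qe.get_table(db, label, kind="precursor")
    entries = rebuild_release(db, label)
    assert list(table["accession"]) == [e.accession for e in entries]
    assert list(table["sequence"]) == [e.sequence for e in entries]


def test_get_catalog_versions_and_species(demo_db, demo_releases):
    versions = qe.get_catalog(demo_db, "versions")
    assert list(versions["version"]) == ["v16", "v17", "v19", "v22"]
    assert list(versions["n_precursors"]) == [
        len(r.entries) for r in demo_releases
    ]
    species = qe.get_catalog(demo_db, "species")
    assert list(species["code"]) == ["dme", "hsa", "mmu"]
    with pytest.raises(DatabaseError):
        qe.get_catalog(demo_db, "mirnas")


def test_get_catalog_species_matches_observed_codes(histories):
    releases, _events, db = histories[7]
    observed = sorted(
        {e.species_code for r in releases for e in r.entries}
    )
    species = qe.get_catalog(db, "species")
    assert sorted(species["code"]) == observed


# ---------------------------------------------------------------------------
# batch contracts
# ---------------------------------------------------------------------------

_weird = st.text(
    alphabet="abcdefghij-*MIAT0123456789 ", min_size=0, max_size=24
)
_inputs = st.lists(
    st.one_of(
        _weird,
        st.sampled_from([
            "hsa-mir-224", "hsa-miR-224*", "HSA-MIR-224", "mmu-miR-1274a",
            "MI0900001", "MIMAT0900001", "hsa-miR-103b-3p", "", "   ",
        ]),
    ),
    max_size=25,
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(inputs=_inputs)
def test_every_batch_operation_preserves_order_without_exceptions(
    demo_db, inputs
):
    """Random garbage, empties, duplicates and mixed-kind inputs: every batch
    operation returns one contiguous, ordered block of rows per input."""
    operations = [
        lambda: qe.check_alive(demo_db, inputs, "v22"),
        lambda: qe.name_to_accession(demo_db, inputs, "v16"),
        lambda: qe.accession_to_name(demo_db, inputs, "v22"),
        lambda: qe.version_convert(demo_db, inputs, "v16", "v22"),
        lambda: qe.precursor_to_mature(demo_db, inputs, "v19"),
        lambda: qe.mature_to_precursor(demo_db, inputs, "v19"),
        lambda: qe.get_sequence(demo_db, inputs, "v16"),
        lambda: qe.check_family(demo_db, inputs, "v22"),
    ]
    for op in operations:
        rows = op()
        positions = [r.position for r in rows]
        assert positions == sorted(positions)
        assert set(positions) == set(range(len(inputs)))
        for row in rows:
            assert row.input == inputs[row.position]
    frame = qe.get_history(demo_db, inputs)
    assert list(frame["position"]) == list(range(len(inputs)))
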