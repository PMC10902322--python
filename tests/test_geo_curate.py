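import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import occaudit as oa
from occaudit.errors import ConfigError
from occaudit.geo_curate import haversine_m
from occaudit.occ_model import FLAG_NO_COORDINATES


def _pt(record_id, lat, lon, species="Hedera helix", source="reviewed",
        country="Spain", island_group=None):
    return oa.OccurrenceRecord(
        record_id=record_id,
        revised_species=species,
        latitude=lat,
        longitude=lon,
        source=source,
        country=country,
        island_group=island_group,
    )


class TestAssignUncertainty:
    def test_mainland_spain_is_high(self, region_table):
        rec = _pt("a", 40.0, -3.0, country="Spain")
        region = oa.assign_uncertainty(rec, region_table)
        assert region.n_species == 3
        assert region.uncertainty == "high"

    def test_azores_is_low(self, region_table):
        rec = _pt("a", 38.0, -27.0, country="Portugal", island_group="Azores")
        region = oa.assign_uncertainty(rec, region_table)
        assert region.n_species == 1
        assert region.uncertainty == "low"

    def test_island_group_overrides_country(self, region_table):
        rec = _pt("a", 28.0, -16.0, country="Spain", island_group="Canary Islands")
        assert oa.assign_uncertainty(rec, region_table).uncertainty == "low"

    def test_unknown_region_defaults_to_single_species(self, region_table):
        rec = _pt("a", 50.0, 10.0, country="Germany")
        region = oa.assign_uncertainty(rec, region_table)
        assert region.n_species == 1

    def test_no_region_information_is_unassignable(self, region_table):
        rec = oa.OccurrenceRecord("a", revised_species="Hedera helix")
        with pytest.raises(ConfigError):
            oa.assign_uncertainty(rec, region_table)


class TestFilterOnline:
    def test_mainland_portugal_dropped(self, region_table):
        rec = _pt("a", 39.0, -8.0, source="online", country="Portugal")
        assert oa.filter_online([rec], region_table) == []

    def test_canary_islands_kept(self, region_table):
        rec = _pt("a", 28.0, -16.0, source="online", country="Spain",
                  island_group="Canary Islands")
        assert oa.filter_online([rec], region_table) == [rec]

    def test_empty_input(self, region_table):
        assert oa.filter_online([], region_table) == []

    def test_idempotent(self, region_table):
        records = [
            _pt("a", 28.0, -16.0, source="online", island_group="Canary Islands"),
            _pt("b", 40.0, -3.0, source="online", country="Spain"),
            _pt("c", 50.0, 10.0, source="online", country="Germany"),
        ]
        once = oa.filter_online(records, region_table)
        assert oa.filter_online(once, region_table) == once

    def test_reviewed_records_rejected(self, region_table):
        with pytest.raises(ConfigError):
            oa.filter_online([_pt("a", 40.0, -3.0, source="reviewed")], region_table)


class TestThinning:
    def test_two_continental_points_5km_apart_keep_one(self):
        a = _pt("a", 40.0, -3.0)
        b = _pt("b", 40.0449, -3.0)  # ~5 km north
        assert haversine_m(40.0, -3.0, 40.0449, -3.0) == pytest.approx(5000, rel=0.01)
        kept = oa.thin_by_buffer([a, b])
        assert [r.record_id for r in kept] == ["a"]

    def test_two_island_points_5km_apart_keep_both(self):
        a = _pt("a", 38.0, -27.0, island_group="Azores")
        b = _pt("b", 38.0449, -27.0, island_group="Azores")
        kept = oa.thin_by_buffer([a, b])
        assert len(kept) == 2

    def test_different_species_never_suppress_each_other(self):
        a = _pt("a", 40.0, -3.0, species="Hedera helix")
        b = _pt("b", 40.0001, -3.0, species="Hedera hibernica")
        assert len(oa.thin_by_buffer([a, b])) == 2

    def test_reviewed_wins_over_online_at_same_point(self):
        online = _pt("a-online", 40.0, -3.0, source="online")
        reviewed = _pt("z-reviewed", 40.0, -3.0, source="reviewed")
        kept = oa.thin_by_buffer([online, reviewed])
        assert [r.record_id for r in kept] == ["z-reviewed"]

    def test_record_without_coordinates_passes_through_flagged(self):
        rec = oa.OccurrenceRecord("a", revised_species="Hedera helix", country="Spain")
        kept = oa.thin_by_buffer([rec])
        assert len(kept) == 1
        assert FLAG_NO_COORDINATES in kept[0].flags

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        records = [
            _pt(f"r{i:03d}", float(rng.uniform(39, 41)), float(rng.uniform(-4, -2)))
            for i in range(80)
        ]
        once = oa.thin_by_buffer(records)
        twice = oa.thin_by_buffer(once)
        assert [r.record_id for r in twice] == [r.record_id for r in once]

    def test_never_increases_counts_and_is_deterministic(self):
        rng = np.random.default_rng(3)
        records = [
            _pt(f"r{i:03d}", float(rng.uniform(39, 41)), float(rng.uniform(-4, -2)))
            for i in range(60)
        ]
        kept1 = oa.thin_by_buffer(records)
        kept2 = oa.thin_by_buffer(list(records))
        assert kept1 == kept2
        assert len(kept1) <= len(records)

    @given(st.integers(0, 2**32 - 1), st.integers(1, 200))
    @settings(max_examples=25)
    def test_maximal_greedy_against_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        species_pool = ["Hedera helix", "Hedera hibernica"]
        records = [
            _pt(
                f"r{i:03d}",
                float(rng.uniform(39.5, 40.5)),
                float(rng.uniform(-3.5, -2.5)),
                species=species_pool[int(rng.integers(2))],
            )
            for i in range(n)
        ]
        cfg = oa.ThinningConfig()
        kept = oa.thin_by_buffer(records, cfg)
        kept_ids = {r.record_id for r in kept}
        by_species = {}
        for r in kept:
            by_species.setdefault(r.revised_species, []).append(r)
        # all retained pairs of the same species are >= buffer apart
        for peers in by_species.values():
            for i in range(len(peers)):
                for j in range(i + 1, len(peers)):
                    d = haversine_m(peers[i].latitude, peers[i].longitude,
                                    peers[j].latitude, peers[j].longitude)
                    assert d >= cfg.buffer_continental_m
        # every dropped record is within buffer of a retained same-species record
        for r in records:
            if r.record_id in kept_ids:
                continue
            close = any(
                haversine_m(r.latitude, r.longitude, k.latitude, k.longitude)
                < cfg.buffer_continental_m
                for k in by_species.get(r.revised_species, [])
            )
            assert close, f"{r.record_id} dropped without a nearby retained record"


class TestMerge:
    def test_reviewed_only_passthrough(self, region_table):
        records = [_pt("a", 40.0, -3.0), _pt("b", 45.0, 2.0, country="France"),
                   oa.OccurrenceRecord("c", revised_species="Hedera helix", country="Spain")]
        merged = oa.merge_mixocc(records, [], region_table)
        assert [r.record_id for r in merged] == ["a", "b"]  # no-coords record dropped

    def test_high_uncertainty_online_never_in_output(self, region_table):
        reviewed = [_pt("a", 40.0, -3.0)]
        online = [_pt("b", 41.0, -3.5, source="online", country="Spain")]
        merged = oa.merge_mixocc(reviewed, online, region_table)
        assert [r.record_id for r in merged] == ["a"]

    def test_duplicate_coordinates_resolved_for_reviewed(self, region_table):
        reviewed = [_pt("a", 50.0, 10.0, country="Germany")]
        online = [_pt("b", 50.0, 10.0, source="online", country="Germany")]
        merged = oa.merge_mixocc(reviewed, online, region_table)
        assert [r.record_id for r in merged] == ["a"]

    def test_accounting_identity_on_synthetic_inputs(self, region_table):
        rng = np.random.default_rng(9)
        reviewed = [
            _pt(f"rev{i:03d}", float(rng.uniform(47, 54)), float(rng.uniform(7, 14)),
                country="Germany")
            for i in range(40)
        ]
        online = [
            _pt(f"onl{i:03d}", float(rng.uniform(47, 54)), float(rng.uniform(7, 14)),
                source="online", country="Germany")
            for i in range(120)
        ]
        merged = oa.merge_mixocc(reviewed, online, region_table)
        n_reviewed = sum(1 for r in merged if r.source == "reviewed")
        n_online = sum(1 for r in merged if r.source == "online")
        assert n_reviewed == len(reviewed)
        assert len(merged) == n_reviewed + n_online
        # reviewed records are all retained even if mutually close
        assert {r.record_id for r in merged if r.source == "reviewed"} == {
            r.record_id for r in reviewed
        }

    def test_merge_provenance_retained(self, region_table):
        reviewed = [_pt("a", 50.0, 10.0, country="Germany")]
        online = [_pt("b", 52.0, 12.0, source="online", country="Germany")]
        merged = oa.merge_mixocc(reviewed, online, region_table)
        assert {r.record_id: r.source for r in merged} == {"a": "reviewed", "b": "online"}
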