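"""Region uncertainty scoring, online-record filtering, spatial thinning, merging.

A region's expected taxonomic uncertainty is *low* when a single congener is
native there and *high* when two or more share range boundaries.  Online
records are only trusted from low-uncertainty regions; reviewed records are
kept everywhere.  Thinning enforces a minimum great-circle distance between
retained records of the same species (a wider buffer on the continent than
on islands, where ranges are compressed).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .errors import ConfigError
from .occ_model import FLAG_NO_COORDINATES, SOURCE_ONLINE, SOURCE_REVIEWED, OccurrenceRecord

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class RegionUncertainty:
    region_key: str
    n_species: int
    island_group: str | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")

    @property
    def uncertainty(self) -> str:
        return "low" if self.n_species == 1 else "high"


#: fallback when a record's region is not in the table (single-congener rule)
DEFAULT_REGION = RegionUncertainty(region_key="<other>", n_species=1)


@dataclass(frozen=True)
class ThinningConfig:
    buffer_continental_m: float = 10_000.0
    buffer_island_m: float = 1_000.0

    def __post_init__(self) -> None:
        if self.buffer_continental_m <= 0 or self.buffer_island_m <= 0:
            raise ConfigError("thinning buffers must be positive")


def read_region_table(path: str | Path, delimiter: str = ",") -> list[RegionUncertainty]:
    rows: list[RegionUncertainty] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"region_key", "n_species"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ConfigError(f"region table missing columns: {sorted(missing)}")
        for row in reader:
            island = (row.get("island_group") or "").strip() or None
            rows.append(
                RegionUncertainty(
                    region_key=row["region_key"].strip(),
                    n_species=int(row["n_species"]),
                    island_group=island,
                )
            )
    keys = [r.region_key for r in rows]
    if len(keys) != len(set(keys)):
        raise ConfigError("duplicate region_key in region table")
    return rows


def assign_uncertainty(
    record: OccurrenceRecord, table: Sequence[RegionUncertainty]
) -> RegionUncertainty:
    """Resolve a record's region; island group takes precedence over country.

    Records from regions absent from the table fall back to the
    single-congener default with a warning.  A record with neither country
    nor island group is unassignable.
    """
    if record.island_group is None and record.country is None:
        record.flags.append("unassignable_region")
        raise ConfigError(f"record {record.record_id!r} has neither country nor island group")
    if record.island_group is not None:
        for region in table:
            if region.island_group and region.island_group.lower() == record.island_group.lower():
                return region
    if record.country is not None:
        for region in table:
            if region.island_group is None and region.region_key.lower() == record.country.lower():
                return region
    key = record.island_group or record.country
    if key not in _warned_regions:
        _warned_regions.add(key)
        logger.warning(
            "region %r not in table; defaulting to single-species (low uncertainty)", key
        )
    return DEFAULT_REGION


_warned_regions: set[str] = set()


def filter_online(
    records: Sequence[OccurrenceRecord], table: Sequence[RegionUncertainty]
) -> list[OccurrenceRecord]:
    """Keep only online records from low-uncertainty regions."""
    kept = []
    for rec in records:
        if rec.source != SOURCE_ONLINE:
            raise ConfigError(
                f"filter_online applies to online records only (got {rec.source!r} "
                f"for {rec.record_id!r})"
            )
        if assign_uncertainty(rec, table).uncertainty == "low":
            kept.append(rec)
    return kept


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres on a spherical Earth."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def _thin_order(rec: OccurrenceRecord) -> tuple[int, str]:
    return (0 if rec.source == SOURCE_REVIEWED else 1, rec.record_id)


def _buffer_for(rec: OccurrenceRecord, cfg: ThinningConfig) -> float:
    return cfg.buffer_island_m if rec.island_group is not None else cfg.buffer_continental_m


def thin_by_buffer(
    records: Sequence[OccurrenceRecord],
    cfg: ThinningConfig | None = None,
    protected_ids: frozenset[str] = frozenset(),
) -> list[OccurrenceRecord]:
    """Greedy sequential per-species thinning.

    Records are visited reviewed-first, then by ascending record id; a record
    is retained iff it lies at least one buffer away from every already
    retained record of the same species.  Records in ``protected_ids`` are
    always retained (used by the merge to privilege reviewed records).
    Records without coordinates cannot be thinned: they pass through with a
    flag.  Output preserves the input order of the retained records.
    """
    cfg = cfg or ThinningConfig()
    kept_ids: set[str] = set()
    kept_by_species: dict[str | None, list[OccurrenceRecord]] = {}
    for rec in sorted(records, key=_thin_order):
        if not rec.has_coordinates:
            rec = replace(rec, flags=[*rec.flags, FLAG_NO_COORDINATES])
            kept_ids.add(rec.record_id)
            continue
        peers = kept_by_species.setdefault(rec.revised_species, [])
        buffer_m = _buffer_for(rec, cfg)
        if rec.record_id in protected_ids or all(
            haversine_m(rec.latitude, rec.longitude, p.latitude, p.longitude) >= buffer_m
            for p in peers
        ):
            peers.append(rec)
            kept_ids.add(rec.record_id)
    out = []
    for rec in records:
        if rec.record_id in kept_ids:
            if not rec.has_coordinates and FLAG_NO_COORDINATES not in rec.flags:
                rec = replace(rec, flags=[*rec.flags, FLAG_NO_COORDINATES])
            out.append(rec)
    return out


def merge_mixocc(
    reviewed: Sequence[OccurrenceRecord],
    online: Sequence[OccurrenceRecord],
    table: Sequence[RegionUncertainty],
    cfg: ThinningConfig | None = None,
) -> list[OccurrenceRecord]:
    """Compile the mixed reviewed/online spatial database.

    Output = every reviewed record with coordinates, plus the online records
    from low-uncertainty regions that survive thinning against the reviewed
    records and each other.  Reviewed records are never dropped, so an online
    duplicate of a reviewed point (distance 0, same species) always loses.
    """
    cfg = cfg or ThinningConfig()
    reviewed_pts = [r for r in reviewed if r.has_coordinates]
    online_kept = filter_online(list(online), table)
    no_coords = [r for r in online_kept if not r.has_coordinates]
    for rec in no_coords:
        logger.warning("online record %s has no coordinates; dropped from merge", rec.record_id)
    online_kept = [r for r in online_kept if r.has_coordinates]
    protected = frozenset(r.record_id for r in reviewed_pts)
    merged = thin_by_buffer([*reviewed_pts, *online_kept], cfg, protected_ids=protected)
    logger.info(
        "merge: %d reviewed with coordinates + %d/%d online kept after region "
        "filter and thinning",
        len(reviewed_pts),
        len(merged) - len(reviewed_pts),
        len(online),
    )
    return merged
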