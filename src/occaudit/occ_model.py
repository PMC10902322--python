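"""Occurrence record model and flat-table (Darwin Core style) readers/writers.

Records are stored in delimited text using Darwin Core term names where such
terms exist (``scientificName``, ``verbatimIdentification``,
``decimalLatitude`` ...).  Missing cells (empty string or literal ``NA``)
become ``None``.  Out-of-range or half-present coordinate pairs never crash
the reader: the pair is dropped and a validation flag is recorded on the
record instead, so rows-in always equals records-out.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError

logger = logging.getLogger(__name__)

SOURCE_REVIEWED = "reviewed"
SOURCE_ONLINE = "online"
VALID_SOURCES = (SOURCE_REVIEWED, SOURCE_ONLINE)

ISLAND_GROUPS = ("Azores", "Madeira", "Canary Islands")

#: canonical column order used by :func:`write_occurrences`
COLUMNS = (
    "occurrenceID",
    "verbatimIdentification",
    "scientificName",
    "identifiedBy",
    "country",
    "islandGroup",
    "decimalLatitude",
    "decimalLongitude",
    "coordinateUncertaintyInMeters",
    "source",
    "locality",
)

#: record field -> default column name
DEFAULT_FIELD_MAP: Mapping[str, str] = {
    "record_id": "occurrenceID",
    "original_name_verbatim": "verbatimIdentification",
    "revised_species": "scientificName",
    "identified_by": "identifiedBy",
    "country": "country",
    "island_group": "islandGroup",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "coordinate_uncertainty_m": "coordinateUncertaintyInMeters",
    "source": "source",
    "locality_verbatim": "locality",
}

FLAG_INVALID_COORDINATES = "invalid_coordinates"
FLAG_INVALID_UNCERTAINTY = "invalid_coordinate_uncertainty"
FLAG_INVALID_SOURCE = "invalid_source"
FLAG_NO_COORDINATES = "no_coordinates"
FLAG_UNASSIGNABLE_REGION = "unassignable_region"


@dataclass
class Dialect:
    """How a delimited occurrence file maps onto :class:`OccurrenceRecord`."""

    delimiter: str = ","
    field_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_FIELD_MAP))
    default_source: str = SOURCE_REVIEWED


@dataclass
class OccurrenceRecord:
    record_id: str
    original_name_verbatim: str = ""
    revised_species: str | None = None
    identified_by: str = ""
    country: str | None = None
    island_group: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    coordinate_uncertainty_m: float | None = None
    source: str = SOURCE_REVIEWED
    locality_verbatim: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None

    def validated(self) -> "OccurrenceRecord":
        """Return a copy with invariant violations downgraded to flags."""
        rec = replace(self, flags=list(self.flags))
        lat, lon = rec.latitude, rec.longitude
        if (lat is None) != (lon is None):
            rec.latitude = rec.longitude = None
            rec.flags.append(FLAG_INVALID_COORDINATES)
        elif lat is not None and lon is not None:
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                rec.latitude = rec.longitude = None
                rec.flags.append(FLAG_INVALID_COORDINATES)
        if rec.coordinate_uncertainty_m is not None and rec.coordinate_uncertainty_m < 0:
            rec.coordinate_uncertainty_m = None
            rec.flags.append(FLAG_INVALID_UNCERTAINTY)
        if rec.source not in VALID_SOURCES:
            rec.flags.append(FLAG_INVALID_SOURCE)
            rec.source = SOURCE_REVIEWED
        return rec


def _absent(cell: str | None) -> bool:
    return cell is None or cell.strip() == "" or cell.strip().upper() == "NA"


def _opt_str(cell: str | None) -> str | None:
    return None if _absent(cell) else cell.strip()


def _opt_float(cell: str | None) -> tuple[float | None, bool]:
    """Parse an optional float; second element is True on parse failure."""
    if _absent(cell):
        return None, False
    try:
        return float(cell.strip()), False
    except ValueError:
        return None, True


def read_occurrences(path: str | Path, dialect: Dialect | None = None) -> list[OccurrenceRecord]:
    """Read one :class:`OccurrenceRecord` per data row, in file order.

    Raises :class:`ConfigError` when the field map names neither an original
    identification column nor a revised identification column present in the
    file header.
    """
    dialect = dialect or Dialect()
    fm = dict(dialect.field_map)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        name_cols = [fm.get("original_name_verbatim"), fm.get("revised_species")]
        if not any(c in header for c in name_cols if c):
            raise ConfigError(
                "field map must name at least one identification column present in "
                f"the file (looked for {name_cols!r} in header {header!r})"
            )
        records: list[OccurrenceRecord] = []
        for i, row in enumerate(reader):
            records.append(_row_to_record(row, fm, dialect, i, path.stem))
    logger.info("read %d records from %s (0 rejected)", len(records), path)
    return records


def _row_to_record(
    row: Mapping[str, str], fm: Mapping[str, str], dialect: Dialect, ordinal: int, stem: str
) -> OccurrenceRecord:
    def cell(fieldname: str) -> str | None:
        col = fm.get(fieldname)
        return row.get(col) if col else None

    record_id = _opt_str(cell("record_id"))
    if record_id is None:
        # stable zero-padded ordinal so downstream tie-breaks are deterministic
        record_id = f"{stem}-{ordinal:06d}"

    flags: list[str] = []
    lat, bad_lat = _opt_float(cell("latitude"))
    lon, bad_lon = _opt_float(cell("longitude"))
    if bad_lat or bad_lon:
        lat = lon = None
        flags.append(FLAG_INVALID_COORDINATES)
    unc, bad_unc = _opt_float(cell("coordinate_uncertainty_m"))
    if bad_unc:
        flags.append(FLAG_INVALID_UNCERTAINTY)

    rec = OccurrenceRecord(
        record_id=record_id,
        original_name_verbatim=_opt_str(cell("original_name_verbatim")) or "",
        revised_species=_opt_str(cell("revised_species")),
        identified_by=_opt_str(cell("identified_by")) or "",
        country=_opt_str(cell("country")),
        island_group=_opt_str(cell("island_group")),
        latitude=lat,
        longitude=lon,
        coordinate_uncertainty_m=unc,
        source=_opt_str(cell("source")) or dialect.default_source,
        locality_verbatim=_opt_str(cell("locality_verbatim")) or "",
        flags=flags,
    )
    return rec.validated()


def _fmt(value: object | None) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_occurrences(
    records: Sequence[OccurrenceRecord], path: str | Path, delimiter: str = ","
) -> int:
    """Write records in the fixed :data:`COLUMNS` order; returns rows written."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.record_id,
                    rec.original_name_verbatim,
                    _fmt(rec.revised_species),
                    rec.identified_by,
                    _fmt(rec.country),
                    _fmt(rec.island_group),
                    _fmt(rec.latitude),
                    _fmt(rec.longitude),
                    _fmt(rec.coordinate_uncertainty_m),
                    rec.source,
                    rec.locality_verbatim,
                ]
            )
    return len(records)


def write_geojson(records: Iterable[OccurrenceRecord], path: str | Path) -> int:
    """Export records with coordinates as a GeoJSON FeatureCollection."""
    features = []
    for rec in records:
        if not rec.has_coordinates:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [rec.longitude, rec.latitude]},
                "properties": {
                    "occurrenceID": rec.record_id,
                    "verbatimIdentification": rec.original_name_verbatim,
                    "scientificName": rec.revised_species,
                    "identifiedBy": rec.identified_by,
                    "country": rec.country,
                    "islandGroup": rec.island_group,
                    "coordinateUncertaintyInMeters": rec.coordinate_uncertainty_m,
                    "source": rec.source,
                    "locality": rec.locality_verbatim,
                },
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")
    return len(features)
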