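"""End-to-end orchestration: audit and merge runs with stage accounting.

Every run writes its outputs into ``out_dir`` plus a plain-text run log of
stage counts (no timestamps, so identical inputs give byte-identical
outputs).  On error, partial outputs are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import resources
from .errors import ConfigError, OccAuditError
from .error_audit import (
    DEFAULT_BLOCKED_IDENTIFIERS,
    CAT_EXCLUDED,
    CAT_UNRESOLVABLE,
    ErrorClassification,
    build_matrix,
    classify_records,
    filter_circularity,
    write_classifications,
)
from .geo_curate import ThinningConfig, merge_mixocc, read_region_table
from .nomenclature import ConceptRuleBook
from .occ_model import (
    SOURCE_ONLINE,
    SOURCE_REVIEWED,
    Dialect,
    read_occurrences,
    write_geojson,
    write_occurrences,
)
from .uncertainty_stats import rate_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    occurrences: Path | None = None
    reviewed: Path | None = None
    online: Path | None = None
    kb_path: Path | None = None  # None -> packaged rule book
    region_table_path: Path | None = None  # None -> packaged table
    out_dir: Path = Path("occaudit-out")
    thinning: ThinningConfig = field(default_factory=ThinningConfig)
    blocked_identifiers: tuple[str, ...] = DEFAULT_BLOCKED_IDENTIFIERS
    delimiter: str = ","
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        kwargs = {}
        for key in ("occurrences", "reviewed", "online", "kb_path", "region_table_path",
                    "out_dir"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        if "thinning" in raw:
            kwargs["thinning"] = ThinningConfig(**raw["thinning"])
        for key in ("delimiter", "seed", "verbosity"):
            if key in raw:
                kwargs[key] = raw[key]
        if "blocked_identifiers" in raw:
            kwargs["blocked_identifiers"] = tuple(raw["blocked_identifiers"])
        return cls(**kwargs)

    def load_kb(self) -> ConceptRuleBook:
        if self.kb_path is not None:
            return ConceptRuleBook.from_csv(self.kb_path)
        return resources.load_concept_rules()

    def load_regions(self):
        if self.region_table_path is not None:
            return read_region_table(self.region_table_path)
        return resources.load_region_table()


class _RunLog:
    def __init__(self) -> None:
        self.lines: list[str] = []

    def stage(self, name: str, **counts: int) -> None:
        rendered = " ".join(f"{k}={v}" for k, v in counts.items())
        line = f"{name}: {rendered}"
        self.lines.append(line)
        logger.info(line)

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n", encoding="utf-8")


def _cleanup(paths: Sequence[Path]) -> None:
    for p in paths:
        try:
            p.unlink(missing_ok=True)
        except OSError:
            pass


def run_audit(cfg: RunConfig) -> dict[str, Path]:
    """Read -> circularity filter -> classify -> matrix + rate tables."""
    if cfg.occurrences is None:
        raise ConfigError("audit needs an occurrence file")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "matrix": out_dir / "classification_matrix.csv",
        "rates_total": out_dir / "rates_total.csv",
        "rates_species": out_dir / "rates_species.csv",
        "rates_uncertainty": out_dir / "rates_uncertainty.csv",
        "classifications": out_dir / "classifications.csv",
        "log": out_dir / "audit_log.txt",
    }
    log = _RunLog()
    try:
        kb = cfg.load_kb()
        regions = cfg.load_regions()
        records = read_occurrences(cfg.occurrences, Dialect(delimiter=cfg.delimiter))
        log.stage("read", rows=len(records))
        kept, excluded = filter_circularity(records, cfg.blocked_identifiers)
        log.stage("circularity_filter", kept=len(kept), excluded_circularity=len(excluded))
        classified = classify_records(kept, kb)
        by_cat: dict[str, int] = {}
        for _, cls_ in classified:
            by_cat[cls_.category] = by_cat.get(cls_.category, 0) + 1
        log.stage("classify", **{k: by_cat[k] for k in sorted(by_cat)})
        full = classified + [
            (rec, ErrorClassification(rec.record_id, CAT_EXCLUDED)) for rec in excluded
        ]
        n_unresolvable = by_cat.get(CAT_UNRESOLVABLE, 0)
        log.stage(
            "accounting",
            input=len(records),
            classified=len(classified) - n_unresolvable,
            unresolvable=n_unresolvable,
            excluded=len(excluded),
        )

        if classified:
            build_matrix(classified).write_csv(outputs["matrix"])
            rate_table(classified, "all").to_csv(outputs["rates_total"])
            rate_table(classified, "species").to_csv(outputs["rates_species"])
            has_region = any(
                rec.country is not None or rec.island_group is not None
                for rec, _ in classified
            )
            if has_region:
                rate_table(classified, "uncertainty_region", regions).to_csv(
                    outputs["rates_uncertainty"]
                )
            else:
                outputs.pop("rates_uncertainty")
        else:
            for key in ("matrix", "rates_total", "rates_species", "rates_uncertainty"):
                outputs[key].write_text("", encoding="utf-8")
        write_classifications(full, outputs["classifications"])
        log.write(outputs["log"])
    except OccAuditError:
        _cleanup(list(outputs.values()))
        raise
    return outputs


def run_merge(cfg: RunConfig) -> dict[str, Path]:
    """Region-filter and thin online records, merge with reviewed points."""
    if cfg.reviewed is None:
        raise ConfigError("merge needs a reviewed occurrence file")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "merged": out_dir / "merged_occurrences.csv",
        "geojson": out_dir / "merged_occurrences.geojson",
        "log": out_dir / "merge_log.txt",
    }
    log = _RunLog()
    try:
        regions = cfg.load_regions()
        dialect = Dialect(delimiter=cfg.delimiter, default_source=SOURCE_REVIEWED)
        reviewed = read_occurrences(cfg.reviewed, dialect)
        online = []
        if cfg.online is not None:
            online_dialect = Dialect(delimiter=cfg.delimiter, default_source=SOURCE_ONLINE)
            online = read_occurrences(cfg.online, online_dialect)
        log.stage("read", reviewed=len(reviewed), online=len(online))
        merged = merge_mixocc(reviewed, online, regions, cfg.thinning)
        n_reviewed_pts = sum(1 for r in merged if r.source == SOURCE_REVIEWED)
        per_species: dict[str, int] = {}
        for rec in merged:
            key = (rec.revised_species or "?").replace(" ", "_")
            per_species[key] = per_species.get(key, 0) + 1
        log.stage(
            "merge",
            merged=len(merged),
            reviewed_points=n_reviewed_pts,
            online_kept=len(merged) - n_reviewed_pts,
            online_dropped=len(online) - (len(merged) - n_reviewed_pts),
        )
        log.stage("per_species", **{k: per_species[k] for k in sorted(per_species)})
        write_occurrences(merged, outputs["merged"], delimiter=cfg.delimiter)
        write_geojson(merged, outputs["geojson"])
        log.write(outputs["log"])
    except OccAuditError:
        _cleanup(list(outputs.values()))
        raise
    return outputs
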