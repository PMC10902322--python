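"""Seeded generator of occurrence databases with known error structure.

Each region carries a species pool; each true species carries a *name
model*: a distribution over emitted verbatim identifications, each tagged
with the category it should be audited into (correct / misidentification /
soft or hard change / not identified).  The revised identification is always
the true species, emulating a full morphological review, so the generator's
per-record truth labels are an exact oracle for the classifier.

Optionally, a per-region log-odds shift scales the total error mass up or
down (holding the mix of error types fixed), which injects a genuine
regional effect for the GLM benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .error_audit import CAT_NOT_IDENTIFIED, NOT_IDENTIFIED_LABEL
from .nomenclature import CAT_CORRECT, CAT_HARD, CAT_MIS, CAT_SOFT, ConceptRuleBook, parse_name
from .occ_model import SOURCE_REVIEWED, OccurrenceRecord

TRUTH_CATEGORIES = (CAT_CORRECT, CAT_MIS, CAT_SOFT, CAT_HARD, CAT_NOT_IDENTIFIED)

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class NameModelEntry:
    """One branch of a species' name distribution."""

    name: str  # emitted verbatim identification; "" for unidentified
    category: str
    p: float

    def __post_init__(self) -> None:
        if self.category not in TRUTH_CATEGORIES:
            raise ConfigError(f"invalid truth category {self.category!r}")
        if not (0.0 <= self.p <= 1.0):
            raise ConfigError(f"probability out of range: {self.p}")
        if (self.category == CAT_NOT_IDENTIFIED) != (self.name == ""):
            raise ConfigError("empty name iff category is not_identified")


@dataclass(frozen=True)
class RegionSpec:
    region_key: str
    species_pool: tuple[str, ...]
    bbox: tuple[float, float, float, float]  # lat_min, lat_max, lon_min, lon_max
    n_records: int
    island_group: str | None = None
    pool_weights: tuple[float, ...] | None = None  # uniform when omitted

    def weights(self) -> np.ndarray:
        if self.pool_weights is None:
            return np.full(len(self.species_pool), 1.0 / len(self.species_pool))
        w = np.asarray(self.pool_weights, dtype=float)
        return w / w.sum()


@dataclass
class GeneratorConfig:
    regions: list[RegionSpec]
    name_models: dict[str, list[NameModelEntry]]
    p_blocked_identifier: float = 0.0
    region_logodds: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    blocked_identifier_name: str = "V. Valcárcel"

    def validate(self) -> None:
        if not self.regions:
            raise ConfigError("at least one region required")
        for species, entries in self.name_models.items():
            total = sum(e.p for e in entries)
            if abs(total - 1.0) > _PROB_TOL:
                raise ConfigError(f"name model for {species!r} sums to {total}, not 1")
        for region in self.regions:
            lat_min, lat_max, lon_min, lon_max = region.bbox
            if not (lat_min < lat_max and lon_min < lon_max):
                raise ConfigError(f"degenerate bbox for region {region.region_key!r}")
            if region.n_records < 0:
                raise ConfigError("n_records must be non-negative")
            for sp in region.species_pool:
                if sp not in self.name_models:
                    raise ConfigError(f"species {sp!r} in pool of {region.region_key!r} "
                                      "has no name model")
            if region.pool_weights is not None and len(region.pool_weights) != len(
                region.species_pool
            ):
                raise ConfigError("pool_weights length mismatch")
        if not (0.0 <= self.p_blocked_identifier <= 1.0):
            raise ConfigError("p_blocked_identifier out of range")

    # -- error-mass adjustment ------------------------------------------------

    def adjusted_model(self, species: str, region_key: str) -> list[NameModelEntry]:
        """Name model with the region's log-odds shift applied to the total
        error probability; the mix of error types is preserved."""
        entries = self.name_models[species]
        shift = self.region_logodds.get(region_key, 0.0)
        if shift == 0.0:
            return list(entries)
        error = sum(e.p for e in entries if e.category != CAT_CORRECT)
        if error <= 0.0 or error >= 1.0:
            return list(entries)
        logit = math.log(error / (1.0 - error)) + shift
        new_error = 1.0 / (1.0 + math.exp(-logit))
        error_scale = new_error / error
        correct_scale = (1.0 - new_error) / (1.0 - error)
        return [
            NameModelEntry(
                e.name,
                e.category,
                e.p * (correct_scale if e.category == CAT_CORRECT else error_scale),
            )
            for e in entries
        ]

    def expected_category_rates(self, species: str) -> dict[str, float]:
        """Exact per-species category probabilities, mixing over regions in
        proportion to the expected number of records generated there."""
        weights, models = [], []
        for region in self.regions:
            if species not in region.species_pool:
                continue
            share = region.weights()[region.species_pool.index(species)]
            weights.append(region.n_records * share)
            models.append(self.adjusted_model(species, region.region_key))
        if not weights:
            raise ConfigError(f"species {species!r} not in any region pool")
        w = np.asarray(weights) / sum(weights)
        rates = {c: 0.0 for c in TRUTH_CATEGORIES}
        for wi, model in zip(w, models):
            for e in model:
                rates[e.category] += wi * e.p
        return rates


def generate(cfg: GeneratorConfig) -> tuple[list[OccurrenceRecord], dict[str, str]]:
    """Generate (records, truth) fully reproducibly from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records: list[OccurrenceRecord] = []
    truth: dict[str, str] = {}
    for region in cfg.regions:
        lat_min, lat_max, lon_min, lon_max = region.bbox
        pool = list(region.species_pool)
        weights = region.weights()
        model_cache = {
            sp: cfg.adjusted_model(sp, region.region_key) for sp in pool
        }
        slug = region.region_key.lower().replace(" ", "_")
        for i in range(region.n_records):
            species = pool[int(rng.choice(len(pool), p=weights))]
            model = model_cache[species]
            probs = np.array([e.p for e in model])
            entry = model[int(rng.choice(len(model), p=probs / probs.sum()))]
            blocked = rng.random() < cfg.p_blocked_identifier
            record_id = f"{slug}-{i:06d}"
            records.append(
                OccurrenceRecord(
                    record_id=record_id,
                    original_name_verbatim=entry.name,
                    revised_species=species,
                    identified_by=cfg.blocked_identifier_name if blocked else "",
                    country=None if region.island_group else region.region_key,
                    island_group=region.island_group,
                    latitude=float(rng.uniform(lat_min, lat_max)),
                    longitude=float(rng.uniform(lon_min, lon_max)),
                    source=SOURCE_REVIEWED,
                )
            )
            truth[record_id] = entry.category
    return records, truth


# -- the benchmark configuration matched to the packaged fixture --------------

_REGION_GEOMETRY: Mapping[str, tuple[tuple[float, float, float, float], str | None]] = {
    "Spain": ((36.0, 43.5, -9.0, 3.0), None),
    "Portugal": ((37.0, 42.0, -9.5, -6.2), None),
    "France": ((43.0, 51.0, -4.5, 7.5), None),
    "United Kingdom": ((50.0, 58.5, -6.0, 1.5), None),
    "Ireland": ((51.5, 55.4, -10.3, -6.0), None),
    "Germany": ((47.4, 55.0, 6.0, 15.0), None),
    "Azores": ((36.9, 39.8, -31.3, -25.0), "Azores"),
    "Madeira": ((32.6, 33.1, -17.3, -16.2), "Madeira"),
    "Canary Islands": ((27.6, 29.5, -18.2, -13.3), "Canary Islands"),
}

#: per-region allocation of records to species, per 2000 records/species
_REGION_ALLOCATIONS: Mapping[str, Mapping[str, int]] = {
    "Azores": {"Hedera azorica": 2000},
    "Canary Islands": {"Hedera canariensis": 2000},
    "Madeira": {"Hedera maderensis": 2000},
    "Germany": {"Hedera helix": 500},
    "France": {"Hedera helix": 500, "Hedera hibernica": 400},
    "United Kingdom": {"Hedera helix": 500, "Hedera hibernica": 400},
    "Ireland": {"Hedera hibernica": 400},
    "Portugal": {"Hedera hibernica": 400, "Hedera iberica": 600},
    "Spain": {"Hedera helix": 500, "Hedera hibernica": 400, "Hedera iberica": 1400},
}

#: log-odds shift of the error rate per congener count (1 / 2 / 3 species)
_LOGODDS_PER_CONGENER_COUNT = {1: -0.5, 2: 0.0, 3: 0.5}


def name_model_from_matrix(matrix, kb: ConceptRuleBook, species: str) -> list[NameModelEntry]:
    """Empirical name distribution of one revised-species column."""
    col_total = matrix.column_total(species)
    entries = []
    for label in matrix.row_labels:
        count = matrix.cell(label, species)
        if count == 0:
            continue
        p = count / col_total
        if label == NOT_IDENTIFIED_LABEL:
            entries.append(NameModelEntry("", CAT_NOT_IDENTIFIED, p))
            continue
        name = parse_name(label)
        rule = kb.lookup(name, species) if name is not None else None
        category = rule.category if rule is not None else CAT_CORRECT
        entries.append(NameModelEntry(label, category, p))
    return entries


def real_structure_config(
    n_per_species: int = 2000, seed: int = 0, regional_effect: bool = True
) -> GeneratorConfig:
    """Benchmark config whose name models equal the packaged fixture's
    empirical per-species rates and whose regions follow the packaged
    congener-count table."""
    from .resources import load_classification_matrix, load_concept_rules, load_region_table

    matrix = load_classification_matrix()
    kb = load_concept_rules()
    region_table = {r.region_key: r for r in load_region_table()}

    name_models = {
        sp: name_model_from_matrix(matrix, kb, sp) for sp in matrix.col_labels
    }
    scale = n_per_species / 2000
    regions = []
    logodds: dict[str, float] = {}
    for key, alloc in _REGION_ALLOCATIONS.items():
        bbox, island = _REGION_GEOMETRY[key]
        pool = tuple(sorted(alloc))
        counts = np.array([alloc[sp] for sp in pool], dtype=float)
        n_records = int(round(counts.sum() * scale))
        regions.append(
            RegionSpec(
                region_key=key,
                species_pool=pool,
                bbox=bbox,
                n_records=n_records,
                island_group=island,
                pool_weights=tuple(float(c) for c in counts / counts.sum()),
            )
        )
        if regional_effect:
            n_sp = region_table[key].n_species if key in region_table else 1
            logodds[key] = _LOGODDS_PER_CONGENER_COUNT[n_sp]
    cfg = GeneratorConfig(
        regions=regions, name_models=name_models, region_logodds=logodds, seed=seed
    )
    cfg.validate()
    return cfg


# -- structured-text config I/O ----------------------------------------------

def config_from_yaml(path: str | Path) -> GeneratorConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        regions = [
            RegionSpec(
                region_key=r["region_key"],
                species_pool=tuple(r["species_pool"]),
                bbox=tuple(r["bbox"]),
                n_records=int(r["n_records"]),
                island_group=r.get("island_group"),
                pool_weights=tuple(r["pool_weights"]) if r.get("pool_weights") else None,
            )
            for r in raw["regions"]
        ]
        name_models = {
            sp: [NameModelEntry(e["name"], e["category"], float(e["p"])) for e in entries]
            for sp, entries in raw["name_models"].items()
        }
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed generator config: {exc}") from exc
    cfg = GeneratorConfig(
        regions=regions,
        name_models=name_models,
        p_blocked_identifier=float(raw.get("p_blocked_identifier", 0.0)),
        region_logodds=dict(raw.get("region_logodds", {})),
        seed=int(raw.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def config_to_yaml(cfg: GeneratorConfig, path: str | Path) -> None:
    payload = {
        "regions": [
            {
                "region_key": r.region_key,
                "species_pool": list(r.species_pool),
                "bbox": [float(v) for v in r.bbox],
                "n_records": int(r.n_records),
                "island_group": r.island_group,
                "pool_weights": (
                    [float(w) for w in r.pool_weights] if r.pool_weights else None
                ),
            }
            for r in cfg.regions
        ],
        "name_models": {
            sp: [{"name": e.name, "category": e.category, "p": e.p} for e in entries]
            for sp, entries in cfg.name_models.items()
        },
        "p_blocked_identifier": cfg.p_blocked_identifier,
        "region_logodds": cfg.region_logodds,
        "seed": cfg.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
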