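"""Loaders for the data files shipped inside the package."""

from __future__ import annotations

from importlib import resources as _ilr
from pathlib import Path

from .error_audit import ClassificationMatrix
from .geo_curate import RegionUncertainty, read_region_table
from .nomenclature import ConceptRuleBook


def data_path(filename: str) -> Path:
    return Path(str(_ilr.files("occaudit").joinpath("data", filename)))


def load_concept_rules() -> ConceptRuleBook:
    """The packaged taxon-concept rule book."""
    return ConceptRuleBook.from_csv(data_path("concept_rules.csv"))


def load_classification_matrix() -> ClassificationMatrix:
    """The packaged reviewed-database classification matrix fixture."""
    return ClassificationMatrix.read_csv(data_path("classification_matrix.csv"))


def load_region_table() -> list[RegionUncertainty]:
    """The packaged region -> congener-count table."""
    return read_region_table(data_path("region_uncertainty.csv"))
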