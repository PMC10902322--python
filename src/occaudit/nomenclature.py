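"""Scientific-name parsing and the taxon-concept rule book.

The rule book maps a (original name, revised species) pair to an error
category describing *why* the two names differ:

``correct``
    same name, same concept.
``misidentification``
    a traceable wrong determination.
``soft_change``
    a nomenclatural difference resolvable without re-examining specimens
    (synonymy, rank change, merge, allopatric split).
``hard_change``
    splitting without spatial segregation, or a historical nomenclatural
    confusion; unresolvable by name harmonization alone.

Categories are shipped as data (``data/concept_rules.csv``) because they
depend on nomenclatural history, not on string structure: the same original
name can be a hard change against one revised species and a plain
misidentification against another.

Infraspecific rank markers (var./subsp./f.) are treated as interchangeable
when matching rules: herbarium labels use them inconsistently for the same
entity, so rules are keyed on (genus, species epithet, infraspecific
epithet) only.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import ConfigError

logger = logging.getLogger(__name__)

CAT_CORRECT = "correct"
CAT_MIS = "misidentification"
CAT_SOFT = "soft_change"
CAT_HARD = "hard_change"

CATEGORIES = (CAT_CORRECT, CAT_MIS, CAT_SOFT, CAT_HARD)

#: change types admissible for each category
CATEGORY_CHANGE_TYPES: Mapping[str, frozenset[str]] = {
    CAT_CORRECT: frozenset({"same_concept"}),
    CAT_MIS: frozenset({"plain_error"}),
    CAT_SOFT: frozenset({"synonym", "rank_change", "merge", "split_allopatric"}),
    CAT_HARD: frozenset({"split_sympatric", "nomenclatural_confusion"}),
}

_RANK_ALIASES = {
    "var": "var",
    "var.": "var",
    "v.": "var",
    "variety": "var",
    "subsp": "subsp",
    "subsp.": "subsp",
    "ssp": "subsp",
    "ssp.": "subsp",
    "subspecies": "subsp",
    "f": "f",
    "f.": "f",
    "fo.": "f",
    "forma": "f",
    "form": "f",
}

#: leading genus abbreviations expanded during parsing
GENUS_EXPANSIONS = {"h.": "Hedera", "h": "Hedera"}

_EPITHET_RE = re.compile(r"^[a-z][a-z\-]*$")


@dataclass(frozen=True)
class TaxonName:
    """A parsed scientific name at species rank or below."""

    genus: str
    specific_epithet: str
    infraspecific_rank: str | None = None  # 'var' | 'subsp' | 'f'
    infraspecific_epithet: str | None = None

    def __post_init__(self) -> None:
        if (self.infraspecific_rank is None) != (self.infraspecific_epithet is None):
            raise ValueError("infraspecific rank and epithet must be present together")

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.specific_epithet}"

    def canonical(self) -> str:
        if self.infraspecific_epithet is None:
            return self.binomial
        return f"{self.binomial} {self.infraspecific_rank}. {self.infraspecific_epithet}"

    def rank_insensitive_key(self) -> tuple[str, str, str | None]:
        """Key that ignores which infraspecific rank marker was used."""
        return (self.genus, self.specific_epithet, self.infraspecific_epithet)

    def matrix_label(self) -> str:
        """Canonical rendering with the rank marker normalized to ``var.``."""
        if self.infraspecific_epithet is None:
            return self.binomial
        return f"{self.binomial} var. {self.infraspecific_epithet}"

    @property
    def is_autonym(self) -> bool:
        return self.infraspecific_epithet == self.specific_epithet


def parse_name(verbatim: str | None) -> TaxonName | None:
    """Parse a verbatim determination; ``None`` for empty/genus-only strings.

    Case-normalizing; strips authorship tokens; expands a leading genus
    abbreviation; normalizes rank markers.  Unparseable input yields ``None``
    with a warning rather than an exception.
    """
    if verbatim is None:
        return None
    text = verbatim.replace("×", " ").strip()
    if not text:
        return None
    tokens = text.split()

    raw_genus = tokens[0]
    genus = GENUS_EXPANSIONS.get(raw_genus.lower(), raw_genus)
    if not genus.replace("-", "").isalpha():
        logger.warning("unparseable name (bad genus token): %r", verbatim)
        return None
    genus = genus[0].upper() + genus[1:].lower()

    if len(tokens) == 1:
        return None  # genus-only determination
    epithet = tokens[1].lower().rstrip(".")
    if epithet in {"sp", "spp", "species", "indet"}:
        return None
    if not _EPITHET_RE.match(epithet):
        logger.warning("unparseable name (bad epithet token): %r", verbatim)
        return None

    rank: str | None = None
    infra: str | None = None
    i = 2
    while i < len(tokens):
        tok = tokens[i]
        alias = _RANK_ALIASES.get(tok.lower())
        if alias is not None and i + 1 < len(tokens):
            cand = tokens[i + 1].lower()
            if _EPITHET_RE.match(cand):
                rank, infra = alias, cand
                i += 2
                continue
        i += 1  # authorship or noise; ignored

    return TaxonName(genus, epithet, rank, infra)


@dataclass(frozen=True)
class ConceptRule:
    original_name: TaxonName
    revised_species: str
    category: str
    change_type: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(f"invalid category {self.category!r}")
        if self.change_type not in CATEGORY_CHANGE_TYPES[self.category]:
            raise ConfigError(
                f"change_type {self.change_type!r} not admissible for category "
                f"{self.category!r}"
            )


class ConceptRuleBook:
    """Validated lookup table of (original name, revised species) -> rule."""

    def __init__(self, rules: list[ConceptRule]):
        self._index: dict[tuple[tuple[str, str, str | None], str], ConceptRule] = {}
        for rule in rules:
            key = (rule.original_name.rank_insensitive_key(), rule.revised_species)
            if key in self._index:
                raise ConfigError(
                    f"duplicate rule for {rule.original_name.canonical()!r} -> "
                    f"{rule.revised_species!r}"
                )
            self._index[key] = rule
        self.rules = list(rules)

    def __len__(self) -> int:
        return len(self.rules)

    def lookup(self, name: TaxonName, revised_species: str) -> ConceptRule | None:
        revised = parse_name(revised_species)
        revised_key = revised.binomial if revised is not None else revised_species
        return self._index.get((name.rank_insensitive_key(), revised_key))

    @classmethod
    def from_csv(cls, path: str | Path, delimiter: str = ",") -> "ConceptRuleBook":
        rules: list[ConceptRule] = []
        with Path(path).open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter=delimiter)
            required = {"original_name", "revised_species", "category", "change_type"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise ConfigError(f"rule table missing columns: {sorted(missing)}")
            for row in reader:
                name = parse_name(row["original_name"])
                if name is None:
                    raise ConfigError(f"unparseable original_name {row['original_name']!r}")
                revised = parse_name(row["revised_species"])
                if revised is None or revised.infraspecific_epithet is not None:
                    raise ConfigError(
                        f"revised_species must be a binomial: {row['revised_species']!r}"
                    )
                rules.append(
                    ConceptRule(
                        original_name=name,
                        revised_species=revised.binomial,
                        category=row["category"].strip(),
                        change_type=row["change_type"].strip(),
                        note=(row.get("note") or "").strip(),
                    )
                )
        return cls(rules)


def names_match_rank_free(name: TaxonName, revised_species: str) -> bool:
    """True when *name* denotes the same species as *revised_species* once
    rank-redundant parts are dropped (binomial equality, allowing the
    autonym infraspecific)."""
    revised = parse_name(revised_species)
    if revised is None:
        return False
    if name.binomial != revised.binomial:
        return False
    return name.infraspecific_epithet is None or name.is_autonym
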