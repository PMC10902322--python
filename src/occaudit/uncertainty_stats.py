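"""Error-rate tables, two-level goodness-of-fit tests, and the error GLM.

The test of record is the one-dimensional two-level chi-squared goodness of
fit against equal expected frequencies::

    chi2 = (a - b)^2 / (a + b)      (1 df, no continuity correction)

Percentages are integer, rounded half-up (54.5% -> 55%).  Significance codes
follow the convention **** <= 1e-4, *** <= 1e-3, ** <= 0.01, * <= 0.05, and
marginal significance (m.s.) at p <= 0.08.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .error_audit import (
    CAT_EXCLUDED,
    CAT_NOT_IDENTIFIED,
    CAT_UNRESOLVABLE,
    INCORRECT_CATEGORIES,
    ErrorClassification,
)
from .errors import DataValidationError
from .geo_curate import RegionUncertainty, assign_uncertainty
from .nomenclature import CAT_HARD, CAT_MIS, CAT_SOFT, parse_name
from .occ_model import OccurrenceRecord

logger = logging.getLogger(__name__)

SIG_THRESHOLDS = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
    (0.08, "m.s."),
)

GROUPINGS = ("all", "uncertainty_region", "species", "country")


def sig_code(p_value: float) -> str:
    for threshold, code in SIG_THRESHOLDS:
        if p_value <= threshold:
            return code
    return "n.s."


def chisq_two_level(a: int, b: int) -> tuple[float, float, str]:
    """Goodness-of-fit of (a, b) against equal frequencies; returns
    (chi2, p, significance code)."""
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0:
        raise DataValidationError("chi-squared test undefined for empty group")
    chi2 = (a - b) ** 2 / (a + b)
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return float(chi2), p, sig_code(p)


def round_pct(count: int, n: int) -> int:
    """Integer percentage of count/n, rounded half-up, in exact arithmetic."""
    if n == 0:
        return 0
    return (200 * count + n) // (2 * n)


RATE_COLUMNS = [
    "n", "n_correct", "n_incorrect", "n_mis", "n_noiden", "n_hard", "n_soft",
    "pct_correct", "pct_incorrect", "pct_mis", "pct_noiden", "pct_hard", "pct_soft",
    "chi2", "p_value", "sig_code",
]


def _group_key(
    rec: OccurrenceRecord,
    grouping: str,
    region_table: Sequence[RegionUncertainty] | None,
) -> str | None:
    if grouping == "all":
        return "total"
    if grouping == "species":
        name = parse_name(rec.revised_species or "")
        return name.binomial if name is not None else rec.revised_species
    if grouping == "country":
        return rec.country
    if grouping == "uncertainty_region":
        if region_table is None:
            raise DataValidationError("uncertainty_region grouping needs a region table")
        if rec.country is None and rec.island_group is None:
            return None  # no region information; excluded from the split
        return assign_uncertainty(rec, region_table).uncertainty
    raise ValueError(f"unknown grouping {grouping!r}")


def rate_table(
    classified: Sequence[tuple[OccurrenceRecord, ErrorClassification]],
    grouping: str = "all",
    region_table: Sequence[RegionUncertainty] | None = None,
) -> pd.DataFrame:
    """Per-group error counts, integer percentages and the two-level test.

    Excluded and unresolvable records never enter the denominators.  Groups
    are rows, sorted by key; ``grouping='all'`` yields the single row
    ``total``.
    """
    groups: dict[str, dict[str, int]] = {}
    for rec, cls_ in classified:
        if cls_.category in (CAT_EXCLUDED, CAT_UNRESOLVABLE):
            continue
        key = _group_key(rec, grouping, region_table)
        if key is None:
            continue
        g = groups.setdefault(
            key, {"n": 0, "n_correct": 0, "n_incorrect": 0, "n_mis": 0,
                  "n_noiden": 0, "n_hard": 0, "n_soft": 0}
        )
        g["n"] += 1
        if cls_.category in INCORRECT_CATEGORIES:
            g["n_incorrect"] += 1
            if cls_.category == CAT_MIS:
                g["n_mis"] += 1
            elif cls_.category == CAT_NOT_IDENTIFIED:
                g["n_noiden"] += 1
            elif cls_.category == CAT_HARD:
                g["n_hard"] += 1
            elif cls_.category == CAT_SOFT:
                g["n_soft"] += 1
        else:
            g["n_correct"] += 1

    rows = []
    for key in sorted(groups):
        g = groups[key]
        chi2, p, code = chisq_two_level(g["n_correct"], g["n_incorrect"])
        rows.append(
            {
                "group": key,
                **g,
                "pct_correct": round_pct(g["n_correct"], g["n"]),
                "pct_incorrect": round_pct(g["n_incorrect"], g["n"]),
                "pct_mis": round_pct(g["n_mis"], g["n"]),
                "pct_noiden": round_pct(g["n_noiden"], g["n"]),
                "pct_hard": round_pct(g["n_hard"], g["n"]),
                "pct_soft": round_pct(g["n_soft"], g["n"]),
                "chi2": chi2,
                "p_value": p,
                "sig_code": code,
            }
        )
    return pd.DataFrame(rows, columns=["group", *RATE_COLUMNS]).set_index("group")


@dataclass
class GlmFit:
    """Binomial (logit) fit of per-record identification error."""

    coefficients: dict[str, tuple[float, float, float]]  # name -> (estimate, SE, p)
    reference_level: str
    separation_flag: bool = False

    def estimate(self, name: str) -> float:
        return self.coefficients[name][0]


def fit_error_glm(
    classified: Sequence[tuple[OccurrenceRecord, ErrorClassification]],
    region_table: Sequence[RegionUncertainty],
) -> GlmFit:
    """Fit ``incorrect ~ species + n_region_species`` with a logit link.

    Species is categorical with the alphabetically first level present as
    reference; the covariate is the number of congeners sharing range
    boundaries in the record's region (1-3).  Suspected complete separation
    is flagged on the fit, never raised.
    """
    rows = []
    for rec, cls_ in classified:
        if cls_.category in (CAT_EXCLUDED, CAT_UNRESOLVABLE):
            continue
        name = parse_name(rec.revised_species or "")
        species = name.binomial if name is not None else rec.revised_species
        if rec.country is None and rec.island_group is None:
            continue
        rows.append(
            {
                "species": species,
                "n_region_species": assign_uncertainty(rec, region_table).n_species,
                "incorrect": int(cls_.category in INCORRECT_CATEGORIES),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or df["species"].nunique() < 2:
        raise DataValidationError("GLM needs records from at least two species")

    reference = sorted(df["species"].unique())[0]
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.glm(
            "incorrect ~ C(species) + n_region_species",
            data=df,
            family=sm.families.Binomial(),
        )
        try:
            result = model.fit()
        except Exception:  # perfect separation can abort IRLS outright
            separation = True
            result = model.fit_regularized(alpha=1e-8)
        for w in caught:
            if "separation" in str(w.message).lower() or "convergence" in str(w.message).lower():
                separation = True

    params = np.asarray(result.params, dtype=float)
    names = list(model.exog_names)
    try:
        bse = np.asarray(result.bse, dtype=float)
        pvalues = np.asarray(result.pvalues, dtype=float)
    except Exception:
        bse = np.full_like(params, np.nan)
        pvalues = np.full_like(params, np.nan)
    if np.nanmax(np.abs(params)) > 15:
        separation = True
    if separation:
        logger.warning("possible complete separation in the error GLM")

    coeffs = {}
    for name, est, se, p in zip(names, params, bse, pvalues):
        clean = name
        if name.startswith("C(species)[T."):
            clean = name[len("C(species)[T."):-1]
        coeffs[clean] = (float(est), float(se), float(p))
    return GlmFit(coefficients=coeffs, reference_level=reference, separation_flag=separation)
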