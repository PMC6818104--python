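"""Population-level summaries of per-death outputs.

Aggregates the per-death results table into the statistics used to
demonstrate the circumstantial-category model at population scale:
cause-specific mortality fractions (CSMFs), COMCAT fractions, sex splits,
person-year mortality rates per stratum, and directly age/sex-standardized
rates.  "Internal" standardization weights each age×sex stratum by the
whole dataset's own person-year distribution (deaths-based internal weights
are also available); the standardized rate is always a convex combination
of stratum rates.

Person-year denominators are supplied by the user (HDSS-style); when they
are absent only fractions are reported — rates are never fabricated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .probbase import COMCAT_ORDER

logger = logging.getLogger(__name__)

BROAD_GROUPS: tuple[str, ...] = (
    "infections",
    "cancer",
    "cardiovascular",
    "other_ncd",
    "injuries",
    "pregnancy_neonatal",
    "indeterminate",
)
UNGROUPED = "ungrouped"


@dataclass(frozen=True)
class Stratum:
    """An age-band × sex × year cell; year may be the pooled token "all"."""

    age_band: str
    sex: str
    year: object = "all"


def outputs_to_frame(outputs: Sequence) -> pd.DataFrame:
    """Flatten DeathOutput objects (or ready-made row dicts) to a DataFrame."""
    rows = [o.to_row() if hasattr(o, "to_row") else dict(o) for o in outputs]
    return pd.DataFrame(rows)


def category_fractions(results: pd.DataFrame, category_field: str) -> dict[str, float]:
    """Fraction of deaths per category — a complete partition summing to 1.

    Derived outcomes ("multiple", "indeterminate") are ordinary categories
    here, so the fractions partition all deaths.
    """
    if results.empty:
        raise ValueError("cannot compute fractions of an empty result set")
    counts = results[category_field].value_counts()
    total = int(counts.sum())
    return {cat: n / total for cat, n in counts.items()}


def sex_fraction_by_category(
    results: pd.DataFrame, category_field: str, sex_value: str
) -> dict[str, float]:
    """Within each category, the fraction of deaths of the given sex.

    Records with unknown sex are excluded from the denominators (with a
    logged count); categories left with zero deaths are omitted.
    """
    known = results[results["sex"].isin(("female", "male"))]
    n_unknown = len(results) - len(known)
    if n_unknown:
        logger.warning("excluding %d records with unknown sex", n_unknown)
    out: dict[str, float] = {}
    for cat, grp in known.groupby(category_field):
        if len(grp):
            out[cat] = float((grp["sex"] == sex_value).mean())
    return out


def count_by_stratum(
    results: pd.DataFrame, category_field: str, by_year: bool = True
) -> dict[tuple[Stratum, str], int]:
    """Death counts per (stratum, category)."""
    counts: dict[tuple[Stratum, str], int] = {}
    for (_, row) in results.iterrows():
        year = row.get("year", "all") if by_year else "all"
        if pd.isna(year) or year == "":
            year = "all"
        s = Stratum(age_band=str(row["age_group"]), sex=str(row["sex"]), year=year)
        key = (s, str(row[category_field]))
        counts[key] = counts.get(key, 0) + 1
    return counts


def stratum_rates(
    counts: Mapping[tuple[Stratum, str], int],
    person_years: Mapping[Stratum, float],
    per: float = 1000.0,
) -> dict[tuple[Stratum, str], float]:
    """Deaths per ``per`` person-years for every (stratum, category).

    A stratum that has deaths but no (or zero) exposure is a hard error —
    a rate cannot be fabricated for it.
    """
    rates: dict[tuple[Stratum, str], float] = {}
    for (stratum, cat), n in counts.items():
        if n < 0:
            raise ValueError(f"negative death count for {stratum}, {cat}")
        py = person_years.get(stratum, 0.0)
        if py <= 0:
            if n > 0:
                raise ValueError(f"deaths observed in stratum with no exposure: {stratum}")
            continue
        rates[(stratum, cat)] = per * n / py
    return rates


def internal_weights(
    person_years: Mapping[Stratum, float], by: str = "person_years"
) -> dict[tuple[str, str], float]:
    """Standard weights over age×sex derived from the dataset itself.

    Collapses years: weight(age, sex) ∝ Σ_year exposure.  ``by`` is kept for
    symmetry with deaths-based weights built via :func:`weights_from_counts`.
    """
    totals: dict[tuple[str, str], float] = {}
    for s, py in person_years.items():
        key = (s.age_band, s.sex)
        totals[key] = totals.get(key, 0.0) + float(py)
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total exposure must be positive")
    return {k: v / grand for k, v in totals.items()}


def weights_from_counts(
    counts: Mapping[tuple[Stratum, str], int]
) -> dict[tuple[str, str], float]:
    """Deaths-based internal weights over age×sex (alternative standard)."""
    totals: dict[tuple[str, str], float] = {}
    for (s, _), n in counts.items():
        key = (s.age_band, s.sex)
        totals[key] = totals.get(key, 0.0) + n
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("no deaths to weight by")
    return {k: v / grand for k, v in totals.items()}


def standardize_rates(
    rates: Mapping[tuple[Stratum, str], float],
    standard_weights: Mapping[tuple[str, str], float],
) -> dict[str, float]:
    """Direct standardization: Σ weight(age, sex) × rate(age, sex, category).

    Weights must be non-negative and sum to 1 (±1e-9).  Rates are first
    pooled over years within each age×sex cell (exposure-free mean); an
    age×sex cell with a weight but no rate contributes 0 with a warning.
    The result is a convex combination, so it lies within [min, max] of the
    stratum rates for each category.
    """
    for k, w in standard_weights.items():
        if w < 0:
            raise ValueError(f"negative standard weight for {k}")
    total_w = sum(standard_weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"standard weights must sum to 1, got {total_w}")

    # pool over years: mean rate per (age, sex, category)
    pooled: dict[tuple[str, str, str], list[float]] = {}
    for (s, cat), r in rates.items():
        pooled.setdefault((s.age_band, s.sex, cat), []).append(r)
    categories = sorted({cat for (_, _, cat) in pooled})
    out: dict[str, float] = {}
    for cat in categories:
        acc = 0.0
        for (age, sex), w in standard_weights.items():
            cell = pooled.get((age, sex, cat))
            if cell is None:
                logger.warning("no rate for stratum (%s, %s), category %s; using 0", age, sex, cat)
                rate = 0.0
            else:
                rate = sum(cell) / len(cell)
            acc += w * rate
        out[cat] = acc
    return out


def comcat_by_cause_ranking(
    results: pd.DataFrame,
    cause_field: str = "broad_cause",
    comcat_field: str = "comcat",
) -> dict[str, list[tuple[str, int, float]]]:
    """Per broad cause group, COMCATs ranked by descending death count.

    Ties break by the canonical COMCAT order (traditions, emergencies,
    recognition, resources, health_systems, inevitability, multiple), so the
    ranking is stable and reproducible.
    """
    rankings: dict[str, list[tuple[str, int, float]]] = {}
    for group, grp in results.groupby(cause_field):
        counts = grp[comcat_field].value_counts().to_dict()
        total = len(grp)
        order = sorted(
            counts,
            key=lambda c: (
                -counts[c],
                COMCAT_ORDER.index(c) if c in COMCAT_ORDER else len(COMCAT_ORDER),
            ),
        )
        rankings[str(group)] = [(c, counts[c], counts[c] / total) for c in order]
    return rankings


def broad_cause_grouping(cause_label: str, grouping_table: Mapping[str, str]) -> str:
    """Map a specific cause label to its broad group; unmapped → "ungrouped"."""
    group = grouping_table.get(cause_label)
    if group is None:
        logger.warning("cause label %r not in grouping table; marking ungrouped", cause_label)
        return UNGROUPED
    return group


def add_broad_cause(
    results: pd.DataFrame,
    grouping_table: Mapping[str, str],
    cause_field: str = "cause1",
    out_field: str = "broad_cause",
) -> pd.DataFrame:
    """Attach a broad-cause column; blank top cause means indeterminate."""
    results = results.copy()

    def _map(label) -> str:
        if pd.isna(label) or str(label) == "":
            return "indeterminate"
        return broad_cause_grouping(str(label), grouping_table)

    results[out_field] = results[cause_field].map(_map)
    return results


def load_person_years(path: str | Path) -> dict[Stratum, float]:
    """Read per-stratum exposure from CSV (age_band, sex, year, person_years)."""
    df = pd.read_csv(path)
    required = {"age_band", "sex", "year", "person_years"}
    if not required.issubset(df.columns):
        raise ValueError(f"person-years CSV must have columns {sorted(required)}")
    out: dict[Stratum, float] = {}
    for _, row in df.iterrows():
        year = row["year"]
        if not isinstance(year, str):
            year = int(year)
        out[Stratum(str(row["age_band"]), str(row["sex"]), year)] = float(row["person_years"])
    return out


def load_grouping_table(path: str | Path) -> dict[str, str]:
    """Read a cause_label → broad_group mapping from CSV."""
    df = pd.read_csv(path)
    if not {"cause_label", "broad_group"}.issubset(df.columns):
        raise ValueError("grouping CSV must have columns cause_label, broad_group")
    return dict(zip(df["cause_label"].astype(str), df["broad_group"].astype(str)))


#: Editable starter mapping from common WHO-2016 VA cause labels to the
#: seven broad groups; users supply their own table for full cause lists.
DEFAULT_BROAD_CAUSE_TABLE: dict[str, str] = {
    "HIV/AIDS related death": "infections",
    "Pulmonary tuberculosis": "infections",
    "Malaria": "infections",
    "Acute respiratory infection incl pneumonia": "infections",
    "Diarrhoeal diseases": "infections",
    "Meningitis and encephalitis": "infections",
    "Sepsis (non-obstetric)": "infections",
    "Digestive neoplasms": "cancer",
    "Respiratory neoplasms": "cancer",
    "Breast neoplasms": "cancer",
    "Reproductive neoplasms MF": "cancer",
    "Other and unspecified neoplasms": "cancer",
    "Acute cardiac disease": "cardiovascular",
    "Stroke": "cardiovascular",
    "Other and unspecified cardiac disease": "cardiovascular",
    "Diabetes mellitus": "other_ncd",
    "Chronic obstructive pulmonary disease": "other_ncd",
    "Asthma": "other_ncd",
    "Renal failure": "other_ncd",
    "Liver cirrhosis": "other_ncd",
    "Epilepsy": "other_ncd",
    "Other and unspecified non-communicable disease": "other_ncd",
    "Road traffic accident": "injuries",
    "Accidental fall": "injuries",
    "Accidental drowning and submersion": "injuries",
    "Assault": "injuries",
    "Intentional self-harm": "injuries",
    "Other and unspecified external cause of death": "injuries",
    "Obstetric haemorrhage": "pregnancy_neonatal",
    "Pregnancy-induced hypertension": "pregnancy_neonatal",
    "Pregnancy-related sepsis": "pregnancy_neonatal",
    "Prematurity": "pregnancy_neonatal",
    "Birth asphyxia": "pregnancy_neonatal",
    "Neonatal sepsis": "pregnancy_neonatal",
    "indeterminate": "indeterminate",
}


def plot_standardized_rates(
    standardized: Mapping[str, float], path: str | Path, title: str = "Standardized rates"
) -> None:
    """Write a simple bar chart of standardized rates per category (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = list(standardized)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(cats, [standardized[c] for c in cats])
    ax.set_ylabel("deaths per 1,000 person-years (standardized)")
    ax.set_title(title)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
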