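"""The probability base ("probbase") driving InterVA-style inference.

A probbase couples a category set (medical causes, or the six circumstantial
categories of mortality — COMCATs) with a prior over categories and a matrix
of conditional probabilities P(response | category) for each substantive
(indicator, yes/no) pair.  The engine multiplies these naive-Bayes style.

The real InterVA-5 matrices were elicited by expert consensus and are not
reproduced here; this module handles any user-supplied probbase CSV and
ships a clearly synthetic illustrative COMCAT matrix for demonstrations.

CSV format
----------
``indicator,response,cat1,...,catK`` with one reserved row
``_prior,,p1,...,pK`` for the prior.  ``response`` is ``yes`` or ``no``; the
``no`` row for an indicator may be omitted, in which case NO responses to
that indicator are non-informative (skipped like MISSING).  Cells may be
grade symbols resolved through a user-supplied symbol table; no default
symbol mapping exists, so numbers are never invented for an author's grades.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .va_records import CIRCUMSTANTIAL_IDS, IndicatorDef, IndicatorDictionary

PRIOR_TOKEN = "_prior"

#: Canonical order of the six assignable COMCATs plus the derived seventh.
#: "multiple" is a decision-rule outcome (no single category dominates),
#: never a probbase column.
COMCAT_LABELS: tuple[str, ...] = (
    "traditions",
    "emergencies",
    "recognition",
    "resources",
    "health_systems",
    "inevitability",
)
MULTIPLE_LABEL = "multiple"
COMCAT_ORDER: tuple[str, ...] = COMCAT_LABELS + (MULTIPLE_LABEL,)

#: Number of cause-of-death output slots in the WHO-2016 cause set,
#: including the derived "indeterminate" residual.
WHO2016_N_CAUSE_SLOTS = 64
INDETERMINATE_LABEL = "indeterminate"


@dataclass(frozen=True)
class CategorySet:
    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("category set must have at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("category labels must be unique")
        if any(not lab for lab in self.labels):
            raise ValueError("category labels must be non-empty")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ProbBaseLoadReport:
    prior_sum_before_normalization: float = 1.0
    symbol_resolved_cells: int = 0


@dataclass
class ProbBase:
    """Priors and conditional response probabilities for one category set.

    ``cond`` maps ``(indicator_id, response)`` — response in {"yes", "no"} —
    to a mapping category → probability in [0, 1].  Rectangularity holds:
    every present (indicator, response) row covers every category.
    """

    category_set: CategorySet
    prior: dict[str, float]
    cond: dict[tuple[str, str], dict[str, float]]
    load_report: ProbBaseLoadReport = field(default_factory=ProbBaseLoadReport)

    def __post_init__(self) -> None:
        labels = self.category_set.labels
        if set(self.prior) != set(labels):
            raise ValueError("prior must cover exactly the category set")
        for cat, p in self.prior.items():
            if p < 0:
                raise ValueError(f"negative prior mass for {cat}: {p!r}")
        for (ind, resp), row in self.cond.items():
            if resp not in ("yes", "no"):
                raise ValueError(f"response must be 'yes' or 'no', got {resp!r}")
            if set(row) != set(labels):
                raise ValueError(
                    f"ragged probbase: row ({ind}, {resp}) does not cover all categories"
                )
            for cat, p in row.items():
                _check_probability(p, f"({ind}, {resp}, {cat})")
        self.normalize_prior()

    def normalize_prior(self) -> float:
        """Normalize the prior to sum to 1; returns the pre-normalization sum.

        Idempotent: normalizing twice changes nothing.
        """
        total = sum(self.prior.values())
        if total <= 0:
            raise ValueError("prior mass must be positive")
        if abs(total - 1.0) > 1e-12:
            for cat in self.prior:
                self.prior[cat] /= total
        return total

    @property
    def indicator_ids(self) -> list[str]:
        seen: list[str] = []
        for ind, _ in self.cond:
            if ind not in seen:
                seen.append(ind)
        return seen

    def get(self, indicator_id: str, response: str) -> dict[str, float] | None:
        return self.cond.get((indicator_id, response))

    def __eq__(self, other) -> bool:
        # category-set *name* is cosmetic and not stored in the CSV format,
        # so equality (and the write→load round trip) ignores it
        if not isinstance(other, ProbBase):
            return NotImplemented
        return (
            self.category_set.labels == other.category_set.labels
            and self.prior == other.prior
            and self.cond == other.cond
        )


def _check_probability(value: float, where: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"probability out of range at {where}: {value!r}")


def _resolve_cell(
    token: str,
    symbol_table: Mapping[str, float] | None,
    report: ProbBaseLoadReport,
    where: str,
) -> float:
    token = str(token).strip()
    try:
        value = float(token)
    except ValueError:
        if symbol_table is not None and token in symbol_table:
            report.symbol_resolved_cells += 1
            value = float(symbol_table[token])
        else:
            raise ValueError(f"unresolvable symbol {token!r} at {where}") from None
    _check_probability(value, where)
    return value


def load_probbase(
    path: str | Path | io.StringIO,
    symbol_table: Mapping[str, float] | None = None,
    name: str = "categories",
) -> ProbBase:
    """Load a probbase CSV; validates ranges, rectangularity, prior."""
    df = pd.read_csv(path, dtype=str)
    required = {"indicator", "response"}
    if not required.issubset(df.columns):
        raise ValueError("probbase CSV must have 'indicator' and 'response' columns")
    cat_cols = [c for c in df.columns if c not in ("indicator", "response")]
    if not cat_cols:
        raise ValueError("probbase CSV has no category columns")
    if df.isna().any(axis=None) and df[cat_cols].isna().any(axis=None):
        raise ValueError("ragged probbase CSV: empty cells in category columns")

    report = ProbBaseLoadReport()
    category_set = CategorySet(name=name, labels=tuple(cat_cols))
    prior: dict[str, float] | None = None
    cond: dict[tuple[str, str], dict[str, float]] = {}
    for _, row in df.iterrows():
        ind = str(row["indicator"]).strip()
        if ind == PRIOR_TOKEN:
            # prior cells need not sum to 1; the loader normalizes
            prior = {
                c: _resolve_cell(row[c], symbol_table, report, f"(_prior, {c})")
                for c in cat_cols
            }
            continue
        resp = str(row["response"]).strip().lower()
        if resp not in ("yes", "no"):
            raise ValueError(f"response must be 'yes' or 'no' at indicator {ind!r}")
        key = (ind, resp)
        if key in cond:
            raise ValueError(f"duplicate probbase row for {key}")
        cond[key] = {
            c: _resolve_cell(row[c], symbol_table, report, f"({ind}, {resp}, {c})")
            for c in cat_cols
        }
    if prior is None:
        raise ValueError(f"probbase CSV lacks the {PRIOR_TOKEN!r} prior row")
    report.prior_sum_before_normalization = sum(prior.values())
    pb = ProbBase(category_set=category_set, prior=prior, cond=cond, load_report=report)
    return pb


def write_probbase(pb: ProbBase, path: str | Path) -> None:
    """Write a probbase to the CSV format load_probbase reads (round trips)."""
    cols = list(pb.category_set.labels)
    rows = [{"indicator": PRIOR_TOKEN, "response": "",
             **{c: repr(float(pb.prior[c])) for c in cols}}]
    for (ind, resp), row in pb.cond.items():
        rows.append({"indicator": ind, "response": resp,
                     **{c: repr(float(row[c])) for c in cols}})
    pd.DataFrame(rows, columns=["indicator", "response", *cols]).to_csv(path, index=False)


@dataclass
class ProbBaseValidationReport:
    """Alignment and degeneracy diagnostics; reporting only, never fatal."""

    indicators_not_in_dictionary: list[str] = field(default_factory=list)
    indicators_not_in_probbase: list[str] = field(default_factory=list)
    unreachable_categories: list[str] = field(default_factory=list)
    constant_rows: list[tuple[str, str]] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (
            self.indicators_not_in_dictionary
            or self.indicators_not_in_probbase
            or self.unreachable_categories
            or self.constant_rows
        )


def validate_probbase(pb: ProbBase, dictionary: IndicatorDictionary) -> ProbBaseValidationReport:
    """Cross-check a probbase against an indicator dictionary.

    Flags indicators on one side only, categories no response supports
    (posterior mass would always be zero) and non-discriminative
    all-constant rows.
    """
    report = ProbBaseValidationReport()
    dict_ids = set(dictionary.ids)
    pb_ids = set(pb.indicator_ids)
    report.indicators_not_in_dictionary = sorted(pb_ids - dict_ids)
    report.indicators_not_in_probbase = sorted(dict_ids - pb_ids)
    for cat in pb.category_set.labels:
        if pb.cond and all(row[cat] == 0.0 for row in pb.cond.values()):
            report.unreachable_categories.append(cat)
    for key, row in pb.cond.items():
        if len(set(row.values())) == 1:
            report.constant_rows.append(key)
    return report


# --- built-in reference fixtures -------------------------------------------

_CIRCUMSTANTIAL_ITEMS: tuple[tuple[str, str, str], ...] = (
    (
        "Id10450",
        "In the final days before death, did she/he travel to a hospital or health facility?",
        "'no' indicates no contact with hospital-level services in the final days",
    ),
    (
        "Id10451",
        "Did she/he use motorised transport to get to the hospital or health facility?",
        "'no' indicates no motorised transport to a facility during the final illness",
    ),
    (
        "Id10452",
        "Were there any problems during admission to the hospital or health facility?",
        "'yes' indicates problems on arrival (delays, paperwork, queues, no staff)",
    ),
    (
        "Id10453",
        "Were there any problems with the way she/he was treated in the hospital or health facility?",
        "'yes' indicates problems with treatment, procedures or interpersonal respect",
    ),
    (
        "Id10454",
        "Were there any problems getting medications, or diagnostic tests in the hospital or health facility?",
        "'yes' indicates problems obtaining drugs, blood products or diagnostic tests",
    ),
    (
        "Id10455",
        "Does it take more than 2 hours to get to the nearest hospital or health facility from the deceased's household?",
        "'yes' indicates the household is more than 2 hours from a 24-hour facility",
    ),
    (
        "Id10456",
        "In the final days before death, were there any doubts about whether medical care was needed?",
        "'yes' indicates doubts among carers whether treatment was needed",
    ),
    (
        "Id10457",
        "In the final days before death, was traditional medicine used?",
        "'yes' indicates a major part of final-illness treatment was traditional/alternative",
    ),
    (
        "Id10458",
        "In the final days before death, did anyone use a telephone or cell phone to call for help?",
        "'no' indicates no telephone was used to call for help in the final 24 hours",
    ),
    (
        "Id10459",
        "Over the course of illness, did the total costs of care and treatment prohibit other household payments?",
        "'yes' indicates catastrophic care costs crowding out other household expenses",
    ),
)


def make_reference_comcat_dictionary() -> tuple[IndicatorDictionary, CategorySet]:
    """The ten WHO-2016 circumstantial indicators and the six COMCAT labels.

    The labels use the revised names ('traditions', 'recognition') rather
    than the earlier 'culture'/'knowledge'.
    """
    dictionary = IndicatorDictionary(
        IndicatorDef(id=i, text=t, note=n) for i, t, n in _CIRCUMSTANTIAL_ITEMS
    )
    assert all(i in dictionary for i in CIRCUMSTANTIAL_IDS)
    return dictionary, CategorySet(name="comcats", labels=COMCAT_LABELS)


# Synthetic illustrative COMCAT matrix.  Each row gives P(yes | category) for
# one circumstantial item; NO rows are the complements.  Values are invented
# for demonstration and testing only — they reflect the items' substantive-
# response polarity (e.g. traditional-medicine use points to 'traditions',
# facility-level problems to 'health_systems'), not any expert consensus.
_SYNTHETIC_P_YES: dict[str, tuple[float, ...]] = {
    # (traditions, emergencies, recognition, resources, health_systems, inevitability)
    "Id10450": (0.30, 0.25, 0.30, 0.25, 0.90, 0.45),  # travelled to facility
    "Id10451": (0.25, 0.30, 0.30, 0.15, 0.80, 0.40),  # motorised transport
    "Id10452": (0.05, 0.05, 0.05, 0.10, 0.70, 0.05),  # admission problems
    "Id10453": (0.05, 0.05, 0.05, 0.08, 0.65, 0.05),  # treatment problems
    "Id10454": (0.05, 0.05, 0.05, 0.12, 0.70, 0.06),  # drugs/tests problems
    "Id10455": (0.20, 0.15, 0.20, 0.70, 0.15, 0.15),  # >2h to facility
    "Id10456": (0.25, 0.10, 0.85, 0.20, 0.10, 0.15),  # doubts care was needed
    "Id10457": (0.90, 0.05, 0.20, 0.15, 0.08, 0.10),  # traditional medicine
    "Id10458": (0.40, 0.75, 0.35, 0.25, 0.55, 0.35),  # phoned for help
    "Id10459": (0.25, 0.10, 0.20, 0.80, 0.25, 0.15),  # catastrophic costs
}


def make_synthetic_comcat_probbase() -> ProbBase:
    """A synthetic COMCAT probbase over the ten circumstantial items.

    Uniform prior over the six categories (whether the real sub-model uses
    distinct priors is unstated; uniform is this package's documented
    default).  Suitable for demonstrations and pipeline tests; makes no
    claim to match the expert-consensus matrix.
    """
    _, cats = make_reference_comcat_dictionary()
    prior = {c: 1.0 / len(cats) for c in cats.labels}
    cond: dict[tuple[str, str], dict[str, float]] = {}
    for ind, p_yes in _SYNTHETIC_P_YES.items():
        cond[(ind, "yes")] = dict(zip(cats.labels, p_yes))
        cond[(ind, "no")] = {c: 1.0 - p for c, p in zip(cats.labels, p_yes)}
    return ProbBase(category_set=cats, prior=prior, cond=cond)
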