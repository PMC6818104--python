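"""Synthetic probbases and VA datasets with known generating structure.

Every other module is testable without external data: a scenario fixes a
category mixture, a probbase sharpness, a missingness rate and demographic
mixtures, and the generator draws records whose responses are conditionally
independent given the true category — exactly the naive-Bayes assumption
the engine makes, so recovery experiments measure the engine rather than
model misspecification.  A pairwise response-correlation toggle breaks that
assumption deliberately for robustness experiments.

All randomness flows through one seeded NumPy generator per operation,
derived from the scenario seed; identical scenarios produce byte-identical
CSV bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes_engine import DeathOutput
from .probbase import COMCAT_LABELS, MULTIPLE_LABEL, CategorySet, ProbBase
from .va_records import (
    DEFAULT_AGE_BANDS,
    IndicatorDef,
    IndicatorDictionary,
    Response,
    VARecord,
)

_MIX_TOL = 1e-9


def _default_demographics() -> dict[tuple[str, str, int], float]:
    """Uniform mixture over the five default age bands × two sexes, one year."""
    cells = [(a, s, 2015) for a in DEFAULT_AGE_BANDS for s in ("female", "male")]
    return {c: 1.0 / len(cells) for c in cells}


@dataclass
class ScenarioSpec:
    """A fully-specified synthetic study.

    ``sharpness`` (>= 1) multiplies the odds of a YES on each category's
    signature indicators: 1 means every category column is identical (no
    signal at all), large values make categories nearly separable.
    ``response_correlation`` optionally copies each response from the
    previous indicator with the given probability, violating conditional
    independence.
    """

    category_mixture: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 / len(COMCAT_LABELS) for c in COMCAT_LABELS}
    )
    n_records: int = 500
    sharpness: float = 20.0
    missingness: float = 0.1
    demographics: dict[tuple[str, str, int], float] = field(
        default_factory=_default_demographics
    )
    seed: int = 0
    response_correlation: float = 0.0

    def __post_init__(self) -> None:
        for label, mix in (("category_mixture", self.category_mixture),
                           ("demographics", self.demographics)):
            if any(not (0.0 <= p <= 1.0) for p in mix.values()):
                raise ValueError(f"{label} probabilities must lie in [0, 1]")
            if abs(sum(mix.values()) - 1.0) > _MIX_TOL:
                raise ValueError(f"{label} must sum to 1")
        if self.sharpness < 1.0:
            raise ValueError("sharpness must be >= 1")
        if not (0.0 <= self.missingness <= 1.0):
            raise ValueError("missingness must lie in [0, 1]")
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.category_mixture)


def make_indicator_dictionary(n_indicators: int) -> IndicatorDictionary:
    """Generic synthetic indicator ids X0001…; dialect-free."""
    return IndicatorDictionary(
        IndicatorDef(id=f"X{k:04d}", text=f"synthetic indicator {k}")
        for k in range(1, n_indicators + 1)
    )


def generate_probbase(spec: ScenarioSpec, n_indicators: int) -> ProbBase:
    """Draw a probbase in which each category has signature indicators.

    Indicator k's baseline YES probability is drawn uniformly on
    [0.1, 0.4]; for its signature category (round-robin, so categories get
    ~n/K signatures each) the YES odds are multiplied by ``sharpness``.
    With sharpness=1 every category column is identical.  NO rows are the
    complements, so negative responses are informative too.  Deterministic
    under the scenario seed.
    """
    if n_indicators < 1:
        raise ValueError("n_indicators must be >= 1")
    rng = np.random.default_rng([spec.seed, 0])
    cats = spec.categories
    prior = dict(spec.category_mixture)
    cond: dict[tuple[str, str], dict[str, float]] = {}
    base = rng.uniform(0.1, 0.4, size=n_indicators)
    for k in range(n_indicators):
        ind = f"X{k + 1:04d}"
        signature = cats[k % len(cats)]
        odds0 = float(base[k]) / (1.0 - float(base[k]))
        p_yes: dict[str, float] = {}
        for c in cats:
            odds = odds0 * (spec.sharpness if c == signature else 1.0)
            p_yes[c] = odds / (1.0 + odds)
        cond[(ind, "yes")] = p_yes
        cond[(ind, "no")] = {c: 1.0 - p for c, p in p_yes.items()}
    return ProbBase(
        category_set=CategorySet(name="synthetic", labels=cats),
        prior=prior,
        cond=cond,
    )


def generate_records(
    spec: ScenarioSpec, pb: ProbBase, dictionary: IndicatorDictionary
) -> tuple[list[VARecord], pd.DataFrame]:
    """Draw records from the probbase's generating process plus a truth table.

    Per record: a true category from the mixture; each indicator YES with
    probability P(yes | true category), else NO; missingness applied
    independently per response; demographics from the demographic mixture.
    The truth table maps record_id → true category.
    """
    ids = [i for i in dictionary.ids if (i, "yes") in pb.cond]
    if set(ids) != set(pb.indicator_ids):
        raise ValueError("probbase and dictionary indicators are not aligned")
    rng = np.random.default_rng([spec.seed, 1])
    cats = list(spec.categories)
    cat_p = np.array([spec.category_mixture[c] for c in cats])
    demo_cells = list(spec.demographics)
    demo_p = np.array([spec.demographics[c] for c in demo_cells])

    records: list[VARecord] = []
    truth_rows: list[dict[str, object]] = []
    n_digits = max(5, len(str(spec.n_records)))
    for i in range(spec.n_records):
        true_cat = cats[rng.choice(len(cats), p=cat_p)]
        age, sex, year = demo_cells[rng.choice(len(demo_cells), p=demo_p)]
        responses: dict[str, Response] = {}
        prev = Response.NO
        for ind in ids:
            if spec.response_correlation > 0 and rng.random() < spec.response_correlation:
                resp = prev
            else:
                p = pb.cond[(ind, "yes")][true_cat]
                resp = Response.YES if rng.random() < p else Response.NO
            prev = resp
            if spec.missingness > 0 and rng.random() < spec.missingness:
                resp = Response.MISSING
            responses[ind] = resp
        rid = f"S{i + 1:0{n_digits}d}"
        records.append(
            VARecord(record_id=rid, responses=responses, age_group=age, sex=sex, year=year)
        )
        truth_rows.append({"record_id": rid, "true_category": true_cat})
    truth = pd.DataFrame(truth_rows, columns=["record_id", "true_category"])
    return records, truth


def records_to_frame(records: Sequence[VARecord], dictionary: IndicatorDictionary) -> pd.DataFrame:
    """Wide CSV-shaped frame for a record list (inverse of read_va_csv)."""
    token = {Response.YES: "y", Response.NO: "n", Response.MISSING: ""}
    rows = []
    for r in records:
        row: dict[str, object] = {
            "record_id": r.record_id,
            "age_group": r.age_group,
            "sex": r.sex,
            "year": "" if r.year is None else r.year,
        }
        for ind in dictionary.ids:
            row[ind] = token[r.responses.get(ind, Response.MISSING)]
        rows.append(row)
    cols = ["record_id", "age_group", "sex", "year", *dictionary.ids]
    return pd.DataFrame(rows, columns=cols)


def save_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    """Serialize a scenario to YAML (stable key order for reproducibility)."""
    payload = {
        "category_mixture": dict(spec.category_mixture),
        "n_records": spec.n_records,
        "sharpness": spec.sharpness,
        "missingness": spec.missingness,
        "demographics": [
            {"age_band": a, "sex": s, "year": int(y), "prob": p}
            for (a, s, y), p in spec.demographics.items()
        ],
        "seed": spec.seed,
        "response_correlation": spec.response_correlation,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_scenario(path: str | Path) -> ScenarioSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    kwargs = dict(payload)
    if "demographics" in kwargs:
        kwargs["demographics"] = {
            (d["age_band"], d["sex"], int(d["year"])): float(d["prob"])
            for d in kwargs["demographics"]
        }
    return ScenarioSpec(**kwargs)


@dataclass
class RecoveryReport:
    """How well assigned categories recover the generating truth.

    ``accuracy`` is over assignments that are not "multiple" (None when every
    assignment was "multiple"); ``multiple_rate`` is the fraction assigned
    "multiple".
    """

    confusion: pd.DataFrame
    accuracy: float | None
    multiple_rate: float

    @property
    def n(self) -> int:
        return int(self.confusion.to_numpy().sum())


def evaluate_recovery(outputs: Sequence[DeathOutput], truth: pd.DataFrame) -> RecoveryReport:
    """Confusion matrix (truth × assigned incl. "multiple") and summary rates."""
    assigned = {o.record_id: o.comcat.assigned for o in outputs}
    truth_map = dict(zip(truth["record_id"], truth["true_category"]))
    if set(assigned) != set(truth_map):
        raise ValueError("outputs and truth table do not share the same record ids")
    true_labels = list(dict.fromkeys(truth["true_category"]))
    assigned_labels = true_labels + [MULTIPLE_LABEL]
    confusion = pd.DataFrame(
        0, index=pd.Index(true_labels, name="true"),
        columns=pd.Index(assigned_labels, name="assigned"), dtype=int,
    )
    n_correct = 0
    n_decided = 0
    n_multiple = 0
    for rid, t in truth_map.items():
        a = assigned[rid]
        if a not in confusion.columns:
            confusion[a] = 0
        confusion.loc[t, a] += 1
        if a == MULTIPLE_LABEL:
            n_multiple += 1
        else:
            n_decided += 1
            n_correct += a == t
    total = len(truth_map)
    return RecoveryReport(
        confusion=confusion,
        accuracy=(n_correct / n_decided) if n_decided else None,
        multiple_rate=n_multiple / total if total else 0.0,
    )
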