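"""Per-death Bayesian classification over a category set.

The model is the InterVA family's naive-Bayes update: for each category c,

    mass(c) = prior(c) * prod over substantive responses r of P(r | c)

with the product taken over the responses for which the probbase supplies a
conditional row, and the masses normalized at the end.  MISSING responses
and responses with no matching probbase row contribute no factor.  Two
assignment rules sit on top:

* COMCATs (circumstantial categories): the dominant category is assigned
  only when its likelihood strictly exceeds the threshold (default 50%);
  otherwise the derived "multiple" category applies.
* Causes: the top categories are reported in descending likelihood down to
  a reporting threshold; the remaining mass is the indeterminate residual.

Products are accumulated in log space whenever any conditional factor is
below 1e-12, so records with hundreds of indicators cannot underflow; the
switch does not change results beyond float rounding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

from .probbase import MULTIPLE_LABEL, CategorySet, ProbBase
from .va_records import Response, VARecord

logger = logging.getLogger(__name__)

_LOG_SWITCH = 1e-12
_NORM_TOL = 1e-9


@dataclass
class PosteriorDistribution:
    """Normalized per-death likelihoods over a category set.

    ``degenerate`` is True iff the total unnormalized mass was zero (every
    category annihilated by a zero factor); the likelihoods are then all 0.
    ``updates_applied`` counts the substantive responses that contributed a
    factor.
    """

    category_set: CategorySet
    likelihood: dict[str, float]
    degenerate: bool = False
    updates_applied: int = 0

    def argmax(self) -> tuple[str, float]:
        """Highest-likelihood category; ties broken by category-set order."""
        best = max(self.category_set.labels, key=lambda c: self.likelihood[c])
        return best, self.likelihood[best]


@dataclass
class ComcatAssignment:
    """Dominant circumstantial category, or "multiple" when none dominates."""

    assigned: str
    distribution: PosteriorDistribution


@dataclass
class CauseAssignment:
    """Ranked causes above the reporting threshold plus the residual.

    Ranked likelihoods and ``indeterminate_residual`` sum to 1 for
    non-degenerate inputs; a degenerate posterior is fully indeterminate.
    """

    ranked: list[tuple[str, float]]
    indeterminate_residual: float


def compute_posterior(record: VARecord, pb: ProbBase) -> PosteriorDistribution:
    """Naive-Bayes posterior for one record under one probbase.

    Each substantive (YES/NO) response with a matching probbase row
    multiplies every category's mass by P(response | category); the result
    is normalized once at the end, so the posterior is invariant to response
    order and to rescaling any conditional row by a positive constant.
    """
    labels = pb.category_set.labels
    if not labels:
        raise ValueError("empty category set")

    factor_rows: list[list[float]] = []
    updates = 0
    for ind, resp in sorted(record.substantive().items()):
        row = pb.get(ind, "yes" if resp is Response.YES else "no")
        if row is None:
            continue
        factor_rows.append([row[c] for c in labels])
        updates += 1

    prior = [pb.prior[c] for c in labels]

    def _log_space_mass() -> list[float]:
        logmass = []
        for j, p in enumerate(prior):
            if p == 0.0 or any(frow[j] == 0.0 for frow in factor_rows):
                logmass.append(-math.inf)
            else:
                logmass.append(math.log(p) + sum(math.log(frow[j]) for frow in factor_rows))
        peak = max(logmass)
        if peak == -math.inf:
            return [0.0] * len(labels)
        return [math.exp(lm - peak) for lm in logmass]

    if any(f < _LOG_SWITCH for frow in factor_rows for f in frow):
        mass = _log_space_mass()
    else:
        mass = list(prior)
        for frow in factor_rows:
            mass = [m * f for m, f in zip(mass, frow)]
        if sum(mass) == 0.0:
            # product of many moderate factors underflowed; redo in log space
            mass = _log_space_mass()

    total = sum(mass)
    if total == 0.0:
        return PosteriorDistribution(
            category_set=pb.category_set,
            likelihood={c: 0.0 for c in labels},
            degenerate=True,
            updates_applied=updates,
        )
    return PosteriorDistribution(
        category_set=pb.category_set,
        likelihood={c: m / total for c, m in zip(labels, mass)},
        degenerate=False,
        updates_applied=updates,
    )


def assign_comcat(dist: PosteriorDistribution, threshold: float = 0.5) -> ComcatAssignment:
    """Apply the dominance rule: argmax iff strictly above threshold.

    A likelihood of exactly the threshold does not dominate; degenerate
    distributions map to "multiple" so a field dataset always processes
    end-to-end.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if dist.degenerate:
        return ComcatAssignment(assigned=MULTIPLE_LABEL, distribution=dist)
    best, p = dist.argmax()
    assigned = best if p > threshold else MULTIPLE_LABEL
    return ComcatAssignment(assigned=assigned, distribution=dist)


def assign_causes(
    dist: PosteriorDistribution,
    max_causes: int = 3,
    report_threshold: float = 0.1,
) -> CauseAssignment:
    """Rank causes above the reporting threshold; rest is indeterminate.

    Takes categories in descending likelihood (ties broken by category-set
    order) while the likelihood is at least ``report_threshold`` and at most
    ``max_causes`` are reported.
    """
    if max_causes < 1:
        raise ValueError(f"max_causes must be >= 1, got {max_causes}")
    if dist.degenerate:
        return CauseAssignment(ranked=[], indeterminate_residual=1.0)
    order = sorted(
        dist.category_set.labels,
        key=lambda c: (-dist.likelihood[c], dist.category_set.labels.index(c)),
    )
    ranked: list[tuple[str, float]] = []
    for cat in order:
        if len(ranked) >= max_causes or dist.likelihood[cat] < report_threshold:
            break
        ranked.append((cat, dist.likelihood[cat]))
    residual = 1.0 - sum(p for _, p in ranked)
    return CauseAssignment(ranked=ranked, indeterminate_residual=max(0.0, residual))


@dataclass
class EngineSettings:
    """Engine tunables; see docs/methods.md for defaults' rationale."""

    comcat_threshold: float = 0.5
    max_causes: int = 3
    report_threshold: float = 0.1


@dataclass
class DeathOutput:
    """Everything computed for one death, flattened by :meth:`to_row`."""

    record_id: str
    age_group: str
    sex: str
    year: int | None
    comcat: ComcatAssignment
    causes: CauseAssignment | None = None
    max_causes: int = 3

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "record_id": self.record_id,
            "age_group": self.age_group,
            "sex": self.sex,
            "year": "" if self.year is None else self.year,
            "comcat": self.comcat.assigned,
        }
        for cat in self.comcat.distribution.category_set.labels:
            row[f"p_{cat}"] = self.comcat.distribution.likelihood[cat]
        if self.causes is not None:
            for k in range(self.max_causes):
                if k < len(self.causes.ranked):
                    cause, lik = self.causes.ranked[k]
                else:
                    cause, lik = "", 0.0
                row[f"cause{k + 1}"] = cause
                row[f"lik{k + 1}"] = lik
            row["indeterminate"] = self.causes.indeterminate_residual
        return row


def process_dataset(
    records: Iterable[VARecord],
    comcat_pb: ProbBase,
    cause_pb: ProbBase | None = None,
    settings: EngineSettings | None = None,
) -> list[DeathOutput]:
    """Process every record: COMCAT assignment always, causes when a cause
    probbase is supplied.

    The two computations share no state — the COMCAT outputs of a run with
    a cause probbase are identical to a COMCAT-only run — and the engine is
    stateless across records, so permuting the input permutes the output.
    Per-record failures are logged and re-raised with the record id.
    """
    settings = settings or EngineSettings()
    outputs: list[DeathOutput] = []
    for record in records:
        try:
            comcat = assign_comcat(
                compute_posterior(record, comcat_pb), threshold=settings.comcat_threshold
            )
            causes = None
            if cause_pb is not None:
                causes = assign_causes(
                    compute_posterior(record, cause_pb),
                    max_causes=settings.max_causes,
                    report_threshold=settings.report_threshold,
                )
        except Exception:
            logger.exception("failed to process record %s", record.record_id)
            raise
        outputs.append(
            DeathOutput(
                record_id=record.record_id,
                age_group=record.age_group,
                sex=record.sex,
                year=record.year,
                comcat=comcat,
                causes=causes,
                max_causes=settings.max_causes,
            )
        )
    return outputs
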