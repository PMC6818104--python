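"""WHO-2016-shaped verbal autopsy records: model, read, write, validate.

A verbal autopsy (VA) record is one death: a response (yes / no / missing)
per interview indicator, plus demographic metadata (age band, sex, year of
death).  This module owns the on-disk CSV conventions — wide format, one
column per indicator id — and the ternary response model.  The WHO
instrument's "don't know" and "refused" answers collapse to MISSING: the
downstream Bayesian engine only consumes substantive responses, so a
non-substantive answer carries no information for it.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default demographic age bands (years), as used in HDSS demonstrations.
DEFAULT_AGE_BANDS: tuple[str, ...] = ("<5", "5-19", "20-49", "50-69", "70+")

SEX_VALUES: tuple[str, ...] = ("female", "male", "unknown")

#: Default token map for response cells (keys lower-cased before lookup).
DEFAULT_TOKEN_MAP: dict[str, str] = {
    "y": "YES",
    "yes": "YES",
    "n": "NO",
    "no": "NO",
    "": "MISSING",
    ".": "MISSING",
    "ref": "MISSING",
    "dk": "MISSING",
}


class Response(enum.Enum):
    """Ternary response to one VA indicator.

    Only YES and NO are substantive; MISSING covers blanks, "don't know",
    "refused" and any unrecognized token (the reader counts coercions).
    """

    YES = "YES"
    NO = "NO"
    MISSING = "MISSING"


@dataclass(frozen=True)
class IndicatorDef:
    """One interview item: WHO id token, question text, polarity note.

    ``note`` records which substantive response is informative for the
    circumstantial interpretation (e.g. for travel-to-facility items a 'no'
    is the informative answer).
    """

    id: str
    text: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise ValueError("indicator id must be a non-empty token")


class IndicatorDictionary:
    """Ordered set of indicator definitions with unique ids."""

    def __init__(self, indicators: Iterable[IndicatorDef]):
        self.indicators: list[IndicatorDef] = list(indicators)
        seen: set[str] = set()
        for ind in self.indicators:
            if ind.id in seen:
                raise ValueError(f"duplicate indicator id: {ind.id!r}")
            seen.add(ind.id)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.indicators]

    def __len__(self) -> int:
        return len(self.indicators)

    def __contains__(self, indicator_id: str) -> bool:
        return any(ind.id == indicator_id for ind in self.indicators)

    def __iter__(self):
        return iter(self.indicators)

    def __eq__(self, other) -> bool:
        return isinstance(other, IndicatorDictionary) and self.indicators == other.indicators


#: The ten WHO-2016 circumstantial items that must be present under the
#: who2016 dialect.
CIRCUMSTANTIAL_IDS: tuple[str, ...] = tuple(f"Id{n}" for n in range(10450, 10460))


@dataclass
class VARecord:
    """One death: responses keyed by indicator id plus demographics."""

    record_id: str
    responses: dict[str, Response]
    age_group: str = "unknown"
    sex: str = "unknown"
    year: int | None = None

    def substantive(self) -> dict[str, Response]:
        """Responses that are YES or NO (the ones the engine consumes)."""
        return {k: v for k, v in self.responses.items() if v is not Response.MISSING}


@dataclass
class IngestReport:
    """Bookkeeping from reading a VA CSV.

    Invariant: ``rows_read == rows_kept + rows_rejected``.
    """

    rows_read: int = 0
    rows_kept: int = 0
    rows_rejected: int = 0
    unknown_columns: list[str] = field(default_factory=list)
    coercions: int = 0
    rejected_ids: list[str] = field(default_factory=list)


def load_dictionary(path: str | Path, dialect: str = "who2016") -> IndicatorDictionary:
    """Load an indicator dictionary CSV (columns: id, text, note).

    ``dialect='who2016'`` additionally requires the ten circumstantial items
    Id10450–Id10459 to be present.
    """
    if dialect not in ("who2016", "custom"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'who2016' or 'custom'")
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    if df.empty or "id" not in df.columns:
        raise ValueError(f"no indicators found in {path}")
    defs = [
        IndicatorDef(
            id=str(row["id"]).strip(),
            text=str(row.get("text", "")),
            note=str(row.get("note", "")),
        )
        for _, row in df.iterrows()
        if str(row["id"]).strip()
    ]
    if not defs:
        raise ValueError(f"no indicators found in {path}")
    dictionary = IndicatorDictionary(defs)  # raises on duplicates
    if dialect == "who2016":
        missing = [i for i in CIRCUMSTANTIAL_IDS if i not in dictionary]
        if missing:
            raise ValueError(
                "who2016 dialect requires the circumstantial items; missing: "
                + ", ".join(missing)
            )
    return dictionary


def write_dictionary(dictionary: IndicatorDictionary, path: str | Path) -> None:
    """Write an indicator dictionary to CSV (columns: id, text, note)."""
    pd.DataFrame(
        [{"id": d.id, "text": d.text, "note": d.note} for d in dictionary]
    ).to_csv(path, index=False)


def parse_response(token: str, token_map: Mapping[str, str] | None = None) -> tuple[Response, bool]:
    """Map one CSV cell to a Response.

    Returns ``(response, coerced)`` where ``coerced`` is True when the token
    was unrecognized and mapped to MISSING.  Parsing is total: every string
    maps to exactly one Response.
    """
    tmap = DEFAULT_TOKEN_MAP if token_map is None else token_map
    key = token.strip().lower()
    if key in tmap:
        return Response(tmap[key]), False
    return Response.MISSING, True


def _parse_year(token: str) -> int | None:
    token = token.strip()
    if not token:
        return None
    try:
        return int(float(token))
    except ValueError:
        return None


def read_va_csv(
    path: str | Path,
    dictionary: IndicatorDictionary,
    token_map: Mapping[str, str] | None = None,
    id_column: str = "record_id",
) -> tuple[list[VARecord], IngestReport]:
    """Read a wide-format VA CSV: one row per death, one column per indicator.

    Columns not in the dictionary (other than the id and demographic columns)
    are ignored with a warning; unrecognized response tokens are coerced to
    MISSING and counted; rows repeating an already-seen record id are
    rejected and listed in the report.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    if id_column not in df.columns:
        raise ValueError(f"missing record-id column {id_column!r} in {path}")

    meta_cols = {id_column, "age_group", "sex", "year"}
    indicator_cols = [c for c in df.columns if c in dictionary]
    unknown = [c for c in df.columns if c not in dictionary and c not in meta_cols]
    if unknown:
        logger.warning("ignoring %d unknown columns: %s", len(unknown), unknown)

    report = IngestReport(unknown_columns=unknown)
    records: list[VARecord] = []
    seen_ids: set[str] = set()
    for _, row in df.iterrows():
        report.rows_read += 1
        rid = str(row[id_column]).strip()
        if not rid or rid in seen_ids:
            report.rows_rejected += 1
            report.rejected_ids.append(rid or "<blank>")
            continue
        seen_ids.add(rid)
        responses: dict[str, Response] = {}
        for col in indicator_cols:
            resp, coerced = parse_response(str(row[col]), token_map)
            if coerced:
                report.coercions += 1
            responses[col] = resp
        sex = str(row.get("sex", "unknown")).strip().lower() or "unknown"
        if sex not in SEX_VALUES:
            sex = "unknown"
        records.append(
            VARecord(
                record_id=rid,
                responses=responses,
                age_group=str(row.get("age_group", "unknown")).strip() or "unknown",
                sex=sex,
                year=_parse_year(str(row.get("year", ""))),
            )
        )
        report.rows_kept += 1
    if report.rows_kept == 0:
        raise ValueError(f"zero parseable rows in {path}")
    return records, report


#: Numeric results are written with this many decimals; the documented
#: round-trip precision of write_results_csv / read_results_csv.
RESULTS_DECIMALS = 6


def write_results_csv(path: str | Path, rows: Sequence[Mapping[str, object]]) -> None:
    """Write per-death results rows (shared schema) to CSV.

    Rows come from :func:`comcatva.bayes_engine.process_dataset` via
    ``output.to_row()``: record id, assigned COMCAT, the six COMCAT
    likelihoods, ranked causes with likelihoods, the indeterminate residual
    and demographics.  An empty result set yields a header-only file when
    a fieldnames-bearing empty DataFrame is passed; with no rows at all a
    minimal header is still written.
    """
    path = Path(path)
    if not rows:
        with open(path, "w", newline="") as fh:
            fh.write("record_id\n")
        return
    fieldnames = list(rows[0].keys())
    for r in rows:
        if list(r.keys()) != fieldnames:
            raise ValueError("result rows do not share a schema")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for r in rows:
            writer.writerow(
                {
                    k: (format(v, f".{RESULTS_DECIMALS}f") if isinstance(v, float) else v)
                    for k, v in r.items()
                }
            )


def read_results_csv(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back into a DataFrame (numerics restored)."""
    df = pd.read_csv(path)
    for col in df.columns:
        if col.startswith(("p_", "lik")) or col in ("indeterminate", "year"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
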