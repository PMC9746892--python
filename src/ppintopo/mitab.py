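"""PSI-MITAB 2.5/2.7 reading, writing and dataset-level quality summaries.

IntAct exports molecular-interaction records as tab-separated MITAB: 15
columns for version 2.5, 42 for 2.7 (which adds, among others, the
interactor-type columns).  Only the columns that matter for network
construction and bias screening are retained: the two primary interactor
identifiers, interactor molecule classes, source taxa, the interaction
detection method, the publication, and IntAct's aggregated confidence
(``intact-miscore``).

No ontology resolution is attempted: PSI-MI controlled-vocabulary fields are
kept as verbatim text, with only the human-readable label in parentheses
extracted where one is needed as a histogram key.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InteractionRecord",
    "DatasetSummary",
    "AnomalyReport",
    "MitabParseError",
    "read_mitab",
    "write_mitab",
    "read_edgelist",
    "summarize_dataset",
    "flag_anomalies",
]

MITAB25_COLUMNS = 15
MITAB27_COLUMNS = 42

#: column indices (0-based) shared by both dialects
_COL_ID_A, _COL_ID_B = 0, 1
_COL_METHOD, _COL_PUB = 6, 8
_COL_TAX_A, _COL_TAX_B = 9, 10
_COL_INTERACTION_ID = 13
_COL_CONFIDENCE = 14
#: 2.7-only interactor-type columns
_COL_TYPE_A, _COL_TYPE_B = 20, 21

_MISSING = "-"

_TAXID_RE = re.compile(r"taxid:(-?\d+)")
_MISCORE_RE = re.compile(r"intact-miscore:([0-9.eE+-]+)")
_LABEL_RE = re.compile(r"\(([^()]*)\)\s*$")


class MitabParseError(ValueError):
    """A MITAB line that cannot be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class InteractionRecord:
    """One molecular-interaction record, reduced to the analysis-relevant fields.

    ``type_a``/``type_b`` are the molecule-class labels (``protein``,
    ``small molecule``, ``gene`` ...) or ``None`` when the dialect does not
    carry them; ``mi_score`` is IntAct's confidence in [0, 1] or ``None``.
    """

    id_a: str
    id_b: str
    interaction_id: str | None = None
    type_a: str | None = None
    type_b: str | None = None
    taxid_a: int | None = None
    taxid_b: int | None = None
    detection_method: str | None = None
    publication_id: str | None = None
    mi_score: float | None = None

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("interactor identifiers must be non-empty")
        if self.mi_score is not None and not (0.0 <= self.mi_score <= 1.0):
            raise ValueError(f"mi_score {self.mi_score} outside [0, 1]")


def _value(field_text: str) -> str | None:
    """First entry of a MITAB field, stripped of its database prefix."""
    if field_text in ("", _MISSING):
        return None
    first = field_text.split("|", 1)[0]
    if ":" in first:
        first = first.split(":", 1)[1]
    return first.strip('"') or None


def _taxid(field_text: str) -> int | None:
    m = _TAXID_RE.search(field_text)
    return int(m.group(1)) if m else None

def _type_label(field_text: str) -> str | None:
    """Human-readable label of a CV term field, e.g. ``psi-mi:"MI:0326"(protein)``."""
    if field_text in ("", _MISSING):
        return None
    m = _LABEL_RE.search(field_text.split("|", 1)[0])
    if m:
        return m.group(1)
    return _value(field_text)


def _miscore(field_text: str) -> float | None:
    m = _MISCORE_RE.search(field_text)
    return float(m.group(1)) if m else None


def _verbatim(field_text: str) -> str | None:
    return None if field_text in ("", _MISSING) else field_text


def _parse_line(cols: Sequence[str], line_number: int) -> InteractionRecord:
    id_a = _value(cols[_COL_ID_A])
    id_b = _value(cols[_COL_ID_B])
    if id_a is None or id_b is None:
        raise MitabParseError("missing primary interactor identifier", line_number)
    has_types = len(cols) >= MITAB27_COLUMNS
    try:
        return InteractionRecord(
            id_a=id_a,
            id_b=id_b,
            interaction_id=_verbatim(cols[_COL_INTERACTION_ID]),
            type_a=_type_label(cols[_COL_TYPE_A]) if has_types else None,
            type_b=_type_label(cols[_COL_TYPE_B]) if has_types else None,
            taxid_a=_taxid(cols[_COL_TAX_A]),
            taxid_b=_taxid(cols[_COL_TAX_B]),
            detection_method=_verbatim(cols[_COL_METHOD]),
            publication_id=_verbatim(cols[_COL_PUB]),
            mi_score=_miscore(cols[_COL_CONFIDENCE]),
        )
    except ValueError as exc:
        raise MitabParseError(str(exc), line_number) from exc


def read_mitab(
    path: str | Path,
    dialect: str = "auto",
    on_error: str = "raise",
) -> list[InteractionRecord]:
    """Read a PSI-MITAB file into interaction records.

    Parameters
    ----------
    path
        Tab-separated MITAB file; a first line starting with ``#`` is treated
        as the header.
    dialect
        ``"mitab25"`` (15 columns), ``"mitab27"`` (42 columns) or ``"auto"``
        to select by column count per line.
    on_error
        ``"raise"`` aborts on a malformed line with its line number;
        ``"skip"`` drops malformed lines silently.
    """
    if dialect not in ("auto", "mitab25", "mitab27"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    expected = {"mitab25": MITAB25_COLUMNS, "mitab27": MITAB27_COLUMNS}.get(dialect)

    records: list[InteractionRecord] = []
    with open(path, encoding="utf-8") as handle:
        for line_number, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or (line_number == 1 and line.startswith("#")):
                continue
            cols = line.split("\t")
            ok = (
                len(cols) in (MITAB25_COLUMNS, MITAB27_COLUMNS)
                if expected is None
                else len(cols) == expected
            )
            if not ok:
                if on_error == "skip":
                    continue
                raise MitabParseError(
                    f"expected {expected or '15 or 42'} columns, found {len(cols)}",
                    line_number,
                )
            try:
                records.append(_parse_line(cols, line_number))
            except MitabParseError:
                if on_error == "raise":
                    raise
    return records


def write_mitab(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Serialize records back to MITAB 2.7 (42 columns, IntAct-style fields).

    Round-trips with :func:`read_mitab`: every retained field is written so
    that re-parsing yields field-identical records.
    """
    header_cols = ["#ID(s) interactor A"] + ["..."] * (MITAB27_COLUMNS - 1)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write("\t".join(header_cols) + "\n")
        for rec in records:
            cols = [_MISSING] * MITAB27_COLUMNS
            cols[_COL_ID_A] = f"uniprotkb:{rec.id_a}"
            cols[_COL_ID_B] = f"uniprotkb:{rec.id_b}"
            if rec.detection_method is not None:
                cols[_COL_METHOD] = rec.detection_method
            if rec.publication_id is not None:
                cols[_COL_PUB] = rec.publication_id
            if rec.taxid_a is not None:
                cols[_COL_TAX_A] = f"taxid:{rec.taxid_a}"
            if rec.taxid_b is not None:
                cols[_COL_TAX_B] = f"taxid:{rec.taxid_b}"
            if rec.interaction_id is not None:
                cols[_COL_INTERACTION_ID] = rec.interaction_id
            if rec.mi_score is not None:
                cols[_COL_CONFIDENCE] = f"intact-miscore:{rec.mi_score:g}"
            if rec.type_a is not None:
                cols[_COL_TYPE_A] = f'psi-mi:"MI:0000"({rec.type_a})'
            if rec.type_b is not None:
                cols[_COL_TYPE_B] = f'psi-mi:"MI:0000"({rec.type_b})'
            handle.write("\t".join(cols) + "\n")


def read_edgelist(path: str | Path) -> list[InteractionRecord]:
    """Read a plain two-column TSV edge list (no metadata) into bare records."""
    records = []
    with open(path, encoding="utf-8") as handle:
        for line_number, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise MitabParseError("expected two tab-separated columns", line_number)
            records.append(InteractionRecord(id_a=cols[0], id_b=cols[1]))
    return records


# ---------------------------------------------------------------------------
# dataset-level summaries

_SCORE_BIN_EDGES = np.linspace(0.0, 1.0, 11)


@dataclass
class DatasetSummary:
    """Quality features of one interaction dataset.

    ``type_histogram`` and ``taxid_histogram`` count interactor *occurrences*
    (two per record); ``method_histogram`` and ``score_histogram`` count
    records, so each of the latter sums to ``n_records`` (the score histogram
    keeps a ``"missing"`` bin for unscored records).
    """

    n_records: int
    n_distinct_interactors: int
    type_histogram: dict[str, int]
    taxid_histogram: dict[str, int]
    method_histogram: dict[str, int]
    score_mean: float
    score_histogram: dict[str, int]
    publication_histogram: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.__dict__, handle, indent=2, default=float)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["section", "key", "count"])
            writer.writerow(["total", "n_records", self.n_records])
            writer.writerow(["total", "n_distinct_interactors", self.n_distinct_interactors])
            writer.writerow(["score", "mean", self.score_mean])
            for section, hist in [
                ("type", self.type_histogram),
                ("taxid", self.taxid_histogram),
                ("method", self.method_histogram),
                ("score_bin", self.score_histogram),
                ("publication", self.publication_histogram),
            ]:
                for key, count in sorted(hist.items()):
                    writer.writerow([section, key, count])


def summarize_dataset(records: Sequence[InteractionRecord]) -> DatasetSummary:
    """Histogram the molecule classes, taxa, detection methods and MI scores.

    The score mean ignores absent scores (``NaN`` if no record is scored).
    Raises ``ValueError`` on empty input.
    """
    if not records:
        raise ValueError("cannot summarize an empty record set")

    types: Counter[str] = Counter()
    taxa: Counter[str] = Counter()
    methods: Counter[str] = Counter()
    pubs: Counter[str] = Counter()
    interactors: set[str] = set()
    scores: list[float] = []
    score_bins: Counter[str] = Counter()

    for rec in records:
        interactors.update((rec.id_a, rec.id_b))
        for t in (rec.type_a, rec.type_b):
            types[t if t is not None else "unlabeled"] += 1
        for tax in (rec.taxid_a, rec.taxid_b):
            taxa[str(tax) if tax is not None else "unknown"] += 1
        methods[rec.detection_method or "unknown"] += 1
        pubs[rec.publication_id or "unknown"] += 1
        if rec.mi_score is None:
            score_bins["missing"] += 1
        else:
            scores.append(rec.mi_score)
            idx = min(int(np.digitize(rec.mi_score, _SCORE_BIN_EDGES[1:-1], right=False)), 9)
            lo, hi = _SCORE_BIN_EDGES[idx], _SCORE_BIN_EDGES[idx + 1]
            score_bins[f"[{lo:.1f},{hi:.1f})"] += 1

    return DatasetSummary(
        n_records=len(records),
        n_distinct_interactors=len(interactors),
        type_histogram=dict(types),
        taxid_histogram=dict(taxa),
        method_histogram=dict(methods),
        score_mean=float(np.mean(scores)) if scores else float("nan"),
        score_histogram=dict(score_bins),
        publication_histogram=dict(pubs),
    )


@dataclass
class AnomalyReport:
    """Per-interactor anomaly flags; reports, never removes.

    ``non_protein`` maps flagged interactor id to its molecule class,
    ``non_reference_taxon`` to its taxid; ``unknown_taxon`` lists interactors
    with no taxid at all.  Interactors whose molecule class is absent
    (MITAB 2.5 has no type column) are not flagged as non-protein.
    """

    reference_taxid: int
    non_protein: dict[str, str]
    non_reference_taxon: dict[str, int]
    unknown_taxon: list[str]

    @property
    def n_non_protein(self) -> int:
        return len(self.non_protein)

    @property
    def n_non_reference_taxon(self) -> int:
        return len(self.non_reference_taxon)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reference_taxid": self.reference_taxid,
            "n_non_protein": self.n_non_protein,
            "n_non_reference_taxon": self.n_non_reference_taxon,
            "non_protein": self.non_protein,
            "non_reference_taxon": self.non_reference_taxon,
            "unknown_taxon": self.unknown_taxon,
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2)


def flag_anomalies(
    records: Sequence[InteractionRecord], reference_taxid: int = 9606
) -> AnomalyReport:
    """Flag non-protein interactors and interactors from foreign taxa.

    Human networks use ``reference_taxid=9606``.  An interactor is flagged at
    most once per category (sets of ids, not record counts).
    """
    non_protein: dict[str, str] = {}
    non_ref: dict[str, int] = {}
    unknown: set[str] = set()
    for rec in records:
        for ident, mol_type, taxid in (
            (rec.id_a, rec.type_a, rec.taxid_a),
            (rec.id_b, rec.type_b, rec.taxid_b),
        ):
            if mol_type is not None and mol_type != "protein":
                non_protein[ident] = mol_type
            if taxid is None:
                unknown.add(ident)
            elif taxid != reference_taxid:
                non_ref[ident] = taxid
    return AnomalyReport(
        reference_taxid=reference_taxid,
        non_protein=non_protein,
        non_reference_taxon=non_ref,
        unknown_taxon=sorted(unknown),
    )
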