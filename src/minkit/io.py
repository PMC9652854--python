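"""Text I/O: PSI-MI TAB (MITAB) reading, edge-list reading and writing.

MITAB files are tab-separated with one interaction per row; columns 1 and 2
hold "|"-separated interactor identifiers (``db:accession``), column 15
holds "|"-separated ``key:value`` confidence scores.  Only the primary
(first) identifier of each endpoint is used, and the confidence is taken
from the first matching key of a configurable list.

Edge lists are 2- or 3-column delimited text (STRING-style dumps); raw
scores may be rescaled into [0, 1] with ``weight_scale`` (e.g. 1000 for
STRING combined scores).  Written edge lists are sorted and rendered with
6 significant digits, so exports are byte-reproducible and round-trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from .errors import InvalidInputError, ParseError
from .model import Interaction, Interactor, MINGraph

logger = logging.getLogger(__name__)

PathOrFile = Union[str, Path, IO[str]]


def _open_for_read(source: PathOrFile):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def _open_for_write(sink: PathOrFile):
    if hasattr(sink, "write"):
        return sink, False
    return open(sink, "w", encoding="utf-8", newline="\n"), True


@dataclass
class MitabDialect:
    """Column layout and confidence-key preferences for MITAB parsing."""

    id_column_a: int = 0
    id_column_b: int = 1
    confidence_column: int = 14
    score_keys: tuple[str, ...] = ("intact-miscore", "score")
    header_detection: bool = True

    def __post_init__(self) -> None:
        columns = (self.id_column_a, self.id_column_b, self.confidence_column)
        if len(set(columns)) != 3 or min(columns) < 0:
            raise InvalidInputError("dialect columns must be distinct and >= 0")
        if not self.score_keys:
            raise InvalidInputError("score_keys must be non-empty")


def _primary_id(raw_field: str) -> str:
    return raw_field.split("|", 1)[0].strip()


def _extract_score(raw_field: str, score_keys: tuple[str, ...]) -> float | None:
    items = [item.strip() for item in raw_field.split("|")]
    for key in score_keys:
        prefix = key + ":"
        for item in items:
            if item.startswith(prefix):
                try:
                    return float(item[len(prefix):])
                except ValueError:
                    continue
    return None


def read_mitab(
    source: PathOrFile, dialect: MitabDialect | None = None
) -> tuple[list[Interaction], list[Interactor]]:
    """Parse a MITAB file into interactions plus the interactors they mention.

    The file must be homogeneously scored: if any row carries a confidence
    score, rows without one are dropped (with a logged count).  Rows with
    too few columns are collected and reported in a single
    :class:`ParseError` carrying the offending line numbers.
    """
    dialect = dialect or MitabDialect()
    needed = max(
        dialect.id_column_a, dialect.id_column_b, dialect.confidence_column
    )
    handle, owned = _open_for_read(source)
    rows: list[tuple[str, str, float | None]] = []
    bad_lines: list[int] = []
    try:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if (
                dialect.header_detection
                and line_no == 1
                and (line.startswith("#") or line.startswith("ID("))
            ):
                continue
            fields = line.split("\t")
            if len(fields) < needed + 1:
                bad_lines.append(line_no)
                continue
            a = _primary_id(fields[dialect.id_column_a])
            b = _primary_id(fields[dialect.id_column_b])
            score = _extract_score(
                fields[dialect.confidence_column], dialect.score_keys
            )
            rows.append((a, b, score))
    finally:
        if owned:
            handle.close()

    if bad_lines:
        raise ParseError(
            f"{len(bad_lines)} malformed row(s) at line(s) "
            + ", ".join(map(str, bad_lines)),
            lines=bad_lines,
        )

    any_scored = any(score is not None for _, _, score in rows)
    interactions: list[Interaction] = []
    dropped = 0
    for a, b, score in rows:
        if any_scored and score is None:
            dropped += 1
            continue
        interactions.append(Interaction(a, b, score if any_scored else None))
    if dropped:
        logger.warning("%d row(s) without a confidence score dropped", dropped)

    seen: dict[str, Interactor] = {}
    for interaction in interactions:
        for endpoint in (interaction.endpoint_a, interaction.endpoint_b):
            if endpoint not in seen:
                seen[endpoint] = Interactor(endpoint)
    return interactions, list(seen.values())


def read_edge_list(
    source: PathOrFile,
    delimiter: str | None = "\t",
    weight_column: int | None = None,
    weight_scale: float = 1.0,
) -> list[Interaction]:
    """Parse a delimited edge list into interactions.

    ``delimiter=None`` splits on any whitespace run.  When ``weight_column``
    is given, raw values are divided by ``weight_scale`` and must land in
    [0, 1]; a header line is skipped iff its weight field is non-numeric.
    """
    if weight_scale <= 0:
        raise InvalidInputError("weight_scale must be positive")
    handle, owned = _open_for_read(source)
    interactions: list[Interaction] = []
    try:
        first_data_line = True
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) < 2:
                raise ParseError(
                    f"line {line_no}: expected >= 2 columns", lines=[line_no]
                )
            if weight_column is None:
                interactions.append(Interaction(fields[0], fields[1]))
                continue
            if len(fields) <= weight_column:
                raise ParseError(
                    f"line {line_no}: missing weight column {weight_column}",
                    lines=[line_no],
                )
            raw = fields[weight_column]
            try:
                value = float(raw)
            except ValueError:
                if first_data_line:  # header row
                    first_data_line = False
                    continue
                raise ParseError(
                    f"line {line_no}: non-numeric weight {raw!r}",
                    lines=[line_no],
                ) from None
            first_data_line = False
            weight = value / weight_scale
            if not (0.0 <= weight <= 1.0):
                raise InvalidInputError(
                    f"line {line_no}: weight {weight} outside [0, 1] "
                    f"after scaling by {weight_scale}"
                )
            interactions.append(Interaction(fields[0], fields[1], weight))
    finally:
        if owned:
            handle.close()
    return interactions


def format_weight(weight: float) -> str:
    """Render a weight with 6 significant digits."""
    return f"{weight:.6g}"


def write_edge_list(g: MINGraph, sink: PathOrFile) -> int:
    """Write ``g`` as a sorted tab-separated edge list; returns row count.

    Rows are ``id_a<TAB>id_b[<TAB>weight]`` in canonical endpoint order,
    sorted lexicographically by pair.
    """
    handle, owned = _open_for_write(sink)
    try:
        count = 0
        for key in sorted(k for k, _ in g.edge_items()):
            a, b = key
            w = g.weight(a, b)
            if w is None:
                handle.write(f"{a}\t{b}\n")
            else:
                handle.write(f"{a}\t{b}\t{format_weight(w)}\n")
            count += 1
        return count
    finally:
        if owned:
            handle.close()
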