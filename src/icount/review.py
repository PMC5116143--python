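"""Semi-automatic workflow: export flagged objects, fold corrections back.

The automatic pipeline flags objects it is unsure about (``uncertain``:
probably several eggs merged; ``rejected``: probably not an egg).  A
reviewer inspects those on the overlay, fills in the true count per
object in a plain CSV, and :func:`apply_corrections` recomputes the
total.  Corrections are applied per object — not as one adjusted total —
so the audit trail records exactly where the automatic count was wrong.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .detection import DetectionResult
from .errors import ConsistencyError, ValidationError

REVIEW_HEADER = ["image_id", "object_id", "status", "auto_count",
                 "corrected_count", "note"]

FLAGGED_STATUSES = ("uncertain", "rejected")


@dataclass(frozen=True)
class ReviewRecord:
    """One row of a review table.

    ``corrected_count`` is ``None`` until a reviewer fills it in; 0 is a
    valid correction (the object was an artefact, not an egg).
    """

    image_id: str
    object_id: int
    status: str
    auto_count: int
    corrected_count: int | None = None
    note: str = ""


def records_from_result(
    result: DetectionResult, flagged_only: bool = True
) -> list[ReviewRecord]:
    objs = result.objects
    if flagged_only:
        objs = [o for o in objs if o.status in FLAGGED_STATUSES]
    return [
        ReviewRecord(
            image_id=result.image_id,
            object_id=o.object_id,
            status=o.status,
            auto_count=o.estimated_count,
        )
        for o in objs
    ]


def export_review(
    results: DetectionResult | Sequence[DetectionResult],
    path: str | Path,
    flagged_only: bool = True,
) -> None:
    """Write a review CSV (header fixed: ``image_id,object_id,status,
    auto_count,corrected_count,note``), corrected_count left empty."""
    if isinstance(results, DetectionResult):
        results = [results]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REVIEW_HEADER)
        for res in results:
            for rec in records_from_result(res, flagged_only=flagged_only):
                writer.writerow([
                    rec.image_id, rec.object_id, rec.status,
                    rec.auto_count, "", rec.note,
                ])


def read_review(path: str | Path) -> list[ReviewRecord]:
    """Parse a review CSV back into records (empty corrections -> None)."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = (row.get("corrected_count") or "").strip()
            records.append(
                ReviewRecord(
                    image_id=row["image_id"],
                    object_id=int(row["object_id"]),
                    status=row["status"],
                    auto_count=int(row["auto_count"]),
                    corrected_count=int(raw) if raw else None,
                    note=row.get("note", ""),
                )
            )
    return records


def apply_corrections(
    result: DetectionResult, records: Iterable[ReviewRecord]
) -> DetectionResult:
    """Return a new result with reviewer counts substituted.

    Objects whose record carries a non-empty ``corrected_count`` take it
    as their estimated count and are marked ``corrected`` (the original
    status is kept for audit).  The input result is not mutated.
    Applying the same corrections twice is idempotent.

    Raises
    ------
    ConsistencyError
        If a record does not match any object of this result.
    ValidationError
        If a corrected count is negative.
    """
    known = {o.object_id for o in result.objects}
    corrections: dict[int, int] = {}
    offenders = []
    for rec in records:
        if rec.image_id != result.image_id or rec.object_id not in known:
            offenders.append((rec.image_id, rec.object_id))
            continue
        if rec.corrected_count is None:
            continue
        if rec.corrected_count < 0:
            raise ValidationError(
                f"corrected_count must be >= 0, got {rec.corrected_count} "
                f"for object {rec.object_id} of {rec.image_id}"
            )
        corrections[rec.object_id] = rec.corrected_count
    if offenders:
        raise ConsistencyError(
            f"review records do not match result {result.image_id!r}: "
            f"unknown (image_id, object_id) pairs {offenders}"
        )
    objects = [
        replace(o, estimated_count=corrections[o.object_id], corrected=True)
        if o.object_id in corrections else replace(o)
        for o in result.objects
    ]
    return DetectionResult(
        image_id=result.image_id,
        params=result.params,
        objects=objects,
        total_estimate=sum(o.estimated_count for o in objects),
        reference_area=result.reference_area,
        image_shape=result.image_shape,
        labels=result.labels,
    )
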