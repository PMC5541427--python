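"""Probe/position -> annotated-gene-name conversion (the standalone converter).

Methylation matrices usually arrive keyed by Illumina probe id (``cg...``)
or genomic position; the pathway overlay needs rows keyed by gene symbol
with the probe id / position / location appended as underscore fields.
The conversion is table-driven: a 4-column TSV (key, key_type, gene,
location) built from an Annovar-style region annotation.

A probe annotated to k genes fans out into k rows sharing one beta vector;
unannotated probes are dropped and counted, never silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable

from .io import (
    LOCATION_VOCAB,
    OmicsMatrix,
    SiteRecord,
    ValidationError,
    _LOCATION_LOOKUP,
    _open_text,
)

__all__ = ["AnnotationTable", "AnnotationReport", "annotate_matrix", "annotation_report"]


def _normalize_position(key: str) -> str:
    """Normalize a position key to ``chrN:pos`` (adds the ``chr`` prefix)."""
    chrom, _, pos = key.partition(":")
    if not chrom.startswith("chr"):
        chrom = "chr" + chrom
    return f"{chrom}:{int(pos)}"


@dataclass
class AnnotationTable:
    """Lookup from probe id or position to (gene, location) annotations."""

    by_probe: dict[str, list[tuple[str, str | None]]] = field(default_factory=dict)
    by_position: dict[str, list[tuple[str, str | None]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.by_probe) + len(self.by_position)

    def add(self, key: str, key_type: str, gene: str, location: str | None) -> None:
        if location is not None:
            location = _LOCATION_LOOKUP.get(location.lower(), "unknown")
        if key_type == "probe":
            self.by_probe.setdefault(key, []).append((gene, location))
        elif key_type == "position":
            self.by_position.setdefault(_normalize_position(key), []).append((gene, location))
        else:
            raise ValidationError(f"unknown annotation key type {key_type!r}")

    def lookup(self, record: SiteRecord) -> list[tuple[str, str | None]]:
        hits = self.by_probe.get(record.site_id, [])
        if not hits and record.position_key is not None:
            hits = self.by_position.get(_normalize_position(record.position_key), [])
        if not hits and ":" in record.site_id:
            hits = self.by_position.get(_normalize_position(record.site_id), [])
        return hits

    @classmethod
    def read(cls, source: str | Path | IO | bytes) -> "AnnotationTable":
        """Read the 4-column TSV: key, key_type (probe|position), gene, location."""
        fh = _open_text(source)
        table = cls()
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValidationError(
                    f"annotation line {line_no}: expected >= 3 columns"
                )
            key, key_type, gene = cols[0].strip(), cols[1].strip(), cols[2].strip()
            location = cols[3].strip() if len(cols) > 3 and cols[3].strip() else None
            table.add(key, key_type, gene, location)
        return table


@dataclass(frozen=True)
class AnnotationReport:
    rows_in: int
    rows_out: int
    dropped: int
    fanned_out: int  # extra rows created by multi-gene probes

    def __post_init__(self) -> None:
        assert min(self.rows_in, self.rows_out, self.dropped, self.fanned_out) >= 0
        assert self.rows_in == self.dropped + self.rows_out - self.fanned_out


def annotate_matrix(
    matrix: OmicsMatrix,
    table: AnnotationTable,
    include: Iterable[str] = ("site_id", "location"),
) -> tuple[OmicsMatrix, AnnotationReport]:
    """Re-key a probe/position matrix by annotated gene name.

    ``include`` selects which underscore fields survive into the new row key,
    drawn from {"site_id", "position", "location"}; the composite order is
    always gene, site_id, position, location so keys re-parse cleanly.  The
    site id itself is always retained on the record (it is the row identity)
    even when omitted from ``include``.  Beta vectors are carried over
    untouched.
    """
    if matrix.kind != "methylation":
        raise ValueError("annotation applies to methylation matrices")
    if len(table) == 0:
        raise ValidationError("empty annotation table")
    include = set(include)
    bad = include - {"site_id", "position", "location"}
    if bad:
        raise ValueError(f"unknown include flags {sorted(bad)}")

    out_rows: list[SiteRecord] = []
    dropped = 0
    fanned = 0
    seen_ids: set[str] = set()
    for rec in matrix.rows:
        hits = table.lookup(rec)
        if not hits:
            dropped += 1
            continue
        fanned += len(hits) - 1
        for gene, location in hits:
            new = SiteRecord(
                gene=gene,
                site_id=rec.site_id,
                betas=rec.betas,
                position=rec.position if "position" in include else None,
                location=(location if "location" in include else None),
            )
            # guarantee unique site ids when one probe fans out to many genes
            sid = new.site_id
            if sid in seen_ids:
                sid = f"{sid}@{gene}"
                new = replace(new, site_id=sid)
            seen_ids.add(sid)
            out_rows.append(new)
    annotated = OmicsMatrix(
        kind="methylation", sample_ids=matrix.sample_ids, rows=out_rows
    )
    report = AnnotationReport(
        rows_in=len(matrix.rows),
        rows_out=len(out_rows),
        dropped=dropped,
        fanned_out=fanned,
    )
    return annotated, report


def annotation_report(before: OmicsMatrix, after: OmicsMatrix, dropped: int, fanned_out: int) -> AnnotationReport:
    """Build the in/out/dropped/fan-out bookkeeping for an annotation run."""
    if before.sample_ids != after.sample_ids:
        raise ValueError("matrices do not share sample ids")
    return AnnotationReport(
        rows_in=len(before.rows),
        rows_out=len(after.rows),
        dropped=dropped,
        fanned_out=fanned_out,
    )
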