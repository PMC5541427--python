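"""Readers and validators for methylation / expression matrices and metadata.

The on-disk formats are deliberately plain:

* methylation matrix — TSV, header row of sample ids, first column an
  *annotated row key* (``GENE_cg012_chr1:100_exonic`` style, underscore
  separated), cells are beta values in [0, 1];
* expression matrix — TSV keyed by bare gene symbol, cells are FPKM >= 0;
* Bismark coverage — 6-column TSV per sample (chrom, start, end, meth %,
  count methylated, count unmethylated), optionally gzipped;
* grouping — 2-column TSV mapping sample id to group label;
* site list — one probe id or genomic position per line.

Missing values are "NA" (any case) or an empty cell.  Validation errors
name the offending row/column so bad cells are findable in large matrices.
"""

from __future__ import annotations

import gzip
import io as _stdio
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LOCATION_VOCAB",
    "SiteRecord",
    "OmicsMatrix",
    "SampleGrouping",
    "ValidationError",
    "parse_annotated_key",
    "render_annotated_key",
    "read_methylation_matrix",
    "read_expression_matrix",
    "read_bismark_coverage",
    "read_grouping",
    "read_site_list",
    "write_matrix",
]

#: Annovar-style genomic region categories; anything else maps to "unknown".
LOCATION_VOCAB = (
    "upstream",
    "downstream",
    "exonic",
    "intronic",
    "UTR5",
    "UTR3",
    "splicing",
    "intergenic",
    "ncRNA",
)
_LOCATION_LOOKUP = {v.lower(): v for v in LOCATION_VOCAB}
_LOCATION_LOOKUP["unknown"] = "unknown"

_PROBE_RE = re.compile(r"^cg\d+$")
_POSITION_RE = re.compile(r"^(chr)?\w+:\d+$")
_NA_TOKENS = {"", "na"}


class ValidationError(ValueError):
    """Input data violates the format contract; message locates the cell."""


@dataclass(frozen=True)
class SiteRecord:
    """One CpG site: host gene, identity, optional position/location, betas."""

    gene: str
    site_id: str
    betas: tuple[float, ...]  # np.nan encodes missing
    position: tuple[str, int] | None = None
    location: str | None = None

    def __post_init__(self) -> None:
        for b in self.betas:
            if not np.isnan(b) and not (0.0 <= b <= 1.0):
                raise ValidationError(
                    f"beta {b} out of [0,1] for site {self.site_id}"
                )

    @property
    def beta_array(self) -> np.ndarray:
        return np.asarray(self.betas, dtype=float)

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.beta_array)))

    def sample_sd(self) -> float:
        """Sample standard deviation (ddof=1) over non-missing betas.

        Returns nan when fewer than two betas are observed.
        """
        arr = self.beta_array
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            return float("nan")
        return float(np.std(arr, ddof=1))

    @property
    def position_key(self) -> str | None:
        if self.position is None:
            return None
        return f"{self.position[0]}:{self.position[1]}"

    def row_key(self) -> str:
        return render_annotated_key(
            self.gene, self.site_id, self.position, self.location
        )


@dataclass
class OmicsMatrix:
    """Sample-by-row value store for methylation (sites) or expression (genes).

    ``rows`` holds :class:`SiteRecord` objects for methylation matrices; for
    expression matrices it is empty and ``expression`` maps gene -> FPKM
    vector aligned with ``sample_ids``.
    """

    kind: str  # "methylation" | "expression"
    sample_ids: tuple[str, ...]
    rows: list[SiteRecord] = field(default_factory=list)
    expression: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("methylation", "expression"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in header")
        seen: set[str] = set()
        for r in self.rows:
            if len(r.betas) != len(self.sample_ids):
                raise ValidationError(
                    f"site {r.site_id}: {len(r.betas)} values for "
                    f"{len(self.sample_ids)} samples"
                )
            if r.site_id in seen:
                raise ValidationError(f"duplicate site id {r.site_id}")
            seen.add(r.site_id)
        for gene, vals in self.expression.items():
            if len(vals) != len(self.sample_ids):
                raise ValidationError(f"gene {gene}: ragged expression row")
            for v in vals:
                if not np.isnan(v) and v < 0:
                    raise ValidationError(f"negative FPKM for gene {gene}")

    # -- convenience accessors -------------------------------------------

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(sample_id) from None

    def sites_by_gene(self) -> dict[str, list[SiteRecord]]:
        out: dict[str, list[SiteRecord]] = {}
        for r in self.rows:
            out.setdefault(r.gene.lower(), []).append(r)
        return out

    def genes(self) -> list[str]:
        if self.kind == "expression":
            return list(self.expression)
        return list(dict.fromkeys(r.gene for r in self.rows))

    def expression_vector(self, gene: str) -> np.ndarray:
        for g, vals in self.expression.items():
            if g.lower() == gene.lower():
                return np.asarray(vals, dtype=float)
        raise KeyError(gene)

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame (rows keyed like the TSV's first column)."""
        if self.kind == "expression":
            data = {g: list(v) for g, v in self.expression.items()}
            return pd.DataFrame.from_dict(
                data, orient="index", columns=list(self.sample_ids)
            )
        return pd.DataFrame(
            [list(r.betas) for r in self.rows],
            index=[r.row_key() for r in self.rows],
            columns=list(self.sample_ids),
        )


@dataclass
class SampleGrouping:
    """Sample -> group assignment with a stable group display order."""

    assignment: dict[str, str]
    group_order: tuple[str, ...]

    UNKNOWN = "unknown"

    def group_of(self, sample_id: str) -> str:
        return self.assignment.get(sample_id, self.UNKNOWN)

    def members(self, group: str, sample_ids: Sequence[str]) -> list[str]:
        return [s for s in sample_ids if self.group_of(s) == group]

    def sizes(self, sample_ids: Sequence[str]) -> dict[str, int]:
        return {g: len(self.members(g, sample_ids)) for g in self.group_order}

    @classmethod
    def trivial(cls, sample_ids: Sequence[str]) -> "SampleGrouping":
        return cls({s: cls.UNKNOWN for s in sample_ids}, (cls.UNKNOWN,))


# --------------------------------------------------------------------------
# annotated row keys


def parse_annotated_key(key: str) -> tuple[str, str | None, tuple[str, int] | None, str | None]:
    """Split an underscore-annotated row key into its fields.

    The first token is the gene symbol.  Each further token is classified by
    pattern: ``cg\\d+`` is a probe id, ``chrom:pos`` a genomic position, a
    member of the Annovar location vocabulary (case-insensitive) a location.
    Unrecognized tokens are folded back into the gene symbol, which keeps
    gene names containing underscores (e.g. ``NKX2_1``) intact.  Total: never
    raises on a non-empty key.
    """
    if not key:
        raise ValueError("empty row key")
    tokens = key.split("_")
    gene_parts = [tokens[0]]
    site_id: str | None = None
    position: tuple[str, int] | None = None
    location: str | None = None
    for tok in tokens[1:]:
        if site_id is None and _PROBE_RE.match(tok):
            site_id = tok
        elif position is None and _POSITION_RE.match(tok):
            chrom, _, pos = tok.partition(":")
            position = (chrom, int(pos))
        elif location is None and tok.lower() in _LOCATION_LOOKUP:
            location = _LOCATION_LOOKUP[tok.lower()]
        else:
            gene_parts.append(tok)
    return "_".join(gene_parts), site_id, position, location


def render_annotated_key(
    gene: str,
    site_id: str | None,
    position: tuple[str, int] | None,
    location: str | None,
) -> str:
    """Canonical re-rendering, fixed field order gene_siteid_position_location."""
    parts = [gene]
    if site_id and _PROBE_RE.match(site_id):
        parts.append(site_id)
    if position is not None:
        parts.append(f"{position[0]}:{position[1]}")
    if location:
        parts.append(location)
    return "_".join(parts)


# --------------------------------------------------------------------------
# TSV matrix readers


def _open_text(source: str | Path | IO) -> IO:
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix == ".gz":
            return gzip.open(p, "rt")
        return open(p, "r", encoding="utf-8")
    if isinstance(source, (bytes, bytearray)):
        return _stdio.StringIO(source.decode())
    return source


def _parse_cell(raw: str, *, line_no: int, col: str, low=None, high=None) -> float:
    raw = raw.strip()
    if raw.lower() in _NA_TOKENS:
        return float("nan")
    try:
        v = float(raw)
    except ValueError:
        raise ValidationError(
            f"line {line_no}, column {col!r}: non-numeric cell {raw!r}"
        ) from None
    if low is not None and v < low or high is not None and v > high:
        raise ValidationError(
            f"line {line_no}, column {col!r}: value {v} outside "
            f"[{low if low is not None else '-inf'}, {high if high is not None else 'inf'}]"
        )
    return v


def read_methylation_matrix(source: str | Path | IO | bytes) -> OmicsMatrix:
    """Read a beta-value matrix whose row keys are annotated gene names.

    Row keys are decomposed with :func:`parse_annotated_key`; a bare gene
    name gets the raw key as its synthetic site id.  Betas outside [0, 1],
    non-numeric cells and ragged rows raise :class:`ValidationError` naming
    the offending line and column.
    """
    fh = _open_text(source)
    header = fh.readline().rstrip("\n").split("\t")
    sample_ids = tuple(h.strip() for h in header[1:])
    if not sample_ids:
        raise ValidationError("header row contains no sample ids")
    rows: list[SiteRecord] = []
    for line_no, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(sample_ids) + 1:
            raise ValidationError(
                f"line {line_no}: {len(cells) - 1} values for {len(sample_ids)} samples"
            )
        key = cells[0].strip()
        gene, site_id, position, location = parse_annotated_key(key)
        betas = tuple(
            _parse_cell(c, line_no=line_no, col=s, low=0.0, high=1.0)
            for c, s in zip(cells[1:], sample_ids)
        )
        rows.append(
            SiteRecord(
                gene=gene,
                site_id=site_id or (f"{position[0]}:{position[1]}" if position else key),
                betas=betas,
                position=position,
                location=location,
            )
        )
    return OmicsMatrix(kind="methylation", sample_ids=sample_ids, rows=rows)


def read_expression_matrix(source: str | Path | IO | bytes) -> OmicsMatrix:
    """Read an FPKM matrix keyed by bare gene symbols; values must be >= 0."""
    fh = _open_text(source)
    header = fh.readline().rstrip("\n").split("\t")
    sample_ids = tuple(h.strip() for h in header[1:])
    if not sample_ids:
        raise ValidationError("header row contains no sample ids")
    expression: dict[str, tuple[float, ...]] = {}
    for line_no, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(sample_ids) + 1:
            raise ValidationError(
                f"line {line_no}: {len(cells) - 1} values for {len(sample_ids)} samples"
            )
        gene = cells[0].strip()
        if gene in expression:
            raise ValidationError(f"duplicate gene row {gene!r} at line {line_no}")
        vals = tuple(
            _parse_cell(c, line_no=line_no, col=s, low=0.0)
            for c, s in zip(cells[1:], sample_ids)
        )
        expression[gene] = vals
    return OmicsMatrix(kind="expression", sample_ids=sample_ids, expression=expression)


def read_bismark_coverage(
    sources: Mapping[str, str | Path | IO | bytes],
) -> OmicsMatrix:
    """Merge per-sample Bismark ``.cov`` files into one methylation matrix.

    Each file is 6-column TSV: chromosome, start, end, methylation
    percentage, count methylated, count unmethylated.  Beta = percentage/100,
    keyed by ``chrom:start`` (1-based, as Bismark emits).  A site absent from
    a sample is missing for that sample.  Where both counts are nonzero the
    percentage is cross-checked against the count ratio and discrepancies
    beyond 0.005 are logged (they often indicate truncated files).
    """
    sample_ids = tuple(sources)
    betas_by_site: dict[str, dict[int, float]] = {}
    order: list[str] = []
    for si, (sample, src) in enumerate(sources.items()):
        fh = _open_text(src)
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 6:
                raise ValidationError(
                    f"{sample} line {line_no}: expected 6 columns, got {len(cols)}"
                )
            chrom, start, _end, pct_s, n_meth_s, n_unmeth_s = cols
            pct = _parse_cell(pct_s, line_no=line_no, col="percentage", low=0.0, high=100.0)
            n_meth, n_unmeth = int(n_meth_s), int(n_unmeth_s)
            if n_meth < 0 or n_unmeth < 0:
                raise ValidationError(f"{sample} line {line_no}: negative count")
            beta = pct / 100.0
            if n_meth + n_unmeth > 0 and (n_meth > 0 or n_unmeth > 0):
                ratio = n_meth / (n_meth + n_unmeth)
                if abs(ratio - beta) > 0.005:
                    logger.warning(
                        "%s %s:%s: percentage %.4f disagrees with count ratio %.4f",
                        sample, chrom, start, beta, ratio,
                    )
            key = f"{chrom}:{int(start)}"
            if key not in betas_by_site:
                betas_by_site[key] = {}
                order.append(key)
            betas_by_site[key][si] = beta
    rows = []
    for key in order:
        chrom, _, pos = key.partition(":")
        per_sample = betas_by_site[key]
        rows.append(
            SiteRecord(
                gene=key,  # gene assignment deferred to site_annotation
                site_id=key,
                betas=tuple(per_sample.get(i, float("nan")) for i in range(len(sample_ids))),
                position=(chrom, int(pos)),
            )
        )
    return OmicsMatrix(kind="methylation", sample_ids=sample_ids, rows=rows)


def read_grouping(source: str | Path | IO | bytes, matrix: OmicsMatrix) -> SampleGrouping:
    """Read a two-column sample -> group TSV against *matrix*'s samples.

    Group order follows first appearance in the file.  Matrix samples absent
    from the file fall into an implicit "unknown" group placed last; file
    samples absent from the matrix are logged and ignored.  Conflicting
    duplicate lines for one sample raise :class:`ValidationError`.
    """
    fh = _open_text(source)
    assignment: dict[str, str] = {}
    order: list[str] = []
    known = set(matrix.sample_ids)
    for line_no, line in enumerate(fh, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise ValidationError(f"grouping line {line_no}: expected 2 columns")
        sample, group = cols[0].strip(), cols[1].strip()
        if sample in assignment and assignment[sample] != group:
            raise ValidationError(
                f"grouping line {line_no}: sample {sample!r} assigned to both "
                f"{assignment[sample]!r} and {group!r}"
            )
        if sample not in known:
            logger.warning("grouping: sample %r not present in the matrix", sample)
            continue
        assignment[sample] = group
        if group not in order:
            order.append(group)
    if len(assignment) < len(matrix.sample_ids) and SampleGrouping.UNKNOWN not in order:
        order.append(SampleGrouping.UNKNOWN)
    return SampleGrouping(assignment=assignment, group_order=tuple(order))


def read_site_list(source: str | Path | IO | bytes) -> set[str]:
    """Read a plain-text list of probe ids / genomic positions (deduplicated).

    Blank lines and ``#`` comments are ignored; entries keep their literal
    spelling (positions are matched against site position keys).
    """
    fh = _open_text(source)
    out: set[str] = set()
    for line in fh:
        entry = line.strip()
        if not entry or entry.startswith("#"):
            continue
        out.add(entry)
    return out


def write_matrix(matrix: OmicsMatrix, dest: str | Path) -> None:
    """Write a matrix back to TSV in the exact shape the readers accept."""
    df = matrix.to_frame()
    with open(dest, "w", encoding="utf-8") as fh:
        fh.write("key\t" + "\t".join(matrix.sample_ids) + "\n")
        for key, row in zip(df.index, df.to_numpy()):
            cells = ["NA" if np.isnan(v) else format(float(v), "g") for v in row]
            fh.write(str(key) + "\t" + "\t".join(cells) + "\n")
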