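"""Overlay analytics: site filtering, gene aggregation, pattern mining.

This is the analytic core that sits between the data model and the
renderers.  It matches CpG sites (or expression rows) to pathway genes,
applies the four site-selection filters, computes per-sample and per-group
display values, log2-fold expression values, Euclidean similar-pattern
search and the methylation-expression Spearman screen, and orders samples
for playback.

Display-value semantics
-----------------------
Methylation: a gene's per-sample value is the mean beta over its passing
sites (missing betas skipped); the group value applies an aggregator
(default mean) over the member samples' values.  Expression: per-sample
value is the clipped log2 fold against the median over all samples; the
group value takes the median of the member samples' raw FPKM first, then
the same fold transform.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import LOCATION_VOCAB, OmicsMatrix, SampleGrouping, SiteRecord
from .kgml import PathwayGraph

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "GeneOverlay",
    "SimilarityHit",
    "match_sites",
    "apply_filters",
    "gene_methylation_value",
    "expression_fold",
    "build_overlays",
    "find_similar",
    "methylation_expression_correlation",
    "correlation_screen",
    "order_samples",
    "DEFAULT_FOLD_SCALE",
    "DEFAULT_PSEUDOCOUNT",
]

DEFAULT_FOLD_SCALE = 4.0
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class FilterSpec:
    """Active site-selection criteria; absent fields are vacuous.

    A site passes iff ALL present criteria hold:

    * ``sd_threshold`` — sample SD (ddof=1, missing excluded) of its betas
      strictly exceeds the threshold; sites with < 2 observed betas fail;
    * ``beta_range`` — betas fall inside [low, high] (all non-missing betas
      by default; ``range_mode="any"`` requires only one);
    * ``locations`` — the site's annotated location is in the set;
    * ``site_list`` — the site id or position key is in the list.
    """

    sd_threshold: float | None = None
    beta_range: tuple[float, float] | None = None
    locations: frozenset[str] | None = None
    site_list: frozenset[str] | None = None
    range_mode: Literal["all", "any"] = "all"

    def __post_init__(self) -> None:
        if self.sd_threshold is not None and self.sd_threshold < 0:
            raise ValueError("sd_threshold must be >= 0")
        if self.beta_range is not None:
            low, high = self.beta_range
            if low > high:
                raise ValueError(f"beta_range low {low} > high {high}")
            if not (0.0 <= low <= 1.0 and 0.0 <= high <= 1.0):
                raise ValueError("beta_range must lie within [0, 1]")
        if self.locations is not None:
            object.__setattr__(self, "locations", frozenset(self.locations))
        if self.site_list is not None:
            object.__setattr__(self, "site_list", frozenset(self.site_list))

    @property
    def is_vacuous(self) -> bool:
        return (
            self.sd_threshold is None
            and self.beta_range is None
            and self.locations is None
            and self.site_list is None
        )

    def passes(self, site: SiteRecord) -> bool:
        arr = site.beta_array
        observed = arr[~np.isnan(arr)]
        if self.sd_threshold is not None:
            if observed.size < 2:
                return False
            if not site.sample_sd() > self.sd_threshold:
                return False
        if self.beta_range is not None:
            low, high = self.beta_range
            if observed.size == 0:
                return False
            inside = (observed >= low) & (observed <= high)
            ok = inside.any() if self.range_mode == "any" else inside.all()
            if not ok:
                return False
        if self.locations is not None:
            if site.location is None or site.location not in self.locations:
                return False
        if self.site_list is not None:
            keys = {site.site_id}
            if site.position_key is not None:
                keys.add(site.position_key)
            if not keys & self.site_list:
                return False
        return True


@dataclass
class GeneOverlay:
    """Display state of one pathway gene after matching and filtering."""

    gene: str
    matched_sites: list[SiteRecord] = field(default_factory=list)
    excluded_sites: list[SiteRecord] = field(default_factory=list)
    per_sample_value: dict[str, float] = field(default_factory=dict)
    per_group_value: dict[str, float] = field(default_factory=dict)
    status: str = "ok"  # ok | no_data | no_passing_sites

    def __post_init__(self) -> None:
        if self.status not in ("ok", "no_data", "no_passing_sites"):
            raise ValueError(f"unknown overlay status {self.status!r}")

    @property
    def multi_site(self) -> bool:
        return len(self.matched_sites) > 1


@dataclass(frozen=True)
class SimilarityHit:
    gene: str
    site_id: str
    distance: float
    rank: int


def match_sites(
    graph: PathwayGraph, matrix: OmicsMatrix
) -> dict[str, list[SiteRecord]]:
    """Map each pathway gene label to its matching rows of *matrix*.

    A site matches an entry when its gene symbol equals any entry alias,
    case-insensitively.  Expression matrices yield one pseudo-record per
    matching gene whose "betas" hold the FPKM vector (only used for
    bookkeeping; fold computation reads the matrix directly).
    """
    out: dict[str, list[SiteRecord]] = {}
    if matrix.kind == "methylation":
        by_gene = matrix.sites_by_gene()
        for entry in graph.gene_entries():
            hits: list[SiteRecord] = []
            seen: set[str] = set()
            for alias in entry.aliases:
                for rec in by_gene.get(alias.lower(), []):
                    if rec.site_id not in seen:
                        hits.append(rec)
                        seen.add(rec.site_id)
            out.setdefault(entry.label, []).extend(
                h for h in hits if h.site_id not in {x.site_id for x in out.get(entry.label, [])}
            )
    else:
        lowered = {g.lower(): g for g in matrix.expression}
        for entry in graph.gene_entries():
            hits = []
            for alias in entry.aliases:
                g = lowered.get(alias.lower())
                if g is not None:
                    hits.append(
                        SiteRecord(
                            gene=g, site_id=f"expr:{g}", betas=(),
                        )
                    )
                    break
            out.setdefault(entry.label, []).extend(
                h for h in hits if not out.get(entry.label)
            )
    return out


def apply_filters(
    sites: Sequence[SiteRecord], spec: FilterSpec
) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Partition *sites* into (passing, excluded) under *spec*.

    The two lists are disjoint, preserve input order, and their union is the
    input; filtering the passing list again with the same spec is a no-op.
    """
    passing, excluded = [], []
    for s in sites:
        (passing if spec.passes(s) else excluded).append(s)
    return passing, excluded


def gene_methylation_value(
    sites: Sequence[SiteRecord],
    sample_ids: Sequence[str],
    *,
    sample: str | None = None,
    grouping: SampleGrouping | None = None,
    group: str | None = None,
    aggregator: Callable[[np.ndarray], float] = np.mean,
) -> float:
    """Displayed methylation value for a gene: mean over passing sites.

    With ``sample`` given, returns the mean beta over *sites* for that
    sample (missing skipped).  With ``group`` and ``grouping`` given,
    returns ``aggregator`` (default mean) over the member samples'
    per-sample values.  Returns nan when no data is available — "undefined"
    is a value state, not an error.
    """
    if not sites:
        return float("nan")
    mat = np.array([s.betas for s in sites], dtype=float)  # sites x samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing -> nan
        per_sample = np.nanmean(mat, axis=0)
    if sample is not None:
        return float(per_sample[list(sample_ids).index(sample)])
    if group is not None:
        if grouping is None:
            raise ValueError("group-wise value needs a grouping")
        members = grouping.members(group, sample_ids)
        vals = np.array(
            [per_sample[list(sample_ids).index(m)] for m in members], dtype=float
        )
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return float("nan")
        return float(aggregator(vals))
    raise ValueError("specify sample= or group=")


def expression_fold(
    value: float,
    all_values: Sequence[float] | np.ndarray,
    *,
    scale: float = DEFAULT_FOLD_SCALE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Clipped log2 fold of *value* against the median of *all_values*.

    ``f = log2((value + eps) / (median + eps))`` clipped to [-scale, +scale].
    The pseudocount keeps zero FPKM finite; the median is taken over
    non-missing values of the full sample vector.
    """
    arr = np.asarray(all_values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("all_values is empty")
    if np.isnan(value):
        return float("nan")
    med = float(np.median(arr))
    f = math.log2((value + pseudocount) / (med + pseudocount))
    return float(np.clip(f, -scale, scale))


def build_overlays(
    graph: PathwayGraph,
    matrix: OmicsMatrix,
    spec: FilterSpec | None = None,
    grouping: SampleGrouping | None = None,
    *,
    meth_aggregator: Callable[[np.ndarray], float] = np.mean,
    expr_aggregator: Callable[[np.ndarray], float] = np.median,
    fold_scale: float = DEFAULT_FOLD_SCALE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, GeneOverlay]:
    """Produce one :class:`GeneOverlay` per pathway gene label.

    Status semantics follow the display convention: ``no_data`` when no row
    matched at all (light green), ``no_passing_sites`` when rows matched but
    none survived the filters (gray).
    """
    spec = spec or FilterSpec()
    matched = match_sites(graph, matrix)
    overlays: dict[str, GeneOverlay] = {}
    for label, recs in matched.items():
        ov = GeneOverlay(gene=label)
        if matrix.kind == "methylation":
            if not recs:
                ov.status = "no_data"
            else:
                passing, excluded = apply_filters(recs, spec)
                ov.matched_sites, ov.excluded_sites = passing, excluded
                if not passing:
                    ov.status = "no_passing_sites"
                else:
                    for s in matrix.sample_ids:
                        ov.per_sample_value[s] = gene_methylation_value(
                            passing, matrix.sample_ids, sample=s
                        )
                    if grouping is not None:
                        for g in grouping.group_order:
                            ov.per_group_value[g] = gene_methylation_value(
                                passing,
                                matrix.sample_ids,
                                group=g,
                                grouping=grouping,
                                aggregator=meth_aggregator,
                            )
        else:  # expression
            if not recs:
                ov.status = "no_data"
            else:
                gene = recs[0].gene
                ov.matched_sites = recs
                vec = matrix.expression_vector(gene)
                for i, s in enumerate(matrix.sample_ids):
                    ov.per_sample_value[s] = expression_fold(
                        float(vec[i]), vec, scale=fold_scale, pseudocount=pseudocount
                    )
                if grouping is not None:
                    for g in grouping.group_order:
                        members = grouping.members(g, matrix.sample_ids)
                        raw = np.array(
                            [vec[matrix.sample_index(m)] for m in members], dtype=float
                        )
                        raw = raw[~np.isnan(raw)]
                        if raw.size == 0:
                            ov.per_group_value[g] = float("nan")
                        else:
                            ov.per_group_value[g] = expression_fold(
                                float(expr_aggregator(raw)),
                                vec,
                                scale=fold_scale,
                                pseudocount=pseudocount,
                            )
        overlays[label] = ov
    return overlays


# --------------------------------------------------------------------------
# similar-pattern mining


def _pairwise_distance(
    a: np.ndarray, b: np.ndarray, *, normalized: bool = True
) -> tuple[float, int]:
    """Euclidean distance over pairwise-complete samples.

    Returns (distance, n_shared).  ``normalized`` gives the root-mean-square
    difference so vectors with different missingness are comparable; the
    unnormalized option is the plain Euclidean norm over shared samples.
    """
    mask = ~np.isnan(a) & ~np.isnan(b)
    n = int(mask.sum())
    if n == 0:
        return float("nan"), 0
    d2 = np.sum((a[mask] - b[mask]) ** 2)
    if normalized:
        return float(np.sqrt(d2 / n)), n
    return float(np.sqrt(d2)), n


def find_similar(
    target: str | Sequence[SiteRecord],
    matrix: OmicsMatrix,
    *,
    top_k: int = 10,
    direction: Literal["similar", "dissimilar"] = "similar",
    normalized: bool = True,
    min_shared: int = 2,
) -> list[SimilarityHit]:
    """Rank all loaded sites by Euclidean distance to a target profile.

    ``target`` is a gene symbol (its per-sample mean over all its sites is
    the reference vector) or an explicit set of site records.  Candidates
    are every site in the matrix — not just the current pathway — so hits
    can seed a gene-grid view.  Per gene only the best (minimum-distance)
    site is kept; the target's own gene is excluded.  Hits are ranked
    ascending for ``similar``, descending for ``dissimilar``; distance ties
    break lexicographically by gene symbol.  Candidates sharing fewer than
    ``min_shared`` non-missing samples with the target are skipped.
    """
    if matrix.kind != "methylation" and isinstance(target, str):
        # expression mining: treat each gene vector as the "site"
        return _find_similar_expression(
            target, matrix, top_k=top_k, direction=direction, normalized=normalized,
            min_shared=min_shared,
        )
    if isinstance(target, str):
        own = [r for r in matrix.rows if r.gene.lower() == target.lower()]
        if not own:
            raise KeyError(f"gene {target!r} has no sites in the matrix")
        target_sites = own
        target_gene = target.lower()
    else:
        target_sites = list(target)
        if not target_sites:
            raise ValueError("empty target site set")
        target_gene = target_sites[0].gene.lower()
    tmat = np.array([s.betas for s in target_sites], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing -> nan
        tvec = np.nanmean(tmat, axis=0)

    best: dict[str, tuple[float, str]] = {}
    for rec in matrix.rows:
        if rec.gene.lower() == target_gene:
            continue
        d, n = _pairwise_distance(tvec, rec.beta_array, normalized=normalized)
        if n < min_shared:
            logger.debug("skipping %s: only %d shared samples", rec.site_id, n)
            continue
        key = rec.gene
        if key not in best or (d, rec.site_id) < best[key]:
            best[key] = (d, rec.site_id)

    reverse = direction == "dissimilar"
    ordered = sorted(
        best.items(),
        key=lambda kv: ((-kv[1][0] if reverse else kv[1][0]), kv[0].lower()),
    )
    hits = [
        SimilarityHit(gene=g, site_id=sid, distance=d, rank=i + 1)
        for i, (g, (d, sid)) in enumerate(ordered[:top_k])
    ]
    return hits


def _find_similar_expression(
    target: str,
    matrix: OmicsMatrix,
    *,
    top_k: int,
    direction: str,
    normalized: bool,
    min_shared: int,
) -> list[SimilarityHit]:
    tvec = matrix.expression_vector(target)
    best: dict[str, tuple[float, str]] = {}
    for gene, vals in matrix.expression.items():
        if gene.lower() == target.lower():
            continue
        d, n = _pairwise_distance(tvec, np.asarray(vals, dtype=float), normalized=normalized)
        if n < min_shared:
            continue
        best[gene] = (d, f"expr:{gene}")
    reverse = direction == "dissimilar"
    ordered = sorted(
        best.items(),
        key=lambda kv: ((-kv[1][0] if reverse else kv[1][0]), kv[0].lower()),
    )
    return [
        SimilarityHit(gene=g, site_id=sid, distance=d, rank=i + 1)
        for i, (g, (d, sid)) in enumerate(ordered[:top_k])
    ]


# --------------------------------------------------------------------------
# methylation-expression correlation


def methylation_expression_correlation(
    meth: Sequence[float] | np.ndarray, expr: Sequence[float] | np.ndarray
) -> tuple[float | None, float | None]:
    """Spearman rank correlation between paired methylation and expression.

    Uses mean ranks for ties; the p-value comes from the t-distribution
    approximation with n-2 degrees of freedom.  Pairs with a missing value
    on either side are dropped.  A constant vector makes rho undefined and
    returns (None, None) rather than a spurious number.
    """
    m = np.asarray(meth, dtype=float)
    e = np.asarray(expr, dtype=float)
    mask = ~np.isnan(m) & ~np.isnan(e)
    m, e = m[mask], e[mask]
    if m.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {m.size}")
    if np.all(m == m[0]) or np.all(e == e[0]):
        return None, None
    rho, p = stats.spearmanr(m, e)
    if np.isnan(rho):
        return None, None
    return float(rho), float(p)


def correlation_screen(
    meth: OmicsMatrix,
    expr: OmicsMatrix,
    *,
    threshold: float = -0.7,
    spec: FilterSpec | None = None,
    bh_alpha: float | None = None,
) -> dict[str, tuple[str, float, float]]:
    """Genes whose best site anti-correlates with expression below *threshold*.

    For every gene with both methylation sites (surviving *spec*) and an
    expression row, each site's beta vector is correlated with the gene's
    FPKM vector; the site with the most negative rho represents the gene.
    Returns gene -> (site_id, rho, p) for genes with rho < threshold.
    With ``bh_alpha`` set, a Benjamini-Hochberg FDR pass over the best-site
    p-values additionally requires significance at that level.
    """
    spec = spec or FilterSpec()
    lowered_expr = {g.lower(): g for g in expr.expression}
    per_gene_best: dict[str, tuple[str, float, float]] = {}
    for gene, sites in meth.sites_by_gene().items():
        expr_gene = lowered_expr.get(gene)
        if expr_gene is None:
            continue
        passing, _ = apply_filters(sites, spec)
        evec = expr.expression_vector(expr_gene)
        best: tuple[str, float, float] | None = None
        for site in passing:
            try:
                rho, p = methylation_expression_correlation(site.beta_array, evec)
            except ValueError:
                continue
            if rho is None:
                continue
            if best is None or rho < best[1]:
                best = (site.site_id, rho, p)
        if best is not None:
            per_gene_best[expr_gene] = best
    hits = {g: v for g, v in per_gene_best.items() if v[1] < threshold}
    if bh_alpha is not None and hits:
        genes = sorted(per_gene_best, key=lambda g: per_gene_best[g][2])
        pvals = np.array([per_gene_best[g][2] for g in genes])
        n = len(pvals)
        passed: set[str] = set()
        # BH step-up
        thresholds = bh_alpha * (np.arange(1, n + 1) / n)
        below = np.nonzero(pvals <= thresholds)[0]
        if below.size:
            passed = set(genes[: below.max() + 1])
        hits = {g: v for g, v in hits.items() if g in passed}
    return hits


def order_samples(
    matrix: OmicsMatrix,
    key_gene: str,
    spec: FilterSpec | None = None,
) -> list[str]:
    """Samples sorted ascending by *key_gene*'s methylation display value.

    Undefined (all-missing) samples sort last; ties and the undefined block
    keep the original sample order (the sort is stable).
    """
    spec = spec or FilterSpec()
    sites = [r for r in matrix.rows if r.gene.lower() == key_gene.lower()]
    if not sites:
        raise KeyError(f"gene {key_gene!r} not present in the matrix")
    passing, _ = apply_filters(sites, spec)
    if not passing:
        raise ValueError(f"gene {key_gene!r} has no sites passing the filter")
    values = {
        s: gene_methylation_value(passing, matrix.sample_ids, sample=s)
        for s in matrix.sample_ids
    }
    defined = [s for s in matrix.sample_ids if not np.isnan(values[s])]
    undefined = [s for s in matrix.sample_ids if np.isnan(values[s])]
    defined.sort(key=lambda s: values[s])  # python sort is stable
    return defined + undefined
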