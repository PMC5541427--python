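"""Synthetic pathways and two-group methylation/expression datasets.

Real demonstrations of this kind of overlay lean on large tumor cohorts
(two groups of samples split by a driver mutation, a handful of CpG sites
whose methylation flips between the groups, and a few genes whose
expression is silenced as methylation rises).  This module emulates that
structure at toy scale so the whole pipeline — parsing, filtering, mining,
correlation and rendering — is exercisable without any download.

Everything is driven by a single integer seed and is bit-reproducible:
the same spec always yields byte-identical TSV/KGML output.

The generator plants, per planted gene, one CpG site whose group means
differ by a chosen delta (default 0.15 vs 0.65, i.e. a 0.5 beta swing, the
kind of swing hypermethylation screens flag) against low-variance
background sites, and couples some planted genes' expression to their
methylation through a strictly decreasing map with multiplicative
log-normal noise.  A truth table of planted site keys and coupled genes is
written next to the matrices so recovery tests are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import OmicsMatrix, read_methylation_matrix
from .kgml import parse_kgml

__all__ = ["SyntheticSpec", "make_kgml", "make_dataset", "read_truth"]

RELATION_SUBTYPE_CYCLE = (
    "activation",
    "inhibition",
    "expression",
    "repression",
    "methylation",
    "unknown",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic two-group dataset.

    Defaults encode the planted-signal conditions the test-suite recovers:
    a 0.5 beta-value separation between groups at the planted sites,
    Gaussian noise of 0.05, and 20 samples per group.
    """

    n_genes: int = 12
    sites_per_gene: int = 3
    n_samples_per_group: int = 20
    groups: tuple[str, ...] = ("mutant", "wild-type")
    n_planted_genes: int = 4
    planted_means: tuple[float, ...] = (0.15, 0.65)  # one mean per group
    background_mean: float = 0.35
    noise_sd: float = 0.05
    n_coupled_genes: int = 2  # coupled genes are the first planted genes
    coupling_strength: float = 4.0  # log2-fold drop per unit beta
    base_fpkm: float = 50.0
    expression_noise_sd: float = 0.1  # sd of log-normal factor, 0 = strict monotone
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.planted_means) != len(self.groups):
            raise ValueError("planted_means must give one mean per group")
        if self.n_planted_genes > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.n_coupled_genes > self.n_planted_genes:
            raise ValueError("coupled genes must be planted genes")
        if not all(0 <= m <= 1 for m in self.planted_means):
            raise ValueError("planted means must be betas in [0,1]")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(f"GENE{i + 1}" for i in range(self.n_genes))

    @property
    def planted_genes(self) -> tuple[str, ...]:
        return self.gene_names[: self.n_planted_genes]

    @property
    def coupled_genes(self) -> tuple[str, ...]:
        return self.gene_names[: self.n_coupled_genes]

    @property
    def sample_ids(self) -> tuple[str, ...]:
        out = []
        for gi, g in enumerate(self.groups):
            for i in range(self.n_samples_per_group):
                out.append(f"S{gi * self.n_samples_per_group + i + 1:03d}")
        return tuple(out)


def make_kgml(n_genes: int, n_relations: int, seed: int = 0, *,
              pathway_id: str = "syn00001", title: str = "synthetic pathway") -> bytes:
    """Emit a small valid KGML document with gene entries on a grid.

    Entries are named GENE1..GENEn and laid out row-major; relations connect
    deterministically chosen pairs with subtypes cycling through activation,
    inhibition, expression, repression, methylation and unknown.  Output is
    byte-identical for identical arguments.
    """
    if n_relations > n_genes * (n_genes - 1):
        raise ValueError("too many relations for the number of genes")
    rng = np.random.default_rng(seed)
    ncol = max(1, int(np.ceil(np.sqrt(n_genes))))
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<pathway name="path:{pathway_id}" org="syn" title="{title}">',
    ]
    for i in range(n_genes):
        r, c = divmod(i, ncol)
        x = 70 + c * 120
        y = 50 + r * 70
        lines.append(
            f'  <entry id="{i + 1}" name="syn:{i + 1}" type="gene">'
            f'<graphics name="GENE{i + 1}" type="rectangle" '
            f'x="{x}" y="{y}" width="46" height="17"/></entry>'
        )
    # deterministic distinct ordered pairs
    pairs = [(a + 1, b + 1) for a in range(n_genes) for b in range(n_genes) if a != b]
    idx = rng.permutation(len(pairs))[:n_relations]
    for k, pi in enumerate(sorted(idx)):
        a, b = pairs[pi]
        subtype = RELATION_SUBTYPE_CYCLE[k % len(RELATION_SUBTYPE_CYCLE)]
        lines.append(
            f'  <relation entry1="{a}" entry2="{b}" type="PPrel">'
            f'<subtype name="{subtype}" value=""/></relation>'
        )
    lines.append("</pathway>")
    return ("\n".join(lines) + "\n").encode("utf-8")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=n), 0.0, 1.0)


def make_dataset(
    spec: SyntheticSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Generate the methylation, expression, grouping and truth-table TSVs.

    Planted sites (the first site of each planted gene) draw group-specific
    means; background sites share ``background_mean`` across groups.
    Coupled genes' FPKM follows ``base * 2^(-k * beta_planted)`` times
    log-normal noise, so with zero noise expression is a strictly decreasing
    function of methylation.  Returns the paths keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    samples = spec.sample_ids
    n_per = spec.n_samples_per_group

    locations = ("upstream", "exonic", "intronic")
    meth_rows: list[tuple[str, np.ndarray]] = []
    planted_keys: list[str] = []
    planted_beta: dict[str, np.ndarray] = {}
    site_counter = 0
    for gene in spec.gene_names:
        for si in range(spec.sites_per_gene):
            site_counter += 1
            site_id = f"cg{site_counter:08d}"
            location = locations[si % len(locations)]
            key = f"{gene}_{site_id}_{location}"
            is_planted = gene in spec.planted_genes and si == 0
            if is_planted:
                parts = [
                    _truncated_normal(rng, m, spec.noise_sd, n_per)
                    for m in spec.planted_means
                ]
                betas = np.concatenate(parts)
                planted_keys.append(site_id)
                planted_beta[gene] = betas
            else:
                betas = _truncated_normal(rng, spec.background_mean, spec.noise_sd,
                                          len(samples))
            meth_rows.append((key, betas))

    expr_rows: list[tuple[str, np.ndarray]] = []
    for gene in spec.gene_names:
        if gene in spec.coupled_genes:
            beta = planted_beta[gene]
            base = spec.base_fpkm * np.power(2.0, -spec.coupling_strength * beta)
            if spec.expression_noise_sd > 0:
                base = base * np.exp(rng.normal(0.0, spec.expression_noise_sd,
                                                len(samples)))
            expr = base
        else:
            expr = spec.base_fpkm * np.exp(rng.normal(0.0, 0.3, len(samples)))
        expr_rows.append((gene, np.maximum(expr, 0.0)))

    meth_path = out_dir / "methylation.tsv"
    with open(meth_path, "w", encoding="utf-8") as fh:
        fh.write("site\t" + "\t".join(samples) + "\n")
        for key, betas in meth_rows:
            fh.write(key + "\t" + "\t".join(f"{b:.6f}" for b in betas) + "\n")

    expr_path = out_dir / "expression.tsv"
    with open(expr_path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(samples) + "\n")
        for gene, vals in expr_rows:
            fh.write(gene + "\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")

    group_path = out_dir / "groups.tsv"
    with open(group_path, "w", encoding="utf-8") as fh:
        for gi, g in enumerate(spec.groups):
            for i in range(n_per):
                fh.write(f"S{gi * n_per + i + 1:03d}\t{g}\n")

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("kind\tkey\tgene\n")
        for site_id, gene in zip(planted_keys, spec.planted_genes):
            fh.write(f"planted_site\t{site_id}\t{gene}\n")
        for gene in spec.coupled_genes:
            fh.write(f"coupled_gene\t{gene}\t{gene}\n")

    kgml_path = out_dir / "pathway.kgml"
    kgml_path.write_bytes(
        make_kgml(spec.n_genes, min(spec.n_genes * 2, spec.n_genes * (spec.n_genes - 1)),
                  spec.seed)
    )

    return {
        "methylation": meth_path,
        "expression": expr_path,
        "grouping": group_path,
        "truth": truth_path,
        "kgml": kgml_path,
    }


def read_truth(path: str | Path) -> tuple[set[str], set[str]]:
    """Read a truth table back as (planted site ids, coupled gene symbols)."""
    planted: set[str] = set()
    coupled: set[str] = set()
    for line in Path(path).read_text().splitlines()[1:]:
        kind, key, _gene = line.split("\t")
        if kind == "planted_site":
            planted.add(key)
        elif kind == "coupled_gene":
            coupled.add(key)
    return planted, coupled
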