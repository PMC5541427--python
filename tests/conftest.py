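import io
import random

import numpy as np
import pytest

from methpath.io import OmicsMatrix, SiteRecord, read_methylation_matrix
from methpath.kgml import EntryNode, GraphicsBox, PathwayGraph, RelationEdge
from methpath.synth import SyntheticSpec, make_dataset

# hand-built KGML: 3 gene entries, 1 map entry, 2 relations
FIXTURE_KGML = b"""<?xml version="1.0" encoding="UTF-8"?>
<pathway name="path:hsa04668" org="hsa" title="TNF signaling pathway">
  <entry id="10" name="hsa:2064" type="gene">
    <graphics name="ERBB2, HER-2, ..." type="rectangle" x="100" y="60" width="46" height="17"/>
  </entry>
  <entry id="11" name="hsa:355" type="gene">
    <graphics name="FAS" type="rectangle" x="220" y="60" width="46" height="17"/>
  </entry>
  <entry id="12" name="hsa:841" type="gene">
    <graphics name="CASP8" type="rectangle" x="160" y="140" width="46" height="17"/>
  </entry>
  <entry id="13" name="path:hsa04210" type="map">
    <graphics name="Apoptosis" type="roundrectangle" x="300" y="140" width="80" height="25"/>
  </entry>
  <relation entry1="10" entry2="12" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="11" entry2="12" type="PPrel">
    <subtype name="inhibition" value="--|"/>
  </relation>
</pathway>
"""


@pytest.fixture
def fixture_kgml() -> bytes:
    return FIXTURE_KGML


def make_matrix(rows, sample_ids=("s1", "s2", "s3")):
    """Build a methylation OmicsMatrix from (key, betas) pairs via the TSV reader."""
    lines = ["site\t" + "\t".join(sample_ids)]
    for key, betas in rows:
        cells = [
            "NA" if b is None or (isinstance(b, (float, np.floating)) and np.isnan(b))
            else format(float(b), ".17g")
            for b in betas
        ]
        lines.append(key + "\t" + "\t".join(cells))
    return read_methylation_matrix(io.StringIO("\n".join(lines) + "\n"))


@pytest.fixture
def small_meth_matrix() -> OmicsMatrix:
    return make_matrix(
        [
            ("ERBB2_cg00000001_UTR5", (0.1, 0.5, 0.9)),
            ("ERBB2_cg00000002_exonic", (0.2, 0.5, 0.8)),
            ("FAS_cg00000003_upstream", (0.4, 0.4, 0.4)),
            ("CASP8_cg00000004", (0.0, 0.5, 1.0)),
        ]
    )


def random_graph(rng: random.Random, max_entries: int = 20) -> PathwayGraph:
    """Random small pathway graph for round-trip property tests."""
    n = rng.randint(1, max_entries)
    entries = []
    for i in range(n):
        etype = rng.choice(["gene", "gene", "compound", "map"])
        label = f"G{i}" if etype == "gene" else (f"C{i}" if etype == "compound" else f"M{i}")
        aliases = tuple([label] + [f"{label}-ALT{j}" for j in range(rng.randint(0, 2))])
        entries.append(
            EntryNode(
                entry_id=str(i + 1),
                entry_type=etype,
                kegg_ids=(f"hsa:{100 + i}",),
                label=label,
                aliases=aliases,
                graphics=GraphicsBox(
                    x_center=float(rng.randint(20, 600)),
                    y_center=float(rng.randint(20, 400)),
                    width=46.0,
                    height=17.0,
                ),
            )
        )
    relations = []
    if n >= 2:
        for _ in range(rng.randint(0, 2 * n)):
            a, b = rng.sample(range(1, n + 1), 2)
            subtypes = frozenset(
                rng.sample(
                    ["activation", "inhibition", "expression", "methylation", "unknown"],
                    rng.randint(0, 2),
                )
            )
            relations.append(RelationEdge(str(a), str(b), "PPrel", subtypes))
    return PathwayGraph("syn00001", "syn", "random pathway", entries, relations)


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    """Default study conditions: planted dbeta = 0.5, sigma = 0.05, 20+20 samples."""
    out = tmp_path_factory.mktemp("synth")
    spec = SyntheticSpec(seed=1)
    paths = make_dataset(spec, out)
    return spec, paths
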