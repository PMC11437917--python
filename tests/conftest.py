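"""Shared fixtures: synthetic datasets at two scales plus brute-force oracles.

The oracles here re-derive expected values by straightforward enumeration,
independently of the library's vectorized code paths.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pytest

from snvmap import FixtureSpec, PipelineConfig, convert, generate
from snvmap.cli import cmd_all

# ---------------------------------------------------------------------------
# brute-force recount oracle (independent of snvmap.variant_ingest)
# ---------------------------------------------------------------------------


def brute_force_recount(cells_dir: Path, keep_class: str = "nonsynonymous SNV"):
    """Line-by-line recount of multianno files: per cell, per gene counts.

    Duplicate (chrom, pos, ref, alt) rows within a cell count once; a row
    listing several genes increments each of them; only single-base
    substitutions of the kept functional class count.
    """
    out = {}
    for f in sorted(Path(cells_dir).iterdir()):
        cell = f.name.split(".")[0]
        counts = {}
        seen = set()
        lines = f.read_text().splitlines()
        header = lines[0].split("\t")
        gi = header.index("Gene.refGene")
        fi = header.index("ExonicFunc.refGene")
        for line in lines[1:]:
            p = line.split("\t")
            key = (p[0], p[1], p[3], p[4])
            if key in seen:
                continue
            seen.add(key)
            if p[fi] != keep_class:
                continue
            if len(p[3]) != 1 or len(p[4]) != 1 or p[3] not in "ACGT" or p[4] not in "ACGT":
                continue
            genes = []
            for tok in re.split(r"[;,]", re.sub(r"\(.*?\)", "", p[gi])):
                g = tok.split(":")[0].strip()
                if g and g not in genes:
                    genes.append(g)
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        out[cell] = counts
    return out


def percentile_oracle(values, p):
    """Sort + linear interpolation percentile, written out longhand."""
    v = sorted(float(x) for x in values)
    if len(v) == 1:
        return v[0]
    h = (p / 100.0) * (len(v) - 1)
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


# ---------------------------------------------------------------------------
# fixture datasets
# ---------------------------------------------------------------------------

SMALL_SPEC = FixtureSpec(
    n_groups=2,
    cells_per_group=6,
    signature_size=12,
    n_background_genes=60,
    per_cell_signature_rate=0.9,
    background_rate=0.05,
    synonymous_rate=0.05,
    patients_per_group=2,
    seed=11,
)

# QC thresholds sized for the small fixture (cells carry ~14 mutated genes)
SMALL_CONFIG = PipelineConfig(
    min_cells_per_gene=2,
    min_genes_per_cell=5,
    upper_percentile=98.0,
    n_hvg=40,
    n_neighbors=3,
    n_pcs=5,
    seed=0,
)

# the planted-cluster study conditions: 3 groups x 20 cells, signature 60,
# signature rate 0.8, background rate 0.02, seed 0, default pipeline config
PLANTED_SPEC = FixtureSpec(n_groups=3, cells_per_group=20, signature_size=60, seed=0)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("small_fixture")
    out = generate(SMALL_SPEC, d)
    out["spec"] = SMALL_SPEC
    return out


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return convert(small_dataset["cells_dir"], small_dataset["metadata_path"])


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("planted_fixture")
    out = generate(PLANTED_SPEC, d)
    out["spec"] = PLANTED_SPEC
    return out


@pytest.fixture(scope="session")
def planted_run(planted_dataset, tmp_path_factory):
    """Full default-config pipeline (`all`) on the planted dataset."""
    out_dir = tmp_path_factory.mktemp("planted_run")
    result = cmd_all(
        planted_dataset["cells_dir"], planted_dataset["metadata_path"], out_dir
    )
    result["out_dir"] = out_dir
    result["truth"] = planted_dataset["truth"]
    return result
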