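"""Synthetic ANNOVAR-style per-cell mutation tables with planted groups.

Each of ``n_groups`` groups owns a disjoint signature set of genes; a member
cell mutates each signature gene with probability
``per_cell_signature_rate`` and every background gene with probability
``background_rate``. Synonymous decoy rows are interleaved so the
functional-class filter has work to do. Positions and alleles are synthetic
(gene symbols G00001...), not tied to a real genome build: the fixtures
exercise counting and clustering, not annotation fidelity.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import SnvmapError, UserInputError

_BASES = np.array(list("ACGT"))
_STAGES = ["I", "II", "III", "IV"]

_MULTIANNO_HEADER = (
    "Chr\tStart\tEnd\tRef\tAlt\tFunc.refGene\tGene.refGene\tExonicFunc.refGene\tcosmic70"
)


@dataclass
class FixtureSpec:
    """Generator parameters for a planted-group mutation dataset."""

    n_groups: int = 3
    cells_per_group: int = 20
    signature_size: int = 60
    n_background_genes: int = 2000
    per_cell_signature_rate: float = 0.8
    background_rate: float = 0.02
    synonymous_rate: float = 0.01
    patients_per_group: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.per_cell_signature_rate, self.background_rate, self.synonymous_rate):
            if not (0.0 <= p <= 1.0):
                raise UserInputError("rates must be probabilities in [0, 1]")
        if self.n_groups < 1 or self.cells_per_group < 1:
            raise UserInputError("need at least one group and one cell per group")
        if self.patients_per_group < 1:
            raise UserInputError("patients_per_group must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.n_groups * self.cells_per_group

    @property
    def n_genes(self) -> int:
        return self.n_groups * self.signature_size + self.n_background_genes

    def gene_names(self) -> List[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]

    def signature_genes(self, group: int) -> List[str]:
        names = self.gene_names()
        start = group * self.signature_size
        return names[start : start + self.signature_size]

    def expected_mutated_genes_per_cell(self) -> Tuple[float, float]:
        """Mean and standard deviation of distinct nonsynonymous-mutated
        genes per cell (sum of independent Bernoulli trials)."""
        ps = [self.per_cell_signature_rate] * self.signature_size
        ps += [self.background_rate] * (
            self.n_background_genes + (self.n_groups - 1) * self.signature_size
        )
        ps = np.asarray(ps)
        return float(ps.sum()), float(np.sqrt((ps * (1 - ps)).sum()))


def _variant_row(rng, gene: str, gene_idx: int, func: str) -> str:
    chrom = f"chr{1 + gene_idx % 22}"
    pos = 1_000_000 + gene_idx * 10_000 + int(rng.integers(0, 5000))
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    exonic = "nonsynonymous SNV" if func == "nonsynonymous SNV" else "synonymous SNV"
    return (
        f"{chrom}\t{pos}\t{pos}\t{ref}\t{alt}\texonic\t{gene}\t{exonic}\t."
    )


def generate(spec: FixtureSpec, out_dir) -> Dict[str, object]:
    """Write per-cell multianno tables, a metadata CSV and ground truth.

    Returns a dict with ``cells_dir``, ``metadata_path``, ``truth_path`` and
    the ground-truth DataFrame (cell_id, patient, group). Fully determined
    by ``spec.seed``.
    """
    out_dir = Path(out_dir)
    cells_dir = out_dir / "cells"
    try:
        cells_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise SnvmapError(f"cannot create output directory {out_dir}: {e}") from e

    rng = np.random.default_rng(spec.seed)
    gene_names = spec.gene_names()
    n_sig_total = spec.n_groups * spec.signature_size

    truth_rows = []
    meta_rows: Dict[str, Dict[str, object]] = {}
    for g in range(spec.n_groups):
        sig_idx = np.arange(g * spec.signature_size, (g + 1) * spec.signature_size)
        group_name = f"group{g + 1}"
        for c in range(spec.cells_per_group):
            p = c % spec.patients_per_group
            patient = f"P{g + 1:02d}{p + 1:02d}"
            cell_id = f"{patient}_c{c:03d}"
            lines = [_MULTIANNO_HEADER]
            # signature genes
            hit = sig_idx[rng.random(spec.signature_size) < spec.per_cell_signature_rate]
            # background genes: everything outside this group's signature
            other = np.concatenate(
                [
                    np.arange(0, g * spec.signature_size),
                    np.arange((g + 1) * spec.signature_size, spec.n_genes),
                ]
            )
            bg_hit = other[rng.random(len(other)) < spec.background_rate]
            for gi in np.concatenate([hit, bg_hit]):
                lines.append(_variant_row(rng, gene_names[gi], int(gi), "nonsynonymous SNV"))
            # synonymous decoys (filtered out by the default functional filter)
            syn = np.flatnonzero(rng.random(spec.n_genes) < spec.synonymous_rate)
            for gi in syn:
                lines.append(_variant_row(rng, gene_names[gi], int(gi), "synonymous SNV"))
            (cells_dir / f"{cell_id}.hg38_multianno.txt").write_text(
                "\n".join(lines) + "\n"
            )
            truth_rows.append({"cell_id": cell_id, "patient": patient, "group": group_name})
            if patient not in meta_rows:
                meta_rows[patient] = {
                    "sample_id": patient,
                    "group": group_name,
                    "stage": _STAGES[(g * spec.patients_per_group + p) % len(_STAGES)],
                    "n_cells": 0,
                }
            meta_rows[patient]["n_cells"] += 1

    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    metadata_path = out_dir / "metadata.csv"
    pd.DataFrame(list(meta_rows.values())).to_csv(metadata_path, index=False)
    return {
        "cells_dir": cells_dir,
        "metadata_path": metadata_path,
        "truth_path": truth_path,
        "truth": truth,
    }


def make_zip(cells_dir, zip_path) -> Path:
    """Zip the per-cell files with fixed timestamps, so the archive bytes are
    a pure function of the file contents."""
    cells_dir = Path(cells_dir)
    zip_path = Path(zip_path)
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for f in sorted(cells_dir.iterdir()):
            if f.is_file():
                info = zipfile.ZipInfo(f.name, date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, f.read_bytes())
    return zip_path
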