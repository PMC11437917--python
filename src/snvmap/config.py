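"""Pipeline configuration with the published default thresholds.

The defaults mirror the adapted single-cell workflow this tool implements:
genes mutated in fewer than 3 cells are dropped, cells with fewer than 30
mutated genes are dropped, cells whose mutated-gene count exceeds the 98th
percentile of all cells are dropped, counts are normalized to the median
per-cell total and log1p-transformed, and the top 3000 highly variable
genes are retained before regressing out total counts per cell.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Union

from .errors import UserInputError


@dataclass
class PipelineConfig:
    """All thresholds and seeds of the processing pipeline.

    Parameters
    ----------
    min_cells_per_gene
        A gene is kept only if mutated in at least this many cells.
    min_genes_per_cell
        A cell is kept only if it has at least this many mutated genes.
    upper_percentile
        Cells whose mutated-gene count strictly exceeds this percentile
        (linear interpolation) of all retained cells are removed as outliers.
    n_hvg
        Number of highly variable genes retained for embedding.
    target_sum
        Per-cell total after normalization; ``"median"`` uses the median of
        the pre-normalization per-cell totals.
    n_pcs
        Number of principal components (capped below the matrix rank).
    n_neighbors
        Size of the kNN neighborhood for the cell graph.
    resolution
        Resolution parameter shared by Leiden and Louvain.
    seed
        Seed for PCA, UMAP and clustering.
    scale
        If True, z-score genes to unit variance before PCA (off by default:
        only the printed pipeline steps run unless asked for).
    percentile_before_min_genes
        If True, compute the upper-percentile cut before the min-genes
        filter instead of after.
    """

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 30
    upper_percentile: float = 98.0
    n_hvg: int = 3000
    target_sum: Union[float, str] = "median"
    n_pcs: int = 50
    n_neighbors: int = 15
    resolution: float = 1.0
    seed: int = 0
    scale: bool = False
    percentile_before_min_genes: bool = False
    min_cells_per_patient_gene: int = 2
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.min_cells_per_gene < 1:
            raise UserInputError("min_cells_per_gene must be >= 1")
        if self.min_genes_per_cell < 1:
            raise UserInputError("min_genes_per_cell must be >= 1")
        if not (0 < self.upper_percentile <= 100):
            raise UserInputError("upper_percentile must be in (0, 100]")
        if self.n_hvg < 1:
            raise UserInputError("n_hvg must be >= 1")
        if isinstance(self.target_sum, str):
            if self.target_sum != "median":
                raise UserInputError('target_sum must be a positive number or "median"')
        elif self.target_sum <= 0:
            raise UserInputError("target_sum must be positive")
        if self.n_pcs < 2:
            raise UserInputError("n_pcs must be >= 2")
        if self.n_neighbors < 2:
            raise UserInputError("n_neighbors must be >= 2")
        if self.resolution <= 0:
            raise UserInputError("resolution must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})
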