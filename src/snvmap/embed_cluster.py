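"""PCA -> kNN graph -> UMAP embedding -> Leiden/Louvain cluster labels.

PCA and the neighbor graph come from the standard single-cell workflow
(scanpy); UMAP runs from the neighbor graph so that the embedding and the
clustering see the same topology. Leiden uses leidenalg's
RBConfiguration partition; Louvain uses igraph's multilevel algorithm.
Cluster labels are renamed in order of descending cluster size so that
label "0" is always the largest cluster.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import PipelineConfig
from .errors import SnvmapError, UserInputError

logger = logging.getLogger(__name__)

VALID_ALGORITHMS = ("leiden", "louvain")


@dataclass
class EmbeddingResult:
    """Per-cell 2-D coordinates, cluster labels and the cell graph."""

    coords: np.ndarray
    leiden_labels: np.ndarray
    louvain_labels: np.ndarray
    graph: sp.csr_matrix
    cell_ids: List[str]
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise SnvmapError("embedding coordinates contain non-finite values")
        n = len(self.cell_ids)
        if self.coords.shape != (n, 2):
            raise SnvmapError("coords must be n_cells x 2")
        if len(self.leiden_labels) != n or len(self.louvain_labels) != n:
            raise SnvmapError("label arrays must align with cell order")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "umap_1": self.coords[:, 0],
                "umap_2": self.coords[:, 1],
                "leiden": self.leiden_labels,
                "louvain": self.louvain_labels,
            },
            index=pd.Index(self.cell_ids, name="cell_id"),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PCA + neighbor graph
# ---------------------------------------------------------------------------


def reduce_and_graph(
    values: np.ndarray,
    n_pcs: int = 50,
    n_neighbors: int = 15,
    seed: int = 0,
) -> Tuple[sp.csr_matrix, np.ndarray]:
    """PCA scores and a symmetric kNN connectivity graph on them.

    ``n_pcs`` is capped at min(n_cells, n_genes) - 1. Returns
    (connectivities, pc_scores).
    """
    import scanpy as sc
    import anndata as ad

    values = np.asarray(values, dtype=np.float64)
    n_cells, n_genes = values.shape
    if n_neighbors < 2:
        raise UserInputError("n_neighbors must be >= 2")
    if n_cells <= n_neighbors:
        raise UserInputError(
            f"n_neighbors={n_neighbors} must be smaller than the number of "
            f"cells ({n_cells}); pass a smaller --n-neighbors"
        )
    n_comps = min(n_pcs, n_cells - 1, n_genes - 1)
    if n_comps < 2:
        raise UserInputError("need at least 3 cells and 3 genes for PCA")

    adata = ad.AnnData(values.astype(np.float32))
    sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, use_rep="X_pca", random_state=seed)
    graph = sp.csr_matrix(adata.obsp["connectivities"])
    graph.setdiag(0)
    graph.eliminate_zeros()
    graph = (graph + graph.T) / 2.0  # enforce symmetric sparsity pattern
    return graph, np.asarray(adata.obsm["X_pca"], dtype=np.float64)


# ---------------------------------------------------------------------------
# UMAP
# ---------------------------------------------------------------------------


def umap_embed(graph: sp.csr_matrix, scores: np.ndarray, seed: int = 0,
               n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP coordinates from the precomputed neighbor graph.

    The graph's connectivities serve as the fuzzy simplicial set, so the
    embedding is consistent with the clustering topology.
    """
    import scanpy as sc
    import anndata as ad

    if graph.nnz == 0:
        raise SnvmapError("degenerate neighbor graph: no edges")
    n = graph.shape[0]
    adata = ad.AnnData(np.asarray(scores, dtype=np.float32))
    adata.obsm["X_pca"] = np.asarray(scores, dtype=np.float32)
    adata.obsp["connectivities"] = sp.csr_matrix(graph)
    adata.obsp["distances"] = sp.csr_matrix(graph.shape)
    adata.uns["neighbors"] = {
        "connectivities_key": "connectivities",
        "distances_key": "distances",
        "params": {"n_neighbors": n_neighbors, "method": "umap", "use_rep": "X_pca"},
    }
    sc.tl.umap(adata, random_state=seed)
    coords = np.asarray(adata.obsm["X_umap"], dtype=np.float64)
    if coords.shape != (n, 2) or not np.all(np.isfinite(coords)):
        raise SnvmapError("UMAP produced invalid coordinates")
    return coords


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _graph_to_igraph(graph: sp.csr_matrix):
    import igraph as ig

    g = sp.coo_matrix(sp.triu(graph, k=1))
    edges = list(zip(g.row.tolist(), g.col.tolist()))
    graph_ig = ig.Graph(n=graph.shape[0], edges=edges)
    graph_ig.es["weight"] = g.data.tolist()
    return graph_ig


def _relabel_by_size(membership: Sequence[int]) -> np.ndarray:
    """Rename cluster labels 0..K-1 in descending cluster size; ties broken
    by first occurrence, for stable naming."""
    membership = np.asarray(membership)
    labels, first_pos = np.unique(membership, return_index=True)
    sizes = np.array([(membership == l).sum() for l in labels])
    order = sorted(range(len(labels)), key=lambda i: (-sizes[i], first_pos[i]))
    mapping = {labels[i]: rank for rank, i in enumerate(order)}
    return np.array([str(mapping[m]) for m in membership], dtype=object)


def cluster(
    graph: sp.csr_matrix,
    algorithm: str = "leiden",
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Partition the cell graph with Leiden or Louvain.

    Returns string labels "0".."K-1" ordered by descending cluster size;
    deterministic given the seed.
    """
    if algorithm not in VALID_ALGORITHMS:
        raise UserInputError(
            f"unknown clustering algorithm {algorithm!r}; valid options: "
            + ", ".join(VALID_ALGORITHMS)
        )
    if graph.nnz == 0:
        raise SnvmapError("cannot cluster a graph with no edges")
    g = _graph_to_igraph(graph)
    if algorithm == "leiden":
        import leidenalg as la

        part = la.find_partition(
            g,
            la.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        membership = part.membership
    else:
        import igraph as ig

        ig.set_random_number_generator(random.Random(seed))
        part = g.community_multilevel(weights="weight", resolution=resolution)
        membership = part.membership
    return _relabel_by_size(membership)


# ---------------------------------------------------------------------------
# full embedding run
# ---------------------------------------------------------------------------


def run_embedding(
    values: np.ndarray,
    cell_ids: Sequence[str],
    config: Optional[PipelineConfig] = None,
) -> EmbeddingResult:
    """PCA -> graph -> UMAP -> Leiden + Louvain, in one deterministic pass."""
    cfg = config or PipelineConfig()
    graph, scores = reduce_and_graph(
        values, n_pcs=cfg.n_pcs, n_neighbors=cfg.n_neighbors, seed=cfg.seed
    )
    coords = umap_embed(graph, scores, seed=cfg.seed, n_neighbors=cfg.n_neighbors)
    leiden = cluster(graph, "leiden", resolution=cfg.resolution, seed=cfg.seed)
    louvain = cluster(graph, "louvain", resolution=cfg.resolution, seed=cfg.seed)
    logger.info(
        "clustering: %d Leiden clusters, %d Louvain clusters",
        len(set(leiden)),
        len(set(louvain)),
    )
    return EmbeddingResult(
        coords=coords,
        leiden_labels=leiden,
        louvain_labels=louvain,
        graph=graph,
        cell_ids=list(cell_ids),
        provenance=cfg.to_dict(),
    )


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


def plot_umap(
    result: EmbeddingResult,
    cell_annotations: pd.DataFrame,
    out_dir,
    color_by: Optional[List[str]] = None,
    categorical_columns: Optional[List[str]] = None,
    dpi: int = 150,
) -> Dict[str, Path]:
    """One UMAP scatter per requested categorical coloring.

    Default colorings: every auto-detected categorical metadata column plus
    the ``leiden`` and ``louvain`` labelings. Requesting a numeric column is
    an error: colorings are categorical by contract, numeric columns are
    not offered. Cells lacking metadata appear in the sentinel "NA" category.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann = cell_annotations.copy()
    ann = ann.loc[result.cell_ids]
    ann["leiden"] = result.leiden_labels
    ann["louvain"] = result.louvain_labels

    if categorical_columns is None:
        categorical_columns = [
            c
            for c in ann.columns
            if c not in ("leiden", "louvain", "metadata_matched")
            and not pd.api.types.is_numeric_dtype(ann[c])
        ]
    valid = list(categorical_columns) + ["leiden", "louvain"]
    if color_by is None:
        color_by = valid
    else:
        for col in color_by:
            if col not in ann.columns:
                raise UserInputError(
                    f"unknown column {col!r}; available categorical columns: "
                    + ", ".join(valid)
                )
            if col not in valid:
                raise UserInputError(
                    f"column {col!r} is numeric; UMAP colorings are categorical "
                    "(categorical metadata columns or leiden/louvain labels)"
                )

    cmap = plt.get_cmap("tab20")
    paths: Dict[str, Path] = {}
    for col in color_by:
        cats = pd.Index(pd.unique(ann[col].astype(str)))
        fig, ax = plt.subplots(figsize=(6, 5))
        for i, cat in enumerate(cats):
            mask = (ann[col].astype(str) == cat).values
            ax.scatter(
                result.coords[mask, 0],
                result.coords[mask, 1],
                s=18,
                color=cmap(i % 20),
                label=str(cat),
                linewidths=0,
            )
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        ax.set_title(f"UMAP colored by {col}")
        ax.legend(fontsize=7, markerscale=1.5, loc="best", frameon=False)
        fig.tight_layout()
        p = out_dir / f"umap_{col}.png"
        fig.savefig(p, dpi=dpi, metadata={"Software": "snvmap"})
        plt.close(fig)
        paths[col] = p
    return paths
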