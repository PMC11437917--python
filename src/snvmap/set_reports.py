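"""Per-group mutated-gene sets, Venn analytics and summary reports.

A gene "qualifies" for a patient when it is mutated in at least two of that
patient's cells (configurable); a group's gene set is the union of its
member patients' qualifying sets. Venn region counts are exclusive: each
gene in the union contributes to exactly one of the 2^k - 1 regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .errors import SnvmapError, UserInputError
from .qc_normalize import FilterReport
from .variant_ingest import MutationMatrix

logger = logging.getLogger(__name__)

MAX_VENN_SETS = 4


@dataclass
class GeneSetCollection:
    """Group label -> set of qualifying mutated genes (plus per-patient sets)."""

    group_column: str
    sets: Dict[str, Set[str]]
    per_patient_sets: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= len(self.sets) <= MAX_VENN_SETS):
            raise UserInputError(
                f"Venn analytics support 1-{MAX_VENN_SETS} groups, got {len(self.sets)}"
            )


def qualifying_genes(
    m: MutationMatrix,
    patient_column: str = "sample_id",
    min_cells: int = 2,
) -> Dict[str, Set[str]]:
    """Per patient, the genes mutated in at least ``min_cells`` of that
    patient's cells (the post-filter matrix is the intended input)."""
    ann = m.cell_annotations
    if patient_column not in ann.columns:
        cats = [c for c in ann.columns if not pd.api.types.is_numeric_dtype(ann[c])]
        raise UserInputError(
            f"unknown column {patient_column!r}; available categorical columns: "
            + ", ".join(cats)
        )
    nonzero = (m.counts > 0).toarray()
    out: Dict[str, Set[str]] = {}
    genes = np.asarray(m.gene_ids)
    for patient, idx in ann.groupby(patient_column, sort=True).indices.items():
        patient = str(patient)
        if len(idx) < min_cells:
            logger.warning(
                "patient %s has %d cell(s), fewer than min_cells=%d: empty gene set",
                patient, len(idx), min_cells,
            )
            out[patient] = set()
            continue
        support = nonzero[idx].sum(axis=0)
        out[patient] = set(genes[support >= min_cells])
    return out


def group_sets(
    per_patient_sets: Mapping[str, Set[str]],
    cell_annotations: pd.DataFrame,
    group_column: str,
    patient_column: str = "sample_id",
) -> GeneSetCollection:
    """Union the qualifying sets of each group's member patients."""
    if group_column not in cell_annotations.columns:
        cats = [
            c for c in cell_annotations.columns
            if not pd.api.types.is_numeric_dtype(cell_annotations[c])
        ]
        raise UserInputError(
            f"unknown group column {group_column!r}; available categorical "
            "columns: " + ", ".join(cats)
        )
    mapping = (
        cell_annotations[[patient_column, group_column]]
        .astype(str)
        .drop_duplicates()
        .groupby(patient_column)[group_column]
        .first()
    )
    groups = sorted(mapping.unique())
    if len(groups) > MAX_VENN_SETS:
        raise UserInputError(
            f"{len(groups)} groups in {group_column!r}, but the Venn renderer "
            f"supports at most {MAX_VENN_SETS}; subset the data or choose "
            "another column"
        )
    sets: Dict[str, Set[str]] = {g: set() for g in groups}
    for patient, genes in per_patient_sets.items():
        if patient in mapping.index:
            sets[mapping.loc[patient]] |= set(genes)
    return GeneSetCollection(
        group_column=group_column, sets=sets, per_patient_sets=dict(per_patient_sets)
    )


# ---------------------------------------------------------------------------
# Venn region counts
# ---------------------------------------------------------------------------


def venn_regions(sets: Mapping[str, Set[str]]) -> Dict[Tuple[bool, ...], Set[str]]:
    """Exclusive membership regions: one per non-empty inclusion pattern."""
    names = list(sets)
    k = len(names)
    if k < 2:
        raise UserInputError("Venn regions need at least 2 sets")
    if k > MAX_VENN_SETS:
        raise UserInputError(f"Venn regions support at most {MAX_VENN_SETS} sets")
    regions: Dict[Tuple[bool, ...], Set[str]] = {
        pattern: set() for pattern in product([True, False], repeat=k)
        if any(pattern)
    }
    universe = set().union(*sets.values())
    for el in universe:
        pattern = tuple(el in sets[n] for n in names)
        regions[pattern].add(el)
    return regions


def venn_counts(c: GeneSetCollection) -> Dict[str, int]:
    """Count per exclusive Venn region, keyed ``"A&B"``-style by group name.

    The counts over all 2^k - 1 regions sum to the size of the union.
    """
    names = list(c.sets)
    regions = venn_regions(c.sets)
    return {
        "&".join(n for n, inc in zip(names, pattern) if inc): len(members)
        for pattern, members in regions.items()
    }


def region_gene_lists(c: GeneSetCollection) -> Dict[str, List[str]]:
    names = list(c.sets)
    regions = venn_regions(c.sets)
    return {
        "&".join(n for n, inc in zip(names, pattern) if inc): sorted(members)
        for pattern, members in regions.items()
    }


# ---------------------------------------------------------------------------
# Venn rendering (2-4 sets, matplotlib)
# ---------------------------------------------------------------------------

# circle/ellipse layouts: (cx, cy, width, height, angle_deg)
_LAYOUTS = {
    2: [(0.375, 0.5, 0.5, 0.5, 0.0), (0.625, 0.5, 0.5, 0.5, 0.0)],
    3: [
        (0.427, 0.565, 0.52, 0.52, 0.0),
        (0.573, 0.565, 0.52, 0.52, 0.0),
        (0.500, 0.435, 0.52, 0.52, 0.0),
    ],
    4: [
        (0.350, 0.400, 0.72, 0.45, 140.0),
        (0.450, 0.500, 0.72, 0.45, 140.0),
        (0.544, 0.500, 0.72, 0.45, 40.0),
        (0.644, 0.400, 0.72, 0.45, 40.0),
    ],
}
_COLORS = ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728"]


def _inside(x, y, layout) -> np.ndarray:
    cx, cy, w, h, ang = layout
    t = np.deg2rad(ang)
    dx, dy = x - cx, y - cy
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (u / (w / 2)) ** 2 + (v / (h / 2)) ** 2 <= 1.0


def _region_centroids(k: int, grid: int = 400) -> Dict[Tuple[bool, ...], Tuple[float, float]]:
    """Label anchor per region: centroid of the grid points with that
    inclusion pattern. Purely geometric, so the layout needs no hand-tuned
    label tables."""
    layouts = _LAYOUTS[k]
    xs, ys = np.meshgrid(np.linspace(0, 1, grid), np.linspace(0, 1, grid))
    masks = [_inside(xs, ys, lay) for lay in layouts]
    centroids: Dict[Tuple[bool, ...], Tuple[float, float]] = {}
    for pattern in product([True, False], repeat=k):
        if not any(pattern):
            continue
        m = np.ones_like(xs, dtype=bool)
        for inc, mask in zip(pattern, masks):
            m &= mask if inc else ~mask
        if m.any():
            centroids[pattern] = (float(xs[m].mean()), float(ys[m].mean()))
    return centroids


def venn_figure(c: GeneSetCollection, counts: Optional[Dict[str, int]] = None):
    """Build the 2-4 set Venn figure; each region text carries a
    ``region:<key>`` gid so its label can be audited against the counts."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    names = list(c.sets)
    k = len(names)
    if k < 2:
        raise UserInputError("Venn rendering needs at least 2 sets")
    if counts is None:
        counts = venn_counts(c)
    layouts = _LAYOUTS[k]
    centroids = _region_centroids(k)

    fig, ax = plt.subplots(figsize=(6, 6))
    for (cx, cy, w, h, ang), color, name in zip(layouts, _COLORS, names):
        ax.add_patch(
            Ellipse((cx, cy), w, h, angle=ang, facecolor=color, alpha=0.3,
                    edgecolor=color, linewidth=1.5)
        )
    for pattern, (x, y) in centroids.items():
        key = "&".join(n for n, inc in zip(names, pattern) if inc)
        txt = ax.text(x, y, str(counts[key]), ha="center", va="center", fontsize=10)
        txt.set_gid(f"region:{key}")
    # set-name labels beside each shape's exclusive region
    for i, name in enumerate(names):
        pattern = tuple(j == i for j in range(k))
        x, y = centroids[pattern]
        dx, dy = x - 0.5, y - 0.5
        norm = max(np.hypot(dx, dy), 1e-9)
        total = len(c.sets[name])
        ax.text(
            x + 0.18 * dx / norm, y + 0.18 * dy / norm,
            f"{name}\n(n={total})",
            ha="center", va="center", fontsize=9, color=_COLORS[i], weight="bold",
        )
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"Shared mutated genes by {c.group_column}")
    return fig


def render_venn(
    c: GeneSetCollection,
    out_path,
    counts: Optional[Dict[str, int]] = None,
    dpi: int = 150,
) -> Path:
    """Render the Venn diagram to ``out_path``."""
    import matplotlib.pyplot as plt

    fig = venn_figure(c, counts)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=dpi, metadata={"Software": "snvmap"})
    plt.close(fig)
    return out_path


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------


def summary_report(
    filter_report: FilterReport,
    m_raw: MutationMatrix,
    m_filtered: MutationMatrix,
    patient_column: str = "sample_id",
    per_patient_sets: Optional[Mapping[str, Set[str]]] = None,
) -> pd.DataFrame:
    """Per-patient summary: cells in, cells surviving the filters, mean
    retained variant count per cell (post-filter), qualifying mutated genes.

    Patients whose cells were all removed are listed with blank statistics
    and flagged "no cells passed filtering".
    """
    raw_ann = m_raw.cell_annotations
    filt_ann = m_filtered.cell_annotations
    if patient_column not in raw_ann.columns:
        raise UserInputError(f"unknown patient column {patient_column!r}")

    totals = np.asarray(m_filtered.counts.sum(axis=1)).ravel()
    rows = []
    for patient, idx in raw_ann.groupby(patient_column, sort=True).indices.items():
        patient = str(patient)
        surv = np.flatnonzero((filt_ann[patient_column].astype(str) == patient).values)
        row: Dict[str, object] = {
            "patient": patient,
            "n_cells": int(len(idx)),
            "n_filtered_cells": int(len(surv)),
        }
        if len(surv) == 0:
            row["mean_retained_variants"] = ""
            row["n_qualifying_genes"] = ""
            row["flag"] = "no cells passed filtering"
        else:
            row["mean_retained_variants"] = round(float(totals[surv].mean()), 1)
            if per_patient_sets is not None:
                row["n_qualifying_genes"] = int(len(per_patient_sets.get(patient, set())))
            else:
                row["n_qualifying_genes"] = ""
            row["flag"] = ""
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patient")

    # reconcile with the filter report
    total_surviving = df["n_filtered_cells"].sum()
    if filter_report.steps and total_surviving != filter_report.steps[-1].n_cells_after:
        raise SnvmapError("summary report cell counts disagree with the filter report")
    return df


def write_summary_report(df: pd.DataFrame, out_base) -> Tuple[Path, Path]:
    out_base = Path(out_base)
    tsv = out_base.with_suffix(".tsv")
    js = out_base.with_suffix(".json")
    df.to_csv(tsv, sep="\t")
    js.write_text(json.dumps(df.reset_index().to_dict(orient="records"), indent=2))
    return tsv, js
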