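"""Ingest per-cell ANNOVAR-annotated SNV tables into a mutation-count matrix.

One annotation file per cell (a directory or a ZIP archive of them) plus a
metadata table whose first column is the patient/sample ID are assembled into
a cells x genes matrix of non-negative integer mutation counts, carried as an
:class:`MutationMatrix` and serialized in the AnnData h5ad convention.

Two ANNOVAR output dialects are auto-detected:

* ``*_multianno.txt`` tables — a header row with ``Gene.refGene`` /
  ``ExonicFunc.refGene``-style columns (any gene-model suffix);
* headerless ``exonic_variant_function`` output — line tag in column 1,
  functional class in column 2, ``GENE:transcript:...`` annotations in
  column 3, then the variant coordinates.

Explicit column overrides are available for non-standard tables.
"""

from __future__ import annotations

import io
import logging
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import SnvmapError, UserInputError

logger = logging.getLogger(__name__)

# Closed functional-class vocabulary; anything else maps to "other".
FUNC_CLASSES = (
    "nonsynonymous SNV",
    "synonymous SNV",
    "stopgain",
    "stoploss",
    "startloss",
    "unknown",
    "other",
)
DEFAULT_KEEP_CLASSES = frozenset({"nonsynonymous SNV"})

# Extension chains stripped from file names to obtain the cell ID, longest first.
_EXTENSION_CHAINS = (
    ".hg38_multianno.txt",
    ".hg19_multianno.txt",
    ".hg18_multianno.txt",
    ".multianno.txt",
    ".exonic_variant_function",
    ".variant_function",
    ".annovar.txt",
    ".tsv",
    ".txt",
)

_BASES = {"A", "C", "G", "T", "a", "c", "g", "t"}


def _normalize_func_class(raw: str) -> str:
    """Map a raw ANNOVAR functional-class string into the closed vocabulary."""
    s = raw.strip().replace("_", " ")
    s = re.sub(r"\s+", " ", s)
    low = s.lower()
    for cls in FUNC_CLASSES:
        if low == cls.lower():
            return cls
    return "other"


@dataclass(frozen=True)
class AnnotatedVariantRecord:
    """A single annotated somatic SNV observed in one cell."""

    cell_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbols: Tuple[str, ...]
    func_class: str
    cosmic_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SnvmapError(f"variant position must be >= 1, got {self.pos}")
        if not self.gene_symbols:
            raise SnvmapError("gene_symbols must be non-empty")
        if self.func_class not in FUNC_CLASSES:
            raise SnvmapError(f"unknown functional class {self.func_class!r}")


@dataclass
class CellMetadata:
    """Sample-level metadata: first column is the sample/patient ID.

    ``table`` is indexed by sample_id; ``column_kinds`` classifies every
    column as ``"numeric"`` (all non-missing values parse as numbers) or
    ``"categorical"``.
    """

    table: pd.DataFrame
    column_kinds: Dict[str, str]

    @property
    def sample_ids(self) -> List[str]:
        return list(self.table.index)

    @property
    def categorical_columns(self) -> List[str]:
        return [c for c, k in self.column_kinds.items() if k == "categorical"]


@dataclass
class MutationMatrix:
    """Cells x genes non-negative integer mutation-count matrix.

    ``counts`` is a CSR matrix of int64; ``cell_annotations`` is aligned to
    ``cell_ids`` and carries the joined sample metadata plus a
    ``metadata_matched`` flag.
    """

    counts: sp.csr_matrix
    cell_ids: List[str]
    gene_ids: List[str]
    cell_annotations: pd.DataFrame

    def __post_init__(self) -> None:
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise SnvmapError("counts shape does not match label lengths")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise SnvmapError("duplicate cell IDs")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SnvmapError("duplicate gene IDs")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise SnvmapError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_anndata(self) -> ad.AnnData:
        obs = self.cell_annotations.copy()
        obs.index = pd.Index(self.cell_ids, name="cell_id")
        var = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        return ad.AnnData(X=self.counts.copy(), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "MutationMatrix":
        X = adata.X
        if not sp.issparse(X):
            X = sp.csr_matrix(X)
        return cls(
            counts=sp.csr_matrix(X).astype(np.int64),
            cell_ids=list(adata.obs_names),
            gene_ids=list(adata.var_names),
            cell_annotations=adata.obs.copy(),
        )

    def equals(self, other: "MutationMatrix") -> bool:
        if self.cell_ids != other.cell_ids or self.gene_ids != other.gene_ids:
            return False
        if (self.counts != other.counts).nnz != 0:
            return False
        a = self.cell_annotations.astype(str)
        b = other.cell_annotations.astype(str)
        return list(a.columns) == list(b.columns) and a.equals(b)

    def to_tsv(self, path) -> None:
        """Plain TSV export (cells as rows) for language-neutral inspection."""
        df = pd.DataFrame(
            self.counts.toarray(), index=self.cell_ids, columns=self.gene_ids
        )
        df.index.name = "cell_id"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# input discovery
# ---------------------------------------------------------------------------


def strip_cell_id(filename: str) -> str:
    """File basename minus the longest recognized extension chain."""
    base = Path(filename).name
    for ext in _EXTENSION_CHAINS:
        if base.lower().endswith(ext):
            return base[: -len(ext)]
    return Path(base).stem


def discover_inputs(path) -> List[Tuple[str, bytes]]:
    """Find per-cell annotation files in a directory or ZIP archive.

    Returns ``(cell_id, raw bytes)`` pairs in deterministic lexicographic
    order of cell ID.
    """
    path = Path(path)
    if not path.exists():
        raise UserInputError(f"input path does not exist: {path}")
    entries: List[Tuple[str, bytes]] = []
    if path.is_dir():
        for f in sorted(path.iterdir()):
            if f.is_file() and not f.name.startswith("."):
                entries.append((strip_cell_id(f.name), f.read_bytes()))
    else:
        try:
            with zipfile.ZipFile(path) as zf:
                for name in sorted(zf.namelist()):
                    base = Path(name).name
                    if name.endswith("/") or not base or base.startswith("."):
                        continue
                    if "__MACOSX" in name:
                        continue
                    entries.append((strip_cell_id(base), zf.read(name)))
        except zipfile.BadZipFile as e:
            raise UserInputError(f"unreadable archive: {path} ({e})") from e
    entries.sort(key=lambda t: t[0])
    if not entries:
        raise UserInputError(f"no input cells found under {path}")
    seen: Set[str] = set()
    for cid, _ in entries:
        if cid in seen:
            raise UserInputError(f"duplicate cell ID after extension stripping: {cid}")
        seen.add(cid)
    return entries


# ---------------------------------------------------------------------------
# ANNOVAR parsing
# ---------------------------------------------------------------------------

_GENE_DETAIL_RE = re.compile(r"\(.*?\)")


def _split_genes(raw: str) -> Tuple[str, ...]:
    """Split a multi-gene annotation field on ANNOVAR separators (';' and ',').

    Parenthetical distance annotations are stripped; duplicates collapse so a
    variant counts once per (cell, variant, gene).
    """
    cleaned = _GENE_DETAIL_RE.sub("", raw)
    out: List[str] = []
    for tok in re.split(r"[;,]", cleaned):
        g = tok.strip()
        if ":" in g:  # exonic_variant_function style GENE:NM_...:c....
            g = g.split(":", 1)[0].strip()
        if g and g not in (".", "NONE", "NA", "-") and g not in out:
            out.append(g)
    return tuple(out)


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES


@dataclass
class ColumnMap:
    """Explicit 0-based column override for non-standard headerless tables."""

    chrom: int
    pos: int
    ref: int
    alt: int
    gene: int
    func: int
    cosmic: Optional[int] = None


def _find_column(header: List[str], prefix: str) -> Optional[int]:
    for i, h in enumerate(header):
        if h.lower().startswith(prefix.lower()):
            return i
    return None


def parse_annovar(
    stream,
    cell_id: str,
    *,
    columns: Optional[ColumnMap] = None,
    include_indels: bool = False,
    max_malformed_frac: float = 0.2,
) -> List[AnnotatedVariantRecord]:
    """Parse one per-cell ANNOVAR table into variant records.

    Dialect is auto-detected unless ``columns`` overrides it. Malformed rows
    are counted and skipped; above ``max_malformed_frac`` of data rows the
    cell is rejected. A file with zero parseable rows yields an empty list
    with a warning (the cell is retained with zero counts downstream).
    """
    if isinstance(stream, (bytes, bytearray)):
        data = bytes(stream)
    else:
        data = stream.read()
        if isinstance(data, str):
            data = data.encode()
    text = data.decode("utf-8", errors="replace")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        logger.warning("cell %s: empty annotation file, retained with zero counts", cell_id)
        return []

    first = lines[0].rstrip("\n").split("\t")
    records: List[AnnotatedVariantRecord] = []
    malformed = 0

    if columns is not None:
        data_lines = lines
        cm = columns
        header_mode = False
    elif any(h.lower().startswith("gene.") for h in first):
        # multianno dialect with header
        header_mode = True
        hdr = [h.strip() for h in first]
        gene_i = _find_column(hdr, "Gene.")
        func_i = _find_column(hdr, "ExonicFunc.")
        chrom_i = _find_column(hdr, "Chr")
        pos_i = _find_column(hdr, "Start")
        ref_i = _find_column(hdr, "Ref")
        alt_i = _find_column(hdr, "Alt")
        cosmic_i = _find_column(hdr, "cosmic")
        if None in (gene_i, func_i, chrom_i, pos_i, ref_i, alt_i):
            raise UserInputError(
                f"cell {cell_id}: multianno header lacks required columns "
                "(Chr/Start/Ref/Alt/Gene.*/ExonicFunc.*)"
            )
        cm = ColumnMap(chrom_i, pos_i, ref_i, alt_i, gene_i, func_i, cosmic_i)
        data_lines = lines[1:]
    elif re.match(r"line\d+$", first[0].strip()):
        # headerless exonic_variant_function: tag, class, gene, chrom, start, end, ref, alt
        header_mode = False
        cm = ColumnMap(chrom=3, pos=4, ref=6, alt=7, gene=2, func=1)
        data_lines = lines
    else:
        raise UserInputError(
            f"cell {cell_id}: cannot detect ANNOVAR dialect; "
            "pass an explicit column mapping"
        )

    n_data = len(data_lines)
    for ln in data_lines:
        fields = ln.rstrip("\n").split("\t")
        try:
            needed = max(cm.chrom, cm.pos, cm.ref, cm.alt, cm.gene, cm.func)
            if len(fields) <= needed:
                raise ValueError("too few columns")
            genes = _split_genes(fields[cm.gene])
            if not genes:
                raise ValueError("missing gene symbol")
            pos = int(fields[cm.pos])
            ref, alt = fields[cm.ref].strip(), fields[cm.alt].strip()
            if not include_indels and not _is_snv(ref, alt):
                continue  # non-SNV rows are excluded by default, not malformed
            cosmic = None
            if cm.cosmic is not None and len(fields) > cm.cosmic:
                val = fields[cm.cosmic].strip()
                cosmic = val if val and val != "." else None
            records.append(
                AnnotatedVariantRecord(
                    cell_id=cell_id,
                    chrom=fields[cm.chrom].strip(),
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene_symbols=genes,
                    func_class=_normalize_func_class(fields[cm.func]),
                    cosmic_id=cosmic,
                )
            )
        except (ValueError, IndexError, SnvmapError):
            malformed += 1

    if n_data and malformed / n_data > max_malformed_frac:
        raise UserInputError(
            f"cell {cell_id}: {malformed}/{n_data} malformed rows exceeds "
            f"tolerance {max_malformed_frac:.0%}"
        )
    if malformed:
        logger.warning("cell %s: skipped %d malformed rows", cell_id, malformed)
    if not records:
        logger.warning("cell %s: no parseable SNV rows, retained with zero counts", cell_id)
    return records


def filter_functional(
    records: Iterable[AnnotatedVariantRecord],
    keep_classes: Optional[Set[str]] = None,
) -> List[AnnotatedVariantRecord]:
    """Retain records whose functional class is in ``keep_classes``.

    Default keeps only non-synonymous SNVs; pass ``keep_classes=None`` via
    :func:`convert`'s keep-all mode (or the full vocabulary) to retain all.
    """
    if keep_classes is None:
        keep_classes = set(DEFAULT_KEEP_CLASSES)
    if not keep_classes:
        raise UserInputError("keep_classes must be non-empty")
    keep = {_normalize_func_class(c) for c in keep_classes}
    return [r for r in records if r.func_class in keep]


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_metadata(path) -> CellMetadata:
    """Read the CSV/TSV metadata table; first column becomes the sample ID.

    A column is numeric iff every non-missing value parses as a number,
    otherwise categorical (categorical columns are the ones offered for
    coloring plots).
    """
    path = Path(path)
    if not path.exists():
        raise UserInputError(f"metadata file does not exist: {path}")
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error) as e:
        raise UserInputError(f"cannot read metadata file {path}: {e}") from e
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise UserInputError(f"metadata file has no data rows: {path}")
    id_col = df.columns[0]
    ids = df[id_col].astype(str).str.strip()
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise UserInputError(f"duplicate sample IDs in metadata: {dups}")
    table = df.drop(columns=[id_col])
    table.index = pd.Index(ids, name=id_col)
    kinds: Dict[str, str] = {}
    for col in table.columns:
        vals = table[col].dropna()
        vals = vals[vals.astype(str).str.strip() != ""]
        numeric = pd.to_numeric(vals, errors="coerce")
        if len(vals) > 0 and not numeric.isna().any():
            kinds[col] = "numeric"
            table[col] = pd.to_numeric(table[col], errors="coerce")
        else:
            kinds[col] = "categorical"
            table[col] = table[col].astype(str).where(~table[col].isna(), other="NA")
    return CellMetadata(table=table, column_kinds=kinds)


_SEPARATORS = ("_", "-", ".")


def match_cell_to_sample(cell_id: str, sample_ids: Sequence[str]) -> Optional[str]:
    """Match a cell to its metadata row: exact ID first, else the longest
    sample ID that prefixes the cell ID at a separator boundary."""
    if cell_id in sample_ids:
        return cell_id
    best = None
    for sid in sample_ids:
        if cell_id.startswith(sid) and len(cell_id) > len(sid) and cell_id[len(sid)] in _SEPARATORS:
            if best is None or len(sid) > len(best):
                best = sid
    return best


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


def count_matrix(
    records_by_cell: Mapping[str, Sequence[AnnotatedVariantRecord]],
    metadata: Optional[CellMetadata] = None,
    *,
    strict_metadata: bool = False,
) -> MutationMatrix:
    """Assemble the cells x genes mutation-count matrix.

    ``counts[c, g]`` is the number of retained variant records in cell ``c``
    annotated to gene ``g``. Duplicate variants (same chrom, pos, ref, alt
    within one cell) are deduplicated first; a record listing k genes
    increments k entries. Cells without a metadata match are kept with every
    metadata field set to the sentinel "NA" unless ``strict_metadata``.
    """
    cell_ids = sorted(records_by_cell)
    if len(cell_ids) != len(set(cell_ids)):
        raise UserInputError("duplicate cell IDs in input")
    if not cell_ids:
        raise UserInputError("no input cells")

    gene_counts: Dict[str, Dict[str, int]] = {}
    genes: Set[str] = set()
    for cid in cell_ids:
        seen_variants: Set[Tuple[str, int, str, str]] = set()
        per_gene: Dict[str, int] = {}
        for rec in records_by_cell[cid]:
            key = (rec.chrom, rec.pos, rec.ref, rec.alt)
            if key in seen_variants:
                continue
            seen_variants.add(key)
            for g in rec.gene_symbols:
                per_gene[g] = per_gene.get(g, 0) + 1
        gene_counts[cid] = per_gene
        genes.update(per_gene)

    gene_ids = sorted(genes)
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    rows, cols, data = [], [], []
    for i, cid in enumerate(cell_ids):
        for g, c in gene_counts[cid].items():
            rows.append(i)
            cols.append(gene_index[g])
            data.append(c)
    counts = sp.csr_matrix(
        (np.asarray(data, dtype=np.int64), (rows, cols)),
        shape=(len(cell_ids), len(gene_ids)),
        dtype=np.int64,
    )
    counts.sort_indices()

    if metadata is not None:
        sample_ids = metadata.sample_ids
        matched = [match_cell_to_sample(cid, sample_ids) for cid in cell_ids]
        unmatched = [cid for cid, m in zip(cell_ids, matched) if m is None]
        if unmatched:
            if strict_metadata:
                raise UserInputError(
                    f"{len(unmatched)} cells have no metadata match: {unmatched[:5]}..."
                )
            logger.warning(
                "%d cells have no metadata match; fields set to 'NA'", len(unmatched)
            )
        ann = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
        ann["sample_id"] = [m if m is not None else "NA" for m in matched]
        for col in metadata.table.columns:
            vals = []
            for m in matched:
                if m is None:
                    vals.append(np.nan if metadata.column_kinds[col] == "numeric" else "NA")
                else:
                    vals.append(metadata.table.loc[m, col])
            ann[col] = vals
        ann["metadata_matched"] = [m is not None for m in matched]
    else:
        ann = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
        ann["sample_id"] = cell_ids
        ann["metadata_matched"] = True

    return MutationMatrix(
        counts=counts, cell_ids=cell_ids, gene_ids=gene_ids, cell_annotations=ann
    )


# ---------------------------------------------------------------------------
# serialization (AnnData h5ad convention)
# ---------------------------------------------------------------------------


def write_matrix(m: MutationMatrix, path) -> Path:
    """Serialize to the AnnData HDF5 (h5ad) on-disk convention."""
    if m.n_cells == 0 or m.n_genes == 0:
        raise SnvmapError("empty matrix")
    path = Path(path)
    adata = m.to_anndata()
    # strings, not pandas categories, so round-trips compare plainly
    for col in adata.obs.columns:
        if adata.obs[col].dtype == object:
            adata.obs[col] = adata.obs[col].astype(str)
    try:
        adata.write_h5ad(path)
    except OSError as e:
        raise SnvmapError(f"cannot write matrix to {path}: {e}") from e
    return path


def read_matrix(path) -> MutationMatrix:
    path = Path(path)
    if not path.exists():
        raise UserInputError(f"matrix file does not exist: {path}")
    adata = ad.read_h5ad(path)
    m = MutationMatrix.from_anndata(adata)
    for col in m.cell_annotations.columns:
        if isinstance(m.cell_annotations[col].dtype, pd.CategoricalDtype):
            m.cell_annotations[col] = m.cell_annotations[col].astype(str)
    if "metadata_matched" in m.cell_annotations:
        m.cell_annotations["metadata_matched"] = (
            m.cell_annotations["metadata_matched"].astype(str) == "True"
        )
    return m


# ---------------------------------------------------------------------------
# one-call convert
# ---------------------------------------------------------------------------


def convert(
    input_path,
    metadata_path=None,
    *,
    keep_classes: Optional[Set[str]] = None,
    keep_all_classes: bool = False,
    include_indels: bool = False,
    strict_metadata: bool = False,
    columns: Optional[ColumnMap] = None,
) -> MutationMatrix:
    """Full ingest: discover files, parse, filter functional classes, count.

    ``keep_all_classes=True`` mirrors the mode where every functional class
    is retained (used when too few genes would otherwise survive).
    """
    entries = discover_inputs(input_path)
    metadata = read_metadata(metadata_path) if metadata_path is not None else None
    records_by_cell: Dict[str, List[AnnotatedVariantRecord]] = {}
    for cid, raw in entries:
        recs = parse_annovar(raw, cid, columns=columns, include_indels=include_indels)
        if not keep_all_classes:
            recs = filter_functional(recs, keep_classes)
        records_by_cell[cid] = recs
    return count_matrix(records_by_cell, metadata, strict_metadata=strict_metadata)
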