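"""Shared data model and readers/writers for all external formats.

The package works with four kinds of external data:

* per-donor expression matrices (genes x samples, log2-scale intensities)
  with a sample annotation table carrying MNI coordinates and anatomical
  structure labels (tab-separated text);
* a binary brain mask in MNI space (NIfTI-1, or a plain coordinate list);
* gene-set collections in GMT format;
* a single-cell count matrix in MatrixMarket format with gene/cell sidecars.

All tabular outputs are tab-separated UTF-8 with a header row and floats at
six significant digits, so that any result table can be re-read and two runs
with identical inputs produce byte-identical files.

Conventions: voxel indices are 0-based, the affine maps voxel index to MNI mm
(NIfTI convention), and readers never reorder genes or samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("stressmap")

#: structure labels counted as cerebral cortex when the annotation table
#: does not carry an explicit ``is_cortex`` column
CORTEX_STRUCTURES = frozenset(
    {"cortex", "cerebral cortex", "frontal gyrus", "cingulate gyrus"}
)

ANNOTATION_COLUMNS = ("sample_id", "donor_id", "mni_x", "mni_y", "mni_z", "structure")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DonorExpression:
    """One donor's genes x samples expression matrix (log2-scale values).

    ``standardized`` is False for raw intensities and True after per-gene
    z-scoring; ``constant_genes`` lists genes that had zero variance in the
    scope they were standardized over (their standardized values are 0).
    """

    donor_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    standardized: bool = False
    constant_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g, s = len(self.gene_ids), len(self.sample_ids)
        if g < 1 or s < 1:
            raise ValueError("expression matrix must have >=1 gene and >=1 sample")
        if self.values.shape != (g, s):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{g} genes x {s} samples"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != s:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values contain NaN/inf")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "DonorExpression":
        """Column subset preserving matrix column order."""
        keep = set(sample_ids)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return DonorExpression(
            donor_id=self.donor_id,
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            standardized=self.standardized,
            constant_genes=self.constant_genes,
        )


@dataclass(frozen=True)
class StressMask:
    """Binary MNI-space volume: the set of in-network voxels.

    ``affine`` maps 0-based voxel indices to MNI mm; ``voxels`` holds the
    integer index triples flagged in-mask.
    """

    affine: np.ndarray
    shape: tuple[int, int, int]
    voxels: frozenset[tuple[int, int, int]]

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise FormatError("mask affine is not invertible")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        vox = frozenset((int(i), int(j), int(k)) for i, j, k in self.voxels)
        if not vox:
            raise ValueError("mask contains no voxels")
        for v in vox:
            if any(c < 0 or c >= n for c, n in zip(v, self.shape)):
                raise ValueError(f"voxel {v} outside volume shape {self.shape}")
        object.__setattr__(self, "voxels", vox)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of one voxel along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_centers_mm(self) -> np.ndarray:
        """MNI mm coordinates of the centers of the in-mask voxels."""
        idx = np.array(sorted(self.voxels), dtype=float)
        return nib.affines.apply_affine(self.affine, idx)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), with an optional explicit universe."""

    name: str
    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for set_name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in gene set {set_name!r}")


# ---------------------------------------------------------------------------
# expression / annotation tables
# ---------------------------------------------------------------------------


def _check_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation table missing column(s): {missing}")
    coords = ann[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("annotation MNI coordinates contain NaN/inf")
    ann = ann.copy()
    if "is_cortex" not in ann.columns:
        ann["is_cortex"] = (
            ann["structure"].str.lower().isin(CORTEX_STRUCTURES)
        )
    else:
        ann["is_cortex"] = ann["is_cortex"].astype(bool)
    return ann


def read_expression(
    matrix_path: str | Path, annotation_path: str | Path
) -> tuple[DonorExpression, pd.DataFrame]:
    """Read one donor's expression matrix and its sample annotation.

    The matrix is tab-separated, genes in rows: a header row of sample ids
    (first column header arbitrary, conventionally ``gene_id``) and the first
    column holding gene ids.  The annotation is tab-separated with columns
    ``sample_id, donor_id, mni_x, mni_y, mni_z, structure`` (and optionally
    ``is_cortex``).  The two files must describe the same sample set.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.shape[1] < 1:
        raise FormatError("expression matrix has no sample columns")
    if mat.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if mat.isna().any().any():
        raise ValueError("expression matrix contains NaN cells")
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    ann = _check_annotation(ann)
    if set(map(str, mat.columns)) != set(ann["sample_id"]):
        raise ValueError("sample ids in matrix and annotation do not match")
    donors = ann["donor_id"].unique()
    if len(donors) != 1:
        raise FormatError(
            f"expression annotation must describe a single donor, got {list(donors)}"
        )
    expr = DonorExpression(
        donor_id=str(donors[0]),
        gene_ids=[str(g) for g in mat.index],
        sample_ids=[str(s) for s in mat.columns],
        values=mat.to_numpy(dtype=float),
    )
    return expr, ann


def write_expression(
    expr: DonorExpression,
    samples: pd.DataFrame,
    matrix_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Inverse of :func:`read_expression` (one donor's rows of ``samples``)."""
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.17g")
    ann = samples[samples["donor_id"] == expr.donor_id]
    cols = list(ANNOTATION_COLUMNS) + ["is_cortex"]
    ann.loc[:, cols].to_csv(annotation_path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def read_mask(path: str | Path, voxel_size_mm: float | None = None) -> StressMask:
    """Read a binary mask from NIfTI (nonzero = in-mask) or a coordinate list.

    The coordinate-list dialect is a tab-separated table with columns
    ``mni_x, mni_y, mni_z`` and requires ``voxel_size_mm``; it constructs a
    diagonal affine with that isotropic voxel size and origin 0, i.e. the
    voxel whose center is at (0,0,0) mm has index (0,0,0).
    """
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        idx = np.argwhere(data != 0)
        if idx.size == 0:
            raise ValueError(f"mask {path} is empty")
        return StressMask(
            affine=img.affine,
            shape=tuple(int(n) for n in data.shape[:3]),
            voxels=frozenset(map(tuple, idx.tolist())),
        )
    if voxel_size_mm is None:
        raise FormatError(
            "coordinate-list masks require an explicit voxel_size_mm"
        )
    coords = pd.read_csv(path, sep="\t")
    missing = [c for c in ("mni_x", "mni_y", "mni_z") if c not in coords.columns]
    if missing:
        raise FormatError(f"coordinate list missing column(s): {missing}")
    xyz = coords[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
    if xyz.shape[0] == 0:
        raise ValueError(f"mask {path} is empty")
    idx = np.rint(xyz / voxel_size_mm).astype(int)
    if (idx < 0).any():
        raise FormatError("coordinate-list mask has negative voxel indices")
    shape = tuple(int(n) for n in idx.max(axis=0) + 1)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    return StressMask(affine=affine, shape=shape, voxels=frozenset(map(tuple, idx.tolist())))


def write_mask(mask: StressMask, path: str | Path) -> None:
    """Write the mask as a NIfTI-1 volume (uint8, nonzero = in-mask)."""
    data = np.zeros(mask.shape, dtype=np.uint8)
    idx = np.array(sorted(mask.voxels))
    data[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    nib.save(nib.Nifti1Image(data, mask.affine), str(path))


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: per line ``set_name<TAB>description<TAB>member...``.

    Duplicate members within a set are dropped (first occurrence kept) with a
    logged warning; a line with fewer than three fields is a format error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3"
                )
            set_name, _desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "gene set %r: dropped %d duplicate member(s)",
                    set_name,
                    len(members) - len(unique),
                )
            sets[set_name] = unique
    return GeneSetCollection(name=name or path.stem, sets=sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_name, members in collection.sets.items():
            fh.write("\t".join([set_name, collection.name, *members]) + "\n")


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------


def write_table(
    rows: pd.DataFrame, path: str | Path, sort_by: Sequence[str] | None = None
) -> None:
    """Write a result table as deterministic TSV.

    UTF-8, tab-separated, header row, floats at six significant digits.
    ``sort_by`` fixes the row order (ties left in current order, stable sort);
    without it the current row order is kept.
    """
    df = rows.copy()
    if sort_by:
        df = df.sort_values(list(sort_by), kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# single-cell counts (MatrixMarket + sidecars)
# ---------------------------------------------------------------------------


def read_sc_counts(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Read a genes x cells count matrix with gene and cell sidecar tables.

    The gene sidecar is a TSV with a ``gene_id`` column; the cell sidecar
    carries ``cell_id``, ``cluster_id`` and ``cell_class`` columns.
    Returns a dense float array (genes x cells), the gene ids, and the cell
    table.
    """
    mat = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    for col in ("cell_id", "cluster_id", "cell_class"):
        if col not in cells.columns:
            raise FormatError(f"cell sidecar missing column {col!r}")
    if "gene_id" not in genes.columns:
        raise FormatError("gene sidecar missing column 'gene_id'")
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"count matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    return mat, [str(g) for g in genes["gene_id"]], cells


def write_sc_counts(
    counts: np.ndarray,
    gene_ids: Sequence[str],
    cells: pd.DataFrame,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    sparse = scipy.sparse.coo_matrix(np.asarray(counts))
    scipy.io.mmwrite(str(mtx_path), sparse)
    pd.DataFrame({"gene_id": list(gene_ids)}).to_csv(genes_path, sep="\t", index=False)
    cells.to_csv(cells_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# donor manifests
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> list[tuple[Path, Path]]:
    """Read a donor manifest: TSV with columns matrix_path, annotation_path.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("matrix_path", "annotation_path"):
        if col not in df.columns:
            raise FormatError(f"manifest missing column {col!r}")
    base = path.parent
    return [
        (base / row.matrix_path, base / row.annotation_path)
        for row in df.itertuples()
    ]
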