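"""Data model and readers/writers for the external file formats.

All count matrices follow one convention: genes are rows, samples/cells are
columns.  Counts are held sparse (CSR) when density < 50% and dense
otherwise; every operation in the package gives identical results on either
representation.  Gene identifiers are opaque strings — soybean ``Glyma.``
ids and Arabidopsis ``AT`` ids need no special handling.

Formats: plain TSV count tables (first column gene id, header = column
ids); 10x-style MatrixMarket triplet directories (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``, gzip-tolerant); sample-metadata TSV;
GMT gene sets; two-column TSV ortholog maps.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

REGIONS = ("embryo", "endosperm", "seed_coat", "other")
STAGES = ("glob", "hrt", "cot", "em")

SPARSE_DENSITY_CUTOFF = 0.5


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


def _as_storage(counts):
    """Store sparse when density < 50%, dense otherwise."""
    if sparse.issparse(counts):
        density = counts.nnz / max(1, counts.shape[0] * counts.shape[1])
        return counts.tocsr() if density < SPARSE_DENSITY_CUTOFF else np.asarray(counts.todense())
    arr = np.asarray(counts)
    density = np.count_nonzero(arr) / max(1, arr.size)
    return sparse.csr_matrix(arr) if density < SPARSE_DENSITY_CUTOFF else arr


@dataclass
class CountTable:
    """Non-negative integer gene x column matrix with identifiers."""

    gene_ids: list
    column_ids: list
    counts: object  # ndarray or scipy.sparse matrix, genes x columns

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicated gene ids")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValidationError("duplicated column ids")
        shape = self.counts.shape
        if shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValidationError(
                f"counts shape {shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns")
        data = self.counts.data if sparse.issparse(self.counts) else np.asarray(self.counts)
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValidationError("counts must be non-negative integers")
        self.counts = _as_storage(self.counts)

    @property
    def shape(self):
        return self.counts.shape

    def dense(self) -> np.ndarray:
        """Counts as a dense float array (genes x columns)."""
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.column_ids)

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(float)

    def select_columns(self, column_ids) -> "CountTable":
        idx = [self.column_ids.index(c) for c in column_ids]
        counts = self.counts[:, idx]
        return CountTable(list(self.gene_ids), list(column_ids), counts)

    def select_genes(self, gene_ids) -> "CountTable":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return CountTable(list(gene_ids), list(self.column_ids), self.counts[idx, :])


@dataclass
class SampleTable:
    """Per-sample metadata for the bulk (LCM) samples."""

    frame: pd.DataFrame  # columns: column_id, region, subregion, stage, replicate

    REQUIRED = ("column_id", "region", "subregion", "stage", "replicate")

    def __post_init__(self):
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        df = df.copy()
        df["column_id"] = df["column_id"].astype(str)
        if df["column_id"].duplicated().any():
            dup = df.loc[df["column_id"].duplicated(), "column_id"].iloc[0]
            raise ValidationError(f"duplicated column_id: {dup}")
        bad_stage = set(df["stage"]) - set(STAGES)
        if bad_stage:
            raise ValidationError(f"unknown stage value(s): {sorted(bad_stage)}")
        bad_region = set(df["region"]) - set(REGIONS)
        if bad_region:
            raise ValidationError(f"unknown region value(s): {sorted(bad_region)}")
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate must be a positive integer")
        self.frame = df.reset_index(drop=True)

    def groups(self, stage=None) -> dict:
        """(subregion, stage) -> list of column_ids, optionally one stage."""
        df = self.frame if stage is None else self.frame[self.frame["stage"] == stage]
        out = {}
        for (sub, stg), grp in df.groupby(["subregion", "stage"], sort=True):
            out[(sub, stg)] = list(grp["column_id"])
        return out

    def subregion_regions(self) -> dict:
        """subregion -> region (must be unique per subregion)."""
        mapping = {}
        for _, row in self.frame.iterrows():
            prev = mapping.setdefault(row["subregion"], row["region"])
            if prev != row["region"]:
                raise ValidationError(
                    f"subregion {row['subregion']} mapped to multiple regions")
        return mapping

    def check_against(self, counts: CountTable):
        missing = set(self.frame["column_id"]) - set(counts.column_ids)
        if missing:
            raise ValidationError(f"sample column_ids absent from counts: {sorted(missing)}")


@dataclass
class GeneSetCollection:
    """set_id -> (description, gene ids); carrier for GO terms, TF lists, modules."""

    sets: dict = field(default_factory=dict)  # id -> (description, frozenset)

    def __post_init__(self):
        clean = {}
        for sid, (desc, genes) in self.sets.items():
            genes = frozenset(str(g) for g in genes)
            if not genes:
                raise ValidationError(f"empty gene set: {sid}")
            clean[str(sid)] = (str(desc), genes)
        self.sets = clean

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, sid):
        return self.sets[sid]

    def items(self):
        return self.sets.items()


@dataclass
class OrthologMap:
    """Unordered many-to-many homology pairs between two species' gene ids."""

    pairs: frozenset = frozenset()

    def __post_init__(self):
        self.pairs = frozenset((str(a), str(b)) for a, b in self.pairs)

    def partners_of(self, gene_a: str) -> set:
        return {b for a, b in self.pairs if a == gene_a}

    def __len__(self):
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find_companion(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"missing companion file {stem}[.gz] in {directory}")


def read_counts(path, format: str = "tsv") -> CountTable:
    """Read a count matrix.

    ``tsv``: first column gene id, header row = column ids.
    ``mtx_triplet``: a directory containing matrix.mtx, features.tsv and
    barcodes.tsv (each optionally gzipped); genes are rows.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if df.index.duplicated().any():
            raise ValidationError("duplicated gene ids in TSV count table")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric entries in count table")
        if np.any(values < 0) or np.any(values != np.round(values)):
            raise ValidationError("non-integer or negative entries in count table")
        return CountTable(list(df.index.astype(str)), list(df.columns.astype(str)),
                          values.astype(np.int64))
    if format == "mtx_triplet":
        if not path.is_dir():
            raise FormatError(f"mtx_triplet expects a directory, got {path}")
        mtx = _find_companion(path, "matrix.mtx")
        features = _find_companion(path, "features.tsv")
        barcodes = _find_companion(path, "barcodes.tsv")
        with _open_maybe_gz(mtx) as fh:
            mat = spio.mmread(fh)
        with _open_maybe_gz(features) as fh:
            gene_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        with _open_maybe_gz(barcodes) as fh:
            col_ids = [line.strip() for line in fh if line.strip()]
        mat = sparse.csr_matrix(mat)
        if np.any(mat.data < 0) or np.any(mat.data != np.round(mat.data)):
            raise ValidationError("non-integer or negative entries in matrix.mtx")
        return CountTable(gene_ids, col_ids, mat.astype(np.int64))
    raise FormatError(f"unknown count format: {format}")


def write_counts(table: CountTable, path, format: str = "tsv"):
    path = Path(path)
    if format == "tsv":
        table.to_frame().astype(np.int64).to_csv(path, sep="\t", index_label="gene_id")
        return
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        mat = table.counts if sparse.issparse(table.counts) else sparse.csr_matrix(table.counts)
        spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(mat))
        (path / "features.tsv").write_text("".join(f"{g}\t{g}\tGene Expression\n"
                                                   for g in table.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in table.column_ids))
        return
    raise FormatError(f"unknown count format: {format}")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path):
    samples.frame.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with _open_maybe_gz(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line {lineno}: set with no genes")
            sid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValidationError(f"GMT line {lineno}: empty gene set {sid}")
            sets[sid] = (desc, frozenset(genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path):
    with open(path, "w") as fh:
        for sid, (desc, genes) in sorted(collection.items()):
            fh.write("\t".join([sid, desc, *sorted(genes)]) + "\n")


def read_ortholog_map(path) -> OrthologMap:
    pairs = set()
    with _open_maybe_gz(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"ortholog map line needs two columns: {line!r}")
            pairs.add((parts[0], parts[1]))
    return OrthologMap(frozenset(pairs))


def write_ortholog_map(mapping: OrthologMap, path):
    with open(path, "w") as fh:
        for a, b in sorted(mapping.pairs):
            fh.write(f"{a}\t{b}\n")
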