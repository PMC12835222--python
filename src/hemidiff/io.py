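"""Readers and writers for the formats the pipeline touches.

Counts travel as TSV (first column ``gene_id``, header row of sample ids,
optionally gzip-compressed by file extension) or MatrixMarket (``.mtx``
plus sibling ``.genes.txt`` / ``.samples.txt`` index files).  Gene sets use
the tab-separated GMT dialect.  Writers and readers are exact inverses on
valid data.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, ExpressionMatrix, GeneSetCollection, NormFactors

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_samples",
    "write_samples",
    "combine_technical_replicates",
    "write_expression",
    "read_expression",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    name = path.name
    if name.endswith(".mtx") or name.endswith(".mtx.gz"):
        return "mtx"
    return "tsv"


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    stem = str(path)
    for suffix in (".mtx.gz", ".mtx"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return Path(stem + ".genes.txt"), Path(stem + ".samples.txt")


def read_counts(path, format: str | None = None) -> CountMatrix:
    """Read a gene x sample count matrix from TSV or MatrixMarket."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated gene rows: {dup[:5]}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample columns: {dup[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric entries in count matrix")
        try:
            return CountMatrix(df.index.astype(str), df.columns.astype(str), values)
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    elif fmt == "mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        for p in (genes_path, samples_path):
            if not p.exists():
                raise FormatError(f"missing MatrixMarket index file {p}")
        mat = scipy.io.mmread(str(path))
        genes = genes_path.read_text().splitlines()
        samples = samples_path.read_text().splitlines()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        try:
            return CountMatrix(pd.Index(genes), pd.Index(samples), dense)
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    raise ValueError(f"unknown counts format {fmt!r}")


def write_counts(counts: CountMatrix, path, format: str | None = None) -> None:
    """Write counts as TSV (gzip by extension) or MatrixMarket triplet."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        df = counts.to_frame()
        df.index.name = "gene_id"
        if path.name.endswith(".gz"):
            # fixed mtime keeps the gzip container byte-reproducible
            df.to_csv(path, sep="\t", compression={"method": "gzip", "mtime": 0})
        else:
            df.to_csv(path, sep="\t")
    elif fmt == "mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(counts.counts))
        genes_path.write_text("\n".join(map(str, counts.gene_ids)) + "\n")
        samples_path.write_text("\n".join(map(str, counts.sample_ids)) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    sets: dict = {}
    descriptions: dict = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_samples(path) -> pd.DataFrame:
    """Read a sample metadata sheet as TSV keyed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("sample sheet must contain a sample_id column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicated sample ids: {dup[:5]}")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def combine_technical_replicates(
    counts: CountMatrix, replicate_map: dict
) -> CountMatrix:
    """Sum technical replicate libraries into their parent samples.

    ``replicate_map`` maps each output sample id to the list of library ids
    (columns of ``counts``) that belong to it.  Every library must appear in
    exactly one group; libraries absent from the map are dropped.
    """
    seen: dict = {}
    for sample, libs in replicate_map.items():
        for lib in libs:
            if lib in seen:
                raise ValueError(
                    f"library {lib!r} mapped to both {seen[lib]!r} and {sample!r}"
                )
            if lib not in counts.sample_ids:
                raise ValueError(f"library {lib!r} not present in count matrix")
            seen[lib] = sample
    new_ids = list(replicate_map)
    out = np.zeros((counts.n_genes, len(new_ids)), dtype=np.int64)
    for j, sample in enumerate(new_ids):
        idx = counts.sample_ids.get_indexer(pd.Index(replicate_map[sample]))
        out[:, j] = counts.counts[:, idx].sum(axis=1)
    return CountMatrix(counts.gene_ids, pd.Index(new_ids), out)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV with a scale tag comment line."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    df = expr.to_frame()
    df.index.name = "gene_id"
    with opener(path, "wt") as fh:
        fh.write(f"# scale={expr.scale}\n")
        df.to_csv(fh, sep="\t")


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline().strip()
        if not first.startswith("# scale="):
            raise FormatError(f"{path}: missing scale tag header")
        scale = first.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return ExpressionMatrix(
        df.index.astype(str), df.columns.astype(str), df.to_numpy(), scale
    )


def write_norm_factors(factors: NormFactors, path) -> None:
    factors.to_frame().to_csv(path, sep="\t", index=False)
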