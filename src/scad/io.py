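"""Readers, writers and gene-space harmonization.

The common currency of the pipeline is :class:`ExpressionMatrix`, a dense
samples × genes matrix with string identifiers and a ``layer_tag`` recording
how far along the preprocessing chain the values are.  All readers normalize
to the samples × genes orientation regardless of on-disk layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

LayerTag = Literal["raw_counts", "normalized", "log_normalized", "zscored"]

_VALID_TAGS = ("raw_counts", "normalized", "log_normalized", "zscored")


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Dense samples × genes expression values with identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_genes)
    sample_ids, gene_ids : ordered unique string identifiers
    layer_tag : one of ``raw_counts``, ``normalized``, ``log_normalized``,
        ``zscored``.  ``raw_counts`` additionally requires finite,
        non-negative values.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    layer_tag: LayerTag = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[0]} rows"
            )
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[1]} columns"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if self.layer_tag not in _VALID_TAGS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag == "raw_counts":
            if not np.all(np.isfinite(self.values)):
                raise ValueError("raw counts must be finite")
            if np.any(self.values < 0):
                raise ValueError("raw counts must be non-negative")
        if self.layer_tag == "zscored" and not np.all(np.isfinite(self.values)):
            raise ValueError("z-scored values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict columns to ``genes`` (must all be present), in given order."""
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in genes]
        return replace(
            self, values=self.values[:, cols], gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self, values=self.values[keep],
            sample_ids=[self.sample_ids[i] for i in keep],
            gene_ids=list(self.gene_ids),
        )


@dataclass
class ResponseLabelTable:
    """Per-sample binary drug sensitivity: 1 sensitive, 0 resistant, None unknown."""

    sample_ids: list[str]
    labels: list[int | None]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels length mismatch")
        for s, l in zip(self.sample_ids, self.labels):
            if l is not None and l not in (0, 1):
                raise ValueError(f"label for {s!r} must be 0, 1 or NA, got {l!r}")

    @property
    def known_mask(self) -> np.ndarray:
        return np.array([l is not None for l in self.labels])

    def known(self) -> "ResponseLabelTable":
        keep = self.known_mask
        return ResponseLabelTable(
            [s for s, k in zip(self.sample_ids, keep) if k],
            [l for l, k in zip(self.labels, keep) if k],
        )

    def to_array(self) -> np.ndarray:
        """Known labels as an int array; raises if any label is unknown."""
        if not self.known_mask.all():
            raise ValueError("table contains unknown labels; call .known() first")
        return np.array(self.labels, dtype=int)

    def align(self, sample_ids: Sequence[str]) -> "ResponseLabelTable":
        lut = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in sample_ids if s not in lut]
        if missing:
            raise KeyError(f"labels missing for samples: {missing[:5]}")
        return ResponseLabelTable(list(sample_ids), [lut[s] for s in sample_ids])


@dataclass
class GenePanel:
    """A named, non-empty set of gene identifiers (e.g. a PPI panel)."""

    gene_ids: set[str]
    name: str = "panel"

    def __post_init__(self) -> None:
        self.gene_ids = set(map(str, self.gene_ids))
        if not self.gene_ids:
            raise ValueError("gene panel is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_expression_matrix(
    path: str | Path,
    orientation: Literal["samples_by_genes", "genes_by_samples"] = "samples_by_genes",
    delimiter: str = "\t",
    layer_tag: LayerTag = "raw_counts",
) -> ExpressionMatrix:
    """Read a delimited matrix (header row + id column) into samples × genes."""
    # check header duplicates ourselves: pandas silently mangles them
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise ValueError(f"duplicate identifier in {path}: {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate identifier in {path}: {dup!r}")
    bad = df.map(lambda v: isinstance(v, str))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation == "genes_by_samples":
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(dtype=float), list(df.index), list(df.columns), layer_tag
    )


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    m.to_frame().to_csv(path, sep=delimiter, index_label="sample_id")


def read_mtx_triplet(directory: str | Path) -> ExpressionMatrix:
    """Read a 10x-style triplet: matrix.mtx (genes × cells), barcodes, features.

    The features file may have one column (gene id) or more (id + symbol ...);
    the first column is used.  Returns cells × genes raw counts.
    """
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    barcodes_f = _find_one(directory, ("barcodes.tsv", "barcodes.txt"))
    features_f = _find_one(directory, ("features.tsv", "genes.tsv", "features.txt"))
    mat = mmread(mtx).toarray()  # genes × cells per 10x convention
    barcodes = _read_lines(barcodes_f)
    features = [line.split("\t")[0] for line in _read_lines(features_f)]
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix is {mat.shape} but features/barcodes are "
            f"{len(features)}/{len(barcodes)}"
        )
    return ExpressionMatrix(mat.T, barcodes, features, "raw_counts")


def _find_one(directory: Path, names: tuple[str, ...]) -> Path:
    for n in names:
        p = directory / n
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {names} found in {directory}")


def _read_lines(path: Path) -> list[str]:
    return [l.strip() for l in path.read_text().splitlines() if l.strip()]


def intersect_genes(
    source: ExpressionMatrix, target: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the shared genes, lexicographically sorted.

    Sorting makes the source/target column alignment deterministic whatever
    the on-disk gene orders were.
    """
    shared = sorted(set(source.gene_ids) & set(target.gene_ids))
    if not shared:
        raise ValueError("gene sets are disjoint: empty intersection")
    return source.subset_genes(shared), target.subset_genes(shared)


def read_labels(path: str | Path, delimiter: str = "\t") -> ResponseLabelTable:
    """Two-column file: sample_id, label in {0, 1, NA}."""
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample_id, label")
    labels: list[int | None] = []
    for raw in df.iloc[:, 1]:
        token = str(raw).strip()
        if token.upper() in ("NA", "NAN", ""):
            labels.append(None)
        elif token in ("0", "1"):
            labels.append(int(token))
        else:
            raise ValueError(f"label must be 0, 1 or NA, got {token!r}")
    return ResponseLabelTable(list(df.iloc[:, 0]), labels)


def write_labels(t: ResponseLabelTable, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"sample_id{delimiter}label\n")
        for s, l in zip(t.sample_ids, t.labels):
            fh.write(f"{s}{delimiter}{'NA' if l is None else l}\n")


def read_gene_panel(path: str | Path, name: str | None = None) -> GenePanel:
    genes = _read_lines(Path(path))
    if len(genes) != len(set(genes)):
        raise ValueError("gene panel contains duplicates")
    return GenePanel(set(genes), name or Path(path).stem)


def write_report(report, path: str | Path) -> None:
    """Write a MetricsReport as JSON plus a sibling per-cell TSV."""
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2))
    report.to_frame().to_csv(path.with_suffix(".tsv"), sep="\t", index=False)


def read_report(path: str | Path):
    from .train import MetricsReport

    return MetricsReport.from_dict(json.loads(Path(path).read_text()))
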