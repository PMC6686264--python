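"""Data model and file I/O for paired two-platform expression cohorts.

The in-memory currency is :class:`ExpressionMatrix`, always oriented samples
x genes. On disk the default orientation is genes x samples (the GEO
series-matrix convention), controlled by an ``orientation`` flag. Inputs are
assumed to be already preprocessed, continuous log-scale expression; missing
values are rejected, not imputed.

Min-max normalization to [0, 1] is provided because the autoencoders use a
sigmoid output layer trained with cross-entropy, whose targets must lie in
the unit interval. Parameters are fitted on training data only; unseen values
outside the fitted range are clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PLATFORMS = ("microarray", "rnaseq", "other")


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Samples x genes real-valued expression matrix with a platform tag."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    platform: str = "other"
    normalized: bool = False

    def __post_init__(self):
        self.sample_ids = list(map(str, self.sample_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values contain NaN or Inf")
        if self.normalized and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("normalized matrix has values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        rows = [idx[s] for s in sample_ids]
        return replace(self, sample_ids=list(sample_ids), values=self.values[rows])


@dataclass
class GeneMap:
    """One-to-one gene-id pairing between two platforms."""

    pairs: list[tuple[str, str]]

    def __post_init__(self):
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        _check_unique([a for a, _ in self.pairs], "platform-A gene")
        _check_unique([b for _, b in self.pairs], "platform-B gene")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class EndpointLabels:
    """Named binary endpoint over a subset of the cohort's samples."""

    name: str
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(map(str, self.sample_ids))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels must align one-to-one with sample_ids")
        _check_unique(self.sample_ids, "sample")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    def subset(self, sample_ids) -> "EndpointLabels":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples without labels: {missing}")
        rows = [idx[s] for s in sample_ids]
        return EndpointLabels(self.name, list(sample_ids), self.labels[rows])


@dataclass
class NormalizationParams:
    """Per-gene min/max fitted on a training set, for [0, 1] scaling."""

    gene_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    constant_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if (self.maxs < self.mins).any():
            raise ValueError("per-gene max must be >= min")


# ---------------------------------------------------------------------------
# file I/O (tab-delimited text)


def read_expression(path, platform: str = "other",
                    orientation: str = "genes_by_samples") -> ExpressionMatrix:
    """Read a delimited expression table into samples x genes orientation.

    The file must have one header row of ids and one leading id column.
    ``orientation`` describes the on-disk layout; the default matches the
    GEO convention of genes on rows.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for axis, what in ((df.index, "row"), (df.columns, "column")):
        dup = axis[axis.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate {what} ids in {path}: {dup}")
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        r, c = np.argwhere(bad.isna().values)[0]
        raise ValueError(
            f"non-numeric value at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    if orientation == "genes_by_samples":
        bad = bad.T
    return ExpressionMatrix(
        sample_ids=bad.index.tolist(),
        gene_ids=bad.columns.tolist(),
        values=bad.values,
        platform=platform,
    )


def write_expression(x: ExpressionMatrix, path,
                     orientation: str = "genes_by_samples") -> None:
    df = x.to_frame()
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_map(path) -> GeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"gene map must have exactly 2 columns, got {df.shape[1]}")
    return GeneMap(list(df.itertuples(index=False, name=None)))


def write_gene_map(m: GeneMap, path) -> None:
    pd.DataFrame(m.pairs, columns=["gene_id_a", "gene_id_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path, name: str | None = None) -> EndpointLabels:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "label"} <= set(df.columns):
        raise ValueError("label file needs columns: sample_id, label")
    return EndpointLabels(name or str(path), df["sample_id"].tolist(), df["label"].values)


def write_labels(e: EndpointLabels, path) -> None:
    pd.DataFrame({"sample_id": e.sample_ids, "label": e.labels}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# cross-platform alignment and normalization


def align_platforms(a: ExpressionMatrix, b: ExpressionMatrix,
                    gene_map: GeneMap) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the mapped genes, identically ordered.

    Output column j of each matrix corresponds to gene_map.pairs[j]. Sample
    order of each input is preserved; both inputs must cover the same cohort.
    """
    if set(a.sample_ids) != set(b.sample_ids):
        only_a = sorted(set(a.sample_ids) - set(b.sample_ids))
        only_b = sorted(set(b.sample_ids) - set(a.sample_ids))
        raise ValueError(f"sample sets differ: only in A {only_a}, only in B {only_b}")
    idx_a = {g: i for i, g in enumerate(a.gene_ids)}
    idx_b = {g: i for i, g in enumerate(b.gene_ids)}
    missing = [ga for ga, _ in gene_map.pairs if ga not in idx_a]
    missing += [gb for _, gb in gene_map.pairs if gb not in idx_b]
    if missing:
        raise KeyError(f"mapped gene ids absent from matrices: {missing}")
    cols_a = [idx_a[ga] for ga, _ in gene_map.pairs]
    cols_b = [idx_b[gb] for _, gb in gene_map.pairs]
    out_a = replace(a, gene_ids=[ga for ga, _ in gene_map.pairs], values=a.values[:, cols_a])
    out_b = replace(b, gene_ids=[gb for _, gb in gene_map.pairs], values=b.values[:, cols_b])
    return out_a, out_b


def fit_minmax(x: ExpressionMatrix) -> NormalizationParams:
    """Fit per-gene min/max on (training) data; flags constant genes."""
    mins = x.values.min(axis=0)
    maxs = x.values.max(axis=0)
    constant = np.flatnonzero(maxs == mins)
    return NormalizationParams(list(x.gene_ids), mins, maxs, constant)


def apply_minmax(x: ExpressionMatrix, p: NormalizationParams) -> ExpressionMatrix:
    """Scale each gene to [0, 1] with p's range; clip out-of-range values.

    Constant genes (max == min on the fitting set) map to 0.0 by convention.
    """
    if list(x.gene_ids) != list(p.gene_ids):
        raise ValueError("gene ids of matrix and normalization params do not match")
    span = p.maxs - p.mins
    safe = np.where(span == 0, 1.0, span)
    vals = np.clip((x.values - p.mins) / safe, 0.0, 1.0)
    if len(p.constant_genes):
        vals[:, p.constant_genes] = 0.0
    return replace(x, values=vals, normalized=True)


def summarize_endpoint(e: EndpointLabels) -> dict:
    """n, per-class counts and the majority-class fraction (prevalence)."""
    n = len(e.labels)
    if n == 0:
        raise ValueError("empty endpoint labels")
    n1 = int(e.labels.sum())
    n0 = n - n1
    return {
        "name": e.name,
        "n": n,
        "count0": n0,
        "count1": n1,
        "majority_fraction": max(n0, n1) / n,
    }
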