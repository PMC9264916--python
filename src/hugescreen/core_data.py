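"""Data containers, file I/O, sample alignment, imputation and variant dichotomization.

The pipeline works on three gene-by-sample matrices — essentiality scores
(DEMETER/CERES-like, more negative = more essential), a binary mutation
indicator and a TPM expression matrix — plus cohort annotations and an
optional minimal variant table that is dichotomized into the mutation
indicator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSampleMatrix",
    "EssentialityMatrix",
    "MutationMatrix",
    "ExpressionMatrix",
    "CohortSpec",
    "VariantTable",
    "VariantFilters",
    "AlignedDataset",
    "read_matrix",
    "write_matrix",
    "knn_impute",
    "dichotomize_variants",
    "align_samples",
]

#: variant classes recognised by the minimal MAF-like dialect
VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "silent", "noncoding", "other"}
)


class MatrixParseError(ValueError):
    """Raised when a delimited matrix file cannot be parsed."""


@dataclass
class GeneSampleMatrix:
    """A real-valued genes x samples matrix with an explicit missing mask.

    ``values`` holds NaN wherever ``missing_mask`` is True; everywhere else
    entries are finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.isinf(self.values).any():
            raise ValueError("matrix contains infinite entries")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneSampleMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: list[str]) -> "GeneSampleMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(self, sample_ids=list(sample_ids), values=self.values[:, idx])

    def subset_genes(self, gene_ids: list[str]) -> "GeneSampleMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return replace(self, gene_ids=list(gene_ids), values=self.values[idx, :])


@dataclass
class EssentialityMatrix(GeneSampleMatrix):
    """Knockout x cell-line essentiality scores (more negative = more essential)."""

    @property
    def knockout_ids(self) -> list[str]:
        return self.gene_ids


@dataclass
class ExpressionMatrix(GeneSampleMatrix):
    """Gene x cell-line TPM expression; entries must be non-negative."""

    def __post_init__(self) -> None:
        super().__post_init__()
        observed = self.values[~np.isnan(self.values)]
        if (observed < 0).any():
            raise ValueError("TPM values must be non-negative")


@dataclass
class MutationMatrix:
    """Binary biomarker x cell-line mutation indicator (1 = mutant, 0 = wild-type)."""

    biomarker_ids: list[str]
    sample_ids: list[str]
    indicator: np.ndarray  # shape (n_biomarkers, n_samples), values in {0, 1}

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator)
        if not np.isin(self.indicator, (0, 1)).all():
            raise ValueError("mutation indicator entries must be exactly 0 or 1")
        self.indicator = self.indicator.astype(np.int8)
        if self.indicator.shape != (len(self.biomarker_ids), len(self.sample_ids)):
            raise ValueError("indicator shape inconsistent with id lists")
        if len(set(self.biomarker_ids)) != len(self.biomarker_ids):
            raise ValueError("duplicate biomarker ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.indicator, index=self.biomarker_ids, columns=self.sample_ids
        )

    def subset_samples(self, sample_ids: list[str]) -> "MutationMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MutationMatrix(
            biomarker_ids=list(self.biomarker_ids),
            sample_ids=list(sample_ids),
            indicator=self.indicator[:, idx],
        )


@dataclass
class CohortSpec:
    """A tumor-type cohort: member cell lines and the complement used for specificity."""

    tumor_label: str
    member_samples: list[str]
    other_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        members = set(self.member_samples)
        if not members:
            raise ValueError(f"cohort {self.tumor_label!r} has no member samples")
        if members & set(self.other_samples):
            raise ValueError("member and other sample sets must be disjoint")


@dataclass
class VariantFilters:
    """Filters applied when dichotomizing a variant table.

    Defaults are configurable placeholders in the spirit of standard cell-line
    variant-panel cleaning (drop common polymorphisms, low allelic fractions,
    putative neutral variants and non-coding substitutions).
    """

    min_allelic_fraction: float = 0.1
    exclude_silent: bool = True
    exclude_noncoding: bool = True
    exclude_common: bool = True
    exclude_neutral: bool = True


#: required columns of the minimal MAF-like variant table
VARIANT_COLUMNS = ["sample_id", "gene", "variant_class", "allelic_fraction", "common", "neutral"]


@dataclass
class VariantTable:
    """Minimal MAF-like variant records (one row per observed variant)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        af = self.rows["allelic_fraction"]
        bad = af.notna() & ((af < 0) | (af > 1))
        if bad.any():
            raise ValueError("allelic_fraction outside [0, 1]")

    @classmethod
    def read(cls, path) -> "VariantTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class AlignedDataset:
    """Sample-aligned essentiality, mutation and expression matrices."""

    essentiality: EssentialityMatrix
    mutations: MutationMatrix
    expression: ExpressionMatrix
    cohorts: list[CohortSpec]
    dropped_samples: dict[str, list[str]]


# ---------------------------------------------------------------------------
# I/O


def _read_delimited(path) -> pd.DataFrame:
    """Read a TSV/CSV (optionally gzipped) matrix with gene rows and sample header."""
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    sep = "," if name.endswith(".csv") else "\t"
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, na_values=["NA", "NaN", ""], keep_default_na=True
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc
    return df


def read_matrix(
    path,
    orientation: str = "genes_rows",
    kind: str = "essentiality",
) -> GeneSampleMatrix:
    """Read a delimited gene/sample matrix.

    Parameters
    ----------
    path
        TSV or CSV file (``.gz`` accepted); one header row and one id column.
    orientation
        ``genes_rows`` (default) or ``genes_cols`` (transposed on disk).
    kind
        ``essentiality`` or ``expression`` — selects the returned container.

    Empty cells and the sentinels ``NA``/``NaN`` become missing entries.
    """
    if orientation not in ("genes_rows", "genes_cols"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    if orientation == "genes_cols":
        df = df.T
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    for axis, ids in (("gene", df.index), ("sample", df.columns)):
        dup = ids[ids.duplicated()].unique()
        if len(dup):
            raise MatrixParseError(f"{path}: duplicated {axis} id(s): {', '.join(dup)}")
    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        # locate the first offending cell for a useful message
        for i, (gene, row) in enumerate(df.iterrows()):
            coerced = pd.to_numeric(row, errors="coerce")
            bad = coerced.isna() & row.notna()
            if bad.any():
                col = bad.idxmax()
                raise MatrixParseError(
                    f"{path}: non-numeric value {row[col]!r} at row {i + 2} "
                    f"(gene {gene!r}, sample {col!r})"
                ) from exc
        raise MatrixParseError(f"{path}: non-numeric data") from exc
    cls = ExpressionMatrix if kind == "expression" else EssentialityMatrix
    return cls(
        gene_ids=list(df.index), sample_ids=list(df.columns), values=values
    )


def write_matrix(matrix: GeneSampleMatrix | MutationMatrix, path) -> None:
    """Write a matrix as TSV, genes as rows; missing entries emitted as ``NA``."""
    matrix.to_frame().to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Imputation


def knn_impute(matrix: EssentialityMatrix, k: int = 10) -> EssentialityMatrix:
    """Nearest-neighbor-averaging imputation of missing essentiality entries.

    For each missing cell the imputed value is the mean over the ``k``
    nearest rows (Euclidean distance on co-observed columns, scaled by the
    fraction of co-observed columns) of their values in that column; rows
    missing that column do not donate.  If no candidate donor exists the row
    mean is used.  Observed entries are never changed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.values.copy()
    mask = np.isnan(values)
    if not mask.any():
        return replace(matrix, values=values)
    all_missing = mask.all(axis=1)
    if all_missing.any():
        bad = [matrix.gene_ids[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"rows with all entries missing cannot be imputed: {bad}")
    e = values.shape[0]
    if k > e - 1:
        warnings.warn(f"k={k} larger than {e - 1} candidate neighbors; clamping")
        k = max(1, e - 1)

    # pairwise distances on co-observed columns, scaled by co-observation fraction
    dist = nan_euclidean_distances(values)
    np.fill_diagonal(dist, np.inf)
    dist[np.isnan(dist)] = np.inf  # row pairs with no co-observed columns

    row_means = np.nanmean(values, axis=1)
    out = values.copy()
    for i in np.flatnonzero(mask.any(axis=1)):
        order = np.argsort(dist[i], kind="stable")
        for j in np.flatnonzero(mask[i]):
            donors = [r for r in order if np.isfinite(dist[i, r]) and not mask[r, j]]
            if donors:
                out[i, j] = values[donors[:k], j].mean()
            else:
                out[i, j] = row_means[i]
    return replace(matrix, values=out)


# ---------------------------------------------------------------------------
# Variant dichotomization


def dichotomize_variants(
    variants: VariantTable,
    genes: list[str],
    samples: list[str],
    filters: VariantFilters | None = None,
) -> MutationMatrix:
    """Collapse a variant table into a dense binary mutation indicator.

    An entry is 1 iff at least one variant for that (sample, gene) survives
    every filter; repeated qualifying variants still yield 1.
    """
    filters = filters or VariantFilters()
    rows = variants.rows.copy()

    unknown = set(rows["variant_class"].dropna()) - VARIANT_CLASSES
    if unknown:
        warnings.warn(f"unknown variant class(es) treated as 'other': {sorted(unknown)}")
        rows.loc[rows["variant_class"].isin(unknown), "variant_class"] = "other"

    keep = pd.Series(True, index=rows.index)
    af = rows["allelic_fraction"]
    keep &= af.isna() | (af >= filters.min_allelic_fraction)
    if filters.exclude_silent:
        keep &= rows["variant_class"] != "silent"
    if filters.exclude_noncoding:
        keep &= rows["variant_class"] != "noncoding"
    if filters.exclude_common:
        keep &= ~rows["common"].fillna(False).astype(bool)
    if filters.exclude_neutral:
        keep &= ~rows["neutral"].fillna(False).astype(bool)
    surviving = rows[keep]

    gene_idx = {g: i for i, g in enumerate(genes)}
    sample_idx = {s: j for j, s in enumerate(samples)}
    indicator = np.zeros((len(genes), len(samples)), dtype=np.int8)
    for gene, sample in zip(surviving["gene"], surviving["sample_id"]):
        gi = gene_idx.get(str(gene).strip())
        sj = sample_idx.get(str(sample).strip())
        if gi is not None and sj is not None:
            indicator[gi, sj] = 1
    return MutationMatrix(
        biomarker_ids=list(genes), sample_ids=list(samples), indicator=indicator
    )


# ---------------------------------------------------------------------------
# Alignment


def align_samples(
    essentiality: EssentialityMatrix,
    mutations: MutationMatrix,
    expression: ExpressionMatrix,
    cohorts: list[CohortSpec] | None = None,
) -> AlignedDataset:
    """Restrict all matrices to the shared cell lines, in a common column order.

    The common order is the essentiality matrix's order restricted to the
    intersection; cohorts are pruned to surviving samples.  Applied twice the
    operation is a no-op.
    """
    def _trim(ids: list[str]) -> list[str]:
        return [s.strip() for s in ids]

    ess_ids = _trim(essentiality.sample_ids)
    shared = set(ess_ids) & set(_trim(mutations.sample_ids)) & set(_trim(expression.sample_ids))
    if not shared:
        raise ValueError("no shared sample ids across essentiality, mutation and expression")
    order = [s for s in ess_ids if s in shared]

    dropped: dict[str, list[str]] = {}
    for name, ids in (
        ("essentiality", ess_ids),
        ("mutations", _trim(mutations.sample_ids)),
        ("expression", _trim(expression.sample_ids)),
    ):
        lost = sorted(set(ids) - shared)
        if lost:
            dropped[name] = lost
            logger.info("align_samples: dropping %d sample(s) from %s: %s", len(lost), name, lost)

    pruned_cohorts: list[CohortSpec] = []
    for cohort in cohorts or []:
        members = [s for s in _trim(cohort.member_samples) if s in shared]
        others = [s for s in _trim(cohort.other_samples) if s in shared]
        lost = sorted(set(_trim(cohort.member_samples)) - shared)
        if lost:
            warnings.warn(
                f"cohort {cohort.tumor_label!r}: pruning sample(s) absent from "
                f"the aligned data: {lost}"
            )
        pruned_cohorts.append(
            CohortSpec(tumor_label=cohort.tumor_label, member_samples=members, other_samples=others)
        )

    return AlignedDataset(
        essentiality=essentiality.subset_samples(order),
        mutations=mutations.subset_samples(order),
        expression=expression.subset_samples(order),
        cohorts=pruned_cohorts,
        dropped_samples=dropped,
    )
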