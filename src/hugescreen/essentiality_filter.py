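"""Selection of cohort-essential, cohort-specific, expressed knockout genes.

A knockout gene enters the downstream association tests only if
(i) it is essential (score at or below a cutoff, default -2) in at least a
minimum fraction of the cohort's cell lines, (ii) it is essential in at most
a maximum fraction of the non-cohort lines (cancer-type specificity), and
(iii) it is expressed (TPM above a cutoff, default 1) in a minimum fraction
of the cohort lines, so that a knockdown phenotype is interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CohortSpec, EssentialityMatrix, ExpressionMatrix

__all__ = ["EssentialityFilterParams", "EssentialGeneSet", "select_essential_genes"]


@dataclass
class EssentialityFilterParams:
    """Thresholds for the three essential-gene criteria.

    ``essential_score_cutoff``: a gene counts as essential in a cell line when
    its score is <= this value (default -2, the conventional strong-dependency
    magnitude for DEMETER-like scores).
    """

    essential_score_cutoff: float = -2.0
    min_fraction_cohort: float = 0.20
    max_fraction_other: float = 0.10
    expression_tpm_cutoff: float = 1.0
    min_fraction_expressed: float = 0.75


#: preset mirroring the AML analysis (essential in >= 25% of cohort lines)
AML_PRESET = EssentialityFilterParams(min_fraction_cohort=0.25)


@dataclass
class EssentialGeneSet:
    """Per-gene criterion fractions and the selected flag."""

    per_gene: pd.DataFrame  # index: knockout id; columns: the three fractions + selected
    params: EssentialityFilterParams = field(default_factory=EssentialityFilterParams)

    @property
    def selected_ids(self) -> list[str]:
        return list(self.per_gene.index[self.per_gene["selected"]])

    def to_tsv(self, path) -> None:
        self.per_gene.to_csv(path, sep="\t", index_label="knockout_id")


def select_essential_genes(
    essentiality: EssentialityMatrix,
    expression: ExpressionMatrix,
    cohort: CohortSpec,
    params: EssentialityFilterParams | None = None,
) -> EssentialGeneSet:
    """Apply the three essential-gene criteria and report all fractions.

    A gene is selected iff

    * fraction of cohort lines with score <= cutoff  >= ``min_fraction_cohort``,
    * fraction of other lines with score <= cutoff   <= ``max_fraction_other``,
    * fraction of cohort lines with TPM > tpm_cutoff >= ``min_fraction_expressed``.

    Missing scores count as not essential; the expression criterion is
    evaluated on cohort samples only.  A gene absent from the expression
    matrix is treated as not expressed (with a warning).
    """
    params = params or EssentialityFilterParams()
    members = [s for s in cohort.member_samples if s in essentiality.sample_ids]
    if len(members) < 2:
        raise ValueError(
            f"cohort {cohort.tumor_label!r} has fewer than 2 cell lines in the data"
        )
    others = cohort.other_samples or [
        s for s in essentiality.sample_ids if s not in set(members)
    ]
    others = [s for s in others if s in essentiality.sample_ids]

    df = essentiality.to_frame()
    cutoff = params.essential_score_cutoff
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        frac_cohort = (df[members] <= cutoff).mean(axis=1)
        frac_other = (
            (df[others] <= cutoff).mean(axis=1) if others else pd.Series(0.0, index=df.index)
        )

    expr = expression.to_frame()
    expr_members = [s for s in members if s in expr.columns]
    missing_genes = [g for g in essentiality.knockout_ids if g not in expr.index]
    if missing_genes:
        warnings.warn(
            f"{len(missing_genes)} knockout gene(s) absent from the expression "
            f"matrix treated as not expressed (e.g. {missing_genes[:5]})"
        )
    frac_expr = pd.Series(0.0, index=df.index)
    present = [g for g in df.index if g in expr.index]
    if present and expr_members:
        frac_expr.loc[present] = (
            (expr.loc[present, expr_members] > params.expression_tpm_cutoff).mean(axis=1)
        )

    selected = (
        (frac_cohort >= params.min_fraction_cohort)
        & (frac_other <= params.max_fraction_other)
        & (frac_expr >= params.min_fraction_expressed)
    )
    per_gene = pd.DataFrame(
        {
            "fraction_essential_cohort": frac_cohort,
            "fraction_essential_other": frac_other,
            "fraction_expressed": frac_expr,
            "selected": selected,
        }
    )
    return EssentialGeneSet(per_gene=per_gene, params=params)
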