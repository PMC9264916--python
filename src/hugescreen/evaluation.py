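"""Method comparison and validation against a clinical-association knowledgebase.

Two complementary evaluations:

* ``compare_methods`` counts significant (knockout, biomarker) pairs under
  each correction strategy at a common nominal level — the covariate-grouped
  procedures against pooled Storey-Tibshirani, BH, Bonferroni and Holm;
* knowledgebase validation labels a ranked LED list against curated clinical
  biomarker-target associations (VICC-like rows with evidence levels),
  optionally expanding targets through a gene network, and scores the
  ranking with ROC/PR curves and a top-k Fisher enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .led_calling import EdgeList, LEDThresholds, call_leds
from .multiple_testing import (
    classical_corrections,
    covariate_bh,
    estimate_pi0,
    grouped_local_fdr,
    storey_qvalues,
)

__all__ = [
    "KnowledgeBase",
    "ContingencyTable2x2",
    "compare_methods",
    "match_knowledgebase",
    "roc_pr",
    "fisher_enrichment",
    "top_k_contingency",
]


KB_COLUMNS = ["disease_label", "biomarker_gene", "target_gene", "evidence_level"]


@dataclass
class KnowledgeBase:
    """Curated clinical biomarker-target associations with evidence levels."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in KB_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"knowledgebase missing columns: {missing}")
        rows = self.rows.copy()
        rows["complete"] = (
            rows["biomarker_gene"].notna()
            & (rows["biomarker_gene"].astype(str).str.strip() != "")
            & rows["target_gene"].notna()
            & (rows["target_gene"].astype(str).str.strip() != "")
        )
        self.rows = rows

    @classmethod
    def read(cls, path) -> "KnowledgeBase":
        return cls(pd.read_csv(path, sep="\t"))

    def filter(
        self,
        disease: str | None = None,
        synonyms: list[str] | None = None,
        evidence_levels: list[str] | None = None,
        include_incomplete: bool = False,
    ) -> pd.DataFrame:
        """Deduplicated associations for one disease (and synonyms)."""
        rows = self.rows
        if not include_incomplete:
            rows = rows[rows["complete"]]
        if disease is not None:
            labels = {disease, *(synonyms or [])}
            rows = rows[rows["disease_label"].isin(labels)]
        if evidence_levels is not None:
            rows = rows[rows["evidence_level"].isin(evidence_levels)]
        return rows.drop_duplicates(subset=["biomarker_gene", "target_gene"]).reset_index(
            drop=True
        )


# ---------------------------------------------------------------------------
# method comparison


def compare_methods(
    results: pd.DataFrame,
    alpha: float = 0.20,
    led_thresholds: LEDThresholds | None = None,
) -> pd.DataFrame:
    """Count significant pairs per correction method at level ``alpha``.

    Pooled methods (Storey q-values, BH, Bonferroni, Holm) are applied to the
    pooled p-values; ``covariate_bh`` uses the biomarker grouping; the
    ``grouped_lfdr`` row counts calls passing the standard LED gates
    (p, lfdr, |delta|) after per-group local-FDR estimation.
    """
    tested = (~results["skipped"]) if "skipped" in results else results["p_value"].notna()
    tested &= results["p_value"].notna()
    p = results.loc[tested, "p_value"].to_numpy()

    counts: dict[str, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pi0 = estimate_pi0(p)
        counts["storey_q"] = int(np.sum(storey_qvalues(p, pi0) <= alpha))
        for method in ("bh", "bonferroni", "holm"):
            counts[method] = classical_corrections(p, method=method).n_significant(alpha)
        counts["covariate_bh"] = covariate_bh(results, alpha=alpha).n_significant_at[alpha]
        with_lfdr = grouped_local_fdr(results)
        counts["grouped_lfdr"] = len(call_leds(with_lfdr, led_thresholds))
    return pd.DataFrame(
        {"method": list(counts), "n_significant": list(counts.values())}
    )


# ---------------------------------------------------------------------------
# knowledgebase matching


def match_knowledgebase(
    leds: pd.DataFrame,
    kb: pd.DataFrame,
    edges: EdgeList | None = None,
    min_score: int = 400,
) -> np.ndarray:
    """Label each ranked LED as knowledgebase-supported or not.

    A LED is positive iff some knowledgebase row has the same biomarker gene
    and its target equals the LED's essential gene — or, when an edge list is
    supplied, the target is a direct network neighbor of the essential gene
    at ``min_score`` (pathway expansion).
    """
    if len(kb) == 0:
        warnings.warn("empty knowledgebase: all labels negative")
        return np.zeros(len(leds), dtype=bool)
    by_biomarker: dict[str, set[str]] = {}
    for b, t in zip(kb["biomarker_gene"], kb["target_gene"]):
        by_biomarker.setdefault(str(b), set()).add(str(t))

    labels = np.zeros(len(leds), dtype=bool)
    for i, (_, row) in enumerate(leds.iterrows()):
        targets = by_biomarker.get(str(row["biomarker_id"]))
        if not targets:
            continue
        gene = str(row["essential_gene_id"])
        if gene in targets:
            labels[i] = True
        elif edges is not None:
            labels[i] = any(edges.has_edge(t, gene, min_score) for t in targets)
    return labels


# ---------------------------------------------------------------------------
# ranking metrics


def roc_pr(labels, scores) -> dict:
    """ROC and PR summary of a scored ranking (higher score = more confident).

    AUROC is the rank statistic with ties averaged; AUPR is the step-wise
    average precision.  Curves are returned as point lists.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("labels must contain at least one positive and one negative")
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    return {
        "auroc": float(roc_auc_score(y, s)),
        "aupr": float(average_precision_score(y, s)),
        "roc_points": list(zip(fpr.tolist(), tpr.tolist())),
        "pr_points": list(zip(rec.tolist(), prec.tolist())),
    }


# ---------------------------------------------------------------------------
# Fisher enrichment


@dataclass
class ContingencyTable2x2:
    """Top-k enrichment table: (top-k ∩ KB, top-k ∖ KB, rest ∩ KB, rest ∖ KB)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_enrichment(
    table: ContingencyTable2x2, alternative: str = "greater"
) -> dict:
    """Exact hypergeometric test of the 2x2 table; returns odds ratio and p."""
    if alternative not in ("greater", "two-sided", "two_sided"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    alt = "two-sided" if alternative.startswith("two") else "greater"
    odds, p = stats.fisher_exact(table.as_array(), alternative=alt)
    return {"odds_ratio": float(odds), "p_value": float(p)}


def top_k_contingency(labels_a, labels_b, k: int | None = None) -> ContingencyTable2x2:
    """Contingency of KB hits between two top-k rankings.

    The universe is the union of the two rankings (2k when disjoint): cells
    count knowledgebase hits and misses in ranking A's top-k versus ranking
    B's top-k.
    """
    la = np.asarray(labels_a, dtype=bool)
    lb = np.asarray(labels_b, dtype=bool)
    if k is not None:
        la, lb = la[:k], lb[:k]
    return ContingencyTable2x2(
        a=int(la.sum()), b=int((~la).sum()), c=int(lb.sum()), d=int((~lb).sum())
    )
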