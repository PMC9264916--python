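"""Threshold-based calling and typing of lethal dependencies (LEDs).

A LED is a (biomarker, essential gene) pair whose knockout essentiality
differs between mutant and wild-type cell lines.  Calls pass three gates —
raw p-value, local FDR and the magnitude of the essentiality increment
delta = mean(mutant) - mean(wild-type) — and are typed by the sign of delta:

* pLED (positive): delta < 0, the alteration marks *sensitivity* to the
  knockout;
* nLED (negative): delta > 0, the alteration marks *resistance*;
* dLED (dual): one biomarker with called partners of both signs — the same
  alteration confers sensitivity to one gene and resistance to another.

An optional relation filter keeps only pairs with support in a scored
gene-gene association network (STRING-like edge list); self-pairs
(biomarker = essential gene) always pass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LEDThresholds",
    "EdgeList",
    "call_leds",
    "classify_leds",
    "relation_filter",
    "write_leds",
    "export_bipartite_graph",
]

LED_COLUMNS = [
    "biomarker_id",
    "essential_gene_id",
    "delta",
    "t_stat",
    "p_value",
    "lfdr",
    "led_type",
    "rank",
]


@dataclass
class LEDThresholds:
    """Calling gates; defaults follow the conventional strong-dependency values."""

    max_p: float = 0.05
    max_lfdr: float = 0.6
    min_abs_delta: float = 2.0

    def __post_init__(self) -> None:
        if self.max_p <= 0 or self.max_lfdr <= 0 or self.min_abs_delta <= 0:
            raise ValueError("thresholds must be positive")


class EdgeList:
    """Scored undirected gene-gene edges with symmetric lookup."""

    def __init__(self, edges: pd.DataFrame):
        required = {"gene_a", "gene_b", "combined_score"}
        if not required.issubset(edges.columns):
            raise ValueError(f"edge list needs columns {sorted(required)}")
        scores = edges["combined_score"]
        if ((scores < 0) | (scores > 1000)).any():
            raise ValueError("combined_score must be in [0, 1000]")
        self._score: dict[frozenset, int] = {}
        self._neighbors: dict[str, set[str]] = {}
        for a, b, s in zip(edges["gene_a"], edges["gene_b"], scores):
            a, b = str(a), str(b)
            key = frozenset((a, b))
            self._score[key] = max(int(s), self._score.get(key, 0))
            self._neighbors.setdefault(a, set()).add(b)
            self._neighbors.setdefault(b, set()).add(a)

    @classmethod
    def read(cls, path) -> "EdgeList":
        return cls(pd.read_csv(path, sep="\t"))

    def __len__(self) -> int:
        return len(self._score)

    def score(self, a: str, b: str) -> int | None:
        return self._score.get(frozenset((a, b)))

    def has_edge(self, a: str, b: str, min_score: int = 0) -> bool:
        s = self.score(a, b)
        return s is not None and s >= min_score

    def neighbors(self, gene: str, min_score: int = 0) -> set[str]:
        return {
            g for g in self._neighbors.get(gene, set())
            if self.has_edge(gene, g, min_score)
        }


def call_leds(
    results: pd.DataFrame,
    thresholds: LEDThresholds | None = None,
) -> pd.DataFrame:
    """Apply the three calling gates and rank the survivors.

    Keeps rows with ``p < max_p`` AND ``lfdr <= max_lfdr`` AND
    ``|delta| > min_abs_delta`` (the delta gate is strict).  Survivors are
    ranked by ascending p, ties broken by descending ``|delta|`` then by
    (knockout, biomarker) ids.
    """
    thresholds = thresholds or LEDThresholds()
    if "lfdr" not in results.columns:
        raise ValueError("results table lacks an 'lfdr' column; run grouped_local_fdr")
    t = results
    keep = (
        (t["p_value"] < thresholds.max_p)
        & (t["lfdr"] <= thresholds.max_lfdr)
        & (t["delta"].abs() > thresholds.min_abs_delta)
    )
    leds = t.loc[keep.fillna(False)].copy()
    leds = leds.rename(columns={"knockout_id": "essential_gene_id"})
    leds["abs_delta"] = leds["delta"].abs()
    leds = leds.sort_values(
        ["p_value", "abs_delta", "essential_gene_id", "biomarker_id"],
        ascending=[True, False, True, True],
        kind="stable",
    ).drop(columns="abs_delta")
    leds["rank"] = np.arange(1, len(leds) + 1)
    return leds.reset_index(drop=True)


def classify_leds(leds: pd.DataFrame) -> pd.DataFrame:
    """Type called LEDs by the sign of delta and flag dual biomarkers.

    ``sign_class`` is pLED (delta < 0) or nLED (delta > 0) and partitions the
    records.  Every record of a biomarker carrying both signs is promoted to
    ``led_type = dLED``; otherwise ``led_type = sign_class``.
    """
    if (leds["delta"] == 0).any():
        raise ValueError("delta = 0 record cannot be typed (should be gated out)")
    out = leds.copy()
    out["sign_class"] = np.where(out["delta"] < 0, "pLED", "nLED")
    both = out.groupby("biomarker_id")["sign_class"].transform("nunique") == 2
    out["led_type"] = np.where(both, "dLED", out["sign_class"])
    return out


def n_dual_biomarkers(classified: pd.DataFrame) -> int:
    """Number of dual (dLED) dependencies = biomarkers with both signs called."""
    return int((classified.groupby("biomarker_id")["sign_class"].nunique() == 2).sum())


def relation_filter(
    leds: pd.DataFrame,
    edges: EdgeList,
    min_score: int = 400,
    mode: str = "direct",
) -> pd.DataFrame:
    """Keep LEDs with support in the gene-gene network.

    ``direct`` requires an edge (biomarker, essential gene) with
    ``combined_score >= min_score`` (inclusive); ``shared_neighbor``
    additionally accepts pairs sharing at least one neighbor at that score.
    Self-pairs always pass.  Every record receives a ``relation_supported``
    flag before filtering.
    """
    if mode not in ("direct", "shared_neighbor"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(edges) == 0:
        warnings.warn("empty edge list: only self-pairs pass the relation filter")

    def _supported(row) -> bool:
        a, b = str(row["biomarker_id"]), str(row["essential_gene_id"])
        if a == b:
            return True
        if edges.has_edge(a, b, min_score):
            return True
        if mode == "shared_neighbor":
            return bool(edges.neighbors(a, min_score) & edges.neighbors(b, min_score))
        return False

    out = leds.copy()
    out["relation_supported"] = [bool(_supported(r)) for _, r in out.iterrows()]
    return out.loc[out["relation_supported"]].reset_index(drop=True)


def write_leds(leds: pd.DataFrame, path) -> None:
    """Write the LED table as TSV (one row per dependency, ranked)."""
    cols = [c for c in LED_COLUMNS if c in leds.columns]
    cols += [c for c in leds.columns if c not in cols]
    leds[cols].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def export_bipartite_graph(classified: pd.DataFrame, path) -> None:
    """Export the variant/knockout bipartite LED graph as a JSON nodes/edges file."""
    nodes = [
        {"id": b, "kind": "variant"} for b in sorted(classified["biomarker_id"].unique())
    ] + [
        {"id": g, "kind": "knockout"}
        for g in sorted(classified["essential_gene_id"].unique())
    ]
    edges = [
        {
            "variant": row["biomarker_id"],
            "knockout": row["essential_gene_id"],
            "delta": float(row["delta"]),
            "led_type": row["led_type"],
        }
        for _, row in classified.iterrows()
    ]
    with open(path, "w") as fh:
        json.dump({"nodes": nodes, "edges": edges}, fh, indent=1)
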