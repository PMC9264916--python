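"""Synthetic loss-of-function screens with hub-structured lethal dependencies.

The generator mirrors the generative structure the covariate-grouped analysis
presumes: a handful of "hub" biomarkers whose alteration shifts the
essentiality of many knockouts, against a background of inert (or weakly
acting) biomarkers.  Per cell line and biomarker, mutation status is
Bernoulli(prevalence); essentiality scores are a knockout baseline plus
Gaussian noise; for each true (biomarker, knockout) dependency, the mutant
lines' scores are shifted by ±effect_size (sign drawn 50/50 so that
positive, negative and dual dependencies are all exercised).

With ``effect_size = 0`` the generator is an exact null: every test's
p-value is uniform.  A Student-t noise option (5 df) is included to stress
the moderated test with heavy tails.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import EssentialityMatrix, ExpressionMatrix, MutationMatrix, write_matrix

__all__ = ["SimulationConfig", "SyntheticScreen", "simulate_screen", "evaluate_fdr_power"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic screen.

    Defaults describe a desk-scale hub-structured screen: 60 cell lines,
    100 knockouts, 100 biomarkers of which 5 are hubs driving 40 true
    dependencies each, mutation prevalence 0.3, essentiality shift ±3 score
    units against unit-variance noise around a baseline of -1.
    """

    n_samples: int = 60
    n_knockouts: int = 100
    n_biomarkers: int = 100
    n_hub_biomarkers: int = 5
    targets_per_hub: int = 40
    targets_per_nonhub: int = 0
    effect_size: float = 3.0
    noise_sd: float = 1.0
    mutation_prevalence: float = 0.3
    baseline_essentiality: float = -1.0
    noise: str = "gaussian"  # or "t5" for heavy tails
    expression_tpm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hub_biomarkers > self.n_biomarkers:
            raise ValueError("n_hub_biomarkers cannot exceed n_biomarkers")
        if self.targets_per_hub > self.n_knockouts:
            raise ValueError("targets_per_hub cannot exceed n_knockouts")
        if not 0.0 < self.mutation_prevalence < 1.0:
            raise ValueError("mutation_prevalence must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.noise not in ("gaussian", "t5"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class SyntheticScreen:
    """A generated screen plus the ground-truth dependency triples."""

    essentiality: EssentialityMatrix
    mutations: MutationMatrix
    expression: ExpressionMatrix
    truth: set = field(default_factory=set)  # {(biomarker_id, knockout_id, sign)}
    config: SimulationConfig | None = None

    @property
    def truth_pairs(self) -> set:
        return {(b, k) for b, k, _ in self.truth}

    def write(self, directory) -> None:
        """Write D/M/X TSVs, the truth table and the config JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_matrix(self.essentiality, directory / "essentiality.tsv")
        write_matrix(self.mutations, directory / "mutations.tsv")
        write_matrix(self.expression, directory / "expression.tsv")
        pd.DataFrame(
            sorted(self.truth), columns=["biomarker_id", "knockout_id", "sign"]
        ).to_csv(directory / "truth.tsv", sep="\t", index=False)
        if self.config is not None:
            (directory / "config.json").write_text(json.dumps(asdict(self.config), indent=1))


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_screen(cfg: SimulationConfig) -> SyntheticScreen:
    """Draw one synthetic screen; identical config (incl. seed) => identical output.

    Hub biomarkers are the first ``n_hub_biomarkers`` ids; each receives
    ``targets_per_hub`` distinct knockout targets, non-hubs receive
    ``targets_per_nonhub``.  A truth-carrying biomarker whose mutation column
    comes out with no mutant line is redrawn up to 10 times.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = _ids("CL", cfg.n_samples)
    knockouts = _ids("KO", cfg.n_knockouts)
    biomarkers = _ids("BM", cfg.n_biomarkers)

    # ground truth: hubs first, then (optionally weak) non-hubs
    truth: set = set()
    targets_of: dict[int, list[tuple[int, int]]] = {}
    for b in range(cfg.n_biomarkers):
        n_targets = cfg.targets_per_hub if b < cfg.n_hub_biomarkers else cfg.targets_per_nonhub
        if n_targets == 0 or cfg.effect_size == 0.0:
            continue
        targets = rng.choice(cfg.n_knockouts, size=n_targets, replace=False)
        signs = rng.choice((-1, 1), size=n_targets)
        targets_of[b] = list(zip(targets.tolist(), signs.tolist()))
        truth.update(
            (biomarkers[b], knockouts[k], int(s)) for k, s in targets_of[b]
        )

    indicator = (rng.random((cfg.n_biomarkers, cfg.n_samples)) < cfg.mutation_prevalence)
    for b in targets_of:
        attempts = 0
        while not indicator[b].any():
            if attempts >= 10:
                raise RuntimeError(
                    f"biomarker {biomarkers[b]} drew zero mutant lines in 10 attempts; "
                    "increase mutation_prevalence or n_samples"
                )
            indicator[b] = rng.random(cfg.n_samples) < cfg.mutation_prevalence
            attempts += 1

    if cfg.noise == "t5":
        noise = rng.standard_t(5, size=(cfg.n_knockouts, cfg.n_samples)) * cfg.noise_sd
    else:
        noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_knockouts, cfg.n_samples))
    scores = cfg.baseline_essentiality + noise
    for b, pairs in targets_of.items():
        mut = indicator[b]
        for k, sign in pairs:
            scores[k, mut] += sign * cfg.effect_size

    return SyntheticScreen(
        essentiality=EssentialityMatrix(
            gene_ids=knockouts, sample_ids=samples, values=scores
        ),
        mutations=MutationMatrix(
            biomarker_ids=biomarkers, sample_ids=samples,
            indicator=indicator.astype(np.int8),
        ),
        expression=ExpressionMatrix(
            gene_ids=knockouts, sample_ids=samples,
            values=np.full((cfg.n_knockouts, cfg.n_samples), cfg.expression_tpm),
        ),
        truth=truth,
        config=cfg,
    )


def evaluate_fdr_power(calls, truth) -> dict:
    """Score a call set against ground truth.

    ``calls`` is an iterable of (biomarker_id, knockout_id) pairs (a LED
    table's pairs, or a rejection set); ``truth`` is a set of pairs or of
    (biomarker, knockout, sign) triples.  ``empirical_fdr`` uses the
    zero-calls convention fdr = 0.
    """
    truth_pairs = {t[:2] for t in truth}
    call_pairs = set(calls)
    n_true = len(call_pairs & truth_pairs)
    n_false = len(call_pairs - truth_pairs)
    return {
        "empirical_fdr": n_false / max(1, len(call_pairs)),
        "power": n_true / len(truth_pairs) if truth_pairs else 0.0,
        "n_true": n_true,
        "n_false": n_false,
    }


def calls_from_table(table: pd.DataFrame, mask) -> set:
    """Helper: (biomarker, knockout) pairs of the rows selected by ``mask``."""
    sub = table.loc[mask]
    gene_col = "essential_gene_id" if "essential_gene_id" in sub else "knockout_id"
    return set(zip(sub["biomarker_id"], sub[gene_col]))
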