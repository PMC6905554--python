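"""Synthetic two-condition expression matrices with known ground truth.

The generator emulates the structure of a preprocessed two-condition
microarray benchmark on log2 scale: each gene has a baseline mean drawn
uniformly from a plausible log2-intensity range, i.i.d. gaussian noise
across samples, and a planted subset of "disease" genes whose mean in the
disease samples is shifted by a fixed effect size with a random sign per
gene (so both over- and under-expressed genes occur, matching a two-sided
|logFC| rule).  A contamination fraction of the planted genes is withheld
from the positive label to hide in the unlabeled pool, which is what makes
positive-unlabeled evaluation non-trivial.

Defaults mirror an AML-style benchmark: ~2500 genes of which just under
half carry the disease signal, 26 disease vs 38 healthy samples, a 3-unit
log2 shift against unit noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import DISEASE, HEALTHY, ExpressionMatrix, PUBenchmark
from .ocsvm import INLIER
from .pu_metrics import f_measure


class SimulationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate an AML-style benchmark."""

    n_genes: int = 2500
    n_disease_samples: int = 26
    n_healthy_samples: int = 38
    disease_gene_fraction: float = 0.47
    effect_size_delta: float = 3.0
    noise_sd: float = 1.0
    baseline_mean_range: tuple = (4.0, 10.0)
    contamination_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_disease_samples, self.n_healthy_samples) < 1:
            raise SimulationError("all counts must be positive")
        if not 0.0 < self.disease_gene_fraction < 1.0:
            raise SimulationError(
                f"disease_gene_fraction must be in (0,1), got {self.disease_gene_fraction}"
            )
        if not self.noise_sd > 0:
            raise SimulationError(f"noise_sd must be positive, got {self.noise_sd}")
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise SimulationError(
                f"contamination_fraction must be in [0,1), got {self.contamination_fraction}"
            )
        lo, hi = self.baseline_mean_range
        if not hi >= lo:
            raise SimulationError(f"invalid baseline_mean_range {self.baseline_mean_range}")


@dataclass
class SyntheticTruth:
    """Ground truth: all planted disease genes, the subset exposed as
    labeled positives, and the hidden positives left in the unlabeled set."""

    disease_genes: list
    labeled_positives: list
    hidden_positives: list

    def __post_init__(self) -> None:
        if set(self.labeled_positives) & set(self.hidden_positives):
            raise SimulationError("labeled and hidden positives overlap")
        if set(self.labeled_positives) | set(self.hidden_positives) != set(self.disease_genes):
            raise SimulationError("labeled + hidden positives must partition disease genes")


def generate_expression(config: SyntheticConfig):
    """Draw one synthetic ExpressionMatrix plus its SyntheticTruth.

    Entry (g, s) = mu_g + delta * sign_g * [g planted and s diseased] + eps,
    eps ~ N(0, noise_sd^2), mu_g ~ U(baseline_mean_range).  Seed-
    reproducible: the same config yields a bit-identical matrix.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    nd, nh = config.n_disease_samples, config.n_healthy_samples
    gene_ids = [f"g{i:05d}" for i in range(n)]
    sample_ids = [f"aml{j:02d}" for j in range(nd)] + [f"ctl{j:02d}" for j in range(nh)]
    condition = pd.Series(
        [DISEASE] * nd + [HEALTHY] * nh, index=sample_ids, name="condition"
    )
    lo, hi = config.baseline_mean_range
    mu = rng.uniform(lo, hi, size=n)
    values = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n, nd + nh))

    n_disease = int(round(config.disease_gene_fraction * n))
    disease_idx = rng.choice(n, size=n_disease, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_disease)
    values[disease_idx, :nd] += config.effect_size_delta * signs[:, None]

    disease_genes = sorted(gene_ids[i] for i in disease_idx)
    n_hidden = int(round(config.contamination_fraction * n_disease))
    hidden = sorted(rng.choice(disease_genes, size=n_hidden, replace=False).tolist())
    labeled = sorted(set(disease_genes) - set(hidden))
    truth = SyntheticTruth(
        disease_genes=disease_genes, labeled_positives=labeled, hidden_positives=hidden
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        condition=condition,
    )
    return expr, truth


def make_benchmark_from_truth(expr: ExpressionMatrix, truth: SyntheticTruth) -> PUBenchmark:
    """Benchmark taking the generator's labels at face value: labeled
    positives are the positive set; everything else (including hidden
    positives) is unlabeled."""
    pos = set(truth.labeled_positives)
    unlabeled = [g for g in expr.values.index if g not in pos]
    return PUBenchmark(
        positives=list(truth.labeled_positives),
        unlabeled=unlabeled,
        features=expr.values,
    )


def ground_truth_metrics(pred: pd.Series, truth: SyntheticTruth):
    """True precision/recall/F of predictions over an evaluated gene pool,
    using the hidden labels.

    ``pred``: Series indexed by gene id with values +1 (inlier) / -1.
    Genes in ``truth.disease_genes`` count as true positives wherever they
    appear in the evaluated pool.  Raises if the prediction index misses
    any gene it claims to cover (the caller passes exactly the evaluated
    pool).
    """
    if pred.index.duplicated().any():
        raise SimulationError("duplicate gene ids in predictions")
    evaluated = set(pred.index)
    disease = set(truth.disease_genes) & evaluated
    predicted_pos = set(pred.index[pred == INLIER])
    tp = len(disease & predicted_pos)
    fp = len(predicted_pos - disease)
    fn = len(disease - predicted_pos)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure(precision, recall),
        "tp": tp,
        "fp": fp,
        "fn": fn,
    }


def write_truth(truth: SyntheticTruth, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(
            {
                "disease_genes": truth.disease_genes,
                "labeled_positives": truth.labeled_positives,
                "hidden_positives": truth.hidden_positives,
            },
            fh,
            indent=1,
        )


def read_truth(path) -> SyntheticTruth:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return SyntheticTruth(
        disease_genes=d["disease_genes"],
        labeled_positives=d["labeled_positives"],
        hidden_positives=d["hidden_positives"],
    )
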