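"""Binary-classifier baselines on balanced positive/pseudo-negative sets.

The comparison protocol the one-class model is judged against: treat a
random, equal-size sample of the unlabeled genes as negatives (|P| = |N|),
train a conventional binary classifier (RBF-SVM, k-nearest-neighbours or a
decision tree via scikit-learn), and score it on the same held-out pool
with the same PU metric code paths as the one-class model.  Because the
pseudo-negatives are drawn from a contaminated unlabeled pool, hidden
positives among them corrupt the decision boundary — the effect the
one-class route avoids by never touching unlabeled genes during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .benchmark import BenchmarkError, PUBenchmark
from .ocsvm import INLIER, OUTLIER
from .pu_metrics import ConfusionCounts, PUMetrics, confusion_from_labels, evaluate_pu

BASELINE_METHODS = ("svm_binary", "knn", "decision_tree")


@dataclass
class BaselineConfig:
    """A named binary baseline with its hyperparameters and sampling seed.

    Defaults: RBF-SVM with C=1, KNN with k=5, unlimited-depth decision
    tree — recorded in every report since exact baseline configurations
    are a free choice of the protocol.
    """

    method: str = "svm_binary"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in BASELINE_METHODS:
            raise BenchmarkError(
                f"unknown baseline method {self.method!r}; choose from {BASELINE_METHODS}"
            )


def _make_estimator(config: BaselineConfig):
    hp = dict(config.hyperparameters)
    if config.method == "svm_binary":
        hp.setdefault("kernel", "rbf")
        hp.setdefault("C", 1.0)
        return SVC(random_state=config.seed, **hp)
    if config.method == "knn":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    hp.setdefault("criterion", "gini")
    return DecisionTreeClassifier(random_state=config.seed, **hp)


def make_balanced_binary(benchmark: PUBenchmark, seed: int = 0):
    """Sample |P| pseudo-negatives uniformly from the unlabeled genes.

    Returns (positive ids, pseudo-negative ids); seed-reproducible, and the
    sample never contains a known positive (it is drawn from the unlabeled
    list only).
    """
    n_pos = len(benchmark.positives)
    if len(benchmark.unlabeled) < n_pos:
        raise BenchmarkError(
            f"cannot balance: {len(benchmark.unlabeled)} unlabeled < {n_pos} positives"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(benchmark.unlabeled), size=n_pos, replace=False)
    negatives = [benchmark.unlabeled[i] for i in sorted(idx)]
    return list(benchmark.positives), negatives


def run_baseline(
    config: BaselineConfig,
    train_features: pd.DataFrame,
    train_labels: np.ndarray,
    test_pos_features: pd.DataFrame,
    test_unl_features: pd.DataFrame,
    unlabeled_truth: int = 0,
):
    """Train the configured binary classifier and evaluate it on the shared
    test pool with the same PU estimators used for the one-class model.

    ``train_labels`` uses +1 for positives and -1 for pseudo-negatives.
    Returns (PUMetrics, ConfusionCounts).  By default the second test pool
    is treated as unlabeled (PU mode: the counts carry tp/fn only); pass
    ``unlabeled_truth=-1`` when that pool holds genuine negatives, which
    fills in fp/tn as well.
    """
    est = _make_estimator(config)
    est.fit(train_features.to_numpy(dtype=float), np.asarray(train_labels))
    pred_pos = est.predict(test_pos_features.to_numpy(dtype=float))
    pred_unl = (
        est.predict(test_unl_features.to_numpy(dtype=float))
        if len(test_unl_features)
        else np.array([])
    )
    metrics = evaluate_pu(pred_pos, pred_unl)
    truth = np.concatenate(
        [np.ones(len(pred_pos)), np.full(len(pred_unl), unlabeled_truth)]
    ).astype(int)
    counts = confusion_from_labels(truth, np.concatenate([pred_pos, pred_unl]).astype(int))
    return metrics, counts


def compare_methods(results) -> pd.DataFrame:
    """Render a method x {precision, recall, F-measure} comparison table.

    ``results``: sequence of (name, PUMetrics-or-dict-or-None); dict rows
    carry externally supplied published numbers with keys precision/recall/
    f_measure as percentages.  Values render as percentages with 2
    decimals; missing entries render as NA.  Rows keep input order.
    """
    if len(results) < 2:
        raise BenchmarkError("comparison needs at least 2 result rows")
    rows = []
    for name, res in results:
        if res is None:
            rows.append({"method": name, "precision": None, "recall": None, "f_measure": None})
        elif isinstance(res, PUMetrics):
            rows.append({"method": name, **res.as_percent()})
        else:
            rows.append(
                {
                    "method": name,
                    "precision": res.get("precision"),
                    "recall": res.get("recall"),
                    "f_measure": res.get("f_measure"),
                }
            )
    df = pd.DataFrame(rows).set_index("method")
    return df


def format_comparison(df: pd.DataFrame) -> str:
    """TSV rendering, percentages with 2 decimals, NA for missing cells."""
    lines = ["method\tprecision\trecall\tf_measure"]
    for name, row in df.iterrows():
        cells = [
            "NA" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.2f}"
            for v in (row["precision"], row["recall"], row["f_measure"])
        ]
        lines.append("\t".join([str(name)] + cells))
    return "\n".join(lines) + "\n"
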