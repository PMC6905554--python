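"""Build a positive/unlabeled gene benchmark from a labeled expression matrix.

The pipeline mirrors the standard construction for disease-gene
prioritization from a two-condition expression study: per-gene differential
expression (Welch t-test on log2 values, Benjamini-Hochberg adjustment),
threshold labeling (|log2 fold change| > 1 and adjusted p < 0.05, strict,
defines the positive set; everything else is unlabeled), robust outlier
removal, min-max scaling of the gene expression profiles used as feature
vectors, a 70/30 split of the positives, and positives-only k-fold
cross-validation.

Gene expression profiles are the feature vectors: a gene's row across all
samples.  Unlabeled genes never enter training; they form the evaluation
pool in which candidate disease genes are searched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("ocgene")

DISEASE = "disease"
HEALTHY = "healthy"


class BenchmarkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample expression table with per-sample condition labels.

    ``values``: DataFrame indexed by gene id, columns sample ids.
    ``condition``: Series mapping sample id -> {"disease", "healthy"}.
    """

    values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()[:5]
            raise BenchmarkError(f"duplicate gene ids: {dups}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise BenchmarkError("expression matrix contains non-finite values")
        missing = [s for s in self.values.columns if s not in self.condition.index]
        if missing:
            raise BenchmarkError(f"samples without condition label: {missing[:5]}")
        bad = set(self.condition.unique()) - {DISEASE, HEALTHY}
        if bad:
            raise BenchmarkError(
                f"unknown condition labels {sorted(bad)}; expected {DISEASE!r}/{HEALTHY!r}"
            )

    @property
    def disease_samples(self) -> list:
        return [s for s in self.values.columns if self.condition[s] == DISEASE]

    @property
    def healthy_samples(self) -> list:
        return [s for s in self.values.columns if self.condition[s] == HEALTHY]


@dataclass
class PUBenchmark:
    """Positive and unlabeled gene id lists plus their feature matrix
    (genes x samples, expression profiles as feature vectors)."""

    positives: list
    unlabeled: list
    features: pd.DataFrame

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.unlabeled)
        if overlap:
            raise BenchmarkError(f"positive/unlabeled overlap: {sorted(overlap)[:5]}")
        missing = (set(self.positives) | set(self.unlabeled)) - set(self.features.index)
        if missing:
            raise BenchmarkError(f"benchmark genes missing from features: {sorted(missing)[:5]}")


@dataclass
class SplitSpec:
    """Train/test and cross-validation configuration."""

    train_fraction: float = 0.7
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise BenchmarkError(f"train_fraction must be in (0,1), got {self.train_fraction}")
        if self.cv_folds < 2:
            raise BenchmarkError(f"cv_folds must be >= 2, got {self.cv_folds}")


@dataclass
class ScaleParams:
    """Per-feature min/max fitted on the training matrix (min-max scaling)."""

    x_min: pd.Series
    x_max: pd.Series


# ---------------------------------------------------------------------------
# differential expression and labeling
# ---------------------------------------------------------------------------


def differential_expression(expr: ExpressionMatrix, already_log: bool = True) -> pd.DataFrame:
    """Per-gene log2 fold change and Welch-test p-values, BH-adjusted.

    log_fc = mean(log2 disease) - mean(log2 healthy).  Input values are
    taken as already log2-scale unless ``already_log=False``, in which case
    log2(x + 1) is applied first.  Genes with zero variance in both groups
    get p = 1 when the group means are equal (no evidence), p = 0 otherwise
    (infinite t).
    """
    dis, hea = expr.disease_samples, expr.healthy_samples
    if len(dis) < 2 or len(hea) < 2:
        raise BenchmarkError(
            f"need >= 2 samples per condition for differential expression, "
            f"got {len(dis)} disease / {len(hea)} healthy"
        )
    vals = expr.values
    if not already_log:
        vals = np.log2(vals + 1.0)
    D = vals[dis].to_numpy()
    H = vals[hea].to_numpy()
    log_fc = D.mean(axis=1) - H.mean(axis=1)
    import warnings

    with warnings.catch_warnings():
        # zero-variance rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p_raw = stats.ttest_ind(D, H, axis=1, equal_var=False)
    # zero variance in both groups: nan from the test
    nan = ~np.isfinite(p_raw)
    if nan.any():
        p_raw = p_raw.copy()
        p_raw[nan & (np.abs(log_fc) > 0)] = 0.0
        p_raw[nan & (np.abs(log_fc) == 0)] = 1.0
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    return pd.DataFrame(
        {"log_fc": log_fc, "p_raw": p_raw, "p_adj": p_adj}, index=expr.values.index
    )


def select_positive_unlabeled(
    de: pd.DataFrame,
    features: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    unlabeled_cap: int | None = None,
) -> PUBenchmark:
    """Label genes positive iff |log_fc| > lfc_threshold (strict) and
    p_adj < alpha (strict); all remaining genes are unlabeled.

    ``unlabeled_cap`` optionally keeps only the cap genes with smallest
    |log_fc| in the unlabeled set (the "least differentially expressed"
    convention for a fixed-size unlabeled pool).
    """
    if lfc_threshold <= 0 or alpha <= 0:
        raise BenchmarkError("thresholds must be positive")
    pos_mask = (de["log_fc"].abs() > lfc_threshold) & (de["p_adj"] < alpha)
    positives = de.index[pos_mask].tolist()
    unl = de.loc[~pos_mask]
    if unlabeled_cap is not None and len(unl) > unlabeled_cap:
        unl = unl.reindex(unl["log_fc"].abs().sort_values(kind="stable").index[:unlabeled_cap])
        unl = unl.loc[[g for g in de.index if g in set(unl.index)]]  # restore input order
    unlabeled = unl.index.tolist()
    if not positives:
        logger.warning("empty positive set: no gene passed |logFC|>%g and p_adj<%g",
                       lfc_threshold, alpha)
    keep = positives + unlabeled
    return PUBenchmark(
        positives=positives,
        unlabeled=unlabeled,
        features=features.loc[keep],
    )


# ---------------------------------------------------------------------------
# outlier removal and scaling
# ---------------------------------------------------------------------------


def remove_outliers(features: pd.DataFrame, z_threshold: float = 4.0):
    """Drop genes whose robust z-score exceeds the threshold on any feature.

    Per feature (sample column), z = (x - median) / (1.4826 * MAD); features
    with MAD = 0 are skipped (degenerate scale).  Returns (reduced features,
    removed gene ids).
    """
    if len(features) < 3:
        raise BenchmarkError(f"need >= 3 rows for outlier screening, got {len(features)}")
    X = features.to_numpy(dtype=float)
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0) * 1.4826
    ok_scale = mad > 0
    z = np.zeros_like(X)
    z[:, ok_scale] = (X[:, ok_scale] - med[ok_scale]) / mad[ok_scale]
    outlier = (np.abs(z) > z_threshold).any(axis=1)
    if outlier.all():
        raise BenchmarkError("outlier removal would drop every gene; lower z_threshold?")
    removed = features.index[outlier].tolist()
    if removed:
        logger.info("outlier removal dropped %d genes", len(removed))
    return features.loc[~outlier], removed


def minmax_scale(train_features: pd.DataFrame, *other_features: pd.DataFrame):
    """Min-max scale to [0, 1] with parameters fitted on training data only.

    x' = (x - x_min) / (x_max - x_min) per feature; other matrices are
    transformed with the training parameters and clipped to [0, 1];
    constant features map to 0.  Returns (scaled train, *scaled others,
    ScaleParams).
    """
    if train_features.empty:
        raise BenchmarkError("cannot fit scaling on an empty training matrix")
    x_min = train_features.min(axis=0)
    x_max = train_features.max(axis=0)
    params = ScaleParams(x_min=x_min, x_max=x_max)
    out = [apply_scale(params, train_features)]
    for other in other_features:
        out.append(apply_scale(params, other))
    out.append(params)
    return tuple(out)


def apply_scale(params: ScaleParams, features: pd.DataFrame) -> pd.DataFrame:
    span = params.x_max - params.x_min
    safe = span.replace(0.0, 1.0)
    scaled = (features - params.x_min) / safe
    scaled.loc[:, span == 0.0] = 0.0
    return scaled.clip(0.0, 1.0)


# ---------------------------------------------------------------------------
# splitting and cross-validation
# ---------------------------------------------------------------------------


def split_train_test(benchmark: PUBenchmark, spec: SplitSpec):
    """Seed-reproducible split of the positives; unlabeled genes all go to
    the evaluation pool (they never appear in training).

    Returns (train_positives, test_positives, test_unlabeled) as id lists.
    """
    pos = list(benchmark.positives)
    if len(pos) < 2:
        raise BenchmarkError(f"need >= 2 positives to split, got {len(pos)}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(pos))
    n_train = int(round(spec.train_fraction * len(pos)))
    n_train = min(max(n_train, 1), len(pos) - 1)
    train = [pos[i] for i in order[:n_train]]
    test = [pos[i] for i in order[n_train:]]
    return train, test, list(benchmark.unlabeled)


def cross_validate(
    train_features: pd.DataFrame,
    kernel=None,
    nu: float = None,
    folds: int = 10,
    seed: int = 0,
):
    """Positives-only k-fold cross-validation of the one-class model.

    Partitions the training positives into ``folds`` disjoint folds, trains
    on folds-1 and scores recall on the held-out fold (the only classical
    metric computable within positives).  Returns (per-fold recalls, mean,
    sd).
    """
    from . import ocsvm as oc

    if kernel is None:
        kernel = oc.KernelSpec("linear")
    if nu is None:
        nu = oc.DEFAULT_NU
    n = len(train_features)
    if folds > n:
        raise BenchmarkError(f"cannot make {folds} folds from {n} training positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, folds)
    X = train_features.to_numpy(dtype=float)
    recalls = []
    for held in fold_ids:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        model = oc.fit_ocsvm(X[mask], kernel=kernel, nu=nu)
        pred = oc.predict(model, X[held])
        recalls.append(float(np.mean(pred == oc.INLIER)))
    recalls = np.asarray(recalls)
    return recalls, float(recalls.mean()), float(recalls.std(ddof=1 if folds > 1 else 0))


# ---------------------------------------------------------------------------
# I/O: expression matrices, condition maps, supplementary-style layouts
# ---------------------------------------------------------------------------


def read_expression(matrix_path, condition_path=None, sep=None) -> ExpressionMatrix:
    """Read an expression CSV/TSV (first column gene id, remaining columns
    samples) plus a sidecar condition map (sample<TAB/comma>condition)."""
    values = pd.read_csv(matrix_path, sep=sep, engine="python", index_col=0)
    if condition_path is None:
        raise BenchmarkError(
            "no condition map given: provide a sidecar file mapping sample id to "
            f"'{DISEASE}' or '{HEALTHY}'"
        )
    cond = pd.read_csv(condition_path, sep=sep, engine="python", index_col=0).iloc[:, 0]
    cond.index = cond.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values=values, condition=cond.astype(str).str.strip())


def write_expression(expr: ExpressionMatrix, matrix_path, condition_path) -> None:
    expr.values.to_csv(matrix_path)
    expr.condition.rename("condition").to_csv(condition_path)


def write_benchmark_supplementary(benchmark: PUBenchmark, positives_path, full_path) -> None:
    """Write the benchmark in the two-file supplementary layout: a positive
    gene matrix CSV and the complete benchmark matrix CSV."""
    benchmark.features.loc[benchmark.positives].to_csv(positives_path)
    benchmark.features.to_csv(full_path)


def read_benchmark_supplementary(positives_path, full_path) -> PUBenchmark:
    """Read a benchmark from the supplementary layout: positives are the
    genes of the positive matrix; unlabeled are the remaining genes of the
    full matrix."""
    pos = pd.read_csv(positives_path, index_col=0)
    full = pd.read_csv(full_path, index_col=0)
    missing = set(pos.index) - set(full.index)
    if missing:
        raise BenchmarkError(
            f"positive genes absent from the full matrix: {sorted(missing)[:5]}"
        )
    positives = pos.index.tolist()
    unlabeled = [g for g in full.index if g not in set(positives)]
    return PUBenchmark(positives=positives, unlabeled=unlabeled, features=full)
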