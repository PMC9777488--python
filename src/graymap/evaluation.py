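"""Cross-validation harness and agreement statistics.

Everything the slide classifiers are scored with: multiclass metrics
(accuracy, macro F1, Cohen's kappa, generalized MCC, macro precision/recall/
specificity/Jaccard), binary metrics with rank-statistic ROC AUC, the
intraclass correlation coefficient ICC(2,1) with an F-based 95% CI,
discordance-rate reporting, a median-of-raters consensus utility, and the
stratified 5-fold cross-validation driver comparing the multitask CNN with
the GrayMax baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .graymax import GrayMaxClassifier
from .maps import slide_max_gray
from .model import MultitaskCNN, SlideSample, TrainConfig, canvas_embed

__all__ = [
    "MetricsReport",
    "compute_multiclass_metrics",
    "compute_binary_metrics",
    "icc",
    "roc_points",
    "discordance_rate",
    "median_consensus",
    "stratified_folds",
    "run_cv",
    "CVResult",
]


@dataclass
class MetricsReport:
    """Named metric values with optional degenerate-input flags."""

    values: dict
    flags: list = field(default_factory=list)

    def __getitem__(self, key):
        return self.values[key]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values)


def _expand_cm(cm: np.ndarray):
    """Confusion matrix (rows truth, cols prediction) -> label vectors."""
    y_true, y_pred = [], []
    k = cm.shape[0]
    for i in range(k):
        for j in range(k):
            y_true.extend([i] * int(cm[i, j]))
            y_pred.extend([j] * int(cm[i, j]))
    return np.array(y_true), np.array(y_pred)


def _specificity(cm: np.ndarray) -> float:
    """Macro-averaged specificity TN / (TN + FP) over one-vs-rest splits."""
    total = cm.sum()
    specs = []
    for i in range(cm.shape[0]):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = total - tp - fp - fn
        specs.append(tn / (tn + fp) if tn + fp else 0.0)
    return float(np.mean(specs))


def compute_multiclass_metrics(cm: np.ndarray) -> MetricsReport:
    """All multiclass metrics from a confusion matrix (rows = truth)."""
    cm = np.asarray(cm, dtype=int)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    y_true, y_pred = _expand_cm(cm)
    flags = []
    single_class = len(np.unique(y_true)) < 2
    if single_class:
        flags.append("single-class truth: kappa/MCC undefined, reported as 0")
        kappa = mcc = 0.0
    else:
        kappa = float(skm.cohen_kappa_score(y_true, y_pred))
        mcc = float(skm.matthews_corrcoef(y_true, y_pred))
    labels = np.arange(cm.shape[0])
    values = {
        "accuracy": float(skm.accuracy_score(y_true, y_pred)),
        "f1_macro": float(skm.f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        "kappa": kappa,
        "mcc": mcc,
        "precision": float(skm.precision_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        "recall": float(skm.recall_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        "specificity": _specificity(cm),
        "jaccard": float(skm.jaccard_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
    }
    return MetricsReport(values, flags)


def compute_binary_metrics(truth, scores, threshold: float = 0.5) -> MetricsReport:
    """Binary metrics from scores in [0, 1]; AUC by the rank statistic."""
    y = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    flags = []
    tp = int(((y == 1) & (pred == 1)).sum())
    tn = int(((y == 0) & (pred == 0)).sum())
    fp = int(((y == 0) & (pred == 1)).sum())
    fn = int(((y == 1) & (pred == 0)).sum())
    if len(np.unique(y)) < 2:
        flags.append("one-class truth: AUC undefined, reported as nan")
        auc = float("nan")
    else:
        auc = float(skm.roc_auc_score(y, s))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    values = {
        "accuracy": (tp + tn) / len(y),
        "precision": p,
        "recall": r,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "f1": 2 * p * r / (p + r) if p + r else 0.0,
        "jaccard": tp / (tp + fp + fn) if tp + fp + fn else 0.0,
        "auc": auc,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }
    return MetricsReport(values, flags)


def roc_points(truth, scores) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for TSV export."""
    fpr, tpr, thr = skm.roc_curve(np.asarray(truth, int), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def icc(ratings: np.ndarray) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (N subjects, R raters) matrix with no missing entries.
    Returns the point estimate and the F-distribution 95% CI.  Zero variance
    everywhere degenerates to ICC = 1.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("ratings must be (N>=5, R>=2)")
    if np.isnan(x).any():
        raise ValueError("ratings must have no missing entries")
    if np.allclose(x, x.flat[0]):
        return 1.0, (1.0, 1.0)
    import pingouin as pg

    n, r = x.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), r),
            "rater": np.tile(np.arange(r), n),
            "score": x.ravel(),
        }
    )
    res = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    # two-way random effects, absolute agreement, single rater
    sel = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    row = sel.iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))


def discordance_rate(n_discordant: int, n_total: int) -> float:
    """Percent discordant, rounded half-up to 2 decimals (e.g. 13/228 -> 5.70)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_discordant <= n_total:
        raise ValueError("n_discordant must be within [0, n_total]")
    pct = Decimal(100 * n_discordant) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def median_consensus(scores: np.ndarray) -> np.ndarray:
    """Median of ordinal rater scores per subject (consensus ground truth)."""
    x = np.asarray(scores)
    return np.median(x, axis=1)


def stratified_folds(strat_labels, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment; fold sizes differ by <= 1.

    Samples are shuffled within each stratum and dealt round-robin, with the
    starting fold rotating across strata so totals balance.
    """
    labels = np.asarray(strat_labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    offset = 0
    for val in sorted(pd.unique(labels).tolist(), key=str):
        idx = np.flatnonzero(labels == val)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[i] = (j + offset) % n_folds
        offset += len(idx)
    return folds


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation results."""

    per_fold: pd.DataFrame  # one row per fold, columns metric_model
    mean: pd.Series
    std: pd.Series  # sample std (ddof=1)
    cnn_fish_auc_pooled: float
    fold_assignment: np.ndarray
    predictions: pd.DataFrame


def run_cv(
    slides,
    cfg: TrainConfig,
    n_folds: int = 5,
    seed: int = 0,
    graymax_baseline: bool = True,
) -> CVResult:
    """Stratified k-fold CV of the multitask CNN (and GrayMax baseline).

    ``slides`` is a sequence of :class:`graymap.simulate.CohortSlide`-like
    objects (``gmap``, ``ihc_class``, ``fish_label``).  Stratification is on
    the joint (IHC class, FISH status) label so both heads keep class
    coverage per fold.  Per fold the CNN trains on the other folds and
    predicts the held-out one; GrayMax fits its thresholds on the same
    training slides' maximum gray values.  Aggregates are the mean and
    sample standard deviation over folds; the FISH AUC is also pooled over
    all held-out predictions.
    """
    ihc = np.array([s.ihc_class for s in slides])
    fish = np.array([s.fish_label for s in slides])
    joint = np.array([f"{a}|{b}" for a, b in zip(ihc, fish)])
    folds = stratified_folds(joint, n_folds=n_folds, seed=seed)

    canvases = [canvas_embed(s.gmap, cfg) for s in slides]
    max_grays = np.array([slide_max_gray(s.gmap) for s in slides])

    rows = []
    pred_records = []
    for k in range(n_folds):
        train_idx = np.flatnonzero(folds != k)
        test_idx = np.flatnonzero(folds == k)
        train_samples = [
            SlideSample(
                canvas=canvases[i],
                ihc_label=int(ihc[i]),
                fish_label=int(fish[i]),
                fold_id=int(folds[i]),
                slide_id=getattr(slides[i], "slide_id", str(i)),
            )
            for i in train_idx
        ]
        net = MultitaskCNN(cfg).fit(train_samples)
        ihc_pred, fish_scores = [], []
        for i in test_idx:
            pred = net.predict_sample(
                SlideSample(canvas=canvases[i], ihc_label=None, fish_label=None)
            )
            ihc_pred.append(pred.ihc_class)
            fish_scores.append(pred.fish_score)
        ihc_pred = np.array(ihc_pred)
        fish_scores = np.array(fish_scores)

        cm = skm.confusion_matrix(ihc[test_idx], ihc_pred, labels=[0, 1, 2])
        mc = compute_multiclass_metrics(cm)
        row = {f"cnn_ihc_{k2}": v for k2, v in mc.values.items()}
        bm = compute_binary_metrics(fish[test_idx], fish_scores)
        row.update({f"cnn_fish_{k2}": v for k2, v in bm.values.items() if k2 not in ("tp", "tn", "fp", "fn")})

        if graymax_baseline:
            gm = GrayMaxClassifier.fit(max_grays[train_idx], ihc[train_idx])
            gm_pred = gm.predict(max_grays[test_idx])
            gm_cm = skm.confusion_matrix(ihc[test_idx], gm_pred, labels=[0, 1, 2])
            gm_metrics = compute_multiclass_metrics(gm_cm)
            row.update({f"graymax_ihc_{k2}": v for k2, v in gm_metrics.values.items()})
            gm_pred_full = gm_pred
        else:
            gm_pred_full = np.full(len(test_idx), -1)

        row["fold"] = k
        rows.append(row)
        for j, i in enumerate(test_idx):
            pred_records.append(
                {
                    "slide_id": getattr(slides[i], "slide_id", str(i)),
                    "fold": k,
                    "ihc_true": int(ihc[i]),
                    "ihc_pred_cnn": int(ihc_pred[j]),
                    "ihc_pred_graymax": int(gm_pred_full[j]),
                    "fish_true": int(fish[i]),
                    "fish_score_cnn": float(fish_scores[j]),
                }
            )

    per_fold = pd.DataFrame(rows).set_index("fold")
    preds = pd.DataFrame(pred_records)
    pooled_auc = float(
        skm.roc_auc_score(preds["fish_true"], preds["fish_score_cnn"])
    )
    return CVResult(
        per_fold=per_fold,
        mean=per_fold.mean(),
        std=per_fold.std(ddof=1),
        cnn_fish_auc_pooled=pooled_auc,
        fold_assignment=folds,
        predictions=preds,
    )
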