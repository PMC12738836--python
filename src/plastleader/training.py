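"""Training, cross-validation and evaluation of the leader classifier.

The optimisation recipe: cross-entropy on logits, Adam (lr 1e-3, L2 weight
decay 1e-5), batches of 64, up to 50 epochs, an 80/20 stratified
train/test split, 5-fold stratified cross-validation on the training side,
plateau-halving learning-rate scheduling and early stopping on validation
loss with best-weight restoration. Everything is reproducible under the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold, train_test_split

from .encoding import EncodedBatch, encode
from .model import LeaderNet, ModelConfig, build_model
from .nn import autograd as ag
from .nn.optim import Adam, ReduceLROnPlateau, clip_grad_norm
from .sd import MotifSet, harvest_misclassified, truncate_leader
from .sequences import LeaderSequence


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    epochs: int = 50
    batch_size: int = 64
    test_fraction: float = 0.2
    cv_folds: int = 5
    early_stopping_patience: int = 5
    lr_factor: float = 0.5
    lr_patience: int = 2
    lr_floor: float = 1e-5
    grad_clip_norm: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 <= self.epochs <= 50:
            raise ValueError("epochs must lie in [0, 50]")


@dataclass
class MetricsReport:
    """Binary-classification metric suite for one evaluated model."""

    n: int
    confusion: np.ndarray            # (2, 2) counts, rows = true class
    confusion_percent: np.ndarray    # row-normalised percentages
    accuracy: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    mcc: float
    roc_auc: float | None
    average_precision: float | None
    roc_curve: tuple[np.ndarray, np.ndarray] | None = None   # (fpr, tpr)
    pr_curve: tuple[np.ndarray, np.ndarray] | None = None    # (recall, precision)
    label_names: list[str] = field(default_factory=list)
    notes: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        d["confusion_percent"] = self.confusion_percent.tolist()
        d.pop("roc_curve")
        d.pop("pr_curve")
        return d


def stratified_split(batch: EncodedBatch, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[EncodedBatch, EncodedBatch]:
    """Disjoint stratified train/test split, deterministic under ``seed``."""
    idx = np.arange(len(batch))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=batch.labels, random_state=seed
    )
    return batch.subset(train_idx), batch.subset(test_idx)


def kfold_indices(labels: np.ndarray, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """k disjoint stratified folds (arrays of indices) partitioning the input."""
    labels = np.asarray(labels)
    if k > np.bincount(labels).min():
        raise ValueError(f"k={k} exceeds the smallest class size")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [val for _, val in skf.split(np.zeros(len(labels)), labels)]


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_accuracy: float
    val_loss: float
    val_accuracy: float
    learning_rate: float


def _dataset_loss(model: LeaderNet, batch: EncodedBatch, batch_size: int) -> tuple[float, float]:
    """Evaluation-mode mean loss and accuracy over a dataset."""
    was_training = model.training
    model.eval()
    losses, correct = [], 0
    try:
        with ag.no_grad():
            for i in range(0, len(batch), batch_size):
                xb = batch.data[i:i + batch_size]
                yb = batch.labels[i:i + batch_size]
                logits = model(xb)
                losses.append(float(ag.softmax_cross_entropy(logits, yb).data) * len(yb))
                correct += int((logits.data.argmax(axis=1) == yb).sum())
    finally:
        model.train(was_training)
    return sum(losses) / len(batch), correct / len(batch)


def train(model: LeaderNet, train_set: EncodedBatch, val_set: EncodedBatch,
          config: TrainConfig) -> list[EpochRecord]:
    """Fit ``model`` in place; returns the per-epoch history.

    Stops at the epoch cap or when validation loss has not improved for
    ``early_stopping_patience`` epochs, then restores the best-validation
    parameters. Raises on divergence (non-finite loss), reporting the epoch.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("empty training or validation set")
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    sched = ReduceLROnPlateau(opt, factor=config.lr_factor,
                              patience=config.lr_patience, min_lr=config.lr_floor)
    rng = np.random.default_rng(config.seed)
    history: list[EpochRecord] = []
    best_loss = np.inf
    best_state = model.state_dict()
    bad_epochs = 0
    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            xb = train_set.data[sel]
            yb = train_set.labels[sel]
            model.zero_grad()
            logits = model(xb)
            loss = ag.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            if config.grad_clip_norm is not None:
                clip_grad_norm(model.parameters(), config.grad_clip_norm)
            opt.step()
            epoch_loss += float(loss.data) * len(sel)
            epoch_correct += int((logits.data.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _dataset_loss(model, val_set, config.batch_size)
        history.append(EpochRecord(
            epoch=epoch,
            train_loss=epoch_loss / len(train_set),
            train_accuracy=epoch_correct / len(train_set),
            val_loss=val_loss,
            val_accuracy=val_acc,
            learning_rate=opt.lr,
        ))
        if val_loss < best_loss - 1e-8:
            best_loss = val_loss
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stopping_patience:
                break
        sched.step(val_loss)
    model.load_state_dict(best_state)
    model.eval()
    return history


def evaluate(model: LeaderNet, test_set: EncodedBatch,
             batch_size: int = 256) -> MetricsReport:
    """Full metric suite on a held-out set (caller guarantees disjointness)."""
    probs = model.predict_proba(test_set.data, batch_size)
    return metrics_from_scores(test_set.labels, probs,
                               label_names=test_set.label_names)


def metrics_from_scores(y_true: np.ndarray, probs: np.ndarray,
                        label_names: list[str] | None = None) -> MetricsReport:
    """Compute the metric suite from true labels and class-1 probabilities."""
    y_true = np.asarray(y_true)
    probs = np.asarray(probs)
    y_pred = probs.argmax(axis=1)
    scores = probs[:, 1]
    cm = skm.confusion_matrix(y_true, y_pred, labels=[0, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cm_pct = 100.0 * cm / cm.sum(axis=1, keepdims=True)
    pw, rw, fw, _ = skm.precision_recall_fscore_support(
        y_true, y_pred, average="weighted", zero_division=0)
    pm, rm, fm, _ = skm.precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0)
    notes = ""
    if len(np.unique(y_true)) < 2:
        roc_auc = ap = None
        roc = pr = None
        notes = "single-class test set: ROC-AUC and AP undefined"
    else:
        roc_auc = float(skm.roc_auc_score(y_true, scores))
        ap = float(skm.average_precision_score(y_true, scores))
        fpr, tpr, _ = skm.roc_curve(y_true, scores)
        prec, rec, _ = skm.precision_recall_curve(y_true, scores)
        roc = (fpr, tpr)
        pr = (rec, prec)
    return MetricsReport(
        n=len(y_true),
        confusion=cm,
        confusion_percent=np.nan_to_num(cm_pct),
        accuracy=float(skm.accuracy_score(y_true, y_pred)),
        precision_weighted=float(pw), recall_weighted=float(rw), f1_weighted=float(fw),
        precision_macro=float(pm), recall_macro=float(rm), f1_macro=float(fm),
        mcc=float(skm.matthews_corrcoef(y_true, y_pred)),
        roc_auc=roc_auc, average_precision=ap,
        roc_curve=roc, pr_curve=pr,
        label_names=label_names or [], notes=notes,
    )


def export_curves(report: MetricsReport, prefix: str | Path) -> None:
    """Write ROC and precision-recall curve points as TSV files."""
    if report.roc_curve is not None:
        fpr, tpr = report.roc_curve
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
            f"{prefix}.roc.tsv", sep="\t", index=False)
    if report.pr_curve is not None:
        rec, prec = report.pr_curve
        pd.DataFrame({"recall": rec, "precision": prec}).to_csv(
            f"{prefix}.pr.tsv", sep="\t", index=False)


@dataclass
class CvResult:
    fold_reports: list[MetricsReport]
    fold_models: list[LeaderNet]
    summary: pd.DataFrame  # metric -> mean, sd over folds

    @property
    def mean_accuracy(self) -> float:
        return float(self.summary.loc["accuracy", "mean"])


_CV_METRICS = ("accuracy", "precision_weighted", "recall_weighted", "f1_weighted",
               "precision_macro", "recall_macro", "f1_macro", "mcc", "roc_auc",
               "average_precision")


def run_cv_experiment(train_set: EncodedBatch, model_config: ModelConfig,
                      train_config: TrainConfig) -> CvResult:
    """Stratified k-fold cross-validation: each fold serves as validation once;
    aggregation is the per-metric mean and standard deviation over folds."""
    folds = kfold_indices(train_set.labels, train_config.cv_folds, train_config.seed)
    all_idx = np.arange(len(train_set))
    reports, models = [], []
    for f, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(all_idx, val_idx)
        model = build_model(model_config)
        train(model, train_set.subset(tr_idx), train_set.subset(val_idx), train_config)
        reports.append(evaluate(model, train_set.subset(val_idx)))
        models.append(model)
    rows = {}
    for m in _CV_METRICS:
        vals = [getattr(r, m) for r in reports]
        vals = [v for v in vals if v is not None]
        rows[m] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1))
                   if len(vals) > 1 else 0.0}
    return CvResult(reports, models, pd.DataFrame(rows).T)


@dataclass
class TruncationResult:
    """Side-by-side outcome of training on full-length vs truncated leaders."""

    full_report: MetricsReport
    truncated_report: MetricsReport
    full_model: LeaderNet
    truncated_model: LeaderNet
    table: pd.DataFrame
    full_history: list[EpochRecord]
    truncated_history: list[EpochRecord]


def truncation_experiment(leaders: list[LeaderSequence], model_config: ModelConfig,
                          train_config: TrainConfig, remove: int = 30,
                          sd_motifs: MotifSet | None = None,
                          sd_window: int = 20) -> TruncationResult:
    """Train and evaluate with the identical recipe on full-length leaders and
    on their ``remove``-nt 3'-truncations, with a per-class breakdown of
    misclassified outputs by SD status.

    The same train/validation/test membership (by sequence identity) is used
    for both arms, so the only difference is the missing proximal window.
    """
    L = len(leaders[0].sequence)
    full = encode(leaders, target_length=L)
    trunc_leaders = [truncate_leader(ld, remove) for ld in leaders]
    truncated = encode(trunc_leaders, target_length=L - remove) if remove else full

    idx = np.arange(len(full))
    tr_idx, te_idx = train_test_split(idx, test_size=train_config.test_fraction,
                                      stratify=full.labels,
                                      random_state=train_config.seed)
    tr_idx2, val_idx = train_test_split(
        tr_idx, test_size=1.0 / train_config.cv_folds,
        stratify=full.labels[tr_idx], random_state=train_config.seed)

    results = {}
    for arm, batch, seq_len, arm_leaders in (
        ("full", full, L, leaders),
        ("truncated", truncated, L - remove if remove else L, trunc_leaders),
    ):
        cfg = ModelConfig(**{**asdict(model_config), "seq_length": seq_len})
        model = build_model(cfg)
        history = train(model, batch.subset(tr_idx2), batch.subset(val_idx),
                        train_config)
        report = evaluate(model, batch.subset(te_idx))
        preds = model.predict(batch.data[te_idx])
        names = batch.label_names
        pred_labels = [names[p] for p in preds]
        true_labels = [names[t] for t in batch.labels[te_idx]]
        # SD status is always judged on the FULL-LENGTH sequence
        harvested = harvest_misclassified(
            pred_labels, true_labels, [leaders[int(i)] for i in te_idx],
            sd_motifs, sd_window)
        results[arm] = (model, history, report, harvested, true_labels, pred_labels)

    rows = []
    names = full.label_names
    for arm in ("full", "truncated"):
        _, _, report, harvested, true_labels, pred_labels = results[arm]
        for cname in names:
            mis = pd.concat([df for (t, _p), df in harvested.items() if t == cname]) \
                if harvested else pd.DataFrame(columns=["has_sd"])
            prec, rec, f1, _ = skm.precision_recall_fscore_support(
                [t == cname for t in true_labels],
                [p == cname for p in pred_labels],
                average="binary", zero_division=0)
            rows.append({
                "inputs": arm, "class": cname,
                "n_inputs": int(sum(t == cname for t in true_labels)),
                "precision": float(prec), "recall": float(rec), "f1": float(f1),
                "misclassified_total": int(len(mis)),
                "misclassified_with_sd": int(mis["has_sd"].sum()) if len(mis) else 0,
                "misclassified_without_sd": int((~mis["has_sd"].astype(bool)).sum())
                if len(mis) else 0,
            })
    table = pd.DataFrame(rows)
    return TruncationResult(
        full_report=results["full"][2],
        truncated_report=results["truncated"][2],
        full_model=results["full"][0],
        truncated_model=results["truncated"][0],
        table=table,
        full_history=results["full"][1],
        truncated_history=results["truncated"][1],
    )
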