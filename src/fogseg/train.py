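"""Training loop, leave-one-subject-out harness, and the sliding-window
recognition scheme.

Training follows the reference recipe: Adam (lr 0.0005), 100 epochs, batch
size 16, the summed multi-stage cross-entropy + truncated smoothing loss.
Variable-length trials are grouped by similar length into padded batches
with a validity mask; batch-norm statistics and the loss are computed over
valid samples only.

Leave-one-subject-out (LOSO) evaluation holds out all trials of one subject
per fold; trials of subjects outside the evaluation set act as train-only
enrichment and join every fold's training set.  Metrics are pooled per
subject and summarized as mean ± SD over the evaluated subjects.

The sliding-window scheme (used with the Bi-LSTM recognition baseline)
trains on fixed two-second windows labelled by majority vote (ties resolved
to functional gait) and predicts per sample by sliding the window in steps
of one, assigning each window's label to its central sample; edge samples
take the nearest valid window's label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam
from .io import DegenerateTrialError, displacement_features
from .losses import LossConfig, total_loss
from .metrics import DEFAULT_THRESHOLDS, EvalReport, aggregate_reports, \
    evaluate_subject

__all__ = [
    "ExperimentPlan", "PlanError", "DivergenceError",
    "loso_folds", "audit_no_leakage", "make_batches", "train",
    "trials_to_xy", "run_loso",
    "majority_label", "make_windows", "sliding_window_predict",
    "train_recognizer",
]

FG = 0


class PlanError(ValueError):
    """Invalid cross-validation plan (e.g. a subject without trials)."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class ExperimentPlan:
    """LOSO folds plus optimizer settings."""

    folds: list                      # of (train_trial_ids, eval_subject_id)
    optimizer: str = "adam"
    lr: float = 5e-4
    epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    meta: dict = field(default_factory=dict)


def loso_folds(trials, eval_subjects=None, **settings) -> ExperimentPlan:
    """Build one fold per evaluation subject.

    ``eval_subjects`` defaults to every subject present; subjects outside it
    are treated as train-only enrichment and their trials appear in every
    fold's training set, never in evaluation.
    """
    by_subject: dict[str, list] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t.trial_id)
    if eval_subjects is None:
        eval_subjects = sorted(by_subject)
    eval_subjects = list(eval_subjects)
    if len(eval_subjects) < 2:
        raise PlanError("LOSO needs at least 2 evaluation subjects")
    for s in eval_subjects:
        if not by_subject.get(s):
            raise PlanError(f"evaluation subject {s!r} has no trials")
    enrichment = [tid for s, tids in by_subject.items()
                  if s not in eval_subjects for tid in tids]
    folds = []
    for s in eval_subjects:
        train_ids = [tid for s2 in eval_subjects if s2 != s
                     for tid in by_subject[s2]] + list(enrichment)
        folds.append((train_ids, s))
    return ExperimentPlan(folds=folds, **settings)


def audit_no_leakage(plan: ExperimentPlan, trials) -> None:
    """Assert that no evaluation trial appears in its fold's training set."""
    by_subject: dict[str, set] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, set()).add(t.trial_id)
    for train_ids, eval_subject in plan.folds:
        overlap = set(train_ids) & by_subject.get(eval_subject, set())
        if overlap:
            raise PlanError(
                f"fold for {eval_subject!r} leaks evaluation trials: {overlap}")


def trials_to_xy(trials):
    """Displacement features and aligned labels for a list of trials."""
    X, y = [], []
    for t in trials:
        fs = displacement_features(t)
        X.append(fs.features.astype(np.float32))
        y.append(fs.labels)
    return X, y


def make_batches(features, labels, batch_size: int):
    """Group sequences of similar length into padded batches with masks.

    Returns a list of ``(x [B, Tmax, N, C], y [B, Tmax], mask [B, Tmax])``.
    """
    order = np.argsort([len(f) for f in features])[::-1]
    batches = []
    for i in range(0, len(order), batch_size):
        idx = order[i:i + batch_size]
        tmax = max(len(features[j]) for j in idx)
        shape = features[idx[0]].shape[1:]
        x = np.zeros((len(idx), tmax) + tuple(shape), dtype=np.float32)
        y = np.zeros((len(idx), tmax), dtype=np.int64)
        mask = np.zeros((len(idx), tmax), dtype=np.float32)
        for b, j in enumerate(idx):
            T = len(features[j])
            x[b, :T] = features[j]
            y[b, :T] = labels[j]
            mask[b, :T] = 1.0
        batches.append((x, y, mask))
    return batches


def train(model, features, labels, loss_config: LossConfig = None,
          lr: float = 5e-4, epochs: int = 100, batch_size: int = 16,
          seed: int = 0, shuffle: bool = True) -> list:
    """Train a segmentation model; returns the per-epoch mean-loss curve.

    Deterministic for a fixed seed (batch order is the only randomness; the
    model's weights are seeded at construction).  Raises
    :class:`DivergenceError` on a non-finite loss.
    """
    loss_config = loss_config or LossConfig()
    opt = Adam(model.parameters(), lr=lr)
    batches = make_batches(features, labels, batch_size)
    rng = np.random.default_rng(seed)
    history = []
    model.train()
    for epoch in range(epochs):
        order = rng.permutation(len(batches)) if shuffle else np.arange(len(batches))
        tot = 0.0
        for bi in order:
            x, y, mask = batches[bi]
            outputs = model.forward(x, mask)
            loss = total_loss(outputs, y, loss_config, mask)
            val = loss.item()
            if not np.isfinite(val):
                raise DivergenceError(
                    f"non-finite loss {val} at epoch {epoch} batch {bi}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += val
        history.append(tot / len(batches))
    model.eval()
    return history


def run_loso(trials, make_estimator, plan: ExperimentPlan = None,
             eval_subjects=None, thresholds=DEFAULT_THRESHOLDS) -> dict:
    """Run the full LOSO experiment with a fresh estimator per fold.

    ``make_estimator`` is a zero-argument callable returning an unfitted
    estimator (see :mod:`fogseg.estimators`).  Returns per-subject pooled
    reports, per-trial reports, and the mean ± SD aggregate.
    """
    if plan is None:
        plan = loso_folds(trials, eval_subjects)
    audit_no_leakage(plan, trials)
    by_id = {t.trial_id: t for t in trials}
    subject_reports: dict[str, EvalReport] = {}
    trial_rows = []
    for train_ids, eval_subject in plan.folds:
        est = make_estimator()
        X_tr, y_tr = trials_to_xy([by_id[i] for i in train_ids])
        est.fit(X_tr, y_tr)
        eval_trials = [t for t in trials if t.subject_id == eval_subject]
        X_ev, y_ev = trials_to_xy(eval_trials)
        preds = est.predict(X_ev)
        subject_reports[eval_subject] = evaluate_subject(
            preds, y_ev, thresholds=thresholds)
        for t, p, r in zip(eval_trials, preds, y_ev):
            trial_rows.append({"subject_id": t.subject_id,
                               "trial_id": t.trial_id,
                               "pred": p, "ref": np.asarray(r)})
    summary = aggregate_reports(list(subject_reports.values()))
    return {"per_subject": subject_reports, "per_trial": trial_rows,
            "summary": summary}


# -- sliding-window recognition scheme --------------------------------------


def majority_label(labels) -> int:
    """Majority vote over a window; ties resolve to FG (the negative class)."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2)
    order = np.argsort(counts, kind="stable")
    best = order[-1]
    if counts[best] == counts[FG]:
        return FG
    return int(best)


def make_windows(features, labels, window: int):
    """Fixed non-overlapping training windows with majority-vote labels."""
    features = np.asarray(features)
    xs, ys = [], []
    for s in range(0, len(features) - window + 1, window):
        xs.append(features[s:s + window])
        ys.append(majority_label(labels[s:s + window]))
    return np.stack(xs), np.asarray(ys)


def sliding_window_predict(recognizer, features, window_s: float = 2.0,
                           rate_hz: float = 100.0, step: int = 1,
                           chunk: int = 512) -> np.ndarray:
    """Per-sample labels from a window recognizer slid in steps of ``step``.

    Each window's predicted label is assigned to its central sample; samples
    before the first / after the last window center take the nearest valid
    window's label.
    """
    features = np.asarray(features, dtype=np.float32)
    T = len(features)
    W = int(round(window_s * rate_hz))
    if T < W:
        raise DegenerateTrialError(
            f"trial of {T} samples is shorter than the {W}-sample window")
    starts = np.arange(0, T - W + 1, step)
    centers = starts + W // 2
    preds = np.empty(len(starts), dtype=np.int64)
    for i in range(0, len(starts), chunk):
        batch = np.stack([features[s:s + W] for s in starts[i:i + chunk]])
        preds[i:i + len(batch)] = recognizer.predict_windows(batch)
    out = np.empty(T, dtype=np.int64)
    out[centers] = preds
    out[:centers[0]] = preds[0]
    out[centers[-1]:] = preds[-1]
    # fill any interior gaps (step > 1) with the nearest center's label
    if step > 1:
        filled = np.interp(np.arange(T), centers, preds)
        out = np.rint(filled).astype(np.int64)
        out[centers] = preds
    return out


def train_recognizer(recognizer, features_list, labels_list,
                     window_s: float = 2.0, rate_hz: float = 100.0,
                     lr: float = 5e-4, epochs: int = 100,
                     batch_size: int = 16, seed: int = 0) -> list:
    """Train a window-level recognizer on majority-labelled fixed windows."""
    from . import autodiff as ad
    from .losses import cls_loss

    W = int(round(window_s * rate_hz))
    xs, ys = [], []
    for f, l in zip(features_list, labels_list):
        if len(f) < W:
            continue
        x, y = make_windows(f, l, W)
        xs.append(x)
        ys.append(y)
    if not xs:
        raise DegenerateTrialError("no trial is long enough for one window")
    X = np.concatenate(xs)
    Y = np.concatenate(ys)
    opt = Adam(recognizer.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    history = []
    recognizer.train()
    for _ in range(epochs):
        order = rng.permutation(len(X))
        tot, nb = 0.0, 0
        for i in range(0, len(X), batch_size):
            idx = order[i:i + batch_size]
            _, probs = recognizer.forward(X[idx])
            probs3 = ad.reshape(probs, (len(idx), 1, probs.shape[-1]))
            loss = cls_loss(probs3, Y[idx][:, None])
            val = loss.item()
            if not np.isfinite(val):
                raise DivergenceError("non-finite recognizer loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += val
            nb += 1
        history.append(tot / nb)
    recognizer.eval()
    return history
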