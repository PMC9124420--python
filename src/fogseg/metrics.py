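"""Segment-wise and sample-wise metrics and clinical FOG outcomes.

Segment-wise F1@k follows the overlap scheme standard in action
segmentation: every predicted FOG segment is compared, in temporal order,
against the same-class reference segments by intersection-over-union (IoU);
if its best IoU reaches the threshold and that reference segment is still
unmatched it counts as a true positive (and the reference is consumed),
otherwise as a false positive.  Unmatched reference segments are false
negatives and ``F1 = 100 * 2TP / (2TP + FP + FN)``.

Sample-wise agreement is summarized by the Matthews correlation coefficient
scaled to [-100, 100]; clinical severity by the percentage of time frozen
(%TF) and the number of FOG episodes (#FOG).  Episode detection additionally
counts a reference episode as detected when at least one predicted FOG
sample overlaps it, without any constraint on the amount of overlap.

Agreement between predicted and reference per-trial outcomes is assessed by
the Pearson correlation (Fisher-z 95% CI, with a strength label) and an
ordinary-least-squares regression of predictions on reference values, with
significance read from whether the slope's 95% CI excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "SegmentList", "EvalReport", "AgreementReport",
    "labels_to_segments", "segments_to_labels", "segment_iou", "segment_f1",
    "mcc", "clinical_outcomes", "episode_detection", "agreement_stats",
    "evaluate_trial", "evaluate_subject", "aggregate_reports",
    "correlation_strength",
]

FG, FOG = 0, 1
DEFAULT_THRESHOLDS = (0.10, 0.25, 0.50, 0.75)


class AlignmentError(ValueError):
    """Predicted and reference sequences do not cover the same samples."""


@dataclass
class SegmentList:
    """Run-length encoding of a label sequence: half-open (start, end, label)."""

    segments: list                # of (start, end, label)
    source_length: int

    def of_class(self, label) -> list:
        return [(s, e) for s, e, c in self.segments if c == label]

    def __len__(self):
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def labels_to_segments(labels) -> SegmentList:
    """Maximal runs of constant label; exact inverse of :func:`segments_to_labels`."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or len(labels) == 0:
        raise ValueError("labels must be a non-empty 1-D sequence")
    changes = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.r_[0, changes, len(labels)]
    segs = [(int(s), int(e), int(labels[s]))
            for s, e in zip(bounds[:-1], bounds[1:])]
    return SegmentList(segments=segs, source_length=len(labels))


def segments_to_labels(seglist: SegmentList) -> np.ndarray:
    out = np.empty(seglist.source_length, dtype=np.int64)
    for s, e, c in seglist:
        out[s:e] = c
    return out


def segment_iou(a, b) -> float:
    """IoU of two half-open sample intervals."""
    (a0, a1), (b0, b1) = a[:2], b[:2]
    if a1 <= a0 or b1 <= b0:
        raise ValueError("intervals must be non-empty half-open (start < end)")
    inter = max(0, min(a1, b1) - max(a0, b0))
    union = (a1 - a0) + (b1 - b0) - inter
    return inter / union


def _as_seglist(x) -> SegmentList:
    return x if isinstance(x, SegmentList) else labels_to_segments(x)


def segment_f1(pred, ref, threshold: float, positive_class=FOG):
    """Segment-wise F1 at one IoU threshold.

    Returns ``(f1_percent, tp, fp, fn)``.  Both-empty yields F1 = 100; if
    only one side is empty F1 = 0.
    """
    pred, ref = _as_seglist(pred), _as_seglist(ref)
    if pred.source_length != ref.source_length:
        raise AlignmentError("pred and ref cover different trial lengths")
    p_segs = pred.of_class(positive_class)
    r_segs = ref.of_class(positive_class)
    matched = [False] * len(r_segs)
    tp = fp = 0
    for seg in p_segs:
        ious = [segment_iou(seg, r) for r in r_segs]
        best = int(np.argmax(ious)) if ious else -1
        if best >= 0 and ious[best] >= threshold and not matched[best]:
            matched[best] = True
            tp += 1
        else:
            fp += 1
    fn = matched.count(False)
    denom = 2 * tp + fp + fn
    f1 = 100.0 if denom == 0 else 100.0 * 2 * tp / denom
    return f1, tp, fp, fn


def mcc(pred_labels, ref_labels) -> float:
    """Sample-wise Matthews correlation coefficient scaled to [-100, 100].

    Zero-denominator cases (e.g. a constant majority-class prediction)
    return 0 by convention.
    """
    pred = np.asarray(pred_labels)
    ref = np.asarray(ref_labels)
    if pred.shape != ref.shape:
        raise AlignmentError("pred and ref label sequences differ in length")
    tp = int(np.sum((pred == FOG) & (ref == FOG)))
    tn = int(np.sum((pred == FG) & (ref == FG)))
    fp = int(np.sum((pred == FOG) & (ref == FG)))
    fn = int(np.sum((pred == FG) & (ref == FOG)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return 100.0 * (tp * tn - fp * fn) / np.sqrt(denom)


def clinical_outcomes(labels):
    """Percentage time frozen and number of FOG episodes of a label sequence."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or len(labels) == 0:
        raise ValueError("labels must be a non-empty 1-D sequence")
    pct_tf = 100.0 * np.mean(labels == FOG)
    n_fog = len(labels_to_segments(labels).of_class(FOG))
    return pct_tf, n_fog


def episode_detection(pred, ref):
    """Overlap-based episode detection counts.

    ``tp`` = reference FOG episodes overlapped by at least one predicted FOG
    sample; ``fp`` = predicted FOG segments overlapping no reference episode.
    """
    pred, ref = _as_seglist(pred), _as_seglist(ref)
    if pred.source_length != ref.source_length:
        raise AlignmentError("pred and ref cover different trial lengths")
    p_segs = pred.of_class(FOG)
    r_segs = ref.of_class(FOG)

    def overlaps(a, b):
        return min(a[1], b[1]) > max(a[0], b[0])

    tp = sum(any(overlaps(r, p) for p in p_segs) for r in r_segs)
    fp = sum(not any(overlaps(p, r) for r in r_segs) for p in p_segs)
    return tp, fp


@dataclass
class EvalReport:
    """Per-trial (or pooled) metric report."""

    f1_at: dict                    # {threshold_percent: f1}
    mcc: float
    tp: dict
    fp: dict
    fn: dict
    pct_tf_pred: float
    pct_tf_ref: float
    n_fog_pred: int
    n_fog_ref: int
    detect_tp: int = 0
    detect_fp: int = 0
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {f"f1@{k}": v for k, v in self.f1_at.items()}
        out.update(mcc=self.mcc, pct_tf_pred=self.pct_tf_pred,
                   pct_tf_ref=self.pct_tf_ref, n_fog_pred=self.n_fog_pred,
                   n_fog_ref=self.n_fog_ref, detect_tp=self.detect_tp,
                   detect_fp=self.detect_fp, **self.meta)
        return out


def evaluate_trial(pred_labels, ref_labels,
                   thresholds=DEFAULT_THRESHOLDS) -> EvalReport:
    """All metrics for one trial's predicted vs reference label sequences."""
    pred_labels = np.asarray(pred_labels)
    ref_labels = np.asarray(ref_labels)
    if pred_labels.shape != ref_labels.shape:
        raise AlignmentError("pred and ref label sequences differ in length")
    pred = labels_to_segments(pred_labels)
    ref = labels_to_segments(ref_labels)
    f1_at, tp_d, fp_d, fn_d = {}, {}, {}, {}
    for thr in thresholds:
        key = int(round(thr * 100))
        f1, tp, fp, fn = segment_f1(pred, ref, thr)
        f1_at[key], tp_d[key], fp_d[key], fn_d[key] = f1, tp, fp, fn
    tf_p, nf_p = clinical_outcomes(pred_labels)
    tf_r, nf_r = clinical_outcomes(ref_labels)
    dtp, dfp = episode_detection(pred, ref)
    return EvalReport(f1_at=f1_at, mcc=mcc(pred_labels, ref_labels),
                      tp=tp_d, fp=fp_d, fn=fn_d,
                      pct_tf_pred=tf_p, pct_tf_ref=tf_r,
                      n_fog_pred=nf_p, n_fog_ref=nf_r,
                      detect_tp=dtp, detect_fp=dfp)


def evaluate_subject(pred_seqs, ref_seqs, thresholds=DEFAULT_THRESHOLDS,
                     pool_tf: str = "fog_trials") -> EvalReport:
    """Pool one subject's trials into a single report.

    Segment TP/FP/FN are summed across trials before F1; MCC is computed
    over the concatenated samples; #FOG sums episode counts.  %TF is pooled
    over the concatenated samples of the trials whose reference contains FOG
    (``pool_tf="fog_trials"``, mirroring the convention of reporting
    severity on FOG trials only) or over all trials (``"all"``).
    """
    if len(pred_seqs) != len(ref_seqs) or not pred_seqs:
        raise AlignmentError("need equally many (and >0) pred/ref sequences")
    f1_at, tp_d, fp_d, fn_d = {}, {}, {}, {}
    for thr in thresholds:
        key = int(round(thr * 100))
        tp = fp = fn = 0
        for p, r in zip(pred_seqs, ref_seqs):
            _, t, f, n = segment_f1(labels_to_segments(p),
                                    labels_to_segments(r), thr)
            tp, fp, fn = tp + t, fp + f, fn + n
        denom = 2 * tp + fp + fn
        f1_at[key] = 100.0 if denom == 0 else 100.0 * 2 * tp / denom
        tp_d[key], fp_d[key], fn_d[key] = tp, fp, fn
    cat_p = np.concatenate([np.asarray(p) for p in pred_seqs])
    cat_r = np.concatenate([np.asarray(r) for r in ref_seqs])
    det_tp = det_fp = n_fog_p = n_fog_r = 0
    for p, r in zip(pred_seqs, ref_seqs):
        t, f = episode_detection(labels_to_segments(p), labels_to_segments(r))
        det_tp, det_fp = det_tp + t, det_fp + f
        n_fog_p += len(labels_to_segments(p).of_class(FOG))
        n_fog_r += len(labels_to_segments(r).of_class(FOG))
    if pool_tf == "fog_trials":
        keep = [i for i, r in enumerate(ref_seqs) if np.any(np.asarray(r) == FOG)]
    else:
        keep = list(range(len(ref_seqs)))
    if keep:
        tf_p = 100.0 * np.mean(np.concatenate(
            [np.asarray(pred_seqs[i]) for i in keep]) == FOG)
        tf_r = 100.0 * np.mean(np.concatenate(
            [np.asarray(ref_seqs[i]) for i in keep]) == FOG)
    else:
        tf_p = tf_r = 0.0
    return EvalReport(f1_at=f1_at, mcc=mcc(cat_p, cat_r),
                      tp=tp_d, fp=fp_d, fn=fn_d,
                      pct_tf_pred=float(tf_p), pct_tf_ref=float(tf_r),
                      n_fog_pred=n_fog_p, n_fog_ref=n_fog_r,
                      detect_tp=det_tp, detect_fp=det_fp)


def aggregate_reports(reports) -> dict:
    """Mean and SD of each numeric metric across reports (one per subject)."""
    rows = [r.to_dict() for r in reports]
    keys = [k for k in rows[0] if isinstance(rows[0][k], (int, float))]
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in rows], dtype=float)
        out[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
                  if len(vals) > 1 else 0.0}
    return out


def subject_table(reports: dict, threshold: int = 50):
    """Per-subject summary table (one row per subject, detail-table style).

    ``reports`` maps subject id to :class:`EvalReport`.  Columns: F1@thr,
    MCC, detected/reference episode counts, false-positive detections,
    predicted/reference #FOG and %TF.
    """
    import pandas as pd

    rows = []
    for subject, r in reports.items():
        rows.append({
            "subject": subject,
            f"f1@{threshold}": r.f1_at[threshold],
            "mcc": r.mcc,
            "tp_detect": r.detect_tp,
            "fp_detect": r.detect_fp,
            "n_fog_pred": r.n_fog_pred,
            "n_fog_ref": r.n_fog_ref,
            "pct_tf_pred": r.pct_tf_pred,
            "pct_tf_ref": r.pct_tf_ref,
        })
    return pd.DataFrame(rows).set_index("subject")


# -- agreement statistics ---------------------------------------------------


def correlation_strength(r: float) -> str:
    """Strength label for a correlation: >=0.8 strong, 0.6-0.8 moderately
    strong, 0.3-0.6 fair, <0.3 poor (boundaries assigned to the upper bin)."""
    a = abs(r)
    if a >= 0.8:
        return "strong"
    if a >= 0.6:
        return "moderately strong"
    if a >= 0.3:
        return "fair"
    return "poor"


@dataclass
class AgreementReport:
    r: float
    r_ci: tuple
    slope: float
    slope_ci: tuple
    intercept: float
    intercept_ci: tuple
    strength: str
    significant: bool
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "r_ci": list(self.r_ci), "slope": self.slope,
                "slope_ci": list(self.slope_ci), "intercept": self.intercept,
                "intercept_ci": list(self.intercept_ci),
                "strength": self.strength, "significant": self.significant,
                "n": self.n}


def agreement_stats(pred_outcomes, ref_outcomes, alpha: float = 0.05) -> AgreementReport:
    """Linear agreement between predicted and reference per-trial outcomes.

    Pearson r with a Fisher-z ``1 - alpha`` CI; OLS regression of the
    predictions on the reference values with coefficient CIs; significance =
    slope CI excludes zero.  Requires at least 3 paired values.
    """
    pred = np.asarray(pred_outcomes, dtype=float)
    ref = np.asarray(ref_outcomes, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("paired 1-D outcome arrays required")
    n = len(pred)
    if n < 3:
        raise ValueError("agreement statistics require at least 3 paired trials")
    r = float(stats.pearsonr(ref, pred).statistic)
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zc = stats.norm.ppf(1 - alpha / 2)
        r_ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    else:
        r_ci = (-1.0, 1.0)
    model = sm.OLS(pred, sm.add_constant(ref)).fit()
    ci = model.conf_int(alpha=alpha)
    intercept, slope = model.params
    int_ci, slope_ci = ci[0], ci[1]
    significant = bool(slope_ci[0] > 0 or slope_ci[1] < 0)
    return AgreementReport(r=r, r_ci=r_ci, slope=float(slope),
                           slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
                           intercept=float(intercept),
                           intercept_ci=(float(int_ci[0]), float(int_ci[1])),
                           strength=correlation_strength(r),
                           significant=significant, n=n)
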