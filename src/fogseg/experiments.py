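"""Self-contained benchmark experiments on synthetic cohorts.

These are the package's reference experiments: everything is generated,
trained and evaluated at desk scale on one CPU.  The cohort and training
settings below are deliberately small — a five-subject cohort (three
freezers, two non-freezers), three 8-14 s trials per subject, and a reduced
network (2 stages, 6 layers, 16 filters) trained for 20 epochs — so the
full leave-one-subject-out protocol, the multi-stage vs single-stage
comparison and the agreement statistics run in minutes while exercising
every component end to end.  See ``docs/methods.md`` for the rationale
behind these sizes.

All randomness derives from a single seed (cohort generation, weight
initialization, batch order), so a run is exactly reproducible.
"""

from __future__ import annotations

import numpy as np

from .estimators import MSGCNSegmenter
from .losses import LossConfig
from .metrics import agreement_stats, clinical_outcomes, evaluate_subject
from .nn import MSGCN, ModelConfig
from .synth import CohortSpec, generate_cohort
from .train import audit_no_leakage, loso_folds, train, trials_to_xy

__all__ = ["BENCHMARK", "run_loso_benchmark", "run_stage_comparison",
           "run_benchmark", "overfit_two_trials"]

#: Reference desk-scale experiment settings.
BENCHMARK = {
    "n_subjects": 5,
    "trials_per_subject": 3,
    "nonfreezer_fraction": 0.4,
    "trial_duration_s": (8.0, 14.0),
    "num_stages": 2,
    "layers_per_stage": 6,
    "filters": 16,
    "epochs": 20,
    "lr": 0.02,
    "batch_size": 2,
}


def _reduced_estimator(seed: int, num_stages: int) -> MSGCNSegmenter:
    return MSGCNSegmenter(num_stages=num_stages,
                          layers_per_stage=BENCHMARK["layers_per_stage"],
                          filters=BENCHMARK["filters"],
                          lr=BENCHMARK["lr"], epochs=BENCHMARK["epochs"],
                          batch_size=BENCHMARK["batch_size"], seed=seed)


def _make_cohort(seed: int):
    spec = CohortSpec(n_subjects=BENCHMARK["n_subjects"],
                      trials_per_subject=BENCHMARK["trials_per_subject"],
                      nonfreezer_fraction=BENCHMARK["nonfreezer_fraction"],
                      trial_duration_s=BENCHMARK["trial_duration_s"],
                      seed=seed)
    trials, manifest = generate_cohort(spec)
    freezers = sorted(s for s, v in manifest["subjects"].items() if v["freezer"])
    nonfreezers = sorted(s for s, v in manifest["subjects"].items()
                         if not v["freezer"])
    return trials, freezers, nonfreezers


def _fit_fold(trials, train_ids, num_stages: int, seed: int):
    by_id = {t.trial_id: t for t in trials}
    X, y = trials_to_xy([by_id[i] for i in train_ids])
    est = _reduced_estimator(seed, num_stages)
    est.fit(X, y)
    return est


def run_loso_benchmark(seed: int = 1) -> dict:
    """Full LOSO with the reduced multi-stage model on the reference cohort.

    Returns per-subject pooled reports, headline metrics averaged over the
    freezer subjects, the false-positive audit on the held-out non-freezer
    subjects, and per-trial clinical outcomes for the agreement analysis.
    """
    ss = np.random.SeedSequence([seed, 0])
    cohort_seed, *fold_seeds = [int(s) % (2 ** 31) for s in
                                ss.generate_state(1 + BENCHMARK["n_subjects"])]
    trials, freezers, nonfreezers = _make_cohort(cohort_seed)
    plan = loso_folds(trials)
    audit_no_leakage(plan, trials)
    per_subject, per_trial = {}, []
    for (train_ids, subject), fold_seed in zip(plan.folds, fold_seeds):
        est = _fit_fold(trials, train_ids, BENCHMARK["num_stages"], fold_seed)
        eval_trials = [t for t in trials if t.subject_id == subject]
        X, y = trials_to_xy(eval_trials)
        preds = est.predict(X)
        per_subject[subject] = evaluate_subject(preds, y)
        for t, p, r in zip(eval_trials, preds, y):
            tf_p, nf_p = clinical_outcomes(p)
            tf_r, nf_r = clinical_outcomes(r)
            per_trial.append({"subject": subject, "trial": t.trial_id,
                              "pct_tf": (tf_p, tf_r),
                              "n_fog": (nf_p, nf_r),
                              "has_fog": bool(np.any(np.asarray(r) == 1))})
    f1_50 = float(np.mean([per_subject[s].f1_at[50] for s in freezers]))
    mcc_mean = float(np.mean([per_subject[s].mcc for s in freezers]))
    nonfreezer_fp = int(sum(per_subject[s].n_fog_pred for s in nonfreezers))
    return {"per_subject": per_subject, "per_trial": per_trial,
            "freezers": freezers, "nonfreezers": nonfreezers,
            "f1_at_50": f1_50, "mcc": mcc_mean,
            "nonfreezer_fp_segments": nonfreezer_fp,
            "cohort_seed": cohort_seed, "fold_seeds": fold_seeds}


def run_stage_comparison(seed: int = 1, n_seeds: int = 3) -> dict:
    """Multi-stage vs single-stage F1@50 on identical freezer folds/seeds.

    For each of ``n_seeds`` seeds both models are trained on the same folds
    with the same weight/batch seeds; reported is the median (over seeds) of
    the mean freezer-subject F1@50 for each model.
    """
    multi_scores, single_scores = [], []
    for k in range(n_seeds):
        ss = np.random.SeedSequence([seed, k])
        cohort_seed, *fold_seeds = [int(s) % (2 ** 31) for s in
                                    ss.generate_state(1 + BENCHMARK["n_subjects"])]
        trials, freezers, _ = _make_cohort(cohort_seed)
        plan = loso_folds(trials, eval_subjects=freezers)
        scores = {1: [], BENCHMARK["num_stages"]: []}
        for (train_ids, subject), fold_seed in zip(plan.folds, fold_seeds):
            eval_trials = [t for t in trials if t.subject_id == subject]
            X, y = trials_to_xy(eval_trials)
            for stages in scores:
                est = _fit_fold(trials, train_ids, stages, fold_seed)
                rep = evaluate_subject(est.predict(X), y)
                scores[stages].append(rep.f1_at[50])
        multi_scores.append(float(np.mean(scores[BENCHMARK["num_stages"]])))
        single_scores.append(float(np.mean(scores[1])))
    return {"multi_f1_at_50": float(np.median(multi_scores)),
            "single_f1_at_50": float(np.median(single_scores)),
            "multi_per_seed": multi_scores, "single_per_seed": single_scores}


def overfit_two_trials(seed: int = 1, epochs: int = 200) -> dict:
    """Memorization smoke test: the reduced model on two synthetic trials.

    Trains the reduced multi-stage model on two trials (one with FOG, one
    without) and evaluates on the training data; a healthy implementation
    drives the loss near zero and reaches segment-wise F1@50 = 100.
    """
    ss = np.random.SeedSequence([seed, 99])
    s_cohort, s_model = [int(s) % (2 ** 31) for s in ss.generate_state(2)]
    spec = CohortSpec(n_subjects=2, trials_per_subject=1,
                      nonfreezer_fraction=0.5, trial_duration_s=(10.0, 12.0),
                      seed=s_cohort)
    trials, _ = generate_cohort(spec)
    X, y = trials_to_xy(trials)
    cfg = ModelConfig(num_stages=BENCHMARK["num_stages"],
                      layers_per_stage=BENCHMARK["layers_per_stage"],
                      filters=BENCHMARK["filters"])
    model = MSGCN(cfg, rng=s_model)
    history = train(model, X, y, LossConfig(), lr=BENCHMARK["lr"],
                    epochs=epochs, batch_size=16, seed=s_model)
    preds = [model.predict(x) for x in X]
    rep = evaluate_subject(preds, y)
    return {"final_loss": history[-1], "train_f1_at_50": rep.f1_at[50],
            "train_mcc": rep.mcc, "history": history}


def run_benchmark(seed: int = 1) -> dict:
    """LOSO benchmark + stage comparison + clinical-outcome agreement."""
    loso = run_loso_benchmark(seed)
    comparison = run_stage_comparison(seed, n_seeds=3)
    fog_rows = [r for r in loso["per_trial"] if r["has_fog"]]
    tf_pred = [r["pct_tf"][0] for r in fog_rows]
    tf_ref = [r["pct_tf"][1] for r in fog_rows]
    nf_pred = [r["n_fog"][0] for r in fog_rows]
    nf_ref = [r["n_fog"][1] for r in fog_rows]
    agreement = {
        "pct_tf": agreement_stats(tf_pred, tf_ref),
        "n_fog": agreement_stats(nf_pred, nf_ref),
    }
    return {"loso": loso, "comparison": comparison, "agreement": agreement}
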