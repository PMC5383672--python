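"""Pairwise MVPA: leave-one-run-out linear SVM scored by classification d'.

Block patterns are z-scored across voxels (removing mean-amplitude
differences between blocks), then a linear soft-margin SVM is trained on
nine of the ten runs and tested on the held-out run, for every run in turn.
One condition is designated "signal": a hit is a correct prediction on a
signal block and a false alarm an incorrect prediction on a noise block,
and the yes/no d' is computed per fold with a loglinear extreme-rate
correction (perfect folds are common with ~3 blocks per class) and averaged
over folds. Group significance uses a bootstrap-T: classification is re-run
with labels reshuffled within subject and run, and the observed one-sample
t of d' across subjects is compared to the null t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .behavior import DetectionOutcome, dprime
from .synthetic_data import PatternData

__all__ = [
    "PatternData",
    "FoldPrediction",
    "BootstrapTResult",
    "znorm_patterns",
    "loro_classify",
    "classification_dprime",
    "subject_dprime",
    "bootstrap_t_test",
]


@dataclass
class FoldPrediction:
    run: int
    true: np.ndarray
    predicted: np.ndarray


@dataclass
class BootstrapTResult:
    t_obs: float
    p_value: float
    subject_dprimes: np.ndarray
    mean_dprime: float
    n_repetitions: int
    seed: int
    t_null: Optional[np.ndarray] = None


def znorm_patterns(dataset: PatternData) -> PatternData:
    """z-score each block's pattern across voxels (mean 0, sd 1)."""
    X = np.asarray(dataset.X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 voxels to z-score across voxels")
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.where(sd.ravel() == 0)[0]
        raise ValueError(f"constant pattern in block(s) {bad.tolist()}; cannot z-score")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    return replace(dataset, X=Z)


def loro_classify(
    dataset: PatternData,
    cond_a: str,
    cond_b: str,
    c: float = 1.0,
) -> list[FoldPrediction]:
    """Leave-one-run-out linear SVM predictions for a condition pair."""
    conds = np.asarray(dataset.conditions)
    runs = np.asarray(dataset.runs)
    sel = np.isin(conds, [cond_a, cond_b])
    X, yc, rr = dataset.X[sel], conds[sel], runs[sel]
    folds = []
    for r in np.unique(rr):
        test = rr == r
        train = ~test
        for cond in (cond_a, cond_b):
            if not np.any(yc[test] == cond):
                raise ValueError(f"run {r} has no {cond!r} blocks")
            if not np.any(yc[train] == cond):
                raise ValueError(f"training folds for run {r} miss condition {cond!r}")
        clf = SVC(kernel="linear", C=c)
        clf.fit(X[train], yc[train])
        folds.append(FoldPrediction(run=int(r), true=yc[test], predicted=clf.predict(X[test])))
    return folds


def classification_dprime(
    predictions: Sequence[FoldPrediction],
    signal_condition: str,
    correction_policy: str = "loglinear",
) -> float:
    """Per-subject classification d': mean over folds of the yes/no d'.

    Within a fold, hits are correct predictions on signal-condition blocks
    and false alarms incorrect predictions on noise-condition blocks.
    """
    fold_ds = []
    for fold in predictions:
        sig = fold.true == signal_condition
        noi = ~sig
        if not (sig.any() and noi.any()):
            raise ValueError(f"fold for run {fold.run} lacks signal or noise blocks")
        hits = int((fold.predicted[sig] == signal_condition).sum())
        fas = int((fold.predicted[noi] == signal_condition).sum())
        out = DetectionOutcome(
            hits=hits, n_signal=int(sig.sum()), false_alarms=fas, n_noise=int(noi.sum())
        )
        fold_ds.append(dprime(out, extreme_rate_policy=correction_policy).d_prime)
    return float(np.mean(fold_ds))


def subject_dprime(
    dataset: PatternData,
    cond_a: str,
    cond_b: str,
    signal_condition: Optional[str] = None,
    c: float = 1.0,
    correction_policy: str = "loglinear",
) -> float:
    """Convenience: z-normalize, classify, and score one subject."""
    ds = znorm_patterns(dataset)
    folds = loro_classify(ds, cond_a, cond_b, c=c)
    return classification_dprime(folds, signal_condition or cond_a, correction_policy)


def _shuffled_labels(
    dataset: PatternData, cond_a: str, cond_b: str, rng: np.random.Generator
) -> PatternData:
    """Reshuffle the two conditions' labels within each run."""
    conds = np.asarray(dataset.conditions).copy()
    runs = np.asarray(dataset.runs)
    sel = np.isin(conds, [cond_a, cond_b])
    for r in np.unique(runs):
        idx = np.where(sel & (runs == r))[0]
        conds[idx] = conds[idx][rng.permutation(len(idx))]
    return replace(dataset, conditions=conds)


def _group_t(dprimes: np.ndarray) -> float:
    d = np.asarray(dprimes, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:  # degenerate: identical d' across subjects (e.g., all folds perfect)
        return float(np.sign(d.mean()) * np.inf) if d.mean() != 0 else 0.0
    return float(d.mean() / (sd / np.sqrt(d.size)))


def bootstrap_t_test(
    datasets: Sequence[PatternData],
    cond_a: str,
    cond_b: str,
    n_repetitions: int = 10000,
    seed: Optional[int] = None,
    signal_condition: Optional[str] = None,
    c: float = 1.0,
    correction_policy: str = "loglinear",
) -> BootstrapTResult:
    """Group-level significance of classification d' by bootstrap-T.

    Per repetition, condition labels are reshuffled within subject and run,
    the full leave-one-run-out classification re-run, per-subject d'
    recomputed, and a one-sample t of d' against 0 formed across subjects.
    p = P(t_null > t_obs) with the add-one convention.
    """
    if seed is None:
        raise ValueError("a seed is required for the bootstrap (reproducibility)")
    if len(datasets) < 2:
        raise ValueError("need at least 2 subjects")
    sig = signal_condition or cond_a

    obs = np.array([subject_dprime(d, cond_a, cond_b, sig, c, correction_policy)
                    for d in datasets])
    t_obs = _group_t(obs)

    rng = np.random.default_rng(seed)
    t_null = np.empty(n_repetitions)
    for k in range(n_repetitions):
        ds = [
            subject_dprime(_shuffled_labels(d, cond_a, cond_b, rng),
                           cond_a, cond_b, sig, c, correction_policy)
            for d in datasets
        ]
        t_null[k] = _group_t(np.asarray(ds))
    p = (float((t_null > t_obs).sum()) + 1) / (n_repetitions + 1)
    return BootstrapTResult(
        t_obs=t_obs,
        p_value=p,
        subject_dprimes=obs,
        mean_dprime=float(obs.mean()),
        n_repetitions=n_repetitions,
        seed=seed,
        t_null=t_null,
    )
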