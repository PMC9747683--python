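"""Discrimination and calibration metrics, data partitions, evaluation.

Metrics
-------
* AUC — rank-based (Mann-Whitney) probability that a random presence
  outscores a random background cell; ties count one half.
* OR10 — omission rate of test presences at the threshold excluding the
  lowest 10% of training presence scores. The threshold is the
  ``(floor(0.1 * n_train) + 1)``-th smallest training score; omission is
  the fraction of test scores strictly below it.
* CBI — continuous Boyce index: Spearman correlation between the
  presence-to-background ratio in moving suitability windows and the
  window centers.
* AICc — small-sample information criterion with the count of nonzero
  coefficients as the parameter count, computed from raw-output presence
  likelihoods normalized over the full background.

Partitions
----------
random 75/25 split, 4-fold spatial block (median longitude/latitude
quadrants), leave-one-out jackknife, and bootstrap replicates (train on
a with-replacement resample, test out-of-bag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .features import build_features
from .model import MaxentModel, fit_maxent


def compute_auc(presence_scores, background_scores) -> float:
    """Rank-based AUC of presences against background; ties count 0.5."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("AUC needs nonempty score vectors")
    ranks = stats.rankdata(np.concatenate([p, b]))
    rp = ranks[: p.size].sum()
    return float((rp - p.size * (p.size + 1) / 2) / (p.size * b.size))


def or10_threshold(train_presence_scores) -> float:
    """The (floor(0.1 n) + 1)-th smallest training presence score."""
    t = np.sort(np.asarray(train_presence_scores, dtype=float))
    if t.size == 0:
        raise ValueError("OR10 needs at least one training score")
    return float(t[int(np.floor(0.1 * t.size))])


def compute_or10(train_presence_scores, test_presence_scores) -> float:
    """Fraction of test presence scores strictly below the OR10 threshold."""
    tau = or10_threshold(train_presence_scores)
    test = np.asarray(test_presence_scores, dtype=float)
    if test.size == 0:
        raise ValueError("OR10 needs at least one test score")
    return float(np.mean(test < tau))


def compute_cbi(test_presence_scores, background_scores,
                n_windows: int = 101, window_width: float = 0.1) -> float:
    """Continuous Boyce index over moving suitability windows in [0, 1]."""
    p = np.asarray(test_presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    centers = np.linspace(0.0, 1.0, n_windows)
    half = window_width / 2.0
    P = np.empty(n_windows)
    E = np.empty(n_windows)
    for i, c in enumerate(centers):
        lo, hi = c - half, c + half
        P[i] = np.mean((p >= lo) & (p <= hi))
        E[i] = np.mean((b >= lo) & (b <= hi))
    ok = E > 0
    if ok.sum() < 2:
        raise ValueError("CBI needs at least 2 windows with background mass")
    ratio = P[ok] / E[ok]
    with warnings.catch_warnings():
        # a constant ratio vector has no defined rank correlation; the NaN
        # result is handled (skipped) by callers
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(ratio, centers[ok]).statistic
    return float(rho)


def compute_aicc(model: MaxentModel, presence_env: Mapping[str, np.ndarray],
                 background_env: Mapping[str, np.ndarray]) -> float:
    """AICc from presence log-likelihoods under the background-normalized raw.

    Returns NaN (undefined) when k >= n - 1; such parameter combinations
    are disqualified from model selection.
    """
    from .features import evaluate_features

    n = len(np.asarray(presence_env[next(iter(presence_env))]))
    k = model.k
    if k >= n - 1:
        return float("nan")
    Xp = evaluate_features(model.features, presence_env)
    Xb = evaluate_features(model.features, background_env)
    eta_p = Xp @ model.beta
    eta_b = Xb @ model.beta
    # log of raw normalized to sum to 1 over the background
    log_norm = logsumexp(eta_b)
    lnL = float(np.sum(eta_p - log_norm))
    return 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class Partition:
    """Fold assignment of presences for cross-validation.

    ``folds[i]`` is the fold of presence i; evaluation trains on the
    complement of each fold and tests on the fold. For
    ``bootstrap_replicate`` the replicates are stored explicitly as
    (train indices, test indices) pairs.
    """

    scheme: str
    folds: np.ndarray | None
    seed: int
    train_fraction: float = 0.75
    replicates: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def splits(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train_idx, test_idx) pairs."""
        if self.scheme == "bootstrap_replicate":
            return list(self.replicates)
        n = self.folds.size
        out = []
        for f in np.unique(self.folds):
            test = np.nonzero(self.folds == f)[0]
            train = np.nonzero(self.folds != f)[0]
            if train.size and test.size:
                out.append((train, test))
        return out


def make_partition(lons, lats, scheme: str, seed: int = 0,
                   train_fraction: float = 0.75, n_replicates: int = 10) -> Partition:
    """Build a presence partition.

    * ``random_split`` — one seeded 75/25 split (fold 1 = test).
    * ``block`` — 4 spatial folds at the median longitude and latitude
      (points exactly on a median go to the west/south side).
    * ``jackknife`` — n leave-one-out folds (the small-sample scheme).
    * ``bootstrap_replicate`` — *n_replicates* with-replacement resamples
      of size n for training, out-of-bag points for testing.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    n = lons.size
    rng = np.random.default_rng(seed)
    if scheme == "random_split":
        n_test = max(1, int(round(n * (1 - train_fraction))))
        folds = np.zeros(n, dtype=int)
        folds[rng.choice(n, size=n_test, replace=False)] = 1
        return Partition(scheme, folds, seed, train_fraction)
    if scheme == "block":
        if n < 4:
            raise ValueError("block partition needs at least 4 presences")
        mlon, mlat = np.median(lons), np.median(lats)
        west = lons <= mlon
        south = lats <= mlat
        folds = np.where(west, 0, 1) + 2 * np.where(south, 0, 1)
        return Partition(scheme, folds, seed)
    if scheme == "jackknife":
        return Partition(scheme, np.arange(n), seed)
    if scheme == "bootstrap_replicate":
        reps = []
        for _ in range(n_replicates):
            train = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), train)
            if oob.size == 0:
                oob = np.array([int(rng.integers(0, n))])
            reps.append((train, oob))
        return Partition(scheme, None, seed, replicates=reps)
    raise ValueError(f"unknown partition scheme: {scheme}")


@dataclass
class EvaluationReport:
    """The tuning currency: discrimination, calibration, complexity."""

    auc_train: float
    auc_test: float
    auc_diff: float
    or10: float
    cbi: float
    aicc: float
    k: int
    delta_aicc: float = float("nan")
    n_folds: int = 0

    def as_dict(self) -> dict:
        return {
            "auc_train": self.auc_train, "auc_test": self.auc_test,
            "auc_diff": self.auc_diff, "or10": self.or10, "cbi": self.cbi,
            "aicc": self.aicc, "delta_aicc": self.delta_aicc, "k": self.k,
            "n_folds": self.n_folds,
        }


def evaluate(presence_env: Mapping[str, np.ndarray],
             background_env: Mapping[str, np.ndarray],
             fc: str, rm: float, partition: Partition,
             transform: str = "cloglog", **fit_kw) -> EvaluationReport:
    """Cross-validated evaluation of one (rm, fc) parameter combination.

    Per fold: fit on training presences, score held-out presences and the
    background, compute AUC/OR10/CBI; metrics average over folds with
    equal weight (folds where a metric is undefined are skipped for that
    metric). AICc comes from a full-data fit.
    """
    names = list(background_env)
    pres = {k: np.asarray(v, float) for k, v in presence_env.items()}
    bg = {k: np.asarray(v, float) for k, v in background_env.items()}

    auc_tr, auc_te, or10s, cbis = [], [], [], []
    for train, test in partition.splits():
        p_tr = {k: v[train] for k, v in pres.items()}
        p_te = {k: v[test] for k, v in pres.items()}
        model, _ = fit_maxent(p_tr, bg, rm=rm, fc=fc,
                              output_transform=transform, **fit_kw)
        s_tr = model.predict_env(p_tr, transform)
        s_te = model.predict_env(p_te, transform)
        s_bg = model.predict_env(bg, transform)
        auc_tr.append(compute_auc(s_tr, s_bg))
        auc_te.append(compute_auc(s_te, s_bg))
        or10s.append(compute_or10(s_tr, s_te))
        try:
            cbis.append(compute_cbi(s_te, s_bg))
        except ValueError:
            pass
        cbis = [c for c in cbis if np.isfinite(c)]

    full_model, _ = fit_maxent(pres, bg, rm=rm, fc=fc,
                               output_transform=transform, **fit_kw)
    aicc = compute_aicc(full_model, pres, bg)
    a_tr = float(np.mean(auc_tr))
    a_te = float(np.mean(auc_te))
    return EvaluationReport(
        auc_train=a_tr, auc_test=a_te, auc_diff=a_tr - a_te,
        or10=float(np.mean(or10s)),
        cbi=float(np.mean(cbis)) if cbis else float("nan"),
        aicc=aicc, k=full_model.k, n_folds=len(auc_te),
    )
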