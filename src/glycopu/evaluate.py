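"""Metrics, the randomization / cross-validation protocols, baselines.

The benchmark protocol draws as many unlabelled as positive samples, splits
50/20/30 (stratified on the PU label), estimates the class prior on the
validation split, retrains on train+validation ("trainingV") and evaluates
on the held-out test split; metrics are aggregated mean +/- SD over
repeats. Baseline learners (RF / SVM / one-class SVM) are thin adapters
over scikit-learn and are optional: the PU pipeline never imports them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import prior as prior_mod
from . import pubayes
from .preprocess import PUDataset, fit_discretizer, mrmr_select

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        return np.array([1 if str(v) == "positive" else 0 for v in arr])
    return arr.astype(int)


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Counts by definition; labels may be 0/1 or 'positive'/'negative'."""
    t = _as_binary(labels_true)
    p = _as_binary(labels_pred)
    if t.size != p.size:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        TP=int(((t == 1) & (p == 1)).sum()),
        TN=int(((t == 0) & (p == 0)).sum()),
        FP=int(((t == 0) & (p == 1)).sum()),
        FN=int(((t == 1) & (p == 0)).sum()),
    )


def f1_acc(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(F1, ACC, Precision, Recall); 0/0 denominators yield 0 with a log."""
    if c.TP + c.FP == 0:
        logger.info("precision denominator 0, flagged as 0")
        precision = 0.0
    else:
        precision = c.TP / (c.TP + c.FP)
    recall = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    acc = (c.TP + c.TN) / c.total if c.total else 0.0
    return f1, acc, precision, recall


def auc(scores, labels_true) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    y = _as_binary(labels_true)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores, labels_true) -> np.ndarray:
    """(FPR, TPR) pairs at every distinct threshold, for plotting/export."""
    y = _as_binary(labels_true)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    keep = np.r_[np.flatnonzero(np.diff(s)), y.size - 1]
    tpr = tp[keep] / max(tp[-1], 1)
    fpr = fp[keep] / max(fp[-1], 1)
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


def write_roc_tsv(path, scores, labels_true) -> None:
    """ROC curve points as a two-column TSV (FPR, TPR) for plotting."""
    pts = roc_points(scores, labels_true)
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in pts:
            fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")


@dataclass
class EvalReport:
    """Per-repeat metrics with mean +/- SD aggregation."""

    metrics: dict  # learner -> {"F1": [..], "ACC": [..], "AUC": [..]}
    protocol: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {}
        for learner, per in self.metrics.items():
            out[learner] = {}
            for name, vals in per.items():
                v = np.asarray(vals, dtype=float)
                out[learner][name] = {"mean": float(v.mean()),
                                      "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0}
        return out

    def format_table(self) -> str:
        lines = ["learner\t" + "\t".join(["F1", "ACC", "AUC"])]
        s = self.summary()
        for learner, per in s.items():
            cells = [f"{per[m]['mean']:.3f} ± {per[m]['sd']:.3f}"
                     for m in ("F1", "ACC", "AUC")]
            lines.append(learner + "\t" + "\t".join(cells))
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({"metrics": self.metrics, "protocol": self.protocol,
                           "summary": self.summary()}, indent=2)


@dataclass
class PULearnerSpec:
    """A PU Bayesian learner plus its prior-estimation recipe.

    ``prior_method``: 'alphamax' (PA2DE V2.0 when family=pande/n=2),
    'elkan-noto' (plain PA2DE), or 'fixed' with ``fixed_alpha``.
    """

    family: str = "pande"
    n: int = 2
    prior_method: str = "alphamax"
    fixed_alpha: float | None = None
    m_smoothing: float = 1.0

    def estimate_prior(self, train: PUDataset, validation: PUDataset | None,
                       seed: int) -> prior_mod.PriorEstimate:
        if self.prior_method == "fixed":
            if self.fixed_alpha is None:
                raise ValueError("fixed prior requires fixed_alpha")
            n_pos = train.s.sum() + (validation.s.sum() if validation else 0)
            n_all = train.n + (validation.n if validation else 0)
            return prior_mod.fixed_prior(self.fixed_alpha, n_pos / n_all)
        if validation is None:
            raise ValueError(f"{self.prior_method} needs a validation split")
        scorer = prior_mod.fit_nontraditional_scorer(train, seed)
        scores = prior_mod.score_set(scorer, validation)
        frac = (train.s.sum() + validation.s.sum()) / (train.n + validation.n)
        if self.prior_method == "elkan-noto":
            return prior_mod.elkan_noto_estimate(scores, frac)
        if self.prior_method == "alphamax":
            # stratified splits keep the validation composition dataset-wide
            return prior_mod.alphamax_estimate(scores)
        raise ValueError(f"unknown prior_method {self.prior_method!r}")

    def fit_predict(self, train: PUDataset, validation: PUDataset | None,
                    test, seed: int):
        est = self.estimate_prior(train, validation, seed)
        merged = _concat(train, validation) if validation is not None else train
        model = pubayes.fit(merged, family=self.family, n=self.n, prior=est,
                            m_smoothing=self.m_smoothing)
        preds, scores = pubayes.predict_batch(model, test.X)
        return scores, [p.label for p in preds], est


def _concat(a: PUDataset, b: PUDataset) -> PUDataset:
    return PUDataset(np.vstack([a.X, b.X]), np.r_[a.s, b.s],
                     list(a.feature_names), list(a.keys) + list(b.keys))


def _stratified_split(s: np.ndarray, fractions, rng) -> list[np.ndarray]:
    """Index sets with each label split in the given proportions."""
    parts = [[] for _ in fractions]
    for value in np.unique(s):
        idx = np.flatnonzero(s == value)
        rng.shuffle(idx)
        bounds = np.cumsum([int(round(f * idx.size)) for f in fractions[:-1]])
        for part, chunk in zip(parts, np.split(idx, bounds)):
            part.append(chunk)
    return [np.sort(np.concatenate(p)) for p in parts]


def _metric_update(store, learner, y_true, scores, labels):
    f1, acc_, _, _ = f1_acc(confusion(y_true, labels))
    store.setdefault(learner, {"F1": [], "ACC": [], "AUC": []})
    store[learner]["F1"].append(f1)
    store[learner]["ACC"].append(acc_)
    y = _as_binary(y_true)
    if 0 < y.sum() < y.size:  # AUC undefined on single-class folds
        store[learner]["AUC"].append(auc(scores, y_true))


def randomization_protocol(features, positive_keys, unlabelled_pool,
                           learners: dict, n_repeats: int = 100,
                           seed: int = 0, n_bins: int = 5,
                           mrmr_k: int | None = None) -> EvalReport:
    """The 100x benchmark protocol on a continuous feature table.

    ``features`` is a DataFrame indexed by site key; per repeat, |P|
    unlabelled keys are drawn from the pool, the rows are split 50/20/30
    stratified on the PU label, discretization (and optional mRMR with the
    label as target) is fit on the training split only, the prior is
    estimated on validation, and the learner retrained on trainingV is
    evaluated on the test split.
    """
    positive_keys = list(positive_keys)
    unlabelled_pool = list(unlabelled_pool)
    if len(unlabelled_pool) < len(positive_keys):
        raise ValueError("unlabelled pool smaller than the positive set")
    rng = np.random.default_rng(seed)
    store: dict = {}
    for rep in range(n_repeats):
        take = rng.choice(len(unlabelled_pool), size=len(positive_keys),
                          replace=False)
        unl_keys = [unlabelled_pool[i] for i in sorted(take)]
        keys = positive_keys + unl_keys
        frame = features.loc[keys]
        s = np.r_[np.ones(len(positive_keys), dtype=int),
                  np.zeros(len(unl_keys), dtype=int)]
        tr, va, te = _stratified_split(s, (0.5, 0.2, 0.3), rng)
        disc = fit_discretizer(frame.iloc[tr], n_bins=n_bins)
        dmat = disc.transform(frame)
        if mrmr_k is not None:
            train_ds = PUDataset(dmat.iloc[tr].to_numpy(dtype=np.int64), s[tr],
                                 list(frame.columns), [keys[i] for i in tr])
            chosen = [fr.feature for fr in mrmr_select(train_ds, mrmr_k)]
            dmat = dmat[chosen]
        X = dmat.to_numpy(dtype=np.int64)
        names = list(dmat.columns)
        mk = lambda idx: PUDataset(X[idx], s[idx], names, [keys[i] for i in idx])
        train, val, test = mk(tr), mk(va), mk(te)
        rep_seed = int(rng.integers(2**31 - 1))
        for lname, learner in learners.items():
            if isinstance(learner, PULearnerSpec):
                scores, labels, _ = learner.fit_predict(train, val, test, rep_seed)
            else:
                scores, labels = learner(_concat(train, val), test)
            _metric_update(store, lname, test.s, scores, labels)
    return EvalReport(store, {"n_repeats": n_repeats, "seed": seed,
                              "split": [0.5, 0.2, 0.3], "n_bins": n_bins,
                              "mrmr_k": mrmr_k})


def cross_validation(dataset: PUDataset, learner, k_folds: int = 5,
                     seed: int = 0) -> EvalReport:
    """Stratified k-fold on the PU label; per-fold metrics, mean reported.

    For PU learners the training folds are further split 80/20 so the prior
    can be estimated on held-out scores before the trainingV retrain. A
    training fold without positives is an error; test folds with a single
    class get F1/ACC but no AUC.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k_folds)]
    for value in np.unique(dataset.s):
        idx = np.flatnonzero(dataset.s == value)
        rng.shuffle(idx)
        for i, chunk in enumerate(np.array_split(idx, k_folds)):
            folds[i].append(chunk)
    folds = [np.sort(np.concatenate(f)) for f in folds]
    store: dict = {}
    name = getattr(learner, "family", "learner")
    for i, test_idx in enumerate(folds):
        train_idx = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != i]))
        # plain container: a test fold may legitimately hold no positives,
        # which the PUDataset invariant forbids
        from types import SimpleNamespace

        test = SimpleNamespace(X=dataset.X[test_idx], s=dataset.s[test_idx],
                               feature_names=list(dataset.feature_names),
                               keys=[dataset.keys[j] for j in test_idx],
                               n=len(test_idx))
        if dataset.s[train_idx].sum() == 0:
            raise ValueError(f"training fold {i} has no positives")
        rep_seed = int(rng.integers(2**31 - 1))
        if isinstance(learner, PULearnerSpec):
            if learner.prior_method == "fixed":
                scores, labels, _ = learner.fit_predict(
                    dataset.subset(train_idx), None, test, rep_seed)
            else:
                tr, va = _stratified_split(dataset.s[train_idx], (0.8, 0.2), rng)
                scores, labels, _ = learner.fit_predict(
                    dataset.subset(train_idx[tr]), dataset.subset(train_idx[va]),
                    test, rep_seed)
        else:
            scores, labels = learner(dataset.subset(train_idx), test)
        _metric_update(store, name, test.s, scores, labels)
    return EvalReport(store, {"k_folds": k_folds, "seed": seed})


def paired_ttest(metric_a, metric_b) -> float:
    """Two-sided paired Student's t-test p-value over repeat metrics."""
    res = stats.ttest_rel(np.asarray(metric_a, dtype=float),
                          np.asarray(metric_b, dtype=float))
    return float(res.pvalue)


def baseline_adapter(name: str, train: PUDataset, test: PUDataset,
                     seed: int = 0):
    """RF / SVM / one-class-SVM baselines treating s as the class label.

    Returns (scores, labels). The one-class SVM trains on positives only
    and its rejected ('?') outputs are mapped to negative. Raises a clear
    ImportError when scikit-learn is unavailable; the PU core never needs
    it.
    """
    try:
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.svm import SVC, OneClassSVM
    except ImportError as exc:  # pragma: no cover - env contract
        raise ImportError(
            "baseline adapters need scikit-learn (pip install glycopu[baselines])"
        ) from exc
    Xtr, Xte = train.X.astype(float), test.X.astype(float)
    if name == "rf":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
        clf.fit(Xtr, train.s)
        scores = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
        labels = ["positive" if p >= 0.5 else "negative" for p in scores]
    elif name == "svm":
        clf = SVC(random_state=seed)
        clf.fit(Xtr, train.s)
        raw = clf.decision_function(Xte)
        scores = 1.0 / (1.0 + np.exp(-raw))
        labels = ["positive" if v == 1 else "negative" for v in clf.predict(Xte)]
    elif name == "one-class-svm":
        clf = OneClassSVM(gamma="scale")
        clf.fit(Xtr[train.s == 1])
        raw = clf.decision_function(Xte)
        scores = 1.0 / (1.0 + np.exp(-raw))
        labels = ["positive" if v == 1 else "negative" for v in clf.predict(Xte)]
    else:
        raise ValueError(f"unknown baseline {name!r}")
    return np.asarray(scores, dtype=float), labels
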