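"""Class-prior (mixture proportion) estimation from PU data.

Two estimators over held-out validation scores of a "nontraditional"
classifier g(x) ~ P(s=1|x):

* Elkan-Noto: the labelling frequency c is the mean score over labelled
  positives (the e1 estimator); alpha = labelled fraction / c.
* AlphaMax: a two-component mixture on the 1-D score scale. Unlabelled
  scores are modelled as alpha* f1 + (1 - alpha*) f0 with f1 fixed from the
  labelled-positive score histogram and f0 free (per-bin, nonnegative,
  normalized); the profile log-likelihood over an alpha grid is maximized
  exactly per grid point by KKT water-filling, and the estimate is the
  largest alpha at which the curve is still statistically on its plateau.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import PUDataset

logger = logging.getLogger(__name__)

PRIOR_FLOOR = 1e-4


@dataclass
class ScoreSet:
    scores_labelled: np.ndarray
    scores_unlabelled: np.ndarray

    def __post_init__(self):
        self.scores_labelled = np.asarray(self.scores_labelled, dtype=float)
        self.scores_unlabelled = np.asarray(self.scores_unlabelled, dtype=float)
        for name, arr in (("labelled", self.scores_labelled),
                          ("unlabelled", self.scores_unlabelled)):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{name} scores must lie in [0, 1]")

    @property
    def frac_labelled(self) -> float:
        n = self.scores_labelled.size + self.scores_unlabelled.size
        return self.scores_labelled.size / n


@dataclass
class PriorEstimate:
    method: str  # fixed | elkan-noto | alphamax
    alpha: float
    c: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not 0 < self.c <= 1:
            raise ValueError(f"c must lie in (0, 1], got {self.c}")

    def to_json(self) -> str:
        d = {"method": self.method, "alpha": self.alpha, "c": self.c,
             "diagnostics": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                             for k, v in self.diagnostics.items()}}
        return json.dumps(d, indent=2)

    @staticmethod
    def from_json(text: str) -> "PriorEstimate":
        d = json.loads(text)
        return PriorEstimate(d["method"], d["alpha"], d["c"], d.get("diagnostics", {}))


def fixed_prior(alpha: float, frac_labelled: float | None = None,
                floor: float = PRIOR_FLOOR) -> PriorEstimate:
    alpha = _apply_floor(alpha, floor)
    c = 1.0 if frac_labelled is None else min(1.0, max(frac_labelled / alpha, 1e-12))
    return PriorEstimate("fixed", alpha, c)


def _apply_floor(alpha: float, floor: float = PRIOR_FLOOR) -> float:
    if alpha < floor:
        logger.warning("prior %.3g below floor, clamped to %.0e", alpha, floor)
        return floor
    return min(alpha, 1.0)


def _platt_fit(z: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Damped Newton fit of P(s=1|z) = sigmoid(a*z + b) on scaled log-odds."""
    from scipy.special import expit

    scale = max(float(np.abs(z).std()), 1e-12)
    zs = z / scale
    a, b = 1.0, 0.0
    for _ in range(200):
        p = np.clip(expit(a * zs + b), 1e-12, 1 - 1e-12)
        grad = np.array([((p - s) * zs).sum(), (p - s).sum()])
        w = np.maximum(p * (1 - p), 1e-12)
        hess = np.array([[(w * zs * zs).sum(), (w * zs).sum()],
                         [(w * zs).sum(), w.sum()]]) + np.eye(2) * 1e-9
        step = np.linalg.solve(hess, grad)
        while np.abs(step).max() > 2:
            step = step / 2
        a, b = a - step[0], b - step[1]
        if np.abs(step).max() < 1e-10:
            break
    return a / scale, b


class NaiveBayesScorer:
    """Naive Bayes of the PU label s against discrete attributes.

    m-estimate smoothing (m=1, uniform base). Raw naive-Bayes posteriors
    are overconfident when attributes are dependent (the unlabelled class
    is a mixture), which directly biases the Elkan-Noto c estimator, so
    scores are Platt-calibrated on the training log-odds by default.
    """

    def __init__(self, m_smoothing: float = 1.0, calibrate: bool = True):
        self.m = m_smoothing
        self.calibrate = calibrate
        self._fitted = False

    def fit(self, dataset: PUDataset) -> "NaiveBayesScorer":
        s = dataset.s
        if s.min() == s.max():
            raise ValueError("scorer needs both labelled and unlabelled rows")
        X = dataset.X
        self.arities = dataset.arities()
        self.k = dataset.k
        n1 = int(s.sum())
        n0 = int(s.size - n1)
        self.log_prior = np.log([n0 / s.size, n1 / s.size])
        self.tables = []
        for j in range(self.k):
            v = int(self.arities[j])
            tab = np.empty((2, v))
            for cls in (0, 1):
                counts = np.bincount(X[s == cls, j] - 1, minlength=v).astype(float)
                tab[cls] = (counts + self.m / v) / (counts.sum() + self.m)
            self.tables.append(np.log(tab))
        if self.calibrate:
            self._platt = _platt_fit(self._log_odds(X), s.astype(float))
        self._fitted = True
        return self

    def _log_odds(self, X) -> np.ndarray:
        X = np.asarray(X)
        n = X.shape[0]
        log_s = np.tile(self.log_prior, (n, 1))
        for j in range(self.k):
            col = np.clip(X[:, j] - 1, 0, self.arities[j] - 1)
            log_s += self.tables[j][:, col].T
        return log_s[:, 1] - log_s[:, 0]

    def score(self, X) -> np.ndarray:
        from scipy.special import expit

        if not self._fitted:
            raise RuntimeError("scorer not fitted")
        z = self._log_odds(X)
        if self.calibrate:
            a, b = self._platt
            return expit(a * z + b)
        return expit(z)


def fit_nontraditional_scorer(train: PUDataset, seed: int = 0) -> NaiveBayesScorer:
    """Probabilistic classifier of s vs features (deterministic; seed kept
    for interface symmetry with stochastic scorers)."""
    return NaiveBayesScorer().fit(train)


def score_set(scorer, dataset: PUDataset) -> ScoreSet:
    scores = scorer.score(dataset.X)
    return ScoreSet(scores[dataset.s == 1], scores[dataset.s == 0])


def elkan_noto_estimate(scores: ScoreSet, frac_labelled: float | None = None,
                        floor: float = PRIOR_FLOOR) -> PriorEstimate:
    """The e1 estimator: c = mean validation score of labelled positives."""
    if scores.scores_labelled.size == 0:
        raise ValueError("no labelled scores")
    c = float(scores.scores_labelled.mean())
    if c <= 0:
        raise ValueError("estimated labelling frequency is zero")
    if frac_labelled is None:
        frac_labelled = scores.frac_labelled
    alpha = _apply_floor(min(frac_labelled / c, 1.0), floor)
    return PriorEstimate("elkan-noto", alpha, min(c, 1.0),
                         {"frac_labelled": frac_labelled})


def _waterfill_loglik(n_u_bins: np.ndarray, p1: np.ndarray, alpha: float) -> float:
    """max_{f0 in simplex} sum_j n_j log(alpha p1_j + (1-alpha) f0_j).

    KKT: active bins satisfy f0_j = n_j/lam - alpha p1_j/(1-alpha); lam is
    found by bisection on the monotone constraint sum f0_j = 1.
    """
    n = n_u_bins.astype(float)
    if alpha >= 1.0:
        with np.errstate(divide="ignore"):
            lp = np.where(n > 0, np.log(p1), 0.0)
        return float((n * lp).sum())
    shift = alpha * p1 / (1.0 - alpha)

    def excess(lam):
        return np.maximum(0.0, n / lam - shift).sum() - 1.0

    lo, hi = 1e-12, float(n.sum()) + 1.0
    while excess(hi) > 0:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    f0 = np.maximum(0.0, n / lam - shift)
    tot = f0.sum()
    if tot > 0:
        f0 /= tot
    mix = alpha * p1 + (1.0 - alpha) * f0
    with np.errstate(divide="ignore"):
        lmix = np.where(n > 0, np.log(mix), 0.0)
    return float((n * lmix).sum())


#: likelihood-ratio drop (2 * delta-log-likelihood) tolerated before the
#: profile curve is considered to have left its plateau; chi-square(1) 99.9%
ELBOW_CRITICAL = 10.83

#: histogram pseudo-count per bin for the positive-component density; kept
#: small so no appreciable mixture mass is wasted on score bins the
#: unlabelled sample never visits
HIST_PSEUDOCOUNT = 0.05


def alphamax_estimate(scores: ScoreSet, grid=None, n_bins: int = 25,
                      critical: float = ELBOW_CRITICAL,
                      floor: float = PRIOR_FLOOR) -> PriorEstimate:
    """AlphaMax on the 1-D score scale with histogram densities.

    Requires >= 50 scores in each set. The profile log-likelihood is flat
    up to the true mixing proportion and falls beyond it; the estimate is
    the largest grid alpha whose likelihood-ratio drop from the plateau
    stays within ``critical`` (the operational form of "largest alpha
    before the curve's slope drops beyond a threshold"). ``alpha`` in the
    result is rescaled to the full dataset composition; diagnostics carry
    the grid and the raw/normalized curves.
    """
    lab, unl = scores.scores_labelled, scores.scores_unlabelled
    if lab.size < 50 or unl.size < 50:
        raise ValueError("alphamax needs at least 50 scores in each set")
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    lab_counts = np.histogram(lab, bins=edges)[0].astype(float)
    unl_counts = np.histogram(unl, bins=edges)[0].astype(float)
    if lab_counts.sum() == 0 or unl_counts.sum() == 0:
        raise ValueError("degenerate score histograms")
    p1 = (lab_counts + HIST_PSEUDOCOUNT) / (lab_counts.sum() + HIST_PSEUDOCOUNT * n_bins)

    loglik = np.array([_waterfill_loglik(unl_counts, p1, a) for a in grid])
    span = loglik.max() - loglik.min()
    norm = (loglik - loglik.min()) / span if span > 0 else np.ones_like(loglik)
    # noise allowance: placing mixture weight a on a positive density that
    # was itself estimated from lab.size samples costs ~ (bins-1) * a^2 *
    # (n_unl / n_lab) in 2*delta-log-likelihood even when the mixture is
    # exact, so the plateau test grows with a
    allowance = (n_bins - 1) * grid ** 2 * (unl.size / lab.size)
    within = 2.0 * (loglik.max() - loglik) <= critical + allowance
    alpha_u = float(grid[np.flatnonzero(within)[-1]])
    n_l, n_u = lab.size, unl.size
    alpha_full = (n_l + alpha_u * n_u) / (n_l + n_u)
    alpha_full = _apply_floor(alpha_full, floor)
    c = min(1.0, (n_l / (n_l + n_u)) / alpha_full)
    return PriorEstimate(
        "alphamax", alpha_full, max(c, 1e-12),
        {"grid": grid, "loglik": loglik, "normalized": norm,
         "alpha_unlabelled": alpha_u, "n_bins": n_bins, "critical": critical},
    )
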