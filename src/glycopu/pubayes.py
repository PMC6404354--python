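"""PU Bayesian classifiers: PNB, PAODE (=PA1DE), PAnDE and PTAN.

All four learners share the same estimation scheme: class-conditional
count tables for the positive class come from the labelled rows, marginal
tables from all rows, and the negative-class tables are derived by mixture
inversion under the "selected completely at random" assumption,

    P(v | y=0) = (P(v) - alpha * P(v | y=1)) / (1 - alpha),

realized at the count level as pseudo-counts
``clip(all_counts - (alpha*N/N_lab) * labelled_counts, 0)`` so that the
supervised limit (fully labelled data, alpha = empirical positive fraction)
reproduces ordinary counts exactly. m-estimate smoothing (m=1, uniform
base) is applied on top of the (pseudo-)counts.

PAnDE scores a sample by summing, over all size-n parent attribute tuples
whose value combination occurs in training (the delta gate), the parent
joint P(y, x_S) times the product of P(x_m | y, x_S) over non-parent
attributes; if every delta is zero the order drops by one, bottoming out at
PNB. PTAN replaces the ensemble with a single Chow-Liu tree over
conditional mutual information given y.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import PUDataset
from .prior import PriorEstimate

logger = logging.getLogger(__name__)

FAMILIES = ("pnb", "paode", "pande", "ptan")

_COMBO_CHUNK = 8192
_ROW_CHUNK = 32


@dataclass(frozen=True)
class Prediction:
    posterior_positive: float
    label: str  # positive | negative
    fallback_depth: int = 0


def derive_negative_conditionals(positive_conditionals, marginals, alpha,
                                 epsilon: float = 1e-6):
    """Mixture-inversion of conditionals for the negative class.

    Arrays are (..., n_values) with the last axis a probability
    distribution per conditioning context. Negative raw values are clipped
    to ``epsilon`` and each context renormalized. Returns (neg, n_clipped).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    pos = np.asarray(positive_conditionals, dtype=float)
    marg = np.asarray(marginals, dtype=float)
    raw = (marg - alpha * pos) / (1.0 - alpha)
    n_clipped = int((raw < epsilon).sum())
    clipped = np.maximum(raw, epsilon)
    total = clipped.sum(axis=-1, keepdims=True)
    return clipped / total, n_clipped


def _cell_indices(X0: np.ndarray, combos: np.ndarray, vmax: int) -> np.ndarray:
    """Mixed-radix (base vmax) cell index per row per combo.

    X0 is the 0-based code matrix; combos is (n_combos, t). Returns
    (n_rows, n_combos); for t == 0, a single all-zero column.
    """
    n = X0.shape[0]
    t = combos.shape[1] if combos.ndim == 2 else 0
    if t == 0:
        return np.zeros((n, 1), dtype=np.int64)
    cells = np.zeros((n, combos.shape[0]), dtype=np.int64)
    for j in range(t):
        cells = cells * vmax + X0[:, combos[:, j]]
    return cells


class _Level:
    """Count tables for all attribute subsets of one size."""

    def __init__(self, t: int, k: int, vmax: int):
        self.t = t
        self.vmax = vmax
        if t == 0:
            self.combos = np.zeros((1, 0), dtype=np.int64)
        else:
            self.combos = np.array(list(itertools.combinations(range(k), t)),
                                   dtype=np.int64)
        self.n_combos = self.combos.shape[0]
        self.cells = vmax ** t
        self.lab = None  # (n_combos, cells) labelled-row counts
        self.all = None  # (n_combos, cells) all-row counts
        self.neg = None  # derived negative pseudo-counts
        self.neg_ctx = None  # list over child positions of context sums
        self.clip_events = 0

    def count(self, X0: np.ndarray, s: np.ndarray) -> None:
        n = X0.shape[0]
        lab = np.zeros(self.n_combos * self.cells, dtype=np.int64)
        allc = np.zeros_like(lab)
        pos_rows = s == 1
        for start in range(0, self.n_combos, _COMBO_CHUNK):
            chunk = self.combos[start:start + _COMBO_CHUNK]
            cells = _cell_indices(X0, chunk, self.vmax)
            base = (np.arange(start, start + chunk.shape[0]) * self.cells)[None, :]
            flat = (base + cells)
            lo, hi = start * self.cells, (start + chunk.shape[0]) * self.cells
            allc[lo:hi] += np.bincount(flat.ravel() - lo, minlength=hi - lo)
            labflat = flat[pos_rows]
            if labflat.size:
                lab[lo:hi] += np.bincount(labflat.ravel() - lo, minlength=hi - lo)
        self.lab = lab.reshape(self.n_combos, self.cells)
        self.all = allc.reshape(self.n_combos, self.cells)

    def derive_negatives(self, r: float) -> None:
        raw = self.all - r * self.lab
        self.clip_events = int((raw < -1e-12).sum())
        self.neg = np.maximum(raw, 0.0)
        # per-child-position context sums keep derived conditionals normalized
        if self.t >= 1:
            shaped = self.neg.reshape((self.n_combos,) + (self.vmax,) * self.t)
            self.neg_ctx = [
                shaped.sum(axis=p + 1).reshape(self.n_combos, self.cells // self.vmax)
                for p in range(self.t)
            ]

    def parent_ids(self, parent_level: "_Level") -> np.ndarray:
        """(n_combos, t) combo ids in parent_level of self minus member p."""
        lookup = {tuple(c): i for i, c in enumerate(parent_level.combos)}
        out = np.empty((self.n_combos, self.t), dtype=np.int64)
        for i, combo in enumerate(self.combos):
            for p in range(self.t):
                out[i, p] = lookup[tuple(np.delete(combo, p))]
        return out


@dataclass
class PUBayesModel:
    family: str
    n: int
    alpha: float
    m_smoothing: float
    feature_names: list
    arities: np.ndarray
    clip_epsilon: float = 1e-6
    n_rows: int = 0
    n_labelled: int = 0
    levels: dict = field(default_factory=dict, repr=False)
    tree_parent: list | None = None  # ptan: parent attr per attr (-1 = root)
    clip_events: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def k(self) -> int:
        return len(self.feature_names)

    @property
    def vmax(self) -> int:
        return int(self.arities.max()) + 1

    # --- serialization (counts stored sparsely; text-only) ---

    def to_json(self) -> str:
        def sparse(arr):
            flat = arr.ravel()
            idx = np.flatnonzero(flat)
            return [idx.tolist(), flat[idx].tolist()]

        d = {
            "family": self.family, "n": self.n, "alpha": self.alpha,
            "m_smoothing": self.m_smoothing, "feature_names": list(self.feature_names),
            "arities": self.arities.tolist(), "clip_epsilon": self.clip_epsilon,
            "n_rows": self.n_rows, "n_labelled": self.n_labelled,
            "tree_parent": self.tree_parent, "clip_events": self.clip_events,
            "levels": {str(t): {"lab": sparse(lv.lab), "all": sparse(lv.all)}
                       for t, lv in self.levels.items()},
        }
        return json.dumps(d)

    @staticmethod
    def from_json(text: str) -> "PUBayesModel":
        d = json.loads(text)
        model = PUBayesModel(
            family=d["family"], n=d["n"], alpha=d["alpha"],
            m_smoothing=d["m_smoothing"], feature_names=d["feature_names"],
            arities=np.array(d["arities"], dtype=np.int64),
            clip_epsilon=d["clip_epsilon"], n_rows=d["n_rows"],
            n_labelled=d["n_labelled"], tree_parent=d["tree_parent"],
            clip_events=d["clip_events"],
        )
        k, vmax = model.k, model.vmax
        r = model.alpha * model.n_rows / model.n_labelled
        for t_str, tables in d["levels"].items():
            t = int(t_str)
            lv = _Level(t, k, vmax)
            for name in ("lab", "all"):
                idx, vals = tables[name]
                flat = np.zeros(lv.n_combos * lv.cells, dtype=np.int64)
                flat[np.array(idx, dtype=np.int64)] = np.array(vals, dtype=np.int64)
                setattr(lv, name, flat.reshape(lv.n_combos, lv.cells))
            lv.derive_negatives(r)
            model.levels[t] = lv
        return model


def _chow_liu_tree(model: PUBayesModel) -> list:
    """Maximum spanning tree over CMI(Xi; Xj | y), rooted at attribute 0.

    CMI uses the smoothed derived class-conditionals; Kruskal with
    deterministic (i, j) tie-breaks; edges oriented away from the root.
    """
    k, vmax, m = model.k, model.vmax, model.m_smoothing
    lv1, lv2 = model.levels[1], model.levels[2]
    alpha = model.alpha

    def cond_probs(level, combo_id, n_cells_true):
        p1 = (level.lab[combo_id] + m / n_cells_true) / (model.n_labelled + m)
        neg = level.neg[combo_id]
        p0 = (neg + m / n_cells_true) / (neg.sum() + m)
        return p1, p0

    singles = {}
    for a in range(k):
        singles[a] = cond_probs(lv1, a, int(model.arities[a]))
    edges = []
    for combo_id, (i, j) in enumerate(lv2.combos):
        ncells = int(model.arities[i] * model.arities[j])
        pj1, pj0 = cond_probs(lv2, combo_id, ncells)
        cmi = 0.0
        for w, pij, pi, pjm in ((alpha, pj1, singles[i][0], singles[j][0]),
                                (1 - alpha, pj0, singles[i][1], singles[j][1])):
            pij = pij.reshape(vmax, vmax)
            outer = np.outer(pi, pjm)
            mask = pij > 0
            cmi += w * float((pij[mask] * np.log(pij[mask] / outer[mask])).sum())
        edges.append((cmi, int(i), int(j)))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    parent_uf = list(range(k))

    def find(x):
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    adj = {a: [] for a in range(k)}
    n_edges = 0
    for _, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent_uf[ri] = rj
            adj[i].append(j)
            adj[j].append(i)
            n_edges += 1
            if n_edges == k - 1:
                break
    parent = [-2] * k
    parent[0] = -1
    queue = [0]
    while queue:
        u = queue.pop(0)
        for v in sorted(adj[u]):
            if parent[v] == -2:
                parent[v] = u
                queue.append(v)
    return parent


def fit(dataset: PUDataset, family: str = "pande", n: int = 2,
        prior: PriorEstimate | None = None, m_smoothing: float = 1.0,
        clip_epsilon: float = 1e-6) -> PUBayesModel:
    """Fit a PU Bayesian model of the requested family.

    ``family='pnb'`` forces n=0, ``'paode'`` n=1; ``'pande'`` uses ``n``
    (n=2 is PA2DE). ``'ptan'`` ignores n and learns a tree. The prior is
    required (alpha unset is an error).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if prior is None:
        raise ValueError("a PriorEstimate (alpha) is required to fit PU models")
    if family == "pnb":
        n = 0
    elif family == "paode":
        n = 1
    elif family == "ptan":
        n = 1  # tree uses singleton parents; structure from pair tables
    k = dataset.k
    if not 0 <= n <= k - 1:
        raise ValueError(f"{family} needs 0 <= n <= k-1 = {k - 1}, got n={n}")
    alpha = float(prior.alpha)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1) for mixture inversion, got {alpha}")
    n_lab = int(dataset.s.sum())
    model = PUBayesModel(
        family=family, n=n, alpha=alpha, m_smoothing=m_smoothing,
        feature_names=list(dataset.feature_names), arities=dataset.arities(),
        clip_epsilon=clip_epsilon, n_rows=dataset.n, n_labelled=n_lab,
    )
    X0 = (dataset.X - 1).astype(np.int64)
    vmax = model.vmax
    max_level = 2 if family == "ptan" else min(n + 1, k)
    r = alpha * dataset.n / n_lab
    for t in range(0, max_level + 1):
        lv = _Level(t, k, vmax)
        lv.count(X0, dataset.s)
        lv.derive_negatives(r)
        model.levels[t] = lv
        model.clip_events += lv.clip_events
    if family == "ptan":
        model.tree_parent = _chow_liu_tree(model)
    return model


def _log_parent_joint(model: PUBayesModel, lv: _Level, cells: np.ndarray):
    """log P(y, x_S) for every row (axis 0) and parent combo (axis 1)."""
    m = model.m_smoothing
    if lv.t == 0:
        true_cells = np.ones(1)
    else:
        true_cells = model.arities[lv.combos].prod(axis=1).astype(float)
    lab = lv.lab[np.arange(lv.n_combos)[None, :], cells]
    neg = lv.neg[np.arange(lv.n_combos)[None, :], cells]
    p1 = (lab + m / true_cells) / (model.n_labelled + m)
    neg_tot = lv.neg.sum(axis=1)
    p0 = (neg + m / true_cells) / (neg_tot + m)
    return (np.log(model.alpha) + np.log(p1),
            np.log1p(-model.alpha) + np.log(p0))


def _ande_level_scores(model: PUBayesModel, X0: np.ndarray, t: int):
    """Per-row log ensemble scores at parent order t.

    Returns (log_score_0, log_score_1, any_delta) with the ensemble sum over
    parents collapsed by log-sum-exp; rows with no occurring parent tuple
    get -inf scores and any_delta False.
    """
    from scipy import sparse

    m = model.m_smoothing
    vmax = model.vmax
    lv_p = model.levels[t]
    lv_c = model.levels[t + 1]
    key = ("maps", t)
    if key not in model._cache:
        pid = lv_c.parent_ids(lv_p)  # (nT, t+1)
        mats = []
        for p in range(t + 1):
            mat = sparse.csr_matrix(
                (np.ones(lv_c.n_combos), (np.arange(lv_c.n_combos), pid[:, p])),
                shape=(lv_c.n_combos, lv_p.n_combos),
            )
            mats.append(mat)
        child_attr = lv_c.combos  # column p is the child attribute for pos p
        model._cache[key] = (pid, mats, child_attr)
    pid, mats, child_attr = model._cache[key]

    n = X0.shape[0]
    out0 = np.empty(n)
    out1 = np.empty(n)
    has = np.empty(n, dtype=bool)
    for lo in range(0, n, _ROW_CHUNK):
        rows = X0[lo:lo + _ROW_CHUNK]
        nr = rows.shape[0]
        pcells = _cell_indices(rows, lv_p.combos, vmax)  # (nr, nS)
        ccells = _cell_indices(rows, lv_c.combos, vmax)  # (nr, nT)
        combo_ar_p = np.arange(lv_p.n_combos)[None, :]
        combo_ar_c = np.arange(lv_c.n_combos)[None, :]
        delta = lv_p.all[combo_ar_p, pcells] > 0
        lp1, lp0 = _log_parent_joint(model, lv_p, pcells)
        lab_p = lv_p.lab[combo_ar_p, pcells].astype(float)
        # child-count gathers at the instance's child cells
        lab_c = lv_c.lab[combo_ar_c, ccells].astype(float)
        neg_c = lv_c.neg[combo_ar_c, ccells]
        S1 = np.zeros((nr, lv_p.n_combos))
        S0 = np.zeros((nr, lv_p.n_combos))
        for p in range(t + 1):
            v_child = model.arities[child_attr[:, p]].astype(float)
            num1 = np.log(lab_c + m / v_child)
            num0 = np.log(neg_c + m / v_child)
            ctx = lv_c.neg_ctx[p][combo_ar_c, pcells[:, pid[:, p]]]
            den0 = np.log(ctx + m)
            S1 += (mats[p].T @ num1.T).T
            S0 += (mats[p].T @ (num0 - den0).T).T
        k_minus_t = model.k - t
        S1 -= k_minus_t * np.log(lab_p + m)
        term1 = np.where(delta, lp1 + S1, -np.inf)
        term0 = np.where(delta, lp0 + S0, -np.inf)
        has[lo:lo + nr] = delta.any(axis=1)
        with np.errstate(invalid="ignore"):
            mx = np.maximum(term1.max(axis=1), term0.max(axis=1))
        mx = np.where(np.isfinite(mx), mx, 0.0)
        with np.errstate(divide="ignore"):  # no-delta rows: -inf, discarded
            out1[lo:lo + nr] = mx + np.log(np.exp(term1 - mx[:, None]).sum(axis=1))
            out0[lo:lo + nr] = mx + np.log(np.exp(term0 - mx[:, None]).sum(axis=1))
    return out0, out1, has


def _ptan_scores(model: PUBayesModel, X0: np.ndarray):
    m = model.m_smoothing
    vmax = model.vmax
    lv1, lv2 = model.levels[1], model.levels[2]
    pair_index = {tuple(c): i for i, c in enumerate(lv2.combos)}
    n = X0.shape[0]
    log1 = np.full(n, np.log(model.alpha))
    log0 = np.full(n, np.log1p(-model.alpha))
    for a in range(model.k):
        par = model.tree_parent[a]
        va = int(model.arities[a])
        if par == -1:
            lab = lv1.lab[a, X0[:, a]].astype(float)
            neg = lv1.neg[a, X0[:, a]]
            log1 += np.log((lab + m / va) / (model.n_labelled + m))
            log0 += np.log((neg + m / va) / (lv1.neg[a].sum() + m))
        else:
            i, j = min(a, par), max(a, par)
            cid = pair_index[(i, j)]
            child_pos = 0 if a == i else 1
            cell = X0[:, i] * vmax + X0[:, j]
            lab2 = lv2.lab[cid, cell].astype(float)
            neg2 = lv2.neg[cid, cell]
            lab_par = lv1.lab[par, X0[:, par]].astype(float)
            ctx = lv2.neg_ctx[child_pos][cid, X0[:, par]]
            log1 += np.log((lab2 + m / va) / (lab_par + m))
            log0 += np.log((neg2 + m / va) / (ctx + m))
    return log0, log1


def predict_batch(model: PUBayesModel, data, threshold: float = 0.5):
    """Row-wise classification; returns (predictions, posterior scores)."""
    if isinstance(data, PUDataset):
        if list(data.feature_names) != list(model.feature_names):
            raise ValueError("dataset schema does not match the model")
        X = data.X
    else:
        X = np.asarray(data)
        if X.ndim != 2 or X.shape[1] != model.k:
            raise ValueError(f"expected {model.k} attribute columns")
    if X.size and X.min() < 1:
        raise ValueError("attribute codes must be 1-based")
    # unseen high codes go to a spare all-zero slot: the smoothed pseudo-count path
    X0 = np.minimum(X - 1, model.arities[None, :]).astype(np.int64)

    n = X0.shape[0]
    if model.family == "ptan":
        log0, log1 = _ptan_scores(model, X0)
        depth = np.zeros(n, dtype=int)
    else:
        log0 = np.full(n, np.nan)
        log1 = np.full(n, np.nan)
        depth = np.zeros(n, dtype=int)
        pending = np.arange(n)
        t = model.n
        while pending.size:
            s0, s1, has = _ande_level_scores(model, X0[pending], t)
            done = pending[has]
            log0[done] = s0[has]
            log1[done] = s1[has]
            depth[done] = model.n - t
            pending = pending[~has]
            if t == 0:
                break  # level 0 always has delta=1; loop ends via has
            t -= 1
    mx = np.maximum(log0, log1)
    p1 = np.exp(log1 - mx)
    posterior = p1 / (p1 + np.exp(log0 - mx))
    preds = [
        Prediction(float(posterior[i]),
                   "positive" if posterior[i] >= threshold else "negative",
                   int(depth[i]))
        for i in range(n)
    ]
    return preds, posterior


def classify(model: PUBayesModel, x) -> Prediction:
    """Classify a single attribute-value row."""
    preds, _ = predict_batch(model, np.asarray(x).reshape(1, -1))
    return preds[0]
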