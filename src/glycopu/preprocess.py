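"""Discretization, PU dataset assembly, unlabelled sampling and mRMR.

The discrete Bayesian classifiers need categorical attributes, so
continuous descriptor columns are equal-frequency binned on training rows
only. Feature selection is greedy mRMR (MID scheme) with plug-in mutual
information in natural log, using the PU label ``s`` as the selection
target.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class DiscretizationModel:
    """Per-feature strictly increasing bin edges; transform maps reals to
    bin ids in [1, n_bins(feature)]. Values equal to an edge fall in the
    lower bin."""

    edges: dict  # feature name -> list of edges (possibly empty = 1 bin)
    n_bins: int
    fit_set: str = ""

    def bins_for(self, feature: str) -> int:
        return len(self.edges[feature]) + 1

    def transform_column(self, feature: str, values) -> np.ndarray:
        e = np.asarray(self.edges[feature])
        x = np.asarray(values, dtype=float)
        if e.size == 0:
            return np.ones(x.shape, dtype=np.int64)
        return np.searchsorted(e, x, side="left") + 1

    def transform(self, frame):
        """DataFrame of discretized columns (same index/columns)."""
        import pandas as pd

        cols = {c: self.transform_column(c, frame[c].to_numpy()) for c in frame.columns}
        return pd.DataFrame(cols, index=frame.index)[list(frame.columns)]

    def to_json(self) -> str:
        return json.dumps(
            {"n_bins": self.n_bins, "fit_set": self.fit_set,
             "edges": {k: list(map(float, v)) for k, v in self.edges.items()}},
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "DiscretizationModel":
        d = json.loads(text)
        return DiscretizationModel(edges=d["edges"], n_bins=d["n_bins"],
                                   fit_set=d.get("fit_set", ""))


def fit_discretizer(frame, n_bins: int = 5, fit_set: str = "train") -> DiscretizationModel:
    """Equal-frequency edges from training rows.

    Edges are midpoints between the order statistics at ranks
    ``round(i*n/n_bins)``; duplicate or degenerate edges collapse, so a
    feature may end up with fewer bins (a constant feature gets one bin,
    with a warning).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges: dict[str, list[float]] = {}
    n_constant = 0
    for col in frame.columns:
        v = np.sort(np.asarray(frame[col], dtype=float))
        n = v.size
        if n == 0:
            raise ValueError("cannot fit a discretizer on zero rows")
        if v[0] == v[-1]:
            n_constant += 1
            edges[col] = []
            continue
        es = []
        for i in range(1, n_bins):
            r = int(round(i * n / n_bins))
            r = min(max(r, 1), n - 1)
            e = (v[r - 1] + v[r]) / 2.0
            if not es or e > es[-1]:
                es.append(float(e))
        edges[col] = es
    if n_constant:
        logger.warning("fit_discretizer: %d constant features got a single bin", n_constant)
    return DiscretizationModel(edges=edges, n_bins=n_bins, fit_set=fit_set)


@dataclass
class PUDataset:
    """Discrete attribute matrix with PU labels (1 = labelled positive)."""

    X: np.ndarray  # (n, k) integer matrix, values in [1, arity_j]
    s: np.ndarray  # (n,) in {0, 1}
    feature_names: list
    keys: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.s = np.asarray(self.s)
        if self.X.ndim != 2 or self.s.ndim != 1 or self.X.shape[0] != self.s.size:
            raise ValueError("X and s shapes are inconsistent")
        if not np.issubdtype(self.X.dtype, np.integer):
            raise ValueError("PUDataset attributes must be integer-coded")
        if self.X.size and self.X.min() < 1:
            raise ValueError("attribute codes must be 1-based")
        if self.s.sum() < 1:
            raise ValueError("PUDataset needs at least one labelled positive")
        if not self.keys:
            self.keys = [str(i) for i in range(self.X.shape[0])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def arities(self) -> np.ndarray:
        return self.X.max(axis=0).astype(np.int64)

    def subset(self, idx) -> "PUDataset":
        idx = np.asarray(idx)
        return PUDataset(self.X[idx], self.s[idx], list(self.feature_names),
                         [self.keys[i] for i in idx])


@dataclass(frozen=True)
class FeatureRelevance:
    feature: str
    relevance: float  # MI with the PU label
    score: float  # mRMR score at selection time

    def __post_init__(self):
        if self.relevance < -1e-12:
            raise ValueError("mutual information must be nonnegative")


def mutual_information(x, y) -> float:
    """Plug-in MI (natural log) between two discrete columns; 0*log0 = 0."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size or x.size == 0:
        raise ValueError("columns must have equal, nonzero length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px * py))
    return float(np.nansum(terms))


def _mi_against_all(X: np.ndarray, y: np.ndarray, arities: np.ndarray,
                    ay: int) -> np.ndarray:
    """MI of every column of X (1-based codes) against y (1-based codes)."""
    n, k = X.shape
    amax = int(arities.max())
    # joint counts per column via one flattened bincount
    col_idx = np.broadcast_to(np.arange(k), (n, k))
    flat = (col_idx * (amax * ay) + (X - 1) * ay + (y[:, None] - 1)).ravel()
    counts = np.bincount(flat, minlength=k * amax * ay).reshape(k, amax, ay).astype(float)
    pxy = counts / n
    px = pxy.sum(axis=2, keepdims=True)
    py = pxy.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px * py))
    return np.nansum(terms, axis=(1, 2))


def mrmr_select(dataset: PUDataset, k: int | None = 100) -> list[FeatureRelevance]:
    """Greedy MID-scheme mRMR ranking of ``k`` features against the PU label.

    The first pick maximizes relevance I(f; s); each subsequent pick
    maximizes I(f; s) minus the mean MI with already-selected features.
    Ties break toward the lexicographically smaller feature name.
    """
    if k is None:
        k = 100
    if k > dataset.k:
        raise ValueError(f"k={k} exceeds the {dataset.k} available features")
    X = dataset.X.astype(np.int64)
    names = list(dataset.feature_names)
    arities = dataset.arities()
    s = dataset.s.astype(np.int64) + 1
    relevance = _mi_against_all(X, s, arities, 2)

    order = np.lexsort((names, -relevance))  # tie-break by ascending name
    selected: list[int] = []
    result: list[FeatureRelevance] = []
    redundancy = np.zeros(dataset.k)
    available = np.ones(dataset.k, dtype=bool)
    first = order[0]
    selected.append(first)
    available[first] = False
    result.append(FeatureRelevance(names[first], float(relevance[first]),
                                   float(relevance[first])))
    while len(selected) < k:
        last = selected[-1]
        redundancy += _mi_against_all(X, X[:, last], arities, int(arities[last]))
        score = relevance - redundancy / len(selected)
        score_masked = np.where(available, score, -np.inf)
        best = score_masked.max()
        cand = np.flatnonzero(score_masked >= best - 1e-12)
        pick = min(cand, key=lambda i: names[i])
        selected.append(pick)
        available[pick] = False
        result.append(FeatureRelevance(names[pick], float(relevance[pick]),
                                       float(score[pick])))
    return result


def write_selection(path, ranking: list[FeatureRelevance]) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tname\trelevance\tscore\n")
        for i, fr in enumerate(ranking, start=1):
            fh.write(f"{i}\t{fr.feature}\t{fr.relevance:.10g}\t{fr.score:.10g}\n")


def sample_unlabelled(proteins, positives, per_protein: int = 20,
                      cap: int = 10_000, seed: int = 0,
                      glyco_type: str = "N") -> list:
    """Sample unlabelled candidate-site keys per the two-stage protocol.

    Per glycosylated protein, up to ``per_protein`` candidate sites not
    annotated positive are drawn uniformly without replacement; the union is
    then uniformly subsampled to ``cap`` (everything kept if fewer).
    Returns SiteAnnotations sorted deterministically.
    """
    from .seqio import enumerate_candidates

    if per_protein < 0 or cap < 0:
        raise ValueError("per_protein and cap must be nonnegative")
    rng = np.random.default_rng(seed)
    pos_by_protein: dict[str, set] = {}
    for site in positives:
        pos_by_protein.setdefault(site.protein_id, set()).add(site.position)
    pool = []
    for protein in proteins:
        if protein.id not in pos_by_protein:
            continue  # only glycosylated proteins contribute unlabelled sites
        cands = enumerate_candidates(protein, glyco_type,
                                     pos_by_protein[protein.id])
        if len(cands) > per_protein:
            idx = rng.choice(len(cands), size=per_protein, replace=False)
            cands = [cands[i] for i in sorted(idx)]
        pool.extend(cands)
    if len(pool) > cap:
        idx = rng.choice(len(pool), size=cap, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    return pool
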