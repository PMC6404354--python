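"""Synthetic ground-truth generators: SCAR PU datasets and motif proteins.

Everything is a pure function of (spec, seed): the same spec yields a
byte-identical dataset. SCAR holds by construction - the true class y is
Bernoulli(alpha_true), attributes are drawn from per-class categorical
tables, and positives are labelled with constant probability c_true
independent of the attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .preprocess import PUDataset
from .seqio import AMINO_ACIDS, ProteinRecord, SiteAnnotation, matches_sequon

#: default separation for the two-class categorical tables. With the k=8
#: binary-attribute default the Bayes-optimal AUC of the log-likelihood
#: ratio is ~0.90 at this value (estimated by estimate_bayes_auc at n=1e5:
#: 0.88 at 0.30, 0.91 at 0.34, 0.96 at 0.46); raising it to ~0.8-1.2 gives
#: near-separable classes (AUC > 0.99).
DEFAULT_SEPARATION = 0.34


@dataclass
class ScarSpec:
    n: int = 5000
    k: int = 8
    arity: int = 2
    alpha_true: float = 0.3
    c_true: float = 0.5
    separation: float = DEFAULT_SEPARATION
    dependence: float = 0.0  # prob. that even attrs copy their predecessor
    class_conditionals: tuple | None = None  # ((k,v) table for y=1, for y=0)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha_true < 1:
            raise ValueError("alpha_true must lie in (0, 1)")
        if not 0 < self.c_true <= 1:
            raise ValueError("c_true must lie in (0, 1]")
        if self.arity < 2 or self.k < 1 or self.n < 1:
            raise ValueError("need n >= 1, k >= 1, arity >= 2")
        if not 0 <= self.dependence <= 1:
            raise ValueError("dependence must lie in [0, 1]")

    def tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(k, arity) categorical tables for y=1 and y=0."""
        if self.class_conditionals is not None:
            p1, p0 = (np.asarray(t, dtype=float) for t in self.class_conditionals)
            for t in (p1, p0):
                if t.shape != (self.k, self.arity):
                    raise ValueError("class_conditionals must be (k, arity)")
                if not np.allclose(t.sum(axis=1), 1.0):
                    raise ValueError("class-conditional rows must sum to 1")
            return p1, p0
        ramp = np.linspace(-1.0, 1.0, self.arity)
        p1 = np.exp(self.separation * ramp)
        p0 = np.exp(-self.separation * ramp)
        p1 /= p1.sum()
        p0 /= p0.sum()
        return (np.tile(p1, (self.k, 1)), np.tile(p0, (self.k, 1)))

    def to_yaml(self) -> str:
        d = asdict(self)
        if d["class_conditionals"] is not None:
            d["class_conditionals"] = [np.asarray(t).tolist()
                                       for t in d["class_conditionals"]]
        return yaml.safe_dump(d)

    @staticmethod
    def from_yaml(text: str) -> "ScarSpec":
        d = yaml.safe_load(text)
        if d.get("class_conditionals") is not None:
            d["class_conditionals"] = tuple(np.array(t) for t in d["class_conditionals"])
        return ScarSpec(**d)


def _sample_categorical(rng, probs: np.ndarray, n: int) -> np.ndarray:
    """n draws (1-based codes) from each row's categorical distribution."""
    cum = np.cumsum(probs)
    u = rng.random(n)
    return np.searchsorted(cum, u, side="right").astype(np.int64) + 1


def generate_scar(spec: ScarSpec) -> tuple[PUDataset, np.ndarray]:
    """A SCAR PU dataset plus the hidden ground-truth class vector y."""
    rng = np.random.default_rng(spec.seed)
    p1, p0 = spec.tables()
    y = (rng.random(spec.n) < spec.alpha_true).astype(np.int64)
    X = np.empty((spec.n, spec.k), dtype=np.int64)
    for j in range(spec.k):
        col = np.where(y == 1,
                       _sample_categorical(rng, p1[j], spec.n),
                       _sample_categorical(rng, p0[j], spec.n))
        X[:, j] = col
    if spec.dependence > 0:
        for j in range(1, spec.k, 2):
            copy = rng.random(spec.n) < spec.dependence
            X[copy, j] = X[copy, j - 1]
    s = np.where((y == 1) & (rng.random(spec.n) < spec.c_true), 1, 0)
    names = [f"attr{j + 1}" for j in range(spec.k)]
    keys = [f"sample:{i + 1}" for i in range(spec.n)]
    return PUDataset(X, s, names, keys), y


def estimate_bayes_auc(spec: ScarSpec, n: int = 200_000, seed: int = 12345) -> float:
    """Monte-Carlo AUC of the true log-likelihood ratio (the Bayes bound)."""
    from .evaluate import auc

    sim = ScarSpec(**{**asdict(spec), "n": n, "seed": seed,
                      "class_conditionals": spec.class_conditionals})
    ds, y = generate_scar(sim)
    p1, p0 = spec.tables()
    llr = np.zeros(n)
    for j in range(spec.k):
        llr += np.log(p1[j][ds.X[:, j] - 1]) - np.log(p0[j][ds.X[:, j] - 1])
    return auc(llr, y)


@dataclass
class SequenceSpec:
    n_proteins: int = 200
    length_range: tuple = (80, 300)
    motif: str = "N[!P][ST][!P]"
    site_rate: float = 0.7
    flank_bias: float = 0.0  # prob. each flank position is redrawn enriched
    enriched_residues: str = "KRDE"
    background: dict | None = None  # residue -> weight; uniform if None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.site_rate <= 1 or not 0 <= self.flank_bias <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.motif != "N[!P][ST][!P]":
            raise ValueError("only the N[!P][ST][!P] sequon is supported")


def find_motif_sites(sequence: str) -> list[int]:
    """1-based positions whose residue starts an N[!P][ST][!P] sequon."""
    protein = ProteinRecord("tmp", sequence)
    return [i for i in range(1, len(sequence) + 1)
            if sequence[i - 1] == "N" and matches_sequon(protein, i)]


def generate_proteins(spec: SequenceSpec) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Random proteins with sequon-embedded positive N-linked sites.

    Residues are i.i.d. from the background; a ``site_rate`` fraction of
    sequon occurrences is annotated positive. With ``flank_bias`` > 0 the
    seven residues either side of each positive site (outside the sequon
    itself) are redrawn from ``enriched_residues`` with that probability,
    so sequence descriptors carry class signal.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    if spec.background is None:
        weights = np.ones(20) / 20
    else:
        weights = np.array([spec.background.get(a, 0.0) for a in AMINO_ACIDS])
        weights = weights / weights.sum()
    enriched = np.array(list(spec.enriched_residues))
    proteins: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    any_motif = False
    for idx in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = list(rng.choice(alphabet, size=length, p=weights))
        sites = find_motif_sites("".join(seq))
        positives = [p for p in sites if rng.random() < spec.site_rate]
        if sites:
            any_motif = True
        # sequon residues of every positive are protected from rewrites so
        # one site's flank enrichment cannot destroy a neighbouring site
        protected = {j for p in positives for j in range(p - 1, p + 3)}
        for p in positives:
            if spec.flank_bias > 0:
                i = p - 1
                flanks = [j for j in range(i - 7, i + 8)
                          if 0 <= j < length and j not in protected]
                for j in flanks:
                    if rng.random() < spec.flank_bias:
                        seq[j] = str(rng.choice(enriched))
        sequence = "".join(seq)
        pid = f"synt{idx + 1:04d}"
        proteins.append(ProteinRecord(pid, sequence))
        protein = proteins[-1]
        for p in positives:
            # flank rewrites never touch the sequon, so p is still a site
            annotations.append(SiteAnnotation(pid, p, protein.residue(p), "N", "positive"))
    if not any_motif:
        import logging

        logging.getLogger(__name__).warning(
            "generate_proteins: no motif occurrences; empty annotations")
    return proteins, annotations
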