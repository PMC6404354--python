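"""The six sequence-derived feature groups for 15-residue peptide windows.

Groups and default dimensionalities:

====== ===========================================  ====
tag    descriptor                                   dim
====== ===========================================  ====
AAC    amino-acid composition                         20
DPC    dipeptide composition                         400
NMB    normalized Moreau-Broto autocorrelation       240
MORAN  Moran autocorrelation                         240
GEARY  Geary autocorrelation                         240
CTD    composition / transition / distribution       147
SOCN   sequence-order-coupling numbers                60
QSO    quasi-sequence-order                          100
PSE1   pseudo-amino-acid composition, type I          50
PSE2   amphiphilic pseudo-amino-acid composition      50
AAIDX  per-position AAindex property encodings     15*n
====== ===========================================  ====

Windows may contain 'X' (unknown residue / terminal padding): 'X' is
excluded from composition counts and carries the mean (zero after z-score)
property value in numeric encodings; residue distances involving 'X' are
zero. Lag-based features whose lag exceeds the usable window length are
structural zeros so every group has fixed dimensionality.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass

import numpy as np

from ..seqio import AMINO_ACIDS, PeptideWindow, WINDOW_LENGTH
from . import data as _data
from . import aaindex as _aaindex

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GROUP_ORDER = ("AAC", "DPC", "NMB", "MORAN", "GEARY", "CTD", "SOCN", "QSO",
               "PSE1", "PSE2", "AAIDX")


@dataclass(frozen=True)
class PropertyTable:
    """A named residue->value scale, optionally z-score normalized.

    After z-scoring the 20 values have mean 0 and population SD 1; 'X' maps
    to the mean (0).
    """

    name: str
    values: dict
    normalization: str = "zscore"

    def __post_init__(self):
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"{self.name}: missing residues {sorted(missing)}")
        if self.normalization not in ("none", "zscore"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def numeric(self) -> np.ndarray:
        """Values in AMINO_ACIDS order, normalized per the table's setting."""
        v = np.array([float(self.values[a]) for a in AMINO_ACIDS])
        if self.normalization == "zscore":
            sd = v.std()
            if sd == 0:
                raise ValueError(f"{self.name}: constant scale cannot be z-scored")
            v = (v - v.mean()) / sd
        return v

    def encode(self, window: PeptideWindow | str) -> np.ndarray:
        """Per-position property values; 'X' -> mean of the (normalized) scale."""
        v = self.numeric()
        fill = float(v.mean())
        sym = str(window)
        return np.array([v[_AA_INDEX[c]] if c != "X" else fill for c in sym])


@dataclass
class FeatureVector:
    names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    def __len__(self):
        return self.values.size

    @staticmethod
    def concat(parts: list["FeatureVector"]) -> "FeatureVector":
        names = list(itertools.chain.from_iterable(p.names for p in parts))
        values = np.concatenate([p.values for p in parts]) if parts else np.empty(0)
        return FeatureVector(names, values)


def _default_tables() -> list[PropertyTable]:
    return [PropertyTable(name, vals)
            for name, vals in _data.AUTOCORRELATION_SCALES.items()]


@dataclass
class DescriptorConfig:
    """Knobs for the descriptor groups; defaults follow the documented counts."""

    nlag_auto: int = 30
    maxlag_so: int = 30
    lambda1: int = 30
    lambda2: int = 15
    w_qso: float = 0.1
    w_pse: float = 0.05
    groups: tuple = GROUP_ORDER
    aaindex_ids: tuple | None = None  # None -> all complete vendored indices
    aaindex_path: str | None = None  # alternative AAindex1 flat file

    def __post_init__(self):
        for name in ("nlag_auto", "maxlag_so", "lambda1", "lambda2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("w_qso", "w_pse"):
            w = getattr(self, name)
            if not 0 < w <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        unknown = set(self.groups) - set(GROUP_ORDER)
        if unknown:
            raise ValueError(f"unknown descriptor groups {sorted(unknown)}")

    def aaindex_tables(self) -> dict:
        if self.aaindex_path is not None:
            entries = _aaindex.complete_indices(_aaindex.read_aaindex1(self.aaindex_path))
        else:
            entries = _aaindex.load_vendored()
        if self.aaindex_ids is not None:
            missing = set(self.aaindex_ids) - set(entries)
            if missing:
                raise ValueError(f"unknown/incomplete AAindex ids {sorted(missing)}")
            entries = {k: entries[k] for k in self.aaindex_ids}
        return entries

    def group_dims(self) -> dict:
        n_idx = len(self.aaindex_tables()) if "AAIDX" in self.groups else 0
        dims = {
            "AAC": 20, "DPC": 400,
            "NMB": 8 * self.nlag_auto, "MORAN": 8 * self.nlag_auto,
            "GEARY": 8 * self.nlag_auto,
            "CTD": 147,
            "SOCN": 2 * self.maxlag_so,
            "QSO": 2 * (20 + self.maxlag_so),
            "PSE1": 20 + self.lambda1, "PSE2": 20 + 2 * self.lambda2,
            "AAIDX": WINDOW_LENGTH * n_idx,
        }
        return {g: dims[g] for g in self.groups}

    @property
    def total_dim(self) -> int:
        return sum(self.group_dims().values())

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("nlag_auto", "maxlag_so", "lambda1", "lambda2", "w_qso", "w_pse")}
        d["groups"] = list(self.groups)
        d["aaindex_ids"] = None if self.aaindex_ids is None else list(self.aaindex_ids)
        d["aaindex_path"] = self.aaindex_path
        return json.dumps(d, indent=2)

    @staticmethod
    def from_json(text: str) -> "DescriptorConfig":
        d = json.loads(text)
        d["groups"] = tuple(d["groups"])
        if d.get("aaindex_ids") is not None:
            d["aaindex_ids"] = tuple(d["aaindex_ids"])
        return DescriptorConfig(**d)


def _symbols(window) -> str:
    return str(window) if isinstance(window, PeptideWindow) else str(PeptideWindow(window))


# --- group 1: compositions -------------------------------------------------

def aac(window) -> FeatureVector:
    """Frequencies of the 20 residues among the non-'X' window symbols."""
    sym = _symbols(window)
    counts = np.zeros(20)
    for c in sym:
        if c != "X":
            counts[_AA_INDEX[c]] += 1
    total = counts.sum()
    if total == 0:
        logger.warning("aac: all-'X' window, returning zeros")
        vals = counts
    else:
        vals = counts / total
    return FeatureVector([f"AAC_{a}" for a in AMINO_ACIDS], vals)


def dpc(window) -> FeatureVector:
    """Frequencies of ordered residue pairs over adjacent non-'X' pairs."""
    sym = _symbols(window)
    counts = np.zeros((20, 20))
    for a, b in zip(sym, sym[1:]):
        if a != "X" and b != "X":
            counts[_AA_INDEX[a], _AA_INDEX[b]] += 1
    total = counts.sum()
    if total == 0:
        logger.warning("dpc: fewer than two adjacent non-'X' residues, returning zeros")
        vals = counts
    else:
        vals = counts / total
    names = [f"DPC_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
    return FeatureVector(names, vals.ravel())


# --- group 2: autocorrelation ---------------------------------------------

_AC_TAGS = {"moreau-broto": "NMB", "moran": "MORAN", "geary": "GEARY"}


def autocorrelation(window, kind: str, properties: list | None = None,
                    nlag: int = 30) -> FeatureVector:
    """Moreau-Broto / Moran / Geary autocorrelation over z-scored scales.

    Lags with no usable residue pair (d >= window length) are zeros so the
    output dimensionality is |properties| * nlag regardless of content.
    """
    if kind not in _AC_TAGS:
        raise ValueError(f"unknown autocorrelation kind {kind!r}")
    tag = _AC_TAGS[kind]
    if properties is None:
        properties = _default_tables()
    sym = _symbols(window)
    L = len(sym)
    names, vals = [], []
    for table in properties:
        p = table.encode(sym)
        pbar = p.mean()
        dev = p - pbar
        ss = float(dev @ dev)
        for d in range(1, nlag + 1):
            names.append(f"{tag}_{table.name}_d{d}")
            if d >= L:
                vals.append(0.0)
                continue
            x, y = p[:-d], p[d:]
            if kind == "moreau-broto":
                vals.append(float(x @ y) / (L - d))
            elif kind == "moran":
                if ss == 0:
                    logger.warning("moran: constant property %s over window", table.name)
                    vals.append(0.0)
                else:
                    num = float(dev[:-d] @ dev[d:]) / (L - d)
                    vals.append(num / (ss / L))
            else:  # geary
                if ss == 0:
                    logger.warning("geary: constant property %s over window", table.name)
                    vals.append(0.0)
                else:
                    num = float(((x - y) ** 2).sum()) / (2 * (L - d))
                    vals.append(num / (ss / (L - 1)))
    return FeatureVector(names, np.array(vals))


# --- group 3: CTD -----------------------------------------------------------

_CTD_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)


def _class_of(attr_groups, residue):
    for g, members in enumerate(attr_groups, start=1):
        if residue in members:
            return g
    raise KeyError(residue)


def ctd(window) -> FeatureVector:
    """Composition (21), transition (21) and distribution (105) features.

    Computed on the window with 'X' symbols removed. For each attribute and
    class, distribution features are the window-relative positions of the
    first, 25%, 50%, 75% and last occurrence (rank max(1, ceil(q*n)) among
    the n occurrences); absent classes yield zeros.
    """
    sym = [c for c in _symbols(window) if c != "X"]
    n = len(sym)
    comp_names, comp_vals = [], []
    tran_names, tran_vals = [], []
    dist_names, dist_vals = [], []
    for attr, groups in _data.CTD_ATTRIBUTES.items():
        classes = [_class_of(groups, c) for c in sym]
        counts = [classes.count(g) for g in (1, 2, 3)]
        for g in (1, 2, 3):
            comp_names.append(f"CTD_C_{attr}_g{g}")
            comp_vals.append(counts[g - 1] / n if n else 0.0)
        pairs = list(zip(classes, classes[1:]))
        for ga, gb in ((1, 2), (1, 3), (2, 3)):
            tran_names.append(f"CTD_T_{attr}_g{ga}{gb}")
            if pairs:
                hits = sum(1 for a, b in pairs if {a, b} == {ga, gb})
                tran_vals.append(hits / len(pairs))
            else:
                tran_vals.append(0.0)
        for g in (1, 2, 3):
            positions = [i + 1 for i, c in enumerate(classes) if c == g]
            for q in _CTD_QUANTILES:
                dist_names.append(f"CTD_D_{attr}_g{g}_q{int(q * 100)}")
                if not positions:
                    dist_vals.append(0.0)
                else:
                    rank = max(1, math.ceil(q * len(positions)))
                    dist_vals.append(positions[rank - 1] / n)
    return FeatureVector(comp_names + tran_names + dist_names,
                         np.array(comp_vals + tran_vals + dist_vals))


# --- group 4: sequence order ------------------------------------------------

def sequence_order(window, maxlag: int = 30, w_qso: float = 0.1,
                   matrices: dict | None = None) -> FeatureVector:
    """Sequence-order-coupling numbers and quasi-sequence-order features.

    tau_d sums squared residue distances at lag d; the QSO block divides
    residue counts and weighted tau values by (sum f + w * sum tau).
    Distances involving 'X' are zero.
    """
    if matrices is None:
        matrices = _data.DISTANCE_MATRICES
    sym = _symbols(window)
    L = len(sym)
    counts = np.zeros(20)
    for c in sym:
        if c != "X":
            counts[_AA_INDEX[c]] += 1
    socn_names, socn_vals = [], []
    qso_names, qso_vals = [], []
    for mname, dist in matrices.items():
        taus = []
        for d in range(1, maxlag + 1):
            if d >= L:
                taus.append(0.0)
                continue
            t = 0.0
            for a, b in zip(sym[:-d], sym[d:]):
                if a != "X" and b != "X":
                    t += dist[(a, b)] ** 2
            taus.append(t)
        socn_names.extend(f"SOCN_{mname}_d{d}" for d in range(1, maxlag + 1))
        socn_vals.extend(taus)
        denom = counts.sum() + w_qso * sum(taus)
        if denom == 0:
            logger.warning("sequence_order: all-'X' window, QSO zeros")
            comp = np.zeros(20)
            order = [0.0] * maxlag
        else:
            comp = counts / denom
            order = [w_qso * t / denom for t in taus]
        qso_names.extend(f"QSO_{mname}_{a}" for a in AMINO_ACIDS)
        qso_vals.extend(comp.tolist())
        qso_names.extend(f"QSO_{mname}_d{d}" for d in range(1, maxlag + 1))
        qso_vals.extend(order)
    return FeatureVector(socn_names + qso_names, np.array(socn_vals + qso_vals))


# --- group 5: pseudo-amino-acid composition ---------------------------------

def pseaac(window, type: int = 1, lam: int | None = None, w: float = 0.05,
           scales: dict | None = None) -> FeatureVector:
    """Chou's pseudo-amino-acid composition, type I or II (amphiphilic).

    Type I: 20 composition terms + lam tier correlations averaging squared
    property differences. Type II: 20 + 2*lam terms from per-property
    products of z-scored values. Tiers with lag >= window length are zeros.
    """
    if type not in (1, 2):
        raise ValueError("pseaac type must be 1 or 2")
    if lam is None:
        lam = 30 if type == 1 else 15
    if scales is None:
        scales = _data.PSEAAC_TYPE1_SCALES if type == 1 else _data.PSEAAC_TYPE2_SCALES
    tables = [PropertyTable(name, vals) for name, vals in scales.items()]
    sym = _symbols(window)
    L = len(sym)
    enc = [t.encode(sym) for t in tables]
    counts = np.zeros(20)
    for c in sym:
        if c != "X":
            counts[_AA_INDEX[c]] += 1
    thetas: list[float] = []
    if type == 1:
        for d in range(1, lam + 1):
            if d >= L:
                thetas.append(0.0)
                continue
            theta = 0.0
            for p in enc:
                theta += float(((p[d:] - p[:-d]) ** 2).mean())
            thetas.append(theta / len(enc))
        tier_names = [f"PSE1_theta{d}" for d in range(1, lam + 1)]
        tag = "PSE1"
    else:
        for d in range(1, lam + 1):
            for t_i, p in enumerate(enc, start=1):
                if d >= L:
                    thetas.append(0.0)
                else:
                    thetas.append(float((p[:-d] * p[d:]).mean()))
        tier_names = [f"PSE2_tau{2 * (d - 1) + t}" for d in range(1, lam + 1)
                      for t in range(1, len(enc) + 1)]
        tag = "PSE2"
    denom = counts.sum() + w * sum(thetas)
    names = [f"{tag}_{a}" for a in AMINO_ACIDS] + tier_names
    if counts.sum() == 0:
        logger.warning("pseaac: all-'X' window, returning zeros")
        return FeatureVector(names, np.zeros(len(names)))
    comp = counts / denom
    tiers = np.array(thetas) * w / denom
    return FeatureVector(names, np.concatenate([comp, tiers]))


# --- group 6: AAindex encodings ---------------------------------------------

def aaindex_encode(window, tables: dict) -> FeatureVector:
    """Per-position z-scored property values; 'X' positions are 0.

    ``tables`` maps accession -> residue->value (complete over the 20 AAs).
    """
    sym = _symbols(window)
    names, vals = [], []
    for acc in tables:
        t = PropertyTable(acc, tables[acc], normalization="zscore")
        v = t.numeric()
        for pos, c in enumerate(sym, start=1):
            names.append(f"AAIDX_{acc}_p{pos}")
            vals.append(float(v[_AA_INDEX[c]]) if c != "X" else 0.0)
    return FeatureVector(names, np.array(vals))


# --- full extraction ---------------------------------------------------------

def extract_all(window, config: DescriptorConfig | None = None) -> FeatureVector:
    """Concatenation of the enabled groups in the fixed documented order."""
    if config is None:
        config = DescriptorConfig()
    parts = []
    enabled = set(config.groups)
    if "AAC" in enabled:
        parts.append(aac(window))
    if "DPC" in enabled:
        parts.append(dpc(window))
    tables = _default_tables()
    for kind in ("moreau-broto", "moran", "geary"):
        if _AC_TAGS[kind] in enabled:
            parts.append(autocorrelation(window, kind, tables, config.nlag_auto))
    if "CTD" in enabled:
        parts.append(ctd(window))
    if "SOCN" in enabled or "QSO" in enabled:
        so = sequence_order(window, config.maxlag_so, config.w_qso)
        keep = [i for i, n in enumerate(so.names)
                if (n.startswith("SOCN") and "SOCN" in enabled)
                or (n.startswith("QSO") and "QSO" in enabled)]
        parts.append(FeatureVector([so.names[i] for i in keep], so.values[keep]))
    if "PSE1" in enabled:
        parts.append(pseaac(window, 1, config.lambda1, config.w_pse))
    if "PSE2" in enabled:
        parts.append(pseaac(window, 2, config.lambda2, config.w_pse))
    if "AAIDX" in enabled:
        parts.append(aaindex_encode(window, config.aaindex_tables()))
    return FeatureVector.concat(parts)


def feature_matrix(windows: dict, config: DescriptorConfig | None = None):
    """Feature table for ``{key: PeptideWindow}``; rows keyed, columns named.

    Returns a pandas DataFrame indexed by key.
    """
    import pandas as pd

    if config is None:
        config = DescriptorConfig()
    keys = list(windows)
    rows = [extract_all(windows[k], config) for k in keys]
    names = rows[0].names if rows else []
    mat = np.vstack([r.values for r in rows]) if rows else np.empty((0, 0))
    return pd.DataFrame(mat, index=keys, columns=names)
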