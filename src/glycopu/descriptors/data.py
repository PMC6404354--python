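"""Vendored amino-acid property scales, CTD partitions and distance matrices.

All scales are transcribed from the primary literature (see each entry);
they are exposed as plain dicts keyed by one-letter residue code so users
can swap in their own tables. Distance matrices are *derived* here from
their published formulas rather than hard-coded, which keeps them auditable.
"""

from __future__ import annotations

import math

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte & Doolittle (1982) hydropathy.
HYDROPATHY_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Hopp & Woods (1981) hydrophilicity.
HYDROPHILICITY_HW = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
    "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
    "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
    "Y": -2.3, "V": -1.5,
}

# Eisenberg et al. (1984) consensus hydrophobicity.
HYDROPHOBICITY_EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}

# Grantham (1974) polarity (p), volume (v) and composition (c) columns.
POLARITY_GRANTHAM = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}
VOLUME_GRANTHAM = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
}
COMPOSITION_GRANTHAM = {
    "A": 0.0, "R": 0.65, "N": 1.33, "D": 1.38, "C": 2.75, "Q": 0.89,
    "E": 0.92, "G": 0.74, "H": 0.58, "I": 0.0, "L": 0.0, "K": 0.33,
    "M": 0.0, "F": 0.0, "P": 0.39, "S": 1.42, "T": 0.71, "W": 0.13,
    "Y": 0.20, "V": 0.0,
}

# Zimmerman et al. (1968) isoelectric point.
ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.05, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.66, "W": 5.89,
    "Y": 5.66, "V": 5.96,
}

# Fasman (1976) molecular weight of the free amino acid.
MOLECULAR_WEIGHT = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.15,
    "Q": 146.15, "E": 147.13, "G": 75.07, "H": 155.16, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.24, "Y": 181.19, "V": 117.15,
}

# Average residue mass minus the glycine residue sans its H side chain,
# i.e. the side-chain mass used by pseudo-amino-acid composition.
_GLY_BACKBONE = 57.05 - 1.01
SIDE_CHAIN_MASS = {
    aa: round({
        "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
        "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
        "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
        "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
    }[aa] - _GLY_BACKBONE, 2)
    for aa in AMINO_ACIDS
}

#: default 8-scale set for the autocorrelation descriptors
AUTOCORRELATION_SCALES = {
    "hydropathy": HYDROPATHY_KD,
    "hydrophilicity": HYDROPHILICITY_HW,
    "hydrophobicity": HYDROPHOBICITY_EISENBERG,
    "polarity": POLARITY_GRANTHAM,
    "volume": VOLUME_GRANTHAM,
    "composition": COMPOSITION_GRANTHAM,
    "isoelectric": ISOELECTRIC_POINT,
    "molweight": MOLECULAR_WEIGHT,
}

#: pseudo-amino-acid composition property sets (Chou's convention)
PSEAAC_TYPE1_SCALES = {
    "hydrophobicity": HYDROPHOBICITY_EISENBERG,
    "hydrophilicity": HYDROPHILICITY_HW,
    "sidechainmass": SIDE_CHAIN_MASS,
}
PSEAAC_TYPE2_SCALES = {
    "hydrophobicity": HYDROPHOBICITY_EISENBERG,
    "hydrophilicity": HYDROPHILICITY_HW,
}

# --- CTD: the standard seven 3-class physicochemical partitions ----------

CTD_ATTRIBUTES = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


def _check_partitions():
    for name, groups in CTD_ATTRIBUTES.items():
        merged = "".join(groups)
        if sorted(merged) != sorted(AMINO_ACIDS):
            raise AssertionError(f"CTD attribute {name} does not partition the alphabet")


_check_partitions()

# --- distance matrices ----------------------------------------------------


def grantham_distance_matrix() -> dict[tuple[str, str], float]:
    """Grantham (1974) chemical distance, recomputed from its definition.

    D_ij = rho * [alpha (c_i-c_j)^2 + beta (p_i-p_j)^2 + gamma (v_i-v_j)^2]^0.5
    with alpha=1.833, beta=0.1018, gamma=0.000399 and rho chosen so the mean
    over residue pairs is 100, which reproduces the published integer table
    to rounding.
    """
    alpha, beta, gamma = 1.833, 0.1018, 0.000399
    raw = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            d = math.sqrt(
                alpha * (COMPOSITION_GRANTHAM[a] - COMPOSITION_GRANTHAM[b]) ** 2
                + beta * (POLARITY_GRANTHAM[a] - POLARITY_GRANTHAM[b]) ** 2
                + gamma * (VOLUME_GRANTHAM[a] - VOLUME_GRANTHAM[b]) ** 2
            )
            raw[(a, b)] = d
    off = [raw[(a, b)] for a in AMINO_ACIDS for b in AMINO_ACIDS if a != b]
    rho = 100.0 / (sum(off) / len(off))
    return {k: v * rho for k, v in raw.items()}


def physicochemical_distance_matrix() -> dict[tuple[str, str], float]:
    """Euclidean distance in z-scored (hydropathy, polarity, volume) space.

    Stand-in for a second published residue-distance scale; scaled so the
    mean off-diagonal distance is 100, matching the Grantham convention.
    """
    import statistics

    def zscore(table):
        vals = [table[a] for a in AMINO_ACIDS]
        mu = statistics.fmean(vals)
        sd = statistics.pstdev(vals)
        return {a: (table[a] - mu) / sd for a in AMINO_ACIDS}

    scales = [zscore(HYDROPATHY_KD), zscore(POLARITY_GRANTHAM), zscore(VOLUME_GRANTHAM)]
    raw = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            raw[(a, b)] = math.sqrt(sum((s[a] - s[b]) ** 2 for s in scales))
    off = [raw[(a, b)] for a in AMINO_ACIDS for b in AMINO_ACIDS if a != b]
    rho = 100.0 / (sum(off) / len(off))
    return {k: v * rho for k, v in raw.items()}


#: the two matrices used by the sequence-order descriptors, in fixed order
DISTANCE_MATRICES = {
    "grantham": grantham_distance_matrix(),
    "physchem": physicochemical_distance_matrix(),
}
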