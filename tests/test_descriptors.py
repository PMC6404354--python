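"""Descriptor unit tests.

The oracle helpers below are deliberate re-derivations of each formula with
plain double loops over the window symbols; they share nothing with the
implementation except the vendored property values.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycopu import descriptors as D
from glycopu.descriptors import data as pdata
from glycopu.descriptors.aaindex import complete_indices, read_aaindex1
from glycopu.seqio import AMINO_ACIDS, PeptideWindow

windows_no_x = st.text(alphabet=AMINO_ACIDS, min_size=15, max_size=15)


def zscored(table):
    vals = np.array([table[a] for a in AMINO_ACIDS])
    return {a: (table[a] - vals.mean()) / vals.std() for a in AMINO_ACIDS}


def encode(window, ztable):
    return np.array([ztable[c] if c != "X" else 0.0 for c in str(window)])


# ---------------------------------------------------------------- oracles

def oracle_moreau_broto(p, d):
    L = len(p)
    if d >= L:
        return 0.0
    acc = sum(p[i] * p[i + d] for i in range(L - d))
    return acc / (L - d)


def oracle_moran(p, d):
    L = len(p)
    if d >= L:
        return 0.0
    pbar = sum(p) / L
    ss = sum((x - pbar) ** 2 for x in p)
    if ss == 0:
        return 0.0
    num = sum((p[i] - pbar) * (p[i + d] - pbar) for i in range(L - d)) / (L - d)
    return num / (ss / L)


def oracle_geary(p, d):
    L = len(p)
    if d >= L:
        return 0.0
    pbar = sum(p) / L
    ss = sum((x - pbar) ** 2 for x in p)
    if ss == 0:
        return 0.0
    num = sum((p[i] - p[i + d]) ** 2 for i in range(L - d)) / (2 * (L - d))
    return num / (ss / (L - 1))


def oracle_tau(window, dist, d):
    sym = str(window)
    L = len(sym)
    if d >= L:
        return 0.0
    total = 0.0
    for i in range(L - d):
        a, b = sym[i], sym[i + d]
        if a != "X" and b != "X":
            total += dist[(a, b)] ** 2
    return total


def oracle_ctd_distribution(window, groups):
    """positions of 1st/25/50/75/100% occurrence per class / length."""
    sym = [c for c in str(window) if c != "X"]
    n = len(sym)
    out = []
    for g in (1, 2, 3):
        members = groups[g - 1]
        occ = [i + 1 for i, c in enumerate(sym) if c in members]
        for q in (0.0, 0.25, 0.5, 0.75, 1.0):
            if not occ:
                out.append(0.0)
            else:
                rank = max(1, math.ceil(q * len(occ)))
                out.append(occ[rank - 1] / n)
    return out


def oracle_pse1(window, lam, w):
    sym = str(window)
    L = len(sym)
    scales = [zscored(t) for t in pdata.PSEAAC_TYPE1_SCALES.values()]
    counts = {a: sym.count(a) for a in AMINO_ACIDS}
    thetas = []
    for d in range(1, lam + 1):
        if d >= L:
            thetas.append(0.0)
            continue
        acc = 0.0
        for i in range(L - d):
            a, b = sym[i], sym[i + d]
            va = [z[a] if a != "X" else 0.0 for z in scales]
            vb = [z[b] if b != "X" else 0.0 for z in scales]
            acc += sum((x - y) ** 2 for x, y in zip(va, vb)) / len(scales)
        thetas.append(acc / (L - d))
    denom = sum(counts.values()) + w * sum(thetas)
    comp = [counts[a] / denom for a in AMINO_ACIDS]
    tiers = [w * t / denom for t in thetas]
    return np.array(comp + tiers)


def oracle_pse2(window, lam, w):
    sym = str(window)
    L = len(sym)
    scales = [zscored(t) for t in pdata.PSEAAC_TYPE2_SCALES.values()]
    counts = {a: sym.count(a) for a in AMINO_ACIDS}
    taus = []
    for d in range(1, lam + 1):
        for z in scales:
            if d >= L:
                taus.append(0.0)
                continue
            acc = 0.0
            for i in range(L - d):
                a, b = sym[i], sym[i + d]
                acc += (z[a] if a != "X" else 0.0) * (z[b] if b != "X" else 0.0)
            taus.append(acc / (L - d))
    denom = sum(counts.values()) + w * sum(taus)
    comp = [counts[a] / denom for a in AMINO_ACIDS]
    return np.array(comp + [w * t / denom for t in taus])


# ------------------------------------------------------------------ tests

class TestPropertyTable:
    def test_zscore_mean_sd(self):
        t = D.PropertyTable("hyd", pdata.HYDROPATHY_KD)
        v = t.numeric()
        assert abs(v.mean()) < 1e-9
        assert abs(v.std() - 1.0) < 1e-9

    def test_missing_residue_rejected(self):
        vals = dict(pdata.HYDROPATHY_KD)
        del vals["W"]
        with pytest.raises(ValueError, match="missing"):
            D.PropertyTable("bad", vals)

    def test_x_maps_to_mean(self):
        t = D.PropertyTable("hyd", pdata.HYDROPATHY_KD)
        enc = t.encode(PeptideWindow("X" * 15))
        assert np.allclose(enc, 0.0, atol=1e-12)


class TestCompositions:
    def test_aac_homopolymer(self):
        fv = D.aac(PeptideWindow("A" * 15))
        vals = dict(zip(fv.names, fv.values))
        assert vals["AAC_A"] == 1.0
        assert fv.values.sum() == 1.0

    def test_aac_with_padding(self):
        fv = D.aac(PeptideWindow("XXXXXXXNVSAXXXX"))
        vals = dict(zip(fv.names, fv.values))
        for aa in "NVSA":
            assert vals[f"AAC_{aa}"] == 0.25

    def test_aac_dimension(self, random_windows):
        for w in random_windows(5, with_x=True):
            assert len(D.aac(w)) == 20

    def test_aac_all_x_zeros(self):
        fv = D.aac(PeptideWindow("X" * 15))
        assert fv.values.sum() == 0.0

    def test_dpc_homopolymer(self):
        fv = D.dpc(PeptideWindow("A" * 15))
        assert dict(zip(fv.names, fv.values))["DPC_AA"] == 1.0

    def test_dpc_alternating(self):
        fv = D.dpc(PeptideWindow("ACACACACACACACA"))
        vals = dict(zip(fv.names, fv.values))
        assert vals["DPC_AC"] == pytest.approx(0.5)
        assert vals["DPC_CA"] == pytest.approx(0.5)

    def test_dpc_dimension(self, random_windows):
        assert all(len(D.dpc(w)) == 400 for w in random_windows(5))

    @given(w=windows_no_x)
    @settings(max_examples=50, deadline=None)
    def test_compositions_sum_to_one_without_x(self, w):
        assert D.aac(w).values.sum() == pytest.approx(1.0, abs=1e-12)
        assert D.dpc(w).values.sum() == pytest.approx(1.0, abs=1e-12)


class TestAutocorrelation:
    def test_constant_property_moreau_broto_closed_form(self):
        t = D.PropertyTable("const", {a: 2.0 for a in AMINO_ACIDS},
                            normalization="none")
        fv = D.autocorrelation(PeptideWindow("ACDEFGHIKLMNPQR"),
                               "moreau-broto", [t], nlag=10)
        assert np.allclose(fv.values, 4.0)

    def test_constant_property_moran_geary_zero(self):
        t = D.PropertyTable("const", {a: 2.0 for a in AMINO_ACIDS},
                            normalization="none")
        for kind in ("moran", "geary"):
            fv = D.autocorrelation(PeptideWindow("ACDEFGHIKLMNPQR"), kind,
                                   [t], nlag=5)
            assert np.allclose(fv.values, 0.0)

    def test_default_dimension_240(self, random_windows):
        w = random_windows(1)[0]
        for kind in ("moreau-broto", "moran", "geary"):
            assert len(D.autocorrelation(w, kind)) == 240

    def test_matches_bruteforce_oracle(self, random_windows):
        oracles = {"moreau-broto": oracle_moreau_broto, "moran": oracle_moran,
                   "geary": oracle_geary}
        tables = [D.PropertyTable(n, v)
                  for n, v in pdata.AUTOCORRELATION_SCALES.items()]
        ztabs = [zscored(v) for v in pdata.AUTOCORRELATION_SCALES.values()]
        for w in random_windows(100, with_x=True):
            encs = [encode(w, z) for z in ztabs]
            for kind, oracle in oracles.items():
                fv = D.autocorrelation(w, kind, tables, nlag=20)
                expected = [oracle(list(p), d)
                            for p in encs for d in range(1, 21)]
                assert np.allclose(fv.values, expected, atol=1e-10)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            D.autocorrelation(PeptideWindow("A" * 15), "sliding")


class TestCTD:
    def test_single_class_window(self):
        # all residues hydrophobic (class 3 of the hydrophobicity attribute)
        fv = D.ctd(PeptideWindow("CLVIMFWCLVIMFWC"))
        vals = dict(zip(fv.names, fv.values))
        assert vals["CTD_C_hydrophobicity_g3"] == 1.0
        assert vals["CTD_C_hydrophobicity_g1"] == 0.0
        for pair in ("g12", "g13", "g23"):
            assert vals[f"CTD_T_hydrophobicity_{pair}"] == 0.0

    def test_dimension_147(self, random_windows):
        assert all(len(D.ctd(w)) == 147 for w in random_windows(5, with_x=True))

    def test_distribution_matches_oracle(self, random_windows):
        for w in random_windows(100, with_x=True):
            fv = D.ctd(w)
            vals = dict(zip(fv.names, fv.values))
            for attr, groups in pdata.CTD_ATTRIBUTES.items():
                expected = oracle_ctd_distribution(w, groups)
                got = [vals[f"CTD_D_{attr}_g{g}_q{q}"]
                       for g in (1, 2, 3) for q in (0, 25, 50, 75, 100)]
                assert got == pytest.approx(expected, abs=1e-12)

    def test_absent_class_zeros(self):
        fv = D.ctd(PeptideWindow("A" * 15))  # no charged residues
        vals = dict(zip(fv.names, fv.values))
        assert all(vals[f"CTD_D_charge_g1_q{q}"] == 0.0
                   for q in (0, 25, 50, 75, 100))


class TestSequenceOrder:
    def test_identical_residues_zero_tau(self):
        fv = D.sequence_order(PeptideWindow("A" * 15))
        vals = dict(zip(fv.names, fv.values))
        socn = [v for n, v in vals.items() if n.startswith("SOCN")]
        order = [v for n, v in vals.items()
                 if n.startswith("QSO") and "_d" in n]
        assert np.allclose(socn, 0.0)
        assert np.allclose(order, 0.0)

    def test_dimensions(self, random_windows):
        fv = D.sequence_order(random_windows(1)[0])
        socn = [n for n in fv.names if n.startswith("SOCN")]
        qso = [n for n in fv.names if n.startswith("QSO")]
        assert len(socn) == 60
        assert len(qso) == 100

    def test_tau_matches_oracle(self, random_windows):
        for w in random_windows(100, with_x=True):
            fv = D.sequence_order(w, maxlag=10)
            vals = dict(zip(fv.names, fv.values))
            for mname, dist in pdata.DISTANCE_MATRICES.items():
                for d in range(1, 11):
                    assert vals[f"SOCN_{mname}_d{d}"] == pytest.approx(
                        oracle_tau(w, dist, d), rel=1e-10)

    def test_qso_normalization(self, random_windows):
        # composition + order terms sum to 1 per matrix on X-free windows
        w = PeptideWindow("ACDEFGHIKLMNPQR")
        fv = D.sequence_order(w)
        vals = dict(zip(fv.names, fv.values))
        for mname in pdata.DISTANCE_MATRICES:
            qso = [v for n, v in vals.items() if n.startswith(f"QSO_{mname}_")]
            taus = [vals[f"SOCN_{mname}_d{d}"] for d in range(1, 31)]
            denom = 15 + 0.1 * sum(taus)
            assert sum(qso) == pytest.approx((15 + 0.1 * sum(taus)) / denom)


class TestPseAAC:
    def test_weight_zero_limit_equals_aac(self):
        w = PeptideWindow("ACDEFGHIKLMNPQR")
        aac_vals = D.aac(w).values
        for typ in (1, 2):
            fv = D.pseaac(w, typ, w=1e-12)
            assert np.allclose(fv.values[:20], aac_vals, atol=1e-9)

    def test_output_lengths(self, random_windows):
        w = random_windows(1)[0]
        assert len(D.pseaac(w, 1)) == 50
        assert len(D.pseaac(w, 2)) == 50

    def test_matches_direct_formula(self, random_windows):
        for w in random_windows(100, with_x=True):
            got1 = D.pseaac(w, 1, lam=10, w=0.05).values
            assert np.allclose(got1, oracle_pse1(w, 10, 0.05), atol=1e-10)
            got2 = D.pseaac(w, 2, lam=6, w=0.05).values
            assert np.allclose(got2, oracle_pse2(w, 6, 0.05), atol=1e-10)

    def test_bad_type(self):
        with pytest.raises(ValueError):
            D.pseaac(PeptideWindow("A" * 15), 3)


class TestAAindex:
    def test_vendored_snapshot_loads(self):
        from glycopu.descriptors.aaindex import load_vendored

        tables = load_vendored()
        assert len(tables) >= 8
        assert all(len(v) == 20 for v in tables.values())

    def test_na_entries_excluded(self):
        text = (
            "H FAKE000001\nD fake with NA\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
            + "   1.0" * 9 + "      NA\n" + "   1.0" * 10 + "\n//\n"
            "H FAKE000002\nD complete\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
            + "   1.0" * 10 + "\n" + "   2.0" * 10 + "\n//\n"
        )
        import io

        entries = read_aaindex1(io.StringIO(text))
        complete = complete_indices(entries)
        assert set(complete) == {"FAKE000002"}

    def test_all_x_window_zero_block(self):
        from glycopu.descriptors.aaindex import load_vendored

        fv = D.aaindex_encode(PeptideWindow("X" * 15), load_vendored())
        assert np.allclose(fv.values, 0.0)

    def test_single_index_hand_check(self):
        table = {"FAKE": {a: (1.0 if a == "A" else 0.0) for a in AMINO_ACIDS}}
        fv = D.aaindex_encode(PeptideWindow("A" * 7 + "C" + "A" * 7), table)
        vals = np.array([1.0 if a == "A" else 0.0 for a in AMINO_ACIDS])
        z = (vals - vals.mean()) / vals.std()
        expected = [z[0]] * 7 + [z[AMINO_ACIDS.index("C")]] + [z[0]] * 7
        assert np.allclose(fv.values, expected, atol=1e-12)

    def test_dimension_is_15_per_index(self):
        from glycopu.descriptors.aaindex import load_vendored

        tables = load_vendored()
        fv = D.aaindex_encode(PeptideWindow("A" * 15), tables)
        assert len(fv) == 15 * len(tables)


class TestExtractAll:
    def test_default_total_matches_group_sum(self, random_windows):
        cfg = D.DescriptorConfig()
        w = random_windows(1)[0]
        fv = D.extract_all(w, cfg)
        assert len(fv) == cfg.total_dim
        assert len(fv) == sum(cfg.group_dims().values())

    def test_aac_only(self):
        cfg = D.DescriptorConfig(groups=("AAC",))
        assert len(D.extract_all(PeptideWindow("A" * 15), cfg)) == 20

    def test_deterministic(self, random_windows):
        w = random_windows(1)[0]
        a = D.extract_all(w)
        b = D.extract_all(w)
        assert a.names == b.names
        assert np.array_equal(a.values, b.values)

    def test_window_only_dependence(self):
        # descriptors see only the 15 symbols, not the source protein
        from glycopu.seqio import ProteinRecord, extract_window

        core = "ACDEFGHNVSAPQKL"
        p1 = ProteinRecord("a", core)
        p2 = ProteinRecord("b", "MMMMMMM" + core + "WWWWWWW")
        w1 = extract_window(p1, 8)
        w2 = extract_window(p2, 15)
        assert w1.symbols == w2.symbols
        assert np.array_equal(D.extract_all(w1).values, D.extract_all(w2).values)

    def test_config_json_roundtrip(self):
        cfg = D.DescriptorConfig(nlag_auto=10, groups=("AAC", "CTD"))
        back = D.DescriptorConfig.from_json(cfg.to_json())
        assert back == cfg

    def test_group_sizes_documented(self):
        dims = D.DescriptorConfig().group_dims()
        assert (dims["AAC"], dims["DPC"]) == (20, 400)
        assert dims["NMB"] == dims["MORAN"] == dims["GEARY"] == 240
        assert dims["CTD"] == 147
        assert (dims["SOCN"], dims["QSO"]) == (60, 100)
        assert dims["PSE1"] == dims["PSE2"] == 50

    def test_feature_matrix(self, random_windows):
        ws = {f"p:{i}": w for i, w in enumerate(random_windows(3))}
        cfg = D.DescriptorConfig(groups=("AAC", "CTD"))
        frame = D.feature_matrix(ws, cfg)
        assert frame.shape == (3, 167)
        assert list(frame.index) == list(ws)
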