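"""Fingerprints, rank transforms and similarity metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibroscreen.errors import (
    AssemblyError,
    ConfigurationError,
    DimensionError,
    InsufficientOverlapError,
    SmilesParseError,
    UndefinedCorrelationError,
)
from fibroscreen.featurize import (
    ExpressionProfile,
    GeneIdMap,
    N_MACCS_BITS,
    StructuralFingerprint,
    assemble_matrix,
    harmonize_ids,
    quantile_rank_transform,
    smiles_to_maccs,
    spearman,
    tanimoto,
)
from fibroscreen.synthetic import bundled_smiles


def profile(values, sample_id="s", ids=None, id_space="symbol"):
    idx = ids if ids is not None else [f"g{i}" for i in range(len(values))]
    return ExpressionProfile(
        sample_id=sample_id, compound_id=None, id_space=id_space,
        values=pd.Series(values, index=idx, dtype=float),
    )


# ---------------------------------------------------------------------------
# MACCS fingerprints
# ---------------------------------------------------------------------------


class TestMACCS:
    def test_length_and_alphabet(self):
        fp = smiles_to_maccs("CCO")
        assert fp.bits.shape == (N_MACCS_BITS,)
        assert set(np.unique(fp.bits)) <= {0, 1}

    def test_same_molecule_same_fingerprint(self):
        assert np.array_equal(
            smiles_to_maccs("OCC").bits, smiles_to_maccs("CCO").bits
        )

    def test_unparseable_smiles_raises(self):
        with pytest.raises(SmilesParseError, match="xyz"):
            smiles_to_maccs("xyz((")
        with pytest.raises(SmilesParseError):
            smiles_to_maccs("")

    def test_benzene_sets_aromatic_ring_bits(self):
        fp = smiles_to_maccs("c1ccccc1")
        # MACCS key 163 is the generic 6-membered-ring key, 162 aromaticity
        assert fp.bits[162] == 1  # key 163
        assert fp.bits[161] == 1  # key 162

    def test_matches_substructure_pattern_oracle(self):
        """Cross-check each bit against an independent evaluation of the
        published MACCS SMARTS dictionary (pattern matched via generic
        substructure search with its count threshold)."""
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys

        molecules = dict(list(bundled_smiles().items())[:20])
        for name, smi in molecules.items():
            mol = Chem.MolFromSmiles(smi)
            fp = smiles_to_maccs(smi)
            for key, (smarts, count) in MACCSkeys.smartsPatts.items():
                if smarts == "?":
                    continue  # keys implemented procedurally, no pattern
                patt = Chem.MolFromSmarts(smarts)
                if count == 0:
                    expected = mol.HasSubstructMatch(patt)
                else:
                    expected = len(mol.GetSubstructMatches(patt)) > count
                assert fp.bits[key - 1] == int(expected), (name, key)

    def test_rejects_wrong_length(self):
        with pytest.raises(DimensionError):
            StructuralFingerprint(None, np.zeros(100, dtype=np.uint8))


class TestTanimoto:
    def test_identical_nonzero_is_one(self):
        fp = smiles_to_maccs("CCO")
        assert tanimoto(fp, fp) == 1.0

    def test_small_example(self):
        a = np.zeros(166, dtype=np.uint8)
        b = np.zeros(166, dtype=np.uint8)
        a[[0, 1, 2]] = 1
        b[[1, 2, 3]] = 1
        assert tanimoto(a, b) == pytest.approx(0.5)

    def test_disjoint_is_zero_and_all_zero_convention(self):
        a = np.zeros(166, dtype=np.uint8)
        b = np.zeros(166, dtype=np.uint8)
        a[:5] = 1
        b[5:10] = 1
        assert tanimoto(a, b) == 0.0
        assert tanimoto(np.zeros(166), np.zeros(166)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            tanimoto(np.zeros(166), np.zeros(100))

    def test_equals_set_arithmetic_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a = (rng.random(166) < 0.3).astype(np.uint8)
            b = (rng.random(166) < 0.3).astype(np.uint8)
            sa, sb = set(np.flatnonzero(a)), set(np.flatnonzero(b))
            expect = len(sa & sb) / len(sa | sb) if (sa | sb) else 0.0
            assert tanimoto(a, b) == pytest.approx(expect, abs=1e-15)
            assert tanimoto(a, b) == tanimoto(b, a)


# ---------------------------------------------------------------------------
# Rank transform
# ---------------------------------------------------------------------------


class TestQuantileRankTransform:
    def test_simple_values(self):
        rp = quantile_rank_transform(profile([5.0, 1.0, 3.0]))
        assert list(rp.values) == [1.0, 0.0, 0.5]

    def test_tied_values_share_average_rank(self):
        rp = quantile_rank_transform(profile([2.0, 2.0, 7.0]))
        assert list(rp.values) == pytest.approx([0.25, 0.25, 1.0])

    def test_monotone_invariance(self):
        vals = [3.0, 8.0, 1.0, 5.5, 5.5]
        a = quantile_rank_transform(profile(vals))
        b = quantile_rank_transform(profile(list(np.log(vals))))
        assert list(a.values) == pytest.approx(list(b.values))

    def test_constant_profile_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            rp = quantile_rank_transform(profile([4.0, 4.0, 4.0]))
        assert list(rp.values) == [0.5, 0.5, 0.5]

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2, max_size=40,
        )
    )
    def test_range_order_and_idempotence(self, vals):
        rp = quantile_rank_transform(profile(vals))
        q = rp.values.to_numpy()
        assert ((q >= 0) & (q <= 1)).all()
        v = np.asarray(vals)
        # order preservation (ties share a value)
        for i in range(len(v)):
            for j in range(len(v)):
                if v[i] < v[j]:
                    assert q[i] < q[j]
                elif v[i] == v[j]:
                    assert q[i] == q[j]
        # transforming the rank profile reproduces it
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = quantile_rank_transform(
                profile(list(q))
            ).values.to_numpy()
        assert np.allclose(again, q)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def brute_spearman(a, b):
    """Oracle: average ranks then plain Pearson."""

    def avg_rank(x):
        x = np.asarray(x)
        order = np.argsort(x, kind="stable")
        r = np.empty(len(x))
        i = 0
        sx = x[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    ra, rb = avg_rank(a), avg_rank(b)
    ra, rb = ra - ra.mean(), rb - rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


class TestSpearman:
    def test_identical_and_reversed(self):
        a = profile([1.0, 5.0, 3.0, 2.0])
        assert spearman(a, a) == pytest.approx(1.0)
        b = profile([4.0, 0.0, 2.0, 3.0])
        assert spearman(a, b) == pytest.approx(-1.0)

    def test_tied_example_by_hand(self):
        # ranks of a: (1, 2.5, 2.5); of b: (1, 2, 3) -> r = 3/(2*sqrt(3))
        a = profile([1.0, 2.0, 2.0])
        b = profile([1.0, 2.0, 3.0])
        assert spearman(a, b) == pytest.approx(3 / (2 * np.sqrt(3)))

    def test_computed_on_gene_intersection(self):
        a = profile([1.0, 2.0, 3.0, 4.0], ids=["g1", "g2", "g3", "g4"])
        b = profile([9.0, 1.0, 2.0, 3.0], ids=["g0", "g1", "g2", "g3"])
        # shared genes g1..g3 are perfectly concordant
        assert spearman(a, b) == pytest.approx(1.0)

    def test_insufficient_overlap(self):
        a = profile([1.0, 2.0], ids=["g1", "g2"])
        b = profile([1.0, 2.0], ids=["g2", "g3"])
        with pytest.raises(InsufficientOverlapError):
            spearman(a, b)

    def test_zero_variance_is_undefined(self):
        a = profile([1.0, 1.0, 1.0])
        b = profile([1.0, 2.0, 3.0])
        with pytest.raises(UndefinedCorrelationError):
            spearman(a, b)

    def test_agrees_with_brute_force_on_random_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            a = rng.integers(0, 6, n).astype(float)
            b = rng.integers(0, 6, n).astype(float)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            got = spearman(profile(a), profile(b))
            assert got == pytest.approx(brute_spearman(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# ID harmonization and matrix assembly
# ---------------------------------------------------------------------------


class TestHarmonize:
    def map_(self):
        return GeneIdMap(
            probe_to_entrez={"p1": "11", "p2": "11", "p3": "22"},
            entrez_to_symbol={"11": "AA", "22": "BB"},
        )

    def test_many_to_one_collapsed_by_mean(self):
        prof = profile([2.0, 4.0, 9.0], ids=["p1", "p2", "p3"], id_space="probe")
        out = harmonize_ids(prof, self.map_(), "symbol")
        assert out.values["AA"] == pytest.approx(3.0)
        assert out.values["BB"] == pytest.approx(9.0)

    def test_identity_when_already_in_target_space(self):
        prof = profile([1.0, 2.0, 3.0])
        assert harmonize_ids(prof, self.map_(), "symbol") is prof

    def test_unmapped_ids_dropped_with_warning(self):
        ids = [f"p{i}" for i in range(1, 4)] + [f"x{i}" for i in range(2)]
        prof = profile([1.0] * 3 + [9.0, 9.0], ids=ids, id_space="probe")
        with pytest.warns(UserWarning, match="2 of 5"):
            out = harmonize_ids(prof, self.map_(), "entrez")
        assert len(out.values) == 2  # p1+p2 -> 11, p3 -> 22

    def test_empty_mapping_is_configuration_error(self):
        prof = profile([1.0, 2.0], ids=["p1", "p2"], id_space="probe")
        with pytest.raises(ConfigurationError):
            harmonize_ids(prof, GeneIdMap(), "entrez")


class TestAssembleMatrix:
    def test_structural_stack(self):
        fps = [smiles_to_maccs(s, compound_id=f"c{i}")
               for i, s in enumerate(["CCO", "c1ccccc1", "CC(=O)O"])]
        fm = assemble_matrix(fps, "structural")
        assert fm.values.shape == (3, 166)
        assert fm.feature_ids[0] == "maccs_1"
        assert fm.sample_ids == ["c0", "c1", "c2"]

    def test_biological_intersection_reported(self):
        a = quantile_rank_transform(
            profile([1.0, 2.0, 3.0, 4.0, 5.0], "s1", ids=list("abcde"))
        )
        b = quantile_rank_transform(
            profile([5.0, 4.0, 3.0, 2.0], "s2", ids=list("abcd"))
        )
        fm = assemble_matrix([a, b], "biological")
        assert fm.feature_ids == list("abcd")
        assert fm.dropped_features == ["e"]

    def test_empty_input_and_empty_overlap(self):
        with pytest.raises(AssemblyError):
            assemble_matrix([], "structural")
        a = quantile_rank_transform(profile([1.0, 2.0], "s1", ids=["a", "b"]))
        b = quantile_rank_transform(profile([1.0, 2.0], "s2", ids=["c", "d"]))
        with pytest.raises(AssemblyError, match="intersection"):
            assemble_matrix([a, b], "biological")
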