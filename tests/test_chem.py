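import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from tadfscreen.chem import (
    EmptyLibraryError,
    MoleculeRecord,
    ParseError,
    ScaffoldError,
    aromatic_ch_sites,
    canonicalize,
    fingerprint,
    mean_aromatic_ch,
    sas_score,
    skeleton_frequencies,
    skeletons,
    tanimoto,
)

BENZENE = "c1ccccc1"
BIPHENYL = "c1ccc(-c2ccccc2)cc1"
PYRIDINE = "c1ccncc1"
TOLUENE = "Cc1ccccc1"


class TestCanonicalize:
    @pytest.mark.parametrize(
        "a,b",
        [
            ("C1=CC=CC=C1", "c1ccccc1"),
            ("c1ccc(cc1)c1ccccc1", BIPHENYL),
            ("N#Cc1ccccc1", "c1ccccc1C#N"),
        ],
    )
    def test_equal_molecules_map_to_equal_strings(self, a, b):
        assert canonicalize(a) == canonicalize(b)

    @pytest.mark.parametrize("smiles", [BENZENE, BIPHENYL, "CC(=O)Oc1ccccc1C(=O)O"])
    def test_idempotent(self, smiles):
        once = canonicalize(smiles)
        assert canonicalize(once) == once

    @pytest.mark.parametrize("bad", ["", "not-a-smiles", "c1ccccc", "C(C)(C)(C)(C)C"])
    def test_unparsable_input_raises_with_offending_string(self, bad):
        with pytest.raises(ParseError) as err:
            canonicalize(bad)
        assert repr(bad) in str(err.value)


class TestAromaticSites:
    @pytest.mark.parametrize(
        "smiles,n",
        [(BENZENE, 6), (BIPHENYL, 10), (PYRIDINE, 5), (TOLUENE, 5), ("CC1CCCCC1", 0)],
    )
    def test_site_counts(self, smiles, n):
        assert len(aromatic_ch_sites(smiles)) == n

    def test_sites_are_aromatic_ch_carbons(self):
        mol = Chem.MolFromSmiles(BIPHENYL)
        for idx in aromatic_ch_sites(BIPHENYL):
            atom = mol.GetAtomWithIdx(idx)
            assert atom.GetIsAromatic() and atom.GetTotalNumHs() == 1

    @pytest.mark.parametrize(
        "library,expected",
        [
            ([BENZENE, BIPHENYL], 8.0),
            ([BENZENE], 6.0),
            ([BIPHENYL] * 4 + [BENZENE], 9.2),
        ],
    )
    def test_mean_aromatic_ch(self, library, expected):
        assert mean_aromatic_ch(library) == pytest.approx(expected)

    def test_mean_over_empty_library_is_an_error(self):
        with pytest.raises(EmptyLibraryError):
            mean_aromatic_ch([])


class TestFingerprint:
    def test_deterministic_and_binary(self):
        a = fingerprint(BENZENE)
        b = fingerprint(BENZENE)
        assert np.array_equal(a, b)
        assert set(np.unique(a)) <= {0, 1}
        assert a.sum() > 0

    def test_distinct_molecules_differ(self):
        assert not np.array_equal(fingerprint(BENZENE), fingerprint(BIPHENYL))


class TestTanimoto:
    def test_identity_is_one(self):
        v = fingerprint(BIPHENYL)
        assert tanimoto(v, v) == 1.0

    def test_disjoint_supports_and_zero_vectors(self):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        b = np.array([0, 0, 1, 1], dtype=np.uint8)
        assert tanimoto(a, b) == 0.0
        zero = np.zeros(4, dtype=np.uint8)
        assert tanimoto(zero, zero) == 0.0

    def test_hand_computed_value(self):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        b = np.array([1, 0, 1, 0], dtype=np.uint8)
        assert tanimoto(a, b) == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(np.ones(4), np.ones(5))

    @given(
        st.lists(st.booleans(), min_size=8, max_size=8),
        st.lists(st.booleans(), min_size=8, max_size=8),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_bounded(self, xs, ys):
        a, b = np.array(xs), np.array(ys)
        s = tanimoto(a, b)
        assert s == tanimoto(b, a)
        assert 0.0 <= s <= 1.0


class TestSkeletons:
    def test_toluene_strips_to_generic_ring(self):
        pair = skeletons(TOLUENE)
        assert pair.common_core == canonicalize(BENZENE)
        assert pair.generic_core == canonicalize("C1CCCCC1")

    def test_diphenylamine_core_genericizes_to_known_string(self):
        # the generic core erases N and aromaticity but keeps ring topology
        pair = skeletons("c1ccc(N2c3ccccc3Nc3ccccc32)cc1")
        assert pair.generic_core == canonicalize("C1CCC(C2C3CCCCC3CC3CCCCC32)CC1")

    def test_scaffold_of_scaffold_is_fixed_point(self):
        pair = skeletons("Cc1ccc(N2c3ccccc3Oc3ccccc32)cc1C#N")
        again = skeletons(pair.common_core)
        assert again.common_core == pair.common_core
        assert again.generic_core == pair.generic_core

    def test_acyclic_molecule_has_no_scaffold(self):
        with pytest.raises(ScaffoldError):
            skeletons("CCO")

    def test_generic_core_invariant_under_heteroatom_identity(self):
        assert skeletons(PYRIDINE).generic_core == skeletons(BENZENE).generic_core


class TestSkeletonFrequencies:
    def test_substituted_benzenes_collapse_to_one_core(self):
        df = skeleton_frequencies([TOLUENE, TOLUENE, TOLUENE, "Oc1ccccc1"], "common")
        assert df["core"].tolist() == [canonicalize(BENZENE)]
        assert df["count"].tolist() == [4]

    def test_counts_conserve_library_size_minus_skipped(self):
        library = [TOLUENE, BIPHENYL, PYRIDINE, "CCO", BENZENE]
        with pytest.warns(UserWarning, match="skipped 1"):
            df = skeleton_frequencies(library, "common")
        assert df["count"].sum() == len(library) - 1
        assert df.attrs["n_skipped"] == 1

    def test_generic_map_coarsens_common_map(self):
        library = [BENZENE, PYRIDINE, TOLUENE, BIPHENYL, "c1ccncn1"]
        common = skeleton_frequencies(library, "common")
        generic = skeleton_frequencies(library, "generic")
        # every generic-core count is a sum over its common-core preimage
        mapping = {}
        for smi in library:
            pair = skeletons(smi)
            mapping.setdefault(pair.generic_core, set()).add(pair.common_core)
        common_counts = dict(zip(common["core"], common["count"]))
        for core, count in zip(generic["core"], generic["count"]):
            assert count == sum(common_counts[c] for c in mapping[core])

    def test_singleton_library(self):
        df = skeleton_frequencies([BIPHENYL], "generic")
        assert len(df) == 1 and df["count"].iloc[0] == 1


class TestSasScore:
    def test_deterministic(self):
        assert sas_score(BIPHENYL) == sas_score(BIPHENYL)

    def test_benzene_easier_than_fused_polycyclic(self):
        fused = "N#Cc1ccc(-c2ccc3c(c2)N(c2ccccc2)c2cc4c(cc2O3)c2ccccc2n4-c2ccccc2)cc1"
        assert sas_score(BENZENE) < sas_score(fused)

    def test_fixture_fragments_score_in_standard_range(self):
        from tadfscreen.fragments import ACCEPTOR_POOL, DONOR_POOL

        for frag in DONOR_POOL + ACCEPTOR_POOL:
            mol = Chem.MolFromSmiles(frag)
            rw = Chem.RWMol(mol)
            for atom in rw.GetAtoms():
                if atom.GetAtomicNum() == 0:
                    atom.SetAtomicNum(1)
            capped = Chem.RemoveHs(rw.GetMol())
            Chem.SanitizeMol(capped)
            score = sas_score(Chem.MolToSmiles(capped))
            assert 1.0 <= score <= 10.0

    def test_custom_scorer_injection(self):
        assert sas_score(BENZENE, scorer=lambda mol: 42.0) == 42.0


class TestMoleculeRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MoleculeRecord(BENZENE, generation_born=-1)
        with pytest.raises(ValueError):
            MoleculeRecord(BENZENE, gap_est=-0.1)
        with pytest.raises(ValueError):
            MoleculeRecord(BENZENE, e_s1=0.0)
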