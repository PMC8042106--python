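"""Generator correctness: planted signatures, pools, determinism, bit tier."""

import numpy as np
import pytest
from rdkit import Chem

from promisig.synthdata import (
    DECORATIONS,
    DECOY_FRAGMENTS,
    SCAFFOLDS,
    SIGNATURE_FRAGMENTS,
    AssemblyError,
    ConfigurationError,
    LibraryConfig,
    SignatureSpec,
    assemble_molecule,
    generate_bitvector_library,
    generate_library,
    signature_query,
)


def _n_dummies(smiles):
    mol = Chem.MolFromSmiles(smiles)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


class TestPools:
    def test_all_building_blocks_parse_with_expected_attachment_points(self):
        for smi in SCAFFOLDS:
            assert Chem.MolFromSmiles(smi) is not None, smi
            assert _n_dummies(smi) >= 1, smi
        for smi in DECORATIONS + DECOY_FRAGMENTS + SIGNATURE_FRAGMENTS:
            assert Chem.MolFromSmiles(smi) is not None, smi
            assert _n_dummies(smi) == 1, smi

    def test_background_pools_are_sulfur_free(self):
        # signatures are (mostly) sulfur-marked; scaffolds and decorations
        # must never be able to assemble one by accident
        for smi in SCAFFOLDS + DECORATIONS:
            mol = Chem.MolFromSmiles(smi)
            assert not any(a.GetAtomicNum() == 16 for a in mol.GetAtoms()), smi

    def test_no_signature_query_matches_foreign_fragments_or_background(self):
        """No signature substructure is reachable except by planting it."""
        hosts = ["[*]c1ccccc1", "[*]N1CCCCC1", "[*]C1CCCCC1", "[*]C(=O)c1ccccc1"]
        queries = {s: signature_query(s) for s in SIGNATURE_FRAGMENTS}
        for host in hosts:
            for frag in SIGNATURE_FRAGMENTS + DECOY_FRAGMENTS:
                mol = Chem.MolFromSmiles(assemble_molecule(host, signature=frag))
                for sig, query in queries.items():
                    if sig != frag:
                        assert not mol.HasSubstructMatch(query), (host, frag, sig)
        for scaffold in SCAFFOLDS:
            n = scaffold.count("[*]")
            for deco in DECORATIONS:
                mol = Chem.MolFromSmiles(assemble_molecule(scaffold, [deco] * n))
                for sig, query in queries.items():
                    assert not mol.HasSubstructMatch(query), (scaffold, deco, sig)


class TestAssembleMolecule:
    def test_bare_scaffold_yields_benzene(self):
        assert assemble_molecule("[*]c1ccccc1") == "c1ccccc1"

    def test_product_contains_signature_iff_supplied(self):
        scaffold = "[*]c1ccc([*])cc1"
        sig = SIGNATURE_FRAGMENTS[0]
        with_sig = Chem.MolFromSmiles(assemble_molecule(scaffold, ["[*]OC"], sig))
        without = Chem.MolFromSmiles(assemble_molecule(scaffold, ["[*]OC"]))
        query = signature_query(sig)
        assert with_sig.HasSubstructMatch(query)
        assert not without.HasSubstructMatch(query)

    def test_none_decoration_leaves_position_unsubstituted(self):
        assert assemble_molecule("[*]c1ccc([*])cc1", [None]) == "c1ccccc1"

    def test_repeated_assembly_is_deterministic(self):
        rng = np.random.default_rng(5)
        picks = [
            (SCAFFOLDS[rng.integers(len(SCAFFOLDS))],
             DECORATIONS[rng.integers(len(DECORATIONS))])
            for _ in range(100)
        ]
        first = [assemble_molecule(s, [d]) for s, d in picks]
        second = [assemble_molecule(s, [d]) for s, d in picks]
        assert first == second

    def test_too_many_fragments_raises(self):
        with pytest.raises(AssemblyError, match="attachment points"):
            assemble_molecule("[*]c1ccccc1", ["[*]C", "[*]C"])

    def test_bad_scaffold_raises(self):
        with pytest.raises(AssemblyError, match="parse"):
            assemble_molecule("not-a-smiles")


class TestGenerateLibrary:
    def test_counts_and_class_labels_follow_config(self, small_library):
        for lib in small_library:
            assert len(lib.st_a) == 50
            assert len(lib.st_b) == 50
            assert len(lib.dt) == 100
            assert all(c.klass == "DT" and len(c.targets) == 2 for c in lib.dt)
            assert all(c.klass == "ST_A" and len(c.targets) == 1 for c in lib.st_a)
            for c in lib.compounds:
                assert Chem.MolFromSmiles(c.smiles) is not None

    def test_local_mode_assigns_distinct_fragments(self, small_library):
        frags = [lib.signature.fragment_smiles for lib in small_library]
        assert len(set(frags)) == len(frags)

    def test_global_mode_shares_one_fragment(self):
        libs = generate_library(LibraryConfig(n_pairs=3, mode="global", seed=1,
                                              n_st_a=5, n_st_b=5, n_dt=10))
        assert len({lib.signature.fragment_smiles for lib in libs}) == 1

    def test_perfect_rates_make_substructure_search_a_perfect_classifier(self):
        cfg = LibraryConfig(n_pairs=3, n_st_a=20, n_st_b=20, n_dt=40,
                            carrier_rate=1.0, leak_rate=0.0, seed=9)
        for lib in generate_library(cfg):
            query = signature_query(lib.signature.fragment_smiles)
            for c in lib.dt:
                assert Chem.MolFromSmiles(c.smiles).HasSubstructMatch(query)
            for c in lib.st_a + lib.st_b:
                assert not Chem.MolFromSmiles(c.smiles).HasSubstructMatch(query)

    def test_local_contract_fragment_never_crosses_pairs(self):
        cfg = LibraryConfig(n_pairs=4, n_st_a=15, n_st_b=15, n_dt=30,
                            carrier_rate=1.0, leak_rate=0.0, seed=2)
        libs = generate_library(cfg)
        for i, lib_i in enumerate(libs):
            query = signature_query(lib_i.signature.fragment_smiles)
            for j, lib_j in enumerate(libs):
                if i != j:
                    for c in lib_j.compounds:
                        assert not Chem.MolFromSmiles(c.smiles).HasSubstructMatch(
                            query
                        ), (i, j, c.compound_id)

    def test_same_config_reproduces_library_exactly(self):
        cfg = LibraryConfig(n_pairs=2, n_st_a=10, n_st_b=10, n_dt=20, seed=42)
        a = generate_library(cfg)
        b = generate_library(cfg)
        assert [c.smiles for lib in a for c in lib.compounds] == [
            c.smiles for lib in b for c in lib.compounds
        ]

    def test_adding_pairs_does_not_perturb_earlier_pairs(self):
        small = generate_library(LibraryConfig(n_pairs=2, n_st_a=5, n_st_b=5,
                                               n_dt=10, seed=13))
        large = generate_library(LibraryConfig(n_pairs=4, n_st_a=5, n_st_b=5,
                                               n_dt=10, seed=13))
        for a, b in zip(small, large):
            assert [c.smiles for c in a.compounds] == [c.smiles for c in b.compounds]

    def test_invalid_configs_are_rejected(self):
        with pytest.raises(ConfigurationError):
            LibraryConfig(n_pairs=1)
        with pytest.raises(ConfigurationError):
            LibraryConfig(n_pairs=len(SIGNATURE_FRAGMENTS) + 1, mode="local")
        with pytest.raises(ConfigurationError):
            LibraryConfig(mode="sideways")
        with pytest.raises(ConfigurationError):
            SignatureSpec("[*]CS", carrier_rate=0.5, leak_rate=0.6, mode="local")
        with pytest.raises(ConfigurationError):
            SignatureSpec("CC", carrier_rate=1.0, leak_rate=0.0, mode="local")


class TestBitvectorLibrary:
    def test_disjoint_blocks_and_shapes(self):
        cfg = LibraryConfig(n_pairs=3, n_st_a=5, n_st_b=5, n_dt=10, seed=1)
        sets = generate_bitvector_library(cfg, n_bits=64)
        blocks = [set(s.signature_bits) for s in sets]
        for i in range(3):
            assert sets[i].X.shape == (20, 64)
            for j in range(i + 1, 3):
                assert not blocks[i] & blocks[j]

    def test_global_mode_shares_the_block(self):
        cfg = LibraryConfig(n_pairs=3, n_st_a=5, n_st_b=5, n_dt=10, seed=1,
                            mode="global")
        sets = generate_bitvector_library(cfg, n_bits=64)
        assert len({s.signature_bits for s in sets}) == 1

    def test_perfect_rates_are_single_bit_separable(self):
        cfg = LibraryConfig(n_pairs=2, n_st_a=10, n_st_b=10, n_dt=20,
                            carrier_rate=1.0, leak_rate=0.0, seed=3)
        for s in generate_bitvector_library(cfg, n_bits=32, background_rate=0.0):
            bit = s.signature_bits[0]
            assert np.array_equal(s.X[:, bit] == 1, s.y == 1)

    def test_empirical_bit_frequencies_match_configured_rates(self):
        cfg = LibraryConfig(n_pairs=2, n_st_a=5000, n_st_b=5000, n_dt=10000,
                            carrier_rate=0.9, leak_rate=0.05, seed=17)
        s = generate_bitvector_library(cfg, n_bits=32, background_rate=0.1)[0]
        dt = s.X[s.y == 1]
        st = s.X[s.y == -1]
        sig = list(s.signature_bits)
        background = [b for b in range(32) if b not in sig]
        assert abs(dt[:, sig].mean() - 0.9) < 0.02
        assert abs(st[:, sig].mean() - 0.05) < 0.02
        assert abs(s.X[:, background].mean() - 0.1) < 0.02

    def test_n_bits_too_small_raises(self):
        cfg = LibraryConfig(n_pairs=3, n_st_a=2, n_st_b=2, n_dt=4, seed=1)
        with pytest.raises(ConfigurationError, match="n_bits"):
            generate_bitvector_library(cfg, n_bits=8, signature_width=4)
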