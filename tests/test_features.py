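"""Pharmacophore feature detection, graphs and fingerprint encoders."""

import itertools
import os

import numpy as np
import pytest
from rdkit import Chem

import phoregen as pg
from phoregen import features as F


def _families_of(smiles):
    mol = pg.parse_molecule(smiles)
    return {F.FAMILIES[f.family] for f in pg.detect_features(mol)}


class TestDetection:
    def test_methane_has_no_features(self):
        assert pg.detect_features(pg.parse_molecule("C")) == []

    def test_ethanol_donor_and_acceptor_share_the_oxygen(self):
        mol = pg.parse_molecule("CCO")
        feats = pg.detect_features(mol)
        donors = [f for f in feats if F.FAMILIES[f.family] == "donor"]
        acceptors = [f for f in feats if F.FAMILIES[f.family] == "acceptor"]
        assert donors and acceptors
        o_idx = {a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O"}
        assert donors[0].member_atoms == frozenset(o_idx)
        assert acceptors[0].member_atoms == frozenset(o_idx)

    def test_aspirin_features(self):
        fams = _families_of("CC(=O)Oc1ccccc1C(=O)O")
        assert "aromatic" in fams
        mol = pg.parse_molecule("CC(=O)Oc1ccccc1C(=O)O")
        acceptors = [f for f in pg.detect_features(mol)
                     if F.FAMILIES[f.family] == "acceptor"]
        assert len(acceptors) >= 2

    def test_no_duplicate_features(self, worked):
        for smi in worked.values():
            feats = pg.detect_features(pg.parse_molecule(smi))
            keys = [(f.family, f.member_atoms) for f in feats]
            assert len(keys) == len(set(keys))

    def test_invalid_smiles_rejected_with_input(self):
        with pytest.raises(F.InvalidSmilesError) as err:
            pg.fingerprint("not_a_smiles", "P72")
        assert "not_a_smiles" in str(err.value)

    def test_agrees_with_rdkit_feature_factory_on_simple_cases(self):
        """Loose cross-check against RDKit's own pharmacophore definitions:
        on simple molecules both implementations find the same H-bond
        donor/acceptor atoms."""
        from rdkit import RDConfig
        from rdkit.Chem import ChemicalFeatures

        factory = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        )
        for smi in ["CCO", "CCN", "CC(=O)C"]:
            mol = pg.parse_molecule(smi)
            ours = {
                (F.FAMILIES[f.family], tuple(sorted(f.member_atoms)))
                for f in pg.detect_features(mol)
                if F.FAMILIES[f.family] in ("donor", "acceptor")
            }
            theirs = {
                (feat.GetFamily().lower(), tuple(sorted(feat.GetAtomIds())))
                for feat in factory.GetFeaturesForMol(mol)
                if feat.GetFamily() in ("Donor", "Acceptor")
            }
            assert ours == theirs


class TestGraph:
    def test_single_feature_graph(self):
        mol = pg.parse_molecule("c1ccccc1")
        feats = pg.detect_features(mol)[:1]
        graph = pg.build_graph(mol, feats)
        assert graph.dist.shape == (1, 1)
        assert graph.dist[0, 0] == 0

    def test_colocated_features_distance_zero(self):
        mol = pg.parse_molecule("CCO")
        feats = [f for f in pg.detect_features(mol)
                 if F.FAMILIES[f.family] in ("donor", "acceptor")]
        graph = pg.build_graph(mol, feats)
        assert graph.dist[0, 1] == 0

    def test_diol_hydroxyls_four_bonds_apart(self):
        mol = pg.parse_molecule("OCCCO")
        feats = [f for f in pg.detect_features(mol)
                 if F.FAMILIES[f.family] == "acceptor"]
        assert len(feats) == 2
        graph = pg.build_graph(mol, feats)
        assert graph.dist[0, 1] == 4

    def test_disconnected_components_are_null_signal(self):
        mol = pg.parse_molecule("CCO.CCN")
        feats = pg.detect_features(mol)
        graph = pg.build_graph(mol, feats)
        comp_o = [i for i, f in enumerate(feats) if max(f.member_atoms) <= 2]
        comp_n = [i for i, f in enumerate(feats) if min(f.member_atoms) > 2]
        for i in comp_o:
            for j in comp_n:
                assert graph.dist[i, j] >= F.MAX_DISTANCE


def _graph(family_names, dist):
    feats = [
        F.PharmacophoreFeature(F.FAMILIES.index(n), frozenset({i}))
        for i, n in enumerate(family_names)
    ]
    return F.PharmacophoreGraph(feats, np.asarray(dist))


class TestTwoPoint:
    def test_empty_graph_is_all_zero(self):
        fp = pg.encode_two_point(_graph([], np.zeros((0, 0))), F.TWO_BIN)
        assert len(fp) == 72 and fp.bits.sum() == 0

    @pytest.mark.parametrize("smiles", ["C", "CCO", "CC(=O)Oc1ccccc1C(=O)O", "OCCCO"])
    def test_lengths(self, smiles):
        assert len(pg.fingerprint(smiles, "P72")) == 72
        assert len(pg.fingerprint(smiles, "P108")) == 108

    def test_single_pair_sets_exactly_one_bit(self):
        # acceptor(0)-donor(1) at distance 4: pair key (0,1) is the second
        # of the 36 sorted pair keys, distance 4 falls in the long bin [3,8)
        g = _graph(["acceptor", "donor"], [[0, 4], [4, 0]])
        fp = pg.encode_two_point(g, F.TWO_BIN)
        assert fp.bits.sum() == 1
        assert fp.bits[1 * 2 + 1] == 1

    def test_three_bin_excludes_distance_zero(self):
        # the 3-bin short range is the open interval (0, 2)
        g = _graph(["acceptor", "donor"], [[0, 0], [0, 0]])
        assert pg.encode_two_point(g, F.THREE_BIN).bits.sum() == 0
        assert pg.encode_two_point(g, F.TWO_BIN).bits.sum() == 1

    def test_distance_beyond_maximum_is_null(self):
        g = _graph(["acceptor", "donor"], [[0, 8], [8, 0]])
        for scheme in (F.TWO_BIN, F.THREE_BIN):
            assert pg.encode_two_point(g, scheme).bits.sum() == 0

    def test_bit_count_law(self, toy_corpus):
        for smi, fp, _c in toy_corpus[:30]:
            mol = pg.parse_molecule(smi)
            feats = pg.detect_features(mol)
            n_pairs = len(feats) * (len(feats) - 1) // 2
            assert fp.sum() <= min(72, n_pairs)


class TestThreePoint:
    def test_total_length_and_two_point_prefix(self, worked):
        for smi in worked.values():
            p72 = pg.fingerprint(smi, "P72")
            p1032 = pg.fingerprint(smi, "P1032")
            assert len(p1032) == 1032
            assert np.array_equal(p1032.bits[:72], p72.bits)

    def test_fewer_than_three_features_zero_triple_segment(self):
        # methanol: donor + acceptor on the oxygen, no hydrophobe
        assert len(pg.detect_features(pg.parse_molecule("CO"))) < 3
        fp = pg.fingerprint("CO", "P1032")
        assert fp.bits[72:].sum() == 0
        assert len(fp) == 1032

    def test_single_triple_sets_exactly_one_bit(self):
        # distances (2, 2, 4): short-short-long pattern for a sorted triple
        g = _graph(["acceptor", "donor", "aromatic"],
                   [[0, 2, 2], [2, 0, 4], [2, 4, 0]])
        fp = pg.encode_three_point(g)
        assert fp.bits[72:].sum() == 1
        # independent index: triple (0,1,2) in lexicographic multiset order,
        # with pairwise bins d(0,1)=short, d(0,2)=short, d(1,2)=long
        triples = list(itertools.combinations_with_replacement(range(8), 3))
        t_index = triples.index((0, 1, 2))
        pattern = 0 * 4 + 0 * 2 + 1
        assert fp.bits[72 + t_index * 8 + pattern] == 1

    def test_permutation_invariance_of_triple_encoding(self):
        dist = np.array([[0, 2, 5], [2, 0, 3], [5, 3, 0]])
        names = ["donor", "acceptor", "hydrophobe"]
        ref = pg.encode_three_point(_graph(names, dist)).bits
        for perm in itertools.permutations(range(3)):
            pnames = [names[p] for p in perm]
            pdist = dist[np.ix_(perm, perm)]
            assert np.array_equal(pg.encode_three_point(_graph(pnames, pdist)).bits, ref)

    def test_matches_brute_force_enumerator(self, toy_corpus):
        """Independent oracle: enumerate all feature triples, bin each
        pairwise distance, canonicalize by trying all orderings, and set
        bits in a layout rebuilt from scratch."""
        pair_keys = list(itertools.combinations_with_replacement(range(8), 2))
        triple_keys = list(itertools.combinations_with_replacement(range(8), 3))

        def bin2(d):
            if 0 <= d < 3:
                return 0
            if 3 <= d < 8:
                return 1
            return None

        def oracle(graph):
            bits = np.zeros(1032, dtype=np.uint8)
            feats = graph.features
            for i, j in itertools.combinations(range(len(feats)), 2):
                b = bin2(int(graph.dist[i, j]))
                if b is not None:
                    key = tuple(sorted((feats[i].family, feats[j].family)))
                    bits[pair_keys.index(key) * 2 + b] = 1
            for trip in itertools.combinations(range(len(feats)), 3):
                bins = {}
                for a, b in itertools.combinations(range(3), 2):
                    bins[(a, b)] = bins[(b, a)] = bin2(int(graph.dist[trip[a], trip[b]]))
                if any(v is None for v in bins.values()):
                    continue
                cands = []
                for perm in itertools.permutations(range(3)):
                    fams = tuple(feats[trip[p]].family for p in perm)
                    if list(fams) == sorted(fams):
                        pat = (bins[(perm[0], perm[1])], bins[(perm[0], perm[2])],
                               bins[(perm[1], perm[2])])
                        cands.append((fams, pat))
                fams, pat = min(cands)
                bits[72 + triple_keys.index(fams) * 8 + pat[0] * 4 + pat[1] * 2 + pat[2]] = 1
            return bits

        checked = 0
        for smi, _fp, _c in toy_corpus:
            mol = pg.parse_molecule(smi)
            feats = pg.detect_features(mol)
            if len(feats) > 6:
                continue
            graph = pg.build_graph(mol, feats)
            assert np.array_equal(pg.encode_three_point(graph).bits, oracle(graph)), smi
            checked += 1
            if checked >= 25:
                break
        assert checked >= 10


class TestPipeline:
    def test_determinism(self):
        smi = "CC(=O)Oc1ccccc1C(=O)O"
        for variant in ("P72", "P108", "P1032"):
            a = pg.fingerprint(smi, variant)
            b = pg.fingerprint(smi, variant)
            assert np.array_equal(a.bits, b.bits)

    def test_atom_order_invariance(self, worked):
        rng = np.random.default_rng(5)
        for smi in worked.values():
            mol = pg.parse_molecule(smi)
            n = mol.GetNumAtoms()
            if n < 2:
                continue
            ref = pg.fingerprint(smi, "P1032").bits
            for _ in range(3):
                perm = rng.permutation(n).tolist()
                renum = Chem.RenumberAtoms(mol, perm)
                alt = Chem.MolToSmiles(renum, canonical=False)
                assert np.array_equal(pg.fingerprint(alt, "P1032").bits, ref), (smi, alt)

    def test_two_features_beyond_max_distance_encode_all_zero(self):
        g = _graph(["acceptor", "aromatic"], [[0, 9], [9, 0]])
        for variant, encode in (("P72", lambda g: pg.encode_two_point(g, F.TWO_BIN)),
                                ("P108", lambda g: pg.encode_two_point(g, F.THREE_BIN)),
                                ("P1032", pg.encode_three_point)):
            assert encode(g).bits.sum() == 0, variant

    def test_feature_counts_conservation(self, worked):
        for smi in worked.values():
            counts = pg.feature_counts(smi)
            feats = pg.detect_features(pg.parse_molecule(smi))
            assert counts.sum() == len(feats)
            assert (counts >= 0).all() and counts.shape == (8,)

    def test_methane_counts_zero(self):
        assert pg.feature_counts("C").tolist() == [0] * 8
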