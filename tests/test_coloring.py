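import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bondheat as bh
from bondheat.coloring import (
    DEFAULT_GRADIENT,
    BondScoreMap,
    Gradient,
    GradientRangeError,
    NormalizationContext,
    NormalizationError,
    atom_scores,
    bond_scores,
    color_molecule,
    normalization_context,
    normalize,
    score_to_color,
)
from bondheat.fingerprint import FeatureOccurrence, ProvenancedFingerprint
from bondheat.model import ConfigMismatchError, LinearModel


def _toy_fp(molecule, feature_bonds, depth=4, hash_bits=22):
    """Fingerprint with hand-chosen features: {fid: [bond-set, ...]}."""
    provenance = {}
    for fid, occs in feature_bonds.items():
        provenance[fid] = [
            FeatureOccurrence(
                center=0, iteration=0,
                member_atoms=frozenset(), member_bonds=frozenset(bonds),
                encoding=f"toy-{fid}-{k}",
            )
            for k, bonds in enumerate(occs)
        ]
    return ProvenancedFingerprint(
        molecule=molecule, depth=depth, hash_bits=hash_bits,
        present_features=frozenset(provenance), provenance=provenance,
        substructure_table={},
    )


def _model(weights, bias=0.0, depth=4, hash_bits=22):
    return LinearModel(weights=weights, bias=bias, C=1.0,
                       negative_class_weight=1.0, depth=depth, hash_bits=hash_bits)


class TestBondScores:
    def test_hand_computed_example(self, ethanol):
        # f: w=2.0 over bonds {0,1}; g: w=-0.5 over {1}
        fp = _toy_fp(ethanol, {10: [{0, 1}], 20: [{1}]})
        model = _model({10: 2.0, 20: -0.5})
        smap = bond_scores(model, fp)
        assert smap.scores[0] == 2.0
        assert smap.scores[1] == 1.5

    def test_hand_computed_size_normalized(self, ethanol):
        fp = _toy_fp(ethanol, {10: [{0, 1}], 20: [{1}]})
        model = _model({10: 2.0, 20: -0.5})
        smap = bond_scores(model, fp, size_normalize=True)
        assert smap.scores[0] == 1.0
        assert smap.scores[1] == 1.0 - 0.5
        assert smap.size_normalized

    def test_zero_weights_all_zero(self, ethanol, small_fps):
        fp = small_fps[0]
        model = _model({})
        smap = bond_scores(model, fp)
        assert all(s == 0.0 for s in smap.scores.values())

    def test_every_bond_has_entry(self, small_fps, random_weight_model):
        for fp in small_fps[:5]:
            smap = bond_scores(random_weight_model, fp)
            assert set(smap.scores) == {b.index for b in fp.molecule.bonds}

    def test_occurrence_multiplicity_counts_each(self, ethanol):
        # one feature, two occurrences over the same bond: added twice
        fp = _toy_fp(ethanol, {10: [{0}, {0}]})
        model = _model({10: 1.0})
        assert bond_scores(model, fp).scores[0] == 2.0

    def test_brute_force_oracle(self, small_fps, random_weight_model):
        for fp in small_fps[:20]:
            smap = bond_scores(random_weight_model, fp)
            for bond in fp.molecule.bonds:
                parts = []
                for fid in fp.present_features:
                    w = random_weight_model.weights.get(fid, 0.0)
                    for occ in fp.provenance[fid]:
                        if bond.index in occ.member_bonds:
                            parts.append(w)
                assert smap.scores[bond.index] == math.fsum(parts)

    def test_additivity(self, small_fps):
        rng = np.random.default_rng(2)
        fp = small_fps[0]
        feats = sorted(fp.present_features)
        w1 = {f: float(x) for f, x in zip(feats, rng.normal(size=len(feats)))}
        w2 = {f: float(x) for f, x in zip(feats, rng.normal(size=len(feats)))}
        w3 = {f: w1[f] + w2[f] for f in feats}
        s1 = bond_scores(_model(w1), fp).scores
        s2 = bond_scores(_model(w2), fp).scores
        s3 = bond_scores(_model(w3), fp).scores
        for b in s3:
            assert s3[b] == pytest.approx(s1[b] + s2[b], abs=1e-10)

    def test_zero_weight_feature_irrelevance(self, ethanol):
        fp = _toy_fp(ethanol, {10: [{0, 1}]})
        fp2 = _toy_fp(ethanol, {10: [{0, 1}], 99: [{0}, {1}]})
        model = _model({10: 1.25, 99: 0.0})
        c1 = color_molecule(model, fp)
        c2 = color_molecule(model, fp2)
        for b in c1.entries:
            assert c1.entries[b].rgb == c2.entries[b].rgb

    def test_config_mismatch(self, ethanol):
        fp = _toy_fp(ethanol, {10: [{0}]}, hash_bits=10)
        with pytest.raises(ConfigMismatchError):
            bond_scores(_model({10: 1.0}), fp)


class TestAtomScores:
    def test_isolated_atom(self):
        mol = bh.parse_smiles("O")
        provenance = {
            5: [FeatureOccurrence(center=0, iteration=0,
                                  member_atoms=frozenset({0}),
                                  member_bonds=frozenset(), encoding="e")]
        }
        fp = ProvenancedFingerprint(
            molecule=mol, depth=4, hash_bits=22,
            present_features=frozenset({5}), provenance=provenance,
            substructure_table={},
        )
        assert atom_scores(_model({5: 1.2}), fp) == {0: 1.2}

    def test_uncovered_atoms_zero(self, ethanol):
        fp = _toy_fp(ethanol, {})
        assert atom_scores(_model({}), fp) == {0: 0.0, 1: 0.0, 2: 0.0}

    def test_brute_force_oracle(self, small_fps, random_weight_model):
        for fp in small_fps[:10]:
            scores = atom_scores(random_weight_model, fp)
            for a in range(fp.molecule.n_atoms):
                parts = [
                    random_weight_model.weights.get(fid, 0.0)
                    for fid in fp.present_features
                    for occ in fp.provenance[fid]
                    if a in occ.member_atoms
                ]
                assert scores[a] == math.fsum(parts)


class TestNormalization:
    def test_single_molecule_extremes(self, ethanol):
        smap = BondScoreMap(ethanol, {0: -1.0, 1: 0.0, 2: 3.0})
        ctx = normalization_context("single_molecule", [smap])
        assert (ctx.s_min, ctx.s_max) == (-1.0, 3.0)

    def test_full_set_extremes(self, ethanol):
        m1 = BondScoreMap(ethanol, {0: -1.0, 1: 0.0})
        m2 = BondScoreMap(ethanol, {0: 2.0, 1: 5.0})
        ctx = normalization_context("full_set", [m1, m2])
        assert (ctx.s_min, ctx.s_max) == (-1.0, 5.0)

    def test_single_molecule_requires_one_map(self, ethanol):
        m = BondScoreMap(ethanol, {0: 0.0})
        with pytest.raises(NormalizationError):
            normalization_context("single_molecule", [m, m])

    def test_empty_input_errors(self):
        with pytest.raises(NormalizationError):
            normalization_context("full_set", [])

    def test_endpoints(self):
        ctx = NormalizationContext("single_molecule", -2.0, 2.0)
        assert normalize(-2.0, ctx) == 0.0
        assert normalize(2.0, ctx) == 1.0
        assert normalize(0.0, ctx) == 0.5

    def test_degenerate_context(self):
        ctx = NormalizationContext("single_molecule", 7.0, 7.0)
        assert normalize(7.0, ctx) == 0.5

    def test_out_of_context_clamped(self):
        ctx = NormalizationContext("full_set", 0.0, 1.0)
        assert normalize(-5.0, ctx) == 0.0
        assert normalize(9.0, ctx) == 1.0

    def test_rank_preserved_across_modes(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=12)
        single = NormalizationContext("single_molecule", scores.min(), scores.max())
        full = NormalizationContext("full_set", scores.min() - 3, scores.max() + 5)
        nu_s = [normalize(s, single) for s in scores]
        nu_f = [normalize(s, full) for s in scores]
        assert np.array_equal(np.argsort(nu_s), np.argsort(nu_f))

    def test_full_set_preserves_cross_molecule_order(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=8)
        b = rng.normal(size=8) + 2.0
        ctx = NormalizationContext("full_set", min(a.min(), b.min()), max(a.max(), b.max()))
        nus = [normalize(s, ctx) for s in np.concatenate([a, b])]
        order_scores = np.argsort(np.concatenate([a, b]))
        assert np.array_equal(order_scores, np.argsort(nus))


class TestGradient:
    def test_anchor_colors(self):
        assert score_to_color(0.0) == (255, 0, 0)
        assert score_to_color(0.5) == (255, 165, 0)
        assert score_to_color(1.0) == (0, 200, 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(GradientRangeError):
            score_to_color(-0.01)
        with pytest.raises(GradientRangeError):
            score_to_color(1.01)

    def test_continuity_at_junction(self):
        eps = 1e-9
        below = score_to_color(0.5 - eps)
        above = score_to_color(0.5 + eps)
        mid = score_to_color(0.5)
        assert max(abs(x - y) for x, y in zip(below, mid)) <= 1
        assert max(abs(x - y) for x, y in zip(above, mid)) <= 1

    def test_custom_anchors(self):
        g = Gradient((0, 0, 0), (10, 10, 10), (20, 20, 20))
        assert score_to_color(0.25, g) == (5, 5, 5)

    def test_bad_channels_rejected(self):
        with pytest.raises(ValueError):
            Gradient((256, 0, 0), (0, 0, 0), (0, 0, 0))

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_channels_always_in_range(self, nu):
        rgb = score_to_color(nu)
        assert all(0 <= c <= 255 for c in rgb)


class TestColorMolecule:
    def test_all_zero_model_uniform_mid_color(self, small_fps):
        fp = small_fps[0]
        coloring = color_molecule(_model({}), fp)
        for entry in coloring.entries.values():
            assert entry.nu == 0.5
            assert entry.rgb == DEFAULT_GRADIENT.mid_color

    def test_full_set_requires_training_maps(self, small_fps):
        with pytest.raises(NormalizationError, match="training"):
            color_molecule(_model({}), small_fps[0], mode="full_set")

    def test_modes_preserve_ranking(self, small_fps, random_weight_model):
        fp = small_fps[1]
        training_maps = [
            bond_scores(random_weight_model, f) for f in small_fps[2:12]
        ]
        single = color_molecule(random_weight_model, fp, mode="single_molecule")
        full = color_molecule(
            random_weight_model, fp, mode="full_set", training_scoremaps=training_maps
        )
        bonds = sorted(single.entries)
        nu_s = [single.entries[b].nu for b in bonds]
        nu_f = [full.entries[b].nu for b in bonds]
        assert np.array_equal(np.argsort(nu_s, kind="stable"),
                              np.argsort(nu_f, kind="stable"))

    def test_single_atom_molecule_empty_coloring(self):
        mol = bh.parse_smiles("O")
        fp = bh.fingerprint(mol)
        coloring = color_molecule(_model({}), fp)
        assert coloring.entries == {}

    def test_raw_and_normalized_retained(self, small_fps, random_weight_model):
        coloring = color_molecule(random_weight_model, small_fps[0])
        smap = bond_scores(random_weight_model, small_fps[0])
        for b, entry in coloring.entries.items():
            assert entry.raw == smap.scores[b]
            assert 0.0 <= entry.nu <= 1.0
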