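"""Structural-alphabet encodings: dihedrals, RMSDA, PB, secondary
structure and the trainable fragment alphabet."""

import numpy as np
import pytest

from conftest import apply_rigid_transform
from saflex.alphabets import (
    MASK,
    FragmentAlphabetEstimator,
    SAEncoding,
    assign_secondary_structure,
    collapse_sec8,
    compute_dihedrals,
    encode_fragment_alphabet,
    encode_pb,
    ks_hbond_energy,
    load_pb_table,
    pb_alphabet,
    pb_angle_windows,
    rmsda,
    sec3_alphabet,
    train_fragment_alphabet,
)
from saflex._geometry import place_atom
from saflex.structure_io import InsufficientDataError
from saflex.synthetic import build_backbone, make_ideal_backbone


class TestDihedrals:
    def test_terminal_angles_masked(self, helix20):
        phi, psi = compute_dihedrals(helix20)
        assert np.isnan(phi[0]) and np.isnan(psi[-1])
        assert np.all(np.isfinite(phi[1:])) and np.all(np.isfinite(psi[:-1]))

    @pytest.mark.parametrize("phi,psi", [(-57.0, -47.0), (-119.0, 113.0)])
    def test_build_recompute_roundtrip(self, phi, psi):
        s = build_backbone(np.full(12, phi), np.full(12, psi))
        rphi, rpsi = compute_dihedrals(s)
        assert np.allclose(rphi[1:], phi, atol=1e-4)
        assert np.allclose(rpsi[:-1], psi, atol=1e-4)

    def test_explicit_cross_product_formula(self):
        """Hand-constructed atoms at a known 180° torsion, checked against
        an explicitly coded cross-product torsion."""
        a = np.array([1.0, 1.0, 0.0])
        b = np.array([0.0, 0.0, 0.0])
        c = np.array([1.0, 0.0, 0.0])
        d = np.array([2.0, -1.0, 0.0])  # anti-periplanar to a
        # independent formula
        b1, b2, b3 = b - a, c - b, d - c
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) == pytest.approx(180.0)
        from saflex._geometry import dihedral

        assert dihedral(a, b, c, d) == pytest.approx(180.0, abs=1e-9)

    def test_invalid_neighbour_masks_angles(self, mixed_structure):
        import copy

        s = copy.deepcopy(mixed_structure)
        s.valid[10] = False
        phi, psi = compute_dihedrals(s)
        assert np.isnan(phi[10]) and np.isnan(psi[10])
        assert np.isnan(phi[11]) and np.isnan(psi[9])


class TestRMSDA:
    def test_identical_zero(self):
        v = np.linspace(-170, 170, 8)
        assert rmsda(v, v) == 0.0

    def test_single_180_offset(self):
        a = np.zeros(8)
        b = np.zeros(8)
        b[3] = 180.0
        assert rmsda(a, b) == pytest.approx(np.sqrt(180.0**2 / 8))

    def test_periodic_wrap(self):
        a = np.zeros(8)
        b = np.zeros(8)
        a[0], b[0] = 179.0, -179.0
        assert rmsda(a, b) == pytest.approx(np.sqrt(4.0 / 8))

    def test_symmetric_and_bounded(self, rng):
        a = rng.uniform(-180, 180, size=8)
        b = rng.uniform(-180, 180, size=8)
        assert rmsda(a, b) == pytest.approx(rmsda(b, a), abs=1e-12)
        assert 0 <= rmsda(a, b) <= 180

    def test_masked_angle_rejected(self):
        a = np.zeros(8)
        a[2] = np.nan
        with pytest.raises(ValueError):
            rmsda(a, np.zeros(8))


class TestPBEncoding:
    def test_bundled_table_shape(self):
        letters, table = load_pb_table()
        assert len(letters) == 16 and table.shape == (16, 8)
        assert np.all(table > -180) and np.all(table <= 180)

    def test_helix_matches_exhaustive_scan(self, helix20):
        """Interior assignment equals a brute-force RMSDA scan of the table."""
        alpha = pb_alphabet()
        enc = encode_pb(helix20)
        win = pb_angle_windows(helix20)
        for i in range(2, 18):
            dists = [rmsda(win[i], alpha.prototypes[j]) for j in range(16)]
            assert enc.letters[i] == alpha.letters[int(np.argmin(dists))]
        assert enc.letters[:2] == MASK * 2 and enc.letters[-2:] == MASK * 2

    def test_prototype_fragment_returns_its_letter(self):
        """A backbone rebuilt from each prototype's angles re-assigns to it."""
        alpha = pb_alphabet()
        for j, row in enumerate(alpha.prototypes):
            phi = np.array([-60.0, row[1], row[3], row[5], row[7]])
            psi = np.array([row[0], row[2], row[4], row[6], 140.0])
            s = build_backbone(phi, psi)
            enc = encode_pb(s, alpha)
            assert enc.letters[2] == alpha.letters[j]
            assert rmsda(pb_angle_windows(s)[2], row) == pytest.approx(0.0, abs=1e-3)

    def test_five_residue_structure_single_assignment(self):
        s = build_backbone(np.full(5, -57.0), np.full(5, -47.0))
        enc = encode_pb(s)
        assert enc.letters[2] != MASK
        assert enc.letters.count(MASK) == 4

    def test_short_structure_all_mask(self):
        s = build_backbone(np.full(4, -57.0), np.full(4, -47.0))
        assert set(encode_pb(s).letters) == {MASK}

    def test_rotation_invariance(self, mixed_structure, rng):
        moved = apply_rigid_transform(mixed_structure, rng)
        assert encode_pb(moved).letters == encode_pb(mixed_structure).letters


class TestSecondaryStructure:
    def test_ideal_helix_interior_h(self, helix20):
        """Interior helix residues are H and the underlying i→i+4 H-bond
        energies clear the Kabsch–Sander cutoff, recomputed independently."""
        enc8 = assign_secondary_structure(helix20, 8)
        enc3 = assign_secondary_structure(helix20, 3)
        assert set(enc8.letters[2:-2]) == {"H"}
        assert set(enc3.letters[2:-2]) == {"H"}
        # independent energy check from raw coordinates
        from saflex.alphabets import amide_hydrogen_positions

        h = amide_hydrogen_positions(helix20)
        for i in range(2, 14):
            j = i + 4
            r = lambda x, y: float(np.linalg.norm(x - y))
            e = 27.888 * (
                1 / r(helix20.coords_o[i], helix20.coords_n[j])
                + 1 / r(helix20.coords_c[i], h[j])
                - 1 / r(helix20.coords_o[i], h[j])
                - 1 / r(helix20.coords_c[i], helix20.coords_n[j])
            )
            assert e < -0.5
            assert ks_hbond_energy(helix20)[i, j] == pytest.approx(e, abs=1e-9)

    def test_isolated_extended_chain_is_coil(self, strand20):
        """No turn or bridge H-bonds anywhere (separations ≥ 3): every
        residue collapses to C."""
        energies = ks_hbond_energy(strand20)
        ii, jj = np.meshgrid(*[np.arange(20)] * 2, indexing="ij")
        nonlocal_pairs = np.abs(ii - jj) >= 3
        assert np.all(energies[nonlocal_pairs] > -0.5)
        assert set(assign_secondary_structure(strand20, 3).letters) == {"C"}

    def test_collapse_mapping(self):
        assert collapse_sec8("HGIEBTSC" + MASK) == "HHHEECCC" + MASK

    def test_invalid_positions_masked(self, helix20):
        import copy

        s = copy.deepcopy(helix20)
        s.valid[7] = False
        enc = assign_secondary_structure(s, 3)
        assert enc.letters[7] == MASK


@pytest.fixture(scope="module")
def corpus():
    return [
        make_ideal_backbone("HHHHHHHHCCCCCEEEEEEECCHHHHHH", seed=i)
        for i in range(8)
    ]


class TestFragmentAlphabet:
    def test_default_dimensions(self, corpus):
        alpha = train_fragment_alphabet(corpus, m=28, fragment_length=7, seed=0)
        assert alpha.size == 28
        assert alpha.fragment_length == 7
        assert alpha.prototypes.shape == (28, 7, 3)
        assert len(set(alpha.letters)) == 28 and MASK not in alpha.letters

    def test_single_prototype_is_generalized_centroid(self, corpus):
        """m=1: the prototype equals the mean of all fragments after
        rotating each onto it (self-consistency of the Procrustes mean)."""
        from saflex._geometry import kabsch_rotation
        from saflex.alphabets import extract_ca_fragments

        alpha = train_fragment_alphabet(corpus[:2], m=1, fragment_length=7, seed=0)
        proto = alpha.prototypes[0]
        frags = extract_ca_fragments(corpus[:2], 7)
        rots = kabsch_rotation(frags, proto[None])
        mean = (frags @ rots).mean(axis=0)
        mean -= mean.mean(axis=0)
        assert np.abs(mean - proto).max() < 1e-6

    def test_seed_determinism(self, corpus):
        a = train_fragment_alphabet(corpus, m=10, fragment_length=7, seed=7)
        b = train_fragment_alphabet(corpus, m=10, fragment_length=7, seed=7)
        assert np.array_equal(a.prototypes, b.prototypes)

    def test_insufficient_fragments(self):
        tiny = [make_ideal_backbone("HHHHHHHH", seed=0)]
        with pytest.raises(InsufficientDataError):
            train_fragment_alphabet(tiny, m=28, fragment_length=7, seed=0)

    def test_encoding_matches_bruteforce_oracle(self, corpus, rng):
        from saflex._geometry import kabsch_rmsd_coords

        alpha = train_fragment_alphabet(corpus, m=12, fragment_length=7, seed=1)
        s = make_ideal_backbone("HHHHCCCCEEEECCHH", seed=99)
        enc = encode_fragment_alphabet(s, alpha)
        for i in range(3, len(s) - 3):
            w = s.coords_ca[i - 3 : i + 4]
            w = w - w.mean(axis=0)
            dists = [
                float(kabsch_rmsd_coords(w, alpha.prototypes[j]))
                for j in range(alpha.size)
            ]
            assert enc.letters[i] == alpha.letters[int(np.argmin(dists))]
        assert enc.letters[:3] == MASK * 3 and enc.letters[-3:] == MASK * 3

    def test_prototype_window_up_to_rigid_motion(self, corpus, rng):
        """A structure whose window reproduces a prototype (rotated and
        translated) is assigned that prototype's letter."""
        alpha = train_fragment_alphabet(corpus, m=6, fragment_length=7, seed=2)
        s = make_ideal_backbone("HHHHHHHHHHHHHH", seed=4)
        enc = encode_fragment_alphabet(s, alpha)
        moved = apply_rigid_transform(s, rng)
        assert encode_fragment_alphabet(moved, alpha).letters == enc.letters

    def test_length_L_structure_single_position(self, corpus):
        alpha = train_fragment_alphabet(corpus, m=6, fragment_length=7, seed=2)
        s = make_ideal_backbone("HHHHHHH", seed=0)
        enc = encode_fragment_alphabet(s, alpha)
        assert enc.letters[3] != MASK and enc.letters.count(MASK) == 6

    def test_estimator_sklearn_interface(self, corpus):
        est = FragmentAlphabetEstimator(n_prototypes=5, fragment_length=5)
        params = est.get_params()
        assert params["n_prototypes"] == 5
        est.set_params(n_prototypes=4)
        est.fit(corpus[:3])
        assert est.prototypes_.shape == (4, 5, 3)
        assert est.labels_.shape == (est.n_fragments_,)


def test_encoding_validates_symbols():
    with pytest.raises(ValueError):
        SAEncoding(alphabet=sec3_alphabet(), letters="HEX")


def test_reencoding_is_pure(mixed_structure):
    a = encode_pb(mixed_structure)
    b = encode_pb(mixed_structure)
    assert a.letters == b.letters
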