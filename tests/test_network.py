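"""Network representation, parsing, and exact structural predicates."""

from fractions import Fraction

import numpy as np
import pytest

from crnosc.dynamics import rhs_exact
from crnosc.network import (
    NetworkError,
    canonical_key,
    canonicalize,
    is_dynamically_nontrivial,
    is_isomorphic,
    is_quadratic,
    is_trimolecular,
    kernel_sign_vector,
    matrices,
    molecularity_profile,
    network_from_arrays,
    network_rank,
    parse_network,
    sources_collinear,
    strip_trivial_species,
    trimolecularize,
    trivial_species,
)


class TestParsing:
    def test_lotka_structure(self, lotka):
        assert lotka.species == ("X", "Y")
        assert (lotka.n, lotka.m) == (2, 3)
        gl, g = matrices(lotka)
        assert gl.tolist() == [[1, 1, 0], [0, 1, 1]]
        assert g.tolist() == [[1, -1, 0], [0, 1, -1]]

    def test_network4_matrices(self, net4):
        assert matrices(net4)[1].tolist() == [[1, -1, 0], [1, 0, -1]]

    @pytest.mark.parametrize(
        "text",
        ["0 -> 0", "X ->", "X -> -2Y", "X + -> Y", "2 -> X", ""],
    )
    def test_rejects_malformed(self, text):
        with pytest.raises(NetworkError):
            parse_network(text)

    def test_round_trip_through_writer(self, lotka, ivanova, net27):
        for net in (lotka, ivanova, net27):
            again = parse_network(net.to_text())
            assert again.species == net.species
            assert np.array_equal(again.gamma, net.gamma)
            assert np.array_equal(again.gamma_l, net.gamma_l)

    def test_gamma_is_target_minus_source(self, lotka, ivanova, net4, net27):
        for net in (lotka, ivanova, net4, net27):
            assert np.array_equal(net.gamma, net.target_matrix - net.gamma_l)

    def test_labels_survive(self):
        net = parse_network("2X -> 3X + Y @ k1\nX + Y -> Y @ k2\nY -> 0 @ k3")
        assert [r.label for r in net.reactions] == ["k1", "k2", "k3"]
        assert "@ k1" in net.to_text()

    def test_unused_species_rejected(self):
        with pytest.raises(NetworkError):
            network_from_arrays([(1, 0)], [(2, 0)], species=("X", "Y"))


class TestRoundTripProperty:
    """Writer/parser round trip and canonical-form invariance on random
    networks (property-based, derandomised)."""

    from hypothesis import given, settings, strategies as st

    complexes = st.lists(
        st.integers(min_value=0, max_value=3), min_size=2, max_size=3
    )

    @given(
        st.lists(st.tuples(complexes, complexes), min_size=1, max_size=4),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_write_parse_round_trip(self, pairs, rnd):
        n = len(pairs[0][0])
        pairs = [(tuple(s[:n]), tuple(t[:n])) for s, t in pairs]
        pairs = [(s, t) for s, t in pairs if len(s) == len(t) == n and s != t]
        if not pairs:
            return
        try:
            net = network_from_arrays(*zip(*pairs))
        except NetworkError:
            return
        again = parse_network(net.to_text())
        # the parser orders species by first appearance; compare by name
        perm = [net.species.index(s) for s in again.species]
        assert np.array_equal(again.gamma, net.gamma[perm])
        assert np.array_equal(again.gamma_l, net.gamma_l[perm])
        assert canonical_key(again) == canonical_key(net)
        # canonical form is invariant under reaction shuffling
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        net2 = network_from_arrays(*zip(*shuffled))
        assert canonical_key(net) == canonical_key(net2)


class TestStructuralPredicates:
    def test_ranks(self, lotka, ivanova):
        assert network_rank(lotka) == 2
        assert network_rank(ivanova) == 2
        assert network_rank(parse_network("X -> 2X\n2X -> 3X")) == 1

    def test_ivanova_mass_conservation(self, ivanova):
        assert np.all(ivanova.gamma.sum(axis=0) == 0)

    def test_molecularity(self, lotka, net4):
        assert molecularity_profile(net4) == (2, 4)
        assert is_quadratic(net4) and not is_trimolecular(net4)
        assert molecularity_profile(lotka) == (2, 2)
        inflow = parse_network("0 -> X\nX -> 0")
        assert inflow.reactions[0].source.molecularity == 0

    def test_trivial_species(self, lotka):
        assert trivial_species(lotka) == set()
        aug = parse_network("X + Z -> 2X + Z\nX + Y -> 2Y\nY -> 0")
        assert {aug.species[i] for i in trivial_species(aug)} == {"Z"}
        stripped, removed = strip_trivial_species(aug)
        assert removed == ("Z",)
        assert is_isomorphic(stripped, parse_network("X -> 2X\nX + Y -> 2Y\nY -> 0"))

    def test_kernel_sign_vector(self, lotka, net4, net27):
        assert kernel_sign_vector(lotka) == (1, 1, 1)
        assert kernel_sign_vector(net4) == (1, 1, 1)
        assert kernel_sign_vector(net27) == (-1, -1, -1)

    def test_sources_collinear(self):
        assert sources_collinear(parse_network("2X -> 3X\nX + Y -> X\n2Y -> Y"))
        assert not sources_collinear(parse_network("2X -> 3X\nX + Y -> X\nY -> 2Y"))
        assert sources_collinear(parse_network("X -> 2X\n2X -> X"))  # m=2


class TestNontriviality:
    def test_lotka_witness(self, lotka):
        cert = is_dynamically_nontrivial(lotka)
        assert cert.status
        u = cert.positive_kernel_vector
        assert all(v > 0 for v in u)
        gamma = lotka.gamma
        assert all(
            sum(Fraction(int(gamma[i, j])) * u[j] for j in range(3)) == 0
            for i in range(2)
        )

    def test_trivial_with_separating_vector(self):
        net = parse_network("X -> 2X\nY -> 2Y\nX + Y -> 2X + 2Y")
        cert = is_dynamically_nontrivial(net)
        assert not cert.status
        v = cert.separating_vector
        gtv = [
            sum(Fraction(int(net.gamma[i, j])) * v[i] for i in range(net.n))
            for j in range(net.m)
        ]
        assert all(x >= 0 for x in gtv) and any(x > 0 for x in gtv)

    def test_certificates_verify_on_random_networks(self):
        """Stiemke alternative: exactly one witness exists and it verifies
        by exact multiplication, for random small integer networks."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 120:
            n = int(rng.integers(2, 5))
            m = int(rng.integers(1, 5))
            srcs = rng.integers(0, 3, size=(m, n))
            tgts = rng.integers(0, 4, size=(m, n))
            if any((s == t).all() for s, t in zip(srcs, tgts)):
                continue
            try:
                net = network_from_arrays(srcs, tgts)
            except NetworkError:
                continue
            cert = is_dynamically_nontrivial(net)
            gamma = net.gamma
            if cert.status:
                u = cert.positive_kernel_vector
                assert all(v > 0 for v in u)
                assert all(
                    sum(Fraction(int(gamma[i, j])) * u[j] for j in range(net.m)) == 0
                    for i in range(net.n)
                )
            else:
                v = cert.separating_vector
                gtv = [
                    sum(Fraction(int(gamma[i, j])) * v[i] for i in range(net.n))
                    for j in range(net.m)
                ]
                assert all(x >= 0 for x in gtv) and any(x > 0 for x in gtv)
            checked += 1

    def test_cross_product_shortcut_agrees(self):
        """For m=3 rank-2 networks, nontriviality is equivalent to the
        kernel cross-product vector having one strict sign."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 80:
            srcs = rng.integers(0, 3, size=(3, 2))
            tgts = rng.integers(0, 4, size=(3, 2))
            if any((s == t).all() for s, t in zip(srcs, tgts)):
                continue
            try:
                net = network_from_arrays(srcs, tgts)
            except NetworkError:
                continue
            if network_rank(net) != 2:
                continue
            u = kernel_sign_vector(net)
            signs = {(v > 0) - (v < 0) for v in u}
            assert is_dynamically_nontrivial(net).status == (
                signs in ({1}, {-1})
            )
            checked += 1


class TestCanonicalForm:
    def test_relabelled_lotka_isomorphic(self, lotka):
        relabelled = parse_network("Y -> 2Y\nY + X -> 2X\nX -> 0")
        assert is_isomorphic(lotka, relabelled)

    def test_reaction_order_irrelevant(self, lotka):
        reversed_net = parse_network("Y -> 0\nX + Y -> 2Y\nX -> 2X")
        assert canonical_key(lotka) == canonical_key(reversed_net)

    def test_distinct_networks_differ(self, lotka, ivanova, lva):
        assert canonical_key(lotka) != canonical_key(lva)
        assert lotka.n != ivanova.n

    def test_idempotent(self, net27):
        once = canonicalize(net27)
        assert canonical_key(once) == canonical_key(net27)
        assert canonicalize(once) == once


class TestTrimolecularize:
    def test_network4_splitting(self, net4):
        tri, kap = trimolecularize(net4, [2.0, 1.0, 1.0])
        assert tri.m == 4
        assert is_trimolecular(tri)
        assert kap == [2.0, 2.0, 1.0, 1.0]

    def test_vector_field_identical_exact(self, net4):
        kappa = [Fraction(3, 2), Fraction(1), Fraction(2)]
        tri, kap = trimolecularize(net4, kappa)
        for x in [(Fraction(1), Fraction(2)), (Fraction(1, 3), Fraction(5, 7))]:
            assert rhs_exact(net4, kappa, x) == rhs_exact(tri, kap, x)

    def test_single_reaction_example(self):
        net = parse_network("X + Y -> 4X")
        tri, kap = trimolecularize(net, [Fraction(1)])
        texts = set(tri.to_text().splitlines())
        assert texts == {"X + Y -> 2X + Y", "X + Y -> X"}
        assert sorted(kap) == [Fraction(1), Fraction(3)]
        for x in [(Fraction(2), Fraction(3))]:
            assert rhs_exact(net, [Fraction(1)], x) == rhs_exact(tri, kap, x)

    def test_trimolecular_unchanged(self, lotka):
        tri, _ = trimolecularize(lotka, None)
        assert tri == lotka

    def test_rejects_nonquadratic(self):
        with pytest.raises(NetworkError):
            trimolecularize(parse_network("3X -> 4X"), None)
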