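import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import random_record
from interlis.interface_metrics import (
    MetricParams,
    compute_actifptm,
    compute_clis,
    compute_ilis,
    compute_ipsae,
    compute_lis,
    compute_pair_metrics,
    compute_score_matrix,
    identify_lir,
    local_score,
)
from interlis.structure_io import ContactSet, compute_contacts


def _two_block_pae(n_a, n_b, fill=28.0):
    n = n_a + n_b
    pae = np.full((n, n), fill)
    np.fill_diagonal(pae, 0.0)
    return pae, np.arange(n_a), np.arange(n_a, n)


class TestLocalScore:
    @pytest.mark.parametrize(
        "pae,cutoff,expected", [(0.0, 12.0, 1.0), (12.0, 12.0, 0.0), (6.0, 12.0, 0.5),
                                (25.0, 12.0, 0.0)]
    )
    def test_linear_transform(self, pae, cutoff, expected):
        assert local_score(pae, cutoff) == pytest.approx(expected)

    def test_negative_pae_rejected(self):
        with pytest.raises(ValueError):
            local_score(-1.0, 12.0)

    @given(st.floats(0.0, 40.0), st.floats(1.0, 30.0))
    @settings(derandomize=True, max_examples=50)
    def test_bounded_in_unit_interval(self, pae, cutoff):
        assert 0.0 <= local_score(pae, cutoff) <= 1.0


class TestLis:
    def test_nothing_qualifies(self):
        pae, ia, ib = _two_block_pae(3, 3, fill=25.0)
        value, pairs = compute_lis(pae, ia, ib)
        assert value == 0.0 and pairs == frozenset()

    def test_uniform_block_closed_form(self):
        pae, ia, ib = _two_block_pae(3, 3, fill=4.0)
        value, pairs = compute_lis(pae, ia, ib)
        assert value == pytest.approx((12 - 4) / 12)
        assert len(pairs) == 2 * 9

    def test_asymmetric_one_by_one_blocks(self):
        # pae[a->b]=6 qualifies, pae[b->a]=18 does not
        pae = np.array([[0.0, 6.0], [18.0, 0.0]])
        value, pairs = compute_lis(pae, [0], [1])
        assert pairs == {(0, 1)}
        assert value == pytest.approx(0.5)

    def test_overlapping_sets_rejected(self):
        pae, ia, _ = _two_block_pae(3, 3)
        with pytest.raises(ValueError):
            compute_lis(pae, ia, ia)


class TestClis:
    def test_vacuous_restriction_equals_lis(self):
        pae, ia, ib = _two_block_pae(2, 2, fill=4.0)
        contacts = ContactSet("A", "B", frozenset((i, j) for i in ia for j in ib))
        lis_v, _ = compute_lis(pae, ia, ib)
        clis_v, _ = compute_clis(pae, ia, ib, contacts)
        assert clis_v == pytest.approx(lis_v) == pytest.approx(2 / 3)

    def test_no_contacts_gives_zero(self):
        pae, ia, ib = _two_block_pae(2, 2, fill=4.0)
        clis_v, cpairs = compute_clis(pae, ia, ib, ContactSet("A", "B", frozenset()))
        assert clis_v == 0.0 and cpairs == frozenset()

    def test_contact_restriction_selects_planted_block(self, mixed_fixture):
        record, truth, _ = mixed_fixture
        ia = record.structure.chain_indices("A")
        ib = record.structure.chain_indices("B")
        contacts = compute_contacts(record.structure, "A", "B")
        clis_v, cpairs = compute_clis(record.confidence.pae, ia, ib, contacts)
        assert clis_v == pytest.approx(truth.metrics[("A", "B")][1])
        # only the 5x5 contact block participates: 2 * 25 directed pairs
        assert len(cpairs) == 50


class TestIlis:
    @pytest.mark.parametrize(
        "lis,clis,expected", [(0.5, 0.5, 0.5), (0.8, 0.0, 0.0), (0.9, 0.4, 0.6)]
    )
    def test_geometric_mean(self, lis, clis, expected):
        assert compute_ilis(lis, clis) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_ilis(1.2, 0.5)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_bounded_by_arguments(self, lis, clis):
        ilis = compute_ilis(lis, clis)
        assert min(lis, clis) - 1e-12 <= ilis <= max(lis, clis) + 1e-12
        if clis == 0.0:
            assert ilis == 0.0


class TestLir:
    def test_all_above_cutoff_empty(self):
        pae, ia, ib = _two_block_pae(3, 3, fill=20.0)
        sets = identify_lir(pae, ia, ib, ContactSet("A", "B", frozenset()))
        assert all(s == frozenset() for s in sets)

    def test_planted_contact_interface(self, planted_fixture):
        record, truth, _ = planted_fixture
        ia = record.structure.chain_indices("A")
        ib = record.structure.chain_indices("B")
        contacts = compute_contacts(record.structure, "A", "B")
        lir_a, lir_b, clir_a, clir_b = identify_lir(
            record.confidence.pae, ia, ib, contacts
        )
        exp_lir_a, exp_lir_b, exp_clir_a, exp_clir_b = truth.lir[("A", "B")]
        assert (lir_a, lir_b, clir_a, clir_b) == (
            exp_lir_a, exp_lir_b, exp_clir_a, exp_clir_b
        )

    def test_non_contact_pair_in_lir_but_not_clir(self, mixed_fixture):
        record, truth, _ = mixed_fixture
        ia = record.structure.chain_indices("A")
        ib = record.structure.chain_indices("B")
        contacts = compute_contacts(record.structure, "A", "B")
        lir_a, _, clir_a, _ = identify_lir(record.confidence.pae, ia, ib, contacts)
        # residues 10-12 of A qualify only via the non-contact block
        assert {10, 11, 12} <= set(lir_a)
        assert not ({10, 11, 12} & set(clir_a))
        assert clir_a <= lir_a


class TestIpsae:
    def test_all_zero_pae_gives_one(self):
        pae, ia, ib = _two_block_pae(4, 4, fill=0.0)
        assert compute_ipsae(pae, ia, ib) == pytest.approx(1.0)

    def test_all_above_cutoff_gives_zero(self):
        pae, ia, ib = _two_block_pae(4, 4, fill=10.0)  # strict < cutoff
        assert compute_ipsae(pae, ia, ib) == 0.0

    def test_single_good_row(self):
        pae, ia, ib = _two_block_pae(3, 3, fill=30.0)
        pae[0, 3:] = 2.0  # one residue of A places all of B well
        got = compute_ipsae(pae, ia, ib)
        # n=3 partners, d0 clamps to 1.0, each term 1/(1+4)
        assert got == pytest.approx(1.0 / (1.0 + 4.0))
        assert got == pytest.approx(
            oracles.ipsae(pae.tolist(), ia.tolist(), ib.tolist())
        )


class TestActifptm:
    def test_full_contact_zero_pae(self):
        pae, ia, ib = _two_block_pae(4, 4, fill=0.0)
        contacts = ContactSet("A", "B", frozenset((i, j) for i in ia for j in ib))
        assert compute_actifptm(pae, ia, ib, contacts) == pytest.approx(1.0)

    def test_no_contacts_zero(self):
        pae, ia, ib = _two_block_pae(4, 4, fill=0.0)
        assert compute_actifptm(pae, ia, ib, ContactSet("A", "B", frozenset())) == 0.0

    def test_uniform_pae_at_d0_gives_half(self):
        # 4 interface residues, d0(4) clamps to 1.0; inter-chain PAE = d0
        pae, ia, ib = _two_block_pae(2, 2, fill=0.0)
        d0 = oracles.d0(4)
        pae[np.ix_(ia, ib)] = d0
        pae[np.ix_(ib, ia)] = d0
        contacts = ContactSet("A", "B", frozenset((i, j) for i in ia for j in ib))
        assert compute_actifptm(pae, ia, ib, contacts) == pytest.approx(0.5)


class TestOracleEquivalence:
    """Vectorized production code against naive double loops."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_metrics_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        record = random_record(rng, n_per_chain=25)
        model = record.structure
        pae = record.confidence.pae
        ia = model.chain_indices("A")
        ib = model.chain_indices("B")
        contacts = compute_contacts(model, "A", "B")
        la, pairs = compute_lis(pae, ia, ib)
        o_lis, o_pairs = oracles.lis(pae, ia.tolist(), ib.tolist())
        assert la == pytest.approx(o_lis, abs=1e-9)
        assert pairs == o_pairs
        ca, cpairs = compute_clis(pae, ia, ib, contacts)
        o_clis, o_cpairs = oracles.clis(pae, ia.tolist(), ib.tolist(), contacts.pairs)
        assert ca == pytest.approx(o_clis, abs=1e-9)
        assert cpairs == o_cpairs
        assert compute_ipsae(pae, ia, ib) == pytest.approx(
            oracles.ipsae(pae, ia.tolist(), ib.tolist()), abs=1e-9
        )
        assert compute_actifptm(pae, ia, ib, contacts) == pytest.approx(
            oracles.actifptm(pae, ia.tolist(), ib.tolist(), contacts.pairs), abs=1e-9
        )


class TestPairMetricsAndMatrix:
    def test_bundles_closed_forms(self, planted_fixture):
        record, truth, _ = planted_fixture
        m = compute_pair_metrics(record, "A", "B")
        lis, clis, ilis = truth.metrics[("A", "B")]
        assert m.lis == pytest.approx(lis)
        assert m.clis == pytest.approx(clis)
        assert m.ilis == pytest.approx(ilis)
        assert m.iptm_reported is None

    def test_chain_swap_symmetry(self, mixed_fixture):
        record, _, _ = mixed_fixture
        ab = compute_pair_metrics(record, "A", "B")
        ba = compute_pair_metrics(record, "B", "A")
        for attr in ("lis", "clis", "ilis", "ipsae", "actifptm"):
            assert getattr(ab, attr) == pytest.approx(getattr(ba, attr))
        assert ab.lir_a == ba.lir_b and ab.lir_b == ba.lir_a
        assert ab.clir_a == ba.clir_b and ab.clir_b == ba.clir_a

    def test_score_matrix_cell_count_and_symmetry(self):
        from interlis.fixtures import FixtureSpec, PlantedInterface, make_complex_fixture

        spec = FixtureSpec(
            n_chains=3,
            residues_per_chain=12,
            interface_pairs=(PlantedInterface("A", (0, 4), "C", (0, 4), 4.0, True),),
            seed=5,
        )
        records, _ = make_complex_fixture(spec)
        matrix = compute_score_matrix(records[0])
        assert len(matrix.cells) == 3
        assert matrix.cell("C", "A").lis == matrix.cell("A", "C").lis
        assert matrix.cell("C", "A").lir_a == matrix.cell("A", "C").lir_b
        # only the planted pair interacts
        positive = [p for p, c in matrix.cells.items() if c.ilis > 0]
        assert positive == [("A", "C")]

    def test_single_chain_rejected(self, monomer_fixture):
        record, _ = monomer_fixture
        with pytest.raises(ValueError, match="subdomains"):
            compute_score_matrix(record)

    def test_metrics_in_unit_interval_and_sets_nested(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            record = random_record(rng, n_per_chain=15)
            m = compute_pair_metrics(record, "A", "B")
            for attr in ("lis", "clis", "ilis", "ipsae", "actifptm"):
                assert 0.0 <= getattr(m, attr) <= 1.0
            assert m.clir_a <= m.lir_a and m.clir_b <= m.lir_b
            assert m.contact_qualifying_pairs <= m.qualifying_pairs
            if m.clis == 0.0:
                assert m.ilis == 0.0
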