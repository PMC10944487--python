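"""Exciton domains and generalized Förster rates.

The load-bearing oracle is the reduction: with every aggregate holding a
single pigment the generalized theory must collapse to classical Förster
transfer exactly, at any temperature.
"""

import numpy as np
import pytest

from eetkit.errors import DomainError, RateError
from eetkit.forster import pairwise_rate, rate_matrix
from eetkit.generalized_forster import (
    all_domain_rates,
    build_domain,
    domain_rate,
    exciton_coupling,
)
from eetkit.lineshapes import LineshapeParams, SpectralModel
from eetkit.structure_io import DomainPartition, DomainRole, PigmentSet, PigmentType
from eetkit.synthetic import make_charge_set, make_pigment
from eetkit.tresp import CouplingMatrix, CouplingMethod, coupling_matrix

CHL_A = LineshapeParams(omega0=14900.0, fwhm=240.0, stokes=160.0)


def _pigment_row(ids, centers):
    return PigmentSet(
        [
            make_pigment(pid, c, [0, 0, 1], chain=pid.split("/")[0], resnum=int(pid.split("/")[1]))
            for pid, c in zip(ids, centers)
        ]
    )


def _fabricated_couplings(ids, V):
    """CouplingMatrix with hand-chosen couplings (geometry bookkeeping zeroed)."""
    V = np.asarray(V, dtype=float)
    n = len(ids)
    return CouplingMatrix(
        ids=list(ids), V=V, R=np.zeros((n, n)), f=np.ones((n, n)),
        method=CouplingMethod.TRESP,
    )


def _charpoly(H):
    """Faddeev–LeVerrier characteristic-polynomial coefficients (independent
    of any eigensolver)."""
    n = H.shape[0]
    M = np.zeros_like(H)
    coeffs = [1.0]
    for k in range(1, n + 1):
        M = H @ M + coeffs[-1] * np.eye(n)
        coeffs.append(-np.trace(H @ M) / k)
    return np.array(coeffs)


class TestBuildDomain:
    def test_single_pigment_domain(self, chl_a_model):
        pigments = _pigment_row(["A/1/CLA"], [[0, 0, 0]])
        cm = _fabricated_couplings(["A/1/CLA"], [[0.0]])
        dom = build_domain("A", pigments, ["A/1/CLA"], cm, chl_a_model)
        assert dom.eigenvalues == pytest.approx([14900.0])
        assert np.allclose(dom.coefficients, [[1.0]])
        assert dom.weights == pytest.approx([1.0])

    def test_symmetric_homodimer_analytic(self, chl_a_model):
        V = 80.0
        ids = ["A/1/CLA", "A/2/CLA"]
        pigments = _pigment_row(ids, [[0, 0, 0], [10, 0, 0]])
        cm = _fabricated_couplings(ids, [[0, V], [V, 0]])
        dom = build_domain("A", pigments, ids, cm, chl_a_model)
        assert dom.eigenvalues == pytest.approx([14900.0 - V, 14900.0 + V])
        assert np.abs(dom.coefficients) == pytest.approx(np.full((2, 2), 1 / np.sqrt(2)))

    def test_random_five_mer_matches_characteristic_polynomial(self, rng, chl_a_model):
        ids = [f"A/{i}/CLA" for i in range(1, 6)]
        centers = [[15.0 * i, 0, 0] for i in range(5)]
        pigments = _pigment_row(ids, centers)
        V = rng.normal(scale=60.0, size=(5, 5))
        V = (V + V.T) / 2.0
        np.fill_diagonal(V, 0.0)
        cm = _fabricated_couplings(ids, V)
        dom = build_domain("A", pigments, ids, cm, chl_a_model)
        # shift out the large site-energy offset so the polynomial roots are
        # well conditioned; eigenvalues shift by the same constant
        shift = np.mean(np.diag(dom.hamiltonian))
        H0 = dom.hamiltonian - shift * np.eye(5)
        roots = np.sort(np.roots(_charpoly(H0)).real) + shift
        assert dom.eigenvalues == pytest.approx(roots, rel=1e-8)
        # eigenpairs actually solve the Hamiltonian
        for alpha in range(5):
            resid = dom.hamiltonian @ dom.coefficients[:, alpha] - dom.eigenvalues[
                alpha
            ] * dom.coefficients[:, alpha]
            assert np.linalg.norm(resid) < 1e-8 * abs(dom.eigenvalues[alpha])

    def test_boltzmann_weights_normalized_and_ordered(self, rng, chl_a_model):
        ids = [f"A/{i}/CLA" for i in range(1, 5)]
        pigments = _pigment_row(ids, [[12.0 * i, 0, 0] for i in range(4)])
        V = rng.normal(scale=100.0, size=(4, 4))
        V = (V + V.T) / 2.0
        np.fill_diagonal(V, 0.0)
        dom = build_domain(
            "A", pigments, ids, _fabricated_couplings(ids, V), chl_a_model,
            temperature=300.0,
        )
        assert dom.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(dom.weights) <= 0)  # ascending ε ⇒ descending w

    def test_missing_site_energy_named(self):
        pigments = _pigment_row(["A/1/CLA"], [[0, 0, 0]])
        empty_model = SpectralModel(by_type={})
        with pytest.raises(Exception, match="A/1/CLA"):
            build_domain(
                "A", pigments, ["A/1/CLA"], _fabricated_couplings(["A/1/CLA"], [[0.0]]),
                empty_model,
            )

    def test_nonpositive_temperature_rejected(self, chl_a_model):
        pigments = _pigment_row(["A/1/CLA"], [[0, 0, 0]])
        with pytest.raises(RateError):
            build_domain(
                "A", pigments, ["A/1/CLA"], _fabricated_couplings(["A/1/CLA"], [[0.0]]),
                chl_a_model, temperature=0.0,
            )


class TestExcitonCoupling:
    def test_single_pigment_domains_reduce_to_site_coupling(self, chl_a_model):
        ids = ["A/1/CLA", "B/1/CLA"]
        pigments = _pigment_row(ids, [[0, 0, 0], [20, 0, 0]])
        cm = _fabricated_couplings(ids, [[0, 42.0], [42.0, 0]])
        d = build_domain("A", pigments, ["A/1/CLA"], cm, chl_a_model)
        a = build_domain("B", pigments, ["B/1/CLA"], cm, chl_a_model)
        V_ab = exciton_coupling(d, a, cm)
        assert abs(V_ab[0, 0]) == pytest.approx(42.0, rel=1e-12)

    def test_zero_inter_couplings_give_zero(self, chl_a_model):
        ids = ["A/1/CLA", "A/2/CLA", "B/1/CLA", "B/2/CLA"]
        pigments = _pigment_row(ids, [[0, 0, 0], [10, 0, 0], [60, 0, 0], [70, 0, 0]])
        V = np.zeros((4, 4))
        V[0, 1] = V[1, 0] = 50.0
        V[2, 3] = V[3, 2] = 30.0
        cm = _fabricated_couplings(ids, V)
        d = build_domain("A", pigments, ids[:2], cm, chl_a_model)
        a = build_domain("B", pigments, ids[2:], cm, chl_a_model)
        assert np.allclose(exciton_coupling(d, a, cm), 0.0)

    def test_dimer_dimer_matches_brute_force_double_sum(self, rng, chl_a_model):
        ids = ["A/1/CLA", "A/2/CLA", "B/1/CLA", "B/2/CLA"]
        pigments = _pigment_row(ids, [[0, 0, 0], [10, 0, 0], [60, 0, 0], [70, 0, 0]])
        V = rng.normal(scale=40.0, size=(4, 4))
        V = (V + V.T) / 2.0
        np.fill_diagonal(V, 0.0)
        cm = _fabricated_couplings(ids, V)
        d = build_domain("A", pigments, ids[:2], cm, chl_a_model)
        a = build_domain("B", pigments, ids[2:], cm, chl_a_model)
        V_ab = exciton_coupling(d, a, cm)
        for alpha in range(2):
            for beta in range(2):
                brute = sum(
                    d.coefficients[i, alpha] * a.coefficients[j, beta] * V[i, 2 + j]
                    for i in range(2)
                    for j in range(2)
                )
                assert V_ab[alpha, beta] == pytest.approx(brute, abs=1e-10)


class TestExcitonLineshape:
    def test_single_pigment_reduces_to_monomer(self, chl_a_model):
        pigments = _pigment_row(["A/1/CLA"], [[0, 0, 0]])
        dom = build_domain(
            "A", pigments, ["A/1/CLA"], _fabricated_couplings(["A/1/CLA"], [[0.0]]),
            chl_a_model,
        )
        params = dom.exciton_lineshape(0)
        assert params.omega0 == CHL_A.omega0
        assert params.fwhm == CHL_A.fwhm
        assert params.stokes == CHL_A.stokes

    def test_homodimer_keeps_monomer_width(self, chl_a_model):
        ids = ["A/1/CLA", "A/2/CLA"]
        pigments = _pigment_row(ids, [[0, 0, 0], [10, 0, 0]])
        dom = build_domain(
            "A", pigments, ids, _fabricated_couplings(ids, [[0, 80], [80, 0]]),
            chl_a_model,
        )
        for alpha in range(2):
            assert dom.exciton_lineshape(alpha).fwhm == pytest.approx(240.0)

    def test_heterodimer_width_between_monomers(self):
        ids = ["A/1/CLA", "A/2/KC1"]
        pigments = PigmentSet(
            [
                make_pigment("A/1/CLA", [0, 0, 0], [0, 0, 1], chain="A", resnum=1),
                make_pigment(
                    "A/2/KC1", [10, 0, 0], [0, 0, 1], chain="A", resnum=2,
                    pigment_type=PigmentType.CHL_C,
                ),
            ]
        )
        model = SpectralModel(
            by_type={
                PigmentType.CHL_A: LineshapeParams(omega0=14900.0, fwhm=200.0, stokes=160.0),
                PigmentType.CHL_C: LineshapeParams(omega0=15750.0, fwhm=400.0, stokes=160.0),
            }
        )
        dom = build_domain(
            "A", pigments, ids, _fabricated_couplings(ids, [[0, 60], [60, 0]]), model
        )
        for alpha in range(2):
            assert 200.0 < dom.exciton_lineshape(alpha).fwhm < 400.0


class TestDomainRate:
    def _classical_vs_generalized(self, V, omega_d, omega_a, temperature):
        ids = ["A/1/CLA", "B/1/CLA"]
        pigments = _pigment_row(ids, [[0, 0, 0], [25, 0, 0]])
        model = SpectralModel(
            by_type={PigmentType.CHL_A: CHL_A},
            by_id={
                "A/1/CLA": LineshapeParams(omega0=omega_d, fwhm=240.0, stokes=160.0),
                "B/1/CLA": LineshapeParams(omega0=omega_a, fwhm=240.0, stokes=160.0),
            },
        )
        cm = _fabricated_couplings(ids, [[0, V], [V, 0]])
        rm = rate_matrix(cm, model, _pigment_row(ids, [[0, 0, 0], [25, 0, 0]]))
        part = DomainPartition(
            members={"A": [ids[0]], "B": [ids[1]]},
            roles={"A": DomainRole.ANTENNA, "B": DomainRole.ANTENNA},
        )
        dr = all_domain_rates(part, pigments, cm, model, temperature=temperature)
        return rm.T[0, 1], dr.rate("A", "B")

    @pytest.mark.parametrize("temperature", [77.0, 300.0, 1000.0])
    def test_reduction_to_classical_forster(self, temperature):
        classical, generalized = self._classical_vs_generalized(
            35.0, 14900.0, 14650.0, temperature
        )
        assert generalized == pytest.approx(classical, rel=1e-10)

    def test_zero_exciton_couplings_give_zero_rate(self, chl_a_model):
        ids = ["A/1/CLA", "A/2/CLA", "B/1/CLA"]
        pigments = _pigment_row(ids, [[0, 0, 0], [10, 0, 0], [80, 0, 0]])
        V = np.zeros((3, 3))
        V[0, 1] = V[1, 0] = 70.0
        cm = _fabricated_couplings(ids, V)
        d = build_domain("A", pigments, ids[:2], cm, chl_a_model)
        a = build_domain("B", pigments, ids[2:], cm, chl_a_model)
        assert domain_rate(d, a, exciton_coupling(d, a, cm)) == 0.0

    def test_infinite_temperature_equalizes_donor_weights(self, chl_a_model):
        ids = ["A/1/CLA", "A/2/CLA"]
        pigments = _pigment_row(ids, [[0, 0, 0], [10, 0, 0]])
        dom = build_domain(
            "A", pigments, ids, _fabricated_couplings(ids, [[0, 120], [120, 0]]),
            chl_a_model, temperature=1e9,
        )
        assert dom.weights == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_raising_temperature_activates_upper_state(self, chl_a_model):
        """Donor dimer whose upper exciton carries all the acceptor coupling:
        heating populates it, so the transfer rate must rise."""
        ids = ["D/1/CLA", "D/2/CLA", "X/1/CLA"]
        pigments = _pigment_row(ids, [[0, 0, 0], [10, 0, 0], [40, 0, 0]])
        model = SpectralModel(
            by_type={PigmentType.CHL_A: CHL_A},
            by_id={
                "D/1/CLA": LineshapeParams(omega0=14600.0, fwhm=240.0, stokes=160.0),
                "D/2/CLA": LineshapeParams(omega0=15200.0, fwhm=240.0, stokes=160.0),
            },
        )
        V = np.zeros((3, 3))
        V[1, 2] = V[2, 1] = 60.0  # only the high-energy site couples out
        cm = _fabricated_couplings(ids, V)
        part = DomainPartition(
            members={"D": ids[:2], "X": ids[2:]},
            roles={"D": DomainRole.ANTENNA, "X": DomainRole.CORE},
        )
        rates = [
            all_domain_rates(part, pigments, cm, model, temperature=T).rate("D", "X")
            for T in (100.0, 300.0, 900.0)
        ]
        assert rates[0] < rates[1] < rates[2]

    def test_member_reordering_leaves_rates_invariant(self, rng, chl_a_model):
        ids = ["A/1/CLA", "A/2/CLA", "A/3/CLA", "B/1/CLA", "B/2/CLA"]
        centers = [[0, 0, 0], [10, 0, 0], [5, 9, 0], [60, 0, 0], [70, 0, 0]]
        pigments = _pigment_row(ids, centers)
        V = rng.normal(scale=50.0, size=(5, 5))
        V = (V + V.T) / 2.0
        np.fill_diagonal(V, 0.0)
        cm = _fabricated_couplings(ids, V)
        part1 = DomainPartition(
            members={"A": ids[:3], "B": ids[3:]},
            roles={"A": DomainRole.ANTENNA, "B": DomainRole.ANTENNA},
        )
        part2 = DomainPartition(
            members={"A": [ids[2], ids[0], ids[1]], "B": [ids[4], ids[3]]},
            roles={"A": DomainRole.ANTENNA, "B": DomainRole.ANTENNA},
        )
        k1 = all_domain_rates(part1, pigments, cm, chl_a_model)
        k2 = all_domain_rates(part2, pigments, cm, chl_a_model)
        assert k1.rate("A", "B") == pytest.approx(k2.rate("A", "B"), rel=1e-10)
        assert k1.rate("B", "A") == pytest.approx(k2.rate("B", "A"), rel=1e-10)

    def test_degenerate_trimer_rates_well_defined(self, chl_a_model):
        """Symmetric homotrimer has a doubly degenerate exciton level; the
        outgoing rate must not depend on the arbitrary basis the solver picks
        inside that subspace (probed by reordering the members)."""
        ids = ["T/1/CLA", "T/2/CLA", "T/3/CLA", "X/1/CLA"]
        pigments = _pigment_row(ids, [[0, 0, 0], [10, 0, 0], [5, 8.66, 0], [50, 0, 0]])
        V = np.zeros((4, 4))
        for i in range(3):
            for j in range(i + 1, 3):
                V[i, j] = V[j, i] = 45.0
        V[0, 3] = V[3, 0] = 20.0
        cm = _fabricated_couplings(ids, V)
        for order in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            part = DomainPartition(
                members={"T": [ids[k] for k in order], "X": ["X/1/CLA"]},
                roles={"T": DomainRole.ANTENNA, "X": DomainRole.CORE},
            )
            k = all_domain_rates(part, pigments, cm, chl_a_model).rate("T", "X")
            if order == [0, 1, 2]:
                reference = k
            assert k == pytest.approx(reference, rel=1e-10)

    def test_isolated_cluster_has_negligible_rates(self, two_point_charges, chl_a_model):
        near_a = make_pigment("A/1/CLA", [0, 0, 0], [0, 0, 1], chain="A", resnum=1)
        near_b = make_pigment("B/1/CLA", [14, 0, 0], [0, 0, 1], chain="B", resnum=1)
        far = make_pigment("F/1/CLA", [800, 0, 0], [0, 0, 1], chain="F", resnum=1)
        pigments = PigmentSet([near_a, near_b, far])
        cm = coupling_matrix(pigments, {PigmentType.CHL_A: two_point_charges})
        part = DomainPartition(
            members={"A": ["A/1/CLA"], "B": ["B/1/CLA"], "F": ["F/1/CLA"]},
            roles={d: DomainRole.ANTENNA for d in "ABF"},
        )
        dr = all_domain_rates(part, pigments, cm, chl_a_model)
        assert dr.rate("A", "B") > 1e6 * dr.rate("F", "A")
        assert dr.rate("F", "B") < 1e-9


def test_classical_rate_helper_consistency():
    """domain_rate's prefactor is the same C_rate used by pairwise_rate."""
    from eetkit.lineshapes import overlap_integral

    J = overlap_integral(CHL_A, CHL_A)
    assert pairwise_rate(25.0, J) == pytest.approx(
        1.1835 * 625.0 * J, rel=1e-4
    )
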