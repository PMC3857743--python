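"""Fixed points, Jacobians, MLE and stiffness."""

import numpy as np
import pytest

from spikestab.network import GainFunction, NetworkSpec
from spikestab.stability import (
    FixedPointReport,
    NotAnAttractorError,
    effective_couplings,
    find_fixed_points,
    jacobian,
    mle,
    mle_two_node_closed_form,
    stiffness,
    stiffness_mle_concordance,
)

from conftest import gain_through


def report_from_jacobian(J, tau=1.0):
    eig = np.linalg.eigvals(J)
    cls = "stable focus" if np.all(eig.real < 0) else "saddle"
    return FixedPointReport(
        location=np.zeros(J.shape[0]), jacobian=J, eigenvalues=eig,
        mle=float(np.max(eig.real)), classification=cls, tau=tau,
    )


class TestFindFixedPoints:
    def test_zero_gain_network_has_origin_fixed_point(self):
        net = NetworkSpec(
            weights=np.array([[0, 1], [1, 0]]),
            gains={(0, 1): GainFunction(c=0.0, B=0.0), (1, 0): GainFunction(c=0.0, B=0.0)},
            sigma=0.0,
        )
        reports = find_fixed_points(net)
        assert len(reports) == 1
        assert np.allclose(reports[0].location, 0.0, atol=1e-8)
        assert reports[0].mle == pytest.approx(-1.0 / net.tau)

    def test_residual_below_tolerance(self, mutual_excitation_net):
        for rep in find_fixed_points(mutual_excitation_net(eta2=2.0)):
            assert rep.residual < 1e-8

    def test_mutual_inhibition_past_pitchfork_has_three_points(self):
        """Brute-force oracle: sign changes of x - g(g(x)) on the diagonal map."""
        s = np.sqrt(1.3)
        net = NetworkSpec(
            weights=np.array([[0, -1], [-1, 0]]),
            gains={(0, 1): gain_through(0.5, s), (1, 0): gain_through(0.5, s)},
            sigma=0.0,
            bias=np.array([1.0, 1.0]),
        )
        g = net.gains[(0, 1)]
        xs = np.linspace(0, 1.02, 20_001)  # the winner-take-all root sits at x = 1
        h = 1.0 - np.clip(g.unclipped(1.0 - np.clip(g.unclipped(xs), 0, 1)), 0, 1) - xs
        signs = np.sign(h)
        signs = signs[signs != 0]  # grid points landing exactly on a root
        crossings = np.sum(signs[1:] != signs[:-1])
        reports = find_fixed_points(net)
        assert crossings == len(reports) == 3
        kinds = sorted(r.classification for r in reports)
        assert kinds == ["saddle", "stable node", "stable node"]


class TestJacobian:
    def test_matches_central_finite_differences(self, rng):
        """Analytic vs numeric Jacobian at 100 random parameter points."""
        for _ in range(100):
            slopes = rng.uniform(0.1, 2.0, size=2)
            values = rng.uniform(0.2, 0.8, size=2)
            net = NetworkSpec(
                weights=np.array([[0, 1], [-1, 0]]),
                gains={(0, 1): gain_through(values[0], slopes[0]),
                       (1, 0): gain_through(values[1], slopes[1])},
                sigma=0.0,
                bias=np.array([0.0, 1.0]),
            )
            x = rng.uniform(0.2, 0.8, size=2)
            J, _ = jacobian(net, x)
            h = 1e-6
            J_num = np.empty((2, 2))
            for j in range(2):
                e = np.zeros(2)
                e[j] = h
                J_num[:, j] = (net.drift(x + e) - net.drift(x - e)) / (2 * h)
            assert np.allclose(J, J_num, rtol=1e-6, atol=1e-9)

    def test_clipped_edges_have_zero_derivative_and_are_flagged(self):
        net = NetworkSpec(
            weights=np.array([[0, 1], [1, 0]]),
            gains={(0, 1): GainFunction(c=1.0, B=-0.9, theta=0.5),  # clipped at small x
                   (1, 0): GainFunction(c=1.0, B=0.0, theta=0.5)},
            sigma=0.0,
        )
        J, clipped = jacobian(net, np.array([0.5, 0.05]))
        assert clipped == ((0, 1),)
        assert J[0, 1] == 0.0
        etas = effective_couplings(net, np.array([0.5, 0.05]))
        assert etas[(0, 1)] == 0.0 and etas[(1, 0)] > 0


class TestMLE:
    def test_uncoupled_node_decays_at_one_over_tau(self, mutual_excitation_net):
        net = mutual_excitation_net(eta1=0.0, eta2=0.0)
        rep = find_fixed_points(net)[0]
        assert mle(rep) == pytest.approx(-1.0 / 20.0, abs=1e-12)

    @pytest.mark.parametrize("slope", [0.2, 0.6, 1.0])
    def test_excitation_inhibition_mle_is_exactly_minus_one_over_tau(self, exc_inh_net, slope):
        """Complex eigenvalues: the MLE is blind to the coupling strength."""
        rep = find_fixed_points(exc_inh_net(slope=slope))[0]
        assert rep.mle_normalized == pytest.approx(-1.0, abs=1e-9)

    def test_two_node_closed_form_matches_eigensolver(self, mutual_excitation_net, rng):
        for _ in range(20):
            e1, e2 = rng.uniform(0.05, 1.5, size=2)
            net = mutual_excitation_net(eta1=e1, eta2=e2)
            reports = find_fixed_points(net)
            rep = min(reports, key=lambda r: np.max(np.abs(r.location - 0.5)))
            assert rep.mle == pytest.approx(
                mle_two_node_closed_form(e1, e2, net.tau), abs=1e-9
            )

    def test_normalized_closed_form_value(self):
        # eta12 = eta21 = 0.5 with tau = 1: eigenvalues -1 +/- 0.5
        assert mle_two_node_closed_form(0.5, 0.5, 1.0) == pytest.approx(-0.5)


class TestStiffness:
    def test_uncoupled_two_node_normalized_stiffness_is_one(self, mutual_excitation_net):
        rep = find_fixed_points(mutual_excitation_net(eta1=0.0, eta2=0.0))[0]
        assert stiffness(rep, normalized=True) == pytest.approx(1.0, abs=1e-9)

    def test_excitation_inhibition_unit_product_gives_two(self, exc_inh_net):
        rep = find_fixed_points(exc_inh_net(slope=1.0))[0]
        assert stiffness(rep, normalized=True) == pytest.approx(2.0, abs=1e-9)

    def test_determinant_equals_eigenvalue_product_on_random_jacobians(self, rng):
        """Independent eigen-solver oracle on random stable 3x3 Jacobians."""
        for _ in range(50):
            J = rng.normal(size=(3, 3))
            J = J - (np.max(np.linalg.eigvals(J).real) + 0.5) * np.eye(3)
            rep = report_from_jacobian(J)
            expected = np.prod(-np.linalg.eigvals(J)).real
            assert stiffness(rep) == pytest.approx(expected, abs=1e-10 * max(1, abs(expected)))

    def test_rejects_non_attractors(self):
        rep = report_from_jacobian(np.array([[0.5, 0.0], [0.0, -1.0]]))
        with pytest.raises(NotAnAttractorError):
            stiffness(rep)

    def test_positive_for_all_attractors_and_vanishes_at_criticality(
        self, mutual_excitation_net
    ):
        values = []
        for eta2 in (0.3, 1.5, 2.8, 3.3):
            rep = min(
                find_fixed_points(mutual_excitation_net(eta1=0.3, eta2=eta2)),
                key=lambda r: np.max(np.abs(r.location - 0.5)),
            )
            s = stiffness(rep, normalized=True)
            assert s > 0
            values.append(s)
        assert values == sorted(values, reverse=True)  # -> 0 as MLE -> 0


class TestStiffnessMleConcordance:
    def test_closed_form_holds_on_the_real_eigenvalue_grid(self, mutual_excitation_net):
        """s*tau^2 swept 1.0 -> 0.0 in 0.25 steps: MLE = (-1+sqrt(1-s*tau^2))/tau."""
        reports = []
        for s_norm in (1.0, 0.75, 0.5, 0.25, 0.0):
            eta = np.sqrt(1.0 - s_norm)
            reports.append(
                min(
                    find_fixed_points(mutual_excitation_net(eta1=eta, eta2=eta)),
                    key=lambda r: np.max(np.abs(r.location - 0.5)),
                )
            )
        max_dev, skipped = stiffness_mle_concordance(reports)
        assert max_dev < 1e-10
        assert skipped == []

    def test_complex_eigenvalue_reports_are_skipped(self, exc_inh_net):
        rep = find_fixed_points(exc_inh_net(slope=0.8))[0]
        max_dev, skipped = stiffness_mle_concordance([rep])
        assert skipped == [rep] and max_dev == 0.0


class TestClassification:
    def test_near_critical_point_is_non_hyperbolic(self, mutual_excitation_net):
        eta = 1.0  # coupling product exactly 1: eigenvalue 0
        reports = find_fixed_points(mutual_excitation_net(eta1=eta, eta2=eta))
        rep = min(reports, key=lambda r: np.max(np.abs(r.location - 0.5)))
        assert rep.classification == "non-hyperbolic"

    def test_focus_vs_node(self, exc_inh_net, mutual_excitation_net):
        assert find_fixed_points(exc_inh_net(slope=0.8))[0].classification == "stable focus"
        rep = min(
            find_fixed_points(mutual_excitation_net()),
            key=lambda r: np.max(np.abs(r.location - 0.5)),
        )
        assert rep.classification == "stable node"

    def test_report_serialises_to_json_dict(self, exc_inh_net):
        rep = find_fixed_points(exc_inh_net(slope=0.5))[0]
        d = rep.to_dict()
        assert set(d) >= {"location", "eigenvalues", "mle", "classification", "stiffness"}
        assert d["stiffness_normalized"] == pytest.approx(1.25, abs=1e-8)  # 1 + 0.5^2
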