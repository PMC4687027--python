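import collections

import numpy as np
import pytest

from solentile import (
    ANK_CONSENSUS,
    EnergyModel,
    SolenoidSpec,
    assign_phase,
    best_foldability_fragment,
    build_solenoid,
    contact_map,
    extract_fragment,
    fragment_energy,
    model_from_arrays,
    phase_distribution,
    relative_foldability,
)
from solentile.phasing import foldability_from_energies
from solentile.structmodel import AA_INDEX
from conftest import rotated_copy


def _potential(entries=None, fill=0.0):
    p = np.full((20, 20), fill)
    for (a, b), v in (entries or {}).items():
        p[AA_INDEX[a], AA_INDEX[b]] = v
        p[AA_INDEX[b], AA_INDEX[a]] = v
    return p


class TestFragmentEnergy:
    def test_no_contacts_is_zero(self):
        m = model_from_arrays("AL", np.array([[0, 0, 0], [30.0, 0, 0]]))
        em = EnergyModel(burial_weight=0.0)
        assert fragment_energy(m, "A", extract_fragment(m, "A", 0, 2), em) == 0.0

    def test_single_handset_contact(self):
        ca = np.array([[0, 0, 0], [4.0, 0, 0], [8.0, 0, 0], [1.0, 5.0, 0]])
        m = model_from_arrays("AGGL", ca)
        em = EnergyModel(
            pair_potential=_potential({("A", "L"): -2.0}),
            burial_weight=0.0, scheme="CA", cutoff=6.0, min_separation=3,
        )
        e = fragment_energy(m, "A", extract_fragment(m, "A", 0, 4), em)
        assert e == pytest.approx(-2.0)

    def test_matches_bruteforce_oracle(self, noisy_solenoid):
        """Sum over an O(n^2) contact enumeration equals fragment_energy."""
        model, _ = noisy_solenoid
        em = EnergyModel()
        frag = extract_fragment(model, "A", 30, 40)
        got = fragment_energy(model, "A", frag, em)
        xyz = model.cb_coords("A")
        seq = model.sequence("A")
        expected = 0.0
        burial = 0
        for i in range(30, 70):
            for j in range(i + 3, 70):
                if np.linalg.norm(xyz[i] - xyz[j]) <= 8.0:
                    expected += em.eps(seq[i], seq[j])
                    burial += 2
        expected += em.burial_weight * burial
        assert got == pytest.approx(expected)

    def test_rigid_invariance(self, noisy_solenoid):
        model, _ = noisy_solenoid
        em = EnergyModel()
        frag = extract_fragment(model, "A", 0, 33)
        moved = rotated_copy(model)
        frag2 = extract_fragment(moved, "A", 0, 33)
        assert fragment_energy(model, "A", frag, em) == pytest.approx(
            fragment_energy(moved, "A", frag2, em), abs=1e-9
        )


class TestFoldability:
    def test_hand_computed_statistics(self):
        """Three fragments with energies {-10, -6, -2}: the best one scores
        (mean - E)/(sd*n) = (-4+10)/(2.828*2) ~ 1.061."""
        recs = foldability_from_energies([-10.0, -6.0, -2.0])
        r0 = recs[0]
        assert r0.mean_E_set == pytest.approx(-4.0)
        assert r0.sd_E_set == pytest.approx(2.828, abs=1e-3)
        assert r0.set_size == 2
        assert r0.theta_fold == pytest.approx(1.0607, abs=1e-3)

    def test_degenerate_equal_energies(self):
        with pytest.raises(ValueError):
            foldability_from_energies([3.0, 3.0, 3.0])

    def test_zscore_variant(self):
        recs = foldability_from_energies([-10.0, -6.0, -2.0], z_score_only=True)
        assert recs[0].theta_fold == pytest.approx(6 / 2.828, abs=1e-3)

    def test_mean_theta_near_zero_on_periodic_chain(self, perfect_solenoid):
        model, _ = perfect_solenoid
        recs = relative_foldability(model, "A", 33, EnergyModel())
        thetas = [r.theta_fold for r in recs if r.defined]
        assert abs(np.mean(thetas)) < 0.5

    def test_phase_recovery_battery(self):
        """The best-foldability fragment starts at the construction phase in
        at least 18 of 20 seeded replicates."""
        em = EnergyModel()
        rng = np.random.default_rng(42)
        hits = 0
        for seed in range(20):
            phase = int(rng.integers(33))
            model, _ = build_solenoid(
                SolenoidSpec(n_units=6, noise_sd=0.3, mutation_rate=0.05,
                             seed=seed, phase=phase)
            )
            best = best_foldability_fragment(
                relative_foldability(model, "A", 33, em)
            )
            hits += (best.start + phase) % 33 == 0
        assert hits >= 18


class TestAssignPhase:
    def test_consensus_is_offset_zero(self):
        assert assign_phase(ANK_CONSENSUS).phase_offset == 0

    @pytest.mark.parametrize("k", [1, 7, 16, 32])
    def test_rotation_recovery(self, k):
        rotated = ANK_CONSENSUS[k:] + ANK_CONSENSUS[:k]
        assert assign_phase(rotated).phase_offset == k

    def test_rotation_composition_property(self):
        """assign_phase(rotate(s, k)) == (assign_phase(s) + k) mod period."""
        seq = ANK_CONSENSUS[5:] + ANK_CONSENSUS[:5]
        base = assign_phase(seq).phase_offset
        for k in (3, 11, 20):
            rot = seq[k:] + seq[:k]
            assert assign_phase(rot).phase_offset == (base + k) % 33

    def test_rejects_bad_residues(self):
        with pytest.raises(ValueError):
            assign_phase("B" * 33)
        with pytest.raises(ValueError):
            assign_phase("AL")


class TestPhaseDistribution:
    def test_identical_solenoids_single_bin(self):
        model, _ = build_solenoid(
            SolenoidSpec(n_units=4, noise_sd=0.1, mutation_rate=0.0, seed=1)
        )
        chains = [(model, "A")] * 3
        hist = phase_distribution(chains, "energetic")
        assert len(hist) == 1
        assert list(hist.values()) == [3]

    def test_two_construction_phases_two_bins(self):
        chains = []
        for phase in (0, 0, 9):
            m, _ = build_solenoid(
                SolenoidSpec(n_units=5, noise_sd=0.1, mutation_rate=0.0,
                             seed=3, phase=phase)
            )
            chains.append((m, "A"))
        hist = phase_distribution(chains, "energetic")
        assert len(hist) == 2
        assert sorted(hist.values()) == [1, 2]

    def test_geometric_reports_tied_phases(self, perfect_solenoid):
        """A perfect solenoid admits several tied tile phases at the period."""
        model, _ = perfect_solenoid
        hist = phase_distribution([(model, "A")], "geometric", period=33)
        assert sum(hist.values()) >= 1
        assert all(0 <= k < 33 for k in hist)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            phase_distribution([], "energetic")
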