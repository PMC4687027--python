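import numpy as np
import pytest

from solentile import (
    EXHAUSTIVE,
    EnergyModel,
    SolenoidSpec,
    Thresholds,
    build_solenoid,
    build_system,
    classify,
    configurational_frustration,
    frustration_by_region,
    chain_residue_frustration,
    model_from_arrays,
    mutational_frustration,
    native_energy,
    single_residue_frustration,
)
from solentile.frustration import HIGH, MINIMAL, NEUTRAL
from solentile.structmodel import AA_INDEX
from solentile.synthgen import Indel

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _potential(entries=None, fill=0.0):
    p = np.full((20, 20), fill)
    for (a, b), v in (entries or {}).items():
        p[AA_INDEX[a], AA_INDEX[b]] = v
        p[AA_INDEX[b], AA_INDEX[a]] = v
    return p


def _line_model(seq, spacing=5.0):
    n = len(seq)
    ca = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    return model_from_arrays(seq, ca)


@pytest.fixture
def uniform_chain():
    """All 20 residue types once, first and last brought into contact."""
    seq = AA20
    ca = np.column_stack([np.arange(20) * 5.0, np.zeros(20), np.zeros(20)])
    ca[19] = [6.0, 5.0, 0.0]  # near residue 0 and 1
    return model_from_arrays(seq, ca)


class TestNativeEnergy:
    def test_no_contacts(self):
        m = _line_model("ALKG", spacing=30.0)
        em = EnergyModel(burial_weight=0.0, scheme="CA", cutoff=8.0)
        total, per_contact = native_energy(m, "A", em)
        assert total == 0.0 and per_contact == {}

    def test_single_contact(self):
        m = _line_model("AGGL", spacing=2.5)
        em = EnergyModel(
            pair_potential=_potential({("A", "L"): -1.5}),
            burial_weight=0.0, scheme="CA", cutoff=8.0, min_separation=3,
        )
        total, per_contact = native_energy(m, "A", em)
        assert total == pytest.approx(-1.5)
        assert per_contact == {(0, 3): -1.5}

    def test_matches_bruteforce(self, noisy_solenoid):
        model, _ = noisy_solenoid
        em = EnergyModel()
        total, per_contact = native_energy(model, "A", em)
        xyz = model.cb_coords("A")
        seq = model.sequence("A")
        n = len(seq)
        exp = 0.0
        deg = np.zeros(n)
        for i in range(n):
            for j in range(i + 3, n):
                if np.linalg.norm(xyz[i] - xyz[j]) <= 8.0:
                    exp += em.eps(seq[i], seq[j])
                    deg[i] += 1
                    deg[j] += 1
        exp += em.burial_weight * deg.sum()
        assert total == pytest.approx(exp)


class TestMutational:
    def test_exhaustive_matches_enumeration_oracle(self, uniform_chain):
        """Potential with a unique minimum at the native pair: the z-score
        equals an explicit loop over all 400 ordered decoys."""
        em = EnergyModel(
            pair_potential=_potential({("A", "Y"): -5.0}),
            burial_weight=0.0, scheme="CA", cutoff=8.0, min_separation=3,
        )
        rec = mutational_frustration(uniform_chain, (0, 19), em,
                                     n_decoys=EXHAUSTIVE)
        energies = [
            em.pair_potential[a, b] for a in range(20) for b in range(20)
        ]
        mean = np.mean(energies)
        sd = np.std(energies)
        expected = (mean - (-5.0)) / sd
        assert rec.F_i == pytest.approx(expected)
        assert rec.klass == MINIMAL

    def test_flat_potential_is_undefined(self, uniform_chain):
        em = EnergyModel(pair_potential=np.full((20, 20), -1.0),
                         burial_weight=0.0, scheme="CA", cutoff=8.0)
        rec = mutational_frustration(uniform_chain, (0, 19), em,
                                     n_decoys=EXHAUSTIVE)
        assert not rec.defined
        assert rec.klass == NEUTRAL

    def test_sampled_mode_is_seed_reproducible(self, uniform_chain):
        em = EnergyModel(scheme="CA", cutoff=8.0)
        a = mutational_frustration(uniform_chain, (0, 19), em, 500, seed=11)
        b = mutational_frustration(uniform_chain, (0, 19), em, 500, seed=11)
        assert a.F_i == b.F_i

    def test_sampled_converges_to_exhaustive(self, uniform_chain):
        em = EnergyModel(scheme="CA", cutoff=8.0, burial_weight=0.0)
        ex = mutational_frustration(uniform_chain, (0, 19), em, EXHAUSTIVE)
        sm = mutational_frustration(uniform_chain, (0, 19), em, 2000, seed=0)
        assert abs(ex.F_i - sm.F_i) < 0.1

    def test_shift_invariance(self, uniform_chain):
        """Adding a constant to every pair-potential entry leaves F unchanged."""
        base = _potential({("A", "Y"): -5.0}, fill=0.5)
        em1 = EnergyModel(pair_potential=base, burial_weight=0.0,
                         scheme="CA", cutoff=8.0)
        em2 = EnergyModel(pair_potential=base + 7.0, burial_weight=0.0,
                         scheme="CA", cutoff=8.0)
        f1 = mutational_frustration(uniform_chain, (0, 19), em1, EXHAUSTIVE)
        f2 = mutational_frustration(uniform_chain, (0, 19), em2, EXHAUSTIVE)
        assert f1.F_i == pytest.approx(f2.F_i)

    def test_not_a_contact_raises(self, uniform_chain):
        em = EnergyModel(scheme="CA", cutoff=8.0)
        with pytest.raises(ValueError):
            mutational_frustration(uniform_chain, (0, 10), em, EXHAUSTIVE)


class TestConfigurational:
    def test_reduces_to_mutational_without_environment_terms(self, uniform_chain):
        """With burial off the environment resampling is inert, so the two
        flavours coincide under a shared seed."""
        em = EnergyModel(scheme="CA", cutoff=8.0, burial_weight=0.0)
        fm = mutational_frustration(uniform_chain, (0, 19), em, 800, seed=5)
        fc = configurational_frustration(uniform_chain, (0, 19), em, 800, seed=5)
        assert fc.F_i == pytest.approx(fm.F_i)

    def test_burial_term_amplifies_buried_pair(self):
        """A pair whose identities are energetically typical but which is
        unusually buried: mutational decoys see nothing special (F ~ 0)
        while configurational decoys, which re-draw the burial environment,
        flag it as minimally frustrated."""
        # tight core of alternating A/L, long dispersed tail of the same
        # composition: native pair (A, L) has the composition-mean pair
        # energy, but its burial is far above the chain's typical burial
        rng = np.random.default_rng(0)
        core = rng.normal(scale=2.5, size=(6, 3))
        tail = np.column_stack(
            [np.arange(30) * 9.0 + 25.0, np.zeros(30), np.zeros(30)]
        )
        ca = np.vstack([core, tail])
        m = model_from_arrays("AL" * 18, ca)
        em = EnergyModel(
            pair_potential=_potential({("A", "A"): -1.0, ("L", "L"): 1.0}),
            burial_weight=-1.5, scheme="CA", cutoff=8.0, min_separation=3,
        )
        sysm = build_system(m, ["A"], em)
        pair = next(p for p in sorted(sysm.contacts)
                    if sysm.seq[p[0]] != sysm.seq[p[1]])
        fm = mutational_frustration(m, pair, em, 2000, seed=1, system=sysm)
        fc = configurational_frustration(m, pair, em, 2000, seed=1, system=sysm)
        assert abs(fm.F_i) < 0.5
        assert abs(fc.F_i) > abs(fm.F_i) + 0.5

    def test_seed_reproducible(self, uniform_chain):
        em = EnergyModel(scheme="CA", cutoff=8.0)
        a = configurational_frustration(uniform_chain, (0, 19), em, 300, seed=2)
        b = configurational_frustration(uniform_chain, (0, 19), em, 300, seed=2)
        assert a.F_i == b.F_i


class TestSingleResidue:
    def test_isolated_residue_is_undefined(self):
        m = _line_model("ALK", spacing=30.0)
        em = EnergyModel(burial_weight=0.0, scheme="CA", cutoff=8.0)
        rec = single_residue_frustration(m, 1, em)
        assert not rec.defined
        assert rec.n_contacts == 0

    def test_hand_computed_over_19_substitutions(self):
        """3-residue toy with one interacting neighbour pair: F equals the
        z-score over explicit substitution energies."""
        ca = np.array([[0, 0, 0], [2.5, 0, 0], [5.0, 0, 0]])
        m = model_from_arrays("ALA", ca)
        pot = _potential({("L", "A"): -3.0, ("C", "A"): 1.0, ("G", "A"): 2.0,
                          ("W", "A"): -1.0})
        em = EnergyModel(pair_potential=pot, burial_weight=0.0,
                         scheme="CA", cutoff=8.0, min_separation=1)
        rec = single_residue_frustration(m, 1, em)
        # residue 1 ('L') contacts residues 0 and 2 (both 'A')
        e_native = 2 * pot[AA_INDEX["L"], AA_INDEX["A"]]
        decoys = [
            2 * pot[k, AA_INDEX["A"]]
            for k in range(20)
            if k != AA_INDEX["L"]
        ]
        expected = (np.mean(decoys) - e_native) / np.std(decoys)
        assert rec.F_i == pytest.approx(expected)
        assert rec.n_contacts == 2

    def test_exhaustive_is_seed_independent(self, uniform_chain):
        em = EnergyModel(scheme="CA", cutoff=8.0)
        a = single_residue_frustration(uniform_chain, 0, em, seed=1)
        b = single_residue_frustration(uniform_chain, 0, em, seed=99)
        assert a.F_i == b.F_i


class TestClassify:
    @pytest.mark.parametrize(
        "F,expected",
        [(2.0, MINIMAL), (0.78, MINIMAL), (-1.5, HIGH), (-1.0, HIGH),
         (0.0, NEUTRAL), (0.77, NEUTRAL), (None, NEUTRAL),
         (float("nan"), NEUTRAL)],
    )
    def test_cut_points(self, F, expected):
        assert classify(F) == expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            Thresholds(minimal_ge=-2.0, high_le=0.0)


class TestRegions:
    def test_single_label_equals_global(self, noisy_solenoid):
        model, _ = noisy_solenoid
        recs = chain_residue_frustration(model, "A")
        n = model.n_residues("A")
        summary = frustration_by_region(recs, {"all": set(range(n))})["all"]
        assert summary.n == n
        global_vals = [r.F_i for r in recs if r.defined]
        assert summary.mean_F == pytest.approx(np.mean(global_vals))

    def test_destabilized_insertion_is_enriched_in_high(self):
        """With a potential that penalizes polar-polar pairs the inserted
        loop (polar residues) shows a larger highly-frustrated fraction
        than the repeat body."""
        model, truth = build_solenoid(
            SolenoidSpec(n_units=4, noise_sd=0.2, mutation_rate=0.0,
                         indels=(Indel(1, "INSERTION", 15, 8),), seed=13)
        )
        pot = np.zeros((20, 20))
        polar = [AA_INDEX[a] for a in "GSTNDPQEKR"]
        for a in polar:
            for b in polar:
                pot[a, b] = 3.0
        hydro = [AA_INDEX[a] for a in "AVLIMFWC"]
        for a in hydro:
            for b in hydro:
                pot[a, b] = -2.0
        em = EnergyModel(pair_potential=pot, burial_weight=0.0)
        recs = chain_residue_frustration(model, "A", em)
        ins = {i for i, c in enumerate(truth.canonical_map) if c is None}
        rep = {i for i, c in enumerate(truth.canonical_map) if c is not None}
        out = frustration_by_region(recs, {"ins": ins, "rep": rep})
        assert out["ins"].class_fractions[HIGH] > out["rep"].class_fractions[HIGH]
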