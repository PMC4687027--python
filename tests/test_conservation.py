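import math

import numpy as np
import pytest

from solentile import (
    canonical_contact_map,
    conserved_network,
    frustration_ic,
    ic_correlation,
    sequence_ic,
)
from solentile.annotate import (
    C_TERMINAL,
    INTERNAL,
    MSARow,
    N_TERMINAL,
    RepeatArray,
    RepeatUnit,
    StructMSA,
)
from solentile.conservation import ICProfile, PositionIC
from solentile.frustration import ContactFrustration, HIGH, MINIMAL, NEUTRAL

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _msa_from_columns(columns):
    """Fabricate a StructMSA whose target rows realize the given columns."""
    n_rows = len(columns[0])
    rows = [
        MSARow(label=f"r{i}", text="".join(col[i] for col in columns),
               is_query=False)
        for i in range(n_rows)
    ]
    return StructMSA(rows=rows,
                     column_canonical=list(range(1, len(columns) + 1)),
                     period=len(columns))


class TestSequenceIC:
    def test_fully_conserved_column(self):
        msa = _msa_from_columns(["LLLL"])
        p = sequence_ic(msa).positions[0]
        assert p.H_obs == 0.0
        assert p.R == pytest.approx(math.log2(20))

    def test_uniform_column_has_zero_ic(self):
        msa = _msa_from_columns([AA20])
        p = sequence_ic(msa).positions[0]
        assert p.R == pytest.approx(0.0, abs=1e-12)

    def test_half_and_half_column(self):
        msa = _msa_from_columns(["AALL"])
        p = sequence_ic(msa).positions[0]
        assert p.H_obs == pytest.approx(1.0)
        assert p.R == pytest.approx(math.log2(20) - 1.0)

    def test_gaps_are_excluded_from_counts(self):
        msa = _msa_from_columns(["LL--"])
        p = sequence_ic(msa).positions[0]
        assert p.n_obs == 2
        assert p.R == pytest.approx(math.log2(20))

    def test_all_gap_column_is_flagged(self):
        msa = _msa_from_columns(["LLLL", "----"])
        prof = sequence_ic(msa)
        assert prof.positions[1].defined is False

    def test_requires_two_rows(self):
        msa = _msa_from_columns(["L"])
        with pytest.raises(ValueError):
            sequence_ic(msa)

    def test_never_exceeds_log2_20(self, noisy_solenoid):
        from solentile import build_struct_msa, extract_fragment

        model, truth = noisy_solenoid
        s, e = truth.unit_boundaries[1]
        frag = extract_fragment(model, "A", s, e - s)
        msa, _ = build_struct_msa(frag, [(model, "A")], 33)
        R = sequence_ic(msa).R_values()
        assert np.nanmax(R) <= math.log2(20) + 1e-12


class TestFrustrationIC:
    def test_conserved_state_uniform_background(self):
        prof = frustration_ic([[MINIMAL] * 10])
        assert prof.positions[0].R == pytest.approx(math.log2(3))

    def test_uniform_states_zero_ic(self):
        prof = frustration_ic([[MINIMAL, NEUTRAL, HIGH] * 4])
        assert prof.positions[0].R == pytest.approx(0.0, abs=1e-12)

    def test_nonuniform_background_hmax(self):
        """Background (0.4, 0.5, 0.1): H_max is the background entropy,
        1.3610 bits, reached by a fully conserved state."""
        bg = (0.4, 0.5, 0.1)
        h_max = -sum(b * math.log2(b) for b in bg)
        prof = frustration_ic([[HIGH] * 6], background=bg)
        assert h_max == pytest.approx(1.3610, abs=1e-4)
        assert prof.positions[0].R == pytest.approx(h_max)

    def test_r_can_be_negative_under_sharp_background(self):
        prof = frustration_ic([[MINIMAL, NEUTRAL, HIGH]],
                              background=(0.98, 0.01, 0.01))
        assert prof.positions[0].R < 0

    def test_empty_observations_flagged(self):
        prof = frustration_ic([[]])
        assert prof.positions[0].defined is False

    def test_bad_background_rejected(self):
        with pytest.raises(ValueError):
            frustration_ic([[MINIMAL]], background=(0.5, 0.5, 0.5))


def _fake_entry(klass_by_cell, period=4, n_pairs_units=4):
    """RepeatArray with internal units 1..n-2 and synthetic contact records.

    ``klass_by_cell`` maps canonical cells (a, b) in the 2-period frame to
    either a class label (contact in every repeat pair) or a list of
    per-pair labels with None for 'absent in this pair'.
    """
    units = []
    for k in range(n_pairs_units):
        start = period * k
        units.append(
            RepeatUnit(
                start=start, end=start + period,
                klass=(N_TERMINAL if k == 0
                       else C_TERMINAL if k == n_pairs_units - 1
                       else INTERNAL),
                canonical_map={start + i: i + 1 for i in range(period)},
            )
        )
    array = RepeatArray("fake", "A", units, "q", period)
    internal = [k for k, u in enumerate(units) if u.klass == INTERNAL]
    n_pairs = len(internal) - 1
    records = []
    for (a, b), spec in klass_by_cell.items():
        labels = [spec] * n_pairs if isinstance(spec, str) else spec
        for pair_idx, label in enumerate(labels):
            if label is None:
                continue
            k1 = internal[pair_idx]
            i = units[k1].start + (a - 1)
            j = (units[k1].start + (b - 1) if b <= period
                 else units[k1 + 1].start + (b - period - 1))
            records.append(
                ContactFrustration(
                    pair=(min(i, j), max(i, j)), E_native=0.0, decoy_mean=0.0,
                    decoy_sd=1.0, F_i=0.0, klass=label, flavour="MUTATIONAL",
                )
            )
    return array, records


class TestCanonicalContactMap:
    def test_single_pair_frequencies_are_zero_or_one(self):
        array, records = _fake_entry({(1, 3): MINIMAL}, n_pairs_units=4)
        cmap = canonical_contact_map([(array, records)], period=4)
        assert cmap.n_pairs == 1
        assert all(c.frequency in (0.0, 1.0) for c in cmap.cells.values())

    def test_conserved_cell_reaches_hmax(self):
        array, records = _fake_entry({(1, 6): MINIMAL}, n_pairs_units=5)
        cmap = canonical_contact_map([(array, records)], period=4)
        cell = cmap.cells[(1, 6)]
        assert cell.frequency == 1.0
        assert cell.most_informative == MINIMAL
        assert cell.weighted_ic == pytest.approx(math.log2(3))

    def test_rare_contact_is_frequency_weighted(self):
        """Present in 1 of 4 pairs with a conserved state: IC = 0.25 * R."""
        array, records = _fake_entry(
            {(2, 3): [MINIMAL, None, None, None]}, n_pairs_units=7,
        )
        cmap = canonical_contact_map([(array, records)], period=4)
        cell = cmap.cells[(2, 3)]
        assert cell.frequency == pytest.approx(0.25)
        assert cell.weighted_ic == pytest.approx(0.25 * math.log2(3))

    def test_contribution_partition(self):
        array, records = _fake_entry(
            {(1, 3): [MINIMAL, MINIMAL, NEUTRAL, HIGH]}, n_pairs_units=7,
        )
        cmap = canonical_contact_map([(array, records)], period=4)
        cell = cmap.cells[(1, 3)]
        total = sum(cell.R * (v / sum(cell.counts.values()))
                    for v in cell.counts.values())
        assert total == pytest.approx(cell.R)

    def test_no_internal_pairs_raises(self):
        array, records = _fake_entry({(1, 3): MINIMAL}, n_pairs_units=3)
        with pytest.raises(ValueError):
            canonical_contact_map([(array, records)], period=4)


class TestConservedNetwork:
    def test_cell_above_neutral_max_is_returned(self):
        array, records = _fake_entry(
            {
                (1, 6): MINIMAL,  # conserved inter-repeat cell
                (2, 3): [MINIMAL, NEUTRAL, NEUTRAL, MINIMAL],  # neutral-ish
            },
            n_pairs_units=7,
        )
        cmap = canonical_contact_map([(array, records)], period=4)
        net = conserved_network(cmap)
        pairs = [m[0] for m in net.members]
        assert (1, 6) in pairs
        tags = {m[0]: m[2] for m in net.members}
        assert tags[(1, 6)] == "inter"

    def test_monotone_in_cell_ic(self):
        """Raising a non-neutral cell's IC never evicts other members."""
        base, rec_a = _fake_entry(
            {(1, 6): MINIMAL, (1, 3): [MINIMAL, MINIMAL, MINIMAL, NEUTRAL]},
            n_pairs_units=7,
        )
        cmap = canonical_contact_map([(base, rec_a)], period=4)
        before = {m[0] for m in conserved_network(cmap).members}
        boosted, rec_b = _fake_entry(
            {(1, 6): MINIMAL, (1, 3): MINIMAL}, n_pairs_units=7,
        )
        cmap2 = canonical_contact_map([(boosted, rec_b)], period=4)
        after = {m[0] for m in conserved_network(cmap2).members}
        assert before <= after

    def test_no_neutral_cells_warns_and_uses_zero(self, caplog):
        array, records = _fake_entry({(1, 6): MINIMAL}, n_pairs_units=5)
        cmap = canonical_contact_map([(array, records)], period=4)
        net = conserved_network(cmap)
        assert net.threshold == 0.0
        assert len(net.members) == 1


def _profile(values):
    return ICProfile(
        positions=[
            PositionIC(i + 1, {}, 0.0, 1.0, v, 10) for i, v in enumerate(values)
        ],
        alphabet_size=3,
    )


class TestICCorrelation:
    def test_identical_profiles(self):
        p = _profile([0.1, 0.5, 0.9, 1.2, 0.3])
        r, pv, n = ic_correlation(p, p)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_anti_correlated_profiles(self):
        a = _profile([0.1, 0.4, 0.8, 1.2, 1.5])
        b = _profile([1.5, 1.2, 0.8, 0.4, 0.1])
        r, pv, n = ic_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_too_few_points(self):
        a = _profile([0.1, 0.2])
        with pytest.raises(ValueError):
            ic_correlation(a, a)

    def test_frame_mismatch(self):
        with pytest.raises(ValueError):
            ic_correlation(_profile([0.1] * 4), _profile([0.1] * 5))
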