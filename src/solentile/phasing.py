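"""Energetic phase selection for repeat arrays.

Among all fragments of the period length, the energetically preferred phase
is the one whose internal energy stands out from the distribution over the
other same-length fragments: the relative foldability

    theta_fold = (mean_E_set - E_frag) / (sd_E_set * set_size)

is highest for the fragment whose internal interactions are most favourable
relative to the rest of the array (higher = more foldable under this sign
convention). The start of the best fragment, modulo the period, is the
energetic phase. Phases are reported relative to a bundled 33-position
ankyrin consensus profile.

The energy is an injectable coarse contact model (default: a
hydrophobicity-driven quasichemical pair potential plus a linear burial
term), not a full force field; the procedure only requires an internal
energy capable of ranking fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structmodel import (
    AMINO_ACIDS,
    AA_INDEX,
    CB,
    ContactMap,
    Fragment,
    StructureModel,
    contact_map,
)

# Kyte–Doolittle hydropathy, rescaled to [0, 1]
_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
_CHARGE = {"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0}


def default_pair_potential() -> np.ndarray:
    """Hydrophobicity-product contact potential (dominant quasichemical
    mode of knowledge-based pair potentials) with a small electrostatic
    correction. Lower = more favourable; symmetric 20x20."""
    h = np.array([(_KD[a] + 4.5) / 9.0 for a in AMINO_ACIDS])
    q = np.array([_CHARGE.get(a, 0.0) for a in AMINO_ACIDS])
    eps = -2.0 * np.outer(h, h) + 0.3 * np.outer(q, q)
    return (eps + eps.T) / 2.0


@dataclass
class EnergyModel:
    pair_potential: np.ndarray = field(default_factory=default_pair_potential)
    burial_weight: float = -0.2  # negative: burial is favourable
    scheme: str = CB
    cutoff: float = 8.0
    min_separation: int = 3

    def __post_init__(self) -> None:
        p = np.asarray(self.pair_potential, dtype=float)
        if p.shape != (20, 20):
            raise ValueError("pair potential must be 20x20")
        if not np.allclose(p, p.T):
            raise ValueError("pair potential must be symmetric")
        if not np.all(np.isfinite(p)):
            raise ValueError("pair potential must be finite")
        self.pair_potential = p

    def eps(self, a: str, b: str) -> float:
        ia = AA_INDEX.get(a)
        ib = AA_INDEX.get(b)
        if ia is None or ib is None:  # unknown residue type: neutral
            return 0.0
        return float(self.pair_potential[ia, ib])

    def contact_map_for(self, s: StructureModel, chain_id: str) -> ContactMap:
        return contact_map(s, chain_id, self.scheme, self.cutoff,
                           self.min_separation)


def fragment_energy(
    chain: StructureModel,
    chain_id: str,
    fragment: Fragment,
    model: EnergyModel,
    cmap: Optional[ContactMap] = None,
) -> float:
    """Internal energy of a fragment: pair terms over contacts internal to
    the fragment plus burial_weight times each residue's internal contact
    count."""
    cmap = cmap or model.contact_map_for(chain, chain_id)
    seq = chain.sequence(chain_id)
    lo, hi = fragment.start, fragment.stop
    e = 0.0
    burial = np.zeros(hi - lo)
    for i, j in cmap.contacts:
        if lo <= i < hi and lo <= j < hi:
            e += model.eps(seq[i], seq[j])
            burial[i - lo] += 1
            burial[j - lo] += 1
    return float(e + model.burial_weight * burial.sum())


@dataclass
class FoldabilityRecord:
    start: int
    E_frag: float
    mean_E_set: float
    sd_E_set: float
    set_size: int
    theta_fold: float
    defined: bool = True


def relative_foldability(
    chain: StructureModel,
    chain_id: str,
    period: int,
    model: EnergyModel,
    z_score_only: bool = False,
) -> list[FoldabilityRecord]:
    """Foldability of every period-length fragment against all others.

    The comparison set for a fragment is every *other* fragment of the same
    length in the chain (sample standard deviation). ``z_score_only`` drops
    the 1/set_size factor from the denominator.
    """
    n = chain.n_residues(chain_id)
    if n <= period:
        raise ValueError("chain must be longer than the period")
    cmap = model.contact_map_for(chain, chain_id)
    energies = np.array(
        [
            fragment_energy(chain, chain_id, Fragment(chain, chain_id, s, period),
                            model, cmap)
            for s in range(n - period + 1)
        ]
    )
    return foldability_from_energies(energies, z_score_only=z_score_only)


def foldability_from_energies(
    energies: Sequence[float], z_score_only: bool = False
) -> list[FoldabilityRecord]:
    """Foldability statistics for a given vector of fragment energies.

    Record k compares energy k against the sample mean and sample standard
    deviation of all *other* energies; theta_fold = (mean - E_k)/(sd * n).
    """
    energies = np.asarray(energies, dtype=float)
    records = []
    for s in range(len(energies)):
        others = np.delete(energies, s)
        mean = float(others.mean())
        sd = float(others.std(ddof=1)) if len(others) > 1 else 0.0
        size = len(others)
        if sd == 0.0:
            records.append(
                FoldabilityRecord(s, float(energies[s]), mean, sd, size,
                                  float("nan"), defined=False)
            )
            continue
        denom = sd if z_score_only else sd * size
        theta = (mean - energies[s]) / denom
        records.append(
            FoldabilityRecord(s, float(energies[s]), mean, sd, size,
                              float(theta))
        )
    if not any(r.defined for r in records):
        raise ValueError("foldability undefined: all fragments have equal energy")
    return records


def best_foldability_fragment(records: Sequence[FoldabilityRecord]) -> FoldabilityRecord:
    """Argmax of theta_fold over defined records; ties → smaller start."""
    defined = [r for r in records if r.defined]
    return max(defined, key=lambda r: (r.theta_fold, -r.start))


# ---------------------------------------------------------------------------
# phase assignment against the bundled consensus profile

#: 33-residue ankyrin-like consensus carrying the canonical GxTPLHLA motif;
#: its own frame defines phase offset 0 (hydrophobic cap residues at the
#: unit boundaries, helix cores at 1-12 and 17-28, loops between).
ANK_CONSENSUS = "VDKDGQTPLHLAARNGHLEIVEVLLKHGALVVL"


def consensus_score_table(
    consensus: str = ANK_CONSENSUS, match_prob: float = 0.6
) -> np.ndarray:
    """Position-specific log-odds table: P(consensus letter) = match_prob,
    remaining mass spread over the other 19 letters; background uniform."""
    p = len(consensus)
    bg = 1.0 / 20.0
    other = (1.0 - match_prob) / 19.0
    table = np.full((p, 20), np.log2(other / bg))
    for pos, aa in enumerate(consensus):
        table[pos, AA_INDEX[aa]] = np.log2(match_prob / bg)
    return table


@dataclass(frozen=True)
class PhaseAssignment:
    phase_offset: int  # 0..period-1
    method: str  # "geometric" | "energetic" | "sequence"
    score: float


def assign_phase(
    fragment_sequence: str,
    reference: Optional[np.ndarray] = None,
    period: int = 33,
    consensus: str = ANK_CONSENSUS,
) -> PhaseAssignment:
    """Offset of a period-length sequence relative to the reference profile.

    Offset k means residue i of the fragment sits at canonical position
    ``(k + i) mod period`` of the reference; the consensus itself scores
    offset 0. Ties break to the smallest k.
    """
    if len(fragment_sequence) != period:
        raise ValueError("fragment sequence must have exactly period residues")
    for aa in fragment_sequence:
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-canonical residue {aa!r} in fragment")
    table = reference if reference is not None else consensus_score_table(consensus)
    if table.shape[0] != period:
        raise ValueError("reference profile length must equal the period")
    idx = np.array([AA_INDEX[a] for a in fragment_sequence])
    scores = np.empty(period)
    for k in range(period):
        pos = (k + np.arange(period)) % period
        scores[k] = table[pos, idx].sum()
    k_best = int(np.argmax(scores))  # argmax returns the first (smallest) k
    return PhaseAssignment(phase_offset=k_best, method="sequence",
                           score=float(scores[k_best]))


def phase_distribution(
    chains: Sequence[tuple[StructureModel, str]],
    method: str,
    period: int = 33,
    model: Optional[EnergyModel] = None,
    tiling_params=None,
) -> dict[int, int]:
    """Histogram of phase offsets over a set of chains.

    ``geometric``: phases tied for the best tile score at L = period
    (tile start mod period). ``energetic``: start of the best-foldability
    fragment mod period.
    """
    from .tiling import TilingParams, _per_length_thetas  # local: avoid cycle

    if not chains:
        raise ValueError("at least one chain required")
    hist: dict[int, int] = {}
    if method == "geometric":
        params = tiling_params or TilingParams()
        for s, cid in chains:
            thetas, _ = _per_length_thetas(s.ca_coords(cid), period, params)
            m = thetas.max()
            tol = max(m * (1.0 - params.tie_tol), 0.0)
            offsets = {int(t) % period for t in np.nonzero(thetas >= tol)[0]}
            for o in offsets:
                hist[o] = hist.get(o, 0) + 1
    elif method == "energetic":
        model = model or EnergyModel()
        for s, cid in chains:
            records = relative_foldability(s, cid, period, model)
            best = best_foldability_fragment(records)
            o = best.start % period
            hist[o] = hist.get(o, 0) + 1
    else:
        raise ValueError(f"unknown method {method!r}")
    return hist
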