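"""Local energetic frustration indices.

The frustration index of a native interaction is the z-score of its energy
against an ensemble of decoys:

    F = (decoy_mean - E_native) / decoy_sd

Positive F means the native interaction is more favourable than typical
decoys (minimally frustrated); strongly negative F marks energetic conflict
(high frustration). Three decoy flavours are provided: *mutational* (swap
the identities of the interacting pair, geometry fixed), *configurational*
(swap identities and re-draw the pair's environment — burial — from the
chain's empirical distribution) and *single-residue* (exhaustively mutate
one residue, summing its interactions with all neighbours).

Contacts are classified minimal / neutral / high with the standard
cut-points F >= 0.78 and F <= -1.0 (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .phasing import EnergyModel
from .structmodel import AA_INDEX, AMINO_ACIDS, StructureModel

MINIMAL, NEUTRAL, HIGH = "MINIMAL", "NEUTRAL", "HIGH"
MUTATIONAL, CONFIGURATIONAL = "MUTATIONAL", "CONFIGURATIONAL"
EXHAUSTIVE = "EXHAUSTIVE"

_CLASSES = (MINIMAL, NEUTRAL, HIGH)


@dataclass(frozen=True)
class Thresholds:
    minimal_ge: float = 0.78
    high_le: float = -1.0

    def __post_init__(self) -> None:
        if not self.minimal_ge > self.high_le:
            raise ValueError("minimal_ge must exceed high_le")


def classify(F: Optional[float], thresholds: Thresholds = Thresholds()) -> str:
    """Three-state call; undefined F (None/NaN) maps to NEUTRAL."""
    if F is None or not np.isfinite(F):
        return NEUTRAL
    if F >= thresholds.minimal_ge:
        return MINIMAL
    if F <= thresholds.high_le:
        return HIGH
    return NEUTRAL


@dataclass
class System:
    """Flattened (possibly multi-chain) view used by the energy terms."""

    seq: str
    aa_idx: np.ndarray  # -1 for unknown residue types
    chain_of: list  # per residue: (chain_id, within-chain index)
    contacts: list  # [(i, j)] flat indices, i < j
    degree: np.ndarray  # burial proxy: contact count per residue
    composition: np.ndarray  # empirical aa frequencies (20,)


def build_system(
    model: StructureModel,
    chains: Optional[Sequence[str]] = None,
    energy_model: Optional[EnergyModel] = None,
) -> System:
    """Flatten the selected chains and compute the contact set.

    The sequence-separation minimum applies within a chain only; cross-chain
    pairs are contacts whenever within the cutoff.
    """
    em = energy_model or EnergyModel()
    chains = list(chains) if chains else model.chain_ids()
    seq_parts, coords, chain_of = [], [], []
    for cid in chains:
        s = model.sequence(cid)
        seq_parts.append(s)
        xyz = model.cb_coords(cid) if em.scheme != "CA" else model.ca_coords(cid)
        coords.append(xyz)
        chain_of.extend((cid, i) for i in range(len(s)))
    seq = "".join(seq_parts)
    X = np.vstack(coords)
    n = len(seq)
    d = np.linalg.norm(X[:, None] - X[None], axis=-1)
    contacts = []
    for i in range(n):
        for j in range(i + 1, n):
            same = chain_of[i][0] == chain_of[j][0]
            sep_ok = (not same) or (j - i >= em.min_separation)
            if sep_ok and d[i, j] <= em.cutoff:
                contacts.append((i, j))
    deg = np.zeros(n)
    for i, j in contacts:
        deg[i] += 1
        deg[j] += 1
    comp = np.zeros(20)
    for a in seq:
        k = AA_INDEX.get(a)
        if k is not None:
            comp[k] += 1
    total = comp.sum()
    comp = comp / total if total else np.full(20, 1 / 20)
    aa_idx = np.array([AA_INDEX.get(a, -1) for a in seq])
    return System(seq, aa_idx, chain_of, contacts, deg, comp)


@dataclass
class ContactFrustration:
    pair: tuple
    E_native: float
    decoy_mean: float
    decoy_sd: float
    F_i: Optional[float]
    klass: str
    flavour: str
    defined: bool = True


@dataclass
class ResidueFrustration:
    residue: int
    F_i: Optional[float]
    klass: str
    n_contacts: int
    defined: bool = True


def _pair_energy(em: EnergyModel, ai: int, aj: int, bi: float, bj: float) -> float:
    eps = em.pair_potential[ai, aj] if ai >= 0 and aj >= 0 else 0.0
    return float(eps + em.burial_weight * (bi + bj))


def native_energy(
    model: StructureModel,
    chain_id: Optional[str] = None,
    energy_model: Optional[EnergyModel] = None,
    system: Optional[System] = None,
):
    """Total contact energy plus burial terms, and the per-contact map."""
    em = energy_model or EnergyModel()
    sysm = system or build_system(model, [chain_id] if chain_id else None, em)
    per_contact = {}
    total = 0.0
    for i, j in sysm.contacts:
        ai, aj = sysm.aa_idx[i], sysm.aa_idx[j]
        e = float(em.pair_potential[ai, aj]) if ai >= 0 and aj >= 0 else 0.0
        per_contact[(i, j)] = e
        total += e
    total += em.burial_weight * sysm.degree.sum()
    return float(total), per_contact


def _zscore(native: float, decoys: np.ndarray, weights: Optional[np.ndarray] = None):
    if weights is None:
        mean = float(decoys.mean())
        sd = float(decoys.std(ddof=0))
    else:
        w = weights / weights.sum()
        mean = float((w * decoys).sum())
        sd = float(np.sqrt(max((w * (decoys - mean) ** 2).sum(), 0.0)))
    if sd < 1e-12:
        return mean, sd, None
    return mean, sd, (mean - native) / sd


def mutational_frustration(
    model: StructureModel,
    pair: tuple,
    energy_model: Optional[EnergyModel] = None,
    n_decoys: int | str = 1000,
    seed: int = 0,
    thresholds: Thresholds = Thresholds(),
    system: Optional[System] = None,
    chain_id: Optional[str] = None,
) -> ContactFrustration:
    """Decoys substitute the identities of the contacting pair, drawn from
    the chain composition; geometry and burial stay native. EXHAUSTIVE mode
    enumerates all 400 ordered identity pairs, composition-weighted."""
    em = energy_model or EnergyModel()
    sysm = system or build_system(model, [chain_id] if chain_id else None, em)
    i, j = min(pair), max(pair)
    if (i, j) not in set(sysm.contacts):
        raise ValueError(f"pair {(i, j)} is not a native contact")
    bi, bj = sysm.degree[i], sysm.degree[j]
    e_native = _pair_energy(em, sysm.aa_idx[i], sysm.aa_idx[j], bi, bj)
    if n_decoys == EXHAUSTIVE:
        A, B = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        energies = em.pair_potential[A, B].ravel() + em.burial_weight * (bi + bj)
        weights = np.outer(sysm.composition, sysm.composition).ravel()
        mean, sd, F = _zscore(e_native, energies, weights)
    else:
        if int(n_decoys) < 50:
            raise ValueError("n_decoys must be >= 50 (or EXHAUSTIVE)")
        rng = np.random.default_rng(seed)
        a = rng.choice(20, size=int(n_decoys), p=sysm.composition)
        b = rng.choice(20, size=int(n_decoys), p=sysm.composition)
        energies = em.pair_potential[a, b] + em.burial_weight * (bi + bj)
        mean, sd, F = _zscore(e_native, energies)
    return ContactFrustration(
        pair=(i, j), E_native=e_native, decoy_mean=mean, decoy_sd=sd,
        F_i=F, klass=classify(F, thresholds), flavour=MUTATIONAL,
        defined=F is not None,
    )


def configurational_frustration(
    model: StructureModel,
    pair: tuple,
    energy_model: Optional[EnergyModel] = None,
    n_decoys: int = 1000,
    seed: int = 0,
    thresholds: Thresholds = Thresholds(),
    system: Optional[System] = None,
    chain_id: Optional[str] = None,
) -> ContactFrustration:
    """Decoys randomize identities *and* the pair's environment: burial
    values are re-drawn from the chain's empirical burial distribution."""
    em = energy_model or EnergyModel()
    sysm = system or build_system(model, [chain_id] if chain_id else None, em)
    i, j = min(pair), max(pair)
    if (i, j) not in set(sysm.contacts):
        raise ValueError(f"pair {(i, j)} is not a native contact")
    e_native = _pair_energy(em, sysm.aa_idx[i], sysm.aa_idx[j],
                            sysm.degree[i], sysm.degree[j])
    if n_decoys < 50:
        raise ValueError("n_decoys must be >= 50")
    rng = np.random.default_rng(seed)
    a = rng.choice(20, size=n_decoys, p=sysm.composition)
    b = rng.choice(20, size=n_decoys, p=sysm.composition)
    bi = rng.choice(sysm.degree, size=n_decoys)
    bj = rng.choice(sysm.degree, size=n_decoys)
    energies = em.pair_potential[a, b] + em.burial_weight * (bi + bj)
    mean, sd, F = _zscore(e_native, energies)
    return ContactFrustration(
        pair=(i, j), E_native=e_native, decoy_mean=mean, decoy_sd=sd,
        F_i=F, klass=classify(F, thresholds), flavour=CONFIGURATIONAL,
        defined=F is not None,
    )


def single_residue_frustration(
    model: StructureModel,
    residue: int,
    energy_model: Optional[EnergyModel] = None,
    n_decoys: int | str = EXHAUSTIVE,
    seed: int = 0,
    thresholds: Thresholds = Thresholds(),
    system: Optional[System] = None,
    chain_id: Optional[str] = None,
) -> ResidueFrustration:
    """Shuffle the identity of one residue, everything else native: the
    energy integrates its interactions with all contact neighbours plus its
    burial term. EXHAUSTIVE (default) enumerates the 19 alternatives."""
    em = energy_model or EnergyModel()
    sysm = system or build_system(model, [chain_id] if chain_id else None, em)
    n = len(sysm.seq)
    if not 0 <= residue < n:
        raise ValueError("residue index out of range")
    neigh = [j for i, j in sysm.contacts if i == residue]
    neigh += [i for i, j in sysm.contacts if j == residue]
    b = sysm.degree[residue]

    def res_energy(a_idx: int) -> float:
        e = sum(
            float(em.pair_potential[a_idx, sysm.aa_idx[k]])
            for k in neigh
            if sysm.aa_idx[k] >= 0
        )
        return e + em.burial_weight * b

    a_nat = sysm.aa_idx[residue]
    e_native = res_energy(a_nat) if a_nat >= 0 else em.burial_weight * b
    if n_decoys == EXHAUSTIVE:
        alts = [k for k in range(20) if k != a_nat]
        energies = np.array([res_energy(k) for k in alts])
    else:
        rng = np.random.default_rng(seed)
        draws = rng.choice(20, size=int(n_decoys), p=sysm.composition)
        energies = np.array([res_energy(k) for k in draws])
    mean, sd, F = _zscore(e_native, energies)
    return ResidueFrustration(
        residue=residue, F_i=F, klass=classify(F, thresholds),
        n_contacts=len(neigh), defined=F is not None,
    )


def chain_contact_frustration(
    model: StructureModel,
    chain_id: Optional[str] = None,
    flavour: str = MUTATIONAL,
    energy_model: Optional[EnergyModel] = None,
    n_decoys: int | str = 1000,
    seed: int = 0,
    thresholds: Thresholds = Thresholds(),
    system: Optional[System] = None,
) -> list:
    """Frustration record for every native contact of a chain (or system)."""
    em = energy_model or EnergyModel()
    sysm = system or build_system(model, [chain_id] if chain_id else None, em)
    fn = (
        mutational_frustration if flavour == MUTATIONAL
        else configurational_frustration
    )
    out = []
    for k, pair in enumerate(sysm.contacts):
        kwargs = dict(
            energy_model=em, seed=seed + k, thresholds=thresholds, system=sysm
        )
        if flavour == MUTATIONAL:
            kwargs["n_decoys"] = n_decoys
        else:
            kwargs["n_decoys"] = 1000 if n_decoys == EXHAUSTIVE else int(n_decoys)
        out.append(fn(model, pair, **kwargs))
    return out


def chain_residue_frustration(
    model: StructureModel,
    chain_id: Optional[str] = None,
    energy_model: Optional[EnergyModel] = None,
    thresholds: Thresholds = Thresholds(),
    system: Optional[System] = None,
) -> list:
    em = energy_model or EnergyModel()
    sysm = system or build_system(model, [chain_id] if chain_id else None, em)
    return [
        single_residue_frustration(
            model, r, energy_model=em, thresholds=thresholds, system=sysm
        )
        for r in range(len(sysm.seq))
    ]


@dataclass
class RegionSummary:
    label: str
    n: int
    mean_F: Optional[float]
    class_fractions: dict
    values: np.ndarray


def frustration_by_region(records: Sequence, regions: dict) -> dict:
    """Per-label frustration distribution summary.

    ``regions`` maps label -> set of residue indices. A contact record
    belongs to a label when either of its residues does; a residue record
    when its residue does. Undefined records are excluded from the mean but
    counted in the class fractions (as NEUTRAL, their classified state).
    """
    out = {}
    for label, members in regions.items():
        sel = []
        for rec in records:
            if hasattr(rec, "pair"):
                i, j = rec.pair
                if i in members or j in members:
                    sel.append(rec)
            else:
                if rec.residue in members:
                    sel.append(rec)
        vals = np.array([r.F_i for r in sel if r.defined], dtype=float)
        fracs = {c: 0.0 for c in _CLASSES}
        for r in sel:
            fracs[r.klass] += 1
        if sel:
            for c in _CLASSES:
                fracs[c] /= len(sel)
        out[label] = RegionSummary(
            label=label,
            n=len(sel),
            mean_F=float(vals.mean()) if len(vals) else None,
            class_fractions=fracs,
            values=vals,
        )
    return out
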