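"""Interface analysis of repeat-protein complexes.

Interface residues of the repeat-bearing chain are those with any atom
(heavy atoms when present, else Cβ, else Cα) within a cutoff of a partner
chain. Against a repeat annotation they classify as CANONICAL (mapped to a
canonical position), INSERTION (annotated insertion within or between
units) or NON_REPETITIVE (outside the array). The bound-vs-unbound
comparison evaluates configurational frustration of the chain's native
contacts twice — once for the isolated chain, once within the complex,
where partner residues contribute contacts and burial — and reports the
per-contact change (positive delta = frustration released on binding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .annotate import RepeatArray
from .frustration import (
    CONFIGURATIONAL,
    build_system,
    configurational_frustration,
)
from .phasing import EnergyModel
from .structmodel import StructureModel

CANONICAL, INSERTION_CLASS, NON_REPETITIVE = (
    "CANONICAL", "INSERTION", "NON_REPETITIVE",
)


@dataclass
class InterfaceRecord:
    ank_chain: str
    partner_chains: list
    residues: list  # internal indices on the ank chain
    per_residue_class: dict = field(default_factory=dict)
    class_fractions: dict = field(default_factory=dict)
    fraction_of_chain: float = 0.0


def _residue_atoms(rec) -> np.ndarray:
    if rec.heavy_atoms is not None:
        return rec.heavy_atoms
    if rec.cb is not None:
        return np.vstack([rec.ca, rec.cb])
    return rec.ca[None]


def detect_interface(
    complex_model: StructureModel,
    ank_chain: str,
    partner_chains: Optional[Sequence[str]] = None,
    cutoff: float = 5.0,
) -> InterfaceRecord:
    """Residues of ``ank_chain`` within ``cutoff`` of any partner atom."""
    if partner_chains is None:
        partner_chains = [c for c in complex_model.chain_ids() if c != ank_chain]
    if not partner_chains:
        raise ValueError("a complex needs at least one partner chain")
    if ank_chain in partner_chains:
        raise ValueError("ank chain cannot be its own partner")
    partner_xyz = []
    for cid in partner_chains:
        for rec in complex_model.chain(cid):
            partner_xyz.append(_residue_atoms(rec))
    tree = cKDTree(np.vstack(partner_xyz))
    residues = []
    chain = complex_model.chain(ank_chain)
    for i, rec in enumerate(chain):
        d, _ = tree.query(_residue_atoms(rec), k=1)
        if np.min(d) <= cutoff:
            residues.append(i)
    return InterfaceRecord(
        ank_chain=ank_chain,
        partner_chains=list(partner_chains),
        residues=residues,
        fraction_of_chain=len(residues) / len(chain),
    )


def classify_binding_residues(
    iface: InterfaceRecord, annotation: RepeatArray
) -> InterfaceRecord:
    """Label interface residues against the repeat annotation."""
    classes = {}
    for r in iface.residues:
        k = annotation.unit_of(r)
        if k is not None:
            unit = annotation.units[k]
            classes[r] = (
                CANONICAL if r in unit.canonical_map else INSERTION_CLASS
            )
            continue
        # between-unit insertions attach to the preceding unit
        between = False
        for u in annotation.units:
            if u.end <= r < u.end + u.trailing_insertion:
                between = True
                break
        classes[r] = INSERTION_CLASS if between else NON_REPETITIVE
    iface.per_residue_class = classes
    n = len(classes)
    fr = {c: 0.0 for c in (CANONICAL, INSERTION_CLASS, NON_REPETITIVE)}
    for c in classes.values():
        fr[c] += 1
    if n:
        for c in fr:
            fr[c] /= n
    iface.class_fractions = fr
    return iface


@dataclass
class FrustrationDelta:
    per_contact: dict  # (i, j) on the ank chain -> (F_unbound, F_bound, delta)
    fraction_released_contacts: Optional[float]
    fraction_released_residues: Optional[float]
    interface: InterfaceRecord


def frustration_delta(
    complex_model: StructureModel,
    ank_chain: str,
    partner_chains: Optional[Sequence[str]] = None,
    energy_model: Optional[EnergyModel] = None,
    n_decoys: int = 1000,
    seed: int = 0,
    interface_cutoff: float = 5.0,
) -> FrustrationDelta:
    """Configurational frustration change of the ank chain's native
    contacts between the isolated chain and the complex.

    The unbound state is the rigid monomer (same coordinates, partners
    removed). Summaries count the fraction of interface contacts — contacts
    with at least one interface residue — whose delta is positive
    (frustration released), at contact and residue level.
    """
    em = energy_model or EnergyModel()
    if partner_chains is None:
        partner_chains = [c for c in complex_model.chain_ids() if c != ank_chain]
    unbound = complex_model.subset([ank_chain])
    sys_unbound = build_system(unbound, [ank_chain], em)
    sys_bound = build_system(complex_model, [ank_chain, *partner_chains], em)
    # ank residues occupy flat indices 0..n-1 in both systems by construction
    n_ank = unbound.n_residues(ank_chain)
    ank_contacts = [p for p in sys_unbound.contacts]
    bound_set = {p for p in sys_bound.contacts if p[0] < n_ank and p[1] < n_ank}
    per_contact = {}
    for k, (i, j) in enumerate(ank_contacts):
        fu = configurational_frustration(
            unbound, (i, j), em, n_decoys=n_decoys, seed=seed + k,
            system=sys_unbound,
        )
        if (i, j) not in bound_set:
            continue  # cannot compare a contact absent from the bound map
        fb = configurational_frustration(
            complex_model, (i, j), em, n_decoys=n_decoys, seed=seed + k,
            system=sys_bound,
        )
        if fu.defined and fb.defined:
            per_contact[(i, j)] = (fu.F_i, fb.F_i, fb.F_i - fu.F_i)
    iface = detect_interface(
        complex_model, ank_chain, partner_chains, cutoff=interface_cutoff
    ) if partner_chains else InterfaceRecord(ank_chain, [], [])
    iface_set = set(iface.residues)
    iface_contacts = {
        p: v for p, v in per_contact.items()
        if p[0] in iface_set or p[1] in iface_set
    }
    frac_contacts = None
    if iface_contacts:
        frac_contacts = float(
            np.mean([v[2] > 0 for v in iface_contacts.values()])
        )
    # residue level: a residue is "released" when the mean delta over its
    # interface contacts is positive
    frac_res = None
    if iface_contacts:
        per_res: dict[int, list] = {}
        for (i, j), v in iface_contacts.items():
            for r in (i, j):
                if r in iface_set:
                    per_res.setdefault(r, []).append(v[2])
        frac_res = float(
            np.mean([np.mean(ds) > 0 for ds in per_res.values()])
        )
    return FrustrationDelta(
        per_contact=per_contact,
        fraction_released_contacts=frac_contacts,
        fraction_released_residues=frac_res,
        interface=iface,
    )
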