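"""Coarse-grained structure container and I/O.

All algorithms downstream operate on ordered per-chain lists of residues
carrying Cα (mandatory) and Cβ (optional, absent for glycine) coordinates.
Author numbering (seq id + insertion code) is preserved for reporting, but
every algorithm addresses residues by a gap-free, 0-based *internal index*
per chain; intervals are half-open.
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: contact-map schemes
CA, CB, HEAVY_MIN = "CA", "CB", "HEAVY_MIN"


class StructureError(Exception):
    """Raised for unreadable files, missing chains, or empty chains."""


@dataclass
class ResidueRecord:
    chain_id: str
    author_seq_id: int
    icode: str
    aa: str  # one of the 20 canonical letters or 'X'
    ca: np.ndarray  # (3,) Å
    cb: Optional[np.ndarray] = None  # (3,) Å; None permitted for Gly
    heavy_atoms: Optional[np.ndarray] = None  # (k,3) Å or None

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if not np.all(np.isfinite(self.ca)):
            raise ValueError("Cα coordinates must be finite")
        if self.aa not in AMINO_ACIDS and self.aa != "X":
            raise ValueError(f"unknown amino-acid code {self.aa!r}")
        if self.cb is not None:
            self.cb = np.asarray(self.cb, dtype=float)


@dataclass
class StructureModel:
    source_id: str
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise StructureError(f"chain {chain_id!r} not in {self.source_id}")

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def n_residues(self, chain_id: str) -> int:
        return len(self.chain(chain_id))

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chain(chain_id))

    def ca_coords(self, chain_id: str) -> np.ndarray:
        return np.array([r.ca for r in self.chain(chain_id)], dtype=float)

    def cb_coords(self, chain_id: str) -> np.ndarray:
        """Cβ coordinates with Cα fallback (glycine or missing Cβ)."""
        return np.array(
            [r.ca if r.cb is None else r.cb for r in self.chain(chain_id)],
            dtype=float,
        )

    def subset(self, chain_ids: Sequence[str]) -> "StructureModel":
        return StructureModel(
            source_id=self.source_id,
            chains={c: self.chain(c) for c in chain_ids},
        )


@dataclass(frozen=True)
class Fragment:
    """A contiguous run of residues of one chain, by internal index."""

    parent: StructureModel
    chain_id: str
    start: int
    length: int

    def __post_init__(self) -> None:
        n = self.parent.n_residues(self.chain_id)
        if self.start < 0 or self.length < 1 or self.start + self.length > n:
            raise IndexError(
                f"fragment [{self.start},{self.start + self.length}) out of "
                f"bounds for chain {self.chain_id} of length {n}"
            )

    @property
    def stop(self) -> int:
        return self.start + self.length

    def residues(self) -> list[ResidueRecord]:
        return self.parent.chain(self.chain_id)[self.start : self.stop]

    def ca_coords(self) -> np.ndarray:
        return self.parent.ca_coords(self.chain_id)[self.start : self.stop]

    def sequence(self) -> str:
        return self.parent.sequence(self.chain_id)[self.start : self.stop]


@dataclass(frozen=True)
class ContactMap:
    scheme: str
    cutoff: float
    min_separation: int
    contacts: frozenset  # of (i, j) with i < j, internal indices

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.contacts

    def neighbours(self, i: int) -> list[int]:
        out = [b for a, b in self.contacts if a == i]
        out += [a for a, b in self.contacts if b == i]
        return sorted(out)

    def degree(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.contacts:
            d[i] = d.get(i, 0) + 1
            d[j] = d.get(j, 0) + 1
        return d


def extract_fragment(
    s: StructureModel, chain_id: str, start: int, length: int
) -> Fragment:
    """View of a contiguous residue run; mutating the parent afterwards is
    undefined behaviour (fragments do not copy coordinates)."""
    return Fragment(s, chain_id, start, length)


def contact_map(
    s: StructureModel,
    chain_id: str,
    scheme: str = CB,
    cutoff: float = 8.0,
    min_separation: int = 3,
) -> ContactMap:
    """Symmetric residue contact set under the stated scheme.

    CB falls back to Cα for glycine (and any residue without a Cβ).
    HEAVY_MIN uses the minimum heavy-atom distance and requires heavy atoms.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    residues = s.chain(chain_id)
    n = len(residues)
    if scheme == CA:
        xyz = s.ca_coords(chain_id)
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    elif scheme == CB:
        xyz = s.cb_coords(chain_id)
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    elif scheme == HEAVY_MIN:
        if any(r.heavy_atoms is None for r in residues):
            raise StructureError(
                "HEAVY_MIN contact scheme requires heavy atoms for every residue"
            )
        d = np.full((n, n), np.inf)
        for i in range(n):
            for j in range(i + 1, n):
                dij = np.linalg.norm(
                    residues[i].heavy_atoms[:, None] - residues[j].heavy_atoms[None],
                    axis=-1,
                ).min()
                d[i, j] = d[j, i] = dij
    else:
        raise ValueError(f"unknown contact scheme {scheme!r}")
    pairs = set()
    for i in range(n):
        for j in range(i + min_separation, n):
            if d[i, j] <= cutoff:
                pairs.add((i, j))
    return ContactMap(scheme, cutoff, min_separation, frozenset(pairs))


# ---------------------------------------------------------------------------
# I/O (gemmi-backed)

_VIRTUAL_CB = (-0.58273431, 0.56802827, -0.54067466)


def _virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # standard tetrahedral reconstruction of Cβ from backbone N, CA, C
    b = ca - n
    c_ = c - ca
    a = np.cross(b, c_)
    w = _VIRTUAL_CB
    return w[0] * a + w[1] * b + w[2] * c_ + ca


def _pick_altloc(res: gemmi.Residue, name: str) -> Optional[gemmi.Atom]:
    """Highest occupancy wins; ties keep the first in file order."""
    best = None
    for atom in res:
        if atom.name != name:
            continue
        if best is None or atom.occ > best.occ + 1e-9:
            best = atom
    return best


def load_structure(
    path,
    chain_selector: Optional[Sequence[str]] = None,
    model_index: int = 0,
) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Residues without a Cα are dropped with a warning; alternate locations are
    resolved to the highest-occupancy conformer; only ``model_index`` (default
    the first model) is read.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    if model_index >= len(st):
        raise StructureError(f"model {model_index} absent ({len(st)} models)")
    model = st[model_index]
    out = StructureModel(source_id=path.stem)
    wanted = list(chain_selector) if chain_selector else [ch.name for ch in model]
    present = {ch.name for ch in model}
    for c in wanted:
        if c not in present:
            raise StructureError(f"chain {c!r} absent from {path}")
    for ch in model:
        if ch.name not in wanted:
            continue
        records: list[ResidueRecord] = []
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            ca = _pick_altloc(res, "CA")
            if ca is None:
                log.warning(
                    "%s %s%d%s: no Cα, residue dropped",
                    path.stem, ch.name, res.seqid.num, res.seqid.icode.strip(),
                )
                continue
            one = info.one_letter_code.upper()
            aa = one if one in AMINO_ACIDS else "X"
            cb_atom = _pick_altloc(res, "CB")
            cb = None
            if cb_atom is not None:
                cb = np.array([cb_atom.pos.x, cb_atom.pos.y, cb_atom.pos.z])
            elif aa != "G":
                n_at = _pick_altloc(res, "N")
                c_at = _pick_altloc(res, "C")
                if n_at is not None and c_at is not None:
                    cb = _virtual_cb(
                        np.array([n_at.pos.x, n_at.pos.y, n_at.pos.z]),
                        np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                        np.array([c_at.pos.x, c_at.pos.y, c_at.pos.z]),
                    )
            heavy = np.array(
                [
                    [a.pos.x, a.pos.y, a.pos.z]
                    for a in res
                    if a.element.name not in ("H", "D")
                ]
            )
            records.append(
                ResidueRecord(
                    chain_id=ch.name,
                    author_seq_id=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    aa=aa,
                    ca=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                    cb=cb,
                    heavy_atoms=heavy if len(heavy) else None,
                )
            )
        if ch.name in wanted:
            if not records:
                raise StructureError(f"chain {ch.name!r} has no Cα residues")
            out.chains[ch.name] = records
    if not out.chains:
        raise StructureError(f"no protein residues parsed from {path}")
    return out


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_structure(s: StructureModel, path) -> None:
    """Write a single-model PDB with Cα (and Cβ where present) records.

    Round-trips through :func:`load_structure` within PDB fixed-width
    precision (1e-3 Å). Chains longer than 9999 residues are rejected
    rather than silently switching numbering schemes.
    """
    st = gemmi.Structure()
    st.name = s.source_id
    model = gemmi.Model("1")
    for chain_id, residues in s.chains.items():
        if len(residues) > 9999:
            raise StructureError("PDB writer limited to 9999 residues per chain")
        ch = gemmi.Chain(chain_id)
        for rec in residues:
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE.get(rec.aa, "UNK")
            res.seqid = gemmi.SeqId(rec.author_seq_id, rec.icode or " ")
            a = gemmi.Atom()
            a.name = "CA"
            a.element = gemmi.Element("C")
            a.pos = gemmi.Position(*rec.ca)
            res.add_atom(a)
            if rec.cb is not None:
                b = gemmi.Atom()
                b.name = "CB"
                b.element = gemmi.Element("C")
                b.pos = gemmi.Position(*rec.cb)
                res.add_atom(b)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def fetch_pdb(pdb_id: str, dest_dir, timeout: float = 15.0) -> Path:
    """Download one PDB entry from RCSB into ``dest_dir`` (cached).

    Real-data workflows only; every test surface runs on synthetic input.
    """
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    out = dest_dir / f"{pdb_id.lower()}.pdb"
    if out.exists():
        return out
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        out.write_bytes(resp.read())
    return out


def model_from_arrays(
    sequence: str,
    ca: np.ndarray,
    cb: Optional[np.ndarray] = None,
    chain_id: str = "A",
    source_id: str = "synthetic",
) -> StructureModel:
    """Assemble a StructureModel from plain arrays (synthetic constructs)."""
    ca = np.asarray(ca, dtype=float)
    if len(sequence) != len(ca):
        raise ValueError("sequence and coordinates disagree in length")
    records = []
    for i, aa in enumerate(sequence):
        cbi = None
        if cb is not None and aa != "G":
            cbi = np.asarray(cb[i], dtype=float)
        records.append(
            ResidueRecord(
                chain_id=chain_id,
                author_seq_id=i + 1,
                icode="",
                aa=aa,
                ca=ca[i],
                cb=cbi,
            )
        )
    return StructureModel(source_id=source_id, chains={chain_id: records})


def merge_models(models: Iterable[StructureModel], source_id: str) -> StructureModel:
    """Combine single-chain models into one multi-chain complex."""
    out = StructureModel(source_id=source_id)
    for m in models:
        for cid, residues in m.chains.items():
            if cid in out.chains:
                raise StructureError(f"duplicate chain id {cid!r} when merging")
            out.chains[cid] = residues
    return out
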