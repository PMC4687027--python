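"""Synthetic ankyrin-like solenoid generator with full ground truth.

Units are idealized helix-loop-helix motifs (two antiparallel α-helical
segments joined by loop arcs, a Cα/Cβ coarse model) stacked by a screw
transformation (twist about, and rise along, the solenoid axis). Seeded
Gaussian coordinate noise, injected insertions/deletions, and sequences
sampled from a mutation-rate-perturbed consensus give every downstream
module a test surface with known period, phase, boundaries, indels and
conservation profile. Geometry is deliberately schematic: loops are smooth
interpolating arcs, not physically closed backbones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .phasing import ANK_CONSENSUS
from .structmodel import AMINO_ACIDS, StructureModel, model_from_arrays

log = logging.getLogger(__name__)

#: residue types sampled for inserted loop residues
_LOOP_AA = "GSTNDPA"


@dataclass(frozen=True)
class Indel:
    unit: int  # 0-based unit index
    kind: str  # "INSERTION" | "DELETION"
    canonical_position: int  # 1..unit_length
    length: int


@dataclass
class SolenoidSpec:
    unit_length: int = 33
    n_units: int = 6
    twist: float = 4.0  # degrees per unit about the stacking axis
    rise: float = 11.0  # Å per unit along the stacking axis
    noise_sd: float = 0.3  # Å Gaussian, per coordinate
    indels: Sequence[Indel] = field(default_factory=tuple)
    consensus: str = ANK_CONSENSUS
    mutation_rate: float = 0.1  # per-position substitution probability
    position_mutation_rates: Optional[np.ndarray] = None  # overrides scalar
    phase: int = 0  # construction phase: chain starts at canonical phase+1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if len(self.consensus) != self.unit_length:
            if self.consensus == ANK_CONSENSUS:
                # default consensus adapts to non-standard periods by cycling
                reps = -(-self.unit_length // len(ANK_CONSENSUS))
                self.consensus = (ANK_CONSENSUS * reps)[: self.unit_length]
            else:
                raise ValueError("consensus length must equal unit_length")
        if not 0 <= self.phase < self.unit_length:
            raise ValueError("phase must be in [0, unit_length)")
        for ind in self.indels:
            if not 1 <= ind.canonical_position <= self.unit_length:
                raise ValueError("indel position outside the unit")
            if ind.length < 1:
                raise ValueError("indel length must be >= 1")


@dataclass
class GroundTruth:
    unit_boundaries: list  # [(start, end)] half-open, final indexing
    canonical_map: list  # per residue: canonical position 1..p, or None
    indels: list  # list of Indel
    phase: int
    consensus: str
    mutation_profile: np.ndarray  # per canonical position substitution rate

    def to_json(self) -> str:
        return json.dumps(
            {
                "unit_boundaries": self.unit_boundaries,
                "canonical_map": self.canonical_map,
                "indels": [vars(i) for i in self.indels],
                "phase": self.phase,
                "consensus": self.consensus,
                "mutation_profile": list(map(float, self.mutation_profile)),
            },
            indent=1,
        )


def _helix(n: int, phase_deg: float = 0.0) -> np.ndarray:
    """Ideal α-helical Cα trace along +x: rise 1.5 Å/res, radius 2.3 Å,
    100°/res."""
    i = np.arange(n)
    theta = np.deg2rad(100.0 * i + phase_deg)
    return np.column_stack([1.5 * i, 2.3 * np.cos(theta), 2.3 * np.sin(theta)])


def _arc(p0: np.ndarray, p1: np.ndarray, bulge: np.ndarray, n: int) -> np.ndarray:
    """n interior points of a quadratic Bezier from p0 to p1 bulging toward
    ``bulge`` (a displacement of the control point from the midpoint)."""
    ctrl = (p0 + p1) / 2.0 + bulge
    t = np.linspace(0, 1, n + 2)[1:-1, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1


def make_unit(unit_length: int = 33) -> np.ndarray:
    """Deterministic idealized helix-loop-helix unit (Cα only).

    Layout: helix 1 along +x, a 4-residue connecting arc, helix 2
    antiparallel and offset in −y, then a hairpin-like tail arcing toward
    where the next unit starts one rise above.
    """
    if unit_length < 12:
        raise ValueError("unit_length must be at least 12")
    h = (unit_length - 9) // 2
    # helices of unequal length (as in real solenoid units, where inner and
    # outer helices differ): breaks the internal near-symmetry that would
    # otherwise let half-unit fragments tile the structure
    delta = 2 if h >= 5 else 0
    n1, n2 = h + delta, h - delta
    loop1 = 4
    tail = unit_length - n1 - n2 - loop1
    h1 = _helix(n1)
    # helix 2: traversed antiparallel (back toward x = 0), packed against
    # helix 1 at a y offset
    h2 = _helix(n2, phase_deg=50.0)[::-1].copy()
    h2[:, 1] -= 9.5
    l1 = _arc(h1[-1], h2[0], np.array([6.0, -1.0, 2.0]), loop1)
    # tail runs back along the side of the unit's own first helix turn
    # (β-hairpin-like cap): its residues pack against residues 1..4 of the
    # same unit but stay clear of the next unit one rise above, so the
    # construction phase is encoded energetically
    over = np.array([5.5, 6.5, 1.5])
    tail_end = np.array([0.0, 6.5, 2.5])
    n_run = max(tail // 2, 1)
    n_arc = tail - n_run - 1
    parts = [_arc(h2[-1], over, np.array([-6.0, 0.0, 1.0]), n_arc),
             over[None]]
    if n_run:
        t = np.linspace(0, 1, n_run + 1)[1:, None]
        parts.append((1 - t) * over + t * tail_end)
    lt = np.vstack(parts)
    unit = np.vstack([h1, l1, h2, lt])
    assert len(unit) == unit_length
    return unit


def _cb_from_trace(ca: np.ndarray, aa: str) -> Optional[np.ndarray]:
    """Pseudo-Cβ array: offset each Cα 1.5 Å away from the local chain
    midpoint (None rows are handled by the caller for glycine)."""
    n = len(ca)
    cb = np.empty_like(ca)
    for i in range(n):
        lo, hi = max(0, i - 1), min(n - 1, i + 1)
        v = ca[i] - (ca[lo] + ca[hi]) / 2.0
        nv = np.linalg.norm(v)
        if nv < 1e-6:
            v = np.array([0.0, 0.0, 1.0])
            nv = 1.0
        cb[i] = ca[i] + 1.5 * v / nv
    return cb


def _screw(twist_deg: float, rise: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.deg2rad(twist_deg * k)
    R = np.array(
        [[np.cos(a), -np.sin(a), 0.0],
         [np.sin(a), np.cos(a), 0.0],
         [0.0, 0.0, 1.0]]
    )
    t = np.array([0.0, 0.0, rise * k])
    return R, t


def build_solenoid(spec: SolenoidSpec) -> tuple[StructureModel, GroundTruth]:
    """Assemble a solenoid chain from the spec; see module docstring."""
    rng = np.random.default_rng(spec.seed)
    p = spec.unit_length
    base = make_unit(p)
    # enough units to realize the requested phase shift
    extra = 1 if spec.phase else 0
    ca_parts, canon = [], []
    for k in range(spec.n_units + extra):
        R, t = _screw(spec.twist, spec.rise, k)
        ca_parts.append(base @ R.T + t)
        canon.extend(range(1, p + 1))
    ca = np.vstack(ca_parts)
    canon = np.array(canon)
    if spec.phase:
        ca = ca[spec.phase : spec.phase + spec.n_units * p]
        canon = canon[spec.phase : spec.phase + spec.n_units * p]
    # per-residue sequence from the consensus
    rates = (
        np.asarray(spec.position_mutation_rates, dtype=float)
        if spec.position_mutation_rates is not None
        else np.full(p, spec.mutation_rate)
    )
    if len(rates) != p:
        raise ValueError("position_mutation_rates must have unit_length entries")
    seq = []
    for c in canon:
        aa = spec.consensus[c - 1]
        if rng.random() < rates[c - 1]:
            others = [a for a in AMINO_ACIDS if a != aa]
            aa = others[rng.integers(len(others))]
        seq.append(aa)
    canonical = [int(c) for c in canon]
    unit_of = [i // p for i in range(spec.n_units * p)]
    coords = [row for row in ca]

    # apply indels from the end of the chain backwards so indices stay valid
    applied = sorted(
        spec.indels,
        key=lambda d: (d.unit, d.canonical_position),
        reverse=True,
    )
    for ind in applied:
        if ind.unit >= spec.n_units:
            raise ValueError("indel unit index out of range")
        # residue index with this canonical position inside this unit
        pos = [
            i
            for i in range(len(canonical))
            if unit_of[i] == ind.unit and canonical[i] == ind.canonical_position
        ]
        if not pos:
            raise ValueError("indel position not present (earlier deletion?)")
        i0 = pos[0]
        if ind.kind == "INSERTION":
            anchor = np.asarray(coords[i0])
            nxt = np.asarray(coords[min(i0 + 1, len(coords) - 1)])
            axis_out = anchor - np.array([0.0, 0.0, anchor[2]])
            nv = np.linalg.norm(axis_out)
            out = axis_out / nv if nv > 1e-6 else np.array([1.0, 0.0, 0.0])
            new_pts = []
            for j in range(ind.length):
                f = (j + 1) / (ind.length + 1)
                bulge = 6.0 * np.sin(np.pi * f)
                new_pts.append((1 - f) * anchor + f * nxt + bulge * out)
            ins_seq = [
                _LOOP_AA[rng.integers(len(_LOOP_AA))] for _ in range(ind.length)
            ]
            coords[i0 + 1 : i0 + 1] = new_pts
            seq[i0 + 1 : i0 + 1] = ins_seq
            canonical[i0 + 1 : i0 + 1] = [None] * ind.length
            unit_of[i0 + 1 : i0 + 1] = [ind.unit] * ind.length
        elif ind.kind == "DELETION":
            i1 = i0
            last = min(ind.canonical_position + ind.length - 1, p)
            while (
                i1 < len(canonical)
                and unit_of[i1] == ind.unit
                and canonical[i1] is not None
                and canonical[i1] <= last
            ):
                i1 += 1
            del coords[i0:i1], seq[i0:i1], canonical[i0:i1], unit_of[i0:i1]
        else:
            raise ValueError(f"unknown indel kind {ind.kind!r}")

    ca = np.array(coords)
    if spec.noise_sd > 0:
        ca = ca + rng.normal(0.0, spec.noise_sd, ca.shape)
    cb = _cb_from_trace(ca, "")
    model = model_from_arrays(
        "".join(seq), ca, cb, chain_id="A",
        source_id=f"solenoid-p{p}-n{spec.n_units}-s{spec.seed}",
    )
    # self-clash check (coarse, the loop arcs are schematic): warn only
    d = np.linalg.norm(ca[:, None] - ca[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    off = np.abs(np.subtract.outer(np.arange(len(ca)), np.arange(len(ca)))) <= 2
    if np.any(d[~off] < 1.5):
        log.warning("solenoid has close non-neighbour Cα pairs (< 1.5 Å)")

    boundaries = []
    for u in range(spec.n_units):
        idx = [i for i in range(len(unit_of)) if unit_of[i] == u]
        if idx:
            boundaries.append((idx[0], idx[-1] + 1))
    truth = GroundTruth(
        unit_boundaries=boundaries,
        canonical_map=canonical,
        indels=list(spec.indels),
        phase=spec.phase,
        consensus=spec.consensus,
        mutation_profile=rates.copy(),
    )
    return model, truth


def make_family(
    base: SolenoidSpec, n_members: int, seeds: Optional[Sequence[int]] = None
) -> list[tuple[StructureModel, GroundTruth]]:
    """Seeded family sharing geometry and consensus, differing in noise,
    mutations (and indels if the base spec carries any)."""
    if n_members < 2:
        raise ValueError("a family needs at least 2 members")
    if seeds is None:
        seeds = [base.seed + i for i in range(n_members)]
    if len(seeds) != n_members:
        raise ValueError("one seed per member required")
    return [build_solenoid(replace(base, seed=int(s))) for s in seeds]
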