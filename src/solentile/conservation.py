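"""Information content of sequence and frustration-state conservation.

Per position (or per canonical contact) the information content is

    R = H_max - H_obs,    H_obs = -sum_i P_i log2 P_i

over M states (20 amino acids, or 3 frustration classes). H_max is log2(M)
for a uniform background; for a non-uniform background it is the entropy of
the background distribution, in which case R can come out negative when the
observed column is *more* uncertain than the background. Gaps are excluded
from the counts (not a 21st state). Schneider's small-sample correction
e(n) is available but off by default.

Contact-level conservation maps the structural contacts of consecutive
internal repeat pairs into a canonical 2-period frame, records the relative
frequency of each canonical contact and the frustration-class IC weighted
by that frequency, and extracts the conserved-interaction network: the
cells whose weighted IC exceeds the highest value among neutral-dominant
cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import pearsonr

from .annotate import INTERNAL, RepeatArray, StructMSA
from .frustration import _CLASSES, NEUTRAL
from .structmodel import AA_INDEX, AMINO_ACIDS

log = logging.getLogger(__name__)


@dataclass
class PositionIC:
    position: int  # canonical position, 1-based
    P: dict  # state -> probability
    H_obs: float
    H_max: float
    R: Optional[float]
    n_obs: int
    defined: bool = True

    def state_contributions(self) -> dict:
        """Per-state logo height R * P(state)."""
        if not self.defined:
            return {}
        return {s: self.R * p for s, p in self.P.items()}


@dataclass
class ICProfile:
    positions: list  # of PositionIC, ordered by canonical position
    alphabet_size: int

    def R_values(self) -> np.ndarray:
        return np.array(
            [p.R if p.defined else np.nan for p in self.positions], dtype=float
        )


def _entropy(probs: Sequence[float]) -> float:
    return -sum(p * math.log2(p) for p in probs if p > 0)


def _schneider_correction(n: int, M: int) -> float:
    # e(n) ≈ (M - 1) / (2 ln 2 · n): expected entropy excess at sample size n
    return (M - 1) / (2 * math.log(2) * n) if n > 0 else 0.0


def sequence_ic(
    msa: StructMSA,
    background: Optional[dict] = None,
    small_sample_correction: bool = False,
) -> ICProfile:
    """Per-canonical-position sequence information content from the
    structure-based MSA (target rows only; gaps excluded from counts)."""
    rows = msa.target_rows()
    if len(rows) < 2:
        raise ValueError("at least 2 target rows required")
    if background is None:
        h_max = math.log2(20)
    else:
        h_max = _entropy([background[a] for a in AMINO_ACIDS])
    cols = {c: j for j, c in enumerate(msa.column_canonical) if c is not None}
    positions = []
    for c in range(1, msa.period + 1):
        j = cols[c]
        letters = [r.text[j] for r in rows if r.text[j] != "-"]
        letters = [a for a in letters if a in AA_INDEX]
        n = len(letters)
        if n == 0:
            positions.append(
                PositionIC(c, {}, float("nan"), h_max, None, 0, defined=False)
            )
            continue
        P = {a: letters.count(a) / n for a in set(letters)}
        h_obs = _entropy(P.values())
        r = h_max - h_obs
        if small_sample_correction:
            r -= _schneider_correction(n, 20)
        positions.append(PositionIC(c, P, h_obs, h_max, r, n))
    return ICProfile(positions=positions, alphabet_size=20)


UNIFORM = "UNIFORM"


def frustration_ic(
    observations: Sequence[Sequence[str]],
    background=UNIFORM,
    small_sample_correction: bool = False,
) -> ICProfile:
    """IC over frustration classes, one entry per position/contact.

    ``observations[k]`` is the list of class labels observed at position
    k+1. ``background`` is UNIFORM (H_max = log2 3) or a 3-vector of
    probabilities ordered (MINIMAL, NEUTRAL, HIGH) whose entropy defines
    H_max.
    """
    if background == UNIFORM:
        h_max = math.log2(3)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (3,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be a 3-state probability vector")
        h_max = _entropy(bg)
    positions = []
    for k, obs in enumerate(observations):
        obs = [o for o in obs if o in _CLASSES]
        n = len(obs)
        if n == 0:
            positions.append(
                PositionIC(k + 1, {}, float("nan"), h_max, None, 0, defined=False)
            )
            continue
        P = {c: obs.count(c) / n for c in set(obs)}
        h_obs = _entropy(P.values())
        r = h_max - h_obs
        if small_sample_correction:
            r -= _schneider_correction(n, 3)
        positions.append(PositionIC(k + 1, P, h_obs, h_max, r, n))
    return ICProfile(positions=positions, alphabet_size=3)


# ---------------------------------------------------------------------------
# canonical contact maps


@dataclass
class ContactCell:
    pair: tuple  # canonical positions (a, b), 1..2*period, a < b
    frequency: float
    counts: dict  # class -> occurrences
    R: Optional[float]
    weighted_ic: Optional[float]
    most_informative: str


@dataclass
class ContactICMap:
    period: int
    n_pairs: int
    cells: dict  # (a, b) -> ContactCell

    def is_intra(self, pair: tuple) -> bool:
        a, b = pair
        p = self.period
        return (a <= p and b <= p) or (a > p and b > p)


def canonical_contact_map(
    entries: Sequence[tuple],
    period: int,
    background=UNIFORM,
) -> ContactICMap:
    """Contact-level conservation over consecutive internal repeat pairs.

    ``entries`` is a list of ``(array, contact_records)`` where ``array`` is
    a classified RepeatArray and ``contact_records`` the per-contact
    frustration records (flat indices matching the array's chain). Every
    consecutive pair of internal repeats contributes one observation: its
    contacts are mapped into the 1..2·period canonical frame (first repeat
    1..period, second period+1..2·period).
    """
    repeat_pairs = 0
    presence: dict[tuple, int] = {}
    counts: dict[tuple, dict] = {}
    for array, records in entries:
        internal = [
            (k, u) for k, u in enumerate(array.units) if u.klass == INTERNAL
        ]
        by_pair = {}
        for rec in records:
            i, j = rec.pair
            by_pair[(min(i, j), max(i, j))] = rec
        for (k1, u1), (k2, u2) in zip(internal, internal[1:]):
            if k2 != k1 + 1:
                continue  # only adjacent repeats form an interface
            repeat_pairs += 1
            canon = {}
            for t, c in u1.canonical_map.items():
                canon[t] = c
            for t, c in u2.canonical_map.items():
                canon[t] = c + period
            seen = set()
            for (i, j), rec in by_pair.items():
                if i in canon and j in canon:
                    a, b = sorted((canon[i], canon[j]))
                    if (a, b) in seen:
                        continue
                    seen.add((a, b))
                    presence[(a, b)] = presence.get((a, b), 0) + 1
                    counts.setdefault((a, b), {c: 0 for c in _CLASSES})
                    counts[(a, b)][rec.klass] += 1
    if repeat_pairs == 0:
        raise ValueError("no consecutive internal repeat pairs available")
    if background == UNIFORM:
        h_max = math.log2(3)
    else:
        bg = np.asarray(background, dtype=float)
        h_max = _entropy(bg)
    cells = {}
    for pair, cnt in counts.items():
        n = sum(cnt.values())
        freq = presence[pair] / repeat_pairs
        P = {c: v / n for c, v in cnt.items() if v > 0}
        h_obs = _entropy(P.values())
        r = h_max - h_obs
        contrib = {c: r * P.get(c, 0.0) for c in _CLASSES}
        best = max(contrib.values())
        winners = [c for c in _CLASSES if math.isclose(contrib[c], best)]
        most = winners[0] if len(winners) == 1 else NEUTRAL
        cells[pair] = ContactCell(
            pair=pair,
            frequency=freq,
            counts=cnt,
            R=r,
            weighted_ic=r * freq,
            most_informative=most,
        )
    return ContactICMap(period=period, n_pairs=repeat_pairs, cells=cells)


@dataclass
class ConservedNetwork:
    threshold: float
    members: list  # of (pair, ContactCell, tag) with tag "intra"|"inter"

    def intra(self) -> list:
        return [m for m in self.members if m[2] == "intra"]

    def inter(self) -> list:
        return [m for m in self.members if m[2] == "inter"]


def conserved_network(cmap: ContactICMap) -> ConservedNetwork:
    """Cells whose weighted IC exceeds the highest neutral-dominant value."""
    neutral_ics = [
        c.weighted_ic
        for c in cmap.cells.values()
        if c.most_informative == NEUTRAL and c.weighted_ic is not None
    ]
    if neutral_ics:
        threshold = max(neutral_ics)
    else:
        threshold = 0.0
        log.warning("no neutral-dominant contacts: conserved-network "
                    "threshold set to 0")
    members = []
    for pair, cell in sorted(cmap.cells.items()):
        if cell.weighted_ic is not None and cell.weighted_ic > threshold:
            tag = "intra" if cmap.is_intra(pair) else "inter"
            members.append((pair, cell, tag))
    return ConservedNetwork(threshold=threshold, members=members)


def ic_correlation(seq_profile: ICProfile, frust_profile: ICProfile):
    """Pearson correlation between sequence and frustration IC profiles
    over the shared canonical frame (undefined positions dropped)."""
    rs = seq_profile.R_values()
    rf = frust_profile.R_values()
    if len(rs) != len(rf):
        raise ValueError("profiles must share the canonical frame")
    ok = np.isfinite(rs) & np.isfinite(rf)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("fewer than 3 paired positions")
    r, p = pearsonr(rs[ok], rf[ok])
    return float(r), float(p), n
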