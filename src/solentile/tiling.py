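"""Structure tiling: tile scores, tileability, and the period spectrum.

A *tile* is any contiguous fragment of the chain. Its score

    theta = (C - L) / (N - L)

is the fraction of the remaining structure that copies of the tile can
cover, where C is the number of residues covered by the accepted placements
(the tile itself included), L the tile length and N the chain length.
Coverage uses greedy selection of placements by descending similarity score,
accepting a placement only if it scores at least ``accept_frac * L`` and
overlaps already-covered residues by at most ``overlap_frac * L``.

Tileability Xi averages, over tile lengths, the maximum theta across
phases; highly periodic solenoids approach 1, compact globular chains and
coils stay low. The per-length maxima as a function of L form the period
spectrum, whose peaks identify the repeat period, and the phases achieving
the per-length maximum identify the geometric phase candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .alignkernel import AlignParams, scan_all_tiles, scan_gapless
from .structmodel import Fragment, StructureModel, extract_fragment


@dataclass
class TilingParams:
    sigma: float = 3.0  # Å, similarity kernel width
    distance_cap: float = 5.0  # Å, residual above which a residue is uncovered
    accept_frac: float = 0.5  # placement accepted when S >= accept_frac * L
    overlap_frac: float = 0.1  # max overlap with covered residues
    tie_tol: float = 0.01  # phases within (1 - tie_tol) * max share the peak
    peak_prominence: float = 0.05


@dataclass
class TileScoreRecord:
    tile: Fragment
    L_ii: int
    C_i: int
    N_total: int
    theta: float
    placements: list = field(default_factory=list)  # accepted (offset, score)


@dataclass
class TileSpectrum:
    lengths: np.ndarray  # evaluated tile lengths
    max_theta: np.ndarray  # per-length maximum theta
    best_phases: dict  # L -> list of tile starts achieving the max (with ties)
    peak_lengths: list  # local maxima of max_theta(L), ranked by amplitude

    @property
    def argmax_length(self) -> int:
        """Global argmax of max_theta; ties resolved to the smaller L."""
        best = np.max(self.max_theta)
        return int(self.lengths[np.nonzero(self.max_theta == best)[0][0]])


@dataclass
class TileabilityResult:
    xi: float
    lengths: np.ndarray
    per_length_max: np.ndarray


@dataclass
class ResidueTileability:
    matrix: np.ndarray  # (n_residues, n_lengths) coverage fractions
    lengths: np.ndarray

    @property
    def per_residue(self) -> np.ndarray:
        return self.matrix.mean(axis=1)


def _greedy_coverage(d2: np.ndarray, L: int, N: int, tile_start: int,
                     params: TilingParams):
    """Greedy placement acceptance for one tile.

    ``d2[o, i]`` is the squared residual of tile residue i placed at offset
    o. A placement covers only the residues that actually superpose (residual
    within ``distance_cap``), so partial matches never claim their whole
    footprint. Returns (covered boolean array, accepted [(offset, score)]).
    """
    scores = np.exp(-d2 / params.sigma**2).sum(axis=1)
    within = d2 <= params.distance_cap**2  # (n_off, L)
    covered = np.zeros(N, dtype=bool)
    accepted = []
    order = np.lexsort((np.arange(len(scores)), -scores))
    threshold = params.accept_frac * L
    max_overlap = params.overlap_frac * L
    # the tile always covers itself
    covered[tile_start : tile_start + L] = True
    accepted.append((tile_start, float(scores[tile_start])))
    for o in order:
        if o == tile_start:
            continue
        if scores[o] < threshold:
            break
        idx = np.nonzero(within[o])[0] + o
        if covered[idx].sum() > max_overlap:
            continue
        covered[idx] = True
        accepted.append((int(o), float(scores[o])))
    return covered, accepted


def tile_score(
    chain: StructureModel,
    chain_id: str,
    tile: Fragment,
    params: Optional[TilingParams] = None,
) -> TileScoreRecord:
    """Tile score theta for a single tile (whole-chain tile → theta 1)."""
    params = params or TilingParams()
    N = chain.n_residues(chain_id)
    if N < 1:
        raise ValueError("empty chain")
    L = tile.length
    if L == N:
        return TileScoreRecord(tile, L, N, N, 1.0, [(0, float(N))])
    X = chain.ca_coords(chain_id)
    d2, _ = scan_gapless(X, tile.ca_coords())
    covered, accepted = _greedy_coverage(d2, L, N, tile.start, params)
    C = int(covered.sum())
    theta = (C - L) / (N - L)
    return TileScoreRecord(tile, L, C, N, float(theta), accepted)


def _per_length_thetas(X: np.ndarray, L: int, params: TilingParams):
    """theta for every phase at length L, plus per-tile coverage masks."""
    N = len(X)
    d2 = scan_all_tiles(X, L)  # (n_tiles, n_offsets, L)
    n_tiles = d2.shape[0]
    thetas = np.empty(n_tiles)
    masks = np.zeros((n_tiles, N), dtype=bool)
    for t in range(n_tiles):
        covered, _ = _greedy_coverage(d2[t], L, N, t, params)
        masks[t] = covered
        thetas[t] = (covered.sum() - L) / (N - L)
    return thetas, masks


def tile_spectrum(
    chain: StructureModel,
    chain_id: str,
    l_min: int = 10,
    l_max: Optional[int] = None,
    params: Optional[TilingParams] = None,
) -> TileSpectrum:
    """Per-length maximum tile score with best phases and peak lengths."""
    params = params or TilingParams()
    N = chain.n_residues(chain_id)
    if l_max is None:
        l_max = min(60, N - 1)
    if not (4 <= l_min < l_max <= N - 1):
        raise ValueError(f"invalid length range [{l_min}, {l_max}] for N={N}")
    X = chain.ca_coords(chain_id)
    lengths = np.arange(l_min, l_max + 1)
    max_theta = np.empty(len(lengths))
    best_phases: dict[int, list[int]] = {}
    for idx, L in enumerate(lengths):
        thetas, _ = _per_length_thetas(X, int(L), params)
        m = thetas.max()
        max_theta[idx] = m
        tol = max(m * (1.0 - params.tie_tol), 0.0)
        best_phases[int(L)] = [int(t) for t in np.nonzero(thetas >= tol)[0]] \
            if m > 0 else [int(np.argmax(thetas))]
    peaks, props = find_peaks(max_theta, prominence=params.peak_prominence)
    ranked = sorted(
        peaks, key=lambda p: (-max_theta[p], lengths[p])
    )
    return TileSpectrum(
        lengths=lengths,
        max_theta=max_theta,
        best_phases=best_phases,
        peak_lengths=[int(lengths[p]) for p in ranked],
    )


def tileability(
    chain: StructureModel,
    chain_id: str,
    l_min: int = 10,
    l_max: Optional[int] = None,
    params: Optional[TilingParams] = None,
) -> TileabilityResult:
    """Xi: mean over tile lengths of the per-length maximum tile score."""
    spec = tile_spectrum(chain, chain_id, l_min, l_max, params)
    return TileabilityResult(
        xi=float(spec.max_theta.mean()),
        lengths=spec.lengths,
        per_length_max=spec.max_theta,
    )


def residue_tileability(
    chain: StructureModel,
    chain_id: str,
    l_min: int = 10,
    l_max: Optional[int] = None,
    params: Optional[TilingParams] = None,
) -> ResidueTileability:
    """Per-residue coverage fractions: entry (r, L) is the fraction of tiles
    of length L whose accepted placements cover residue r."""
    params = params or TilingParams()
    N = chain.n_residues(chain_id)
    if l_max is None:
        l_max = min(60, N - 1)
    if not (4 <= l_min < l_max <= N - 1):
        raise ValueError(f"invalid length range [{l_min}, {l_max}] for N={N}")
    X = chain.ca_coords(chain_id)
    lengths = np.arange(l_min, l_max + 1)
    mat = np.zeros((N, len(lengths)))
    for idx, L in enumerate(lengths):
        _, masks = _per_length_thetas(X, int(L), params)
        mat[:, idx] = masks.mean(axis=0)
    return ResidueTileability(matrix=mat, lengths=lengths)
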