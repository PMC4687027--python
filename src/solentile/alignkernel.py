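"""Rigid-body superposition and fragment-vs-chain structural alignment.

The aligner finds every distinct placement of a query fragment on a
target chain, each scored with

    S = sum_i exp(-r_i^2 / sigma^2)

over the per-pair Cα residuals r_i after optimal superposition. Placements
are found by seeding (Kabsch fit of every short query window at every target
offset), then refined by iterating superposition and banded dynamic
programming that re-derives the monotonic residue equivalences (gaps allowed
on both sides, affine gap penalties). Overlapping placements are
deduplicated keeping the higher score.

A vectorized gapless mode (whole-query Kabsch fit at every target offset,
batched SVD) backs the tiling module, where every tile length and phase must
be evaluated; it realizes the exhaustive sliding-window scan exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .structmodel import Fragment, StructureModel


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation; maps moving coordinates onto fixed."""

    rotation: np.ndarray  # (3,3), det +1
    translation: np.ndarray  # (3,)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class AlignParams:
    sigma: float = 3.0  # Å, width of the score kernel
    seed_window: int = 8  # residues per seed window
    seed_rmsd_max: float = 2.5  # Å, seed acceptance
    distance_cap: float = 5.0  # Å, max residual for an equivalence
    min_score: float = 10.0
    gap_open: float = 0.5  # score units
    gap_extend: float = 0.1
    band: int = 8  # DP half-band around the seed diagonal
    max_iter: int = 20
    max_candidates: int = 200
    dedup_overlap: float = 0.5


@dataclass
class StructuralAlignment:
    pairs: list  # [(query_index, target_index)] strictly increasing in both
    distances: np.ndarray  # per-pair residual, Å
    transform: RigidTransform
    score_S: float
    length_L: int
    identity_I: float  # percent over equivalenced pairs
    sigma: float

    @property
    def target_start(self) -> int:
        return self.pairs[0][1]

    @property
    def target_end(self) -> int:
        return self.pairs[-1][1] + 1

    def target_indices(self) -> set:
        return {t for _, t in self.pairs}

    @property
    def rmsd(self) -> float:
        return float(np.sqrt(np.mean(self.distances**2)))


def kabsch_superpose(coordsA: np.ndarray, coordsB: np.ndarray):
    """Optimal proper-rotation superposition of A onto B.

    Returns ``(transform, rmsd)`` with ``transform.apply(A) ≈ B`` in the
    least-squares sense; reflections are corrected so chirality is kept.
    Raises ValueError for fewer than 3 points. Collinear/degenerate input is
    handled best-effort (SVD is still defined; the rotation about the
    degenerate axis is arbitrary but deterministic).
    """
    A = np.asarray(coordsA, dtype=float)
    B = np.asarray(coordsB, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n,3)")
    if len(A) < 3:
        raise ValueError("at least 3 points are required")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    rmsd = float(np.sqrt(max(np.mean(np.sum((Ac @ R.T - Bc) ** 2, axis=1)), 0.0)))
    return RigidTransform(R, t), rmsd


def alignment_score(distances, sigma: float) -> float:
    """Gaussian-weighted structural similarity S = Σ exp(−r²/σ²)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.asarray(distances, dtype=float)
    return float(np.exp(-(r**2) / sigma**2).sum())


# ---------------------------------------------------------------------------
# batched gapless scan


def scan_gapless(target_xyz: np.ndarray, query_xyz: np.ndarray):
    """Kabsch-fit the whole query at every target offset (vectorized).

    Returns ``(scores_fn, rmsd, rotations, meta)`` is overkill; instead this
    returns a tuple ``(d2, rmsd)`` where ``d2[o, i]`` is the squared residual
    of query residue ``i`` after optimal superposition onto the target window
    starting at offset ``o``, and ``rmsd[o]`` the per-offset RMSD.
    """
    T = np.asarray(target_xyz, dtype=float)
    Q = np.asarray(query_xyz, dtype=float)
    L = len(Q)
    if len(T) < L:
        return np.zeros((0, L)), np.zeros(0)
    W = sliding_window_view(T, (L, 3)).reshape(-1, L, 3)  # (n_off, L, 3)
    Wc = W - W.mean(axis=1, keepdims=True)
    Qc = Q - Q.mean(axis=0)
    H = np.einsum("la,olb->oab", Qc, Wc)  # per-offset covariance
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("oab,obc->oac", np.transpose(Vt, (0, 2, 1)),
                                  np.transpose(U, (0, 2, 1))))
    D = np.repeat(np.eye(3)[None], len(W), axis=0).copy()
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("oab,obc,ocd->oad", np.transpose(Vt, (0, 2, 1)), D,
                  np.transpose(U, (0, 2, 1)))
    aligned = np.einsum("oab,lb->ola", R, Qc)
    d2 = np.sum((aligned - Wc) ** 2, axis=2)  # (n_off, L)
    rmsd = np.sqrt(np.maximum(d2.mean(axis=1), 0.0))
    return d2, rmsd


def scan_all_tiles(chain_xyz: np.ndarray, L: int):
    """Score every tile of length ``L`` against every same-length window.

    Returns ``S[t, o]`` = Σ_i exp(−r_i²/σ²) is *not* computed here (sigma
    belongs to the caller); instead returns ``d2[t, o, i]``: squared residual
    of residue ``i`` when the tile starting at ``t`` is Kabsch-fitted onto
    the window starting at ``o``. Memory is O(n_windows² · L).
    """
    X = np.asarray(chain_xyz, dtype=float)
    W = sliding_window_view(X, (L, 3)).reshape(-1, L, 3)
    Wc = W - W.mean(axis=1, keepdims=True)
    H = np.einsum("tla,olb->toab", Wc, Wc)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(
        np.einsum("toab,tobc->toac", np.transpose(Vt, (0, 1, 3, 2)),
                  np.transpose(U, (0, 1, 3, 2)))
    )
    D = np.zeros_like(H)
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = 1.0
    D[..., 2, 2] = np.sign(det)
    R = np.einsum("toab,tobc,tocd->toad", np.transpose(Vt, (0, 1, 3, 2)), D,
                  np.transpose(U, (0, 1, 3, 2)))
    aligned = np.einsum("toab,tlb->tola", R, Wc)
    d2 = np.sum((aligned - Wc[None, :, :, :]) ** 2, axis=3)
    return d2


# ---------------------------------------------------------------------------
# banded DP refinement


def _banded_dp(dist: np.ndarray, qlo: np.ndarray, params: AlignParams):
    """Monotonic equivalences maximizing Σ e^(−r²/σ²) − gap penalties.

    ``dist[i, k]`` is the residual between query residue ``i`` and target
    residue ``qlo[i] + k`` (k indexes the band); entries beyond the chain or
    beyond ``distance_cap`` are +inf. End gaps are free (semi-global).
    Returns the pair list [(i, t)].
    """
    nq, bw = dist.shape
    sim = np.where(np.isfinite(dist), np.exp(-(dist**2) / params.sigma**2), -np.inf)
    NEG = -1e18
    # DP over absolute target coordinate via band offset bookkeeping.
    # M[i,k]: best score of a path ending with pair (i, qlo[i]+k).
    M = np.full((nq, bw), NEG)
    back = np.full((nq, bw, 2), -1, dtype=int)  # predecessor (i', k')
    for i in range(nq):
        ti = qlo[i]
        for k in range(bw):
            if sim[i, k] == -np.inf:
                continue
            t = ti + k
            best, bi, bk = 0.0, -1, -1  # start fresh (free leading gaps)
            for ip in range(max(0, i - 6), i):
                tp_lo = qlo[ip]
                # predecessor target must be < t
                kp_max = min(bw - 1, t - 1 - tp_lo)
                if kp_max < 0:
                    continue
                for kp in range(0, kp_max + 1):
                    v = M[ip, kp]
                    if v <= NEG / 2:
                        continue
                    tq_gap = i - ip - 1  # skipped query residues
                    tt_gap = t - (tp_lo + kp) - 1  # skipped target residues
                    pen = 0.0
                    if tq_gap:
                        pen += params.gap_open + params.gap_extend * (tq_gap - 1)
                    if tt_gap:
                        pen += params.gap_open + params.gap_extend * (tt_gap - 1)
                    if v - pen > best:
                        best, bi, bk = v - pen, ip, kp
            M[i, k] = best + sim[i, k]
            back[i, k] = (bi, bk)
    if np.all(M <= NEG / 2):
        return []
    i, k = np.unravel_index(np.argmax(M), M.shape)
    pairs = []
    while i >= 0:
        pairs.append((int(i), int(qlo[i] + k)))
        i, k = back[i, k]
    pairs.reverse()
    return pairs


def _gapless_pairs(dist_diag: np.ndarray, offset: int, cap: float):
    return [
        (i, offset + i) for i, r in enumerate(dist_diag) if np.isfinite(r) and r <= cap
    ]


def _refine_placement(
    T: np.ndarray,
    Q: np.ndarray,
    qseq: str,
    tseq: str,
    diag: int,
    params: AlignParams,
    allow_gaps: bool,
) -> Optional[StructuralAlignment]:
    nt, nq = len(T), len(Q)
    pairs = [(i, diag + i) for i in range(nq) if 0 <= diag + i < nt]
    if len(pairs) < 3:
        return None
    transform = None
    for _ in range(params.max_iter):
        qi = np.array([p[0] for p in pairs])
        ti = np.array([p[1] for p in pairs])
        transform, _ = kabsch_superpose(Q[qi], T[ti])
        Qm = transform.apply(Q)
        if allow_gaps:
            bw = 2 * params.band + 1
            qlo = np.clip(np.arange(nq) + diag - params.band, -params.band, nt - 1)
            dist = np.full((nq, bw), np.inf)
            for i in range(nq):
                t0 = qlo[i]
                ks = np.arange(bw)
                ts = t0 + ks
                ok = (ts >= 0) & (ts < nt)
                if not ok.any():
                    continue
                d = np.linalg.norm(T[ts[ok]] - Qm[i], axis=1)
                d[d > params.distance_cap] = np.inf
                dist[i, ks[ok]] = d
            new_pairs = _banded_dp(dist, qlo, params)
        else:
            d = np.full(nq, np.inf)
            for i in range(nq):
                t = diag + i
                if 0 <= t < nt:
                    d[i] = np.linalg.norm(T[t] - Qm[i])
            new_pairs = _gapless_pairs(d, diag, params.distance_cap)
        if len(new_pairs) < 3:
            return None
        if new_pairs == pairs:
            break
        pairs = new_pairs
    qi = np.array([p[0] for p in pairs])
    ti = np.array([p[1] for p in pairs])
    transform, _ = kabsch_superpose(Q[qi], T[ti])
    dists = np.linalg.norm(transform.apply(Q[qi]) - T[ti], axis=1)
    keep = dists <= params.distance_cap
    if keep.sum() < 3:
        return None
    pairs = [p for p, k in zip(pairs, keep) if k]
    dists = dists[keep]
    score = alignment_score(dists, params.sigma)
    ident = 100.0 * np.mean([qseq[a] == tseq[b] for a, b in pairs])
    return StructuralAlignment(
        pairs=pairs,
        distances=dists,
        transform=transform,
        score_S=score,
        length_L=len(pairs),
        identity_I=float(ident),
        sigma=params.sigma,
    )


def align_fragment(
    target: StructureModel,
    target_chain: str,
    query: Fragment,
    params: Optional[AlignParams] = None,
    allow_gaps: bool = True,
) -> list[StructuralAlignment]:
    """All distinct placements of ``query`` on the target chain.

    Seeds come from Kabsch-fitting every query window of ``seed_window``
    residues at every target offset; each surviving seed diagonal is refined
    iteratively; near-duplicate placements (target-residue overlap above
    ``dedup_overlap``) keep only the higher score. The result is sorted by
    score descending, ties broken by smaller target start.
    """
    params = params or AlignParams()
    if query.length < params.seed_window:
        raise ValueError("query shorter than seed_window")
    T = target.ca_coords(target_chain)
    Q = query.ca_coords()
    tseq = target.sequence(target_chain)
    qseq = query.sequence()
    if len(T) < params.seed_window:
        return []
    w = params.seed_window
    diag_best: dict[int, float] = {}
    for qw in range(0, query.length - w + 1):
        _, rmsd = scan_gapless(T, Q[qw : qw + w])
        for to in np.nonzero(rmsd <= params.seed_rmsd_max)[0]:
            diag = int(to) - qw
            r = float(rmsd[to])
            if diag not in diag_best or r < diag_best[diag]:
                diag_best[diag] = r
    candidates = sorted(diag_best, key=lambda d: (diag_best[d], d))
    candidates = candidates[: params.max_candidates]
    placements = []
    for diag in candidates:
        aln = _refine_placement(T, Q, qseq, tseq, diag, params, allow_gaps)
        if aln is not None and aln.score_S >= params.min_score:
            placements.append(aln)
    placements.sort(key=lambda a: (-a.score_S, a.target_start))
    kept: list[StructuralAlignment] = []
    for aln in placements:
        tset = aln.target_indices()
        dup = False
        for other in kept:
            oset = other.target_indices()
            inter = len(tset & oset)
            if inter > params.dedup_overlap * min(len(tset), len(oset)):
                dup = True
                break
        if not dup:
            kept.append(aln)
    return kept


@dataclass(frozen=True)
class PairSimilarity:
    Sab: float
    la: int
    lb: int
    relS: float
    relI: float


def pair_similarity(best: StructuralAlignment, la: int, lb: int) -> PairSimilarity:
    """Length-normalized similarity: relS = 2·Sab/(la+lb), relI scales by
    fractional identity. Symmetric in (la, lb)."""
    if la < 1 or lb < 1:
        raise ValueError("chain lengths must be positive")
    s = best.score_S
    rel_s = 2.0 * s / (la + lb)
    rel_i = 2.0 * s * (best.identity_I / 100.0) / (la + lb)
    return PairSimilarity(Sab=s, la=la, lb=lb, relS=rel_s, relI=rel_i)
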