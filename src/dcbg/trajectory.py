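"""Post-processing of coarse-grained FG-nup bead trajectories.

Operates on one-bead-per-residue trajectories (side-chain bead proxy) and
implements the three analyses used to characterise disordered nucleoporins:
residue–residue contact probability maps with a 16 Å (1.6 nm) side-chain
criterion, radius-of-gyration estimation, and a block-structure classifier
that distinguishes single-block collapsed-coil ("shrub") chains from
di-block ("tree") chains with an extended stalk and a collapsed terminal
FG domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Trajectory",
    "ContactMap",
    "ArchitectureCall",
    "contact_probability_map",
    "radius_of_gyration",
    "radius_of_gyration_series",
    "classify_architecture",
]

COLLAPSED_BLOCK = "collapsed_block"
EXTENDED = "extended"
SINGLE_BLOCK = "single_block"
DI_BLOCK = "di_block"

#: contact criterion: side-chain beads within 16 Angstroms, stored in nm
DEFAULT_CONTACT_CUTOFF_NM = 1.6


@dataclass(frozen=True)
class Trajectory:
    """Ordered snapshots of one polymer chain, one bead per residue.

    ``coords`` has shape ``(n_frames, chain_length, 3)`` in nm; residue
    ``i`` (1-based along the simulated disordered domain) is row ``i - 1``.
    ``frame_interval_ps`` is the time between stored snapshots.
    """

    coords: np.ndarray
    frame_interval_ps: float = 100.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, chain_length, 3)")
        if coords.shape[0] < 1 or coords.shape[1] < 1:
            raise ValueError("trajectory must contain at least one frame and one bead")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        object.__setattr__(self, "coords", coords)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def chain_length(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class ContactMap:
    """Symmetric residue-pair contact probability matrix with unit diagonal."""

    P: np.ndarray
    cutoff: float
    n_frames: int

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be a square matrix")
        object.__setattr__(self, "P", P)

    @property
    def chain_length(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class ArchitectureCall:
    """Segmentation of a chain into collapsed/extended blocks plus overall call.

    ``segments`` is a list of ``(start, end, kind)`` with 1-based inclusive
    residue ranges covering the whole chain; ``call`` is ``single_block`` or
    ``di_block``.
    """

    segments: List[Tuple[int, int, str]]
    call: str


def contact_probability_map(
    traj: Trajectory, cutoff: float = DEFAULT_CONTACT_CUTOFF_NM
) -> ContactMap:
    """Fraction of snapshots in which each bead pair lies within ``cutoff``.

    The distance is Euclidean and the comparison inclusive (``<= cutoff``),
    so ``P[i, i] = 1`` exactly.  Counts are normalised by the number of
    snapshots.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not isinstance(traj, Trajectory):
        raise TypeError("traj must be a Trajectory")
    n = traj.chain_length
    counts = np.zeros((n, n))
    for frame in traj.coords:
        if n > 1:
            counts += squareform(pdist(frame) <= cutoff).astype(float)
    P = counts / traj.n_frames
    np.fill_diagonal(P, 1.0)
    return ContactMap(P=P, cutoff=float(cutoff), n_frames=traj.n_frames)


def radius_of_gyration_series(traj: Trajectory) -> np.ndarray:
    """Per-frame radius of gyration, nm (equal-mass beads).

    Rg of a frame is the root-mean-square bead distance from that frame's
    centroid.
    """
    if traj.chain_length < 2:
        raise ValueError("radius of gyration requires at least 2 beads")
    centred = traj.coords - traj.coords.mean(axis=1, keepdims=True)
    return np.sqrt((centred ** 2).sum(axis=2).mean(axis=1))


def radius_of_gyration(traj: Trajectory) -> float:
    """Unweighted time average of the per-frame radius of gyration, nm."""
    return float(radius_of_gyration_series(traj).mean())


def _block_statistic(P: np.ndarray, sep_min: int, sep_max: int) -> np.ndarray:
    """Per-residue mean contact probability over medium-range pairs.

    Averages ``P[i, j]`` over ``sep_min <= |i - j| <= sep_max``.  Excluding
    near-diagonal pairs is essential: chain connectivity keeps sequence
    neighbours within the contact cutoff in *any* architecture, so the
    discriminating signal is the medium-range block structure, not the
    diagonal band.
    """
    n = P.shape[0]
    idx = np.arange(n)
    stat = np.empty(n)
    for i in range(n):
        sep = np.abs(idx - i)
        mask = (sep >= sep_min) & (sep <= sep_max)
        stat[i] = P[i, mask].mean() if mask.any() else 0.0
    return stat


def _segments_from_labels(collapsed: np.ndarray) -> List[List]:
    segs: List[List] = []
    start = 0
    n = collapsed.size
    for i in range(1, n + 1):
        if i == n or collapsed[i] != collapsed[start]:
            segs.append([start, i - 1, bool(collapsed[start])])
            start = i
    return segs


def _merge_short(segs: List[List], min_segment: int) -> List[List]:
    """Absorb segments shorter than ``min_segment`` into their longer neighbour."""
    segs = [list(s) for s in segs]
    while len(segs) > 1:
        lengths = [e - s + 1 for s, e, _ in segs]
        k = int(np.argmin(lengths))
        if lengths[k] >= min_segment:
            break
        if k == 0:
            j = 1
        elif k == len(segs) - 1:
            j = k - 1
        else:
            j = k - 1 if lengths[k - 1] >= lengths[k + 1] else k + 1
        lo, hi = sorted((j, k))
        segs[lo] = [segs[lo][0], segs[hi][1], segs[j][2]]
        del segs[hi]
        # coalesce newly adjacent same-kind segments
        merged = [segs[0]]
        for s in segs[1:]:
            if s[2] == merged[-1][2]:
                merged[-1][1] = s[1]
            else:
                merged.append(s)
        segs = merged
    return segs


def classify_architecture(
    cmap: ContactMap,
    block_threshold: float = 0.06,
    min_segment: int = 10,
    sep_min: int = 5,
    sep_max: int = 50,
    single_block_coverage: float = 0.8,
) -> ArchitectureCall:
    """Call a chain single-block (shrub) or di-block (tree) from its contact map.

    Residues whose medium-range mean contact probability (pairs with
    sequence separation in ``[sep_min, sep_max]``) exceeds
    ``block_threshold`` are labelled collapsed; segments shorter than
    ``min_segment`` are merged into their longer neighbour.  The call is
    ``single_block`` when one collapsed segment covers at least
    ``single_block_coverage`` of the chain, and ``di_block`` when a
    collapsed block touching a chain terminus coexists with an extended
    segment.  A chain with no dominant collapsed block and no terminal
    block / extended split falls back on majority coverage.

    All thresholds are exposed because the underlying visual criterion —
    "a monolithic contact block" versus "one terminal block plus a diagonal
    band" — has no canonical quantitative form.
    """
    if not 0 < block_threshold < 1:
        raise ValueError("block_threshold must lie in (0, 1)")
    if min_segment < 5:
        raise ValueError("min_segment must be >= 5")
    n = cmap.chain_length
    if n < min_segment:
        raise ValueError("chain shorter than min_segment cannot be segmented")
    stat = _block_statistic(cmap.P, sep_min, sep_max)
    segs = _merge_short(_segments_from_labels(stat > block_threshold), min_segment)
    collapsed = [s for s in segs if s[2]]
    coverage = sum(e - s + 1 for s, e, _ in collapsed) / n
    if len(collapsed) == 1 and coverage >= single_block_coverage:
        call = SINGLE_BLOCK
    elif any(s == 0 or e == n - 1 for s, e, _ in collapsed) and any(
        not kind for _, _, kind in segs
    ):
        call = DI_BLOCK
    else:
        call = SINGLE_BLOCK if coverage >= 0.5 else DI_BLOCK
    segments = [
        (s + 1, e + 1, COLLAPSED_BLOCK if kind else EXTENDED) for s, e, kind in segs
    ]
    return ArchitectureCall(segments=segments, call=call)
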