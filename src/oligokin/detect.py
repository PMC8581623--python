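"""Oligomer detection from multi-copy coordinate trajectories.

Turns bead trajectories into per-frame minimum-distance series, smoothed
association/dissociation event counts, per-frame oligomer partitions
(single-linkage connected components at a fixed distance cutoff) and
oligomer-order distributions.  Distances use the minimum-image
convention in the membrane (xy) plane.

The default association cutoff is 0.75 nm, chosen where the density of
pairwise minimum distances shows a first bound-state peak (~0.55 nm)
separated from the unbound background by a trough (~0.7 nm); the
:func:`distance_density` helper reproduces that diagnostic so the cutoff
can be justified or overridden per system.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import gaussian_kde

DEFAULT_CUTOFF = 0.75  # nm
DEFAULT_GAP_TOLERANCE = 100.0  # ns
DEFAULT_SMOOTH_WINDOW = 31  # frames

__all__ = [
    "DistanceSeries",
    "OligomerPartition",
    "EventRecord",
    "DensityProfile",
    "min_distance_series",
    "smooth_series",
    "distance_density",
    "pairwise_min_distances",
    "assign_oligomers",
    "partitions_from_trajectory",
    "fill_flickers",
    "count_events",
    "composition_counts",
    "oligomer_distribution",
]


@dataclass
class DistanceSeries:
    """Per-frame minimum bead-bead distance between one protein pair."""

    pair: tuple[int, int]
    times: np.ndarray  # ns, strictly increasing
    values: np.ndarray  # nm
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class OligomerPartition:
    """Disjoint grouping of protein copies into oligomers at one frame."""

    frame_time: float  # ns
    groups: tuple[frozenset[int], ...]

    @property
    def n_copies(self) -> int:
        return sum(len(g) for g in self.groups)

    def validate(self, n_copies: int) -> None:
        members = [i for g in self.groups for i in g]
        if sorted(members) != list(range(n_copies)):
            raise ValueError("groups do not partition the copy indices")


@dataclass(frozen=True)
class EventRecord:
    pair: tuple[int, int]
    time: float  # ns
    kind: str  # "association" | "dissociation"


def _min_image_diff(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def min_distance_series(
    traj, pair: tuple[int, int], bead_selection=None, chunk: int = 4000
) -> DistanceSeries:
    """Minimum inter-protein bead distance per frame for one pair.

    ``traj`` is any object exposing ``bead_coordinates(frame)``,
    ``n_frames``, ``box`` and ``frame_dt`` (the simulator's
    :class:`~oligokin.synthetic.Trajectory` or an external loader).
    ``bead_selection`` optionally restricts the beads of both proteins.
    """
    i, j = pair
    box = np.asarray(traj.box, dtype=float)
    if bead_selection is not None:
        bead_selection = np.asarray(bead_selection, dtype=int)
        if bead_selection.size == 0:
            raise ValueError("bead_selection must not be empty")
    n_frames = traj.n_frames
    out = np.empty(n_frames)
    for start in range(0, n_frames, chunk):
        stop = min(start + chunk, n_frames)
        block_i, block_j = [], []
        for f in range(start, stop):
            coords = traj.bead_coordinates(f)
            bi, bj = np.asarray(coords[i]), np.asarray(coords[j])
            if bead_selection is not None:
                bi, bj = bi[bead_selection], bj[bead_selection]
            block_i.append(bi)
            block_j.append(bj)
        A = np.stack(block_i)  # (F, Bi, 2)
        B = np.stack(block_j)  # (F, Bj, 2)
        diff = _min_image_diff(A[:, :, None, :] - B[:, None, :, :], box)
        d = np.sqrt((diff**2).sum(axis=-1))
        out[start:stop] = d.reshape(stop - start, -1).min(axis=1)
    times = np.arange(n_frames) * traj.frame_dt
    return DistanceSeries(pair=(i, j), times=times, values=out)


def smooth_series(series: DistanceSeries, window: int) -> DistanceSeries:
    """Centered moving average; edge windows shrink symmetrically."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > len(series):
        raise ValueError("window exceeds series length")
    if window == 1:
        return replace(series, smoothing_window=1)
    kernel = np.ones(window)
    num = np.convolve(series.values, kernel, mode="same")
    den = np.convolve(np.ones_like(series.values), kernel, mode="same")
    return replace(series, values=num / den, smoothing_window=window)


@dataclass
class DensityProfile:
    """Kernel density of pairwise minimum distances with extrema."""

    grid: np.ndarray  # nm
    density: np.ndarray
    peaks: np.ndarray  # nm, local maxima positions
    troughs: np.ndarray  # nm, local minima positions
    degenerate: bool = False


def distance_density(
    samples, bandwidth: float | None = None, n_grid: int = 512
) -> DensityProfile:
    """KDE of a collection of distance samples, locating peaks/troughs.

    Used to check where the bound-state peak and the following trough
    sit, i.e. whether the default 0.75 nm association cutoff is
    appropriate for the system at hand.
    """
    samples = np.concatenate(
        [np.ravel(np.asarray(s, dtype=float)) for s in np.atleast_1d(samples)]
        if isinstance(samples, (list, tuple))
        else [np.ravel(np.asarray(samples, dtype=float))]
    )
    if samples.size < 100:
        raise ValueError("need at least 100 distance samples")
    if np.ptp(samples) < 1e-12:
        g = np.array([samples[0]])
        return DensityProfile(
            grid=g, density=np.array([np.inf]), peaks=g, troughs=np.array([]),
            degenerate=True,
        )
    if bandwidth is not None and bandwidth <= 1e-6:
        raise ValueError("bandwidth too small; KDE degenerates to spikes")
    kde = gaussian_kde(samples, bw_method=bandwidth)
    lo, hi = samples.min(), samples.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    dens = kde(grid)
    d1 = np.diff(dens)
    sign = np.sign(d1)
    turn = np.diff(sign)
    peaks = grid[1:-1][turn < 0]
    troughs = grid[1:-1][turn > 0]
    return DensityProfile(grid=grid, density=dens, peaks=peaks, troughs=troughs)


def pairwise_min_distances(frame_coords, box) -> np.ndarray:
    """Symmetric (n, n) matrix of minimum inter-protein bead distances.

    ``frame_coords`` is a sequence of per-protein bead arrays (B_i, 2).
    A cheap center-distance prefilter skips bead-level work for pairs
    that cannot possibly be near contact.
    """
    box = np.asarray(box, dtype=float)
    coords = [np.asarray(c, dtype=float) for c in frame_coords]
    n = len(coords)
    centers = np.array([c.mean(axis=0) for c in coords])
    extents = np.array(
        [np.linalg.norm(c - c.mean(axis=0), axis=1).max() for c in coords]
    )
    out = np.full((n, n), np.inf)
    np.fill_diagonal(out, 0.0)
    cd = np.linalg.norm(
        _min_image_diff(centers[:, None, :] - centers[None, :, :], box), axis=-1
    )
    for i in range(n):
        for j in range(i + 1, n):
            lower_bound = cd[i, j] - extents[i] - extents[j]
            if lower_bound > 0.25 * min(box):
                # even the closest beads are far; report the center-based bound
                out[i, j] = out[j, i] = max(lower_bound, 0.0)
                continue
            diff = _min_image_diff(
                coords[i][:, None, :] - coords[j][None, :, :], box
            )
            d = np.sqrt((diff**2).sum(axis=-1)).min()
            out[i, j] = out[j, i] = d
    return out


def assign_oligomers(
    frame_coords, box, cutoff: float = DEFAULT_CUTOFF, frame_time: float = 0.0
) -> OligomerPartition:
    """Partition proteins into oligomers at one frame.

    Single-linkage grouping at a fixed threshold: two proteins are in
    the same oligomer iff they are joined by a path of pairwise minimum
    bead distances <= ``cutoff``, i.e. the groups are the connected
    components of the thresholded contact graph.
    """
    dmat = pairwise_min_distances(frame_coords, box)
    n = dmat.shape[0]
    adj = sparse.csr_matrix((dmat <= cutoff) & ~np.eye(n, dtype=bool))
    n_comp, labels = connected_components(adj, directed=False)
    groups = tuple(
        frozenset(np.flatnonzero(labels == c).tolist()) for c in range(n_comp)
    )
    return OligomerPartition(frame_time=frame_time, groups=groups)


def partitions_from_trajectory(
    traj, cutoff: float = DEFAULT_CUTOFF, stride: int = 1
) -> list[OligomerPartition]:
    """Per-frame oligomer partitions for a whole trajectory."""
    out = []
    for f in range(0, traj.n_frames, stride):
        coords = traj.bead_coordinates(f)
        out.append(
            assign_oligomers(
                coords, traj.box, cutoff=cutoff, frame_time=f * traj.frame_dt
            )
        )
    return out


def fill_flickers(intervals, gap_tolerance: float = DEFAULT_GAP_TOLERANCE):
    """Merge consecutive intervals separated by gaps < ``gap_tolerance``.

    Contact breaks shorter than the tolerance (default 100 ns) are
    treated as flickers and the flanking intervals joined into one
    continuous appearance.
    """
    ivals = [(float(a), float(b)) for a, b in intervals]
    for (a, b) in ivals:
        if b < a:
            raise ValueError("interval end precedes start")
    for k in range(1, len(ivals)):
        if ivals[k][0] < ivals[k - 1][1]:
            raise ValueError("intervals must be sorted and non-overlapping")
    if not ivals:
        return []
    merged = [ivals[0]]
    for a, b in ivals[1:]:
        pa, pb = merged[-1]
        if a - pb < gap_tolerance:
            merged[-1] = (pa, max(pb, b))
        else:
            merged.append((a, b))
    return merged


def count_events(
    series: DistanceSeries, cutoff: float = DEFAULT_CUTOFF
) -> tuple[int, int, list[EventRecord]]:
    """Count association/dissociation events of one (smoothed) pair series.

    An association is a downward crossing of the cutoff, a dissociation
    an upward crossing; alternation is automatic because crossings of a
    single threshold alternate in direction.
    """
    below = series.values < cutoff
    flips = np.flatnonzero(np.diff(below.astype(np.int8)))
    events = []
    for idx in flips:
        kind = "association" if below[idx + 1] else "dissociation"
        events.append(
            EventRecord(pair=series.pair, time=series.times[idx + 1], kind=kind)
        )
    n_assoc = sum(1 for e in events if e.kind == "association")
    return n_assoc, len(events) - n_assoc, events


def composition_counts(partition: OligomerPartition) -> dict[int, int]:
    """Map oligomer order -> number of oligomers of that order."""
    counts: dict[int, int] = {}
    for g in partition.groups:
        counts[len(g)] = counts.get(len(g), 0) + 1
    return counts


def oligomer_distribution(
    partitions, window: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Oligomer-order counts over the final ``window`` fraction of frames.

    Returns ``(per_frame, summary)``: per-frame counts by order, and the
    ensemble mean +/- SD of each order's count along the time course.
    """
    partitions = list(partitions)
    if not partitions:
        raise ValueError("no partitions given")
    if not 0 < window <= 1:
        raise ValueError("window must lie in (0, 1]")
    start = int(np.floor(len(partitions) * (1 - window)))
    tail = partitions[start:]
    orders = sorted({len(g) for p in tail for g in p.groups})
    rows = []
    for p in tail:
        c = composition_counts(p)
        rows.append([p.frame_time] + [c.get(o, 0) for o in orders])
    per_frame = pd.DataFrame(rows, columns=["time_ns"] + orders).set_index(
        "time_ns"
    )
    summary = pd.DataFrame(
        {"mean": per_frame.mean(axis=0), "sd": per_frame.std(axis=0, ddof=0)}
    )
    summary.index.name = "order"
    return per_frame, summary
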