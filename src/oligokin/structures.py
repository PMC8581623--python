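"""Permutation-invariant clustering of oligomer quaternary structures.

Oligomers of the same order form an "oligomer pool".  Coordinate RMSD
between two oligomers depends on how their member proteins are indexed,
so before clustering every structure is reordered against a common
reference: all permutations of its members are tried and the one giving
the lowest RMSD after optimal in-plane rigid superposition is kept.
Pools are then clustered with KMeans on the flattened reordered
coordinates, and each cluster is labeled ``A.b`` (A = oligomeric order,
b = cluster id by descending size).

Geometric descriptors of the clustered configurations:

* dimers - two binding angles (theta1, theta2), the clockwise in-plane
  angle from each protomer's reference axis to the direction of its
  partner (viewed from the extracellular side, +z);
* trimers - the bending angle phi at the vertex protomer subtended by
  the other two centers;
* tetramers/pentamers - the spans D1 >= D2 of the protomer centers
  projected on their first and second principal axes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .detect import DEFAULT_CUTOFF, pairwise_min_distances

__all__ = [
    "GeometryError",
    "OligomerStructure",
    "ConfigurationCluster",
    "DimerMetrics",
    "TrimerMetrics",
    "SpanMetrics",
    "collect_structures",
    "superpose_rmsd",
    "canonical_order",
    "cluster_configurations",
    "dimer_binding_angles",
    "trimer_bending_angle",
    "principal_axis_lengths",
]

CLUSTERABLE_ORDERS = (2, 3, 4, 5)  # higher orders are recorded, not clustered


class GeometryError(ValueError):
    """Raised for degenerate geometry (e.g. coincident centers)."""


@dataclass
class OligomerStructure:
    """One oligomer's member coordinates at one frame (unwrapped)."""

    member_ids: tuple[int, ...]
    coords: np.ndarray  # (order, n_beads, 2), nm, unwrapped across PBC
    frame_time: float  # ns
    orientation_bead: int = 1

    @property
    def order(self) -> int:
        return len(self.member_ids)

    def centers(self) -> np.ndarray:
        """Center of geometry of each member, (order, 2)."""
        return self.coords.mean(axis=1)

    def reference_axes(self) -> np.ndarray:
        """Unit in-plane reference axis per member, (order, 2)."""
        ax = self.coords[:, self.orientation_bead, :] - self.centers()
        norms = np.linalg.norm(ax, axis=1, keepdims=True)
        if np.any(norms < 1e-9):
            raise GeometryError("orientation bead coincides with center")
        return ax / norms


@dataclass
class ConfigurationCluster:
    """A quaternary-structure cluster labeled ``A.b``."""

    label: str
    order: int
    member_indices: np.ndarray  # indices into the pool
    centroid: np.ndarray  # mean reordered, superposed coordinates
    metric_summary: dict[str, float] = field(default_factory=dict)
    residence_time: float | None = None  # us, filled by the kinetics layer

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class DimerMetrics:
    theta1: float  # degrees in [0, 360)
    theta2: float  # degrees in [0, 360)


@dataclass(frozen=True)
class TrimerMetrics:
    phi: float  # degrees in (0, 180]


@dataclass(frozen=True)
class SpanMetrics:
    d1: float  # nm
    d2: float  # nm


def _unwrap_group(coords: list[np.ndarray], box: np.ndarray) -> np.ndarray:
    """Unwrap a connected group across periodic boundaries.

    Greedy: anchor at the member with the lexicographically smallest
    center (a labeling-independent choice, so results are bitwise
    reproducible under protein relabeling); repeatedly attach the
    remaining member closest (minimum image) to an already-unwrapped
    one, shifting it by whole box vectors so centers are genuinely
    adjacent.
    """
    coords = [np.asarray(c, dtype=float).copy() for c in coords]
    n = len(coords)
    centers = np.array([c.mean(axis=0) for c in coords])
    anchor = int(np.lexsort((centers[:, 1], centers[:, 0]))[0])
    placed = [anchor]
    remaining = set(range(n)) - {anchor}
    while remaining:
        best = None
        for r in remaining:
            for p in placed:
                delta = centers[r] - centers[p]
                shift = -box * np.round(delta / box)
                dist = float(np.linalg.norm(delta + shift))
                cand = (dist, float(centers[r][0]), float(centers[r][1]), r, shift)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        r, shift = best[3], best[4]
        coords[r] += shift
        centers[r] += shift
        placed.append(r)
        remaining.discard(r)
    return np.stack(coords)


def collect_structures(
    traj, partitions, orders=CLUSTERABLE_ORDERS
) -> dict[int, list[OligomerStructure]]:
    """Extract oligomer pools (by order) from a trajectory's partitions.

    Frame times in ``partitions`` must index into ``traj``; member
    coordinates are unwrapped so each oligomer is geometrically
    contiguous regardless of box wrapping.
    """
    pools: dict[int, list[OligomerStructure]] = {o: [] for o in orders}
    box = np.asarray(traj.box, dtype=float)
    for part in partitions:
        frame = int(round(part.frame_time / traj.frame_dt))
        coords = None
        for g in part.groups:
            if len(g) not in pools:
                continue
            if coords is None:
                coords = traj.bead_coordinates(frame)
            members = tuple(sorted(g))
            raw = [np.asarray(coords[m]) for m in members]
            pools[len(g)].append(
                OligomerStructure(
                    member_ids=members,
                    coords=_unwrap_group(raw, box),
                    frame_time=part.frame_time,
                    orientation_bead=getattr(traj.body, "orientation_bead", 1),
                )
            )
    return pools


def superpose_rmsd(A: np.ndarray, B: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum RMSD of point sets A onto B over in-plane rotation+translation.

    No reflection is allowed.  Returns (rmsd, A_superposed).
    """
    A = np.asarray(A, dtype=float).reshape(-1, 2)
    B = np.asarray(B, dtype=float).reshape(-1, 2)
    if A.shape != B.shape:
        raise ValueError("point sets must have equal shape")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    c = float(np.sum(Ac * Bc))
    s = float(np.sum(Ac[:, 0] * Bc[:, 1] - Ac[:, 1] * Bc[:, 0]))
    theta = np.arctan2(s, c)
    ct, st = np.cos(theta), np.sin(theta)
    rot = np.array([[ct, -st], [st, ct]])
    aligned = Ac @ rot.T
    msd = max(np.mean(np.sum((aligned - Bc) ** 2, axis=1)), 0.0)
    return float(np.sqrt(msd)), aligned + B.mean(axis=0)


def canonical_order(
    structure: OligomerStructure, reference: OligomerStructure
) -> tuple[tuple[int, ...], float]:
    """Member permutation minimizing RMSD to the reference.

    All ``order!`` member orderings are tried (order <= 5, so at most
    120); ties go to the lexicographically smallest permutation.
    """
    if structure.order != reference.order:
        raise ValueError("structure and reference orders differ")
    if structure.coords.shape != reference.coords.shape:
        raise ValueError("bead counts per member differ")
    if structure.order > 5:
        raise ValueError("canonical ordering is defined for order <= 5")
    ref_flat = reference.coords.reshape(-1, 2)
    best_perm, best_rmsd = None, np.inf
    for perm in itertools.permutations(range(structure.order)):
        rmsd, _ = superpose_rmsd(
            structure.coords[list(perm)].reshape(-1, 2), ref_flat
        )
        if rmsd < best_rmsd:
            best_rmsd, best_perm = rmsd, perm
    return best_perm, best_rmsd


def _reordered_coords(pool, reference) -> np.ndarray:
    """Canonically reordered, superposed, flattened coordinates per structure."""
    ref_flat = reference.coords.reshape(-1, 2)
    rows = []
    for s in pool:
        perm, _ = canonical_order(s, reference)
        _, aligned = superpose_rmsd(s.coords[list(perm)].reshape(-1, 2), ref_flat)
        rows.append(aligned.ravel())
    return np.array(rows)


def _structure_metrics(s: OligomerStructure, cutoff: float) -> dict[str, float]:
    if s.order == 2:
        m = dimer_binding_angles(s)
        return {"theta1": m.theta1, "theta2": m.theta2}
    if s.order == 3:
        return {"phi": trimer_bending_angle(s, cutoff=cutoff).phi}
    if s.order in (4, 5):
        m = principal_axis_lengths(s)
        return {"d1": m.d1, "d2": m.d2}
    return {}


def _circular_mean_deg(angles: np.ndarray) -> float:
    rad = np.deg2rad(angles)
    return float(
        np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0
    )


def cluster_configurations(
    pool,
    k: int | None = None,
    seed: int = 0,
    reference: OligomerStructure | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    k_range: tuple[int, int] = (2, 15),
) -> list[ConfigurationCluster]:
    """Cluster an equal-order oligomer pool into configurations ``A.b``.

    The reference for canonical reordering defaults to the pool's
    first-occurring structure (reproducible, unlike a random pick).
    ``k=None`` selects the cluster count by a silhouette-score scan over
    ``k_range``.  Labels are assigned by descending cluster size.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("empty pool")
    order = pool[0].order
    if any(s.order != order for s in pool):
        raise ValueError("pool must contain a single oligomeric order")
    if reference is None:
        reference = pool[0]
    X = _reordered_coords(pool, reference)
    if k is not None and k > len(pool):
        raise ValueError("k exceeds pool size")
    if k == 1 or len(pool) == 1:
        assignments = np.zeros(len(pool), dtype=int)
        k_used = 1
    else:
        if k is None:
            lo, hi = k_range
            hi = min(hi, len(pool) - 1)
            best = (-np.inf, 2, None)
            for kk in range(max(lo, 2), hi + 1):
                km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(X)
                if len(set(km.labels_)) < 2:
                    continue
                score = silhouette_score(X, km.labels_)
                if score > best[0]:
                    best = (score, kk, km.labels_)
            k_used, assignments = best[1], best[2]
            if assignments is None:
                assignments = np.zeros(len(pool), dtype=int)
                k_used = 1
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
            assignments, k_used = km.labels_, k

    by_size = sorted(range(k_used), key=lambda c: (-np.sum(assignments == c), c))
    clusters = []
    for b, c in enumerate(by_size, start=1):
        idx = np.flatnonzero(assignments == c)
        centroid = X[idx].mean(axis=0).reshape(order, -1, 2)
        metrics = [_structure_metrics(pool[i], cutoff) for i in idx]
        summary: dict[str, float] = {}
        if metrics and metrics[0]:
            for key in metrics[0]:
                vals = np.array([m[key] for m in metrics])
                if key.startswith("theta"):
                    summary[key] = _circular_mean_deg(vals)
                else:
                    summary[key] = float(vals.mean())
        clusters.append(
            ConfigurationCluster(
                label=f"{order}.{b}",
                order=order,
                member_indices=idx,
                centroid=centroid,
                metric_summary=summary,
            )
        )
    return clusters


def _clockwise_angle(reference: np.ndarray, target: np.ndarray) -> float:
    """Clockwise in-plane angle (deg, viewed from +z) from reference to target."""
    ccw = np.arctan2(
        reference[0] * target[1] - reference[1] * target[0],
        reference[0] * target[0] + reference[1] * target[1],
    )
    deg = float(np.rad2deg(-ccw) % 360.0)
    return 0.0 if deg > 360.0 - 1e-9 else deg  # keep the range [0, 360)


def dimer_binding_angles(dimer: OligomerStructure) -> DimerMetrics:
    """Binding angles (theta1, theta2) of a dimer.

    For each protomer, theta is the clockwise angle (viewed from the
    extracellular side, +z) from its reference axis to the in-plane
    vector pointing at the partner's center of geometry.
    """
    if dimer.order != 2:
        raise ValueError("dimer_binding_angles requires order 2")
    centers = dimer.centers()
    sep = centers[1] - centers[0]
    if np.linalg.norm(sep) < 1e-9:
        raise GeometryError("protomer centers coincide")
    axes = dimer.reference_axes()
    theta1 = _clockwise_angle(axes[0], sep)
    theta2 = _clockwise_angle(axes[1], -sep)
    return DimerMetrics(theta1=theta1, theta2=theta2)


def trimer_bending_angle(
    trimer: OligomerStructure, cutoff: float = DEFAULT_CUTOFF
) -> TrimerMetrics:
    """Bending angle phi at the vertex protomer of a trimer.

    The vertex is the protomer in contact with both others (chain
    topology); for a cyclic trimer phi is the smallest of the three
    vertex angles.  Contact topology is evaluated at the association
    cutoff on an effectively infinite box (coordinates are unwrapped).
    """
    if trimer.order != 3:
        raise ValueError("trimer_bending_angle requires order 3")
    centers = trimer.centers()
    span = np.abs(trimer.coords.reshape(-1, 2)).max() + 1.0
    big_box = np.array([4 * span + 1, 4 * span + 1])
    shifted = [c + 2 * span for c in trimer.coords]
    dmat = pairwise_min_distances(shifted, big_box)
    contacts = [
        (i, j) for i in range(3) for j in range(i + 1, 3) if dmat[i, j] <= cutoff
    ]

    def vertex_angle(v: int) -> float:
        others = [m for m in range(3) if m != v]
        u1 = centers[others[0]] - centers[v]
        u2 = centers[others[1]] - centers[v]
        n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
        if n1 < 1e-9 or n2 < 1e-9:
            raise GeometryError("coincident protomer centers")
        cosang = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
        return float(np.rad2deg(np.arccos(cosang)))

    if len(contacts) < 2:
        raise GeometryError("trimer contact graph is not connected at the cutoff")
    if len(contacts) == 3:
        phi = min(vertex_angle(v) for v in range(3))
    else:
        degree = [0, 0, 0]
        for i, j in contacts:
            degree[i] += 1
            degree[j] += 1
        vertex = degree.index(2)
        phi = vertex_angle(vertex)
    return TrimerMetrics(phi=phi)


def principal_axis_lengths(oligomer: OligomerStructure) -> SpanMetrics:
    """Spans D1 >= D2 of protomer centers on their principal axes.

    Principal axes are the eigenvectors of the in-plane covariance of
    the centers; D_i is the max-min extent of center projections on
    axis i.  If the covariance is isotropic (equal eigenvalues) the x
    axis is taken as the first axis.
    """
    if oligomer.order not in (4, 5):
        raise ValueError("principal_axis_lengths requires order 4 or 5")
    centers = oligomer.centers()
    # canonical (lexicographic) member order: the metric is order-free and
    # this keeps it bitwise reproducible under protein relabeling
    centers = centers[np.lexsort((centers[:, 1], centers[:, 0]))]
    centered = centers - centers.mean(axis=0)
    cov = centered.T @ centered / len(centers)
    evals, evecs = np.linalg.eigh(cov)
    if abs(evals[1] - evals[0]) < 1e-12:
        axes = np.eye(2)
    else:
        axes = evecs[:, ::-1]  # descending eigenvalue order
    proj = centered @ axes
    spans = proj.max(axis=0) - proj.min(axis=0)
    d1, d2 = sorted(spans, reverse=True)
    return SpanMetrics(d1=float(d1), d2=float(d2))
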