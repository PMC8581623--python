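"""Synthetic trajectory generators with exact ground truth.

The centerpiece is a 2D Brownian association/dissociation simulator:
``n_copies`` rigid in-plane bodies ("pseudo-receptors") diffuse in a
periodic membrane patch, bind when their centers come within a capture
radius and unbind with a first-order rate.  Because every binding and
unbinding event is recorded, the generated trajectories carry exact
per-frame oligomer partitions, event lists and dwell times against which
the detection, kinetics and Markov-model machinery can be validated.

Three lighter generators produce (i) i.i.d. dwell times from exponential
mixtures, (ii) residue-lipid head-group distance series with planted
binding sites and known contact kinetics, and (iii) discrete Markov
chains from a known transition matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimConfig",
    "PseudoReceptor",
    "Trajectory",
    "Event",
    "GroundTruth",
    "PlacementError",
    "simulate_association_dynamics",
    "generate_dwell_durations",
    "LipidContactData",
    "generate_lipid_distance_series",
    "generate_markov_chain",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping initial positions cannot be found."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the Brownian association/dissociation simulator.

    Lengths are nm, times ns, rates ns^-1.  Defaults emulate a dilute,
    dissociation-dominated membrane patch: a 45 x 45 nm^2 periodic box
    with 9 receptor copies, coarse-grained-scale lateral diffusion
    (0.05 nm^2/ns) and a 100 ns mean bound dwell, so that association is
    the rate-limiting, second-order step.
    """

    n_copies: int = 9
    box_xy: tuple[float, float] = (45.0, 45.0)
    n_frames: int = 50_000
    frame_dt: float = 1.0
    diffusion_coeff: float = 0.05
    capture_radius: float = 3.0
    k_off_true: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if min(self.box_xy) <= 0:
            raise ValueError("box dimensions must be positive")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.k_off_true < 0:
            raise ValueError("k_off_true must be >= 0")
        if not self.capture_radius < min(self.box_xy) / 4:
            raise ValueError("capture_radius must be < min(box_xy)/4")


@dataclass(frozen=True)
class PseudoReceptor:
    """Rigid in-plane bead model of one receptor copy.

    ``bead_offsets`` are 2D positions in the body frame; the vector from
    the geometric center to ``orientation_bead`` defines the body
    reference axis used for binding-angle metrics (the in-plane analogue
    of an H8-parallel principal axis).
    """

    bead_offsets: np.ndarray
    orientation_bead: int = 1

    def __post_init__(self) -> None:
        off = np.asarray(self.bead_offsets, dtype=float)
        if off.ndim != 2 or off.shape[1] != 2 or off.shape[0] < 3:
            raise ValueError("bead_offsets must be (n_beads >= 3, 2)")
        object.__setattr__(self, "bead_offsets", off)
        if not (0 <= self.orientation_bead < off.shape[0]):
            raise ValueError("orientation_bead out of range")
        if np.linalg.norm(off[self.orientation_bead] - off.mean(axis=0)) < 1e-9:
            raise ValueError("orientation bead must be offset from the center")

    @property
    def n_beads(self) -> int:
        return self.bead_offsets.shape[0]

    @property
    def radius(self) -> float:
        """Largest bead distance from the body center."""
        return float(np.linalg.norm(self.bead_offsets, axis=1).max())

    @classmethod
    def default(cls, n_perimeter: int = 12, radius: float = 1.1) -> "PseudoReceptor":
        """Near-circular body: a center bead plus a ring of perimeter beads.

        With the default capture radius (3.0 nm) and bond contact
        distance (2.7 nm), bound pairs show bead-bead minimum distances
        of ~0.5-0.58 nm while free pairs stay above 0.8 nm, so a 0.75 nm
        contact cutoff separates the two regimes unambiguously.
        """
        ang = 2 * np.pi * np.arange(n_perimeter) / n_perimeter
        ring = radius * np.column_stack([np.cos(ang), np.sin(ang)])
        offsets = np.vstack([[0.0, 0.0], ring])
        return cls(bead_offsets=offsets, orientation_bead=1)


def _rotate(offsets: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return offsets @ rot.T


@dataclass
class Trajectory:
    """Rigid-body trajectory in the internal array format.

    Stores per-frame body centers (wrapped into the box) and body
    orientation angles; bead coordinates are reconstructed on demand
    from the shared :class:`PseudoReceptor` template.
    """

    centers: np.ndarray  # (n_frames, n_copies, 2), nm, wrapped
    angles: np.ndarray  # (n_frames, n_copies), rad
    box: np.ndarray  # (2,), nm
    frame_dt: float  # ns
    body: PseudoReceptor

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]

    @property
    def n_copies(self) -> int:
        return self.centers.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_dt

    def bead_coordinates(self, frame: int) -> np.ndarray:
        """Bead coordinates (n_copies, n_beads, 2) for one frame."""
        ang = self.angles[frame]
        c, s = np.cos(ang), np.sin(ang)
        off = self.body.bead_offsets  # (B, 2)
        x = off[:, 0][None, :] * c[:, None] - off[:, 1][None, :] * s[:, None]
        y = off[:, 0][None, :] * s[:, None] + off[:, 1][None, :] * c[:, None]
        coords = np.stack([x, y], axis=-1) + self.centers[frame][:, None, :]
        return coords

    def orientation_axes(self, frame: int) -> np.ndarray:
        """Unit reference-axis vectors (n_copies, 2) for one frame."""
        beads = self.bead_coordinates(frame)
        cog = beads.mean(axis=1)
        axes = beads[:, self.body.orientation_bead, :] - cog
        return axes / np.linalg.norm(axes, axis=1, keepdims=True)


@dataclass(frozen=True)
class Event:
    time: float  # ns
    pair: tuple[int, int]
    kind: str  # "assoc" | "dissoc"


@dataclass
class GroundTruth:
    """Exact bookkeeping of the simulated association dynamics.

    ``partition_labels[f, i]`` is the smallest member index of the
    oligomer containing copy ``i`` at frame ``f`` — a canonical encoding
    of the per-frame disjoint partition.  ``durations`` lists completed
    bond dwells only; bonds still intact at the end of the run are in
    ``open_durations``.
    """

    partition_labels: np.ndarray  # (n_frames, n_copies) int
    events: list[Event]
    durations: np.ndarray  # ns, completed dwells
    open_durations: np.ndarray  # ns, right-truncated dwells
    true_koff: float
    transition_matrix: np.ndarray | None = None

    def partition(self, frame: int) -> list[frozenset[int]]:
        lab = self.partition_labels[frame]
        return [
            frozenset(np.flatnonzero(lab == r).tolist())
            for r in sorted(set(lab.tolist()))
        ]


def _min_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


def _components(n: int, bonds: set[tuple[int, int]]) -> np.ndarray:
    """Connected-component labels; each label is the smallest member index."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    labels = np.full(n, -1, dtype=np.int64)
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack, members = [start], [start]
        labels[start] = start
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if labels[v] < 0:
                    labels[v] = start
                    stack.append(v)
                    members.append(v)
    return labels


def _initial_placement(
    rng: np.random.Generator, n: int, box: np.ndarray, min_sep: float
) -> np.ndarray:
    pos = np.empty((n, 2))
    for i in range(n):
        for _ in range(2000):
            cand = rng.uniform(0, box, size=2)
            if i == 0:
                pos[i] = cand
                break
            d = np.linalg.norm(_min_image(pos[:i] - cand, box), axis=1)
            if d.min() >= min_sep:
                pos[i] = cand
                break
        else:
            raise PlacementError(
                f"could not place copy {i} with separation >= {min_sep} nm"
            )
    return pos


def simulate_association_dynamics(
    config: SimConfig, body: PseudoReceptor | None = None
) -> tuple[Trajectory, GroundTruth]:
    """Simulate Brownian in-plane association/dissociation dynamics.

    Bodies diffuse (translation + rotation) in a periodic xy box.  When
    the centers of two bodies in different oligomers come within
    ``capture_radius`` they form a bond and the joining oligomer is
    snapped so the pair sits at the contact distance
    ``0.9 * capture_radius``; bonded oligomers move as rigid units.
    Each bond breaks independently with per-step probability
    ``1 - exp(-k_off_true * frame_dt)``.  When a break separates two
    oligomers, they receive an immediate dissociative displacement to
    just beyond the capture radius, so bound and unbound states are
    geometrically unambiguous at every stored frame: a pair of bodies
    sits within capture iff its oligomers are bonded.

    Returns the trajectory and a :class:`GroundTruth` with every event,
    per-frame partition and bond dwell time.
    """
    if body is None:
        body = PseudoReceptor.default()
    n = config.n_copies
    box = np.asarray(config.box_xy, dtype=float)
    dt = config.frame_dt
    rng = np.random.default_rng(config.seed)

    sigma_t = np.sqrt(2.0 * config.diffusion_coeff * dt)
    sigma_r = np.sqrt(2.0 * config.diffusion_coeff * dt)  # D_rot = D numerically
    p_off = 1.0 - np.exp(-config.k_off_true * dt)
    capture = config.capture_radius
    contact = 0.9 * capture

    pos = _initial_placement(rng, n, box, min_sep=1.05 * capture)
    ang = rng.uniform(0, 2 * np.pi, size=n)

    bonds: set[tuple[int, int]] = set()
    bond_start: dict[tuple[int, int], float] = {}
    labels = np.arange(n, dtype=np.int64)
    release = 1.05 * capture  # separation imposed on freshly split oligomers

    centers_out = np.empty((config.n_frames, n, 2), dtype=np.float32)
    angles_out = np.empty((config.n_frames, n), dtype=np.float32)
    labels_out = np.empty((config.n_frames, n), dtype=np.int16)

    events: list[Event] = []
    durations: list[float] = []

    iu, ju = np.triu_indices(n, k=1)

    def store(f: int) -> None:
        centers_out[f] = np.mod(pos, box)
        angles_out[f] = np.mod(ang, 2 * np.pi)
        labels_out[f] = labels

    store(0)
    for f in range(1, config.n_frames):
        t = f * dt
        # 1. dissociation; freshly split oligomers are pushed apart so the
        #    geometry reflects the broken bond immediately
        if bonds and p_off > 0:
            broke = [b for b in bonds if rng.random() < p_off]
            for i, j in broke:
                bonds.discard((i, j))
                events.append(Event(t, (i, j), "dissoc"))
                durations.append(t - bond_start.pop((i, j)))
                labels = _components(n, bonds)
                if labels[i] != labels[j]:
                    move = np.flatnonzero(labels == labels[j])
                    other = np.flatnonzero(labels == labels[i])
                    if move.size > other.size:
                        move, (i, j) = other, (j, i)
                    sep = _min_image(
                        np.mod(pos[j], box) - np.mod(pos[i], box), box
                    )
                    dist = np.linalg.norm(sep)
                    if dist > 1e-12:
                        # place j's oligomer adjacent in unwrapped coords too,
                        # so later rigid rotations stay consistent
                        pos[move] += pos[i] + (release / dist) * sep - pos[j]

        # 2. diffusion: each oligomer translates/rotates as a rigid unit,
        #    driven by the noise drawn for its label representative
        noise_t = rng.normal(0.0, sigma_t, size=(n, 2))
        noise_r = rng.normal(0.0, sigma_r, size=n)
        pos += noise_t[labels]
        dth = noise_r[labels]
        ang += dth
        if bonds:
            for root in np.unique(labels[labels != np.arange(n)]):
                members = np.flatnonzero(labels == root)
                if members.size < 2:
                    continue
                centroid = pos[members].mean(axis=0)
                rel = pos[members] - centroid
                c, s = np.cos(dth[root]), np.sin(dth[root])
                pos[members, 0] = centroid[0] + c * rel[:, 0] - s * rel[:, 1]
                pos[members, 1] = centroid[1] + s * rel[:, 0] + c * rel[:, 1]

        # 3. association; iterate because snapping an oligomer into contact
        #    can drag further pairs inside the capture radius
        if n > 1:
            for _ in range(8):
                wrapped = np.mod(pos, box)
                diff = _min_image(wrapped[iu] - wrapped[ju], box)
                d = np.linalg.norm(diff, axis=1)
                new_bond = False
                for idx in np.flatnonzero(d < capture):
                    i, j = int(iu[idx]), int(ju[idx])
                    if (i, j) in bonds:
                        continue
                    if labels[i] != labels[j]:
                        # snap the smaller oligomer so the pair sits at contact
                        mi = np.flatnonzero(labels == labels[i])
                        mj = np.flatnonzero(labels == labels[j])
                        move = mj if mj.size <= mi.size else mi
                        mover, anchor = (j, i) if mj.size <= mi.size else (i, j)
                        sep = _min_image(
                            np.mod(pos[mover], box) - np.mod(pos[anchor], box), box
                        )
                        dist = np.linalg.norm(sep)
                        if dist > 1e-12:
                            # adjacency must hold in unwrapped coords as well
                            pos[move] += (
                                pos[anchor] + (contact / dist) * sep - pos[mover]
                            )
                    # else: already in the same oligomer (chained); record
                    # the new link at the current rigid geometry
                    bonds.add((i, j))
                    bond_start[(i, j)] = t
                    events.append(Event(t, (i, j), "assoc"))
                    labels = _components(n, bonds)
                    new_bond = True
                if not new_bond:
                    break

        store(f)

    open_durations = np.array(
        [config.n_frames * dt - bond_start[b] for b in bonds], dtype=float
    )
    traj = Trajectory(
        centers=centers_out, angles=angles_out, box=box, frame_dt=dt, body=body
    )
    truth = GroundTruth(
        partition_labels=labels_out,
        events=events,
        durations=np.asarray(durations, dtype=float),
        open_durations=open_durations,
        true_koff=config.k_off_true,
    )
    return traj, truth


def generate_dwell_durations(
    k1: float, k2: float, w1: float, n: int, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` i.i.d. dwell times from ``w1*Exp(k1) + (1-w1)*Exp(k2)``.

    Rates in ns^-1, durations in ns.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rates must be positive")
    if not 0.0 <= w1 <= 1.0:
        raise ValueError("w1 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pick_fast = rng.random(n) < w1
    out = np.where(
        pick_fast,
        rng.exponential(1.0 / k1, size=n),
        rng.exponential(1.0 / k2, size=n),
    )
    return out


@dataclass
class LipidContactData:
    """Residue-lipid head-group distance series with planted sites.

    ``segments`` maps ``(residue, lipid_id)`` to ``(start_frame,
    distances)``; outside its segment every pair sits at
    ``far_distance``.  Each site-level bound epoch uses a fresh lipid
    id, during which all member residues sit below the lower contact
    cutoff simultaneously.
    """

    n_frames: int
    frame_dt: float
    n_residues: int
    segments: dict[tuple[int, int], tuple[int, np.ndarray]]
    far_distance: float
    true_site_members: list[frozenset[int]]
    true_durations: np.ndarray  # ns, bound dwells (all sites pooled)
    true_koff: float

    @property
    def total_time(self) -> float:
        return self.n_frames * self.frame_dt

    def dense_series(self, residue: int, lipid: int) -> np.ndarray:
        """Full-length distance series for one (residue, lipid) pair."""
        out = np.full(self.n_frames, self.far_distance)
        seg = self.segments.get((residue, lipid))
        if seg is not None:
            start, vals = seg
            out[start : start + len(vals)] = vals
        return out

    @property
    def lipid_ids(self) -> list[int]:
        return sorted({lip for (_, lip) in self.segments})


def generate_lipid_distance_series(
    koff_site: float,
    n_residues: int,
    site_members,
    n_frames: int,
    seed: int = 0,
    frame_dt: float = 1.0,
    mean_unbound: float = 20.0,
    far_distance: float = 3.0,
) -> LipidContactData:
    """Generate head-group distance series with known contact kinetics.

    ``site_members`` is either one residue set (a single site) or a
    sequence of disjoint residue sets (several sites).  Each site binds
    one pseudo-lipid at a time: bound epochs last Exp(koff_site), gaps
    last Exp(1/mean_unbound), and every epoch is assigned a fresh lipid
    id.  During an epoch, all member residues have distances drawn in
    (0.35, 0.50) nm (below the 0.55 nm entry cutoff); outside it they
    sit at ``far_distance`` (> the 1.0 nm exit cutoff).  Non-member
    residues never approach any lipid.
    """
    if koff_site <= 0:
        raise ValueError("koff_site must be positive")
    if n_frames < 1 or n_residues < 1:
        raise ValueError("n_frames and n_residues must be positive")
    first = next(iter(site_members))
    sites = (
        [frozenset(site_members)]
        if isinstance(first, (int, np.integer))
        else [frozenset(s) for s in site_members]
    )
    all_members = set().union(*sites)
    if not all_members <= set(range(n_residues)):
        raise ValueError("site members must be residue indices < n_residues")
    if sum(len(s) for s in sites) != len(all_members):
        raise ValueError("sites must be disjoint")

    rng = np.random.default_rng(seed)
    segments: dict[tuple[int, int], tuple[int, np.ndarray]] = {}
    true_durations: list[float] = []
    lipid_counter = itertools.count()
    for members in sites:
        frame = int(np.ceil(rng.exponential(mean_unbound) / frame_dt))
        while frame < n_frames:
            dwell = rng.exponential(1.0 / koff_site)
            n_bound = max(1, int(np.ceil(dwell / frame_dt)))
            n_bound = min(n_bound, n_frames - frame)
            lip = next(lipid_counter)
            for res in members:
                vals = rng.uniform(0.35, 0.50, size=n_bound)
                segments[(res, lip)] = (frame, vals)
            true_durations.append(n_bound * frame_dt)
            frame += n_bound
            frame += max(1, int(np.ceil(rng.exponential(mean_unbound) / frame_dt)))
    return LipidContactData(
        n_frames=n_frames,
        frame_dt=frame_dt,
        n_residues=n_residues,
        segments=segments,
        far_distance=far_distance,
        true_site_members=sites,
        true_durations=np.asarray(true_durations, dtype=float),
        true_koff=koff_site,
    )


def generate_markov_chain(
    P: np.ndarray, n_steps: int, seed: int = 0, initial: int = 0
) -> np.ndarray:
    """Sample a state sequence of length ``n_steps`` from transition matrix P."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < 0) or np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-9:
        raise ValueError("P must be row-stochastic")
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    if not 0 <= initial < P.shape[0]:
        raise ValueError("initial state out of range")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    u = rng.random(n_steps - 1)
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = initial
    s = initial
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        states[t] = s
    return states
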