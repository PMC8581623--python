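"""File I/O: internal array format, GRO/XTC export, NDX groups, JSON truth.

The internal trajectory format is a NumPy ``.npz`` holding the rigid-body
arrays (centers, angles, box, frame_dt, bead offsets); it round-trips
:class:`~oligokin.synthetic.Trajectory` exactly.  For interoperability
with standard tools, trajectories can be exported as GRO + XTC through
MDAnalysis (beads become atoms named B00, B01, ... in residues PSR, one
residue per receptor copy, z = 0).  External coordinate trajectories are
read back through MDAnalysis with protein bead groups declared in a
GROMACS-style NDX index file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import Event, GroundTruth, PseudoReceptor, Trajectory

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "write_gro_xtc",
    "read_ndx",
    "write_ndx",
    "BeadTrajectory",
    "load_bead_trajectory",
    "ground_truth_to_json",
    "ground_truth_from_json",
    "write_events_tsv",
    "write_partitions_jsonl",
    "read_partitions_jsonl",
]


def save_trajectory(traj: Trajectory, path) -> None:
    np.savez_compressed(
        path,
        centers=traj.centers,
        angles=traj.angles,
        box=traj.box,
        frame_dt=traj.frame_dt,
        bead_offsets=traj.body.bead_offsets,
        orientation_bead=traj.body.orientation_bead,
    )


def load_trajectory(path) -> Trajectory:
    with np.load(path) as f:
        body = PseudoReceptor(
            bead_offsets=f["bead_offsets"],
            orientation_bead=int(f["orientation_bead"]),
        )
        return Trajectory(
            centers=f["centers"],
            angles=f["angles"],
            box=f["box"],
            frame_dt=float(f["frame_dt"]),
            body=body,
        )


def write_gro_xtc(traj: Trajectory, gro_path, xtc_path=None, stride: int = 1) -> None:
    """Export a rigid-body trajectory as GRO (+ optional XTC).

    One residue (PSR) per receptor copy; the membrane plane is xy and
    all beads sit at z = 0 in a box of height 10 nm.
    """
    import MDAnalysis as mda

    n, B = traj.n_copies, traj.body.n_beads
    u = mda.Universe.empty(
        n_atoms=n * B,
        n_residues=n,
        atom_resindex=np.repeat(np.arange(n), B),
        residue_segindex=np.zeros(n, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("name", [f"B{b:02d}" for _ in range(n) for b in range(B)])
    u.add_TopologyAttr("resname", ["PSR"] * n)
    u.add_TopologyAttr("resid", np.arange(1, n + 1))

    def frame_positions(f: int) -> np.ndarray:
        xy = traj.bead_coordinates(f).reshape(-1, 2)
        return np.column_stack([xy, np.zeros(len(xy))]) * 10.0  # nm -> Angstrom

    u.atoms.positions = frame_positions(0)
    u.dimensions = [traj.box[0] * 10, traj.box[1] * 10, 100.0, 90, 90, 90]
    u.atoms.write(str(gro_path))
    if xtc_path is not None:
        with mda.Writer(str(xtc_path), n_atoms=n * B) as w:
            for f in range(0, traj.n_frames, stride):
                u.atoms.positions = frame_positions(f)
                u.trajectory.ts.dt = traj.frame_dt * stride / 1000.0  # ps
                w.write(u.atoms)


def read_ndx(path) -> dict[str, list[int]]:
    """Read a GROMACS-style NDX file (1-based indices -> 0-based)."""
    groups: dict[str, list[int]] = {}
    current = None
    for line in Path(path).read_text().splitlines():
        line = line.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            groups[current] = []
        elif current is not None:
            groups[current].extend(int(tok) - 1 for tok in line.split())
    return groups


def write_ndx(groups: dict[str, list[int]], path) -> None:
    lines = []
    for name, idx in groups.items():
        lines.append(f"[ {name} ]")
        one_based = [i + 1 for i in idx]
        for start in range(0, len(one_based), 15):
            lines.append(" ".join(str(i) for i in one_based[start : start + 15]))
    Path(path).write_text("\n".join(lines) + "\n")


class BeadTrajectory:
    """Adapter exposing an MDAnalysis Universe as per-protein bead frames.

    Implements the duck-typed interface used by the detection layer:
    ``bead_coordinates(frame)``, ``n_frames``, ``box``, ``frame_dt``.
    Coordinates are projected onto the membrane (xy) plane in nm.
    """

    def __init__(self, universe, groups: dict[str, list[int]], frame_dt: float):
        self._u = universe
        self._groups = [np.asarray(g, dtype=int) for g in groups.values()]
        self.frame_dt = frame_dt
        self.n_copies = len(self._groups)

    @property
    def n_frames(self) -> int:
        return len(self._u.trajectory)

    @property
    def box(self) -> np.ndarray:
        return self._u.dimensions[:2] / 10.0  # Angstrom -> nm

    def bead_coordinates(self, frame: int):
        self._u.trajectory[frame]
        pos = self._u.atoms.positions / 10.0
        return [pos[g][:, :2] for g in self._groups]


def load_bead_trajectory(
    topology, trajectory=None, ndx=None, frame_dt: float = 1.0
) -> BeadTrajectory:
    """Load GRO/PDB (+XTC) coordinates with NDX-declared protein groups.

    Without an NDX file, each residue is treated as one protein copy.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology)) if trajectory is None else mda.Universe(
        str(topology), str(trajectory)
    )
    if ndx is not None:
        groups = read_ndx(ndx)
    else:
        groups = {
            f"res{r.resid}": r.atoms.indices.tolist() for r in u.residues
        }
    return BeadTrajectory(u, groups, frame_dt=frame_dt)


def ground_truth_to_json(truth: GroundTruth, path) -> None:
    payload = {
        "true_koff": truth.true_koff,
        "durations": truth.durations.tolist(),
        "open_durations": truth.open_durations.tolist(),
        "events": [
            {"time": e.time, "pair": list(e.pair), "kind": e.kind}
            for e in truth.events
        ],
        "partition_labels": truth.partition_labels.tolist(),
        "transition_matrix": (
            truth.transition_matrix.tolist()
            if truth.transition_matrix is not None
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload))


def ground_truth_from_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    tm = payload.get("transition_matrix")
    return GroundTruth(
        partition_labels=np.asarray(payload["partition_labels"], dtype=np.int16),
        events=[
            Event(time=e["time"], pair=tuple(e["pair"]), kind=e["kind"])
            for e in payload["events"]
        ],
        durations=np.asarray(payload["durations"], dtype=float),
        open_durations=np.asarray(payload["open_durations"], dtype=float),
        true_koff=payload["true_koff"],
        transition_matrix=None if tm is None else np.asarray(tm, dtype=float),
    )


def write_events_tsv(events, path) -> None:
    """Write association/dissociation events as a TSV table."""
    lines = ["time_ns\tprotein_i\tprotein_j\tkind"]
    for e in events:
        kind = getattr(e, "kind", None)
        lines.append(f"{e.time}\t{e.pair[0]}\t{e.pair[1]}\t{kind}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_partitions_jsonl(partitions, path) -> None:
    """Write per-frame oligomer partitions as JSON lines."""
    with open(path, "w") as fh:
        for p in partitions:
            fh.write(
                json.dumps(
                    {
                        "time_ns": p.frame_time,
                        "groups": [sorted(g) for g in p.groups],
                    }
                )
                + "\n"
            )


def read_partitions_jsonl(path):
    """Read partitions written by :func:`write_partitions_jsonl`."""
    from .detect import OligomerPartition

    out = []
    for line in Path(path).read_text().splitlines():
        rec = json.loads(line)
        out.append(
            OligomerPartition(
                frame_time=rec["time_ns"],
                groups=tuple(frozenset(g) for g in rec["groups"]),
            )
        )
    return out
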