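import numpy as np
import pytest

from oligokin.synthetic import SimConfig, simulate_association_dynamics


def brute_force_min_distance(beads_a, beads_b, box):
    """Exhaustive double-loop minimum-image bead distance (oracle)."""
    box = np.asarray(box, dtype=float)
    best = np.inf
    for a in np.asarray(beads_a, dtype=float):
        for b in np.asarray(beads_b, dtype=float):
            d = a - b
            d = d - box * np.round(d / box)
            best = min(best, float(np.hypot(*d)))
    return best


def brute_force_components(dmat, cutoff):
    """BFS connected components of the thresholded contact graph (oracle)."""
    n = dmat.shape[0]
    seen = [False] * n
    groups = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.add(u)
            for v in range(n):
                if v != u and not seen[v] and dmat[u, v] <= cutoff:
                    seen[v] = True
                    stack.append(v)
        groups.append(frozenset(comp))
    return sorted(groups, key=lambda g: sorted(g))


@pytest.fixture(scope="session")
def small_sim():
    """A short 9-copy Brownian run shared across tests (fixed seed)."""
    cfg = SimConfig(n_copies=9, n_frames=4000, seed=11)
    traj, truth = simulate_association_dynamics(cfg)
    return cfg, traj, truth
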