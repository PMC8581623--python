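"""Markov state models over membrane oligomerization states.

The state of the whole membrane patch at a frame is its oligomer
composition, labeled ``A^a-B^b-C^c`` where A, B, C are the oligomeric
orders present (ascending) and a, b, c how many oligomers of each order
exist — e.g. ``1^9`` is nine monomers, ``1^7-2^1`` seven monomers and
one dimer.  Transitions between composition states are counted at a lag
time tau with a sliding window, the transition matrix is estimated by
maximum likelihood on the largest strongly connected state set, and the
model yields stationary probabilities, implied timescales
``k = -tau / ln(mu)``, mean first passage times, state lifetimes and the
reaction-rate network (rate = 1/mfpt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy import sparse

from .detect import OligomerPartition, composition_counts
from .synthetic import generate_markov_chain

__all__ = [
    "DiscreteTrajectory",
    "CountMatrix",
    "MSMModel",
    "composition_label",
    "label_states",
    "count_transitions",
    "estimate_transition_matrix",
    "implied_timescales",
    "mean_first_passage_times",
    "state_lifetimes",
    "simulate_msm_trajectory",
    "rate_network",
]

RATE_DISPLAY_THRESHOLD = 50.0  # s^-1, network display cut


def composition_label(counts_by_order: dict[int, int]) -> str:
    """Canonical ``A^a-B^b-C^c`` label, orders ascending."""
    parts = [f"{order}^{counts_by_order[order]}" for order in sorted(counts_by_order)]
    return "-".join(parts)


@dataclass
class DiscreteTrajectory:
    """Per-frame state indices plus the index <-> label dictionary."""

    states: np.ndarray  # (n_frames,) int
    frame_dt: float  # ns
    labels: list[str]  # index -> composition label

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.size and (
            self.states.min() < 0 or self.states.max() >= len(self.labels)
        ):
            raise ValueError("state index outside the dictionary")

    def __len__(self) -> int:
        return len(self.states)


def label_states(partitions, n_copies: int, frame_dt: float) -> DiscreteTrajectory:
    """Composition state label per frame from oligomer partitions.

    The dictionary contains observed states only, sorted by first
    occurrence is avoided: labels are sorted lexicographically for
    reproducibility across runs and input orderings.
    """
    raw_labels = []
    for p in partitions:
        counts = (
            composition_counts(p)
            if isinstance(p, OligomerPartition)
            else dict(p)
        )
        if sum(o * c for o, c in counts.items()) != n_copies:
            raise ValueError(
                f"composition {counts} inconsistent with n_copies={n_copies}"
            )
        raw_labels.append(composition_label(counts))
    dictionary = sorted(set(raw_labels))
    index = {lab: i for i, lab in enumerate(dictionary)}
    states = np.array([index[lab] for lab in raw_labels], dtype=np.int64)
    return DiscreteTrajectory(states=states, frame_dt=frame_dt, labels=dictionary)


@dataclass
class CountMatrix:
    counts: np.ndarray  # (n, n) ints, c_ij at lag tau
    lag: float  # ns
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def count_transitions(dtrajs, lag: float) -> CountMatrix:
    """Sliding-window transition counts at lag time ``lag``.

    ``dtrajs`` is one :class:`DiscreteTrajectory` or a list of replicas
    sharing a dictionary; counts are summed over replicas and never
    bridge between them.
    """
    if isinstance(dtrajs, DiscreteTrajectory):
        dtrajs = [dtrajs]
    frame_dt = dtrajs[0].frame_dt
    labels = dtrajs[0].labels
    steps = lag / frame_dt
    if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
        raise ValueError("lag must be a positive multiple of frame_dt")
    steps = int(round(steps))
    n = len(labels)
    counts = np.zeros((n, n), dtype=np.int64)
    for d in dtrajs:
        if d.labels != labels or d.frame_dt != frame_dt:
            raise ValueError("all trajectories must share dictionary and frame_dt")
        if len(d) <= steps:
            raise ValueError("lag exceeds trajectory span")
        np.add.at(counts, (d.states[:-steps], d.states[steps:]), 1)
    return CountMatrix(counts=counts, lag=lag, labels=labels)


@dataclass
class MSMModel:
    P: np.ndarray  # row-stochastic transition matrix at lag tau
    lag: float  # ns
    labels: list[str]  # states in the active (connected) set
    pi: np.ndarray  # stationary distribution
    eigenvalues: np.ndarray  # sorted by |mu| descending, mu_1 = 1
    excluded: list[str] = field(default_factory=list)  # disconnected states

    def __post_init__(self) -> None:
        rows = self.P.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-10:
            raise ValueError("P rows must sum to 1")
        if np.max(np.abs(self.pi @ self.P - self.pi)) > 1e-8:
            raise ValueError("pi must be stationary for P")

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    def implied_timescales(self) -> np.ndarray:
        """k_i = -tau / ln(mu_i) per non-unit eigenvalue (ns).

        Complex eigenvalues use their modulus; non-positive moduli give
        NaN (undefined timescale).
        """
        mus = np.abs(self.eigenvalues[1:])
        out = np.full(mus.shape, np.nan)
        valid = (mus > 0) & (mus < 1)
        out[valid] = -self.lag / np.log(mus[valid])
        out[mus >= 1] = np.inf
        return out

    def lifetimes(self) -> np.ndarray:
        return state_lifetimes(self)

    def mfpt(self) -> np.ndarray:
        return mean_first_passage_times(self)


def _stationary(P: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eig(P.T)
    idx = np.argmin(np.abs(evals - 1.0))
    pi = np.real(evecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _reversible_mle(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000):
    """Detailed-balance MLE via the classic fixed-point iteration."""
    C = counts.astype(float)
    Csym = C + C.T
    c_i = C.sum(axis=1)
    X = Csym.copy()
    X[X == 0] = 0.0
    for _ in range(max_iter):
        x_i = X.sum(axis=1)
        denom = (c_i / x_i)[:, None] + (c_i / x_i)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            X_new = np.where(Csym > 0, Csym / denom, 0.0)
        if np.max(np.abs(X_new - X)) < tol:
            X = X_new
            break
        X = X_new
    return X / X.sum(axis=1, keepdims=True)


def estimate_transition_matrix(
    counts: CountMatrix, reversible: bool = False
) -> MSMModel:
    """Maximum-likelihood transition matrix on the largest connected set.

    The default (non-reversible) MLE is the row normalization
    ``P_ij = c_ij / sum_k c_ik``.  With ``reversible=True`` a
    detailed-balance-constrained MLE is computed by fixed-point
    iteration.  States outside the largest strongly connected component
    of the count graph are excluded and reported in ``excluded``.
    """
    C = counts.counts
    n = C.shape[0]
    adj = sparse.csr_matrix(C > 0)
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    sizes = np.bincount(comp, weights=C.sum(axis=1))  # weight by outgoing counts
    keep = np.flatnonzero(comp == np.argmax(sizes))
    if keep.size == 0 or C[np.ix_(keep, keep)].sum() == 0:
        raise ValueError("no connected state set with transition counts")
    excluded = [counts.labels[i] for i in range(n) if i not in set(keep.tolist())]
    sub = C[np.ix_(keep, keep)].astype(float)
    if reversible:
        P = _reversible_mle(sub)
    else:
        P = sub / sub.sum(axis=1, keepdims=True)
    pi = _stationary(P)
    evals = np.linalg.eigvals(P)
    evals = evals[np.argsort(-np.abs(evals))]
    return MSMModel(
        P=P,
        lag=counts.lag,
        labels=[counts.labels[i] for i in keep],
        pi=pi,
        eigenvalues=evals,
        excluded=excluded,
    )


def implied_timescales(dtrajs, lags, reversible: bool = False) -> pd.DataFrame:
    """Implied timescales for each lag in ``lags`` (ns).

    Returns a DataFrame indexed by lag with columns t1, t2, ... for the
    slowest processes; use it to check convergence and choose the model
    lag (flat timescales indicate Markovian behavior).
    """
    rows = {}
    n_ts = None
    for lag in lags:
        model = estimate_transition_matrix(count_transitions(dtrajs, lag), reversible)
        ts = np.sort(model.implied_timescales())[::-1]
        rows[lag] = ts
        n_ts = len(ts) if n_ts is None else min(n_ts, len(ts))
    data = {lag: ts[:n_ts] for lag, ts in rows.items()}
    df = pd.DataFrame(data).T
    df.columns = [f"t{i + 1}" for i in range(n_ts)]
    df.index.name = "lag_ns"
    return df


def mean_first_passage_times(model: MSMModel) -> np.ndarray:
    """mfpt(i -> j) in ns; mfpt(i, i) = 0.

    Solves m_i = tau + sum_{k != j} P_ik m_k for each target j; requires
    an irreducible transition matrix.
    """
    P = model.P
    n = model.n_states
    adj = sparse.csr_matrix(P > 0)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp > 1:
        raise ValueError("transition matrix is reducible; mfpt undefined")
    mfpt = np.zeros((n, n))
    tau = model.lag
    for j in range(n):
        others = [i for i in range(n) if i != j]
        A = np.eye(n - 1) - P[np.ix_(others, others)]
        m = np.linalg.solve(A, np.full(n - 1, tau))
        mfpt[others, j] = m
    return mfpt


def state_lifetimes(model: MSMModel) -> np.ndarray:
    """Lifetime of each state: mean first passage to any other state.

    For a Markov chain this first-exit time is ``tau / (1 - P_ii)``;
    absorbing states (P_ii = 1) get an infinite lifetime.
    """
    diag = np.diag(model.P)
    out = np.full(diag.shape, np.inf)
    mask = diag < 1.0
    out[mask] = model.lag / (1.0 - diag[mask])
    return out


def simulate_msm_trajectory(
    model: MSMModel, n_steps: int, seed: int = 0, initial: int = 0
) -> DiscreteTrajectory:
    """Monte Carlo state sequence at the model's lag time."""
    states = generate_markov_chain(model.P, n_steps, seed=seed, initial=initial)
    return DiscreteTrajectory(states=states, frame_dt=model.lag, labels=model.labels)


def rate_network(
    model: MSMModel, threshold: float = RATE_DISPLAY_THRESHOLD
) -> pd.DataFrame:
    """Reaction-rate edge list: rate(i -> j) = 1 / mfpt(i -> j) in s^-1.

    ``threshold`` filters the display edge list (default 50 s^-1, the
    conventional cut for network figures); pass 0 to keep all pairs.
    """
    mfpt = mean_first_passage_times(model)
    rows = []
    for i in range(model.n_states):
        for j in range(model.n_states):
            if i == j:
                continue
            rate = 1e9 / mfpt[i, j]  # ns -> s
            if rate > threshold:
                rows.append((model.labels[i], model.labels[j], rate))
    return pd.DataFrame(rows, columns=["source", "target", "rate_per_s"])
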