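# oligokin

Analysis toolkit for quantifying membrane-receptor oligomerization from
multi-copy coarse-grained simulation trajectories — the regime of class A
GPCRs such as the adenosine A2a receptor, where many receptor copies
diffuse in a membrane patch and reversibly associate into dimers and
higher-order oligomers.

It is written for simulators who have such trajectories (or want
ground-truth synthetic stand-ins) and need the full chain of analyses:

- **Oligomer detection** — per-frame minimum-image bead distances, a fixed
  contact cutoff (default 0.75 nm, where the bound-state distance peak at
  ~0.55 nm is separated from the unbound background by a trough at
  ~0.7 nm), single-linkage partitions, association/dissociation event
  counting from smoothed distance traces, oligomer-order distributions.
- **Configuration clustering** — permutation-invariant clustering of
  oligomer quaternary structures: members are reordered against a
  reference by lowest-RMSD permutation (all orders tried, in-plane rigid
  superposition), KMeans on the reordered coordinates, labels `A.b`
  (A = oligomeric order, b = cluster id by size), with geometric
  descriptors: dimer binding angles (θ₁, θ₂), trimer bending angle ϕ, and
  tetramer/pentamer principal-axis spans D₁ ≥ D₂.
- **Residence-time kinetics** — dwell durations of "continuous
  appearances" (contact breaks shorter than 100 ns are merged as
  flickers), the normalized survival function σ(t), a constrained
  biexponential fit

      σ(t) ≈ A e^(−k₁t) + B e^(−k₂t),   A + B = 1,  k₁ ≥ k₂ > 0,

  with k_off = k₂ (the slower rate), residence time 1/k_off, and
  bootstrap SD / 95% percentile intervals.
- **Lipid binding sites** — dual-cutoff (hysteresis) residue–lipid
  contacts (enter < 0.55 nm, exit > 1.0 nm), per-residue residence times
  and occupancies, a residue interaction graph weighted by same-lipid
  co-contact, Louvain communities as binding sites, site-level kinetics
  and bound-lipid counts, plus in-plane radial distributions g(r).
- **Markov state models** — whole-membrane composition states labeled
  `A^a-B^b-C^c` (e.g. `1^9` = nine monomers, `1^7-2^1` = seven monomers
  and one dimer), sliding-window transition counts at lag τ,
  maximum-likelihood transition matrices (non-reversible by default,
  reversible optional), stationary distributions, implied timescales
  k = −τ/ln(μ), mean first passage times, state lifetimes τ/(1−P_ii) and
  the reaction-rate network with rate = 1/mfpt.
- **Synthetic data with exact ground truth** — a 2D Brownian
  association/dissociation simulator (rigid bodies in a periodic
  45 × 45 nm box, capture-radius binding, first-order unbinding) whose
  every event, partition and dwell is recorded; exponential dwell
  mixtures; planted lipid binding sites; discrete Markov chains.

## Worked example

`examples/02_residence_time.py` draws 2000 dwell times from a known
two-phase mixture (fast 0.05 ns⁻¹, slow 0.002 ns⁻¹) and recovers the
slow rate:

```
n = 2000 dwells, sigma(0) = 1
fit: A = 0.60, k1 = 0.0499/ns, B = 0.40, k2 = 0.0020/ns
koff = min(k1, k2) = 0.00200/ns (true slow rate 0.00200/ns)
residence time 1/koff = 500 ns
bootstrap: SD = 8.87e-05/ns, 95% interval [0.00183, 0.00217]/ns
```

k_off is the slower fitted rate; the residence time 1/k_off (500 ns)
is the mean lifetime of the association, and the bootstrap interval
quantifies its sampling uncertainty.

`examples/04_lipid_sites.py` plants two binding sites with 10 ns contact
kinetics and recovers both, their memberships and their kinetics:

```
2 binding sites detected:
  site 1: residues [0, 1, 2, 3], residence 10.8 ns (koff 0.092/ns), mean bound lipids 0.34
  site 2: residues [8, 9, 10], residence 10.9 ns (koff 0.092/ns), mean bound lipids 0.34
```

The other examples cover simulation + event counting (`01`),
configuration clustering (`03`) and Markov state models (`05`); each is
a short script that builds its own input and prints what it computes.

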