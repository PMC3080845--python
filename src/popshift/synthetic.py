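"""Synthetic Boltzmann-sampled ensembles, time-correlated series, toy
ligands and synthetic RDCs with known ground truth.

These generators stand in for molecular-dynamics trajectories: every stage
of the analysis can be exercised against exact closed forms. The toy
"protein" is a chain of beads whose conformational free energy is a
Gaussian-mixture landscape

    E(x) = -kT ln sum_b exp(-E_b(x)/kT),
    E_b(x) = 1/2 sum_k k_bk (x_k - c_bk)^2 + depth_b,

so the equilibrium density is exactly a mixture of Gaussians and substate
populations have analytic values - the independent oracle the reweighting
stage is verified against. The default "ubiquitin-like" preset has three
basins of near-equal depth separated along one collective (pincer-like)
coordinate, mirroring the three-substate structure of the free-protein
landscape this package is built to analyse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.special import logsumexp, ndtr

from .constants import kt
from .ensemble import ConformerEnsemble, Topology
from .rdc import RDC_COLUMNS, RDCDataset, order_matrix

__all__ = [
    "BasinSpec",
    "ToySystem",
    "TrajectorySeries",
    "make_toy_system",
    "sample_metropolis",
    "sample_langevin_series",
    "make_toy_ligand",
    "analytic_two_state_oracle",
    "make_synthetic_rdc",
]


@dataclass
class BasinSpec:
    """One harmonic basin of the toy free-energy landscape.

    ``center`` is a point in conformation space (flattened coordinates, A);
    ``stiffness`` the per-coordinate harmonic force constant(s)
    (kcal/mol/A^2, scalar broadcast allowed, zero = flat direction);
    ``depth_offset`` the basin's energy offset (kcal/mol).
    """

    center: np.ndarray
    stiffness: np.ndarray
    depth_offset: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float)).ravel()
        self.stiffness = np.broadcast_to(
            np.asarray(self.stiffness, dtype=float), self.center.shape
        ).copy()
        if np.any(self.stiffness < 0):
            raise ValueError("stiffness must be non-negative")


@dataclass
class ToySystem:
    """A bead system with a multi-basin landscape at a fixed temperature."""

    basins: list
    temperature: float
    reference: np.ndarray              # (n_beads, 3) reference frame
    topology: Topology | None = None

    def __post_init__(self) -> None:
        if not self.basins:
            raise ValueError("system needs at least one basin")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        self.reference = np.asarray(self.reference, dtype=float)
        d = self.reference.size
        labels = [b.label for b in self.basins]
        if len(set(labels)) != len(labels):
            raise ValueError("basin labels must be unique")
        for b in self.basins:
            if b.center.size != d:
                raise ValueError(
                    f"basin {b.label!r} dimensionality {b.center.size} does not match "
                    f"system dimensionality {d}"
                )

    @property
    def dim(self) -> int:
        return self.reference.size

    def energy(self, x: np.ndarray) -> float:
        """Mixture free energy at flattened coordinates x (kcal/mol)."""
        kbt = kt(self.temperature)
        e_b = np.array(
            [0.5 * np.sum(b.stiffness * (x - b.center) ** 2) + b.depth_offset for b in self.basins]
        )
        return float(-kbt * logsumexp(-e_b / kbt))


def make_toy_system(
    n_beads: int = 5,
    basin_layout="ubiquitin-like",
    temperature: float = 300.0,
    seed: int = 0,
) -> ToySystem:
    """Construct a toy bead system.

    The default ``"ubiquitin-like"`` preset places the beads on a short
    helix and defines three near-equal-depth basins whose centers differ
    along one pincer-like collective coordinate (the terminal beads moving
    toward/away from each other): adjacent basin centers are 4 A apart in
    configuration space, soft (0.3 kcal/mol/A^2) along the pincer
    coordinates and stiff (2.0 kcal/mol/A^2) elsewhere, with depth offsets
    (0.06, 0.0, 0.12) kcal/mol. An explicit list of :class:`BasinSpec` may
    be passed instead. Deterministic for a given seed.
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    # helix-like, non-collinear bead arrangement
    i = np.arange(n_beads)
    reference = np.column_stack(
        [1.5 * np.cos(2.2 * i), 1.5 * np.sin(2.2 * i), 2.9 * i]
    )
    d = 3 * n_beads

    if isinstance(basin_layout, str):
        if basin_layout != "ubiquitin-like":
            raise ValueError(f"unknown basin preset: {basin_layout!r}")
        soft = np.zeros(d, dtype=bool)
        soft[0] = True                 # x of first bead
        soft[3 * (n_beads - 1)] = True  # x of last bead
        stiffness = np.where(soft, 0.3, 2.0)
        # pincer displacement: terminal beads move along +x / -x
        pincer = np.zeros(d)
        pincer[0] = 1.0 / np.sqrt(2.0)
        pincer[3 * (n_beads - 1)] = -1.0 / np.sqrt(2.0)
        base = reference.ravel()
        offsets = (-4.0, 0.0, 4.0)
        depths = (0.06, 0.0, 0.12)
        basins = [
            BasinSpec(base + s * pincer, stiffness, depth, label)
            for s, depth, label in zip(offsets, depths, ("S1", "S2", "S3"))
        ]
    else:
        basins = list(basin_layout)

    charge = rng.normal(0.0, 0.25, n_beads)
    charge -= charge.mean()  # neutral toy protein
    topology = Topology(
        charge=charge,
        lj_sigma=np.full(n_beads, 3.4),
        lj_epsilon=np.full(n_beads, 0.1),
        born_radius=np.full(n_beads, 1.7),
    )
    return ToySystem(basins=basins, temperature=temperature, reference=reference, topology=topology)


def sample_metropolis(
    system: ToySystem,
    n_samples: int,
    step_size: float = 0.25,
    seed: int = 0,
    burn_in: int | None = None,
    thin: int = 1,
) -> ConformerEnsemble:
    """Metropolis Monte Carlo sampling of the system's Boltzmann
    distribution exp(-E/kT).

    Proposals are global isotropic Gaussian moves of width ``step_size``
    (A per coordinate). ``burn_in`` defaults to 10% of the requested
    samples; ``thin`` keeps every thin-th post-burn-in state. The
    acceptance rate is stored in the returned ensemble's ``meta`` and a
    diagnostic warning is raised if nothing was accepted.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if burn_in is None:
        burn_in = n_samples // 10
    rng = np.random.default_rng(seed)
    kbt = kt(system.temperature)
    centers = np.stack([b.center for b in system.basins])       # (B, d)
    stiffness = np.stack([b.stiffness for b in system.basins])  # (B, d)
    depths = np.array([b.depth_offset for b in system.basins])
    d = system.dim

    import math

    def energy(x):
        diff = x - centers
        e_b = 0.5 * (stiffness * diff * diff).sum(axis=1) + depths
        m = e_b.min()
        return m - kbt * math.log(np.exp(-(e_b - m) / kbt).sum())

    n_steps = burn_in + n_samples * thin
    steps = rng.normal(0.0, step_size, size=(n_steps, d))
    log_unif = np.log(rng.random(n_steps))
    x = system.reference.ravel().copy()
    e = energy(x)
    samples = np.empty((n_samples, d))
    accepted = 0
    kept = 0
    for step_i in range(n_steps):
        proposal = x + steps[step_i]
        e_new = energy(proposal)
        if e_new <= e or log_unif[step_i] < -(e_new - e) / kbt:
            x, e = proposal, e_new
            accepted += 1
        post = step_i - burn_in
        if post >= 0 and (post + 1) % thin == 0 and kept < n_samples:
            samples[kept] = x
            kept += 1
    acceptance = accepted / n_steps
    if accepted == 0:
        warnings.warn(
            f"Metropolis sampler accepted no move in {n_steps} steps "
            f"(step_size={step_size}, T={system.temperature} K); "
            "reduce the step size",
            stacklevel=2,
        )
    n_beads = system.reference.shape[0] if system.reference.ndim == 2 else 1
    frames = samples.reshape(n_samples, n_beads, -1)
    if frames.shape[2] != 3:  # non-3D toy coordinates: embed in x, pad y/z with 0
        padded = np.zeros((n_samples, frames.shape[1] * frames.shape[2], 3))
        padded[:, :, 0] = samples.reshape(n_samples, -1)
        frames = padded
        n_beads = frames.shape[1]
    return ConformerEnsemble(
        atom_id=np.arange(1, n_beads + 1),
        res_id=np.arange(1, n_beads + 1),
        atom_name=np.full(n_beads, "CA"),
        element=np.full(n_beads, "C"),
        frames=frames,
        meta={
            "sampler": "metropolis",
            "seed": seed,
            "step_size": step_size,
            "burn_in": burn_in,
            "thin": thin,
            "acceptance_rate": acceptance,
            "temperature": system.temperature,
        },
    )


@dataclass
class TrajectorySeries:
    """Scalar time series with a uniform time step (ns)."""

    values: np.ndarray
    dt: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("series must have length >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def sample_langevin_series(
    tau_list,
    amplitude_list,
    dt: float,
    n_steps: int,
    seed: int = 0,
) -> TrajectorySeries:
    """Stationary series as a sum of independent OU components.

    Component i is an exactly discretized Ornstein-Uhlenbeck process with
    correlation time ``tau_list[i]`` (ns) and stationary variance
    ``amplitude_list[i]`` (the amplitudes must sum to 1, so the series has
    unit variance and population autocorrelation
    C(t) = sum_i a_i exp(-t/tau_i)). ``dt`` must be below min(tau)/2 to
    avoid discretization bias.
    """
    tau = np.asarray(tau_list, dtype=float)
    amp = np.asarray(amplitude_list, dtype=float)
    if tau.shape != amp.shape:
        raise ValueError("tau_list and amplitude_list lengths differ")
    if np.any(tau <= 0):
        raise ValueError("all correlation times must be positive")
    if np.any(amp < 0):
        raise ValueError("amplitudes must be non-negative")
    if abs(amp.sum() - 1.0) > 1e-9:
        raise ValueError("amplitudes must sum to 1")
    if amp.max() <= 0:
        raise ValueError("degenerate series: all component variances are zero")
    if dt >= tau.min() / 2:
        raise ValueError(
            f"dt={dt} ns too large relative to min(tau)={tau.min()} ns "
            "(discretization bias); need dt < min(tau)/2"
        )
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    total = np.zeros(n_steps)
    for a, t in zip(amp, tau):
        if a == 0:
            continue
        phi = np.exp(-dt / t)
        innov_sd = np.sqrt(a * (1.0 - phi * phi))
        x0 = rng.normal(0.0, np.sqrt(a))
        noise = rng.normal(0.0, innov_sd, n_steps)
        comp, _ = lfilter([1.0], [1.0, -phi], noise, zi=[phi * x0])
        total += comp
    return TrajectorySeries(values=total, dt=dt, seed=seed)


def make_toy_ligand(n_atoms: int, net_charge: float = 0.0, seed: int = 0):
    """Rigid toy ligand: a compact random cluster with charges summing to
    ``net_charge`` and plausible LJ/Born parameters. Returns
    (Topology, coordinates)."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    coords = rng.normal(0.0, 1.2, size=(n_atoms, 3))
    coords -= coords.mean(axis=0)
    charge = rng.normal(0.0, 0.3, n_atoms)
    charge += (net_charge - charge.sum()) / n_atoms
    topology = Topology(
        charge=charge,
        lj_sigma=rng.uniform(3.0, 3.6, n_atoms),
        lj_epsilon=rng.uniform(0.05, 0.15, n_atoms),
        born_radius=rng.uniform(1.5, 2.0, n_atoms),
    )
    return topology, coords


def analytic_two_state_oracle(
    basins,
    perturbation: float = 0.0,
    temperature: float = 300.0,
) -> np.ndarray:
    """Closed-form substate populations of a 1D two-basin landscape under a
    linear field.

    For the Gaussian-mixture landscape plus field slope s (kcal/mol/A along
    the collective coordinate), each basin's Boltzmann integral is Gaussian:

        w_b ∝ k_b^(-1/2) exp(-(depth_b + s c_b - s^2/(2 k_b)) / kT)
        mu_b = c_b - s / k_b,  sigma_b^2 = kT / k_b

    and the substate populations are the mixture masses on either side of
    the midpoint between the two unperturbed centers. Orthogonal (stiff)
    coordinates must have identical stiffness in both basins so their
    integrals cancel.
    """
    if len(basins) != 2:
        raise ValueError("the oracle handles exactly two basins")
    b1, b2 = basins
    if b1.center.size > 1:
        if not np.allclose(b1.stiffness[1:], b2.stiffness[1:]):
            raise ValueError(
                "orthogonal-coordinate stiffnesses differ between basins; "
                "only the first coordinate may differ (unsupported otherwise)"
            )
        if not np.allclose(b1.center[1:], b2.center[1:]):
            raise ValueError("basins must share all non-leading center coordinates")
    kbt = kt(temperature)
    s = float(perturbation)
    c = np.array([b1.center[0], b2.center[0]])
    k = np.array([b1.stiffness[0], b2.stiffness[0]])
    depth = np.array([b1.depth_offset, b2.depth_offset])
    if np.any(k <= 0):
        raise ValueError("the oracle requires harmonic (positive-stiffness) basins")
    log_w = -(depth + s * c - s * s / (2.0 * k)) / kbt - 0.5 * np.log(k)
    log_w -= logsumexp(log_w)
    w = np.exp(log_w)
    mu = c - s / k
    sigma = np.sqrt(kbt / k)
    m = 0.5 * (c[0] + c[1])
    lower = c[0] <= c[1]
    # mass of each mixture component on basin 1's side of the midpoint
    phi = ndtr((m - mu) / sigma) if lower else 1.0 - ndtr((m - mu) / sigma)
    p1 = float(np.sum(w * phi))
    return np.array([p1, 1.0 - p1])


def make_synthetic_rdc(
    ensemble: ConformerEnsemble,
    tensor,
    noise_sd: float = 0.0,
    seed: int = 0,
    medium: str = "synthetic",
) -> RDCDataset:
    """Synthetic couplings from a known 5-component alignment tensor.

    Pseudo-bond vectors run between consecutive Calpha atoms (residue k to
    k+1); couplings are the ensemble-averaged tensor contraction plus
    Gaussian noise of width ``noise_sd`` (Hz).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    res = np.unique(ensemble.res_id)
    records = pd.DataFrame(
        {
            "res_id": res[:-1],
            "atom1": "CA",
            "atom2": "CA",
            "medium": medium,
            "D_exp": 0.0,
        }
    )
    used, a = order_matrix(ensemble, records)
    d = a @ np.asarray(tensor, dtype=float)
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, d.size)
    records = records.iloc[used].copy()
    records["D_exp"] = d
    return RDCDataset(records[RDC_COLUMNS].reset_index(drop=True))
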