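"""Synthetic generators for every pipeline input, with known ground truth.

Each generator emulates the statistical structure the downstream analysis
assumes, not the physics that produced the original data:

* ``generate_decoys`` — energy-ranked docking-decoy ensembles with a
  controllable receptor-conformation bias in the low-energy tail;
* ``generate_trajectory`` — multi-frame node coordinates whose per-frame
  displacements follow a prescribed covariance (block) structure, with
  selected node pairs placed so that their contact occupancy hits a
  target value;
* ``generate_residence_series`` — peptide-to-pocket distance series in
  stay / leave / blow-up regimes;
* ``generate_sensorgram`` — single-cycle two-state sensorgrams with
  i.i.d. Gaussian read noise.

Displacements are sampled independently per frame (no autocorrelation):
the downstream correlation statistic is a per-frame covariance, so
temporal correlation is not needed to exercise it.  All draws for one
spec come from a single seeded generator, so fixed seed means
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, ncx2

from .spr_kinetics import InjectionSeries, Sensorgram, TwoStateRates, simulate_sensorgram
from .trajectory_io import Trajectory

__all__ = [
    "InvalidSpecError",
    "EnergyModel",
    "DecoyEnsembleSpec",
    "TrajectorySpec",
    "ResidenceSpec",
    "SensorgramSpec",
    "generate_decoys",
    "generate_trajectory",
    "generate_residence_series",
    "generate_sensorgram",
]


class InvalidSpecError(ValueError):
    """A generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# docking decoys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyModel:
    """Per-(receptor, peptide) Gaussian binding-energy model, kcal/mol.

    ``pair_mean``/``pair_spread`` override the base values for specific
    (receptor_id, peptide) cells.
    """

    base_mean: float = -8.0
    base_spread: float = 1.5
    pair_mean: Mapping[tuple[str, str], float] = field(default_factory=dict)
    pair_spread: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def mean(self, receptor_id: str, peptide: str) -> float:
        return self.pair_mean.get((receptor_id, peptide), self.base_mean)

    def spread(self, receptor_id: str, peptide: str) -> float:
        return self.pair_spread.get((receptor_id, peptide), self.base_spread)


@dataclass(frozen=True)
class DecoyEnsembleSpec:
    """Ensemble-docking decoy table spec.

    ``bias`` maps receptor ids to an additive energy offset (kcal/mol);
    a negative offset makes that conformation dominate the low-energy
    tail.  ``dropout`` is the probability that a cluster slot is missing
    (real docking runs sometimes produce fewer clusters than requested).
    """

    receptor_ids: tuple[str, ...]
    peptides: tuple[str, ...]
    clusters_per_pair: int = 10
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    bias: Mapping[str, float] = field(default_factory=dict)
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.receptor_ids:
            raise InvalidSpecError("receptor_ids must be non-empty")
        if not self.peptides:
            raise InvalidSpecError("peptides must be non-empty")
        if self.clusters_per_pair < 1:
            raise InvalidSpecError("clusters_per_pair must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidSpecError("dropout must be in [0, 1)")
        if self.energy_model.base_spread <= 0 or any(
            s <= 0 for s in self.energy_model.pair_spread.values()
        ):
            raise InvalidSpecError("energy spread must be positive")
        unknown = set(self.bias) - set(self.receptor_ids)
        if unknown:
            raise InvalidSpecError(f"bias references unknown receptors {sorted(unknown)}")


def generate_decoys(spec: DecoyEnsembleSpec) -> pd.DataFrame:
    """Draw a decoy table (columns receptor_id, peptide, cluster_rank,
    energy_kcal_mol).

    Per (receptor, peptide) cell, ``clusters_per_pair`` energies are drawn
    from the cell's Gaussian plus the receptor bias, sorted ascending and
    assigned cluster ranks 1..k (rank 1 = best), mirroring energy-ranked
    cluster representatives.
    """
    rng = np.random.default_rng(spec.seed)
    n_r, n_p, k = len(spec.receptor_ids), len(spec.peptides), spec.clusters_per_pair
    means = np.array(
        [
            [spec.energy_model.mean(r, p) + spec.bias.get(r, 0.0) for p in spec.peptides]
            for r in spec.receptor_ids
        ]
    )
    spreads = np.array(
        [[spec.energy_model.spread(r, p) for p in spec.peptides] for r in spec.receptor_ids]
    )
    energies = rng.normal(means[:, :, None], spreads[:, :, None], size=(n_r, n_p, k))
    energies.sort(axis=2)
    keep = (
        rng.random((n_r, n_p, k)) >= spec.dropout
        if spec.dropout
        else np.ones((n_r, n_p, k), dtype=bool)
    )
    ri, pi, ki = np.nonzero(keep)
    table = pd.DataFrame(
        {
            "receptor_id": np.array(spec.receptor_ids)[ri],
            "peptide": np.array(spec.peptides)[pi],
            "cluster_rank": ki + 1,
            "energy_kcal_mol": energies[ri, pi, ki],
        }
    )
    return table


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Node-trajectory spec.

    ``chains`` maps chain id to node count; nodes are numbered 1..n per
    chain, in chain order.  ``covariance`` is the per-axis displacement
    covariance over all nodes (node-isotropic: the same matrix is used
    independently for x, y and z); a scalar ``displacement_sd`` builds a
    diagonal covariance instead.  ``contact_targets`` is a list of
    (node_i, node_j, target_occupancy) index pairs (0-based over the
    concatenated node list) whose reference separation is calibrated so
    the pair's contact occupancy at ``contact_cutoff`` hits the target.
    """

    chains: Mapping[str, int]
    n_frames: int = 200
    frame_interval_ps: float = 100.0
    reference: Optional[np.ndarray] = None
    covariance: Optional[np.ndarray] = None
    displacement_sd: float = 1.0
    contact_targets: tuple[tuple[int, int, float], ...] = ()
    contact_cutoff: float = 4.5
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return int(sum(self.chains.values()))

    def __post_init__(self) -> None:
        if not self.chains or any(n < 1 for n in self.chains.values()):
            raise InvalidSpecError("chains must map to positive node counts")
        if self.n_frames < 2:
            raise InvalidSpecError("n_frames must be >= 2")
        n = self.n_nodes
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (n, n):
                raise InvalidSpecError(f"covariance must be {n}x{n}")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise InvalidSpecError("covariance must be symmetric")
            w = np.linalg.eigvalsh(cov)
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise InvalidSpecError("covariance must be positive semi-definite")
        elif self.displacement_sd < 0:
            raise InvalidSpecError("displacement_sd must be >= 0")
        for i, j, occ in self.contact_targets:
            if not 0 <= i < n or not 0 <= j < n or i == j:
                raise InvalidSpecError(f"bad contact target pair ({i}, {j})")
            if not 0.0 <= occ <= 1.0:
                raise InvalidSpecError("target occupancy must be in [0, 1]")
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (n, 3):
                raise InvalidSpecError(f"reference must be {n}x3")

    def covariance_matrix(self) -> np.ndarray:
        if self.covariance is not None:
            return np.asarray(self.covariance, dtype=float)
        return np.eye(self.n_nodes) * self.displacement_sd**2


def _default_reference(spec: TrajectorySpec) -> np.ndarray:
    """Chains laid out as parallel lines, 10 Å node spacing, 10 Å apart."""
    ref = np.zeros((spec.n_nodes, 3))
    row = 0
    for c, (chain, n) in enumerate(spec.chains.items()):
        for k in range(n):
            ref[row] = (10.0 * k, 10.0 * c, 0.0)
            row += 1
    return ref


def _occupancy_probability(sep: float, rel_var: float, cutoff: float) -> float:
    """P(|sep*e_x + d| < cutoff), d ~ N(0, rel_var I3).

    The squared distance over rel_var is noncentral chi-square with 3
    degrees of freedom and noncentrality sep^2/rel_var.
    """
    if rel_var <= 0:
        return 1.0 if sep < cutoff else 0.0
    return float(ncx2.cdf(cutoff**2 / rel_var, df=3, nc=sep**2 / rel_var))


def _calibrate_separation(target: float, rel_var: float, cutoff: float) -> float:
    """Reference separation whose contact occupancy equals ``target``."""
    if rel_var <= 0:
        # occupancy is a step function of separation
        if target not in (0.0, 1.0):
            raise InvalidSpecError(
                "fractional occupancy target needs nonzero displacement variance"
            )
        return 0.5 * cutoff if target == 1.0 else 2.0 * cutoff
    max_occ = float(chi2.cdf(cutoff**2 / rel_var, df=3))  # occupancy at sep=0
    if target > max_occ and target - max_occ <= 1e-3:
        return 0.0  # target at (or negligibly above) the achievable maximum
    if target > max_occ:
        raise InvalidSpecError(
            f"occupancy target {target} unreachable: displacement spread too "
            f"large for the cutoff (max {max_occ:.3f})"
        )
    if target <= 0.0:
        return cutoff + 10.0 * np.sqrt(rel_var)
    hi = cutoff + 10.0 * np.sqrt(rel_var)
    f = lambda s: _occupancy_probability(s, rel_var, cutoff) - target
    if f(0.0) <= 0:  # target == max_occ within tolerance
        return 0.0
    return float(brentq(f, 0.0, hi, xtol=1e-10))


def generate_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Sample a trajectory with the spec'd displacement covariance.

    Frames are reference + displacement with displacements drawn i.i.d.
    per frame and per axis from N(0, covariance).  Contact-target pairs
    have node j moved along the i->j direction to the calibrated
    separation before sampling, which fixes their occupancy without
    touching the covariance.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    ref = (
        np.array(spec.reference, dtype=float)
        if spec.reference is not None
        else _default_reference(spec)
    )
    cov = spec.covariance_matrix()

    for i, j, occ in spec.contact_targets:
        rel_var = cov[i, i] + cov[j, j] - 2.0 * cov[i, j]
        sep = _calibrate_separation(occ, rel_var, spec.contact_cutoff)
        direction = ref[j] - ref[i]
        norm = np.linalg.norm(direction)
        unit = direction / norm if norm > 1e-12 else np.array([1.0, 0.0, 0.0])
        ref[j] = ref[i] + sep * unit

    # PSD square root via eigendecomposition (cholesky fails on singular cov)
    w, v = np.linalg.eigh(cov)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((spec.n_frames, 3, n))
    disp = z @ factor.T                      # (F, 3, N)
    coords = ref.T[None, :, :] + disp        # broadcast over frames
    coords = coords.transpose(0, 2, 1)       # (F, N, 3)

    atoms = pd.DataFrame(
        {
            "chain": [c for c, k in spec.chains.items() for _ in range(k)],
            "resid": [r for _, k in spec.chains.items() for r in range(1, k + 1)],
            "resname": "GLY",
            "name": "CA",
        }
    )
    return Trajectory(coords=coords, atoms=atoms, frame_interval_ps=spec.frame_interval_ps)


# ---------------------------------------------------------------------------
# pocket-residence distance series
# ---------------------------------------------------------------------------

REGIMES = ("stay", "leave", "blow_up")


@dataclass(frozen=True)
class ResidenceSpec:
    """Peptide-to-pocket distance-series spec for one regime.

    stay: stationary noise around ``initial_distance``; leave: linear
    mean drift of ``drift_rate`` Å/frame; blow_up: stay-like until
    ``divergence_frame`` then super-linear (quadratic) divergence.
    """

    regime: str
    initial_distance: float = 4.0
    drift_rate: float = 0.3
    divergence_frame: int = 40
    noise_sd: float = 0.5
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise InvalidSpecError(f"regime must be one of {REGIMES}")
        if self.initial_distance < 0:
            raise InvalidSpecError("initial distance must be >= 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise sd must be >= 0")
        if self.n_frames < 10:
            raise InvalidSpecError("n_frames must be >= 10")
        if self.regime == "blow_up" and not 0 <= self.divergence_frame < self.n_frames:
            raise InvalidSpecError("divergence_frame must lie inside the series")


def generate_residence_series(spec: ResidenceSpec) -> np.ndarray:
    """Distance series (Å, length n_frames) for the spec'd regime.

    Closed-form means: stay -> initial; leave -> initial + drift * t;
    blow_up -> stay-like mean plus 2 (t - t_div)^2 beyond the divergence
    frame.  Values are clipped at zero (distances).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames, dtype=float)
    noise = rng.normal(0.0, spec.noise_sd, spec.n_frames) if spec.noise_sd else 0.0
    if spec.regime == "stay":
        mean = np.full(spec.n_frames, spec.initial_distance)
    elif spec.regime == "leave":
        mean = spec.initial_distance + spec.drift_rate * t
    else:
        mean = np.full(spec.n_frames, spec.initial_distance)
        over = t >= spec.divergence_frame
        mean = mean + np.where(over, 2.0 * (t - spec.divergence_frame) ** 2, 0.0)
    return np.clip(mean + noise, 0.0, None)


# ---------------------------------------------------------------------------
# sensorgrams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorgramSpec:
    """Noisy single-cycle two-state sensorgram spec."""

    rates: TwoStateRates
    rmax: float
    schedule: InjectionSeries
    noise_sd: float = 1.0
    timestep_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rmax <= 0:
            raise InvalidSpecError("Rmax must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise sd must be >= 0")
        if self.timestep_s <= 0:
            raise InvalidSpecError("timestep must be positive")


def generate_sensorgram(spec: SensorgramSpec) -> Sensorgram:
    """Simulate the noiseless two-state response and add i.i.d. read noise."""
    clean = simulate_sensorgram(
        spec.rates, spec.rmax, spec.schedule, timestep_s=spec.timestep_s
    )
    if spec.noise_sd == 0:
        return clean
    rng = np.random.default_rng(spec.seed)
    noisy = clean.response_ru + rng.normal(0.0, spec.noise_sd, clean.response_ru.shape)
    return Sensorgram(clean.time_s, noisy, clean.concentration_m)
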