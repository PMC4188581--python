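"""Pocket-residence triage: does a docked peptide stay in the allosteric
pocket, swim away, or blow up over a trajectory?

The pocket is defined by key CDK2 residues (R150, K178, Y180 by default —
the experimentally identified anchor residues of the allosteric site next
to the T-loop).  The per-frame statistic is the minimum distance between
any peptide node and any pocket key-residue node; the classifier then
applies simple, fully configurable rules to that distance series.  The
thresholds quantify what is otherwise a visual judgement on trajectory
snapshots, so they are artifact choices, not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trajectory_io import NodeSelection, Trajectory, subset

__all__ = [
    "DEFAULT_POCKET_RESIDUES",
    "PocketSpec",
    "ResidenceCall",
    "distance_series",
    "classify_residence",
]

#: CDK2 allosteric-pocket anchor residues.
DEFAULT_POCKET_RESIDUES: tuple[int, ...] = (150, 178, 180)

STAY, LEAVE, BLOW_UP = "stay", "leave", "blow_up"


@dataclass(frozen=True)
class PocketSpec:
    """Key pocket residues (by residue index) and the receptor chain."""

    residues: tuple[int, ...] = DEFAULT_POCKET_RESIDUES
    chain: str = "A"
    reference_distance: float | None = None  # Å, optional initial distance

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("pocket needs at least one key residue")


@dataclass
class ResidenceCall:
    """Classifier output with its numeric evidence."""

    label: str
    initial_mean: float
    final_mean: float
    drift_slope: float          # Å per frame, least-squares over the series
    diverged: bool

    def __post_init__(self) -> None:
        if self.label not in (STAY, LEAVE, BLOW_UP):
            raise ValueError(f"unknown label {self.label!r}")


def distance_series(
    traj: Trajectory,
    peptide_selection: NodeSelection,
    pocket: PocketSpec,
) -> np.ndarray:
    """Per-frame minimum peptide-to-pocket inter-node distance, Å."""
    pep = subset(traj, peptide_selection)
    chains = traj.atoms["chain"].to_numpy()
    resids = traj.atoms["resid"].to_numpy()
    present = set(resids[chains == pocket.chain].tolist())
    missing = [r for r in pocket.residues if r not in present]
    if missing:
        raise ValueError(
            f"pocket residues {missing} absent from chain {pocket.chain!r}"
        )
    mask = (chains == pocket.chain) & np.isin(resids, list(pocket.residues))
    pocket_xyz = traj.coords[:, mask, :]
    diff = pep.coords[:, :, None, :] - pocket_xyz[:, None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    return d.reshape(traj.n_frames, -1).min(axis=1)


def classify_residence(
    series: Sequence[float],
    stay_margin: float = 3.0,
    final_window: float = 0.2,
    divergence_cutoff: float = 50.0,
) -> ResidenceCall:
    """Label a peptide-to-pocket distance series.

    Rules, in order:

    * ``blow_up`` — any non-finite value or any distance above
      ``divergence_cutoff`` (Å);
    * ``leave`` — the mean over the final ``final_window`` fraction of
      frames exceeds the mean over the matching initial window by more
      than ``stay_margin`` (Å);
    * ``stay`` — otherwise.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("distance series needs at least 10 points")
    if not 0 < final_window <= 0.5:
        raise ValueError("final_window must be in (0, 0.5]")
    w = max(1, int(round(final_window * len(x))))
    finite = np.isfinite(x)
    diverged = bool((~finite).any() or np.nanmax(np.where(finite, x, -np.inf)) > divergence_cutoff)
    initial_mean = float(np.nanmean(x[:w])) if finite[:w].any() else float("nan")
    final_mean = float(np.nanmean(x[-w:])) if finite[-w:].any() else float("inf")
    t = np.arange(len(x))
    slope = (
        float(np.polyfit(t[finite], x[finite], 1)[0]) if finite.sum() >= 2 else float("inf")
    )
    if diverged:
        label = BLOW_UP
    elif final_mean > initial_mean + stay_margin:
        label = LEAVE
    else:
        label = STAY
    return ResidenceCall(
        label=label,
        initial_mean=initial_mean,
        final_mean=final_mean,
        drift_slope=slope,
        diverged=diverged,
    )
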