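"""Candidate-peptide selection from ensemble-docking decoy tables.

A decoy is one retained docked pose of a pentapeptide against one receptor
conformation (the CDK2 ensemble members, e.g. ``SET2_06``), carrying the
docking binding energy in kcal/mol (lower = better) and the rank of the
energy cluster it represents.  Three complementary selectors are provided:

``select_by_frequency``
    conformational-selection logic: which receptor conformations dominate
    the low-energy tail of the ensemble, then the best peptides docked to
    those "favourite" conformations;
``select_by_energy``
    plain ranking by each peptide's best docking energy;
``select_by_rescoring``
    the same ranking driven by an external knowledge-based potential
    (e.g. a statistical contact potential) instead of the docking energy.

The union of the three selections is the candidate list carried forward
to molecular-dynamics triage.

Ties in any energy-like score are broken lexicographically by
(peptide, receptor_id, cluster_rank) so every selector is invariant to
input row order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DECOY_COLUMNS",
    "DockingDecoy",
    "SelectionResult",
    "ToyContactPotential",
    "read_decoys",
    "write_decoys",
    "select_by_frequency",
    "select_by_energy",
    "select_by_rescoring",
    "combine_selections",
]

#: Canonical TSV schema for decoy tables.
DECOY_COLUMNS = ["receptor_id", "peptide", "cluster_rank", "energy_kcal_mol"]


class DockingDecoy(NamedTuple):
    """One docked pose: provenance plus score(s)."""

    receptor_id: str
    peptide: str
    cluster_rank: int
    energy_kcal_mol: float
    rescore_kcal_mol: Optional[float] = None


@dataclass
class SelectionResult:
    """Outcome of one selection method.

    ``conformation_counts`` is populated only by the frequency method and
    maps receptor conformation id to its occurrence count among the
    low-energy decoys.
    """

    method: str
    peptides: list[str]
    conformation_counts: Optional[dict[str, int]] = None
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.peptides)) != len(self.peptides):
            raise ValueError("selected peptides must be unique")

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "peptides": self.peptides,
                "conformation_counts": self.conformation_counts,
                "scores": self.scores,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# table I/O and validation
# ---------------------------------------------------------------------------

def _check_table(decoys: pd.DataFrame) -> pd.DataFrame:
    if decoys.empty:
        raise ValueError("decoy table is empty")
    missing = [c for c in DECOY_COLUMNS if c not in decoys.columns]
    if missing:
        raise ValueError(f"decoy table missing columns {missing}")
    if not np.isfinite(decoys["energy_kcal_mol"]).all():
        raise ValueError("decoy energies must be finite")
    if (decoys["cluster_rank"] < 1).any():
        raise ValueError("cluster_rank must be >= 1")
    return decoys


def read_decoys(path) -> pd.DataFrame:
    """Read a decoy table from TSV (schema :data:`DECOY_COLUMNS`)."""
    return _check_table(pd.read_csv(path, sep="\t"))


def write_decoys(decoys: pd.DataFrame, path) -> None:
    _check_table(decoys).to_csv(path, sep="\t", index=False)


def _sorted_by_energy(decoys: pd.DataFrame, energy_col: str) -> pd.DataFrame:
    return decoys.sort_values(
        [energy_col, "peptide", "receptor_id", "cluster_rank"],
        kind="mergesort",
    )


def _best_per_peptide(decoys: pd.DataFrame, energy_col: str) -> pd.DataFrame:
    """One row per peptide: its minimum (best) score, deterministic ties."""
    ordered = _sorted_by_energy(decoys, energy_col)
    return ordered.drop_duplicates("peptide", keep="first")


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def select_by_energy(decoys: pd.DataFrame, k: int = 5) -> SelectionResult:
    """Top-``k`` distinct peptides by best (minimum) docking energy."""
    _check_table(decoys)
    best = _best_per_peptide(decoys, "energy_kcal_mol").head(k)
    return SelectionResult(
        method="energy",
        peptides=best["peptide"].tolist(),
        scores=dict(zip(best["peptide"], best["energy_kcal_mol"])),
    )


def select_by_frequency(
    decoys: pd.DataFrame,
    top_n: int = 1000,
    k_conformations: int = 3,
    k_peptides: int = 5,
) -> SelectionResult:
    """Conformational-frequency selection.

    1. Take the ``top_n`` lowest-energy decoys of the whole ensemble.
    2. Count receptor-conformation occurrences among them; the
       ``k_conformations`` most frequent are the favourite conformations.
    3. Restrict the low-energy set to those conformations and return the
       ``k_peptides`` distinct peptides with the lowest best energy,
       ordered by that energy.
    """
    _check_table(decoys)
    if len(decoys) < top_n:
        warnings.warn(
            f"decoy table has {len(decoys)} rows < top_n={top_n}; using all rows",
            stacklevel=2,
        )
        top_n = len(decoys)
    top = _sorted_by_energy(decoys, "energy_kcal_mol").head(top_n)

    counts = top["receptor_id"].value_counts()
    # deterministic: count descending, receptor id ascending on ties
    counts = counts.sort_index().sort_values(ascending=False, kind="mergesort")
    favourites = counts.head(k_conformations)

    pool = top[top["receptor_id"].isin(favourites.index)]
    best = _best_per_peptide(pool, "energy_kcal_mol").head(k_peptides)
    return SelectionResult(
        method="frequency",
        peptides=best["peptide"].tolist(),
        conformation_counts=favourites.to_dict(),
        scores=dict(zip(best["peptide"], best["energy_kcal_mol"])),
    )


def select_by_rescoring(
    decoys: pd.DataFrame,
    potential: Callable[[DockingDecoy], float],
    k: int = 5,
) -> SelectionResult:
    """Re-rank every decoy with a knowledge-based ``potential`` and select.

    The potential maps a :class:`DockingDecoy` to a score in kcal/mol
    (lower = better) and must be deterministic.  Original docking energies
    are left untouched; the rescore is carried in a separate column.
    """
    _check_table(decoys)
    rescored = decoys.copy()
    scores = []
    for row in rescored.itertuples(index=False):
        decoy = DockingDecoy(
            receptor_id=row.receptor_id,
            peptide=row.peptide,
            cluster_rank=int(row.cluster_rank),
            energy_kcal_mol=float(row.energy_kcal_mol),
        )
        try:
            scores.append(float(potential(decoy)))
        except Exception as exc:  # noqa: BLE001 - re-raise with provenance
            raise RuntimeError(
                f"scoring potential failed on decoy "
                f"{decoy.receptor_id}/{decoy.peptide}/cluster {decoy.cluster_rank}: {exc}"
            ) from exc
    rescored["rescore_kcal_mol"] = scores
    best = _best_per_peptide(rescored, "rescore_kcal_mol").head(k)
    return SelectionResult(
        method="rescoring",
        peptides=best["peptide"].tolist(),
        scores=dict(zip(best["peptide"], best["rescore_kcal_mol"])),
    )


def combine_selections(
    results: Sequence[SelectionResult | Iterable[str]],
) -> list[str]:
    """Union of per-method peptide lists, first-seen order, duplicates dropped."""
    if not results:
        raise ValueError("need at least one selection result")
    combined: list[str] = []
    seen: set[str] = set()
    for res in results:
        peptides = res.peptides if isinstance(res, SelectionResult) else list(res)
        for p in peptides:
            if p not in seen:
                seen.add(p)
                combined.append(p)
    return combined


# ---------------------------------------------------------------------------
# bundled toy potential (ScoringPotential contract)
# ---------------------------------------------------------------------------

#: Kyte-Doolittle hydropathy, used to tabulate toy residue-pair well depths.
_HYDROPATHY: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class ToyContactPotential:
    """A deterministic 12-6-style residue-pair contact potential.

    This is a *toy* stand-in that satisfies the ScoringPotential contract
    for tests and demos: pair well depths are tabulated from hydropathy
    products, evaluated on a 12-6 profile at an idealized inter-residue
    distance set by sequence separation (3.8 Å per peptide bond, capped by
    a contact radius).  It is not a database-derived statistical potential.
    """

    r0: float = 5.0        # Å, well minimum
    spacing: float = 3.8   # Å per residue of sequence separation
    depth_scale: float = 0.05

    def pair_energy(self, a: str, b: str, r: float) -> float:
        eps = self.depth_scale * (_HYDROPATHY[a] * _HYDROPATHY[b])
        x = (self.r0 / r) ** 6
        return eps * (x * x - 2.0 * x)

    def __call__(self, decoy: DockingDecoy) -> float:
        seq = decoy.peptide
        total = 0.0
        for i in range(len(seq)):
            for j in range(i + 1, len(seq)):
                r = min(self.spacing * (j - i), 2.0 * self.r0)
                total += self.pair_energy(seq[i], seq[j], r)
        # small, deterministic pose-quality penalty
        return total + 0.1 * (decoy.cluster_rank - 1)
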