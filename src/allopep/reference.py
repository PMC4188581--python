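"""Published reference constants for the CDK2/Cyclin E peptide study system.

These are the printed experimental and computational constants the
package's worked examples and consistency checks run against: the
SPR-derived two-state rate constants for the four tested pentapeptides
(with and without 60 µM ATP in the running buffer), the docking-energy
worked-example table, the per-method selection lists, and the screening
bookkeeping (ensemble sizes, frequency counts, interface-correlation
scores).  All values are inputs, not outputs, of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .spr_kinetics import TwoStateRates

__all__ = [
    "RateSet",
    "TWO_STATE_RATE_SETS",
    "ENERGY_TABLE",
    "RESCORE_TABLE",
    "SELECTION_LISTS",
    "FREQUENCY_COUNTS",
    "INTERFACE_SCORES",
    "BASELINE_INTERFACE_SCORE",
    "POCKET_KEY_RESIDUES",
    "TLOOP_RANGE",
    "DOCKING_GRID_CENTER",
    "RECEPTOR_SETS",
    "CLUSTERS_PER_PAIR",
    "energy_fixture_table",
]


@dataclass(frozen=True)
class RateSet:
    """One published two-state rate set with its printed K_D.

    ``printed_label`` preserves the label exactly as published; the
    TAALS-with-ATP row was printed under the label "TALLS", retained here
    and treated as a typographical variant of TAALS.
    """

    peptide: str
    with_atp: bool
    rates: TwoStateRates
    printed_kd_m: float
    printed_kd_uncertainty_m: float
    printed_label: str


TWO_STATE_RATE_SETS: tuple[RateSet, ...] = (
    RateSet("TAALS", False, TwoStateRates(11.3, 26.0e-3, 11.1e-3, 6.8e-6),
            1.4e-6, 0.6e-6, "TAALS"),
    RateSet("TAALS", True, TwoStateRates(3.7, 28.2e-3, 9.1e-3, 3.8e-6),
            3.3e-6, 0.8e-6, "TALLS"),
    RateSet("LAALS", False, TwoStateRates(498.0, 11.9e-3, 5.8e-5, 2.9e-5),
            8.0e-6, 2.9e-6, "LAALS"),
    RateSet("LAALS", True, TwoStateRates(237.4, 51.8e-3, 7.9e-3, 3.1e-3),
            6.1e-5, 0.6e-5, "LAALS"),
    RateSet("DAALT", False, TwoStateRates(434.1, 23.2e-3, 14.1e-4, 1.3e-5),
            4.7e-7, 2.0e-7, "DAALT"),
    RateSet("DAALT", True, TwoStateRates(612.9, 101.2e-3, 34.6e-3, 10.1e-3),
            3.7e-5, 0.3e-5, "DAALT"),
    RateSet("YAALQ", False, TwoStateRates(165.7, 84.0e-3, 9.0e-3, 2.2e-3),
            9.8e-5, 0.7e-5, "YAALQ"),
    RateSet("YAALQ", True, TwoStateRates(100.9, 53.9e-3, 12.3e-3, 1.6e-3),
            6.1e-5, 0.3e-5, "YAALQ"),
)

#: Published docking-energy worked example: best printed AutoDock binding
#: energy (kcal/mol) per receptor-conformation/peptide model, including the
#: three previously characterized control peptides.
ENERGY_TABLE: tuple[tuple[str, str, float], ...] = (
    ("SET2", "RAALW", -15.89),
    ("SET3", "RAALQ", -14.67),
    ("SET2", "GAALY", -14.33),
    ("SET2", "PAALA", -13.86),
    ("SET3", "RAALM", -13.82),
    ("SET2", "FAALA", -13.30),
    ("SET2", "RAALG", -13.11),
    ("SET2", "RAALF", -12.84),
    ("SET2", "TAALD", -11.58),
    ("SET2", "TAALS", -11.28),
    ("SET2", "LAALS", -10.98),
)

#: Published knowledge-based (statistical potential) rescoring block:
#: (receptor set, peptide, rescore kcal/mol, docking energy kcal/mol or None).
#: Both scores are carried where both were printed.
RESCORE_TABLE: tuple[tuple[str, str, float, float | None], ...] = (
    ("SET2", "KAALE", -11.34, -9.35),
    ("SET2", "DAALT", -10.37, -7.90),
    ("SET1", "YAALE", -10.34, None),
    ("SET1", "YAALQ", -9.99, -6.05),
    ("SET2", "TAALL", -9.87, None),
)

#: Per-method published candidate lists (the three-column selection table).
SELECTION_LISTS: dict[str, tuple[str, ...]] = {
    "frequency": ("FAALA", "RAALF", "RAALG", "RAALQ", "GAALY"),
    "energy": ("RAALM", "RAALQ", "RAALW", "GAALY", "PAALA"),
    "rescoring": ("KAALE", "DAALT", "YAALE", "YAALQ", "TAALL"),
}

#: Receptor-conformation occurrence counts among the 1000 lowest-energy
#: decoys (the three favourite conformations).
FREQUENCY_COUNTS: dict[str, int] = {"SET2_06": 528, "SET3_07": 110, "SET3_09": 92}

#: Published interface mean-correlation scores per bound peptide.
INTERFACE_SCORES: dict[str, float] = {
    "DAALT": 0.31,
    "YAALQ": 0.27,
    "RAALG": 0.44,
    "FAALA": 0.39,
    "KAALE": 0.33,
    "RAALW": 0.38,
}

#: Interface mean correlation of the peptide-free complex.
BASELINE_INTERFACE_SCORE: float = 0.38

#: CDK2 allosteric-pocket anchor residues (flexible during docking).
POCKET_KEY_RESIDUES: tuple[int, ...] = (150, 178, 180)

#: CDK2 activation (T-)loop residue range.
TLOOP_RANGE: tuple[int, int] = (150, 165)

#: Docking grid center in the receptor frame (config metadata only).
DOCKING_GRID_CENTER: tuple[float, float, float] = (-12.299, 28.510, 35.091)

#: Receptor conformational ensemble: three sets of ten CDK2 models.
RECEPTOR_SETS: tuple[str, ...] = tuple(
    f"SET{s}_{i:02d}" for s in (1, 2, 3) for i in range(1, 11)
)

#: Docked poses kept per receptor/peptide pair (energy clusters).
CLUSTERS_PER_PAIR: int = 10


def energy_fixture_table() -> pd.DataFrame:
    """The published energy worked example as a decoy table.

    Cluster ranks are 1 throughout (only each model's best energy was
    printed); receptor ids are the printed set labels.
    """
    return pd.DataFrame(
        [
            {"receptor_id": rec, "peptide": pep, "cluster_rank": 1,
             "energy_kcal_mol": e}
            for rec, pep, e in ENERGY_TABLE
        ]
    )
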