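"""Labeled multi-frame coordinate trajectories: container, selection, windowing, I/O.

Conventions: coordinates in Å, times in ps.  A *node* is one residue,
identified by (chain id, residue index); each node owns one or more atoms.
The default node representative is the CA atom when present, otherwise the
centroid of the node's atoms.  Heavy-atom members are retained so contact
occupancies can use the all-atom minimum distance while correlations use
one representative point per residue.

Formats: multi-frame PDB (MODEL/ENDMDL blocks, via Biopython) and a plain
XYZ dialect (standard two-line frame headers) paired with a metadata
sidecar TSV carrying chain/residue labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser, PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

__all__ = [
    "ATOM_COLUMNS",
    "Trajectory",
    "NodeSelection",
    "TrajectoryFormatError",
    "read_trajectory",
    "write_trajectory",
    "subset",
    "window",
]

#: Per-atom metadata schema.
ATOM_COLUMNS = ["chain", "resid", "resname", "name"]


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file violates its format contract."""


@dataclass
class Trajectory:
    """frames x atoms x 3 coordinates with per-atom chain/residue labels.

    Attributes
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3), Å
    atoms : DataFrame with columns ``chain, resid, resname, name``
    frame_interval_ps : spacing between successive frames, ps
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_interval_ps: float = 100.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError(
                f"{len(self.atoms)} atom records for {self.coords.shape[1]} coordinate columns"
            )
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns {missing}")
        self.atoms = self.atoms.reset_index(drop=True)

    # -- basic shape ------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps

    # -- node (residue) level ---------------------------------------------
    @property
    def nodes(self) -> pd.DataFrame:
        """One row per (chain, resid), in first-appearance order."""
        nd = self.atoms.drop_duplicates(["chain", "resid"])[["chain", "resid", "resname"]]
        return nd.reset_index(drop=True)

    @property
    def node_of_atom(self) -> np.ndarray:
        """Integer node index of every atom."""
        keys = list(zip(self.atoms["chain"], self.atoms["resid"]))
        order: dict[tuple, int] = {}
        for k in keys:
            if k not in order:
                order[k] = len(order)
        return np.array([order[k] for k in keys], dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def representative_coords(self, mode: str = "CA") -> np.ndarray:
        """(n_frames, n_nodes, 3) one point per residue.

        ``mode="CA"`` uses the CA atom when a node has one (centroid
        otherwise); ``mode="centroid"`` always averages the node's atoms.
        """
        if mode not in ("CA", "centroid"):
            raise ValueError(f"unknown representative mode {mode!r}")
        node_idx = self.node_of_atom
        out = np.zeros((self.n_frames, self.n_nodes, 3))
        counts = np.zeros(self.n_nodes)
        np.add.at(out, (slice(None), node_idx), self.coords)
        np.add.at(counts, node_idx, 1.0)
        out /= counts[None, :, None]
        if mode == "CA":
            is_ca = (self.atoms["name"] == "CA").to_numpy()
            for a in np.nonzero(is_ca)[0]:
                out[:, node_idx[a], :] = self.coords[:, a, :]
        return out


@dataclass(frozen=True)
class NodeSelection:
    """Predicate over node metadata (chain ids and/or a residue-index range)."""

    chains: Optional[frozenset] = None
    resid_range: Optional[tuple[int, int]] = None  # inclusive bounds
    predicate: Optional[Callable[[str, int], bool]] = None
    invert: bool = False

    @classmethod
    def chain(cls, *chains: str) -> "NodeSelection":
        return cls(chains=frozenset(chains))

    @classmethod
    def residues(cls, lo: int, hi: int, chain: Optional[str] = None) -> "NodeSelection":
        chains = frozenset([chain]) if chain else None
        return cls(chains=chains, resid_range=(lo, hi))

    def matches(self, chain: str, resid: int) -> bool:
        ok = True
        if self.chains is not None:
            ok = ok and chain in self.chains
        if self.resid_range is not None:
            ok = ok and self.resid_range[0] <= resid <= self.resid_range[1]
        if self.predicate is not None:
            ok = ok and self.predicate(chain, resid)
        return ok != self.invert

    def complement(self) -> "NodeSelection":
        return replace(self, invert=not self.invert)


def subset(traj: Trajectory, selection: NodeSelection) -> Trajectory:
    """Restrict a trajectory to the nodes matched by ``selection``."""
    mask = np.array(
        [selection.matches(c, int(r)) for c, r in zip(traj.atoms["chain"], traj.atoms["resid"])]
    )
    if not mask.any():
        raise ValueError("node selection matched no atoms")
    return Trajectory(
        coords=traj.coords[:, mask, :],
        atoms=traj.atoms.loc[mask].reset_index(drop=True),
        frame_interval_ps=traj.frame_interval_ps,
    )


def window(traj: Trajectory, discard_initial_ps: float, stride_ps: Optional[float] = None) -> Trajectory:
    """Drop the equilibration prefix and resample at ``stride_ps``.

    Frames sit at t = k * frame_interval; frames with t >= discard are
    kept, every stride.  E.g. 300 frames at 100 ps with 10 ns discarded at
    100 ps stride leaves the final 200 frames (20 ns).  The stride must be
    a positive integer multiple of the frame interval.
    """
    dt = traj.frame_interval_ps
    stride_ps = dt if stride_ps is None else stride_ps
    total = traj.n_frames * dt
    if discard_initial_ps >= total:
        raise ValueError(f"discard {discard_initial_ps} ps >= trajectory duration {total} ps")
    step = stride_ps / dt
    if step < 1 or abs(step - round(step)) > 1e-9:
        raise ValueError(f"stride {stride_ps} ps is not a multiple of frame interval {dt} ps")
    start = int(np.ceil(discard_initial_ps / dt - 1e-9))
    idx = np.arange(start, traj.n_frames, int(round(step)))
    return Trajectory(
        coords=traj.coords[idx],
        atoms=traj.atoms.copy(),
        frame_interval_ps=stride_ps,
    )


# ---------------------------------------------------------------------------
# multi-frame PDB
# ---------------------------------------------------------------------------

def _write_pdb(traj: Trajectory, path: Path) -> None:
    builder = StructureBuilder()
    builder.init_structure("traj")
    for f in range(traj.n_frames):
        builder.init_model(f, f)
        current_chain = None
        current_res = None
        serial = 1
        for a, row in enumerate(traj.atoms.itertuples(index=False)):
            if row.chain != current_chain:
                builder.init_chain(str(row.chain))
                builder.init_seg("    ")
                current_chain = row.chain
                current_res = None
            if (row.chain, row.resid) != current_res:
                builder.init_residue(str(row.resname), " ", int(row.resid), " ")
                current_res = (row.chain, row.resid)
            builder.init_atom(
                str(row.name),
                traj.coords[f, a].astype(np.float32),
                0.0,
                1.0,
                " ",
                str(row.name).ljust(3),
                serial,
                element=str(row.name)[:1],
            )
            serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def _scan_model_blocks(path: Path) -> None:
    """Reject multi-model files with ATOM records outside MODEL/ENDMDL blocks."""
    n_models = 0
    in_model = False
    stray_after_frame = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                n_models += 1
                in_model = True
            elif rec == "ENDMDL":
                in_model = False
            elif rec in ("ATOM", "HETATM") and not in_model and stray_after_frame is None:
                stray_after_frame = n_models
    if n_models and stray_after_frame:
        raise TrajectoryFormatError(
            f"frame {stray_after_frame}: ATOM records outside a MODEL/ENDMDL block "
            f"(missing MODEL record?)"
        )


def _read_pdb(path: Path, frame_interval_ps: float) -> Trajectory:
    _scan_model_blocks(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("traj", str(path))
    models = list(structure)
    if not models:
        raise TrajectoryFormatError(f"no MODEL blocks found in {path}")
    frames, keys = [], []
    for f, model in enumerate(models):
        records, xyz = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    records.append((chain.id, res.id[1], res.resname.strip(), atom.get_name()))
                    xyz.append(atom.coord)
        if f == 0:
            keys = records
            atoms = pd.DataFrame(records, columns=ATOM_COLUMNS)
        elif records != keys:
            raise TrajectoryFormatError(
                f"frame {f} has inconsistent atoms ({len(records)} vs {len(keys)} in frame 0)"
            )
        frames.append(np.asarray(xyz, dtype=float))
    return Trajectory(np.stack(frames), atoms, frame_interval_ps)


# ---------------------------------------------------------------------------
# XYZ dialect (+ metadata sidecar TSV)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".nodes.tsv")


def _write_xyz(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {f} t_ps {f * traj.frame_interval_ps:.6g}\n")
            for a, name in enumerate(traj.atoms["name"]):
                x, y, z = traj.coords[f, a]
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
    meta = traj.atoms.copy()
    meta.insert(0, "atom_index", np.arange(traj.n_atoms))
    meta.to_csv(_sidecar_path(path), sep="\t", index=False)


def _read_xyz(path: Path, frame_interval_ps: float) -> Trajectory:
    frames = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i, n_atoms = 0, None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"frame {len(frames)}: expected atom count line, got {lines[i]!r}"
            ) from exc
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise TrajectoryFormatError(
                f"frame {len(frames)} declares {count} atoms, expected {n_atoms}"
            )
        block = lines[i + 2 : i + 2 + count]
        if len(block) < count:
            raise TrajectoryFormatError(f"frame {len(frames)} truncated")
        xyz = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(xyz)
        i += 2 + count
    if not frames:
        raise TrajectoryFormatError(f"no frames found in {path}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = pd.read_csv(sidecar, sep="\t")
        atoms = meta[ATOM_COLUMNS]
    else:
        names = [ln.split()[0] for ln in lines if ln.strip()][2 : 2 + n_atoms]
        atoms = pd.DataFrame(
            {"chain": "A", "resid": np.arange(1, n_atoms + 1), "resname": "UNK", "name": names[:n_atoms]}
        )
    return Trajectory(np.stack(frames), atoms, frame_interval_ps)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    raise ValueError(f"cannot infer trajectory format from {path.name!r}; pass format=")


def read_trajectory(path, format: Optional[str] = None, frame_interval_ps: float = 100.0) -> Trajectory:
    """Read a multi-frame PDB or XYZ trajectory (format inferred from suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        return _read_pdb(path, frame_interval_ps)
    if fmt == "xyz":
        return _read_xyz(path, frame_interval_ps)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path, format: Optional[str] = None) -> None:
    """Write ``traj`` as multi-frame PDB or XYZ (+ metadata sidecar TSV)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _write_pdb(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
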