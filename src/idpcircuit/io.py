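"""Conformer / ensemble / pose-set containers and PDB + CSV round-tripping.

Frames are MODEL/ENDMDL blocks of a multi-model PDB file; a single-model file
is a one-frame ensemble.  The writer emits fixed-width PDB records such that
read -> write -> read is a fixed point (the second write is byte-identical).
Binary trajectory formats are out of scope: the interchange formats are
multi-model PDB and per-frame coordinate CSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ConformerFrame",
    "Ensemble",
    "PoseSet",
    "PDBParseError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "read_pose_set",
    "frame_to_csv",
    "ensemble_from_csv",
]


class PDBParseError(ValueError):
    """Malformed PDB content; carries the offending line number."""


class TopologyError(ValueError):
    """Frames of one ensemble disagree in atom count or ordering."""


class PoseError(ValueError):
    """A pose file violates the two-chain contract."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, element, chain, 1-based residue index/name, Å coords."""

    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue index must be >= 1")
        if not np.isfinite([self.x, self.y, self.z]).all():
            raise ValueError("non-finite coordinates")


@dataclass
class ConformerFrame:
    """Atoms with coordinates, grouped by (chain, residue); optional time in ns."""

    atoms: list[AtomRecord]
    time_ns: float | None = None

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        seen: dict[tuple[str, int], bool] = {}
        for a in self.atoms:
            prev = last.get(a.chain_id)
            if prev is not None and a.residue_index < prev:
                raise ValueError(
                    f"residue indices decrease within chain {a.chain_id!r}"
                )
            last[a.chain_id] = a.residue_index
            seen[(a.chain_id, a.residue_index)] = True
        self._coords = np.array(
            [[a.x, a.y, a.z] for a in self.atoms], dtype=float
        ).reshape(len(self.atoms), 3)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array in Å."""
        return self._coords

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue_index) keys."""
        out: list[tuple[str, int]] = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            key = (a.chain_id, a.residue_index)
            if not out or out[-1] != key:
                if key in out:
                    continue
                out.append(key)
        return out

    def residue_atom_indices(
        self, chain_id: str | None = None
    ) -> dict[tuple[str, int], np.ndarray]:
        """Map (chain, residue_index) -> atom row indices into ``coords``."""
        groups: dict[tuple[str, int], list[int]] = {}
        for k, a in enumerate(self.atoms):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            groups.setdefault((a.chain_id, a.residue_index), []).append(k)
        return {key: np.asarray(v, dtype=int) for key, v in groups.items()}

    def with_coords(self, coords: np.ndarray, time_ns: float | None = None) -> "ConformerFrame":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate shape mismatch")
        atoms = [
            AtomRecord(
                a.name, a.element, a.residue_index, a.residue_name, a.chain_id,
                float(c[0]), float(c[1]), float(c[2]),
            )
            for a, c in zip(self.atoms, coords)
        ]
        return ConformerFrame(atoms, time_ns if time_ns is not None else self.time_ns)

    def select(self, atom_names: set[str] | None = None, chain_id: str | None = None) -> np.ndarray:
        """Row indices of atoms matching the name/chain filters."""
        idx = [
            k
            for k, a in enumerate(self.atoms)
            if (atom_names is None or a.name in atom_names)
            and (chain_id is None or a.chain_id == chain_id)
        ]
        return np.asarray(idx, dtype=int)

    @property
    def is_coarse_grained(self) -> bool:
        """True when only Cα beads are present (CG input)."""
        return all(a.name == "CA" for a in self.atoms)


def _same_topology(a: ConformerFrame, b: ConformerFrame) -> bool:
    if a.n_atoms != b.n_atoms:
        return False
    return all(
        (x.name, x.residue_index, x.residue_name, x.chain_id)
        == (y.name, y.residue_index, y.residue_name, y.chain_id)
        for x, y in zip(a.atoms, b.atoms)
    )


@dataclass
class Ensemble:
    """Ordered conformer frames sharing one topology.

    ``sampling_interval_ns`` mirrors trajectory analyses that subsample at a
    fixed stride (e.g. one frame every 25 ns); ``replicate_id`` tags
    independent simulation repeats.
    """

    frames: list[ConformerFrame]
    replicate_id: str = "rep1"
    sampling_interval_ns: float | None = None
    coarse_grained: bool = False

    def __post_init__(self) -> None:
        if self.frames:
            ref = self.frames[0]
            for k, fr in enumerate(self.frames[1:], start=2):
                if not _same_topology(ref, fr):
                    raise TopologyError(
                        f"frame {k} differs in atom count/ordering from frame 1"
                    )
            times = [f.time_ns for f in self.frames if f.time_ns is not None]
            if len(times) == len(self.frames) and len(times) > 1:
                if not all(b > a for a, b in zip(times, times[1:])):
                    raise ValueError("time stamps must be strictly increasing")
            if not self.coarse_grained:
                self.coarse_grained = ref.is_coarse_grained

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k: int) -> ConformerFrame:
        return self.frames[k]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([f.coords for f in self.frames])


@dataclass
class PoseSet:
    """Two-chain docking poses, indexed in lexicographic filename order."""

    poses: list[ConformerFrame]
    names: list[str] = field(default_factory=list)
    receptor_chain: str = "A"
    ligand_chain: str = "B"
    skipped: int = 0

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


# ---------------------------------------------------------------------------
# PDB fixed-width records

_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _pad_atom_name(name: str, element: str) -> str:
    # Columns 13-16: element right-justified in 13-14 for 1-letter elements.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if stripped[:2].upper() in ("FE", "ZN", "MG", "NA", "CL", "BR", "SE"):
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def read_pdb(path: str | Path) -> Ensemble:
    """Parse a (multi-model) PDB file into an :class:`Ensemble`.

    MODEL/ENDMDL blocks define frames.  Alternate locations resolve to the
    highest occupancy; insertion codes are rejected; an inconsistent atom
    count across models raises :class:`TopologyError`.
    """
    frames: list[ConformerFrame] = []
    current: list[AtomRecord] = []
    # altloc bookkeeping: (chain, resseq, name) -> (occupancy, position in current)
    best_alt: dict[tuple[str, int, str], tuple[float, int]] = {}
    in_model = False
    saw_model = False

    def flush() -> None:
        nonlocal current, best_alt
        if current:
            frames.append(ConformerFrame(list(current)))
        current = []
        best_alt = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                in_model = True
                continue
            if rec == "ENDMDL":
                in_model = False
                flush()
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            try:
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain = line[21]
                resseq = int(line[22:26])
                icode = line[26]
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ_str = line[54:60].strip()
                occ = float(occ_str) if occ_str else 1.0
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}")
            if icode.strip():
                raise PDBParseError(f"insertion code at line {lineno} not supported")
            element = line[76:78].strip() or _guess_element(name)
            atom = AtomRecord(name, element, resseq, resname, chain, x, y, z)
            key = (chain, resseq, name)
            if altloc.strip():
                if key in best_alt:
                    prev_occ, pos = best_alt[key]
                    if occ > prev_occ:
                        current[pos] = atom
                        best_alt[key] = (occ, pos)
                    continue
                best_alt[key] = (occ, len(current))
            current.append(atom)
    if current:
        if saw_model and in_model:
            flush()  # trailing MODEL without ENDMDL
        elif not saw_model:
            flush()
        else:
            raise PDBParseError("ATOM records outside MODEL blocks in multi-model file")
    if not frames:
        raise PDBParseError(f"no ATOM records found in {path}")
    try:
        return Ensemble(frames)
    except TopologyError as exc:
        raise TopologyError(f"{path}: {exc}")


def write_pdb(ensemble: Ensemble | ConformerFrame, path: str | Path) -> None:
    """Write frames as MODEL/ENDMDL blocks with fixed-width ATOM records."""
    if isinstance(ensemble, ConformerFrame):
        ensemble = Ensemble([ensemble])
    multi = ensemble.n_frames > 1
    with open(path, "w") as fh:
        for k, frame in enumerate(ensemble.frames, start=1):
            if multi:
                fh.write(f"MODEL     {k:>4d}\n")
            prev_chain = None
            serial = 0
            for a in frame.atoms:
                if len(a.chain_id) != 1:
                    raise ValueError(
                        f"chain id {a.chain_id!r} must be a single character"
                    )
                if prev_chain is not None and a.chain_id != prev_chain:
                    fh.write("TER\n")
                prev_chain = a.chain_id
                serial += 1
                fh.write(
                    _ATOM_FMT.format(
                        serial=serial,
                        name=_pad_atom_name(a.name, a.element),
                        altloc=" ",
                        resname=a.residue_name,
                        chain=a.chain_id,
                        resseq=a.residue_index,
                        icode=" ",
                        x=a.x, y=a.y, z=a.z,
                        occ=1.0, b=0.0,
                        element=a.element,
                    )
                )
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pose_set(
    directory: str | Path,
    receptor_chain: str = "A",
    ligand_chain: str = "B",
) -> PoseSet:
    """Load every ``*.pdb`` in *directory* as one two-chain pose.

    Files with a chain count other than two are skipped with a warning and
    counted in ``PoseSet.skipped``.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.pdb"))
    poses: list[ConformerFrame] = []
    names: list[str] = []
    skipped = 0
    for f in files:
        ens = read_pdb(f)
        frame = ens.frames[0]
        if len(frame.chain_ids) != 2:
            warnings.warn(
                f"pose {f.name} has {len(frame.chain_ids)} chains (expected 2); skipped"
            )
            skipped += 1
            continue
        poses.append(frame)
        names.append(f.name)
    if not files:
        warnings.warn(f"no PDB files found in {directory}")
    return PoseSet(
        poses=poses,
        names=names,
        receptor_chain=receptor_chain,
        ligand_chain=ligand_chain,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# CSV frame tables

_CSV_COLUMNS = [
    "frame", "chain", "residue_index", "residue_name", "atom_name", "x", "y", "z",
]


def frame_to_csv(ensemble: Ensemble, path: str | Path) -> None:
    rows = []
    for k, frame in enumerate(ensemble.frames):
        for a in frame.atoms:
            rows.append((k, a.chain_id, a.residue_index, a.residue_name, a.name,
                         a.x, a.y, a.z))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def ensemble_from_csv(path: str | Path) -> Ensemble:
    df = pd.read_csv(path)
    frames = []
    for _, sub in df.groupby("frame", sort=True):
        atoms = [
            AtomRecord(
                str(r.atom_name), _guess_element(str(r.atom_name)),
                int(r.residue_index), str(r.residue_name), str(r.chain),
                float(r.x), float(r.y), float(r.z),
            )
            for r in sub.itertuples()
        ]
        frames.append(ConformerFrame(atoms))
    return Ensemble(frames)
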