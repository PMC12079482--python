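"""Synthetic conformer, ensemble and dimer-pose generators with known ground
truth.

Every generator plants a property (helical segments, a residue-contact set,
per-residue fluctuation amplitudes, an interaction-typed interface) and then
re-checks it with the package's own analysis code before returning, so the
fixtures downstream tests rely on are verified, not assumed.  Fixtures are
geometric, not thermodynamic: they emulate the observable a given analysis
consumes (distances, dihedrals, interface geometry), nothing more.

All generators are deterministic functions of their spec plus a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._geometry import build_backbone
from .contacts import ContactCriteria, residue_contacts
from .io import AtomRecord, ConformerFrame, Ensemble
from .interface import InteractionWindows, interface_residues, type_interactions

__all__ = [
    "GenerationError",
    "make_ideal_helix",
    "make_extended_chain",
    "make_torsion_chain",
    "make_contact_scaffold",
    "make_fluctuation_ensemble",
    "make_two_basin_ensemble",
    "InteractionSpec",
    "DimerSpec",
    "make_dimer_pose",
    "ContactSchedule",
]

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-120.0, 120.0)
COIL_PHI_PSI = (-75.0, 145.0)  # polyproline-II-like, outside the helical basin

BACKBONE_NAMES = ("N", "CA", "C", "O")


class GenerationError(RuntimeError):
    """A generator failed to realize its planted property within max retries."""


def _backbone_frame(
    coords: np.ndarray, chain_id: str = "A", resname: str = "ALA"
) -> ConformerFrame:
    atoms = []
    for r in range(coords.shape[0]):
        for a, name in enumerate(BACKBONE_NAMES):
            x, y, z = coords[r, a]
            atoms.append(AtomRecord(name, name[0], r + 1, resname, chain_id,
                                    float(x), float(y), float(z)))
    return ConformerFrame(atoms)


def make_ideal_helix(n_residues: int, chain_id: str = "A") -> ConformerFrame:
    """Poly-alanine backbone at canonical α-helix torsions (φ=−57°, ψ=−47°)."""
    if n_residues < 4:
        raise ValueError("an α-helix needs at least 4 residues")
    coords = build_backbone([HELIX_PHI_PSI] * n_residues)
    return _backbone_frame(coords, chain_id)


def make_extended_chain(n_residues: int, chain_id: str = "A") -> ConformerFrame:
    """Backbone at extended β-strand torsions (φ=−120°, ψ=+120°)."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    coords = build_backbone([EXTENDED_PHI_PSI] * n_residues)
    return _backbone_frame(coords, chain_id)


def make_torsion_chain(
    segments: list[tuple[int, str]], chain_id: str = "A"
) -> tuple[ConformerFrame, np.ndarray]:
    """Backbone from labelled segments, e.g. ``[(8, "helix"), (10, "coil"), (8, "helix")]``.

    Returns the frame plus the planted per-residue helix labels (True inside
    helix segments).  Segment torsion sets: ``helix``, ``coil``, ``extended``.
    """
    table = {"helix": HELIX_PHI_PSI, "coil": COIL_PHI_PSI, "extended": EXTENDED_PHI_PSI}
    phi_psi: list[tuple[float, float]] = []
    labels: list[bool] = []
    for length, kind in segments:
        if kind not in table:
            raise ValueError(f"unknown segment kind {kind!r}")
        phi_psi += [table[kind]] * length
        labels += [kind == "helix"] * length
    coords = build_backbone(phi_psi)
    return _backbone_frame(coords, chain_id), np.asarray(labels, dtype=bool)


# ---------------------------------------------------------------------------
# Planted-contact scaffolds

N_DECORATION = 5          # pseudo side-chain atoms per residue
DECORATION_RADIUS = 1.0   # Å from the residue center
CONTACT_TARGET = 3.0      # planted pair center distance, Å
FAR_TARGET = 9.0          # minimum non-planted center distance, Å
MAX_RETRIES = 20


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


#: second-shell pairs (two residues sharing a planted partner) cannot be
#: pushed to FAR_TARGET — both sit at contact distance from the shared hub —
#: so they get a weaker repulsion to just outside the contact window.
SECOND_SHELL_TARGET = 6.2


def _relax_centers(
    centers: np.ndarray,
    planted: np.ndarray,
    rng: np.random.Generator,
    n_iter: int = 400,
) -> np.ndarray:
    """Spring relaxation: planted pairs to CONTACT_TARGET, others pushed apart."""
    n = len(centers)
    planted_mask = np.zeros((n, n), dtype=bool)
    if len(planted):
        planted_mask[planted[:, 0], planted[:, 1]] = True
        planted_mask[planted[:, 1], planted[:, 0]] = True
    adjacency = planted_mask.astype(int)
    second_shell = (adjacency @ adjacency > 0) & ~planted_mask
    np.fill_diagonal(second_shell, False)
    repulsion_target = np.where(second_shell, SECOND_SHELL_TARGET, FAR_TARGET + 1.0)
    pos = centers.copy()
    for _ in range(n_iter):
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dist, np.inf)
        force = np.zeros_like(pos)
        # attractive springs on planted pairs
        err = dist - CONTACT_TARGET
        w = np.where(planted_mask, err, 0.0) / dist
        force -= 0.4 * (w[:, :, None] * diff).sum(axis=1)
        # repulsion for non-planted pairs that are too close
        close = (~planted_mask) & (dist < repulsion_target)
        w2 = np.where(close, repulsion_target - dist, 0.0) / dist
        force += 0.3 * (w2[:, :, None] * diff).sum(axis=1)
        pos += force
    return pos


def make_contact_scaffold(
    n_residues: int,
    contacts: list[tuple[int, int]],
    seed: int = 0,
    criteria: ContactCriteria | None = None,
    chain_id: str = "A",
) -> ConformerFrame:
    """A decorated bead chain whose contact set equals exactly the planted set.

    Each residue is a center bead (``CA``) plus five pseudo side-chain atoms
    on a 1 Å sphere, so the ≥5-atom-pair contact criterion is exercised
    realistically.  Residue centers are spring-relaxed (planted pairs close,
    everything else far), the result is verified against
    :func:`~idpcircuit.contacts.residue_contacts`, and generation retries
    with a fresh seed on failure (bounded).
    """
    criteria = criteria or ContactCriteria()
    k = criteria.neighbor_exclusion
    planted = []
    for i, j in contacts:
        i, j = int(min(i, j)), int(max(i, j))
        if not (1 <= i < j <= n_residues):
            raise ValueError(f"contact ({i},{j}) outside chain 1..{n_residues}")
        if j - i <= k:
            raise ValueError(
                f"contact ({i},{j}) violates the neighbor-exclusion window |i-j| > {k}"
            )
        planted.append((i, j))
    planted_set = set(planted)
    planted_arr = (np.asarray(sorted(planted_set), dtype=int) - 1
                   if planted_set else np.empty((0, 2), dtype=int))

    for attempt in range(MAX_RETRIES):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt, n_residues]))
        # initial layout: well-separated jittered grid
        side = math.ceil(n_residues ** (1.0 / 3.0))
        grid = np.array([
            [a, b, c] for a in range(side) for b in range(side) for c in range(side)
        ][:n_residues], dtype=float) * (FAR_TARGET + 4.0)
        grid = grid[rng.permutation(n_residues)]
        grid += rng.normal(scale=1.0, size=grid.shape)
        # pull planted partners together before relaxation
        for i, j in planted_arr:
            grid[j] = grid[i] + CONTACT_TARGET * _random_unit_vectors(rng, 1)[0]
        centers = _relax_centers(grid, planted_arr, rng)
        frame = _decorate_scaffold(centers, rng, chain_id)
        try:
            found = residue_contacts(frame, criteria, chain_id).pairs
        except ValueError:
            continue
        if set(found) == planted_set:
            return frame
    raise GenerationError(
        f"could not realize planted contact set after {MAX_RETRIES} attempts"
    )


def _decorate_scaffold(
    centers: np.ndarray, rng: np.random.Generator, chain_id: str
) -> ConformerFrame:
    atoms = []
    offsets = DECORATION_RADIUS * _random_unit_vectors(rng, len(centers) * N_DECORATION)
    for r, c in enumerate(centers):
        atoms.append(AtomRecord("CA", "C", r + 1, "GLY", chain_id,
                                float(c[0]), float(c[1]), float(c[2])))
        for d in range(N_DECORATION):
            o = c + offsets[r * N_DECORATION + d]
            atoms.append(AtomRecord(f"CQ{d + 1}", "C", r + 1, "GLY", chain_id,
                                    float(o[0]), float(o[1]), float(o[2])))
    return ConformerFrame(atoms)


# ---------------------------------------------------------------------------
# Fluctuation ensembles with contact schedules


@dataclass(frozen=True)
class ContactSchedule:
    """Plant a contact (i, j) in a prescribed subset of frames.

    In "on" frames residue j is moved next to residue i; in "off" frames it
    stays at its base position (which must be far from i).  The moved
    residues of different entries must be distinct.
    """

    pair: tuple[int, int]
    on_frames: frozenset[int]

    @classmethod
    def fraction(cls, pair: tuple[int, int], n_frames: int, on_fraction: float):
        """Switch the pair on in the first ``round(on_fraction * n_frames)`` frames."""
        n_on = round(on_fraction * n_frames)
        return cls(pair=tuple(pair), on_frames=frozenset(range(n_on)))


def make_fluctuation_ensemble(
    base: ConformerFrame,
    sigma: float | np.ndarray,
    n_frames: int,
    schedule: list[ContactSchedule] | None = None,
    seed: int = 0,
    replicate_id: str = "rep1",
    sampling_interval_ns: float | None = None,
    criteria: ContactCriteria | None = None,
    chain_id: str | None = None,
) -> Ensemble:
    """Frames = base + per-residue isotropic Gaussian displacements.

    ``sigma`` is a scalar or per-residue array of displacement scales in Å;
    each residue moves rigidly (all its atoms share the frame's displacement),
    so the planted Cα fluctuation about the mean is exactly σ_r per axis
    (RMSF σ_r·√3).  Scheduled contacts are imposed after the noise by placing
    the moved residue at the contact distance from its partner; the schedule
    is verified on every frame.
    """
    cid = chain_id or base.chain_ids[0]
    res_atoms = base.residue_atom_indices(cid)
    keys = sorted(res_atoms, key=lambda kk: kk[1])
    n_res = len(keys)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (n_res,))
    rng = np.random.default_rng(seed)
    schedule = schedule or []
    moved = [s.pair[1] for s in schedule]
    if len(set(moved)) != len(moved):
        raise ValueError("each schedule entry must move a distinct residue")
    criteria = criteria or ContactCriteria()
    frames = []
    base_coords = base.coords
    for f in range(n_frames):
        disp = rng.normal(size=(n_res, 3)) * sig[:, None]
        coords = base_coords.copy()
        for r, key in enumerate(keys):
            coords[res_atoms[key]] += disp[r]
        for s in schedule:
            i, j = s.pair
            ci = coords[res_atoms[(cid, i)]].mean(axis=0)
            cj = coords[res_atoms[(cid, j)]].mean(axis=0)
            if f in s.on_frames:
                u = cj - ci
                norm = np.linalg.norm(u)
                u = u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
                shift = (ci + CONTACT_TARGET * u) - cj
                coords[res_atoms[(cid, j)]] += shift
        t = None if sampling_interval_ns is None else f * sampling_interval_ns
        frames.append(base.with_coords(coords, time_ns=t))
    ens = Ensemble(frames, replicate_id=replicate_id,
                   sampling_interval_ns=sampling_interval_ns)
    _verify_schedule(ens, schedule, criteria, cid)
    return ens


def _verify_schedule(ensemble, schedule, criteria, chain_id) -> None:
    for s in schedule:
        i, j = int(min(s.pair)), int(max(s.pair))
        for f, frame in enumerate(ensemble.frames):
            cm = residue_contacts(frame, criteria, chain_id, frame_index=f)
            have = (i, j) in cm.pairs
            want = f in s.on_frames
            if have != want:
                raise GenerationError(
                    f"schedule violation: pair ({i},{j}) "
                    f"{'present' if have else 'absent'} in frame {f}"
                )


def make_two_basin_ensemble(
    n_residues: int = 30,
    n_frames_per_basin: int = 10,
    separation_nm: float = 3.0,
    jitter_nm: float = 0.02,
    seed: int = 0,
) -> tuple[Ensemble, np.ndarray]:
    """Two rigid conformers far apart in RMSD, each with small jitter.

    Returns the ensemble (basin A frames first) and the planted basin labels.
    The inter-basin Cα RMSD is ≈ ``separation_nm`` (every residue of the
    second conformer is displaced by that amount), and the intra-basin spread
    is ``jitter_nm`` ≪ any sensible clustering cutoff.
    """
    rng = np.random.default_rng(seed)
    base = make_contact_scaffold(n_residues, [], seed=seed)
    coords_a = base.coords
    shift = separation_nm * 10.0
    # displace along per-residue random directions so basin B is a genuinely
    # different conformation, not a rigid translation (which superposition
    # would remove)
    res_atoms = base.residue_atom_indices()
    keys = sorted(res_atoms, key=lambda kk: kk[1])
    coords_b = coords_a.copy()
    for key in keys:
        u = _random_unit_vectors(rng, 1)[0]
        coords_b[res_atoms[key]] += shift * u
    frames = []
    labels = []
    for basin, coords in ((0, coords_a), (1, coords_b)):
        for _ in range(n_frames_per_basin):
            jit = rng.normal(scale=jitter_nm * 10.0, size=coords.shape)
            frames.append(base.with_coords(coords + jit))
            labels.append(basin)
    return Ensemble(frames), np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# Designed dimer poses

#: Per-type template geometry: (residue names, key-atom separation in Å).
_INTERACTION_RESIDUES = {
    "hydrogen_bond": ("THR", "THR"),
    "salt_bridge": ("LYS", "GLU"),
    "pi_cation": ("PHE", "LYS"),
    "pi_stacking": ("PHE", "PHE"),
}

_SITE_SPACING = 14.0   # Å between designed interaction sites
_CHAIN_GAP = 36.0      # Å between the non-interface chain lines
_DESIGN_PLANE_Z = 12.0  # designed sites live on a separate z-plane


@dataclass(frozen=True)
class InteractionSpec:
    """One designed cross-chain interaction between two named residues."""

    kind: str
    receptor_residue: int
    ligand_residue: int

    def __post_init__(self) -> None:
        if self.kind not in _INTERACTION_RESIDUES:
            raise ValueError(f"unknown interaction kind {self.kind!r}")


@dataclass
class DimerSpec:
    """Design of a two-chain pose: chain sizes plus planted interactions."""

    n_receptor: int
    n_ligand: int
    interactions: list[InteractionSpec] = field(default_factory=list)
    receptor_chain: str = "A"
    ligand_chain: str = "B"

    def __post_init__(self) -> None:
        rec = [s.receptor_residue for s in self.interactions]
        lig = [s.ligand_residue for s in self.interactions]
        if len(set(rec)) != len(rec) or len(set(lig)) != len(lig):
            raise ValueError("designed residues must be distinct per chain")
        for s in self.interactions:
            if not (1 <= s.receptor_residue <= self.n_receptor):
                raise ValueError(f"receptor residue {s.receptor_residue} out of range")
            if not (1 <= s.ligand_residue <= self.n_ligand):
                raise ValueError(f"ligand residue {s.ligand_residue} out of range")


def _ring_atoms(center: np.ndarray, normal_axis: int, radius: float = 1.39):
    """Six ring-carbon positions in the plane perpendicular to an axis."""
    pts = []
    for a in range(6):
        ang = math.pi * a / 3.0
        vec = np.zeros(3)
        axes = [k for k in range(3) if k != normal_axis]
        vec[axes[0]] = radius * math.cos(ang)
        vec[axes[1]] = radius * math.sin(ang)
        pts.append(center + vec)
    return pts


def _backbone_cluster(anchor: np.ndarray, direction: float):
    """N/CA/C/O positions stacked away from the interface along +/- y."""
    return {
        "N": anchor + np.array([-0.6, 2.2 * direction, 0.3]),
        "CA": anchor + np.array([0.0, 1.5 * direction, 0.0]),
        "C": anchor + np.array([0.8, 2.3 * direction, -0.3]),
        "O": anchor + np.array([0.9, 3.4 * direction, -0.3]),
    }


def _designed_site_atoms(kind: str, x0: float):
    """Atom name -> position for both sides of one designed interaction.

    Receptor-side atoms sit at y ≥ -1.5, ligand-side below; the key-atom
    geometry satisfies exactly the intended interaction window.
    """
    z = _DESIGN_PLANE_Z
    a_anchor = np.array([x0, 0.0, z])
    rec: dict[str, np.ndarray] = {}
    lig: dict[str, np.ndarray] = {}
    if kind == "hydrogen_bond":
        # THR OG1...OG1 at 3.0 Å; CB/CG2 boosters raise the atom-pair count
        rec["OG1"] = np.array([x0, -1.0, z])
        rec["CB"] = np.array([x0, -0.1, z + 0.9])
        rec["CG2"] = np.array([x0 + 1.0, -0.6, z - 0.6])
        lig["OG1"] = np.array([x0, -4.0, z])
        lig["CB"] = np.array([x0, -4.9, z + 0.9])
        lig["CG2"] = np.array([x0 + 1.0, -4.4, z - 0.6])
    elif kind == "salt_bridge":
        # LYS NZ ... GLU OE1 at 3.8 Å (> 3.5, so no hydrogen-bond co-record)
        rec["NZ"] = np.array([x0, -1.0, z])
        rec["CE"] = np.array([x0, -0.1, z + 0.8])
        rec["CD"] = np.array([x0 + 1.0, -0.8, z - 0.6])
        rec["CG"] = np.array([x0 + 0.2, -0.5, z + 0.6])
        lig["OE1"] = np.array([x0, -4.8, z])
        lig["OE2"] = np.array([x0 + 1.1, -4.7, z + 0.5])
        lig["CD"] = np.array([x0 + 0.4, -4.2, z - 0.7])
    elif kind == "pi_cation":
        # PHE ring with normal along y; LYS NZ on the normal at 4.0 Å
        ring_c = np.array([x0, -1.0, z])
        for name, pos in zip(AROMA_NAMES, _ring_atoms(ring_c, normal_axis=1)):
            rec[name] = pos
        lig["NZ"] = np.array([x0, -5.0, z])
        lig["CE"] = np.array([x0, -5.9, z + 0.8])
    elif kind == "pi_stacking":
        # parallel PHE rings, centroids 4.0 Å apart along the shared normal
        ring_a = np.array([x0, -1.0, z])
        ring_b = np.array([x0, -5.0, z])
        for name, pos in zip(AROMA_NAMES, _ring_atoms(ring_a, normal_axis=1)):
            rec[name] = pos
        for name, pos in zip(AROMA_NAMES, _ring_atoms(ring_b, normal_axis=1)):
            lig[name] = pos
    else:  # pragma: no cover - guarded by InteractionSpec
        raise ValueError(kind)
    rec.update(_backbone_cluster(a_anchor, direction=+1.0))
    lig.update(_backbone_cluster(np.array([x0, -6.0, z]), direction=-1.0))
    return rec, lig


AROMA_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


def make_dimer_pose(spec: DimerSpec, seed: int = 0) -> ConformerFrame:
    """Two chains whose interface realizes exactly the designed interactions.

    Non-designed residues lie on parallel lines more than 8 Å from every
    partner-chain atom; designed residue pairs sit on a separate plane, one
    site per interaction, meeting exactly their interaction's geometric
    window.  The result is verified with the interface engine (designed
    residues = interface residues; designed types present per pair) before
    returning.
    """
    rng = np.random.default_rng(seed)
    jitter = rng.normal(scale=0.01, size=3)  # seed-determined global offset
    designed_rec = {s.receptor_residue: s for s in spec.interactions}
    designed_lig = {s.ligand_residue: s for s in spec.interactions}
    site_x = {id(s): _SITE_SPACING * m for m, s in enumerate(spec.interactions)}

    atoms: list[AtomRecord] = []

    def add(chain: str, resindex: int, resname: str, atom_map: dict[str, np.ndarray]):
        for name, pos in atom_map.items():
            pos = pos + jitter
            atoms.append(AtomRecord(name, name[0], resindex, resname, chain,
                                    float(pos[0]), float(pos[1]), float(pos[2])))

    site_cache: dict[int, tuple[dict, dict]] = {}
    for s in spec.interactions:
        site_cache[id(s)] = _designed_site_atoms(s.kind, site_x[id(s)])

    for r in range(1, spec.n_receptor + 1):
        if r in designed_rec:
            s = designed_rec[r]
            rec_map, _ = site_cache[id(s)]
            add(spec.receptor_chain, r, _INTERACTION_RESIDUES[s.kind][0], rec_map)
        else:
            anchor = np.array([6.0 * r, _CHAIN_GAP / 2.0, 0.0])
            add(spec.receptor_chain, r, "GLY", _backbone_cluster(anchor, +1.0))
    for r in range(1, spec.n_ligand + 1):
        if r in designed_lig:
            s = designed_lig[r]
            _, lig_map = site_cache[id(s)]
            add(spec.ligand_chain, r, _INTERACTION_RESIDUES[s.kind][1], lig_map)
        else:
            anchor = np.array([6.0 * r, -_CHAIN_GAP / 2.0, 0.0])
            add(spec.ligand_chain, r, "GLY", _backbone_cluster(anchor, -1.0))
    pose = ConformerFrame(atoms)
    _verify_dimer(pose, spec)
    return pose


def _verify_dimer(pose: ConformerFrame, spec: DimerSpec) -> None:
    rec, lig = interface_residues(
        pose, receptor_chain=spec.receptor_chain, ligand_chain=spec.ligand_chain
    )
    want_rec = {s.receptor_residue for s in spec.interactions}
    want_lig = {s.ligand_residue for s in spec.interactions}
    if rec != want_rec or lig != want_lig:
        raise GenerationError(
            f"designed interface mismatch: got {sorted(rec)}/{sorted(lig)}, "
            f"wanted {sorted(want_rec)}/{sorted(want_lig)}"
        )
    records = type_interactions(
        pose, InteractionWindows(),
        receptor_chain=spec.receptor_chain, ligand_chain=spec.ligand_chain,
    )
    by_pair: dict[tuple[int, int], set[str]] = {}
    for rr in records:
        by_pair.setdefault((rr.residue_a, rr.residue_b), set()).add(rr.interaction_type)
    for s in spec.interactions:
        found = by_pair.get((s.receptor_residue, s.ligand_residue), set())
        if found != {s.kind}:
            raise GenerationError(
                f"designed pair ({s.receptor_residue},{s.ligand_residue}) "
                f"typed as {sorted(found)}, wanted {{{s.kind!r}}}"
            )
    extra = set(by_pair) - {(s.receptor_residue, s.ligand_residue) for s in spec.interactions}
    if extra:
        raise GenerationError(f"unplanned typed interactions at pairs {sorted(extra)}")
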