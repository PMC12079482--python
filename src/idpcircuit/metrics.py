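"""Superposition, RMSF, helicity and GROMOS-style conformational clustering.

Distances are handled internally in Å (the PDB unit); RMSD/RMSF results are
reported in nm to match the conventions of trajectory analysis (e.g. the
0.9 nm clustering cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from ._geometry import backbone_dihedrals
from .io import ConformerFrame, Ensemble

__all__ = [
    "RMSFProfile",
    "HelicityProfile",
    "ClusterSolution",
    "kabsch_superpose",
    "rmsf_profile",
    "assign_secondary_structure",
    "helicity_profile",
    "gromos_cluster",
    "select_representatives",
    "HELIX_PHI_WINDOW",
    "HELIX_PSI_WINDOW",
]

A_PER_NM = 10.0

#: Backbone-dihedral windows for the α-helical basin (degrees).
HELIX_PHI_WINDOW = (-100.0, -30.0)
HELIX_PSI_WINDOW = (-80.0, -5.0)
#: Minimum run of consecutive in-window residues to call a helix.
HELIX_MIN_RUN = 4

#: Cα-only (P-SEA-style) helix criteria: d(i, i+3) and d(i, i+4) windows in Å.
CA_D13_WINDOW = (4.8, 5.6)
CA_D14_WINDOW = (5.9, 6.9)
CA_MIN_RUN = 5


class DegenerateGeometryError(ValueError):
    pass


def _kabsch_transform(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation + translation of mobile onto reference."""
    if len(mobile) < 3:
        raise DegenerateGeometryError("need at least 3 atoms to superpose")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    mc = mobile - mu_m
    rc = reference - mu_r
    if np.linalg.matrix_rank(mc, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear selection")
    rot, _ = Rotation.align_vectors(rc, mc)
    return rot, mu_m, mu_r


def kabsch_superpose(
    mobile: ConformerFrame | np.ndarray,
    reference: ConformerFrame | np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[ConformerFrame | np.ndarray, float]:
    """Least-squares rigid superposition (proper rotations only).

    Returns the transformed mobile frame (or coordinate array) and the RMSD
    in nm over the selection.
    """
    mob_is_frame = isinstance(mobile, ConformerFrame)
    mob = mobile.coords if mob_is_frame else np.asarray(mobile, dtype=float)
    ref = reference.coords if isinstance(reference, ConformerFrame) else np.asarray(reference, dtype=float)
    sel = np.arange(len(mob)) if selection is None else np.asarray(selection, dtype=int)
    m_sel, r_sel = mob[sel], ref[sel]
    if m_sel.shape != r_sel.shape:
        raise ValueError("selections must have equal atom counts")
    rot, mu_m, mu_r = _kabsch_transform(m_sel, r_sel)
    moved = rot.apply(mob - mu_m) + mu_r
    rmsd_A = float(np.sqrt(((moved[sel] - r_sel) ** 2).sum(axis=1).mean()))
    rmsd = rmsd_A / A_PER_NM
    if mob_is_frame:
        return mobile.with_coords(moved), rmsd
    return moved, rmsd


def _pairwise_rmsd_A(coords: np.ndarray) -> float:
    return float(np.sqrt((coords ** 2).sum(axis=1).mean()))


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation about the ensemble mean (nm)."""

    residues: np.ndarray
    values_nm: np.ndarray
    atom_selection: str = "CA"
    reference: str = "iterative mean structure"


def rmsf_profile(
    ensemble: Ensemble,
    atom_names: set[str] | None = None,
    chain_id: str | None = None,
    superpose: bool = True,
    max_iter: int = 5,
    tol_nm: float = 1e-6,
) -> RMSFProfile:
    """RMSF per residue after superposition onto the iteratively refined mean.

    Each frame is Kabsch-superposed onto the running mean structure; the mean
    is recomputed until it moves by less than ``tol_nm``.  Default selection
    is Cα.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    names = atom_names or {"CA"}
    frame0 = ensemble.frames[0]
    cid = chain_id or frame0.chain_ids[0]
    sel = frame0.select(atom_names=names, chain_id=cid)
    if len(sel) == 0:
        raise ValueError(f"no atoms matching {names} in chain {cid}")
    residues = np.array([frame0.atoms[k].residue_index for k in sel])
    X = np.stack([f.coords[sel] for f in ensemble.frames])  # (F, n, 3)
    if superpose:
        mean = X[0].copy()
        for _ in range(max_iter):
            aligned = np.empty_like(X)
            for f in range(X.shape[0]):
                aligned[f], _ = kabsch_superpose(X[f], mean)
            new_mean = aligned.mean(axis=0)
            shift = np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()) / A_PER_NM
            X = aligned
            mean = new_mean
            if shift < tol_nm:
                break
    mean = X.mean(axis=0)
    rmsf_A = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))
    return RMSFProfile(
        residues=residues,
        values_nm=rmsf_A / A_PER_NM,
        atom_selection="+".join(sorted(names)),
        reference="iterative mean structure" if superpose else "arithmetic mean (no fit)",
    )


# ---------------------------------------------------------------------------
# Secondary structure


def _runs_to_labels(ok: np.ndarray, min_run: int) -> np.ndarray:
    """H labels for maximal runs of consecutive True of length >= min_run."""
    labels = np.zeros(len(ok), dtype=bool)
    start = None
    for k, flag in enumerate(list(ok) + [False]):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            if k - start >= min_run:
                labels[start:k] = True
            start = None
    return labels


def assign_secondary_structure(
    frame: ConformerFrame, chain_id: str | None = None
) -> np.ndarray:
    """Per-residue helix labels: True = H, False = other.

    All-atom path: a residue qualifies when every defined backbone dihedral
    (φ, ψ) lies in the α-helical window; maximal runs of ≥4 qualifying
    residues are labelled H (chain-terminal residues join a run via their one
    defined dihedral).  Cα-only path: P-SEA-style d(i,i+3)/d(i,i+4) distance
    windows over runs of ≥5.
    """
    cid = chain_id or frame.chain_ids[0]
    res_atoms = frame.residue_atom_indices(cid)
    keys = sorted(res_atoms, key=lambda k: k[1])
    n_res = len(keys)
    names_per_res = [
        {frame.atoms[k].name for k in res_atoms[key]} for key in keys
    ]
    has_backbone = all({"N", "CA", "C"} <= s for s in names_per_res)
    if not has_backbone:
        if not all("CA" in s for s in names_per_res):
            raise ValueError("neither full backbone nor Cα trace available")
        if any({"N", "C"} & s for s in names_per_res):
            import warnings

            warnings.warn("incomplete backbone; falling back to Cα-only helix criteria")
        return _ca_helix_labels(frame, cid, keys, res_atoms)
    def atom_xyz(key, name):
        for k in res_atoms[key]:
            if frame.atoms[k].name == name:
                return frame.coords[k]
        raise KeyError(name)
    n_xyz = np.stack([atom_xyz(k, "N") for k in keys])
    ca_xyz = np.stack([atom_xyz(k, "CA") for k in keys])
    c_xyz = np.stack([atom_xyz(k, "C") for k in keys])
    phi, psi = backbone_dihedrals(n_xyz, ca_xyz, c_xyz)
    ok = np.ones(n_res, dtype=bool)
    defined = np.zeros(n_res, dtype=bool)
    for r in range(n_res):
        if not np.isnan(phi[r]):
            defined[r] = True
            ok[r] &= HELIX_PHI_WINDOW[0] <= phi[r] <= HELIX_PHI_WINDOW[1]
        if not np.isnan(psi[r]):
            defined[r] = True
            ok[r] &= HELIX_PSI_WINDOW[0] <= psi[r] <= HELIX_PSI_WINDOW[1]
    ok &= defined
    return _runs_to_labels(ok, HELIX_MIN_RUN)


def _ca_helix_labels(frame, cid, keys, res_atoms) -> np.ndarray:
    ca = []
    for key in keys:
        for k in res_atoms[key]:
            if frame.atoms[k].name == "CA":
                ca.append(frame.coords[k])
                break
    ca = np.stack(ca)
    n_res = len(ca)
    ok = np.zeros(n_res, dtype=bool)
    for r in range(n_res):
        checks = []
        if r + 3 < n_res:
            d13 = np.linalg.norm(ca[r + 3] - ca[r])
            checks.append(CA_D13_WINDOW[0] <= d13 <= CA_D13_WINDOW[1])
        if r + 4 < n_res:
            d14 = np.linalg.norm(ca[r + 4] - ca[r])
            checks.append(CA_D14_WINDOW[0] <= d14 <= CA_D14_WINDOW[1])
        ok[r] = bool(checks) and all(checks)
    labels = _runs_to_labels(ok, CA_MIN_RUN)
    # extend each run to cover the i+3/i+4 partners of its last window anchors
    out = labels.copy()
    run_start = None
    for k in range(n_res + 1):
        flag = labels[k] if k < n_res else False
        if flag and run_start is None:
            run_start = k
        elif not flag and run_start is not None:
            out[run_start : min(k + 4, n_res)] = True
            run_start = None
    return out


@dataclass
class HelicityProfile:
    """Per-residue helix probability plus overall helical content (%)."""

    residues: np.ndarray
    probability: np.ndarray
    content_percent: float
    content_std: float
    per_replicate_percent: list[float] = field(default_factory=list)
    stable_threshold: float = 0.30

    @property
    def stable_residues(self) -> np.ndarray:
        """Residues with helix probability above the stable-formation threshold."""
        return self.residues[self.probability > self.stable_threshold]


def helicity_profile(
    ensembles: Ensemble | list[Ensemble],
    chain_id: str | None = None,
    stable_threshold: float = 0.30,
) -> HelicityProfile:
    """Helix probability per residue and overall helical content.

    Content is the mean over residues and frames of the helix indicator,
    in percent, computed per replicate; the headline value is the mean with
    population STD over replicates.  Residues with probability above
    ``stable_threshold`` (default 0.30) are the stably helical set.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    per_rep = []
    total = None
    n_frames = 0
    residues = None
    for ens in ensembles:
        rep_sum = 0.0
        rep_n = 0
        for frame in ens:
            labels = assign_secondary_structure(frame, chain_id)
            if residues is None:
                cid = chain_id or frame.chain_ids[0]
                residues = np.array([r for _, r in frame.residues(cid)])
                total = np.zeros(len(labels))
            total += labels
            n_frames += 1
            rep_sum += labels.mean()
            rep_n += 1
        per_rep.append(100.0 * rep_sum / rep_n)
    prob = total / n_frames
    return HelicityProfile(
        residues=residues,
        probability=prob,
        content_percent=float(np.mean(per_rep)),
        content_std=float(np.std(per_rep)),  # population STD over replicates
        per_replicate_percent=[float(x) for x in per_rep],
        stable_threshold=stable_threshold,
    )


# ---------------------------------------------------------------------------
# GROMOS clustering


@dataclass
class ClusterSolution:
    """Disjoint, exhaustive frame clusters in decreasing size order."""

    memberships: list[list[int]]
    centers: list[int]
    cutoff_nm: float
    n_frames: int

    @property
    def sizes(self) -> list[int]:
        return [len(m) for m in self.memberships]


def pairwise_rmsd_matrix(
    ensemble: Ensemble,
    atom_names: set[str] | None = None,
    chain_id: str | None = None,
) -> np.ndarray:
    """Symmetric (F, F) matrix of pairwise Cα RMSD in nm (Kabsch per pair)."""
    names = atom_names or {"CA"}
    frame0 = ensemble.frames[0]
    cid = chain_id or frame0.chain_ids[0]
    sel = frame0.select(atom_names=names, chain_id=cid)
    X = np.stack([f.coords[sel] for f in ensemble.frames])
    F = len(X)
    D = np.zeros((F, F))
    centered = X - X.mean(axis=1, keepdims=True)
    for a in range(F):
        for b in range(a + 1, F):
            _, rmsd = kabsch_superpose(centered[a], centered[b])
            D[a, b] = D[b, a] = rmsd
    return D


def gromos_cluster(
    ensemble: Ensemble,
    cutoff_nm: float = 0.9,
    atom_names: set[str] | None = None,
    chain_id: str | None = None,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterSolution:
    """Iterative neighbor-count (GROMOS) clustering under an RMSD cutoff.

    The frame with the most neighbors within ``cutoff_nm`` becomes a cluster
    center; it and its neighbors are removed, and the procedure repeats until
    no frames remain.  Ties in neighbor count break toward the lowest frame
    index, making the result deterministic.  Clusters are returned in
    decreasing size order.
    """
    D = pairwise_rmsd_matrix(ensemble, atom_names, chain_id) if rmsd_matrix is None else rmsd_matrix
    F = D.shape[0]
    alive = np.ones(F, dtype=bool)
    clusters: list[tuple[int, list[int]]] = []
    within = D <= cutoff_nm
    while alive.any():
        counts = (within & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(within[center] & alive)[0].tolist()
        clusters.append((center, members))
        alive[members] = False
    clusters.sort(key=lambda cm: (-len(cm[1]), cm[0]))
    return ClusterSolution(
        memberships=[m for _, m in clusters],
        centers=[c for c, _ in clusters],
        cutoff_nm=cutoff_nm,
        n_frames=F,
    )


def select_representatives(solution: ClusterSolution, coverage: float = 0.5) -> list[int]:
    """Centers of the smallest size-ordered cluster prefix covering ≥ coverage.

    This is the representative-selection rule used before docking: keep the
    largest clusters until they jointly account for at least the requested
    fraction (default 50%) of all frames.
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")
    needed = coverage * solution.n_frames
    out: list[int] = []
    cum = 0
    for center, members in zip(solution.centers, solution.memberships):
        out.append(center)
        cum += len(members)
        if cum >= needed - 1e-12:
            break
    return out
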