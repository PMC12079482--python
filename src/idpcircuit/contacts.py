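"""Residue–residue contact detection and contact-time statistics.

A residue pair (i, j) is in contact when at least ``min_atom_pairs`` atom
pairs (one atom from each residue) lie within ``cutoff`` Å, and the pair is
farther apart in sequence than the neighbor-exclusion window (|i−j| > k,
default k = 3).  These are the criteria commonly used for residue-based
circuit-topology analysis of disordered chains: a 4.5 Å cutoff with ≥5
atom–atom contacts and the three nearest sequence neighbors excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import ConformerFrame, Ensemble

__all__ = [
    "ContactCriteria",
    "ContactMap",
    "residue_contacts",
    "contact_frequency",
    "group_contact_fraction",
]


class CriteriaIncompatibilityError(ValueError):
    """Criteria cannot be evaluated on this input (e.g. CG beads vs min pairs)."""


@dataclass(frozen=True)
class ContactCriteria:
    """Distance / atom-pair-count / neighbor-exclusion contact criteria.

    ``strict_per_side`` switches to the stricter reading that at least
    ``min_atom_pairs`` *distinct atoms on each side* must participate,
    instead of counting atom pairs.
    """

    cutoff: float = 4.5  # Å
    min_atom_pairs: int = 5
    neighbor_exclusion: int = 3  # exclude |i-j| <= k
    strict_per_side: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_atom_pairs < 1:
            raise ValueError("min_atom_pairs must be >= 1")
        if self.neighbor_exclusion < 0:
            raise ValueError("neighbor_exclusion must be >= 0")


@dataclass
class ContactMap:
    """Unordered residue pairs (i < j) in contact for one frame."""

    pairs: frozenset[tuple[int, int]]
    frame_index: int = 0
    criteria: ContactCriteria = field(default_factory=ContactCriteria)
    pair_counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def as_array(self) -> np.ndarray:
        """(m, 2) sorted array of contact pairs."""
        if not self.pairs:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.pairs), dtype=int)


def _chain_residue_arrays(frame: ConformerFrame, chain_id: str | None):
    """Coordinates plus per-atom residue index and per-atom atom-id arrays."""
    sel = frame.select(chain_id=chain_id)
    coords = frame.coords[sel]
    res_idx = np.array([frame.atoms[k].residue_index for k in sel], dtype=int)
    return coords, res_idx, sel


def _count_contact_pairs(
    coords_a: np.ndarray,
    res_a: np.ndarray,
    coords_b: np.ndarray,
    res_b: np.ndarray,
    criteria: ContactCriteria,
    cross: bool,
):
    """Count qualifying atom pairs per residue pair via a KD-tree sweep.

    Returns {(ri, rj): n_atom_pairs} (plus per-side distinct-atom counts when
    the strict reading is enabled).
    """
    if len(coords_a) == 0 or len(coords_b) == 0:
        return {}
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    pairs = tree_a.query_ball_tree(tree_b, criteria.cutoff)
    counts: dict[tuple[int, int], int] = {}
    side_atoms: dict[tuple[int, int], tuple[set, set]] = {}
    for ka, neighbors in enumerate(pairs):
        ri = res_a[ka]
        for kb in neighbors:
            rj = res_b[kb]
            if cross:
                key = (int(ri), int(rj))
            else:
                if ri == rj:
                    continue
                key = (int(min(ri, rj)), int(max(ri, rj)))
            counts[key] = counts.get(key, 0) + 1
            if criteria.strict_per_side:
                sa, sb = side_atoms.setdefault(key, (set(), set()))
                if cross or ri < rj:
                    sa.add(ka), sb.add(kb)
                else:
                    sa.add(kb), sb.add(ka)
    if not cross:
        # intra-chain query_ball_tree on the same point set counts each atom
        # pair twice (a->b and b->a)
        counts = {k: v // 2 for k, v in counts.items()}
    if criteria.strict_per_side:
        return counts, side_atoms
    return counts


def residue_contacts(
    frame: ConformerFrame,
    criteria: ContactCriteria | None = None,
    chain_id: str | None = None,
    frame_index: int = 0,
) -> ContactMap:
    """Contacts within one chain of one frame under the stated criteria."""
    criteria = criteria or ContactCriteria()
    if chain_id is None:
        chains = frame.chain_ids
        if len(chains) != 1:
            raise ValueError("multi-chain frame: pass chain_id explicitly")
        chain_id = chains[0]
    residues = frame.residues(chain_id)
    if len(residues) < 2:
        raise ValueError("frame must contain at least 2 residues")
    per_res = frame.residue_atom_indices(chain_id)
    if criteria.min_atom_pairs > 1 and all(len(v) == 1 for v in per_res.values()):
        raise CriteriaIncompatibilityError(
            "single-bead (CG) input cannot satisfy min_atom_pairs "
            f"{criteria.min_atom_pairs}; lower min_atom_pairs for CG analysis"
        )
    coords, res_idx, _ = _chain_residue_arrays(frame, chain_id)
    result = _count_contact_pairs(coords, res_idx, coords, res_idx, criteria, cross=False)
    if criteria.strict_per_side:
        counts, side_atoms = result
    else:
        counts = result
    pairs = set()
    kept_counts = {}
    for (i, j), n in counts.items():
        if j - i <= criteria.neighbor_exclusion:
            continue
        if criteria.strict_per_side:
            sa, sb = side_atoms[(i, j)]
            if len(sa) < criteria.min_atom_pairs or len(sb) < criteria.min_atom_pairs:
                continue
        elif n < criteria.min_atom_pairs:
            continue
        pairs.add((i, j))
        kept_counts[(i, j)] = n
    return ContactMap(
        pairs=frozenset(pairs),
        frame_index=frame_index,
        criteria=criteria,
        pair_counts=kept_counts,
    )


def contact_frequency(
    ensemble: Ensemble,
    criteria: ContactCriteria | None = None,
    chain_id: str | None = None,
) -> dict[tuple[int, int], float]:
    """Per-pair fraction of frames in contact, over the whole ensemble."""
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    counts: dict[tuple[int, int], int] = {}
    for k, frame in enumerate(ensemble):
        cm = residue_contacts(frame, criteria, chain_id, frame_index=k)
        for p in cm.pairs:
            counts[p] = counts.get(p, 0) + 1
    n = ensemble.n_frames
    return {p: c / n for p, c in sorted(counts.items())}


def group_contact_fraction(
    ensembles: Ensemble | list[Ensemble],
    group_a: set[int],
    group_b: set[int],
    criteria: ContactCriteria | None = None,
    chain_id: str | None = None,
) -> tuple[float, float, list[float]]:
    """Fraction of frames with ≥1 contact between two residue groups.

    Computed per replicate ensemble; returns (mean, population STD over
    replicates, per-replicate fractions).  This is the contact-time statistic
    used to quantify inter-region (e.g. NR–CR) association, with the
    dispersion taken over independent simulation repeats.
    """
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    fractions: list[float] = []
    for ens in ensembles:
        if ens.n_frames == 0:
            raise ValueError("empty ensemble")
        hits = 0
        for k, frame in enumerate(ens):
            cm = residue_contacts(frame, criteria, chain_id, frame_index=k)
            if any(
                (i in group_a and j in group_b) or (i in group_b and j in group_a)
                for i, j in cm.pairs
            ):
                hits += 1
        fractions.append(hits / ens.n_frames)
    mean = float(np.mean(fractions))
    std = float(np.std(fractions))  # population STD, n = number of replicates
    return mean, std, fractions
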