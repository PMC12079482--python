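"""Circuit topology of intra-chain contact pairs.

Circuit topology (CT) classifies every pair of contacts on a chain by the
arrangement of their sequence intervals:

* **series (S)** — the intervals are disjoint,
* **parallel (P)** — one interval is nested inside the other (the enclosed
  member is in the *inverse parallel* relation to the enclosing one),
* **cross (X)** — the intervals interleave.

For a contact set of size m the three counts partition all C(m, 2)
unordered pairs.  Whole-frame censuses, the per-residue inverse-parallel
profile (how sequestered each residue is inside enclosing contacts), and the
(n_S, n_P + n_X) configuration-space density together give a geometry-free
fingerprint of a deforming chain — well suited to intrinsically disordered
proteins, where conventional structural descriptors wash out.

Tie rules for contacts sharing a residue are deterministic and preserve the
partition: nesting with one shared boundary counts as P; intervals that touch
end-to-start (j1 = i2) count as S.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .contacts import ContactCriteria, ContactMap, residue_contacts
from .io import Ensemble

__all__ = [
    "Relation",
    "RelationCensus",
    "LocalCTProfile",
    "classify_relation",
    "topology_census",
    "inverse_parallel_counts",
    "local_inverse_parallel_profile",
    "topology_density",
    "sample_frames",
]


class Relation(str, Enum):
    S = "S"
    P = "P"       # relation(c1, c2) = P: c2 nested inside c1
    Pinv = "Pinv"  # c1 nested inside c2
    X = "X"


def classify_relation(c1: tuple[int, int], c2: tuple[int, int]) -> Relation:
    """Classify the directed relation of contact pair intervals c1, c2.

    Each contact is (i, j) with i < j.  ``P`` means c2's interval is nested
    inside c1's; ``Pinv`` the reverse.  S and X are symmetric.
    """
    i1, j1 = c1
    i2, j2 = c2
    if not (i1 < j1 and i2 < j2):
        raise ValueError("contacts must satisfy i < j")
    if c1 == c2:
        raise ValueError("identical contacts have no pairwise relation")
    if j1 <= i2 or j2 <= i1:
        return Relation.S
    if i1 <= i2 and j2 <= j1:
        return Relation.P
    if i2 <= i1 and j1 <= j2:
        return Relation.Pinv
    return Relation.X


@dataclass(frozen=True)
class RelationCensus:
    """Counts of S / P / X over all unordered contact pairs of one frame.

    P is counted once per unordered pair (the P/Pinv direction collapses).
    ``n_PX = n_P + n_X`` is the combined-entanglement coordinate used for
    configuration-space densities.
    """

    n_S: int
    n_P: int
    n_X: int
    n_contacts: int = 0

    @property
    def n_PX(self) -> int:
        return self.n_P + self.n_X

    @property
    def total(self) -> int:
        return self.n_S + self.n_P + self.n_X


def _census_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[int, int, int]:
    """Vectorised pairwise classification over contact interval arrays."""
    m = len(starts)
    if m < 2:
        return 0, 0, 0
    iu, ju = np.triu_indices(m, k=1)
    i1, j1 = starts[iu], ends[iu]
    i2, j2 = starts[ju], ends[ju]
    s = (j1 <= i2) | (j2 <= i1)
    p = ~s & (((i1 <= i2) & (j2 <= j1)) | ((i2 <= i1) & (j1 <= j2)))
    n_s = int(s.sum())
    n_p = int(p.sum())
    n_x = len(iu) - n_s - n_p
    return n_s, n_p, n_x


def topology_census(contact_map: ContactMap | np.ndarray) -> RelationCensus:
    """Whole-frame S/P/X census of a contact set.

    Satisfies the completeness invariant n_S + n_P + n_X = C(m, 2).
    """
    arr = contact_map.as_array() if isinstance(contact_map, ContactMap) else np.asarray(contact_map, dtype=int)
    if arr.size == 0:
        return RelationCensus(0, 0, 0, 0)
    n_s, n_p, n_x = _census_arrays(arr[:, 0], arr[:, 1])
    return RelationCensus(n_s, n_p, n_x, n_contacts=len(arr))


def inverse_parallel_counts(contacts: np.ndarray) -> np.ndarray:
    """For each contact, the number of other contacts strictly enclosing it.

    "Enclosing" follows the closed-interval P rule (shared boundaries count).
    Returns an (m,) integer array aligned with the input rows.
    """
    contacts = np.asarray(contacts, dtype=int)
    m = len(contacts)
    if m == 0:
        return np.zeros(0, dtype=int)
    s, e = contacts[:, 0], contacts[:, 1]
    # enclosing[a, b] = contact b encloses contact a
    enclosed = (s[None, :] <= s[:, None]) & (e[:, None] <= e[None, :])
    np.fill_diagonal(enclosed, False)
    # guard duplicates-by-interval: identical intervals would count both ways;
    # contact maps are sets so this cannot arise, but keep the rule explicit.
    return enclosed.sum(axis=1).astype(int)


@dataclass
class LocalCTProfile:
    """Per-residue mean ± SEM of inverse-parallel counts over sampled frames."""

    residues: np.ndarray       # residue indices (1-based)
    mean: np.ndarray
    sem: np.ndarray
    n_frames: int
    sampling_interval_ns: float | None = None


def sample_frames(ensemble: Ensemble, sample_interval_ns: float | None) -> list[int]:
    """Frame indices at the requested time stride.

    With no time stamps (or no stride requested) every frame is used.
    """
    if sample_interval_ns is None:
        return list(range(ensemble.n_frames))
    times = [f.time_ns for f in ensemble.frames]
    if any(t is None for t in times):
        if ensemble.sampling_interval_ns:
            stride = max(1, round(sample_interval_ns / ensemble.sampling_interval_ns))
            return list(range(0, ensemble.n_frames, stride))
        return list(range(ensemble.n_frames))
    if len(times) > 1:
        spacing = min(b - a for a, b in zip(times, times[1:]))
        if sample_interval_ns < spacing - 1e-9:
            raise ValueError(
                f"sample interval {sample_interval_ns} ns finer than frame spacing {spacing} ns"
            )
    picked, next_t = [], times[0]
    for k, t in enumerate(times):
        if t >= next_t - 1e-9:
            picked.append(k)
            next_t = t + sample_interval_ns
    return picked


def _frame_residue_ip(frame, criteria, chain_id, n_residues) -> np.ndarray:
    cm = residue_contacts(frame, criteria, chain_id)
    arr = cm.as_array()
    out = np.zeros(n_residues + 1)  # 1-based
    if len(arr) == 0:
        return out
    ip = inverse_parallel_counts(arr)
    # a contact contributes its enclosing count to both endpoint residues
    np.add.at(out, arr[:, 0], ip)
    np.add.at(out, arr[:, 1], ip)
    return out


def local_inverse_parallel_profile(
    ensembles: Ensemble | list[Ensemble],
    criteria: ContactCriteria | None = None,
    sample_interval_ns: float | None = None,
    chain_id: str | None = None,
    aggregation: str = "sum",
) -> LocalCTProfile:
    """Per-residue inverse-parallel profile, mean ± SEM over sampled frames.

    For each sampled frame and residue r, sum (default) over the contacts
    incident to r of the number of contacts enclosing them; residues with no
    contacts contribute 0 for that frame.  Frames are pooled across
    replicates before the SEM.  ``aggregation="mean"`` divides by the number
    of incident contacts instead.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    criteria = criteria or ContactCriteria()
    frame0 = ensembles[0].frames[0]
    cid = chain_id or frame0.chain_ids[0]
    n_res = max(r for _, r in frame0.residues(cid))
    per_frame: list[np.ndarray] = []
    for ens in ensembles:
        for k in sample_frames(ens, sample_interval_ns):
            frame = ens.frames[k]
            if aggregation == "sum":
                vals = _frame_residue_ip(frame, criteria, cid, n_res)
            elif aggregation == "mean":
                cm = residue_contacts(frame, criteria, cid)
                arr = cm.as_array()
                vals = np.zeros(n_res + 1)
                if len(arr):
                    ip = inverse_parallel_counts(arr)
                    cnt = np.zeros(n_res + 1)
                    np.add.at(vals, arr[:, 0], ip)
                    np.add.at(vals, arr[:, 1], ip)
                    np.add.at(cnt, arr[:, 0], 1)
                    np.add.at(cnt, arr[:, 1], 1)
                    vals = np.divide(vals, cnt, out=np.zeros_like(vals), where=cnt > 0)
            else:
                raise ValueError(f"unknown aggregation {aggregation!r}")
            per_frame.append(vals[1:])
    stack = np.stack(per_frame)
    n = len(per_frame)
    mean = stack.mean(axis=0)
    # population-STD SEM: keeps the frame-duplication invariant (SEM / sqrt(2)) exact
    sem = stack.std(axis=0) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return LocalCTProfile(
        residues=np.arange(1, n_res + 1),
        mean=mean,
        sem=sem,
        n_frames=n,
        sampling_interval_ns=sample_interval_ns,
    )


def topology_density(
    ensembles: Ensemble | list[Ensemble],
    criteria: ContactCriteria | None = None,
    sample_interval_ns: float | None = None,
    chain_id: str | None = None,
    bins: int | tuple = 20,
):
    """Normalised 2D histogram of (n_S, n_P + n_X) over sampled frames.

    One census point per sampled frame, aggregated over all replicate
    ensembles; the histogram sums to 1.  Returns (hist, s_edges, px_edges,
    points) where ``points`` is the (n_frames, 2) array of raw censuses.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    criteria = criteria or ContactCriteria()
    points = []
    for ens in ensembles:
        for k in sample_frames(ens, sample_interval_ns):
            cm = residue_contacts(ens.frames[k], criteria, chain_id, frame_index=k)
            census = topology_census(cm)
            points.append((census.n_S, census.n_PX))
    pts = np.asarray(points, dtype=float)
    hist, s_edges, px_edges = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return hist, s_edges, px_edges, pts
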