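"""Sequence constructs, region/motif maps and numbering lifts.

The androgen receptor N-terminal domain (AR-NTD, residues 1-538) carries a
polyglutamine (pQ) tract whose pathological expansion (here 23 Q -> 45 Q)
shifts the numbering of everything C-terminal of the tract.  This module
represents such constructs, named region/motif intervals (NR, CR, ANTS,
FQNLF, Tau-5, P-box, ...) and the monotone index lift between numbering
frames, e.g. the ANTS motif at UniProt residues 233-246 maps to pQe-chain
residues 255-268 for a 45 Q tract.

All intervals are 1-based and inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

__all__ = [
    "Interval",
    "SequenceConstruct",
    "Region",
    "RegionMap",
    "NumberingLift",
    "build_construct",
    "lift_index",
    "classify_region",
    "wt_synthetic_construct",
    "default_region_map",
    "load_region_map_toml",
    "write_fasta",
]

#: UniProt P10275-style polyQ annotation for the wild-type (23 Q) chain.
#: The tract's own coordinates are config-supplied throughout; this is the
#: documented default.
DEFAULT_PQ_SPAN = (58, 80)

NR_SPAN = (1, 224)
CR_SPAN = (225, 538)

# Config-only motif defaults (wt/UniProt frame unless noted).
DEFAULT_MOTIFS = {
    "FQNLF": (23, 27),
    "ANTS": (233, 246),
    "Tau-5": (361, 490),
    "P-box": (577, 581),  # partner-chain (DBD) frame
}


@dataclass(frozen=True)
class Interval:
    """Closed 1-based residue interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    def __contains__(self, index: int) -> bool:
        return self.start <= index <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset)


@dataclass(frozen=True)
class SequenceConstruct:
    """A one-letter residue sequence with an annotated pQ tract.

    Parameters
    ----------
    residues:
        One-letter amino-acid string, indexed from 1.
    pq_span:
        Inclusive interval of the polyglutamine tract; every residue inside
        must be ``Q``.
    variant_label:
        ``"wt"``, ``"pQe"`` or ``"custom"``.
    """

    residues: str
    pq_span: Interval
    variant_label: str = "custom"

    def __post_init__(self) -> None:
        if self.pq_span.end > len(self.residues):
            raise ValueError("pq_span extends beyond chain length")
        tract = self.residues[self.pq_span.start - 1 : self.pq_span.end]
        if set(tract) != {"Q"}:
            raise ValueError("pq_span must contain only glutamine (Q)")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def pq_length(self) -> int:
        return len(self.pq_span)


def build_construct(
    base: SequenceConstruct,
    target_pq_length: int,
    *,
    variant_label: str | None = None,
    insert_at: str = "c_terminus",
) -> SequenceConstruct:
    """Expand or contract the pQ tract of *base* to ``target_pq_length``.

    Flanking sequence is unchanged; chain length changes by
    ``target_pq_length - base.pq_length``.  Whether extra glutamines are
    inserted at the tract C-terminus or mid-tract is immaterial for numbering
    (the tract is homopolymeric) but is exposed via ``insert_at`` in
    ``{"c_terminus", "middle"}``.
    """
    if target_pq_length < 1:
        raise ValueError("target_pq_length must be >= 1")
    if insert_at not in ("c_terminus", "middle"):
        raise ValueError(f"unknown insert_at {insert_at!r}")
    span = base.pq_span
    if target_pq_length == base.pq_length:
        if variant_label is None:
            return base
        return replace(base, variant_label=variant_label)
    before = base.residues[: span.start - 1]
    after = base.residues[span.end :]
    residues = before + "Q" * target_pq_length + after
    new_span = Interval(span.start, span.start + target_pq_length - 1)
    return SequenceConstruct(
        residues=residues,
        pq_span=new_span,
        variant_label=variant_label or "custom",
    )


def wt_synthetic_construct(
    pq_span: tuple[int, int] = DEFAULT_PQ_SPAN, length: int = 538
) -> SequenceConstruct:
    """A synthetic stand-in for the wild-type NTD construct.

    Generic alanine background with the Q tract planted at the annotated
    coordinates.  This is NOT the real AR sequence: every analysis in this
    package consumes only the numbering and tract layout, so a synthetic
    sequence with the correct geometry of annotation is the honest default.
    """
    span = Interval(*pq_span)
    if span.end > length:
        raise ValueError("pq_span beyond chain length")
    residues = "".join(
        "Q" if i in span else "A" for i in range(1, length + 1)
    )
    return SequenceConstruct(residues=residues, pq_span=span, variant_label="wt")


@dataclass(frozen=True)
class NumberingLift:
    """Monotone index map between two numbering frames differing by a tract.

    Identity N-terminal of the tract insertion point; adds ``offset``
    (target tract length minus source tract length) C-terminal of it.
    Indices strictly inside the expanded tract interior are ambiguous.
    """

    source_frame: str
    target_frame: str
    insertion_point: int  # pQ tract end in the source frame
    offset: int

    def __call__(self, residue_index: int) -> int:
        return lift_index(self, residue_index)

    @property
    def inverse(self) -> "NumberingLift":
        return NumberingLift(
            source_frame=self.target_frame,
            target_frame=self.source_frame,
            insertion_point=self.insertion_point + self.offset,
            offset=-self.offset,
        )

    @classmethod
    def between(
        cls, source: SequenceConstruct, target: SequenceConstruct
    ) -> "NumberingLift":
        if source.pq_span.start != target.pq_span.start:
            raise ValueError("constructs must share the tract start")
        return cls(
            source_frame=source.variant_label,
            target_frame=target.variant_label,
            insertion_point=source.pq_span.end,
            offset=target.pq_length - source.pq_length,
        )


class AmbiguousMappingError(ValueError):
    """Raised for indices inside the expanded tract interior."""


def lift_index(lift: NumberingLift, residue_index: int) -> int:
    """Map ``residue_index`` from the lift's source frame to its target frame."""
    if residue_index < 1:
        raise ValueError("residue index must be >= 1")
    if residue_index <= lift.insertion_point and lift.offset < 0:
        # contracting lift: source indices inside the removed stretch have no image
        if residue_index > lift.insertion_point + lift.offset:
            raise AmbiguousMappingError(
                f"index {residue_index} lies inside the contracted tract interior"
            )
    if residue_index <= lift.insertion_point:
        return residue_index
    return residue_index + lift.offset


def lift_interval(lift: NumberingLift, interval: Interval) -> Interval:
    return Interval(lift_index(lift, interval.start), lift_index(lift, interval.end))


@dataclass(frozen=True)
class Region:
    name: str
    interval: Interval
    frame: str = "wt"


@dataclass
class RegionMap:
    """Named inclusive residue intervals on a chain of declared length.

    ``NR`` and ``CR`` must be present, disjoint, and jointly cover the chain
    for NTD constructs; motif intervals may overlap regions freely.
    """

    chain_length: int
    regions: dict[str, Region] = field(default_factory=dict)

    def add(self, name: str, start: int, end: int, frame: str = "wt") -> None:
        iv = Interval(start, end)
        if iv.end > self.chain_length:
            raise ValueError(
                f"region {name} [{start},{end}] beyond chain length {self.chain_length}"
            )
        self.regions[name] = Region(name, iv, frame)

    def __getitem__(self, name: str) -> Region:
        return self.regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def validate_nr_cr(self) -> None:
        nr, cr = self.regions["NR"].interval, self.regions["CR"].interval
        if not (nr.end < cr.start or cr.end < nr.start):
            raise ValueError("NR and CR must be disjoint")

    def motifs_at(self, residue_index: int) -> list[str]:
        return sorted(
            name
            for name, reg in self.regions.items()
            if name not in ("NR", "CR") and residue_index in reg.interval
        )


def classify_region(region_map: RegionMap, residue_index: int) -> tuple[str, list[str]]:
    """Return the (NR|CR) label and any motif labels containing the index."""
    if not (1 <= residue_index <= region_map.chain_length):
        raise IndexError(
            f"residue {residue_index} outside chain 1..{region_map.chain_length}"
        )
    label = None
    for name in ("NR", "CR"):
        if name in region_map and residue_index in region_map[name].interval:
            label = name
            break
    if label is None:
        raise ValueError(f"residue {residue_index} not covered by NR or CR")
    return label, region_map.motifs_at(residue_index)


def default_region_map(
    variant: str = "wt",
    pq_span: tuple[int, int] = DEFAULT_PQ_SPAN,
    target_pq_length: int | None = None,
) -> RegionMap:
    """Region map for the NTD with documented defaults.

    For ``variant="pQe"`` all intervals C-terminal of the tract are lifted by
    the tract-length difference (default 45 - 23 = 22).
    """
    src_span = Interval(*pq_span)
    offset = 0
    if variant == "pQe":
        target = 45 if target_pq_length is None else target_pq_length
        offset = target - len(src_span)
    lift = NumberingLift("wt", variant, src_span.end, offset)
    chain_length = CR_SPAN[1] + offset
    rm = RegionMap(chain_length=chain_length)
    rm.add("NR", *NR_SPAN, frame=variant)
    rm.add("CR", CR_SPAN[0], CR_SPAN[1] + offset, frame=variant)
    rm.add("pQ", src_span.start, src_span.end + offset, frame=variant)
    for name, (s, e) in DEFAULT_MOTIFS.items():
        if name == "P-box":
            continue  # partner-chain frame; not on the NTD chain
        iv = lift_interval(lift, Interval(s, e)) if s > src_span.end else Interval(s, e)
        if iv.end <= chain_length:
            rm.add(name, iv.start, iv.end, frame=variant)
    rm.validate_nr_cr()
    return rm


def load_region_map_toml(path: str | Path, section: str = "regions") -> RegionMap:
    """Read a region map from a TOML file.

    Expected layout::

        [regions]
        chain_length = 538
        [[regions.interval]]
        name = "NR"
        start = 1
        end = 224
        frame = "wt"
    """
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    sec = cfg[section]
    rm = RegionMap(chain_length=int(sec["chain_length"]))
    for item in sec.get("interval", []):
        frame = item.get("frame", "wt")
        if frame not in ("wt", "pQe", "uniprot", "chain-local"):
            raise ValueError(f"unknown numbering frame {frame!r}")
        rm.add(item["name"], int(item["start"]), int(item["end"]), frame)
    return rm


def write_fasta(constructs: Iterable[SequenceConstruct], path: str | Path) -> None:
    """Write constructs as FASTA; headers carry the variant label and tract span."""
    lines = []
    for c in constructs:
        lines.append(
            f">{c.variant_label} length={c.length} pq={c.pq_span.start}-{c.pq_span.end}"
        )
        for i in range(0, c.length, 60):
            lines.append(c.residues[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n")
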