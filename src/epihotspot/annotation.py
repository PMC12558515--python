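"""Membrane-topology annotation and variant differential analysis.

Rh antigens are multi-pass membrane proteins; each residue lies in an
exofacial loop, a transmembrane helix, or an intracellular segment.  A
hotspot core receives a single region label.  The default ``start_residue``
rule labels a core by the interval containing its first residue: it is the
only simple rule consistent with published core labels in which, e.g., a
core starting on the last residue of an exofacial loop is still called
exofacial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import ValidationError
from .hotspots import HotspotCall
from .sequences import PeptideWindow, ProteinSequence, ProteinVariant

EXOFACIAL = "exofacial"
TRANSMEMBRANE = "transmembrane"
INTRACELLULAR = "intracellular"
REGION_LABELS = (EXOFACIAL, TRANSMEMBRANE, INTRACELLULAR)

START_RESIDUE = "start_residue"
MAJORITY_OVERLAP = "majority_overlap"


@dataclass(frozen=True)
class TopologyMap:
    """Ordered, gap-free 1-based inclusive intervals covering a whole antigen.

    ``intervals`` is a tuple of (start, end, label) triples, sorted,
    non-overlapping, and jointly covering 1..length.
    """

    antigen_id: str
    intervals: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValidationError(f"topology map {self.antigen_id!r}: no intervals")
        prev_end = 0
        for start, end, label in self.intervals:
            if label not in REGION_LABELS:
                raise ValidationError(
                    f"topology map {self.antigen_id!r}: unknown label {label!r}"
                )
            if start != prev_end + 1:
                kind = "gap" if start > prev_end + 1 else "overlap"
                raise ValidationError(
                    f"topology map {self.antigen_id!r}: {kind} between position "
                    f"{prev_end} and interval ({start}, {end}, {label})"
                )
            if end < start:
                raise ValidationError(
                    f"topology map {self.antigen_id!r}: empty interval "
                    f"({start}, {end}, {label})"
                )
            prev_end = end

    @property
    def length(self) -> int:
        return self.intervals[-1][1]

    def label_at(self, position: int) -> str:
        """Region label of a 1-based residue position."""
        if not 1 <= position <= self.length:
            raise ValidationError(
                f"position {position} outside topology map "
                f"{self.antigen_id!r} (1..{self.length})"
            )
        for start, end, label in self.intervals:
            if start <= position <= end:
                return label
        raise AssertionError("unreachable: validated map covers 1..length")


def build_topology_map(
    antigen_id: str, intervals: Iterable[tuple[int, int, str]]
) -> TopologyMap:
    """Validate and build a topology map from (start, end, label) triples."""
    ordered = tuple(sorted(intervals, key=lambda t: t[0]))
    return TopologyMap(antigen_id=antigen_id, intervals=ordered)


def classify_region(
    window: PeptideWindow | int,
    topology: TopologyMap,
    rule: str = START_RESIDUE,
    k: int = 9,
) -> str:
    """Region label for a peptide window (or bare 1-based start).

    ``start_residue`` (default): the label of the interval containing the
    window's first residue.  ``majority_overlap``: the label covering most
    of the k residues, ties broken toward exofacial then transmembrane.
    """
    if isinstance(window, PeptideWindow):
        start, length = window.start, window.k
    else:
        start, length = int(window), k
    if rule == START_RESIDUE:
        return topology.label_at(start)
    if rule == MAJORITY_OVERLAP:
        votes = {label: 0 for label in REGION_LABELS}
        for pos in range(start, min(start + length - 1, topology.length) + 1):
            votes[topology.label_at(pos)] += 1
        # tie-break priority: exofacial, then transmembrane, then intracellular
        return max(REGION_LABELS, key=lambda lab: (votes[lab], -REGION_LABELS.index(lab)))
    raise ValidationError(f"unknown classification rule {rule!r}")


@dataclass(frozen=True)
class CoreChange:
    """A hotspot start shared by both alleles but with differing cores."""

    start: int
    ref_core: str
    cmp_core: str
    changed_positions: tuple[int, ...]  # absolute 1-based protein positions


@dataclass(frozen=True)
class HotspotDiff:
    """Partition of hotspot starts between a reference and comparator allele.

    ``shared`` holds starts present in both with identical cores;
    ``changed_core`` starts present in both with differing cores (with the
    absolute positions of every differing residue); ``lost`` starts only in
    the reference; ``gained`` starts only in the comparator.  The four sets
    partition the union of start positions.
    """

    shared: tuple[int, ...]
    changed_core: tuple[CoreChange, ...]
    lost: tuple[int, ...]
    gained: tuple[int, ...]

    def all_starts(self) -> set[int]:
        return (
            set(self.shared)
            | {c.start for c in self.changed_core}
            | set(self.lost)
            | set(self.gained)
        )


def _dedup_by_start(calls: Sequence[HotspotCall], role: str) -> dict[int, str]:
    cores: dict[int, str] = {}
    for c in calls:
        if c.start in cores:
            raise ValidationError(f"{role} hotspot list has duplicate start {c.start}")
        cores[c.start] = c.core
    return cores


def diff_hotspots(
    reference: Sequence[HotspotCall], comparator: Sequence[HotspotCall]
) -> HotspotDiff:
    """Differential hotspot analysis between two antigen alleles.

    Keys on start position: a start present in both lists with different
    cores is reported as ``changed_core`` (the same hotspot with substituted
    residues), not as lost plus gained.  Changed-core entries carry the
    absolute protein position of each differing residue: the core's start
    plus the zero-based offset of the residue within the core.
    """
    ref = _dedup_by_start(reference, "reference")
    cmp_ = _dedup_by_start(comparator, "comparator")
    shared, changed = [], []
    for start in sorted(ref.keys() & cmp_.keys()):
        a, b = ref[start], cmp_[start]
        if a == b:
            shared.append(start)
        else:
            if len(a) != len(b):
                raise ValidationError(
                    f"cores at start {start} have different lengths: {a!r} vs {b!r}"
                )
            positions = tuple(
                start + i for i, (x, y) in enumerate(zip(a, b)) if x != y
            )
            changed.append(
                CoreChange(start=start, ref_core=a, cmp_core=b, changed_positions=positions)
            )
    lost = tuple(sorted(ref.keys() - cmp_.keys()))
    gained = tuple(sorted(cmp_.keys() - ref.keys()))
    return HotspotDiff(
        shared=tuple(shared), changed_core=tuple(changed), lost=lost, gained=gained
    )


def variant_core_changes(
    seq: ProteinSequence, variant: ProteinVariant, k: int = 9
) -> list[int]:
    """Window starts whose k-mer covers the variant position.

    For a variant at position p these are max(1, p-k+1) .. min(p, L-k+1):
    every core a single substitution can alter.
    """
    if variant.position > seq.length:
        raise ValidationError(
            f"variant position {variant.position} outside sequence "
            f"{seq.id!r} (1..{seq.length})"
        )
    lo = max(1, variant.position - k + 1)
    hi = min(variant.position, seq.length - k + 1)
    return list(range(lo, hi + 1))


# --------------------------------------------------------------------------
# Topology config I/O.  The TSV dialect is BED-like but 1-based inclusive:
# columns antigen_id, start, end, label; the convention is stated in a
# comment line of every file written.  YAML files carry
# {antigen_id: [[start, end, label], ...], ...}.
# --------------------------------------------------------------------------


def read_topology(path: str | Path) -> dict[str, TopologyMap]:
    """Read topology maps from TSV or YAML, keyed by antigen id."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        return {
            antigen: build_topology_map(
                antigen, [(int(s), int(e), str(lab)) for s, e, lab in triples]
            )
            for antigen, triples in data.items()
        }
    per_antigen: dict[str, list[tuple[int, int, str]]] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("antigen_id\t"):
            continue
        antigen, start, end, label = line.split("\t")
        per_antigen.setdefault(antigen, []).append((int(start), int(end), label))
    return {a: build_topology_map(a, triples) for a, triples in per_antigen.items()}


def write_topology_tsv(maps: Iterable[TopologyMap], path: str | Path) -> None:
    """Write topology maps as TSV (antigen_id, start, end, label)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# topology intervals; start and end are 1-based inclusive\n")
        fh.write("antigen_id\tstart\tend\tlabel\n")
        for tmap in maps:
            for start, end, label in tmap.intervals:
                fh.write(f"{tmap.antigen_id}\t{start}\t{end}\t{label}\n")


def write_diff_tsv(diff: HotspotDiff, path: str | Path) -> None:
    """Write a hotspot diff as TSV with a category column."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# hotspot differential; start is 1-based inclusive\n")
        fh.write("category\tstart\tref_core\tcmp_core\tchanged_positions\n")
        for start in diff.shared:
            fh.write(f"shared\t{start}\t\t\t\n")
        for c in diff.changed_core:
            pos = ",".join(str(p) for p in c.changed_positions)
            fh.write(f"changed_core\t{c.start}\t{c.ref_core}\t{c.cmp_core}\t{pos}\n")
        for start in diff.lost:
            fh.write(f"lost\t{start}\t\t\t\n")
        for start in diff.gained:
            fh.write(f"gained\t{start}\t\t\t\n")
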