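"""Strong-binder aggregation: per-position profiles, hotspot calls, heatmaps.

A *hotspot* is a peptide core of the antigen predicted to bind strongly
(%rank below the SB bound) to MHC class II molecules of the panel.  The
default calling rule is ``min_alleles = 1`` — a core that is a strong binder
for at least one panel allele — because the operational definition is
per-peptide, not per-panel-fraction; stricter panel-level calling is exposed
through the ``min_alleles`` parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import SB, BinderThresholds, BindingRecord, classify_binder
from .errors import ValidationError
from .sequences import ProteinSequence

PER_START = "per_start"
PER_RESIDUE = "per_residue"


@dataclass(frozen=True)
class BindingProfile:
    """Per-position strong-binder counts across an allele panel.

    ``counts[i]`` (0-based array index) is the count at 1-based position
    ``i + 1``.  In ``per_start`` mode positions are window starts and the
    vector spans starts 1..L-k+1; in ``per_residue`` mode positions are
    residues and every SB window increments all k residues it covers.
    """

    antigen_id: str
    panel_id: str
    mode: str
    counts: np.ndarray
    k: int = 9

    def __post_init__(self) -> None:
        if self.mode not in (PER_START, PER_RESIDUE):
            raise ValidationError(f"unknown profile mode {self.mode!r}")
        if np.any(self.counts < 0):
            raise ValidationError("profile counts must be non-negative")

    def count_at(self, position: int) -> int:
        """Count at a 1-based position."""
        if not 1 <= position <= len(self.counts):
            raise ValidationError(
                f"position {position} outside profile (1..{len(self.counts)})"
            )
        return int(self.counts[position - 1])

    def as_series(self) -> pd.Series:
        """Counts as a pandas Series indexed by 1-based position."""
        return pd.Series(
            self.counts, index=np.arange(1, len(self.counts) + 1), name="n_alleles_sb"
        )


@dataclass(frozen=True)
class HotspotCall:
    """A window start called as a hotspot, with its core and SB allele count."""

    antigen_id: str
    start: int
    core: str
    n_alleles_sb: int
    region: str | None = field(default=None, compare=False)


def _sb_records(
    records: Sequence[BindingRecord], thresholds: BinderThresholds
) -> list[BindingRecord]:
    return [r for r in records if classify_binder(r, thresholds) == SB]


def _check_single_antigen(records: Sequence[BindingRecord]) -> str:
    antigens = {r.antigen_id for r in records}
    if len(antigens) > 1:
        raise ValidationError(f"records span multiple antigens: {sorted(antigens)}")
    return antigens.pop() if antigens else ""


def build_profile(
    records: Sequence[BindingRecord],
    thresholds: BinderThresholds = BinderThresholds(),
    mode: str = PER_START,
    antigen_length: int | None = None,
    k: int = 9,
    panel_id: str = "panel",
) -> BindingProfile:
    """Aggregate records into a strong-binder count profile.

    In ``per_start`` mode, ``counts[s]`` is the number of distinct panel
    alleles whose record at start ``s`` is SB.  Records must cover a single
    antigen, and duplicate (allele, start) pairs are an error.  When
    ``antigen_length`` is omitted the vector extends to the largest start
    (per_start) or largest covered residue (per_residue) seen.
    """
    if mode not in (PER_START, PER_RESIDUE):
        raise ValidationError(f"unknown profile mode {mode!r}")
    antigen_id = _check_single_antigen(records)
    seen: set[tuple[str, int]] = set()
    for r in records:
        key = (r.allele.name, r.start)
        if key in seen:
            raise ValidationError(
                f"duplicate record for allele {r.allele.name} at start {r.start}"
            )
        seen.add(key)
    sb = _sb_records(records, thresholds)
    if mode == PER_START:
        n = (antigen_length - k + 1) if antigen_length else max(
            (r.start for r in records), default=0
        )
    else:
        n = antigen_length if antigen_length else max(
            (r.start + len(r.core) - 1 for r in records), default=0
        )
    counts = np.zeros(max(n, 0), dtype=int)
    for r in sb:
        if mode == PER_START:
            if r.start > len(counts):
                raise ValidationError(
                    f"record start {r.start} beyond profile length {len(counts)}"
                )
            counts[r.start - 1] += 1
        else:
            end = min(r.start + len(r.core) - 1, len(counts))
            counts[r.start - 1 : end] += 1
    return BindingProfile(
        antigen_id=antigen_id, panel_id=panel_id, mode=mode, counts=counts, k=k
    )


def call_hotspots(
    profile: BindingProfile,
    min_alleles: int = 1,
    sequence: ProteinSequence | None = None,
    cores: Mapping[int, str] | None = None,
) -> list[HotspotCall]:
    """Call hotspot starts from a per_start profile, ascending by start.

    A start is called when at least ``min_alleles`` panel alleles bind it
    strongly.  Cores are sliced from ``sequence`` when given, otherwise
    looked up in ``cores`` (start -> k-mer), otherwise left as '?' * k.
    """
    if profile.mode != PER_START:
        raise ValidationError("call_hotspots requires a per_start profile")
    if min_alleles < 1:
        raise ValidationError(f"min_alleles must be >= 1, got {min_alleles}")
    calls = []
    for start0, n in enumerate(profile.counts):
        if n < min_alleles:
            continue
        start = start0 + 1
        if sequence is not None:
            core = sequence.slice(start, profile.k)
        elif cores is not None and start in cores:
            core = cores[start]
        else:
            core = "?" * profile.k
        calls.append(
            HotspotCall(
                antigen_id=profile.antigen_id, start=start, core=core,
                n_alleles_sb=int(n),
            )
        )
    return calls


def heatmap_matrix(
    records: Sequence[BindingRecord],
    thresholds: BinderThresholds = BinderThresholds(),
    values: str = "binary",
) -> pd.DataFrame:
    """Alleles x start-positions matrix of SB indicators or %rank values.

    Rows are alleles in lexicographic order, columns are ascending starts.
    ``values='binary'`` gives 1 where the record is SB (its column sums then
    equal the per_start profile); ``values='rank'`` gives the %rank, with
    missing (allele, start) pairs as NaN.
    """
    if values not in ("binary", "rank"):
        raise ValidationError(f"values must be 'binary' or 'rank', got {values!r}")
    _check_single_antigen(records)
    if not records:
        import warnings

        warnings.warn("heatmap_matrix: empty record list, returning empty matrix",
                      stacklevel=2)
        return pd.DataFrame()
    alleles = sorted({r.allele.name for r in records})
    starts = sorted({r.start for r in records})
    if values == "binary":
        mat = pd.DataFrame(0, index=alleles, columns=starts, dtype=int)
    else:
        mat = pd.DataFrame(np.nan, index=alleles, columns=starts, dtype=float)
    for r in records:
        if values == "binary":
            if classify_binder(r, thresholds) == SB:
                mat.loc[r.allele.name, r.start] = 1
        else:
            mat.loc[r.allele.name, r.start] = r.percent_rank
    mat.index.name = "allele"
    mat.columns.name = "start"
    return mat


def summarize_by_locus(
    hotspot_tables: Mapping[tuple[str, str], Sequence[HotspotCall]]
) -> pd.DataFrame:
    """Count distinct hotspot starts per (antigen, locus_group).

    Input maps (antigen label, locus group) to its hotspot list; the result
    is a tidy table with columns antigen, locus_group, n_hotspots.
    """
    rows = []
    for (antigen, locus_group), calls in sorted(hotspot_tables.items()):
        starts = {c.start for c in calls}
        if len(starts) != len(list(calls)):
            raise ValidationError(
                f"hotspot list for ({antigen}, {locus_group}) has duplicate starts"
            )
        rows.append(
            {"antigen": antigen, "locus_group": locus_group, "n_hotspots": len(starts)}
        )
    return pd.DataFrame(rows, columns=["antigen", "locus_group", "n_hotspots"])


def merge_adjacent(
    calls: Sequence[HotspotCall], gap: int = 0
) -> list[tuple[int, int, list[HotspotCall]]]:
    """Optionally merge nearby hotspot starts into regions.

    Two consecutive called starts join one region when their start distance
    is at most ``gap + 1``.  Individual cores remain the primary unit; this
    is a convenience for region-level reporting.  Returns (first_start,
    last_start, member calls) triples.
    """
    if gap < 0:
        raise ValidationError(f"gap must be >= 0, got {gap}")
    ordered = sorted(calls, key=lambda c: c.start)
    regions: list[tuple[int, int, list[HotspotCall]]] = []
    for call in ordered:
        if regions and call.start - regions[-1][1] <= gap + 1:
            first, _, members = regions[-1]
            regions[-1] = (first, call.start, members + [call])
        else:
            regions.append((call.start, call.start, [call]))
    return regions


def write_hotspots_tsv(
    calls: Iterable[HotspotCall], path: str | Path, locus_group: str = ""
) -> None:
    """Write hotspot calls as TSV: antigen, locus_group, start, core, region.

    Starts are 1-based inclusive; region is empty until annotation.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# hotspot calls; start is 1-based inclusive\n")
        fh.write("antigen\tlocus_group\tstart\tcore\tregion\tn_alleles_sb\n")
        for c in sorted(calls, key=lambda c: (c.antigen_id, c.start)):
            fh.write(
                f"{c.antigen_id}\t{locus_group}\t{c.start}\t{c.core}\t"
                f"{c.region or ''}\t{c.n_alleles_sb}\n"
            )


def read_hotspots_tsv(path: str | Path) -> list[HotspotCall]:
    """Read hotspot calls written by :func:`write_hotspots_tsv`."""
    calls = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("antigen\t"):
            continue
        antigen, _locus, start, core, region, n_sb = line.split("\t")
        calls.append(
            HotspotCall(
                antigen_id=antigen, start=int(start), core=core,
                n_alleles_sb=int(n_sb), region=region or None,
            )
        )
    return calls


def annotate_calls(calls: Sequence[HotspotCall], labels: Mapping[int, str]) -> list[HotspotCall]:
    """Attach region labels (start -> label) to calls, returning new calls."""
    return [replace(c, region=labels.get(c.start, c.region)) for c in calls]
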