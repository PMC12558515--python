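"""Peptide-MHC binding records, %rank thresholds, and engine-output parsers.

The binding-prediction engines themselves (NetMHCpan-4.1 / NetMHCIIpan-4.1)
are external: this module defines the record model, the strong/weak/non-binder
classification on %rank, parsers for the engines' plain-text tabular result
layouts, and the pluggable predictor contract that the synthetic pseudo-
predictor also satisfies.

%Rank semantics: a prediction's percentile rank against a background peptide
set, in (0, 100]; lower means stronger predicted binding.  A peptide is a
strong binder (SB) when its %rank is strictly below the SB bound (default
0.5), a weak binder (WB) when it lies in [sb_rank, wb_rank), and a
non-binder (NB) otherwise.  Boundary values fall into the weaker class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from .errors import DialectError, RowParseError, ValidationError
from .sequences import PeptideWindow

LOCUS_GROUPS = ("A", "B", "C", "DRB", "DQA-DQB", "DPA-DPB")

SB = "SB"
WB = "WB"
NB = "NB"

# Engine spellings of class II allele names, e.g. "DRB1_1501" or
# "HLA-DQA10101-DQB10301"; canonical forms are "DRB1*15:01" and
# "DQA1*01:01-DQB1*03:01" (single hyphen between the chains).
_DRB_COMPACT_RE = re.compile(r"^(DRB[1345])_?(\d{2})(\d{2,3})$")
_PAIR_COMPACT_RE = re.compile(
    r"^(?:HLA-)?(D[QP]A1)(\d{2})(\d{2,3})-(D[QP]B1)(\d{2})(\d{2,3})$"
)
_CLASS1_RE = re.compile(r"^(?:HLA-)?([ABC])\*?(\d{2}):?(\d{2,3})$")
_CANONICAL_RE = re.compile(
    r"^(?:[ABC]\*\d{2}:\d{2,3}"
    r"|DRB[1345]\*\d{2}:\d{2,3}"
    r"|D[QP]A1\*\d{2}:\d{2,3}-D[QP]B1\*\d{2}:\d{2,3})$"
)


def normalize_allele_name(raw: str) -> str:
    """Canonicalize an HLA allele name from common engine spellings.

    ``DRB1_1501`` -> ``DRB1*15:01``; ``HLA-DQA10101-DQB10301`` ->
    ``DQA1*01:01-DQB1*03:01``; ``HLA-A02:01`` -> ``A*02:01``.  Names already
    canonical pass through; names matching no known HLA pattern (e.g.
    synthetic panel names) are returned unchanged.
    """
    name = raw.strip()
    if _CANONICAL_RE.match(name):
        return name
    m = _DRB_COMPACT_RE.match(name)
    if m:
        locus, g1, g2 = m.groups()
        return f"{locus}*{g1}:{g2}"
    m = _PAIR_COMPACT_RE.match(name)
    if m:
        a, a1, a2, b, b1, b2 = m.groups()
        return f"{a}*{a1}:{a2}-{b}*{b1}:{b2}"
    m = _CLASS1_RE.match(name)
    if m:
        locus, g1, g2 = m.groups()
        return f"{locus}*{g1}:{g2}"
    if name.startswith("HLA-"):
        stripped = name[4:]
        if _CANONICAL_RE.match(stripped):
            return stripped
    return name


def infer_locus_group(name: str) -> tuple[str | None, str | None]:
    """(locus_group, mhc_class) inferred from a canonical allele name.

    Returns (None, None) for names matching no HLA pattern.
    """
    if re.match(r"^[ABC]\*", name):
        return name[0], "I"
    if re.match(r"^DRB[1345]\*", name):
        return "DRB", "II"
    if re.match(r"^DQA1\*.*-DQB1\*", name):
        return "DQA-DQB", "II"
    if re.match(r"^DPA1\*.*-DPB1\*", name):
        return "DPA-DPB", "II"
    return None, None


@dataclass(frozen=True)
class HlaAllele:
    """An HLA allele of the panel.

    Paired alpha-beta names (single hyphen) are used for the DQ and DP
    heterodimers; DR is identified by its beta chain alone.  For names that
    match an HLA pattern, locus_group and mhc_class must agree with the
    name prefix; non-HLA (synthetic) names carry whatever group the caller
    assigns.
    """

    name: str
    locus_group: str
    mhc_class: str

    def __post_init__(self) -> None:
        if self.locus_group not in LOCUS_GROUPS:
            raise ValidationError(
                f"unknown locus group {self.locus_group!r}; expected one of {LOCUS_GROUPS}"
            )
        if self.mhc_class not in ("I", "II"):
            raise ValidationError(f"mhc_class must be 'I' or 'II', got {self.mhc_class!r}")
        inferred_group, inferred_class = infer_locus_group(self.name)
        if inferred_group is not None and (
            inferred_group != self.locus_group or inferred_class != self.mhc_class
        ):
            raise ValidationError(
                f"allele {self.name!r}: locus_group/mhc_class "
                f"({self.locus_group}, {self.mhc_class}) inconsistent with name "
                f"(expected {inferred_group}, {inferred_class})"
            )

    @classmethod
    def from_name(cls, raw: str) -> "HlaAllele":
        """Build an allele from any recognized spelling, inferring its group."""
        name = normalize_allele_name(raw)
        group, mhc_class = infer_locus_group(name)
        if group is None:
            raise ValidationError(
                f"cannot infer locus group from allele name {raw!r}; "
                "construct HlaAllele explicitly"
            )
        return cls(name=name, locus_group=group, mhc_class=mhc_class)


@dataclass(frozen=True)
class BinderThresholds:
    """%rank bounds for binder classes: SB strictly below sb_rank, WB in
    [sb_rank, wb_rank).  The SB default follows the analysis convention of
    0.5% for both engine classes."""

    sb_rank: float = 0.5
    wb_rank: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.sb_rank < self.wb_rank:
            raise ValidationError(
                f"thresholds must satisfy 0 < sb_rank < wb_rank, got "
                f"({self.sb_rank}, {self.wb_rank})"
            )


@dataclass(frozen=True)
class BindingRecord:
    """One allele's %rank prediction for one peptide core.

    ``start`` is the 1-based position of the core in the antigen.
    ``core_from_engine`` marks records where the engine reported a longer
    peptide and the 9-mer binding core was taken from the engine's core
    column rather than from direct window enumeration.
    """

    allele: HlaAllele
    antigen_id: str
    start: int
    core: str
    percent_rank: float
    score: float | None = None
    core_from_engine: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.percent_rank <= 100:
            raise ValidationError(
                f"percent_rank must lie in (0, 100], got {self.percent_rank}"
            )
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if not self.core:
            raise ValidationError("core must be non-empty")

    @property
    def window(self) -> PeptideWindow:
        return PeptideWindow(antigen_id=self.antigen_id, start=self.start, sequence=self.core)


def classify_binder(
    record: BindingRecord | float, thresholds: BinderThresholds = BinderThresholds()
) -> str:
    """Classify a record (or bare %rank) as SB, WB or NB.

    Comparisons are strict at both bounds: rank < sb_rank -> SB;
    sb_rank <= rank < wb_rank -> WB; otherwise NB.  A rank sitting exactly
    on a bound therefore falls into the weaker class.
    """
    rank = record.percent_rank if isinstance(record, BindingRecord) else float(record)
    if rank <= 0:
        raise ValidationError(f"percent_rank must be positive, got {rank}")
    if rank < thresholds.sb_rank:
        return SB
    if rank < thresholds.wb_rank:
        return WB
    return NB


class Predictor(Protocol):
    """Contract for pluggable binding predictors.

    Implementations return exactly one record per (window, allele) pair
    unless they document skipping (e.g. flagged 'X'-containing windows),
    and are deterministic for fixed inputs and seed.
    """

    def predict(
        self, windows: Sequence[PeptideWindow], alleles: Sequence[HlaAllele]
    ) -> list[BindingRecord]: ...


# --------------------------------------------------------------------------
# Engine output parsing.
#
# Both engines print a whitespace-aligned table after a header line.  The
# layouts modelled here:
#
# netmhcpan41 (class I; Pos is 0-based in engine files, shifted +1 on parse):
#   Pos  MHC  Peptide  Core  Of  Gp  Gl  Ip  Il  Icore  Identity  Score_EL  %Rank_EL  [<= SB]
#
# netmhciipan41 (class II; Pos is the 1-based peptide start, core start =
# Pos + Of where Of is the core offset within the peptide):
#   Pos  MHC  Peptide  Of  Core  Core_Rel  Identity  Score_EL  %Rank_EL  [<= SB]
#
# The class I layout is identified by its Icore column, the class II layout
# by Core_Rel; asking for the wrong dialect raises DialectError naming the
# offending header line.
# --------------------------------------------------------------------------

DIALECTS = ("netmhcpan41", "netmhciipan41")

_CLASS1_COLUMNS = [
    "Pos", "MHC", "Peptide", "Core", "Of", "Gp", "Gl", "Ip", "Il",
    "Icore", "Identity", "Score_EL", "%Rank_EL",
]
_CLASS2_COLUMNS = [
    "Pos", "MHC", "Peptide", "Of", "Core", "Core_Rel", "Identity",
    "Score_EL", "%Rank_EL",
]


def _require_dialect(dialect: str) -> list[str]:
    if dialect == "netmhcpan41":
        return _CLASS1_COLUMNS
    if dialect == "netmhciipan41":
        return _CLASS2_COLUMNS
    raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def parse_netmhc_output(path: str | Path, dialect: str) -> list[BindingRecord]:
    """Parse an engine plain-text result file into normalized records.

    Positions are normalized to 1-based starts against the submitted
    sequence (class I engine positions are 0-based and shifted by +1;
    class II core starts are Pos + Of).  Allele names are canonicalized.
    For class II rows whose peptide is longer than the core, the engine-
    reported core becomes the record's window and the record is flagged
    ``core_from_engine``.
    """
    columns = _require_dialect(dialect)
    path = Path(path)
    records: list[BindingRecord] = []
    header_seen = False
    for lineno, rawline in enumerate(path.read_text().splitlines(), start=1):
        line = rawline.strip()
        if not line or line.startswith("#") or set(line) <= {"-"}:
            continue
        tokens = line.split()
        if not header_seen:
            if tokens[0] == "Pos" and "MHC" in tokens:
                if tokens[: len(columns)] != columns:
                    raise DialectError(
                        f"{path}:{lineno}: header does not match dialect "
                        f"{dialect!r}: {line!r}"
                    )
                header_seen = True
                continue
            raise DialectError(
                f"{path}:{lineno}: expected a '{columns[0]} {columns[1]} ...' "
                f"header before data, found {line!r}"
            )
        if not tokens[0].lstrip("-").isdigit():
            # footer / summary text after the table
            continue
        if len(tokens) < len(columns):
            raise RowParseError(
                f"{path}:{lineno}: truncated row ({len(tokens)} of "
                f"{len(columns)} columns): {line!r}"
            )
        row = dict(zip(columns, tokens))
        try:
            pos = int(row["Pos"])
            rank = float(row["%Rank_EL"])
            score = float(row["Score_EL"])
            offset = int(row["Of"])
        except ValueError as exc:
            raise RowParseError(f"{path}:{lineno}: unparseable field: {exc}") from exc
        try:
            allele = HlaAllele.from_name(row["MHC"])
        except ValidationError:
            if dialect == "netmhcpan41":
                raise
            # synthetic class II panel names pass through with a DRB grouping
            allele = HlaAllele(
                name=normalize_allele_name(row["MHC"]), locus_group="DRB", mhc_class="II"
            )
        peptide, core = row["Peptide"], row["Core"]
        if dialect == "netmhcpan41":
            start = pos + 1  # engine positions are 0-based
            record_core = peptide
            flagged = False
        else:
            start = pos + offset  # 1-based peptide start plus core offset
            record_core = core
            flagged = len(peptide) != len(core)
        records.append(
            BindingRecord(
                allele=allele,
                antigen_id=row["Identity"],
                start=start,
                core=record_core,
                percent_rank=rank,
                score=score,
                core_from_engine=flagged,
            )
        )
    if not header_seen:
        raise DialectError(f"{path}: no recognizable {dialect!r} header found")
    return records


def write_records_tsv(records: Iterable[BindingRecord], path: str | Path,
                      thresholds: BinderThresholds = BinderThresholds()) -> None:
    """Write normalized records as TSV with the binder class attached.

    Columns: antigen_id, start (1-based), core, allele, locus_group,
    percent_rank, binder_class.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# binding records; start is 1-based inclusive core start\n")
        fh.write(
            f"# thresholds: SB < {thresholds.sb_rank}, WB < {thresholds.wb_rank}\n"
        )
        fh.write("antigen_id\tstart\tcore\tallele\tlocus_group\tpercent_rank\tbinder_class\n")
        for r in records:
            fh.write(
                f"{r.antigen_id}\t{r.start}\t{r.core}\t{r.allele.name}\t"
                f"{r.allele.locus_group}\t{r.percent_rank:g}\t"
                f"{classify_binder(r, thresholds)}\n"
            )
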