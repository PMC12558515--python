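"""Synthetic antigens, allele panels and calibrated pseudo-%rank predictions.

Every pipeline stage is testable without the external prediction engines:
a synthetic allele is a position-specific scoring matrix (PSSM) over k-mer
cores with a few sharply peaked anchor columns, emulating motif-driven MHC
class II binding.  %Rank is defined exactly as an empirical quantile against
a finite seeded background sample of B peptides,

    rank = 100 * (1 + #{background peptides scoring >= s}) / (B + 1),

so the best achievable rank is 100/(B+1) and a peptide scoring below the
whole background ranks 100.  No parametric score distribution is fitted;
the grid is small, exact and testable.

``plant_motifs`` writes an allele's consensus core into a random antigen at
chosen starts and verifies at generation time that planted windows are
strong binders and all other windows non-binders for their alleles,
retrying with a fresh fill on failure.  The generator's truth is the oracle
for end-to-end hotspot recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .binding import (
    SB,
    BinderThresholds,
    BindingRecord,
    HlaAllele,
    classify_binder,
    infer_locus_group,
)
from .errors import GenerationError, UnsupportedAlleleError, ValidationError
from .sequences import PeptideWindow, ProteinSequence

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

ANCHOR_WEIGHT = 4.0
NOISE_SCALE = 0.05  # sd of non-anchor column weights


@dataclass(frozen=True)
class SyntheticAllelePSSM:
    """A synthetic allele's scoring model.

    ``weights`` is a (k, 20) matrix over :data:`AA_ORDER`; ``anchors`` are
    the 1-based peaked columns; ``background_scores`` is the sorted score
    sample of the B seeded background peptides the %rank quantile is taken
    against.
    """

    name: str
    k: int
    weights: np.ndarray
    anchors: tuple[int, ...]
    background_scores: np.ndarray
    background_freqs: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValidationError("PSSM must have at least one anchor position")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("PSSM weights must be finite")
        if len(self.background_scores) < 100:
            raise ValidationError("background sample size B must be >= 100")

    @property
    def B(self) -> int:
        return len(self.background_scores)

    def score(self, peptide: str) -> float:
        """Sum of per-position weights for a k-mer peptide."""
        if len(peptide) != self.k:
            raise ValidationError(
                f"peptide length {len(peptide)} != PSSM core length {self.k}"
            )
        try:
            idx = [_AA_INDEX[aa] for aa in peptide]
        except KeyError as exc:
            raise ValidationError(f"non-standard residue in peptide {peptide!r}") from exc
        return float(self.weights[np.arange(self.k), idx].sum())

    def consensus(self) -> str:
        """The top-scoring (argmax per column) peptide."""
        return "".join(AA_ORDER[j] for j in self.weights.argmax(axis=1))

    def as_allele(self) -> HlaAllele:
        group, mhc_class = infer_locus_group(self.name)
        if group is None:
            group, mhc_class = "DRB", "II"  # synthetic panels emulate DRB
        return HlaAllele(name=self.name, locus_group=group, mhc_class=mhc_class)


def make_synthetic_allele(
    seed: int,
    k: int = 9,
    n_anchors: int = 3,
    B: int = 1000,
    name: str | None = None,
    background_freqs: Sequence[float] | None = None,
) -> SyntheticAllelePSSM:
    """Deterministically generate a synthetic allele PSSM from a seed.

    Anchor columns carry a single sharply peaked residue (weight
    :data:`ANCHOR_WEIGHT`); non-anchor columns are near-flat Gaussian noise.
    The background sample of B peptides is drawn from ``background_freqs``
    (uniform over the 20 residues by default) with the same seed, so the
    whole model — matrix, anchors and rank calibration — is a pure function
    of its arguments.
    """
    if not 1 <= n_anchors <= k:
        raise ValidationError(f"n_anchors must be in 1..k={k}, got {n_anchors}")
    if B < 100:
        raise ValidationError(f"background sample size B must be >= 100, got {B}")
    rng = np.random.default_rng(seed)
    if background_freqs is None:
        freqs = np.full(20, 1 / 20)
    else:
        freqs = np.asarray(background_freqs, dtype=float)
        if freqs.shape != (20,) or not np.isclose(freqs.sum(), 1.0) or np.any(freqs < 0):
            raise ValidationError("background_freqs must be 20 non-negative values summing to 1")
    weights = rng.normal(0.0, NOISE_SCALE, size=(k, 20))
    anchors = tuple(sorted(int(a) + 1 for a in rng.choice(k, size=n_anchors, replace=False)))
    for a in anchors:
        peak = int(rng.integers(20))
        weights[a - 1, peak] += ANCHOR_WEIGHT
    # background peptides and their scores, drawn with the same generator
    bg = rng.choice(20, size=(B, k), p=freqs)
    bg_scores = weights[np.arange(k)[None, :], bg].sum(axis=1)
    return SyntheticAllelePSSM(
        name=name or f"SYN-{seed:02d}",
        k=k,
        weights=weights,
        anchors=anchors,
        background_scores=np.sort(bg_scores),
        background_freqs=freqs,
        seed=seed,
    )


def pseudo_rank(pssm: SyntheticAllelePSSM, peptide: str, score: float | None = None) -> float:
    """Empirical %rank of a peptide against the PSSM's background sample.

    ``rank = 100 * (1 + m) / (B + 1)`` where m counts background peptides
    scoring >= the peptide (ties count).  Deterministic per (pssm, peptide).
    An explicit ``score`` overrides the peptide's own (used for noise
    perturbation experiments).
    """
    s = pssm.score(peptide) if score is None else float(score)
    # background_scores is sorted ascending: m = B - (# strictly below s)
    m = pssm.B - int(np.searchsorted(pssm.background_scores, s, side="left"))
    return 100.0 * (1 + m) / (pssm.B + 1)


class SyntheticPredictor:
    """Pluggable predictor backed by synthetic PSSMs.

    Satisfies the :class:`~epihotspot.binding.Predictor` contract: one
    record per (window, allele) pair, deterministic for fixed inputs and
    seed.  Flagged ('X'-containing) windows are skipped with a warning,
    never silently dropped.  ``noise_sigma`` adds seeded Gaussian noise to
    scores before ranking, emulating prediction error.
    """

    def __init__(
        self,
        pssms: Sequence[SyntheticAllelePSSM],
        noise_sigma: float = 0.0,
        seed: int = 0,
    ) -> None:
        if noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {noise_sigma}")
        self.pssms = {p.name: p for p in pssms}
        if len(self.pssms) != len(pssms):
            raise ValidationError("duplicate PSSM names in panel")
        self.noise_sigma = noise_sigma
        self.seed = seed

    def predict(
        self,
        windows: Sequence[PeptideWindow],
        alleles: Sequence[HlaAllele] | None = None,
    ) -> list[BindingRecord]:
        if not windows:
            raise ValidationError("predict requires a non-empty window list")
        if alleles is None:
            alleles = [p.as_allele() for p in self.pssms.values()]
        if not alleles:
            raise ValidationError("predict requires a non-empty allele list")
        for allele in alleles:
            if allele.name not in self.pssms:
                raise UnsupportedAlleleError(
                    f"no synthetic model for allele {allele.name!r}; "
                    f"available: {sorted(self.pssms)}"
                )
        skipped = [w for w in windows if w.flagged]
        if skipped:
            warnings.warn(
                f"skipping {len(skipped)} ambiguous ('X'-containing) windows at "
                f"starts {[w.start for w in skipped]}",
                stacklevel=2,
            )
        rng = np.random.default_rng(self.seed)
        records = []
        for allele in alleles:
            pssm = self.pssms[allele.name]
            for w in windows:
                if w.flagged:
                    continue
                s = pssm.score(w.sequence)
                if self.noise_sigma > 0:
                    s += rng.normal(0.0, self.noise_sigma)
                records.append(
                    BindingRecord(
                        allele=allele,
                        antigen_id=w.antigen_id,
                        start=w.start,
                        core=w.sequence,
                        percent_rank=pseudo_rank(pssm, w.sequence, score=s),
                        score=s,
                    )
                )
        return records


@dataclass(frozen=True)
class PlantedTruth:
    """A synthetic antigen with known strong-binding cores per allele."""

    antigen: ProteinSequence
    planted: Mapping[str, frozenset[int]]
    pssms: Mapping[str, SyntheticAllelePSSM]


def plant_motifs(
    length: int,
    plants: Sequence[tuple[int, SyntheticAllelePSSM]],
    seed: int,
    k: int = 9,
    thresholds: BinderThresholds = BinderThresholds(),
    panel: Sequence[SyntheticAllelePSSM] = (),
    max_retries: int = 25,
    allow_overlap: bool = False,
    antigen_id: str = "synthetic_antigen",
) -> PlantedTruth:
    """Generate an antigen with allele consensus cores planted at known starts.

    Every planted window must rank as a strong binder for its allele and
    every other window as a non-binder for every panel allele, verified by
    scoring all windows at generation time.  Because the empirical %rank is
    a background quantile, a few percent of random windows land in the
    weak-binder band by chance; offending windows are repaired by
    re-sampling residues outside the planted spans (bounded inner loop),
    and the whole fill is regenerated on repair failure (bounded retries).
    ``panel`` may list additional alleles to verify (and report truth for)
    beyond those planted.
    """
    pssms: dict[str, SyntheticAllelePSSM] = {}
    for _, pssm in plants:
        pssms[pssm.name] = pssm
    for pssm in panel:
        pssms[pssm.name] = pssm
    truth: dict[str, set[int]] = {name: set() for name in pssms}
    occupied: list[tuple[int, int]] = []
    for start, pssm in plants:
        if not 1 <= start <= length - k + 1:
            raise ValidationError(
                f"plant start {start} outside 1..{length - k + 1} for length {length}"
            )
        span = (start, start + k - 1)
        if not allow_overlap:
            for other in occupied:
                if span[0] <= other[1] and other[0] <= span[1]:
                    raise ValidationError(
                        f"plants overlap at k-mer scale: {span} vs {other}; "
                        "pass allow_overlap=True to permit this"
                    )
        occupied.append(span)
        truth[pssm.name].add(start)

    planted_positions: dict[int, str] = {}
    for start, pssm in plants:
        consensus = pssm.consensus()
        for i, aa in enumerate(consensus):
            planted_positions[start + i] = aa

    n_windows = length - k + 1
    planted_masks = {
        name: np.isin(np.arange(1, n_windows + 1), sorted(starts))
        for name, starts in truth.items()
    }
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        idx = rng.integers(0, 20, size=length)
        for pos, aa in planted_positions.items():
            idx[pos - 1] = _AA_INDEX[aa]
        # repair budget: violations arise at a few percent of windows and
        # almost always resolve within a handful of resamples; a fill that
        # exhausts this budget is treated as infeasible and regenerated
        for _ in range(max(200, 2 * length)):
            start = _first_violation(idx, planted_masks, pssms, k, thresholds)
            if start is None:
                residues = "".join(AA_ORDER[j] for j in idx)
                antigen = ProteinSequence(id=antigen_id, residues=residues)
                return PlantedTruth(
                    antigen=antigen,
                    planted={name: frozenset(starts) for name, starts in truth.items()},
                    pssms=dict(pssms),
                )
            repairable = [p for p in range(start, start + k) if p not in planted_positions]
            if not repairable:
                break  # violation sits entirely inside planted spans: refill
            pos = int(rng.choice(repairable))
            idx[pos - 1] = int(rng.integers(0, 20))
    raise GenerationError(
        f"could not satisfy SB/NB margins after {max_retries} retries; "
        "reduce plant density, increase length, or widen thresholds"
    )


def _first_violation(
    idx: np.ndarray,
    planted_masks: Mapping[str, np.ndarray],
    pssms: Mapping[str, SyntheticAllelePSSM],
    k: int,
    thresholds: BinderThresholds,
) -> int | None:
    """Start of the first window violating the SB/NB contract, else None.

    Vectorized over windows per allele: planted windows must rank SB,
    all others NB.
    """
    windows = np.lib.stride_tricks.sliding_window_view(idx, k)
    cols = np.arange(k)[None, :]
    first: int | None = None
    for name, pssm in pssms.items():
        scores = pssm.weights[cols, windows].sum(axis=1)
        m = pssm.B - np.searchsorted(pssm.background_scores, scores, side="left")
        ranks = 100.0 * (1 + m) / (pssm.B + 1)
        planted = planted_masks[name]
        bad = np.where(
            planted, ranks >= thresholds.sb_rank, ranks < thresholds.wb_rank
        )
        hits = np.nonzero(bad)[0]
        if hits.size and (first is None or hits[0] + 1 < first):
            first = int(hits[0]) + 1
    return first


# --------------------------------------------------------------------------
# Engine-dialect fixture writers.  Files imitate the engines' column layout
# closely enough for the real parsers, with a leading comment marking them
# synthetic; the parsers' round-trip is the correctness oracle.
# --------------------------------------------------------------------------


def _engine_spelling(record: BindingRecord, dialect: str) -> str:
    name = record.allele.name
    if dialect == "netmhcpan41":
        return f"HLA-{name}" if name[0] in "ABC" and "*" in name else name
    if name.startswith("DRB") and "*" in name:
        return name.replace("*", "_").replace(":", "")
    if "-" in name and "*" in name:  # paired alpha-beta form
        return "HLA-" + name.replace("*", "").replace(":", "")
    return name


def write_netmhc_fixture(
    records: Sequence[BindingRecord], dialect: str, path: str | Path
) -> None:
    """Write records in an engine's plain-text layout (marked synthetic).

    Lossless round-trip with :func:`~epihotspot.binding.parse_netmhc_output`
    on allele, antigen id, position, core and %rank (floats are written in
    shortest round-tripping form).  Records without a score are written with
    score 0.0.  Class I positions are written 0-based, matching the engine.
    """
    if dialect not in ("netmhcpan41", "netmhciipan41"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    path = Path(path)
    thresholds = BinderThresholds()
    sep = "-" * 100
    with path.open("w") as fh:
        fh.write(f"# synthetic fixture in {dialect} layout; not engine output\n")
        fh.write(sep + "\n")
        if dialect == "netmhcpan41":
            fh.write(
                " Pos MHC Peptide Core Of Gp Gl Ip Il Icore Identity "
                "Score_EL %Rank_EL BindLevel\n"
            )
        else:
            fh.write(
                " Pos MHC Peptide Of Core Core_Rel Identity Score_EL "
                "%Rank_EL BindLevel\n"
            )
        fh.write(sep + "\n")
        for r in records:
            mhc = _engine_spelling(r, dialect)
            if " " in mhc or " " in r.antigen_id:
                raise ValidationError(
                    f"allele/antigen names must be whitespace-free for fixture "
                    f"output: {mhc!r}, {r.antigen_id!r}"
                )
            score = 0.0 if r.score is None else r.score
            cls = classify_binder(r, thresholds)
            level = f" <= {cls}" if cls in (SB, "WB") else ""
            if dialect == "netmhcpan41":
                fh.write(
                    f"{r.start - 1:>5} {mhc} {r.core} {r.core} 0 0 0 0 0 "
                    f"{r.core} {r.antigen_id} {score!r} {r.percent_rank!r}{level}\n"
                )
            else:
                fh.write(
                    f"{r.start:>5} {mhc} {r.core} 0 {r.core} 1.000 "
                    f"{r.antigen_id} {score!r} {r.percent_rank!r}{level}\n"
                )
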