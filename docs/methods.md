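# Methods

## Model and definitions

The package operates on the standard epitope-prediction abstraction for
MHC class II: although class II molecules accommodate peptides of 12–30
residues, binding specificity is dominated by a 9-residue **core**, so an
antigen of length *L* is enumerated as its *L* − 9 + 1 overlapping 9-mer
windows at 1-based starts.  A prediction engine assigns each (core,
allele) pair a **%rank** — the percentile of the prediction against a
background peptide set, in (0, 100], lower = stronger.  Classification is
strict at both bounds:

* **SB** (strong binder): %rank < `sb_rank` (default 0.5)
* **WB** (weak binder): `sb_rank` ≤ %rank < `wb_rank` (default 2.0)
* **NB** otherwise; boundary values fall into the weaker class.

The 0.5% SB default is used for both class I and class II dialects as the
analysis convention; both bounds are explicit parameters
(`BinderThresholds`) and command-line flags, and are never silently
replaced by engine-specific defaults.

A **hotspot** is a core that is a strong binder for at least
`min_alleles` panel alleles.  The default is `min_alleles = 1` because the
operational definition is per-peptide (an antigen peptide strongly bound
by class II), not per-panel-fraction; stricter panel-level calling is one
argument away.  Adjacent called starts are *not* merged into intervals by
default — the core is the unit of reporting — but `merge_adjacent(gap=g)`
provides region-level merging when wanted.

Profiles come in two modes: `per_start` (default; counts[s] = number of
distinct SB alleles at start *s*, matching position-profile figures whose
x-axis is the peptide start) and `per_residue` (each SB core increments
all nine residues it covers, for residue-level coverage analyses).
Conservation invariants — Σ counts = #SB records (per_start) and
9 × #SB records (per_residue, unclipped) — are tested.

## Topology annotation

Rh proteins are 12-pass membrane proteins of 417 residues.  A topology map
is an ordered, gap-free list of 1-based inclusive intervals labelled
exofacial / transmembrane / intracellular.  Cores receive the label of the
interval containing their **first residue** (`start_residue` rule).  This
rule, not majority overlap, is the one consistent with the published core
labels: the core starting at 358 is labelled exofacial although only its
first residue lies in the 347–358 loop.  A `majority_overlap` rule (ties
broken toward exofacial, then transmembrane) is available for comparison.

Only the exofacial loops (32–53, 94–107, 158–167, 230–231, 282–290,
347–358) are published.  The transmembrane/intracellular boundaries in
`datasets.rhd_topology()` / `rhce_topology()` were fitted once so that the
start-residue rule reproduces the published core labels, and are shipped
as editable data clearly marked as reconstructed — they are a
label-consistent reconstruction, not measured topology.  Two genuine
irregularities in the source labels are preserved rather than harmonized:

1. For RhD, start 390 is labelled intracellular in the DRB column but
   transmembrane in the DQA-DQB column of the same antigen.  No single map
   can satisfy both under a start-keyed rule.  The packaged RhD map starts
   the intracellular C-terminal tail at residue 390 (consistent with the
   DRB label, with the intracellular labels at 391/399/402/406/407, and
   with the cytoplasmic tail of the topology literature); the lone DQA-DQB
   390 entry is the documented exception (`datasets.KNOWN_LABEL_CONFLICTS`)
   and the corresponding full-reproduction acceptance test fails honestly
   at 39/40 labels (97.5%).
2. RhCE labels start 390 transmembrane, so the RhCE map extends the final
   helix through 390 (tail 391–417) and reproduces 41/41 RhCE labels.
   Whether RhCE truly differs here or the source is inconsistent is
   unresolved; per-antigen maps keep both readings.

## Variant differentials

Protein variants are simple HGVS p. substitutions (`p.Val270Gly`);
nucleotide-level labels and indels are out of scope.  `diff_hotspots`
keys on start position and partitions the union of starts into shared /
changed-core / lost / gained; a start present in both lists with different
cores is a *changed core* — the same hotspot with a substituted residue,
reported with the absolute protein position of every differing residue
(start + offset).  `variant_core_changes` gives the windows a substitution
at position *p* can touch (starts max(1, p−8) … min(p, L−8)); changed-core
positions are provably a subset, which is property-tested.

## Population analysis

Allele frequencies are used exactly as reported (allele counts / 2n, in
[0, 1]); no Hardy–Weinberg phenotype conversion is applied.  Blank cells
mean *not typed* and stay missing (NaN), distinct from an observed 0;
untyped alleles never pass the frequency filter and are skipped (with a
warning and a report) in burden sums.  The frequency filter is strict
(`>`) by default with an `inclusive` flag, since both printed conventions
(">10%" and "≥10%") select identical allele sets on the packaged table.
The weighted burden at start *s* is Σ_a f_a · 1[s ∈ SB(a)] — linear in
the frequencies and equal to the SB count profile when all frequencies
are 1 (both property-tested).

## Synthetic prediction stage

The external engines are replaced, for testing and simulation, by a
transparent generative model:

* **Allele model**: a (9 × 20) PSSM with `n_anchors = 3` sharply peaked
  anchor columns (peak weight 4.0) over near-flat noise columns
  (σ = 0.05); a peptide's score is the sum of its per-position weights.
* **%rank**: the empirical quantile against `B = 1000` seeded background
  peptides, `rank = 100 (1 + m)/(B + 1)` with m the count of background
  peptides scoring ≥ the query.  The grid is exact and testable: the best
  achievable rank is 100/(B+1) ≈ 0.0999 (< 0.5, so a clear SB), and a
  score below the whole background ranks 100.  No parametric score
  distribution is fitted.
* **Planted truth**: `plant_motifs` writes allele consensus cores into a
  random antigen at chosen starts and verifies at generation time that
  planted windows rank SB for their allele and every other window NB for
  every panel allele.  Because ranks are background quantiles, a few
  percent of random windows land in the WB band by chance; such windows
  are repaired by re-sampling residues outside planted spans (bounded
  budget), and the fill is regenerated on failure (bounded retries).  A
  residual failure mode is *panel cross-reactivity*: if another panel
  allele ranks a planted consensus inside its own SB/WB band, no fill can
  help, and generation fails with advice to change parameters — callers
  that need an unconditional result (the `simulate` command, the
  acceptance script) deterministically try successive panel seeds.
* **Noise**: `SyntheticPredictor(noise_sigma=σ)` perturbs scores with
  seeded Gaussian noise before ranking; planted-window ranks degrade
  monotonically in σ on average (tested over seeds), and σ = 0 recovery is
  exact by construction.

What the generator does **not** emulate: biophysically realistic binding
energetics, length-variant class II ligands, allele-specific background
distributions, or correlated engine errors.  Passing synthetic tests
therefore demonstrates the correctness of aggregation, calling,
annotation, differential and population arithmetic — not predictive
accuracy on real antigens, which is entirely inherited from the external
engine used.

## Engine output parsing

Two whitespace-aligned tabular dialects are modelled on the engines'
plain-text result layouts: `netmhcpan41` (class I; identified by its
`Icore` column; engine positions are 0-based and shifted +1 on parse) and
`netmhciipan41` (class II; identified by `Core_Rel`; positions are 1-based
peptide starts, and the record's core start is Pos + Of so that a 15-mer
row with an offset core still lands on the right 9-mer, flagged
`core_from_engine`).  Allele spellings are canonicalized
(`DRB1_1501` → `DRB1*15:01`, `HLA-DQA10101-DQB10301` →
`DQA1*01:01-DQB1*03:01`); paired α-β names use a single hyphen.  The
fixture writers invert the parsers exactly, and lossless round-trip of
(allele, antigen, position, core, %rank) is the tested contract.  Parsing
with the wrong dialect fails on the header line; truncated rows fail with
their line number; ambiguous ('X'-containing) windows are skipped with a
warning, never silently.

## Packaged data and scaffolds

All packaged tables are small in-code data: the per-locus hotspot core
lists for the three antigen groups, the 34-allele × 4-population HLA-DRB1
frequency table (with per-allele hotspot assignments per antigen group,
including one verbatim-preserved start/core irregularity noted in the
source), sample sizes, exofacial intervals, and the reconstructed topology
maps.  Because the full reference protein sequences are not part of the
published summary data, sequence-level operations are exercised against a
**synthetic scaffold**: a 417-residue sequence reproducing every published
9-mer core of the normal-RhD group at its stated start (overlapping cores
are verified mutually consistent at build time) with seeded random fill
elsewhere.  It is named and documented as synthetic; real analyses should
supply reference FASTA for the named transcripts.  No RhCE scaffold is
shipped: the published RhCE cores are not mutually consistent at overlap
(e.g. the cores at starts 62 and 64 disagree at residue 68), so a
faithful scaffold cannot be constructed from them.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 200-residue synthetic
antigens, panels of 3–5 alleles, B = 1000 background peptides, 100-record
parser round-trips — sizes at which every oracle (brute-force loops,
background recounts, substring extraction) is exact and the whole suite
runs in seconds.  Every stochastic component (PSSM generation, background
sampling, antigen fill, predictor noise) is a pure function of an explicit
seed; the pipeline records seed, config hash and input checksums in its
manifest, and identical configs reproduce byte-identical tables.
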