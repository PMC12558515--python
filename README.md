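# epihotspot

T-cell epitope **hotspot** mapping for blood-group antigens from
peptide–MHC class II binding predictions.

## The problem

Alloimmunization — antibody formation against non-self red-cell antigens
after transfusion or pregnancy — begins when antigen-presenting cells
digest transfused red cells and display antigen-derived peptides on MHC
class II (HLA-DR/DQ/DP) molecules to CD4⁺ T cells.  Whether a recipient's
HLA repertoire can present a given antigen peptide is therefore a
candidate predictor of immunogenicity.  `epihotspot` turns per-peptide,
per-allele **%rank** binding predictions (e.g. NetMHCpan-4.1 /
NetMHCIIpan-4.1 output) into position-level answers for antigens such as
the Rh blood-group proteins RhD and RhCE:

* per-position **strong-binder profiles**: for each 9-mer core start *s*,
  the number of panel alleles with %rank < 0.5 (the strong-binder bound);
* **hotspot calls** — cores strongly bound by at least `min_alleles` panel
  alleles (default 1, matching a per-peptide definition of a hotspot);
* **membrane-topology annotation** of each core (exofacial /
  transmembrane / intracellular) under the start-residue rule;
* **variant differentials**, e.g. weak D type 1 (p.Val270Gly) versus
  normal RhD: shared cores, changed cores (with the absolute position of
  every substituted residue), lost and gained hotspots;
* **population summaries** from allele-frequency tables: frequency
  filtering and the frequency-weighted burden
  `burden(s) = Σ_a f_a · 1[core at s is a strong binder for allele a]`.

The binding predictors themselves are external and pluggable: the package
parses their tabular output, and ships a fully synthetic predictor (PSSM
scoring with an empirical %rank calibrated against a seeded background
sample) so that every pipeline stage is testable with planted ground truth
and no external tool.

## Worked example

```python
import epihotspot as eh
from epihotspot import datasets as ds

# hotspot counts per antigen group and HLA class II locus group
print(eh.summarize_by_locus(ds.hotspot_tables_by_locus()).to_string(index=False))
```

```
  antigen locus_group  n_hotspots
  RHCE*01     DPA-DPB          11
  RHCE*01     DQA-DQB          15
  RHCE*01         DRB          15
   RHD*01     DPA-DPB          12
   RHD*01     DQA-DQB          13
   RHD*01         DRB          15
RHD*01W.1     DPA-DPB           9
RHD*01W.1     DQA-DQB          13
RHD*01W.1         DRB          15
```

The normal-RhD allele group (`RHD*01` here covers RHD*01, 01.01, 01W.2 and
01W.3, which share identical hotspots) carries 15 hotspots under HLA-DRB
but 13 under HLA-DQA-DQB — immunogenic potential depends on the HLA locus,
not only the antigen.  The weak D type 1 differential:

```python
diff = eh.diff_hotspots(
    ds.rh_hotspot_calls(ds.RHD_NORMAL, ds.DRB),
    ds.rh_hotspot_calls(ds.RHD_WEAK_D1, ds.DRB),
)
print(diff.changed_core)
# (CoreChange(start=269, ref_core='YVHSAVLAG', cmp_core='YGHSAVLAG',
#             changed_positions=(270,)),)
```

The variant keeps every DRB hotspot but substitutes one residue (Val270Gly)
inside the core starting at 269; under DPA-DPB it instead loses the three
hotspots at starts 264, 267 and 269 whose cores covered the substituted
site.  More narrative walk-throughs live in `examples/` (one script per
capability; each prints its numbers and what they mean).

A shell interface mirrors the library (`epihotspot peptides / parse /
profile / call / heatmap / annotate / diff / population / simulate / run`);
`epihotspot run --config run.yaml` executes the whole pipeline and writes a
manifest with config hash, seed and input checksums, so identical configs
reproduce byte-identical tables.

## Data and caveats

Packaged tables (hotspot core lists, the 34-allele HLA-DRB1 frequency
table on the 2n-alleles basis, exofacial loop intervals) are published
summary data; transmembrane/intracellular topology boundaries are a
reconstruction fitted to the published core labels, and the full-length
antigen sequences shipped for sequence-level operations are clearly
labelled synthetic scaffolds, not reference proteins — supply your own
FASTA for real analyses.  See `docs/methods.md` for the model, parameter
and design details, including the one published region label the
reconstructed RhD map cannot reproduce because the source table is
internally inconsistent at that position.
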