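"""Summarize the packaged Rh hotspot lists per HLA class II locus group.

A hotspot is a 9-mer core of the antigen that at least one HLA class II
allele of the panel is predicted to bind strongly (%rank < 0.5).  The
packaged lists cover the normal-RhD allele group (RHD*01 / 01.01 / 01W.2 /
01W.3, which share identical hotspots), the weak D type 1 allele
(RHD*01W.1, p.Val270Gly) and RHCE*01, for the DRB, DQA-DQB and DPA-DPB
locus groups.
"""

import epihotspot as eh
from epihotspot import datasets as ds

summary = eh.summarize_by_locus(ds.hotspot_tables_by_locus())
print(summary.to_string(index=False))
print()
print("Each row counts distinct strong-binding core start positions for one")
print("antigen allele group under one HLA class II locus group; e.g. the")
print("normal-RhD group carries 15 DRB hotspots but only 13 DQA-DQB ones,")
print("so predicted immunogenicity differs by HLA locus, not just antigen.")
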