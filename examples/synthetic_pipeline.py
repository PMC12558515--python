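"""End-to-end run on synthetic data with known ground truth.

Builds a panel of synthetic alleles (each a PSSM with sharply peaked anchor
columns and an empirically calibrated %rank), plants their consensus cores
into a random antigen at known starts, predicts %ranks for every 9-mer
window, and checks that hotspot calling recovers exactly the planted
positions.
"""

import epihotspot as eh

panel = [eh.make_synthetic_allele(seed=100 + i) for i in range(5)]
plants = [(10, panel[0]), (60, panel[1]), (120, panel[2])]
truth = eh.plant_motifs(200, plants, seed=42, panel=panel)

records = eh.SyntheticPredictor(panel, seed=42).predict(
    eh.enumerate_peptides(truth.antigen)
)
profile = eh.build_profile(records, antigen_length=200)
calls = eh.call_hotspots(profile, sequence=truth.antigen)

planted = sorted(set().union(*truth.planted.values()))
print(f"planted starts:   {planted}")
print(f"called hotspots:  {[c.start for c in calls]}")
for c in calls:
    print(f"  start {c.start}: core {c.core}, strong binder for "
          f"{c.n_alleles_sb} of {len(panel)} panel alleles")
print()
print("With noise-free synthetic predictions the generator guarantees that")
print("planted windows rank below the 0.5% strong-binder bound and all other")
print("windows above the 2% weak-binder bound, so recovery is exact:")
print(f"recovered == planted: {sorted(c.start for c in calls) == planted}")
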