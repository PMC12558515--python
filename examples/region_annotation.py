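"""Classify hotspot cores into membrane regions of the RhD protein.

The packaged RhD topology map combines the published exofacial loop
intervals (32-53, 94-107, 158-167, 230-231, 282-290, 347-358) with
reconstructed transmembrane/intracellular boundaries.  A core is labelled
by the region containing its first residue (start-residue rule): a core
starting on the last exofacial residue still counts as exofacial, which is
the convention the published labels follow.
"""

import epihotspot as eh
from epihotspot import datasets as ds

tmap = ds.rhd_topology()
calls = ds.rh_hotspot_calls(ds.RHD_NORMAL, ds.DRB)
print(f"{'start':>5} {'core':<11} {'published':<14} predicted")
for call in calls:
    predicted = eh.classify_region(call.start, tmap)
    flag = "" if predicted == call.region else "  <- differs"
    print(f"{call.start:>5} {call.core:<11} {call.region:<14} {predicted}{flag}")

print()
print("Exofacial hotspots face the plasma; transmembrane and intracellular")
print("ones only become accessible after the red cell is phagocytosed and")
print("processed, which is how class II presentation works anyway.")
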