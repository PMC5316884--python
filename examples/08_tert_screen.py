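"""TERT promoter hotspot mapping and the recurrence-status screen.

Maps the two activating hotspot offsets (-124, -146) to genomic
coordinates relative to the minus-strand TERT TSS, then tabulates mutation
frequency by recurrence status for a screen with 4 hits among 31 recurrent
samples and none among 110 primary samples.
"""

import pandas as pd

from meningomics.stats import (
    TERT_STRAND,
    TERT_TSS,
    TertCall,
    tert_offset_to_coord,
    tert_recurrence_report,
)

for offset, label in ((-124, "C228T"), (-146, "C250T")):
    pos = tert_offset_to_coord(TERT_TSS, TERT_STRAND, offset)
    print(f"{label}: offset {offset} -> chr5:{pos:,}")

sheet = pd.DataFrame(
    {
        "sample_id": [f"rec{i}" for i in range(31)] + [f"prim{i}" for i in range(110)],
        "recurrence": ["recurrent"] * 31 + ["primary"] * 110,
    }
)
calls = [
    TertCall("rec0", "recurrent", -124, tert_offset_to_coord(TERT_TSS, "-", -124), "C228T"),
    TertCall("rec1", "recurrent", -146, tert_offset_to_coord(TERT_TSS, "-", -146), "C250T"),
    TertCall("rec2", "recurrent", -124, tert_offset_to_coord(TERT_TSS, "-", -124), "C228T"),
    TertCall("rec3", "recurrent", -124, tert_offset_to_coord(TERT_TSS, "-", -124), "C228T"),
]
print(tert_recurrence_report(calls, sheet).to_string(index=False))
# The hotspots land on chr5:1,295,228 and chr5:1,295,250; 4/31 recurrent
# samples (13%) carry a hotspot while 0/110 primary samples do — the
# signature of progression-associated rather than de novo atypia.
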