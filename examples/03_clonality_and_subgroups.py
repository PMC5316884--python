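"""Cancer-cell fraction of a driver mutation and driver-subgroup labels.

An NF2 frameshift on the lost chr22q arm (copy number 1) in a 60%-pure
tumour should read out as fully clonal once VAF is corrected for purity and
local copy number; the subgroup assigner then combines the variant with the
chr22 status.
"""

import pandas as pd

from meningomics.variants import VariantRecord, assign_driver_subgroup, clonality

purity = 0.6
# expected VAF for a clonal mutation on the retained chr22 copy:
# p*1 / (p*1 + (1-p)*2) = 0.6/1.4 ~ 0.43
record = VariantRecord(
    chrom="chr22", pos=65_000_000, ref="C", alt="T",
    tumour_ref_depth=86, tumour_alt_depth=64, normal_ref_depth=90, normal_alt_depth=0,
    tumour_gl=(-30.0, 0.0, -20.0), normal_gl=(0.0, -30.0, -60.0),
    qual=200.0, qd=10.0, gene="NF2", protein_change="p.Trp60fs",
)
est = clonality(record, purity=purity, tumour_cn=1)
print(f"VAF {est.vaf:.3f}, multiplicity {est.multiplicity}, CCF {est.ccf:.2f}")

variants = pd.DataFrame(
    {"gene": ["NF2", "SMARCB1"], "protein_change": ["p.Trp60fs", "p.Arg383Gln"]}
)
print("subgroup:", assign_driver_subgroup(variants, chr22_loss=True, nf2_loss=True))
print("subgroup without SMARCB1:",
      assign_driver_subgroup(variants.iloc[:1], chr22_loss=True, nf2_loss=True))
# CCF near 1.0 marks the NF2 hit as an early, clonal event; the recurrent
# SMARCB1 p.Arg383Gln hotspot on top of NF2 loss yields the NF2/SMARCB1 label.
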