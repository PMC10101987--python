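"""Longitudinal phospho-flow marker shifts on the arcsinh-ratio scale.

Transforms serial-sample marker medians into arcsinh ratios relative to an
isotype reference (reference maps to zero), reports each marker's T1-vs-T0
change as an integer percent, and clusters the sample x marker matrix
(Manhattan distance, Ward linkage) the way a heatmap would order it.
Anti-apoptotic markers rising severalfold at progression on a Bcl-2
antagonist is the classic resistance signature this view surfaces.
"""

import numpy as np
import pandas as pd

from cllscreen import FlowMarkerTable, marker_heatmap_matrix, percent_relative

# medians chosen so T0/T1 land near ratios reported for a venetoclax-relapse
# profile: Bcl-2 (pS70) 0.28 -> 1.97, Bcl-2 2.65 -> 4.16, Mcl-1 0.38 -> 1.92
cofactor = 150.0
markers = ["Bcl-2 (pS70)", "Bcl-2", "Mcl-1", "Bcl-xL"]
ref = pd.Series(10.0, index=markers)
target = pd.DataFrame(
    {"Bcl-2 (pS70)": [0.28, 1.97], "Bcl-2": [2.65, 4.16],
     "Mcl-1": [0.38, 1.92], "Bcl-xL": [2.49, 2.99]},
    index=["T0", "T1"],
)
# invert the transform to get medians that reproduce those ratios exactly
medians = cofactor * np.sinh(target + np.arcsinh(ref / cofactor))
table = FlowMarkerTable(medians=medians, reference=ref, cofactor=cofactor)

ratios = table.arcsinh_ratios()
print("arcsinh ratios (reference = 0):")
print(ratios.round(2).to_string())
print("\nT1 as percent of T0:")
for m in markers:
    pct = percent_relative(ratios.loc["T1", m], ratios.loc["T0", m])
    print(f"  {m}: {pct}%")

hm = marker_heatmap_matrix(table)
print("\nheatmap column order (Ward/Manhattan):",
      list(ratios.columns[hm.col_order]))
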