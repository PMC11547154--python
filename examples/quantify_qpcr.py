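"""ddCt relative expression and qMSP methylation from a raw Ct table.

Builds a four-well toy experiment, quantifies a target gene against a
reference with a calibrator sample, and a methylation-specific locus
against a fully methylated control.
"""

import pandas as pd

from lncmeth import qmsp_level, relative_expression

rows = []
for sample, assay, ct in [
    ("tumor", "GAS5", 24.0), ("tumor", "B2M", 20.0),
    ("normal", "GAS5", 22.0), ("normal", "B2M", 20.0),
    # qMSP wells: methylated-specific locus + converted-template ACTB
    ("tumor", "meth_GAS5", 27.0), ("tumor", "ACTB_conv", 24.0),
    ("CTRL100", "meth_GAS5", 26.0), ("CTRL100", "ACTB_conv", 24.0),
]:
    for rep in (1, 2, 3):
        rows.append((sample, assay, rep, ct))
ct_table = pd.DataFrame(rows, columns=["sample", "assay", "replicate", "ct"])

(level,) = relative_expression(ct_table, "GAS5", "B2M",
                               case_samples=["tumor"],
                               calibrator_samples=["normal"])
print(f"ddCt = {level.delta_delta_ct:+.2f}, fold = {level.fold:.3f}, "
      f"classified '{level.classification}'")
# ddCt = +2 means the tumor runs two cycles late: a fourfold drop, well
# past the twofold retention boundary, hence 'down'.

(meth,) = qmsp_level(ct_table, "meth_GAS5", "CTRL100", samples=["tumor"])
print(f"PMR = {meth.pmr:.1f}% (conversion ok: {meth.conversion_ok})")
# One cycle above the 100%-methylated control halves the signal: PMR 50%.
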