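"""Assemble a ceRNA (lncRNA/miRNA/mRNA) triplet from screened edges.

Plants a sponge chain -- a lncRNA negatively coupled to a miRNA which in
turn represses an EMT driver -- screens the three edge types, and joins
them under the ceRNA sign pattern.
"""

from lncmeth import (
    ScreenConfig,
    TripletConfig,
    build_triplets,
    screen_partners,
    simulate_expression_matrix,
)

network = [
    ("MAGI2-AS3", "miR-33b-5p", -0.85),   # sponge edge
    ("miR-33b-5p", "ZEB1", -0.7),         # repression edge
    ("MAGI2-AS3", "SERPINF1", 0.55),      # unrelated positive partner
]
matrix = simulate_expression_matrix(150, network, seed=2, n_background=30)
mrnas = [g for g in matrix.index if g not in ("MAGI2-AS3", "miR-33b-5p")]

lnc_mi = screen_partners(matrix, ["MAGI2-AS3"], ScreenConfig.mirna_default(),
                         partners=["miR-33b-5p"])
mi_mrna = screen_partners(
    matrix, ["miR-33b-5p"],
    ScreenConfig(rs_threshold=-0.4, p_threshold=0.05, sign="negative"),
    partners=mrnas,
)
lnc_mrna = screen_partners(matrix, ["MAGI2-AS3"],
                           ScreenConfig(rs_threshold=0.4, p_threshold=1e-5),
                           partners=mrnas)

for t in build_triplets(lnc_mi, mi_mrna, lnc_mrna, config=TripletConfig()):
    print(f"{t.lncrna} / {t.mirna} / {t.mrna}")
    print(f"  lnc~miR rs={t.lnc_mi.rs:+.2f}  miR~mRNA rs={t.mi_mrna.rs:+.2f}  "
          f"lnc~mRNA rs={t.lnc_mrna.rs:+.2f}")
# The sign pattern (-, -, +) is the ceRNA signature: the lncRNA and the
# mRNA rise and fall together because they compete for the same miRNA.
# Note the SERPINF1 triplet rides along: any mRNA positively coupled to
# the lncRNA inherits a negative correlation with the sponged miRNA, so
# correlation-only triplets overcall -- sequence evidence (seed sites,
# require_seed_on_mrna) is the gate that separates the direct target.
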