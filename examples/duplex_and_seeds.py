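"""Complementarity search between transcripts and miRNA seed-site calls.

Plants a 32-nt reverse-complement segment of a lncRNA inside an mRNA,
enumerates complementary sites with the local aligner, and classifies the
seed sites of a miRNA on the same mRNA.
"""

from lncmeth import (
    PlantedSite,
    SequenceSpec,
    classify_seed,
    enumerate_sites,
    simulate_sequences,
)
from lncmeth.align import ScoringScheme

spec = SequenceSpec(
    length_range=(1231, 1231),
    planted_sites=(
        PlantedSite("MRNA", "LNC", "revcomp", 32, 200),
        PlantedSite("MRNA", "MIR", "seed:8mer", 8, 600),
        PlantedSite("MRNA", "MIR", "seed:6mer", 8, 900),
    ),
    guest_lengths={"LNC": 32, "MIR": 22},
    seed=3,
)
seqs = {r.id: str(r.seq) for r in simulate_sequences(spec)}

report = enumerate_sites(seqs["LNC"], seqs["MRNA"],
                         ScoringScheme(min_site_score=40),
                         query_id="LNC", subject_id="MRNA")
print(f"{len(report.sites)} complementary site(s); "
      f"total matched nt = {report.total_matched}, "
      f"proportion of mRNA = {report.proportion:.3f}")
# 32 matched nucleotides over a 1231-nt mRNA gives proportion 0.026 --
# the site-count / proportion pair used to rank transcript pairs.

for s in classify_seed(seqs["MIR"], seqs["MRNA"],
                       mirna_id="MIR", target_id="MRNA"):
    print(f"  seed site at {s.position}: {s.site_type}")
# The 8mer (positions 2-8 paired + A opposite position 1) is the
# strongest canonical site type; the 6mer pairs positions 2-7 only.
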