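"""Assembly of candidate lncRNA/miRNA/mRNA ceRNA triplets.

Under the competing-endogenous-RNA model a lncRNA and an mRNA share
response elements for a common miRNA and titrate it away from each other,
which predicts a characteristic correlation sign pattern: lncRNA-miRNA
negative, miRNA-mRNA negative, lncRNA-mRNA positive.  ``build_triplets``
is a relational join over three screened edge lists under configurable
rs/p bounds, with optional sequence-site evidence (seed sites on the
lncRNA and/or the mRNA) attached and, when required, enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from lncmeth.align import SeedSite
from lncmeth.screen import CorrelationHit


@dataclass(frozen=True)
class TripletConfig:
    """Edge bounds for triplet assembly.  Defaults mirror empirical gates
    reported for clinical-sample RT-qPCR correlations (lnc-miR rs <= -0.3,
    p < 0.05; miR-mRNA rs <= -0.4; lnc-mRNA rs >= +0.3)."""

    lnc_mi_rs_max: float = -0.3
    lnc_mi_p: float = 0.05
    mi_mrna_rs_max: float = -0.4
    mi_mrna_p: float = 0.05
    lnc_mrna_rs_min: float = 0.3
    lnc_mrna_p: float = 0.05
    require_seed_on_lnc: bool = False
    require_seed_on_mrna: bool = False

    def __post_init__(self) -> None:
        if self.lnc_mi_rs_max > 0 or self.mi_mrna_rs_max > 0:
            raise ValueError("negative-edge bounds must be <= 0")
        if self.lnc_mrna_rs_min < 0:
            raise ValueError("lnc_mrna_rs_min must be >= 0")


@dataclass(frozen=True)
class Edge:
    rs: float
    p: float
    seed_evidence: bool = False


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna: str
    mirna: str
    mrna: str
    lnc_mi: Edge
    mi_mrna: Edge
    lnc_mrna: Edge

    @property
    def min_abs_rs(self) -> float:
        return min(abs(self.lnc_mi.rs), abs(self.mi_mrna.rs), abs(self.lnc_mrna.rs))


def _seed_pairs(sites: Iterable[SeedSite] | None) -> set[tuple[str, str]]:
    if sites is None:
        return set()
    return {(s.mirna_id, s.target_id) for s in sites}


def build_triplets(
    lnc_mi: Sequence[CorrelationHit],
    mi_mrna: Sequence[CorrelationHit],
    lnc_mrna: Sequence[CorrelationHit],
    lnc_seed_sites: Iterable[SeedSite] | None = None,
    mrna_seed_sites: Iterable[SeedSite] | None = None,
    config: TripletConfig | None = None,
) -> list[CeRNATriplet]:
    """Join the three edge lists into sign-consistent ceRNA triplets.

    ``lnc_mi`` hits pair a lncRNA with a miRNA (expected negative),
    ``mi_mrna`` a miRNA with an mRNA under the miRNA's repression
    (negative; the hit's ``lncrna`` field holds the miRNA id), and
    ``lnc_mrna`` a lncRNA with an mRNA (positive).  A triplet is emitted
    iff all three edges exist and satisfy the config bounds; seed-site
    evidence on the lncRNA/mRNA is attached when present and enforced when
    required.  Output is sorted by the minimum |rs| across the three
    edges, descending (ties broken lexicographically).
    """
    config = config or TripletConfig()
    lnc_seeds = _seed_pairs(lnc_seed_sites)
    mrna_seeds = _seed_pairs(mrna_seed_sites)

    lm = {
        (h.lncrna, h.partner): h for h in lnc_mi
        if h.rs <= config.lnc_mi_rs_max and h.p < config.lnc_mi_p
    }
    mm = {
        (h.lncrna, h.partner): h for h in mi_mrna
        if h.rs <= config.mi_mrna_rs_max and h.p < config.mi_mrna_p
    }
    lr = {
        (h.lncrna, h.partner): h for h in lnc_mrna
        if h.rs >= config.lnc_mrna_rs_min and h.p < config.lnc_mrna_p
    }

    out: list[CeRNATriplet] = []
    for (lnc, mi), h_lm in lm.items():
        for (mi2, mrna), h_mm in mm.items():
            if mi2 != mi:
                continue
            h_lr = lr.get((lnc, mrna))
            if h_lr is None:
                continue
            seed_lnc = (mi, lnc) in lnc_seeds
            seed_mrna = (mi, mrna) in mrna_seeds
            if config.require_seed_on_lnc and not seed_lnc:
                continue
            if config.require_seed_on_mrna and not seed_mrna:
                continue
            out.append(
                CeRNATriplet(
                    lncrna=lnc, mirna=mi, mrna=mrna,
                    lnc_mi=Edge(h_lm.rs, h_lm.p, seed_lnc),
                    mi_mrna=Edge(h_mm.rs, h_mm.p, seed_mrna),
                    lnc_mrna=Edge(h_lr.rs, h_lr.p, False),
                )
            )
    out.sort(key=lambda t: (-t.min_abs_rs, t.lncrna, t.mirna, t.mrna))
    return out
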