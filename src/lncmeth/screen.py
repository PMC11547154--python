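"""Co-expression partner screening and EMT gene-set intersection.

A screen evaluates every (lncRNA, candidate partner) pair in an
expression matrix (genes x samples) with Spearman rank correlation and
retains hits passing a signed coefficient bound and a p bound.  Default
thresholds follow common practice for GEO-derived co-expression screens:
rs > 0.4 with p < 1e-8 for mRNA partners at n ~ 131 samples, and
rs < -0.6 with p < 0.0025 for miRNA partners from small-n miRNA profiling.

Screened partner lists are intersected with EMT gene sets (GMT-format
files); the report carries the correlated count, intersected count, and
the percentage rounded to two significant figures, matching how such
tables are printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from lncmeth.stats import spearman


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for one screening run."""

    rs_threshold: float = 0.4
    p_threshold: float = 1e-8
    sign: str = "positive"           # positive | negative | both
    partner_class: str = "mRNA"      # mRNA | miRNA

    def __post_init__(self) -> None:
        if not abs(self.rs_threshold) < 1:
            raise ValueError("|rs_threshold| must be < 1")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.sign not in ("positive", "negative", "both"):
            raise ValueError(f"unknown sign {self.sign!r}")

    @classmethod
    def mirna_default(cls) -> "ScreenConfig":
        return cls(rs_threshold=-0.6, p_threshold=0.0025,
                   sign="negative", partner_class="miRNA")


@dataclass(frozen=True)
class CorrelationHit:
    lncrna: str
    partner: str
    partner_class: str
    rs: float
    p: float
    direction: str


@dataclass(frozen=True)
class IntersectionReport:
    lncrna: str
    gene_set: str
    n_correlated: int
    n_intersected: int
    percentage: float | None
    intersected: tuple[str, ...]


def _passes(rs: float, p: float, config: ScreenConfig) -> bool:
    if np.isnan(rs) or np.isnan(p) or p >= config.p_threshold:
        return False
    thr = abs(config.rs_threshold)
    if config.sign == "positive":
        return rs > thr
    if config.sign == "negative":
        return rs < -thr
    return abs(rs) > thr


def screen_partners(
    matrix: pd.DataFrame,
    lncrnas: Sequence[str],
    config: ScreenConfig | None = None,
    partners: Sequence[str] | None = None,
    min_shared_samples: int = 5,
    include_lncrna_pairs: bool = False,
) -> list[CorrelationHit]:
    """Screen candidate partners of each lncRNA by rank correlation.

    ``matrix`` has genes as rows and samples as columns.  Self-pairs and
    lncRNA-lncRNA pairs are excluded unless requested.  Missing values are
    dropped pairwise; pairs with fewer than ``min_shared_samples`` shared
    samples are skipped.
    """
    config = config or ScreenConfig()
    for lnc in lncrnas:
        if lnc not in matrix.index:
            raise ValueError(f"lncRNA {lnc!r} absent from the expression matrix")
    cand = list(partners) if partners is not None else list(matrix.index)
    lnc_set = set(lncrnas)
    hits: list[CorrelationHit] = []
    for lnc in lncrnas:
        x = matrix.loc[lnc]
        for partner in cand:
            if partner == lnc:
                continue
            if partner in lnc_set and not include_lncrna_pairs:
                continue
            y = matrix.loc[partner]
            mask = x.notna() & y.notna()
            if int(mask.sum()) < min_shared_samples:
                continue
            res = spearman(x[mask], y[mask])
            if _passes(res.rs, res.p, config):
                hits.append(
                    CorrelationHit(
                        lncrna=lnc, partner=partner,
                        partner_class=config.partner_class,
                        rs=res.rs, p=res.p,
                        direction="positive" if res.rs > 0 else "negative",
                    )
                )
    return hits


def round2sf(x: float) -> float:
    """Two significant figures, round-half-to-even (matches printed tables:
    41.8 -> 42, 6.16 -> 6.2, 2.44 -> 2.4)."""
    return float(f"{x:.2g}")


def intersect_gene_sets(
    hits: Sequence[CorrelationHit] | Sequence[str],
    gene_set: Iterable[str],
    set_name: str,
    lncrna: str | None = None,
) -> IntersectionReport:
    """Intersect a screened partner list with a gene set.

    ``hits`` may be CorrelationHit records (all sharing one lncRNA and one
    direction) or plain symbol lists.  Matching is by exact symbol after
    uppercase normalisation.  The percentage 100 * k / n is rounded to two
    significant figures; with an empty hit list it is undefined (None).
    """
    if hits and isinstance(hits[0], CorrelationHit):
        lncs = {h.lncrna for h in hits}
        dirs = {h.direction for h in hits}
        if len(lncs) > 1 or len(dirs) > 1:
            raise ValueError("hits must share one lncRNA and one direction")
        lncrna = lncrna or next(iter(lncs))
        symbols = [h.partner for h in hits]
    else:
        symbols = [str(s) for s in hits]
        lncrna = lncrna or ""
    norm = {s.upper() for s in symbols}
    gs = {str(s).upper() for s in gene_set}
    inter = sorted(norm & gs)
    n = len(norm)
    k = len(inter)
    pct = round2sf(100.0 * k / n) if n else None
    return IntersectionReport(
        lncrna=lncrna, gene_set=set_name,
        n_correlated=n, n_intersected=k,
        percentage=pct, intersected=tuple(inter),
    )


def rank_lncrna_activity(
    reports: Sequence[IntersectionReport],
) -> pd.DataFrame:
    """Order lncRNAs by regulatory 'activity': correlated-partner count
    and gene-set-intersected count (ties broken alphabetically).  Returns
    a frame with both rankings."""
    df = pd.DataFrame(
        [
            {
                "lncrna": r.lncrna,
                "gene_set": r.gene_set,
                "n_correlated": r.n_correlated,
                "n_intersected": r.n_intersected,
                "percentage": r.percentage,
            }
            for r in reports
        ]
    )
    if df.empty:
        df["rank_by_correlated"] = []
        df["rank_by_intersected"] = []
        return df
    df = df.sort_values(
        ["n_correlated", "lncrna"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank_by_correlated"] = np.arange(1, len(df) + 1)
    order_int = df.sort_values(
        ["n_intersected", "lncrna"], ascending=[False, True]
    ).index
    ranks = pd.Series(np.arange(1, len(df) + 1), index=order_int)
    df["rank_by_intersected"] = ranks.sort_index().to_numpy()
    return df


def partners_shared_by_all(
    hits: Sequence[CorrelationHit], lncrnas: Sequence[str]
) -> list[str]:
    """Partners (typically miRNAs) hit by *every* listed lncRNA -- the
    all-lncRNA intersection filter used to shortlist broadly coupled
    miRNAs."""
    by_partner: dict[str, set[str]] = {}
    for h in hits:
        by_partner.setdefault(h.partner, set()).add(h.lncrna)
    need = set(lncrnas)
    return sorted(p for p, ls in by_partner.items() if need <= ls)


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT gene-set file: name TAB description TAB symbol..."""
    sets: dict[str, tuple[str, set[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = (parts[1], {s.upper() for s in parts[2:] if s})
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([name, desc, *sorted(set(symbols))])
        for name, (desc, symbols) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hits_to_frame(hits: Sequence[CorrelationHit]) -> pd.DataFrame:
    return pd.DataFrame([vars(h) for h in hits])
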