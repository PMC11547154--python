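"""Smith-Waterman local alignment in identity and complementarity mode,
iterative complementary-site enumeration, and miRNA seed-site taxonomy.

Complementarity mode asks how well two transcripts could base-pair: the
subject is reverse-complemented and then aligned with the standard local
dynamic program, so a "match" is a Watson-Crick pair on the original
strands.  All sequences are handled in DNA alphabet; U is mapped to T on
input.  G:U wobble pairing is off by default (the site metrics count
strict complementary identities) but can be enabled through the scoring
scheme.

Site enumeration repeats the alignment, masking the footprint of each
accepted site on both sequences, until no alignment reaches the minimum
site score.  The report carries the two metrics used for transcript-pair
ranking: the summed count of complementary nucleotides over all sites, and
that count divided by the subject (mRNA) length.

Seed-site classification scans a target for the canonical site types
defined by pairing of miRNA positions 1-8 (numbered from the 5' end):

- 6mer: positions 2-7 paired;
- 7mer-A1: positions 2-7 paired and an A in the target opposite
  position 1 (the A is recognised as A regardless of the miRNA base);
- 7mer-m8: positions 2-8 paired;
- 8mer: positions 2-8 paired plus the A opposite position 1;
- 7mer-m8 g-bulged: positions 2-8 paired with exactly one unpaired G
  bulged out on the target side inside the seed span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")

#: default priority when one target position satisfies several types
SEED_PRIORITY = ("8mer", "7mer-m8", "7mer-A1", "6mer", "7mer-m8 g-bulged")


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring. Linear gap penalty; ``wobble_gt`` (score for
    G:T pairs in complementarity mode, i.e. G:U on the RNA level) is
    disabled when None."""

    match: float = 2.0
    mismatch: float = -3.0
    gap: float = -5.0
    wobble_gt: float | None = None
    min_site_score: float = 12.0
    min_site_length: int = 6
    max_sites: int = 50

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap > 0:
            raise ValueError("mismatch and gap scores must be <= 0")
        if self.min_site_length < 4:
            raise ValueError("min_site_length must be >= 4")


@dataclass(frozen=True)
class Alignment:
    """One local alignment. Coordinates are 0-based half-open on the
    sequences as given (for complementarity mode, ``b_start``/``b_end``
    refer to the original subject strand)."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str
    matches: int

    @property
    def empty(self) -> bool:
        return self.score <= 0


@dataclass(frozen=True)
class DuplexSite:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: float
    matched_nucleotides: int
    aligned_a: str
    aligned_b: str


@dataclass(frozen=True)
class DuplexReport:
    query_id: str
    subject_id: str
    sites: tuple[DuplexSite, ...]
    total_matched: int
    proportion: float


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    target_id: str
    position: int        # 0-based start of the matched target span
    end: int             # half-open end of the span
    site_type: str


def clean_seq(seq: str, name: str = "sequence") -> str:
    """Uppercase, map U->T, validate the alphabet (A, C, G, T, N)."""
    s = str(seq).upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise ValueError(f"illegal character {ch!r} at position {i} of {name}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _pair_score(x: str, y: str, scheme: ScoringScheme) -> float:
    if x == "N" or y == "N":
        return -1e9  # masked: can never be part of a site
    if x == y:
        return scheme.match
    if scheme.wobble_gt is not None and {x, y} == {"G", "T"}:
        return scheme.wobble_gt
    return scheme.mismatch


def _sw_core(a: str, b: str, scheme: ScoringScheme) -> Alignment:
    """Standard local DP with deterministic traceback.

    Tie-break on the best cell: smallest end coordinates (row-major scan).
    Tie-break on moves: diagonal, then up (gap in b), then left (gap in a).
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=float)
    # move codes: 0 stop, 1 diag, 2 up, 3 left
    P = np.zeros((n + 1, m + 1), dtype=np.int8)
    best, bi, bj = 0.0, 0, 0
    gap = scheme.gap
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi = H[i]
        Hp = H[i - 1]
        Pi = P[i]
        for j in range(1, m + 1):
            diag = Hp[j - 1] + _pair_score(ai, b[j - 1], scheme)
            up = Hp[j] + gap
            left = Hi[j - 1] + gap
            s, mv = 0.0, 0
            if diag >= s and diag >= up and diag >= left:
                if diag > 0:
                    s, mv = diag, 1
            elif up >= left:
                if up > 0:
                    s, mv = up, 2
            else:
                if left > 0:
                    s, mv = left, 3
            Hi[j] = s
            Pi[j] = mv
            if s > best:
                best, bi, bj = s, i, j
    if best <= 0:
        return Alignment(0.0, 0, 0, 0, 0, "", "", 0)
    # traceback
    i, j = bi, bj
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 and j > 0 and P[i, j] != 0:
        mv = P[i, j]
        if mv == 1:
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif mv == 2:
            ra.append(a[i - 1]); rb.append("-"); i -= 1
        else:
            ra.append("-"); rb.append(b[j - 1]); j -= 1
    aligned_a = "".join(reversed(ra))
    aligned_b = "".join(reversed(rb))
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return Alignment(
        score=float(best), a_start=i, a_end=bi, b_start=j, b_end=bj,
        aligned_a=aligned_a, aligned_b=aligned_b, matches=matches,
    )


def smith_waterman(
    a: str,
    b: str,
    scheme: ScoringScheme | None = None,
    mode: str = "identity",
) -> Alignment:
    """Best local alignment of ``a`` against ``b``.

    In ``complementarity`` mode ``b`` is reverse-complemented before the
    DP and the reported subject coordinates are mapped back to the
    original strand, so the aligned span of ``b`` is the segment that
    would base-pair with the aligned span of ``a``.  ``matches`` then
    counts complementary base pairs.
    """
    if mode not in ("identity", "complementarity"):
        raise ValueError(f"unknown mode {mode!r}")
    scheme = scheme or ScoringScheme()
    a = clean_seq(a, "query")
    b = clean_seq(b, "subject")
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if mode == "identity":
        return _sw_core(a, b, scheme)
    brc = revcomp(b)
    aln = _sw_core(a, brc, scheme)
    if aln.empty:
        return aln
    m = len(b)
    return replace(aln, b_start=m - aln.b_end, b_end=m - aln.b_start)


def enumerate_sites(
    a: str,
    b: str,
    scheme: ScoringScheme | None = None,
    mode: str = "complementarity",
    query_id: str = "query",
    subject_id: str = "subject",
) -> DuplexReport:
    """Iterative best-site extraction with masking.

    After each accepted site its footprint is masked (N) on both working
    sequences and the DP repeats, until the best score drops below
    ``min_site_score`` or ``max_sites`` is reached.  Alignments shorter
    than ``min_site_length`` on either sequence are masked without being
    accepted.  ``total_matched`` counts complementary pairs only (gaps and
    mismatches excluded); ``proportion`` divides by the subject length.
    """
    scheme = scheme or ScoringScheme()
    wa = clean_seq(a, "query")
    wb = clean_seq(b, "subject")
    subject_len = len(wb)
    work_a = list(wa)
    # complementarity: operate on the reverse complement throughout and map
    # coordinates at the end, so masking coordinates stay internal
    comp = mode == "complementarity"
    work_b = list(revcomp(wb)) if comp else list(wb)
    sites: list[DuplexSite] = []
    while len(sites) < scheme.max_sites:
        aln = _sw_core("".join(work_a), "".join(work_b), scheme)
        if aln.score < scheme.min_site_score or aln.empty:
            break
        for i in range(aln.a_start, aln.a_end):
            work_a[i] = "N"
        for j in range(aln.b_start, aln.b_end):
            work_b[j] = "N"
        span_a = aln.a_end - aln.a_start
        span_b = aln.b_end - aln.b_start
        if min(span_a, span_b) < scheme.min_site_length:
            continue  # masked but not accepted
        if comp:
            b_start, b_end = subject_len - aln.b_end, subject_len - aln.b_start
        else:
            b_start, b_end = aln.b_start, aln.b_end
        sites.append(
            DuplexSite(
                a_start=aln.a_start, a_end=aln.a_end,
                b_start=b_start, b_end=b_end,
                score=aln.score, matched_nucleotides=aln.matches,
                aligned_a=aln.aligned_a, aligned_b=aln.aligned_b,
            )
        )
    total = sum(s.matched_nucleotides for s in sites)
    return DuplexReport(
        query_id=query_id,
        subject_id=subject_id,
        sites=tuple(sorted(sites, key=lambda s: (s.a_start, s.b_start))),
        total_matched=total,
        proportion=total / subject_len,
    )


def _complement(ch: str) -> str:
    return ch.translate(_COMPLEMENT)


def _gbulge_patterns(site7: str) -> list[str]:
    """All 8-mers formed by inserting one G strictly inside the 7-nt
    perfect-complement span (the bulged target G is unpaired)."""
    out = []
    for k in range(1, len(site7)):
        pat = site7[:k] + "G" + site7[k:]
        out.append(pat)
    return sorted(set(out))


def classify_seed(
    mirna: str,
    target: str,
    mirna_id: str = "mirna",
    target_id: str = "target",
    priority: Sequence[str] = SEED_PRIORITY,
) -> list[SeedSite]:
    """Scan ``target`` for seed sites of ``mirna``.

    A target site is written 5'->3' and pairs antiparallel with the miRNA
    5' region, so the base opposite miRNA position 1 sits at the 3' end of
    the site.  For each candidate location the strongest applicable type
    under ``priority`` is reported; overlapping reports of weaker types at
    the same core are suppressed.
    """
    m = clean_seq(mirna, "mirna")
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt for seed classification")
    t = clean_seq(target, "target")
    core6 = revcomp(m[1:7])      # complement of positions 2-7
    comp_m8 = _complement(m[7])  # base pairing miRNA position 8
    found: dict[tuple[int, int], str] = {}

    # canonical types anchored on the 6mer core
    start = t.find(core6)
    while start != -1:
        has_m8 = start > 0 and t[start - 1] == comp_m8
        has_a1 = start + 6 < len(t) and t[start + 6] == "A"
        if has_m8 and has_a1:
            typ, lo, hi = "8mer", start - 1, start + 7
        elif has_m8:
            typ, lo, hi = "7mer-m8", start - 1, start + 6
        elif has_a1:
            typ, lo, hi = "7mer-A1", start, start + 7
        else:
            typ, lo, hi = "6mer", start, start + 6
        found[(lo, hi)] = typ
        start = t.find(core6, start + 1)

    # bulged variant: positions 2-8 paired with one extra target G inside
    site7 = revcomp(m[1:8])
    for pat in _gbulge_patterns(site7):
        start = t.find(pat)
        while start != -1:
            span = (start, start + 8)
            if span not in found:
                found[span] = "7mer-m8 g-bulged"
            start = t.find(pat, start + 1)

    order = {typ: k for k, typ in enumerate(priority)}
    # suppress weaker types whose span is contained in a stronger site's span
    spans = sorted(found.items(), key=lambda kv: (order.get(kv[1], 99), kv[0]))
    kept: list[tuple[tuple[int, int], str]] = []
    for (lo, hi), typ in spans:
        shadowed = any(
            lo >= klo and hi <= khi and order.get(ktyp, 99) < order.get(typ, 99)
            for (klo, khi), ktyp in kept
        )
        if not shadowed:
            kept.append(((lo, hi), typ))
    kept.sort(key=lambda kv: kv[0])
    return [
        SeedSite(mirna_id=mirna_id, target_id=target_id,
                 position=lo, end=hi, site_type=typ)
        for (lo, hi), typ in kept
    ]
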