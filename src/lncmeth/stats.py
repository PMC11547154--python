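"""Cohort statistics: Mann-Whitney group comparisons with BH-FDR and
significance tiers, Spearman methylation-expression correlation, binary
hypermethylation calls, and a clinical-table summarizer.

The central container is the *cohort frame*: one row per tissue sample with

- ``sample``, ``patient`` keys and ``tissue`` class in {D, N, T, PM}
  (donor ovary, matched histologically normal, primary tumor, peritoneal
  metastasis);
- clinical covariates ``stage`` (I..IV), ``t_stage`` (T1..T3), ``nodal``
  (N0..N3), ``m_stage`` (M0/M1), ``grade`` (G1..G4), boolean
  ``peritoneal_met``, ``omental_met``, ``ascites``, ``any_met``,
  ``histology``, survival ``time_months`` + ``event``;
- per-gene columns ``meth_<GENE>`` (PMR, 0-100 scale) and ``expr_<GENE>``
  (log2 relative expression).

Comparison designs mirror the figure designs of tumor-methylation cohort
studies: tumor vs normal, tumor vs donor, paired PM vs primary tumor,
early vs late stage, tumor extent, grade, per-metastasis-type flags,
ascites and any-metastasis.  Each design is tested per gene with the
Mann-Whitney U, BH-adjusted across the gene panel, and assigned the
conventional significance tiers (* p<0.05, ** p<0.01, *** p<0.001,
# p<0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

TISSUES = ("D", "N", "T", "PM")
STAGES = ("I", "II", "III", "IV")

#: tier thresholds, strongest first
TIER_THRESHOLDS = (("#", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2))


@dataclass(frozen=True)
class ComparisonResult:
    gene: str
    design: str
    n1: int
    n2: int
    U: float
    p: float
    q: float
    tier: str


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    rs: float
    p: float
    n: int


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) where U is the statistic of the first group.  The
    p-value is exact (full enumeration) when n1 + n2 <= 20 and there are
    no ties, otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0:
        raise ValueError("group 'a' is empty")
    if b.size == 0:
        raise ValueError("group 'b' is empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= 20 and no_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Adjustments attach to the original input positions; values are clipped
    at 1 and monotone-enforced from the largest rank down.  NaN inputs are
    rejected.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed in bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x: Sequence[float], y: Sequence[float], gene: str = "") -> CorrelationResult:
    """Spearman rank correlation with midrank ties and t-approximation p.

    With zero variance in either rank vector the coefficient is undefined
    and reported as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman requires n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(gene=gene, rs=float("nan"), p=float("nan"), n=int(x.size))
    rs, p = sps.spearmanr(x, y)
    return CorrelationResult(gene=gene, rs=float(rs), p=float(p), n=int(x.size))


def significance_tier(p: float) -> str:
    """Figure-caption tiers: # p<0.0001, *** p<0.001, ** p<0.01, * p<0.05."""
    for tier, thr in TIER_THRESHOLDS:
        if p < thr:
            return tier
    return "ns"


def meth_col(gene: str) -> str:
    return f"meth_{gene}"


def expr_col(gene: str) -> str:
    return f"expr_{gene}"


def _genes_in_frame(frame: pd.DataFrame) -> list[str]:
    return [c[len("meth_"):] for c in frame.columns if c.startswith("meth_")]


# design label -> how to split samples into (group1, group2)
DESIGNS = (
    "T_vs_N",
    "T_vs_D",
    "PM_vs_T_paired",
    "stage_I_II_vs_III_IV",
    "T1_T2_vs_T3",
    "G1_G2_vs_G3_G4",
    "lymphatic_met",
    "distant_met",
    "peritoneal_met",
    "omental_met",
    "ascites",
    "any_met",
)


def _design_groups(frame: pd.DataFrame, design: str, column: str) -> tuple[pd.Series, pd.Series, str]:
    """Return the two value series for a design plus a note.

    Group 1 is the 'higher burden' group (tumor, late stage, with
    metastasis ...), group 2 the comparator.
    """
    t = frame[frame["tissue"] == "T"]
    if design == "T_vs_N":
        return t[column], frame.loc[frame["tissue"] == "N", column], ""
    if design == "T_vs_D":
        return t[column], frame.loc[frame["tissue"] == "D", column], ""
    if design == "PM_vs_T_paired":
        pm = frame[frame["tissue"] == "PM"]
        common = sorted(set(pm["patient"]) & set(t["patient"]))
        pm_v = pm.set_index("patient").loc[common, column]
        t_v = t.set_index("patient").loc[common, column]
        return pm_v, t_v, f"paired on {len(common)} patients"
    if design == "stage_I_II_vs_III_IV":
        late = t[t["stage"].isin(["III", "IV"])]
        early = t[t["stage"].isin(["I", "II"])]
        return late[column], early[column], ""
    if design == "T1_T2_vs_T3":
        return (
            t.loc[t["t_stage"] == "T3", column],
            t.loc[t["t_stage"].isin(["T1", "T2"]), column],
            "",
        )
    if design == "G1_G2_vs_G3_G4":
        return (
            t.loc[t["grade"].isin(["G3", "G4"]), column],
            t.loc[t["grade"].isin(["G1", "G2"]), column],
            "",
        )
    if design == "lymphatic_met":
        return (
            t.loc[t["nodal"] != "N0", column],
            t.loc[t["nodal"] == "N0", column],
            "",
        )
    if design == "distant_met":
        return (
            t.loc[t["m_stage"] == "M1", column],
            t.loc[t["m_stage"] == "M0", column],
            "",
        )
    if design in ("peritoneal_met", "omental_met", "ascites", "any_met"):
        flag = t[design].astype(bool)
        return t.loc[flag, column], t.loc[~flag, column], ""
    raise ValueError(f"unknown design {design!r}; known designs: {DESIGNS}")


def compare_design(
    frame: pd.DataFrame,
    design: str,
    genes: Sequence[str] | None = None,
    variable: str = "meth",
) -> list[ComparisonResult]:
    """Per-gene Mann-Whitney comparison for one cohort design.

    One BH family per design across the gene panel.  ``variable`` selects
    methylation (``meth``, PMR) or expression (``expr``, log2 fold)
    columns.  An empty stratum raises with the observed stratum sizes.
    """
    genes = list(genes) if genes is not None else _genes_in_frame(frame)
    col = meth_col if variable == "meth" else expr_col
    raw: list[tuple[str, int, int, float, float]] = []
    for g in genes:
        g1, g2, _ = _design_groups(frame, design, col(g))
        g1 = g1.dropna()
        g2 = g2.dropna()
        if len(g1) == 0 or len(g2) == 0:
            raise ValueError(
                f"design {design!r} has an empty stratum for gene {g!r}: "
                f"sizes ({len(g1)}, {len(g2)})"
            )
        U, p = mann_whitney(g1.to_numpy(), g2.to_numpy())
        raw.append((g, len(g1), len(g2), U, p))
    qvals = bh_adjust([r[4] for r in raw])
    return [
        ComparisonResult(
            gene=g, design=design, n1=n1, n2=n2, U=U, p=p,
            q=float(q), tier=significance_tier(p),
        )
        for (g, n1, n2, U, p), q in zip(raw, qvals)
    ]


def methylation_expression_correlation(
    frame: pd.DataFrame,
    genes: Sequence[str] | None = None,
    tissues: Sequence[str] = ("T", "N"),
) -> list[CorrelationResult]:
    """Spearman correlation of PMR against log2 expression per gene,
    computed over the samples of the given tissue classes."""
    genes = list(genes) if genes is not None else _genes_in_frame(frame)
    sub = frame[frame["tissue"].isin(tissues)]
    out = []
    for g in genes:
        pair = sub[[meth_col(g), expr_col(g)]].dropna()
        out.append(spearman(pair[meth_col(g)], pair[expr_col(g)], gene=g))
    return out


def hypermethylation_calls(
    frame: pd.DataFrame,
    genes: Sequence[str] | None = None,
    reference_tissues: Sequence[str] = ("N", "D"),
    percentile: float = 95.0,
    tissue: str = "T",
) -> pd.DataFrame:
    """Binary hypermethylation call per tumor sample and gene.

    A tumor is called methylation-positive for a gene when its PMR exceeds
    the given percentile of the pooled normal + donor reference
    distribution for that gene.  The percentile is configurable; no
    consensus cutoff exists for tumor hypermethylation calls.
    """
    genes = list(genes) if genes is not None else _genes_in_frame(frame)
    ref = frame[frame["tissue"].isin(reference_tissues)]
    tum = frame[frame["tissue"] == tissue]
    if len(ref) == 0:
        raise ValueError(f"no reference samples in tissues {reference_tissues}")
    calls = pd.DataFrame(index=tum["sample"].to_numpy())
    for g in genes:
        thr = np.percentile(ref[meth_col(g)].dropna(), percentile)
        calls[g] = (tum[meth_col(g)] > thr).to_numpy()
    calls.index.name = "sample"
    return calls


def _round2sf(x: float) -> float:
    # two significant figures, round-half-to-even (IEEE formatting)
    return float(f"{x:.2g}")


def summarize_clinical(frame: pd.DataFrame) -> dict:
    """Composition summary of the clinical table (primary tumors).

    Reports sample counts per tissue class and the histology breakdown of
    primary tumors, with percentages printed to two significant figures
    (e.g. 106 serous of 140 -> 76%).
    """
    t = frame[frame["tissue"] == "T"]
    n_t = len(t)
    counts = frame["tissue"].value_counts().to_dict()
    hist = t["histology"].value_counts().to_dict() if "histology" in t else {}
    hist_pct = {k: _round2sf(100.0 * v / n_t) for k, v in hist.items()} if n_t else {}
    summary = {
        "n_samples": int(len(frame)),
        "tissue_counts": {k: int(v) for k, v in counts.items()},
        "n_tumors": int(n_t),
        "histology_counts": {k: int(v) for k, v in hist.items()},
        "histology_percent": hist_pct,
    }
    if "stage" in t:
        summary["stage_counts"] = {k: int(v) for k, v in t["stage"].value_counts().to_dict().items()}
    return summary


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
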