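"""Seeded synthetic data with the statistical structure of a lncRNA-gene
methylation cohort study.

The generator emulates a clinical design of 140 primary epithelial
ovarian tumors (T) with 123 matched histologically normal tissues (N),
59 peritoneal metastases (PM) paired to primary tumors of the same
patients, and 18 cancer-free donor ovaries (D).  Ten lncRNA genes are
profiled.  Planted structure:

- tumor-vs-normal hypermethylation of all ten genes (beta-distributed
  percent-methylated-reference levels, mean shift per gene);
- additional metastasis-type-specific shifts (lymphatic: HAND2-AS1;
  peritoneal: KCNK15-AS1, MEG3, SEMA3B-AS1; omental: MEG3, SEMA3B-AS1,
  ZNF667-AS1);
- a *reversal* in peritoneal metastases: five genes (MEG3, SEMA3B-AS1,
  SSTR5-AS1, ZEB1-AS1, ZNF667-AS1) drop back below their primary-tumor
  level in PM samples;
- inverse methylation-expression coupling (log2 expression = intercept +
  slope * methylation fraction + Gaussian noise, slope < 0), tuned to a
  Spearman rs of roughly -0.4 .. -0.8;
- overall survival with an exponential hazard multiplied by a per-gene
  hazard ratio for methylation-positive tumors (survival genes:
  SEMA3B-AS1, SSTR5-AS1, ZNF667-AS1) under uniform censoring.

Clinical covariates (stage, extent, grade, nodal/distant status,
peritoneal/omental/ascites flags, serous histology fraction) are drawn to
match the marginal composition of such a cohort and are coupled to the
metastasis flags so that stage/grade comparisons inherit signal.

All outputs are deterministic functions of the spec and its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from lncmeth.align import clean_seq, revcomp, _complement
from lncmeth.stats import meth_col, expr_col

LNCRNA_GENES = (
    "GAS5", "HAND2-AS1", "KCNK15-AS1", "MAGI2-AS3", "MEG3",
    "SEMA3B-AS1", "SNHG6", "SSTR5-AS1", "ZEB1-AS1", "ZNF667-AS1",
)

METASTASIS_TYPES = ("lymphatic", "peritoneal", "omental", "distant")

#: genes whose methylation reverts (drops) in peritoneal metastases
PM_REVERSAL_GENES = ("MEG3", "SEMA3B-AS1", "SSTR5-AS1", "ZEB1-AS1", "ZNF667-AS1")

#: genes whose hypermethylation carries a survival hazard
SURVIVAL_GENES = ("SEMA3B-AS1", "SSTR5-AS1", "ZNF667-AS1")

#: six-gene metastasis marker panel
PANEL_GENES = ("GAS5", "KCNK15-AS1", "MEG3", "SEMA3B-AS1", "ZEB1-AS1", "ZNF667-AS1")

_DEFAULT_MET_SHIFT: dict[tuple[str, str], float] = {
    ("HAND2-AS1", "lymphatic"): 0.12,
    ("KCNK15-AS1", "peritoneal"): 0.12,
    ("MEG3", "peritoneal"): 0.12,
    ("SEMA3B-AS1", "peritoneal"): 0.12,
    ("MEG3", "omental"): 0.12,
    ("SEMA3B-AS1", "omental"): 0.12,
    ("ZNF667-AS1", "omental"): 0.12,
}

_HISTOLOGIES = ("serous", "endometrioid", "mucinous", "clear_cell", "undifferentiated")
_HISTOLOGY_P = (106 / 140, 21 / 140, 8 / 140, 4 / 140, 1 / 140)


def _as_gene_map(value: float | Mapping[str, float], genes: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {g: float(value.get(g, 0.0)) for g in genes}
    return {g: float(value) for g in genes}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Shifts are on the methylation *fraction* scale (the PMR scale divided
    by 100).  ``metastasis_shift`` maps (gene, metastasis type) to an
    extra shift applied to tumors of patients with that metastasis;
    ``pm_reversal`` maps gene to a signed shift applied on top of the
    patient's tumor mean in the PM sample.  ``survival_hazard_ratio``
    multiplies the baseline hazard for each gene called
    methylation-positive in the tumor.
    """

    n_patients: int = 140
    n_normals: int = 123
    n_donors: int = 18
    n_pm_samples: int = 59
    fraction_with_metastasis: Mapping[str, float] = field(
        default_factory=lambda: {
            "lymphatic": 30 / 140,
            "peritoneal": 70 / 140,
            "omental": 70 / 140,
            "distant": 15 / 140,
        }
    )
    gene_panel: Sequence[str] = LNCRNA_GENES
    baseline_methylation: float | Mapping[str, float] = 0.10
    methylation_shift_normal_to_tumor: float | Mapping[str, float] = 0.30
    metastasis_shift: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_MET_SHIFT)
    )
    pm_reversal: Mapping[str, float] = field(
        default_factory=lambda: {g: -0.20 for g in PM_REVERSAL_GENES}
    )
    beta_concentration: float = 8.0
    coupling_slope: float | Mapping[str, float] = -4.0
    expression_intercept: float = 1.0
    noise_sd: float = 1.0
    survival_hazard_ratio: Mapping[str, float] = field(
        default_factory=lambda: {g: 2.0 for g in SURVIVAL_GENES}
    )
    baseline_hazard: float = 0.0008    # events per month
    follow_up_months: float = 180.0
    censoring_rate: float = 0.3
    # tumor PMR above this drives the hazard; set near the reference-tissue
    # 95th percentile so the generative call matches the analysis call
    hyper_pmr_threshold: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0 <= self.n_normals <= self.n_patients:
            raise ValueError("n_normals must lie in 0..n_patients")
        if self.n_pm_samples > self.n_patients:
            raise ValueError("n_pm_samples cannot exceed n_patients")
        for k, v in dict(self.fraction_with_metastasis).items():
            if k not in METASTASIS_TYPES:
                raise ValueError(f"unknown metastasis type {k!r}")
            if not 0 <= v <= 1:
                raise ValueError(f"fraction_with_metastasis[{k!r}] outside [0, 1]")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if self.noise_sd <= 0 or not np.isfinite(self.noise_sd):
            raise ValueError("noise_sd must be positive and finite")
        if self.beta_concentration <= 0:
            raise ValueError("beta_concentration must be positive")
        slopes = _as_gene_map(self.coupling_slope, self.gene_panel)
        for g, s in slopes.items():
            if not np.isfinite(s):
                raise ValueError(f"coupling_slope[{g!r}] is not finite")
            if s > 0:
                raise ValueError(
                    f"coupling_slope[{g!r}] must be <= 0 for inverse coupling"
                )
        for name in ("baseline_methylation", "methylation_shift_normal_to_tumor"):
            vals = _as_gene_map(getattr(self, name), self.gene_panel)
            if not all(np.isfinite(v) for v in vals.values()):
                raise ValueError(f"{name} contains non-finite values")


def _beta_pmr(rng: np.random.Generator, mean: float, conc: float, size: int) -> np.ndarray:
    m = float(np.clip(mean, 0.02, 0.95))
    return 100.0 * rng.beta(m * conc, (1 - m) * conc, size=size)


def simulate_cohort(
    spec: CohortSpec, make_ct: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Generate a cohort frame and, optionally, a raw Ct table.

    The returned frame holds one row per tissue sample (D/N/T/PM) with the
    clinical covariates and per-gene ``meth_<GENE>`` (PMR, 0-100) and
    ``expr_<GENE>`` (log2 relative expression) columns.  When ``make_ct``
    is true, a long-format Ct table is emitted whose quantification with
    the qPCR module reproduces the planted levels exactly (triplicate
    wells with symmetric +-0.1-cycle offsets; qMSP anchored to a
    ``FULLY_METH`` control sample; an undetermined unconverted-ACTB assay
    marks complete bisulfite conversion).
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_panel)
    base = _as_gene_map(spec.baseline_methylation, genes)
    shift = _as_gene_map(spec.methylation_shift_normal_to_tumor, genes)
    slopes = _as_gene_map(spec.coupling_slope, genes)
    met_shift = {(g, t): float(v) for (g, t), v in dict(spec.metastasis_shift).items()}
    pm_rev = {g: float(v) for g, v in dict(spec.pm_reversal).items()}
    n = spec.n_patients

    # --- clinical covariates -------------------------------------------------
    flags = {
        t: rng.random(n) < spec.fraction_with_metastasis.get(t, 0.0)
        for t in METASTASIS_TYPES
    }
    any_met = np.logical_or.reduce([flags[t] for t in METASTASIS_TYPES])
    stage = np.empty(n, dtype=object)
    t_stage = np.empty(n, dtype=object)
    grade = np.empty(n, dtype=object)
    for i in range(n):
        if flags["distant"][i]:
            stage[i] = "IV"
        elif any_met[i]:
            stage[i] = rng.choice(["II", "III"], p=[0.12, 0.88])
        else:
            stage[i] = rng.choice(["I", "II", "III"], p=[0.50, 0.30, 0.20])
        if any_met[i]:
            t_stage[i] = rng.choice(["T2", "T3"], p=[0.15, 0.85])
        else:
            t_stage[i] = rng.choice(["T1", "T2", "T3"], p=[0.45, 0.30, 0.25])
        g_p = [0.15, 0.25, 0.55, 0.05] if any_met[i] else [0.40, 0.35, 0.24, 0.01]
        grade[i] = rng.choice(["G1", "G2", "G3", "G4"], p=g_p)
    nodal = np.where(flags["lymphatic"], "N1", "N0")
    m_stage = np.where(flags["distant"], "M1", "M0")
    ascites = np.where(
        flags["peritoneal"], rng.random(n) < 0.55, rng.random(n) < 0.25
    )
    histology = rng.choice(_HISTOLOGIES, size=n, p=_HISTOLOGY_P)

    patients = [f"P{i + 1:03d}" for i in range(n)]
    normal_patients = sorted(rng.choice(n, size=spec.n_normals, replace=False))
    # PM samples preferentially from patients with peritoneal spread
    perit_idx = np.flatnonzero(flags["peritoneal"])
    other_idx = np.flatnonzero(~flags["peritoneal"])
    if perit_idx.size >= spec.n_pm_samples:
        pm_patients = sorted(rng.choice(perit_idx, size=spec.n_pm_samples, replace=False))
    else:
        extra = rng.choice(
            other_idx, size=spec.n_pm_samples - perit_idx.size, replace=False
        )
        pm_patients = sorted(np.concatenate([perit_idx, extra]))

    # --- methylation means per patient/tissue --------------------------------
    tumor_mean = {
        g: base[g]
        + shift[g]
        + sum(
            met_shift.get((g, t), 0.0) * flags[t].astype(float)
            for t in METASTASIS_TYPES
        )
        for g in genes
    }

    rows: list[dict] = []

    def expr_from_meth(g: str, pmr: np.ndarray) -> np.ndarray:
        return (
            spec.expression_intercept
            + slopes[g] * (pmr / 100.0)
            + rng.normal(0.0, spec.noise_sd, size=pmr.size)
        )

    def add_samples(tissue: str, idx: Sequence[int], mean_of) -> None:
        idx = list(idx)
        meth = {
            g: np.concatenate(
                [_beta_pmr(rng, mean_of(g, i), spec.beta_concentration, 1) for i in idx]
            )
            if idx else np.empty(0)
            for g in genes
        }
        expr = {g: expr_from_meth(g, meth[g]) for g in genes}
        for k, i in enumerate(idx):
            row = {
                "sample": f"{tissue}_{patients[i]}",
                "patient": patients[i],
                "tissue": tissue,
                "stage": stage[i],
                "t_stage": t_stage[i],
                "nodal": nodal[i],
                "m_stage": m_stage[i],
                "grade": grade[i],
                "histology": histology[i],
                "lymphatic_met": bool(flags["lymphatic"][i]),
                "peritoneal_met": bool(flags["peritoneal"][i]),
                "omental_met": bool(flags["omental"][i]),
                "distant_met": bool(flags["distant"][i]),
                "ascites": bool(ascites[i]),
                "any_met": bool(any_met[i]),
            }
            for g in genes:
                row[meth_col(g)] = float(meth[g][k])
                row[expr_col(g)] = float(expr[g][k])
            rows.append(row)

    add_samples("T", range(n), lambda g, i: tumor_mean[g][i])
    add_samples("N", normal_patients, lambda g, i: base[g])
    add_samples("PM", pm_patients, lambda g, i: tumor_mean[g][i] + pm_rev.get(g, 0.0))

    # donors: no patient pairing, same marginal as normals
    donor_rows_start = len(rows)
    for d in range(spec.n_donors):
        row = {
            "sample": f"D_{d + 1:03d}", "patient": f"D{d + 1:03d}", "tissue": "D",
            "stage": None, "t_stage": None, "nodal": None, "m_stage": None,
            "grade": None, "histology": None,
            "lymphatic_met": False, "peritoneal_met": False,
            "omental_met": False, "distant_met": False,
            "ascites": False, "any_met": False,
        }
        rows.append(row)
    if spec.n_donors:
        for g in genes:
            vals = _beta_pmr(rng, base[g], spec.beta_concentration, spec.n_donors)
            ex = expr_from_meth(g, vals)
            for k in range(spec.n_donors):
                rows[donor_rows_start + k][meth_col(g)] = float(vals[k])
                rows[donor_rows_start + k][expr_col(g)] = float(ex[k])

    frame = pd.DataFrame(rows)

    # --- survival -------------------------------------------------------------
    hr = {g: float(v) for g, v in dict(spec.survival_hazard_ratio).items()}
    tum = frame[frame["tissue"] == "T"].set_index("patient")
    log_hr = np.zeros(n)
    for g, ratio in hr.items():
        pos = tum.loc[patients, meth_col(g)].to_numpy() > spec.hyper_pmr_threshold
        log_hr += np.log(ratio) * pos
    lam = spec.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / lam)
    censor = np.where(
        rng.random(n) < spec.censoring_rate,
        rng.uniform(1e-3, spec.follow_up_months, size=n),
        spec.follow_up_months,
    )
    time = np.minimum(t_event, censor)
    event = t_event <= censor
    surv = pd.DataFrame(
        {"patient": patients, "time_months": time, "event": event}
    )
    frame = frame.merge(surv, on="patient", how="left")

    ct = _emit_ct_table(frame, genes) if make_ct else None
    return frame, ct


def _emit_ct_table(frame: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Back-compute a raw triplicate Ct table from the planted levels.

    qMSP: the FULLY_METH control has (Ct_locus - Ct_ACTB) = 2.0; a sample
    with PMR p gets delta-Ct = 2 - log2(p / 100).  Expression: reference
    Ct fixed at 20, target Ct = 20 - log2-expression, so any ddCt against
    a calibrator reproduces the planted log2 differences.
    """
    records: list[tuple] = []
    offsets = (-0.1, 0.0, 0.1)

    def wells(sample: str, assay: str, ct: float) -> None:
        for r, off in enumerate(offsets, start=1):
            records.append((sample, assay, r, ct + off if np.isfinite(ct) else np.nan))

    # control sample anchoring 100% methylation
    wells("FULLY_METH", "ACTB_conv", 24.0)
    for g in genes:
        wells("FULLY_METH", f"meth_{g}", 26.0)

    for _, row in frame.iterrows():
        s = row["sample"]
        wells(s, "ACTB_conv", 24.0)
        wells(s, "ACTB_unconv", np.nan)  # complete conversion: no signal
        wells(s, "B2M", 20.0)
        for g in genes:
            pmr = row[meth_col(g)]
            dct = 2.0 - np.log2(pmr / 100.0) if pmr > 0 else np.nan
            wells(s, f"meth_{g}", 24.0 + dct if np.isfinite(dct) else np.nan)
            wells(s, f"expr_{g}", 20.0 - row[expr_col(g)])
    return pd.DataFrame(records, columns=["sample", "assay", "replicate", "ct"])


# ---------------------------------------------------------------------------
# expression matrices with planted correlation edges
# ---------------------------------------------------------------------------

def simulate_expression_matrix(
    n_samples: int,
    network: Sequence[tuple],
    seed: int,
    n_background: int = 0,
    background_prefix: str = "BG",
) -> pd.DataFrame:
    """Genes x samples matrix with planted Spearman correlation edges.

    ``network`` lists edges ``(source, partner, target_rs)`` (a trailing
    sign element is accepted and ignored; the sign lives in ``target_rs``,
    |target_rs| < 1).  Each new source is a latent standard normal; a
    partner is built with the Pearson coefficient rho = 2 sin(pi * rs / 6)
    that yields the requested Spearman rs under bivariate normality.
    Edges may chain (a partner may later act as a source, inducing the
    transitive correlations a real regulatory cascade produces), but a
    gene may be *defined* as a partner only once -- duplicate partner or
    background identifiers are rejected.  Undeclared pairs not linked
    through a chain are independent.
    """
    rng = np.random.default_rng(seed)
    edges = []
    for e in network:
        src, partner, rs = str(e[0]), str(e[1]), float(e[2])
        if not abs(rs) < 1:
            raise ValueError(f"|target rs| must be < 1 for edge {src}->{partner}")
        edges.append((src, partner, rs))
    partners = [p for _, p, _ in edges]
    bg = [f"{background_prefix}{i + 1:04d}" for i in range(n_background)]
    sources = [s for s, _, _ in edges if s not in set(partners)]
    all_names = list(dict.fromkeys(sources)) + partners + bg
    if len(set(all_names)) != len(all_names):
        dup = sorted({x for x in all_names if all_names.count(x) > 1})
        raise ValueError(f"duplicate gene identifiers: {dup}")

    data: dict[str, np.ndarray] = {}
    for src, partner, rs in edges:
        if src not in data:
            data[src] = rng.standard_normal(n_samples)
        if partner in data:
            raise ValueError(
                f"gene {partner!r} defined as a partner after being used as a "
                "source; order chain edges source-first"
            )
        rho = 2.0 * np.sin(np.pi * rs / 6.0)
        eps = rng.standard_normal(n_samples)
        data[partner] = rho * data[src] + np.sqrt(1.0 - rho**2) * eps
    for b in bg:
        data[b] = rng.standard_normal(n_samples)
    cols = [f"S{i + 1:04d}" for i in range(n_samples)]
    return pd.DataFrame(
        np.vstack([data[g] for g in all_names]), index=all_names, columns=cols
    )


# ---------------------------------------------------------------------------
# sequence fixtures with planted complementary segments and seed sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    """One site planted into a host sequence.

    ``kind`` is either ``revcomp`` (a reverse-complement copy of a guest
    segment, producing full-length exact complementarity) or
    ``seed:<type>`` with a seed-site type such as ``8mer`` or
    ``7mer-m8 g-bulged`` constructed for the guest miRNA.
    """

    host: str
    guest: str
    kind: str
    length: int
    position: int
    guest_offset: int = 0


@dataclass
class SequenceSpec:
    n_background: int = 0
    length_range: tuple[int, int] = (500, 2000)
    planted_sites: Sequence[PlantedSite] = ()
    guest_lengths: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 20 or hi < lo:
            raise ValueError("length_range must satisfy 20 <= lo <= hi")


def _seed_site_sequence(mirna: str, site_type: str, rng: np.random.Generator) -> str:
    """Construct a target segment of the requested seed-site type."""
    core6 = revcomp(mirna[1:7])
    site7 = revcomp(mirna[1:8])
    non_a = "C"
    if site_type == "6mer":
        # guard the flanks so the site cannot strengthen by accident
        pre = "T" if _complement(mirna[7]) != "T" else "C"
        return pre + core6 + non_a
    if site_type == "7mer-A1":
        pre = "T" if _complement(mirna[7]) != "T" else "C"
        return pre + core6 + "A"
    if site_type == "7mer-m8":
        return site7 + non_a
    if site_type == "8mer":
        return site7 + "A"
    if site_type == "7mer-m8 g-bulged":
        k = int(rng.integers(1, len(site7)))
        return site7[:k] + "G" + site7[k:] + non_a
    raise ValueError(f"unknown seed-site type {site_type!r}")


def simulate_sequences(spec: SequenceSpec) -> list[SeqRecord]:
    """FASTA fixtures: uniform-random DNA backgrounds plus planted sites.

    Hosts and guests named in ``planted_sites`` are generated first (guest
    length defaults to 22 nt for seed guests, otherwise drawn from
    ``length_range``); every reverse-complement plant aligns to its guest
    segment with full-length exact complementarity, and every seed plant
    classifies to its declared type by construction.  Overlapping plants
    within one host are rejected.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list("ACGT"))

    def rand_seq(length: int) -> str:
        return "".join(rng.choice(alphabet, size=length))

    hosts = list(dict.fromkeys(s.host for s in spec.planted_sites))
    guests = list(dict.fromkeys(s.guest for s in spec.planted_sites))

    seqs: dict[str, str] = {}
    for gid in guests:
        if gid in spec.guest_lengths:
            glen = spec.guest_lengths[gid]
        elif any(s.guest == gid and s.kind.startswith("seed") for s in spec.planted_sites):
            glen = 22
        else:
            glen = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seqs[gid] = rand_seq(glen)

    spans: dict[str, list[tuple[int, int]]] = {h: [] for h in hosts}
    planted: dict[str, list[tuple[int, str]]] = {h: [] for h in hosts}
    for site in spec.planted_sites:
        guest_seq = seqs[site.guest]
        if site.kind == "revcomp":
            if site.guest_offset + site.length > len(guest_seq):
                raise ValueError(
                    f"planted segment exceeds guest {site.guest!r} length"
                )
            segment = revcomp(
                guest_seq[site.guest_offset:site.guest_offset + site.length]
            )
        elif site.kind.startswith("seed:"):
            segment = _seed_site_sequence(guest_seq, site.kind[5:], rng)
        else:
            raise ValueError(f"unknown planted-site kind {site.kind!r}")
        lo, hi = site.position, site.position + len(segment)
        for (olo, ohi) in spans[site.host]:
            if lo < ohi and olo < hi:
                raise ValueError(
                    f"overlapping planted sites in host {site.host!r}: "
                    f"({lo}, {hi}) vs ({olo}, {ohi})"
                )
        spans[site.host].append((lo, hi))
        planted[site.host].append((lo, segment))

    for h in hosts:
        need = max((hi for _, hi in spans[h]), default=0)
        hlen = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        if hlen < need:
            raise ValueError(
                f"planted site does not fit in host {h!r} "
                f"(needs {need} nt, host length {hlen})"
            )
        s = list(rand_seq(hlen))
        for lo, segment in planted[h]:
            s[lo:lo + len(segment)] = segment
        seqs[h] = "".join(s)

    for i in range(spec.n_background):
        seqs[f"BGSEQ{i + 1:04d}"] = rand_seq(
            int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        )
    return [
        SeqRecord(Seq(clean_seq(s)), id=name, description="")
        for name, s in seqs.items()
    ]


def simulate_survival(
    n: int,
    hazard_ratio: float,
    exposed_fraction: float = 0.5,
    baseline_hazard: float = 0.01,
    follow_up: float = 120.0,
    censoring_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-arm exponential survival data for estimator checks.

    Returns columns exposed (binary), time, event.
    """
    rng = np.random.default_rng(seed)
    exposed = rng.random(n) < exposed_fraction
    lam = baseline_hazard * np.where(exposed, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    censor = np.where(
        rng.random(n) < censoring_rate,
        rng.uniform(1e-3, follow_up, size=n),
        follow_up,
    )
    return pd.DataFrame(
        {
            "exposed": exposed.astype(int),
            "time": np.minimum(t_event, censor),
            "event": t_event <= censor,
        }
    )


def spec_to_json(spec: CohortSpec | SequenceSpec) -> dict:
    """JSON-serialisable dump of a spec (tuple keys flattened)."""
    d = dataclasses.asdict(spec)

    def fix(v):
        if isinstance(v, Mapping):
            return {
                ("|".join(k) if isinstance(k, tuple) else str(k)): fix(x)
                for k, x in v.items()
            }
        if isinstance(v, (list, tuple)):
            return [fix(x) for x in v]
        if isinstance(v, np.generic):
            return v.item()
        return v

    return {k: fix(v) for k, v in d.items()}
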