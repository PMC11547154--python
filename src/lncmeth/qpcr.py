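"""qPCR quantification: ddCt relative expression and qMSP methylation levels.

Raw input is a long-format Ct table with one row per well:
columns ``sample``, ``assay``, ``replicate``, ``ct``.  An undetermined Ct
(no amplification within the run) is encoded as NaN.  Replicates are
averaged; a replicate spread beyond a tolerance (default 0.5 cycles) is
flagged but not dropped.

Relative expression follows the ddCt convention::

    dCt   = Ct_target - Ct_reference          (per sample)
    ddCt  = dCt_case - dCt_calibrator
    fold  = 2 ** -ddCt

with the calibrator dCt taken as the mean over the calibrator samples, or
the matched sample in paired mode.  Folds within twofold of the calibrator
(|ddCt| <= 1) are classified as *retained*; larger shifts as *down*
(ddCt > 1) or *up* (ddCt < -1).

Methylation is quantified as PMR (percent of methylated reference) against
a fully methylated control DNA::

    pmr = 100 * 2 ** -[(Ct_locus - Ct_ACTB)_sample - (Ct_locus - Ct_ACTB)_control]

Completeness of bisulfite conversion is checked with an ACTB assay specific
to the unconverted template: amplification of that assay below a Ct floor
marks the sample as conversion-failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default assay names for the bisulfite-conversion controls
ACTB_CONVERTED = "ACTB_conv"
ACTB_UNCONVERTED = "ACTB_unconv"

#: PMR values above this cap are truncated and flagged (efficiency noise)
PMR_CAP = 150.0

REQUIRED_COLUMNS = ("sample", "assay", "replicate", "ct")


@dataclass(frozen=True)
class RelativeLevel:
    """ddCt quantification result for one (sample, gene)."""

    sample: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    fold: float
    classification: str


@dataclass(frozen=True)
class MethylationLevel:
    """qMSP quantification result for one (sample, locus)."""

    sample: str
    locus: str
    pmr: float
    conversion_ok: bool
    capped: bool = False


def _validate_ct_table(ct: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    finite = ct["ct"].dropna()
    if (finite <= 0).any():
        bad = ct.loc[ct["ct"].notna() & (ct["ct"] <= 0)]
        raise ValueError(
            f"Ct values must be positive or NaN (undetermined); offending rows: "
            f"{bad[['sample', 'assay']].to_dict('records')[:3]}"
        )


def aggregate_replicates(
    ct: pd.DataFrame, tolerance: float = 0.5
) -> pd.DataFrame:
    """Collapse replicate wells to one mean Ct per (sample, assay).

    Undetermined replicates (NaN) are ignored in the mean; if every
    replicate of a (sample, assay) is undetermined the mean is NaN.
    Returns a frame with columns sample, assay, ct, n_detected,
    spread_flag (replicate range beyond `tolerance` cycles).
    """
    _validate_ct_table(ct)
    grouped = ct.groupby(["sample", "assay"], sort=False)["ct"]
    out = grouped.agg(
        ct="mean",
        n_detected="count",
        spread=lambda v: (v.max() - v.min()) if v.notna().any() else 0.0,
    ).reset_index()
    out["spread_flag"] = out.pop("spread") > tolerance
    return out


def _mean_dct(
    agg: pd.DataFrame,
    sample: str,
    target: str,
    reference: str | Sequence[str],
) -> float:
    """dCt for one sample; the reference may be one assay or several, in
    which case the mean reference Ct is used (e.g. small-RNA assays
    normalised to the mean of RNU48 and RNU6)."""
    sub = agg.loc[agg["sample"] == sample].set_index("assay")["ct"]
    if target not in sub.index:
        raise ValueError(f"assay {target!r} not measured in sample {sample!r}")
    refs = [reference] if isinstance(reference, str) else list(reference)
    for r in refs:
        if r not in sub.index:
            raise ValueError(f"assay {r!r} not measured in sample {sample!r}")
    t = sub[target]
    r = float(np.mean([sub[x] for x in refs]))
    if np.isnan(t) or np.isnan(r):
        return np.nan
    return float(t - r)


def retention_classify(delta_delta_ct: float) -> str:
    """Twofold retention rule: |ddCt| <= 1 is *retained* (boundary
    inclusive), ddCt > 1 is *down*, ddCt < -1 is *up*."""
    if abs(delta_delta_ct) <= 1.0:
        return "retained"
    return "down" if delta_delta_ct > 1.0 else "up"


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str | Sequence[str],
    case_samples: Sequence[str],
    calibrator_samples: Sequence[str] | None = None,
    paired: Mapping[str, str] | None = None,
    tolerance: float = 0.5,
) -> list[RelativeLevel]:
    """ddCt relative expression of `target` against `reference`.

    Either ``calibrator_samples`` (one shared calibrator dCt, the mean over
    those samples) or ``paired`` (case sample -> its matched calibrator,
    e.g. the normal tissue of the same patient) must be given.  Samples in
    which a required assay never amplified are excluded with a logged
    reason.
    """
    if calibrator_samples is None and paired is None:
        raise ValueError("either calibrator_samples or paired must be given")
    agg = aggregate_replicates(ct, tolerance=tolerance)

    def dct_or_none(sample: str) -> float:
        v = _mean_dct(agg, sample, target, reference)
        return v

    shared_calib = np.nan
    if paired is None:
        if len(calibrator_samples) == 0:
            raise ValueError("calibrator sample set is empty")
        vals = []
        for s in calibrator_samples:
            v = dct_or_none(s)
            if np.isnan(v):
                logger.warning(
                    "calibrator sample %s excluded: undetermined Ct for %s",
                    s, target,
                )
            else:
                vals.append(v)
        if not vals:
            raise ValueError("no calibrator sample with determined Ct")
        shared_calib = float(np.mean(vals))

    out: list[RelativeLevel] = []
    for s in case_samples:
        d = dct_or_none(s)
        if np.isnan(d):
            logger.warning(
                "sample %s excluded: undetermined Ct in all replicates of a "
                "required assay (%s)", s, target,
            )
            continue
        if paired is not None:
            if s not in paired:
                raise ValueError(f"paired mode: no calibrator given for sample {s!r}")
            calib = dct_or_none(paired[s])
            if np.isnan(calib):
                logger.warning(
                    "sample %s excluded: matched calibrator %s undetermined",
                    s, paired[s],
                )
                continue
        else:
            calib = shared_calib
        ddct = d - calib
        out.append(
            RelativeLevel(
                sample=s,
                gene=target,
                delta_ct=d,
                delta_delta_ct=ddct,
                fold=float(2.0 ** (-ddct)),
                classification=retention_classify(ddct),
            )
        )
    return out


def qmsp_level(
    ct: pd.DataFrame,
    locus: str,
    fully_methylated_control: str,
    actb_converted: str = ACTB_CONVERTED,
    actb_unconverted: str = ACTB_UNCONVERTED,
    conversion_ct_floor: float = 35.0,
    samples: Iterable[str] | None = None,
    cap: float = PMR_CAP,
    tolerance: float = 0.5,
) -> list[MethylationLevel]:
    """Percent-of-methylated-reference (PMR) for one locus.

    The fully methylated control sample anchors 100%.  A sample whose
    unconverted-template ACTB assay amplifies below ``conversion_ct_floor``
    carries unconverted DNA and is flagged ``conversion_ok=False``
    (excluded from group statistics by default downstream).  An
    undetermined locus Ct with a valid converted-ACTB assay is reported as
    pmr = 0 (below detection).  PMR above ``cap`` is truncated and flagged.
    """
    agg = aggregate_replicates(ct, tolerance=tolerance)
    all_samples = list(dict.fromkeys(agg["sample"])) if samples is None else list(samples)
    if fully_methylated_control not in set(agg["sample"]):
        raise ValueError(
            f"fully methylated control sample {fully_methylated_control!r} "
            "is absent from the Ct table"
        )
    control_dct = _mean_dct(agg, fully_methylated_control, locus, actb_converted)
    if np.isnan(control_dct):
        raise ValueError(
            "fully methylated control has undetermined Ct for "
            f"{locus!r} or {actb_converted!r}"
        )

    out: list[MethylationLevel] = []
    for s in all_samples:
        if s == fully_methylated_control:
            continue
        sub = agg.loc[agg["sample"] == s].set_index("assay")["ct"]
        conversion_ok = True
        if actb_unconverted in sub.index:
            unconv = sub[actb_unconverted]
            if not np.isnan(unconv) and unconv < conversion_ct_floor:
                conversion_ok = False
        if actb_converted not in sub.index or np.isnan(sub[actb_converted]):
            logger.warning("sample %s excluded: no converted-ACTB signal", s)
            continue
        locus_ct = sub[locus] if locus in sub.index else np.nan
        if np.isnan(locus_ct):
            # below detection at the methylated-specific locus
            pmr, capped = 0.0, False
        else:
            dct = float(locus_ct - sub[actb_converted])
            pmr = float(100.0 * 2.0 ** (-(dct - control_dct)))
            capped = pmr > cap
            if capped:
                pmr = cap
        out.append(
            MethylationLevel(
                sample=s, locus=locus, pmr=pmr,
                conversion_ok=conversion_ok, capped=capped,
            )
        )
    return out


def levels_to_frame(levels: Sequence[RelativeLevel | MethylationLevel]) -> pd.DataFrame:
    """Tabulate a list of quantification results."""
    return pd.DataFrame([vars(x) for x in levels])
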