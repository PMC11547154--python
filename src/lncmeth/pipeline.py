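"""End-to-end orchestration: simulate -> quantify -> cohort statistics ->
partner screening -> gene-set intersection -> duplex alignment and seed
classification -> ceRNA triplets -> survival and marker panel.

A run is driven by a :class:`RunConfig` with one global seed.  The seed
is fanned out to per-stage sub-seeds with ``numpy.random.SeedSequence``
(splittable), so any stage re-run in isolation with its sub-seed
reproduces its outputs.  Every stage records its parameter block, a
parameter hash and its output files in the run manifest
(``manifest.json``); a stage failure halts downstream stages and leaves a
machine-readable error in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from lncmeth import align, cerna, io, qpcr, screen, stats, survival, synthetic

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; details are recorded in the manifest."""


@dataclass
class RunConfig:
    out_dir: str = "lncmeth_run"
    seed: int = 0
    cohort: Mapping[str, Any] = field(default_factory=dict)   # CohortSpec overrides
    n_matrix_samples: int = 150
    screen_mrna: screen.ScreenConfig = field(
        default_factory=lambda: screen.ScreenConfig(
            rs_threshold=0.4, p_threshold=1e-5, sign="positive", partner_class="mRNA"
        )
    )
    screen_mirna: screen.ScreenConfig = field(
        default_factory=screen.ScreenConfig.mirna_default
    )
    scoring: align.ScoringScheme = field(default_factory=align.ScoringScheme)
    triplets: cerna.TripletConfig = field(default_factory=cerna.TripletConfig)
    panel_genes: Sequence[str] = synthetic.PANEL_GENES
    panel_k: int = 4
    survival_genes: Sequence[str] = synthetic.SURVIVAL_GENES
    designs: Sequence[str] = stats.DESIGNS
    hyper_percentile: float = 95.0
    include_sequences: bool = True
    log_level: str = "INFO"


def _param_hash(obj: Any) -> str:
    blob = json.dumps(_params_dict(obj), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _params_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {k: _params_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {("|".join(k) if isinstance(k, tuple) else str(k)): _params_dict(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_params_dict(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# the planted regulatory network used by the screening / ceRNA stages: one
# true ceRNA chain (lncRNA sponges a miRNA that represses an EMT driver,
# inducing the positive lncRNA-mRNA correlation transitively) plus positive
# mRNA partners and null background
def default_network() -> list[tuple[str, str, float]]:
    return [
        ("MAGI2-AS3", "miR-33b-5p", -0.85),
        ("miR-33b-5p", "ZEB1", -0.7),
        ("MAGI2-AS3", "SERPINF1", 0.55),
        ("HAND2-AS1", "SERPINF2", 0.6),
        ("MEG3", "BBIP1", 0.5),
        ("ZNF667-AS1", "EPC1", 0.5),
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sub = np.random.SeedSequence(config.seed).spawn(4)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]

    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, params: Any, files: Sequence[Path], extra: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "params": _params_dict(params),
            "param_hash": _param_hash(params),
            "outputs": [str(f) for f in files],
            **(extra or {}),
        }
        manifest["outputs"].extend(str(f) for f in files)

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = {"error": {"type": type(exc).__name__, "message": str(exc)}}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    t0 = time.time()

    # ---- stage 1: cohort simulation + quantification round trip -----------
    stage = "cohort"
    try:
        spec = synthetic.CohortSpec(**{"seed": stage_seeds[0], **dict(config.cohort)})
        frame, ct = synthetic.simulate_cohort(spec, make_ct=True)
        f_frame = io.write_tsv(frame, out / "cohort.tsv")
        f_ct = io.write_tsv(ct, out / "ct_table.tsv")
        # quantify one locus back from raw Ct as a pipeline-level check
        lvls = qpcr.qmsp_level(ct, f"meth_{spec.gene_panel[0]}", "FULLY_METH")
        f_q = io.write_tsv(qpcr.levels_to_frame(lvls), out / "qmsp_check.tsv")
        record(stage, spec, [f_frame, f_ct, f_q], {"n_samples": int(len(frame))})
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- stage 2: cohort statistics ----------------------------------------
    stage = "cohort_stats"
    try:
        files = []
        tier_rows = []
        for design in config.designs:
            res = stats.compare_design(frame, design)
            df = stats.comparisons_to_frame(res)
            files.append(io.write_tsv(df, out / f"compare_{design}.tsv"))
            tier_rows.append(df)
        f_long = io.write_tsv(pd.concat(tier_rows), out / "compare_all_long.tsv")
        corr = stats.methylation_expression_correlation(frame)
        f_corr = io.write_tsv(
            pd.DataFrame([vars(c) for c in corr]), out / "meth_expr_correlation.tsv"
        )
        summary = stats.summarize_clinical(frame)
        record(stage, {"designs": list(config.designs)}, files + [f_long, f_corr],
               {"clinical_summary": summary})
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- stage 3: co-expression screening + gene sets ----------------------
    stage = "screening"
    try:
        network = default_network()
        matrix = synthetic.simulate_expression_matrix(
            config.n_matrix_samples, network, seed=stage_seeds[1], n_background=60
        )
        f_matrix = io.write_tsv(matrix, out / "expression_matrix.tsv", index=True)
        lncs = ["MAGI2-AS3", "HAND2-AS1", "MEG3", "ZNF667-AS1"]
        mirnas = sorted({p for _, p, _ in network if p.startswith("miR")})
        mrnas = [g for g in matrix.index if g not in set(lncs) | set(mirnas)]
        hits_mrna = screen.screen_partners(
            matrix, lncs, config.screen_mrna, partners=mrnas
        )
        hits_mirna = screen.screen_partners(
            matrix, lncs, config.screen_mirna, partners=mirnas
        )
        mi_mrna_hits = screen.screen_partners(
            matrix, mirnas,
            screen.ScreenConfig(rs_threshold=-0.4, p_threshold=0.05,
                                sign="negative", partner_class="mRNA"),
            partners=mrnas,
        )
        f_hits = io.write_tsv(
            screen.hits_to_frame(hits_mrna + hits_mirna + mi_mrna_hits),
            out / "screen_hits.tsv",
        )
        # synthetic EMT gene set: planted EMT drivers plus decoys
        emt = {"EMT_SYNTH": ("synthetic EMT set", {"ZEB1", "VIM", "SNAI2", "CDH1", "SERPINF1"})}
        f_gmt = out / "emt_sets.gmt"
        screen.write_gmt(emt, f_gmt)
        reports = [
            screen.intersect_gene_sets(
                [h for h in hits_mrna if h.lncrna == l] or [], emt["EMT_SYNTH"][1],
                "EMT_SYNTH", lncrna=l,
            )
            for l in lncs
        ]
        ranking = screen.rank_lncrna_activity(reports)
        f_rank = io.write_tsv(ranking, out / "lncrna_activity.tsv")
        record(stage, {"mrna": config.screen_mrna, "mirna": config.screen_mirna},
               [f_matrix, f_hits, f_gmt, f_rank],
               {"n_mrna_hits": len(hits_mrna), "n_mirna_hits": len(hits_mirna)})
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- stage 4: sequence alignment (optional) -----------------------------
    seed_sites: list[align.SeedSite] = []
    stage = "alignment"
    if config.include_sequences:
        try:
            seq_spec = synthetic.SequenceSpec(
                n_background=2,
                length_range=(400, 1200),
                planted_sites=(
                    synthetic.PlantedSite("ZEB1", "MAGI2-AS3", "revcomp", 32, 100),
                    synthetic.PlantedSite("ZEB1", "miR-33b-5p", "seed:7mer-m8", 8, 300),
                    synthetic.PlantedSite("MAGI2-AS3_seq", "miR-33b-5p", "seed:7mer-m8", 8, 50),
                ),
                guest_lengths={"miR-33b-5p": 22},
                seed=stage_seeds[2],
            )
            records = synthetic.simulate_sequences(seq_spec)
            f_fa = io.write_fasta(records, out / "sequences.fasta")
            seq_by_id = {r.id: str(r.seq) for r in records}
            report = align.enumerate_sites(
                seq_by_id["MAGI2-AS3"] if "MAGI2-AS3" in seq_by_id else seq_by_id["MAGI2-AS3_seq"],
                seq_by_id["ZEB1"],
                config.scoring,
                query_id="MAGI2-AS3", subject_id="ZEB1",
            )
            f_sites = io.write_tsv(
                pd.DataFrame([vars(s) for s in report.sites]).assign(
                    query=report.query_id, subject=report.subject_id,
                    total_matched=report.total_matched,
                    proportion=report.proportion,
                ),
                out / "duplex_sites.tsv",
            )
            mir = seq_by_id["miR-33b-5p"]
            for target_id in ("ZEB1", "MAGI2-AS3_seq"):
                seed_sites.extend(
                    align.classify_seed(mir, seq_by_id[target_id],
                                        mirna_id="miR-33b-5p", target_id=target_id)
                )
            # map the lncRNA sequence id back to the matrix gene id
            seed_sites = [
                dataclasses.replace(s, target_id="MAGI2-AS3")
                if s.target_id == "MAGI2-AS3_seq" else s
                for s in seed_sites
            ]
            f_seeds = io.write_tsv(
                pd.DataFrame([vars(s) for s in seed_sites]), out / "seed_sites.tsv"
            )
            record(stage, {"scheme": config.scoring, "spec": seq_spec},
                   [f_fa, f_sites, f_seeds],
                   {"n_duplex_sites": len(report.sites), "n_seed_sites": len(seed_sites)})
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)
    else:
        manifest["stages"][stage] = {"skipped": True}

    # ---- stage 5: ceRNA triplets -------------------------------------------
    stage = "cerna"
    try:
        triplets = cerna.build_triplets(
            lnc_mi=hits_mirna,
            mi_mrna=mi_mrna_hits,
            lnc_mrna=hits_mrna,
            lnc_seed_sites=[s for s in seed_sites if not s.target_id.startswith("ZEB")],
            mrna_seed_sites=[s for s in seed_sites if s.target_id.startswith("ZEB")],
            config=config.triplets,
        )
        trip_df = pd.DataFrame(
            [
                {
                    "lncrna": t.lncrna, "mirna": t.mirna, "mrna": t.mrna,
                    "lnc_mi_rs": t.lnc_mi.rs, "lnc_mi_p": t.lnc_mi.p,
                    "mi_mrna_rs": t.mi_mrna.rs, "mi_mrna_p": t.mi_mrna.p,
                    "lnc_mrna_rs": t.lnc_mrna.rs, "lnc_mrna_p": t.lnc_mrna.p,
                    "seed_on_lnc": t.lnc_mi.seed_evidence,
                    "seed_on_mrna": t.mi_mrna.seed_evidence,
                }
                for t in triplets
            ]
        )
        f_trip = io.write_tsv(trip_df, out / "cerna_triplets.tsv")
        graph = {
            "nodes": sorted(
                {t.lncrna for t in triplets} | {t.mirna for t in triplets}
                | {t.mrna for t in triplets}
            ),
            "edges": [
                {"source": t.lncrna, "target": t.mirna, "rs": t.lnc_mi.rs}
                for t in triplets
            ] + [
                {"source": t.mirna, "target": t.mrna, "rs": t.mi_mrna.rs}
                for t in triplets
            ] + [
                {"source": t.lncrna, "target": t.mrna, "rs": t.lnc_mrna.rs}
                for t in triplets
            ],
        }
        f_graph = out / "cerna_graph.json"
        f_graph.write_text(json.dumps(graph, indent=2))
        record(stage, config.triplets, [f_trip, f_graph], {"n_triplets": len(triplets)})
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- stage 6: survival + marker panel -----------------------------------
    stage = "survival_panel"
    try:
        calls = stats.hypermethylation_calls(frame, percentile=config.hyper_percentile)
        tum = frame[frame["tissue"] == "T"].set_index("sample")
        files = []
        logrank_rows = []
        for g in config.survival_genes:
            grp = calls[g].reindex(tum.index)
            t_pos, e_pos = tum.loc[grp, "time_months"], tum.loc[grp, "event"]
            t_neg, e_neg = tum.loc[~grp, "time_months"], tum.loc[~grp, "event"]
            chi2, p = survival.logrank(t_pos, e_pos, t_neg, e_neg)
            curve = survival.km_curve(t_pos, e_pos)
            km_df = pd.DataFrame(
                {"time": curve.times, "at_risk": curve.at_risk,
                 "survival": curve.survival, "greenwood_var": curve.variance}
            )
            files.append(io.write_tsv(km_df, out / f"km_{g}_methylated.tsv"))
            logrank_rows.append({"gene": g, "chi2": chi2, "p": p,
                                 "n_methylated": int(grp.sum()),
                                 "n_unmethylated": int((~grp).sum())})
        f_lr = io.write_tsv(pd.DataFrame(logrank_rows), out / "logrank.tsv")
        cov = calls[list(config.survival_genes)].reindex(tum.index).astype(float)
        cox = survival.cox_cumulative(
            tum["time_months"].to_numpy(), tum["event"].to_numpy(), cov
        )
        cox_df = pd.DataFrame(
            {"factor": cox.names, "coef": cox.coef, "hazard_ratio": cox.hazard_ratio,
             "se": cox.se, "p": cox.p}
        )
        f_cox = io.write_tsv(cox_df, out / "cox_cumulative.tsv")
        truth = tum["any_met"].to_numpy(dtype=bool)
        panel = survival.panel_evaluate(
            calls[list(config.panel_genes)].reindex(tum.index), truth, k=config.panel_k
        )
        panel_summary = {
            "genes": list(panel.genes), "k": panel.k,
            "tp": panel.tp, "fp": panel.fp, "tn": panel.tn, "fn": panel.fn,
            "sensitivity": panel.sensitivity, "specificity": panel.specificity,
            "auc": panel.auc, "roc": [list(pt) for pt in panel.roc],
        }
        f_panel = out / "panel_evaluation.json"
        f_panel.write_text(json.dumps(panel_summary, indent=2))
        record(stage, {"panel_genes": list(config.panel_genes), "k": config.panel_k,
                       "survival_genes": list(config.survival_genes),
                       "hyper_percentile": config.hyper_percentile},
               files + [f_lr, f_cox, f_panel],
               {"panel": {k: panel_summary[k] for k in
                          ("sensitivity", "specificity", "auc")}})
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest_path = out / "manifest.json"
    logger.info("pipeline complete: %s", manifest_path)
    return manifest
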