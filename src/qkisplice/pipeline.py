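"""End-to-end orchestration: simulate -> PSI -> contrasts -> cross-cancer
matrix -> differential splicing -> CLIP map -> target ranking.

Every stage writes plain TSV under the output directory and records its
filter accounting (events in/out) in a JSON manifest along with the full
configuration, the seed and sha256 hashes of the written inputs, so a run
is reproducible from the manifest alone.  Outputs contain no timestamps:
two runs with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clipmap import (
    build_splicing_map,
    motif_enrichment,
    motif_positional_profile,
    position_enrichment,
)
from .config import PipelineConfig
from .contrast import (
    build_cross_cancer_matrix,
    cluster_delta_psi,
    decile_split,
    delta_psi_contrast,
    per_gene_best_event,
)
from .diffsplice import (
    MethodRanking,
    call_differential,
    integrate_method_rankings,
    intersect_evidence_sets,
    test_events,
)
from .io import write_bed_peaks, write_event_table, write_expression_tsv
from .psi import build_psi_matrix
from .simulate import (
    REGULATOR,
    SimulationConfig,
    generate_clip_profiles,
    generate_cohort,
    generate_emt_experiment,
    generate_target_evidence,
)
from .targets import consistency_rank, mirna_gene_correlations, recurrence_score

__all__ = ["StageError", "run_pipeline", "events_annotation"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def events_annotation(events: pd.DataFrame) -> pd.DataFrame:
    """A minimal gene-model frame (read_gtf schema) from an event table."""
    rows = []
    for _, ev in events.iterrows():
        for a, b in ((ev.up_start, ev.up_end), (ev.alt_start, ev.alt_end),
                     (ev.dn_start, ev.dn_end)):
            rows.append((ev.chrom, "CDS", int(a), int(b), ev.strand,
                         ev.gene, f"{ev.gene}.t1", "protein_coding"))
        lo = int(min(ev.up_start, ev.dn_start))
        hi = int(max(ev.up_end, ev.dn_end))
        rows.append((ev.chrom, "gene", lo, hi, ev.strand, ev.gene, "",
                     "protein_coding"))
    return pd.DataFrame(
        rows, columns=["chrom", "feature", "start", "end", "strand",
                       "gene_id", "transcript_id", "gene_biotype"]
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 simulate: bool = True,
                 sim_config: SimulationConfig | None = None) -> dict:
    """Run every analysis stage; returns the manifest dict.

    With ``simulate=True`` (the default and only desk-scale mode) all
    inputs come from the synthetic-data generators seeded from
    ``config.seed``.  Without it, ``config.paths`` must provide
    ``junctions``, ``expression`` and ``events``; a missing input aborts
    with the stage name.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    if sim_config is None:
        sim_config = SimulationConfig(seed=config.seed)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "sim_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(sim_config).items()
        },
        "stages": {},
        "inputs_sha256": {},
    }

    # ---------------------------------------------------------------- cohorts
    stage = "cohort_contrast"
    try:
        if not simulate:
            for key in ("junctions", "expression", "events"):
                if key not in config.paths:
                    raise FileNotFoundError(f"missing input path {key!r}")
        contrasts, measured, n_samples = {}, {}, {}
        for c in range(sim_config.n_cancers):
            cancer = f"cancer{c + 1}"
            cfg_c = dataclasses.replace(sim_config, seed=sim_config.seed + c)
            expression, mirna, junctions, events, truth = generate_cohort(cfg_c)
            cdir = out / cancer
            cdir.mkdir(exist_ok=True)
            write_expression_tsv(expression, cdir / "expression.tsv")
            write_expression_tsv(mirna, cdir / "mirna.tsv")
            write_event_table(events, cdir / "events.tsv")
            truth.to_frame().to_csv(cdir / "truth.tsv", sep="\t", index=False)
            matrix = build_psi_matrix(junctions, events, th.min_coverage)
            matrix.write(cdir / "psi.tsv", cdir / "coverage.tsv")
            high, low = decile_split(
                expression.loc[REGULATOR], th.decile_fraction
            )
            contrast = delta_psi_contrast(matrix, high, low, th.min_group_n)
            contrast.to_csv(cdir / "decile_contrast.tsv", sep="\t", index=False)
            best = per_gene_best_event(
                contrast, dict(zip(events.event_id, events.gene))
            )
            best.to_csv(cdir / "per_gene_best.tsv", sep="\t", index=False)
            contrasts[cancer] = contrast
            measured[cancer] = matrix.psi.notna().mean(axis=1)
            n_samples[cancer] = sim_config.n_samples
            log.info("%s: %d events contrasted, %d dropped",
                     cancer, len(contrast), len(matrix.dropped))
            manifest["stages"].setdefault(stage, {})[cancer] = {
                "events_in": len(events),
                "events_contrasted": len(contrast),
                "events_dropped": len(matrix.dropped),
            }
            for f in cdir.iterdir():
                manifest["inputs_sha256"][f"{cancer}/{f.name}"] = _sha256(f)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ------------------------------------------------------- cross-cancer map
    stage = "cross_cancer"
    try:
        mf = pd.DataFrame(measured)
        matrix, flags = build_cross_cancer_matrix(
            contrasts, n_samples,
            min_samples_per_cancer=th.min_samples_per_cancer,
            min_max_abs_delta=th.cross_cancer_min_delta,
            measured_fraction=mf,
            constitutive_fraction=th.constitutive_fraction,
        )
        matrix.to_csv(out / "cross_cancer_delta_psi.tsv", sep="\t")
        flags.to_csv(out / "cross_cancer_filter_flags.tsv", sep="\t")
        manifest["stages"][stage] = {
            "events_in": int(len(flags)),
            "events_retained": int(flags["retained"].sum()),
            "events_dropped": int((~flags["retained"]).sum()),
        }
        if len(matrix) >= 2:
            row_order, col_order, _, _ = cluster_delta_psi(matrix)
            pd.DataFrame({"row_order": row_order}).to_csv(
                out / "cluster_row_order.tsv", sep="\t", index=False
            )
            pd.DataFrame({"col_order": col_order}).to_csv(
                out / "cluster_col_order.tsv", sep="\t", index=False
            )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -------------------------------------------------- differential splicing
    stage = "emt_differential"
    try:
        cfg_emt = dataclasses.replace(sim_config, seed=sim_config.seed + 1000)
        counts, events_emt, truth_emt = generate_emt_experiment(cfg_emt)
        counts.to_csv(out / "emt_junction_counts.tsv", sep="\t", index=False)
        results = test_events(counts)
        calls = call_differential(
            results, th.delta_psi_call, th.fdr, th.delta_psi_stringent
        )
        calls.to_csv(out / "emt_differential.tsv", sep="\t", index=False)
        tested = calls[calls["p_value"].notna()]
        by_p = tested.sort_values(
            ["p_value", "event_id"], kind="stable"
        )["event_id"].tolist()
        by_delta = tested.reindex(
            tested["delta_psi"].abs().sort_values(ascending=False, kind="stable").index
        )["event_id"].tolist()
        by_stat = tested.sort_values(
            ["stat", "event_id"], ascending=[False, True], kind="stable"
        )["event_id"].tolist()
        integrated = integrate_method_rankings([
            MethodRanking("pvalue", tuple(by_p)),
            MethodRanking("abs_delta", tuple(by_delta)),
            MethodRanking("lrt_stat", tuple(by_stat)),
        ])
        integrated.to_csv(out / "emt_rank_integration.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "events_in": int(len(events_emt)),
            "events_tested": int(len(tested)),
            "events_dropped": int(len(events_emt) - len(tested)),
            "events_called": int(calls["called"].sum()),
            "events_stringent": int(calls["stringent"].sum()),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ------------------------------------------------------- CLIP splicing map
    stage = "clip_map"
    try:
        peaks = generate_clip_profiles(
            events_emt, truth_emt, seed=sim_config.seed + 2000
        )
        write_bed_peaks(peaks, out / "clip_peaks.bed")
        side = events_emt["event_id"].map(truth_emt.true_binding_side)
        groups = {
            "regulator_skipped": events_emt[side == "upstream_intron"],
            "regulator_included": events_emt[side == "downstream_intron"],
            "background": events_emt[side == "none"],
        }
        groups = {k: v for k, v in groups.items() if len(v)}
        profiles = build_splicing_map(peaks, groups)
        prof_tbl = {}
        for label, prof in profiles.items():
            prof_tbl[f"{label}_mean_height"] = prof.mean_height
            if label != "background" and "background" in profiles:
                prof_tbl[f"{label}_neg_log10_p"] = position_enrichment(
                    prof, profiles["background"]
                )
        pd.DataFrame(prof_tbl).to_csv(
            out / "splicing_map.tsv", sep="\t", index_label="position"
        )
        sig = peaks[peaks["kind"] == "signal"]
        bg = peaks[peaks["kind"] == "background"]
        if len(sig) and len(bg):
            ms = motif_enrichment(sig["sequence"].tolist(), bg["sequence"].tolist())
            hist = motif_positional_profile(sig)
            json_stats = {
                "motif": ms.motif,
                "peak_hit_fraction": ms.peak_hit_fraction,
                "background_hit_fraction": ms.background_hit_fraction,
                "enrichment_p": ms.enrichment_p,
                "sense_offsets_mean": float(np.mean(hist["sense"]))
                if len(hist["sense"]) else None,
                "n_sense_hits": int(len(hist["sense"])),
                "n_antisense_hits": int(len(hist["antisense"])),
            }
            (out / "motif_stats.json").write_text(
                json.dumps(json_stats, sort_keys=True, indent=1)
            )
        from .clipmap import annotate_peak_regions
        proportions, _ = annotate_peak_regions(peaks, events_annotation(events_emt))
        proportions.to_csv(out / "peak_region_proportions.tsv", sep="\t",
                           header=["proportion"])
        manifest["stages"][stage] = {
            "peaks_in": int(len(peaks)),
            "signal_peaks": int(len(sig)),
            "background_peaks": int(len(bg)),
            "groups": {k: int(len(v)) for k, v in groups.items()},
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---------------------------------------------------------- target ranking
    stage = "target_ranking"
    try:
        expr, mirna_v, folds, flags_tbl, truth_t = generate_target_evidence(
            sim_config, planted_targets={REGULATOR},
            seed=sim_config.seed + 3000, n_genes=200,
        )
        from .targets import apply_experimental_filters
        exp_flags = apply_experimental_filters(folds)
        evidence = pd.concat([exp_flags, flags_tbl], axis=1)
        clinical = {}
        for d in sorted(expr):
            res, _ = mirna_gene_correlations(expr[d], mirna_v[d], dataset=d)
            clinical[d] = res
        ranked = consistency_rank(evidence, clinical, th.clinical_alpha)
        ranked.to_csv(out / "target_ranking.tsv", sep="\t", index=False)
        per_cancer = {
            d: clinical[d].set_index("gene").loc[REGULATOR]
            for d in clinical if REGULATOR in set(clinical[d]["gene"])
        }
        rec, detail = recurrence_score(per_cancer, th.clinical_alpha)
        detail.to_csv(out / "recurrence_detail.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "genes_in": int(len(evidence)),
            "genes_ranked": int(len(ranked)),
            "planted_rank": int(
                ranked.loc[ranked["gene"] == REGULATOR, "rank"].iloc[0]
            ),
            "rec_surrogate": rec,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # --------------------------------------------------------- evidence overlap
    stage = "evidence_overlap"
    try:
        stringent_genes = set(
            events_emt.set_index("event_id").loc[
                calls.loc[calls["stringent"], "event_id"], "gene"
            ]
        )
        clip_genes = set()
        sig_peaks = peaks[peaks["kind"] == "signal"]
        for name in sig_peaks["name"]:
            ev_id = name.split("_")[1]
            g = events_emt.loc[events_emt.event_id == ev_id, "gene"]
            if len(g):
                clip_genes.add(g.iloc[0])
        both, venn, prov = intersect_evidence_sets(
            stringent_genes, clip_genes, "stringent_splicing", "clip_bound"
        )
        prov.to_csv(out / "evidence_overlap.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "venn": venn, "intersection": len(both),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return manifest
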