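"""End-to-end pipeline: quantify -> map-qtl -> predict-ecs -> qtl-structure.

Each stage reads/writes plain-text tables whose single ``#`` header line
carries the configuration hash and seed, so a rerun with the same config and
inputs is byte-identical for every deterministic stage (all stages here are
deterministic given the seed).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as eio
from . import ecs_prediction as ecs
from . import qtl_structure as qs
from .editing_quant import build_editing_matrix, site_variability
from .edqtl_mapping import map_edqtls
from .io import PipelineConfig


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig) -> Dict[str, Path]:
    """Execute all stages in order; returns the output file paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    log: List[Dict[str, object]] = []

    if cfg.conservation and not Path(cfg.conservation).exists():
        raise PipelineError(
            "validate", FileNotFoundError(f"conservation track {cfg.conservation} not found")
        )

    # ---- quantify ----
    try:
        counts = eio.read_counts_tsv(cfg.counts)
        sites = eio.read_sites_bed(cfg.sites_bed)
        genes = eio.read_genes_tsv(cfg.genes)
        sites = eio.assign_genes_to_sites(sites, genes)
        matrix = build_editing_matrix(
            counts,
            sites,
            min_strains=cfg.min_strains,
            min_coverage=cfg.min_coverage,
            max_replicate_diff=cfg.max_replicate_diff,
        )
        paths["editing_matrix"] = outdir / "editing_matrix.tsv"
        eio.write_editing_matrix(matrix, paths["editing_matrix"], cfg.header("quantify"))
        variability = site_variability(matrix)
        paths["variability"] = outdir / "variability.tsv"
        with open(paths["variability"], "w") as fh:
            fh.write(cfg.header("quantify"))
            variability.to_csv(fh, sep="\t")
        log.append(
            {
                "stage": "quantify",
                "n_count_rows": len(counts),
                "n_sites_in": len(sites),
                "n_sites_kept": len(matrix.sites),
                "n_strains": len(matrix.strains),
            }
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("quantify", exc) from exc

    # ---- map-qtl ----
    try:
        genotypes, skipped = eio.read_vcf_genotypes(cfg.vcf, genes)
        mapping = map_edqtls(
            matrix, genotypes, n_perm=cfg.n_perm, seed=cfg.seed, fdr=cfg.fdr
        )
        edqtl_tbl = mapping.to_frame()
        paths["edqtls"] = outdir / "edqtls.tsv"
        with open(paths["edqtls"], "w") as fh:
            fh.write(cfg.header("map-qtl"))
            edqtl_tbl.round(10).to_csv(fh, sep="\t", index=False)
        paths["edqtl_scan"] = outdir / "edqtl_scan.tsv"
        with open(paths["edqtl_scan"], "w") as fh:
            fh.write(cfg.header("map-qtl"))
            mapping.per_site.round(10).to_csv(fh, sep="\t", index=False)
        log.append(
            {
                "stage": "map-qtl",
                "n_variants": len(genotypes.variants),
                "skipped_vcf_records": skipped,
                "n_sites_scanned": len(mapping.per_site),
                "n_edqtls": len(mapping.edqtls),
            }
        )
    except Exception as exc:
        raise PipelineError("map-qtl", exc) from exc

    # ---- predict-ecs ----
    try:
        genome = eio.read_fasta(cfg.fasta)
        contig_lengths = {c: len(s) for c, s in genome.items()}
        cons_tracks = (
            eio.read_conservation(cfg.conservation, contig_lengths)
            if cfg.conservation
            else None
        )
        predictions: Dict[str, ecs.EcsPrediction] = {}
        pred_rows = []
        dot_lines = []
        for site in matrix.sites:
            seq = genome[site.chrom]
            pred = ecs.predict_proximal_ecs(
                site,
                seq,
                window=cfg.window,
                min_pairs=cfg.min_stem_pairs,
                max_bulge=cfg.max_bulge,
            )
            if (pred is None or not pred.accepted) and cons_tracks is not None:
                smoothed = ecs.smooth_conservation(
                    cons_tracks[site.chrom], cfg.cons_window
                )
                cands = ecs.candidate_conserved_regions(
                    smoothed,
                    site.pos - 1,
                    max_dist=cfg.cons_max_distance,
                    min_len=cfg.cons_min_length,
                    min_score=cfg.cons_min_score,
                )
                distal = ecs.predict_distal_ecs(
                    site,
                    cands,
                    seq,
                    buffer=cfg.distal_buffer,
                    site_flank=cfg.distal_site_flank,
                    linker=cfg.linker,
                    min_pairs=cfg.min_stem_pairs,
                    max_bulge=cfg.max_bulge,
                )
                accepted = [p for p in distal if p.accepted]
                if accepted:
                    pred = accepted[0]
            if pred is not None:
                predictions[site.site_id] = pred
                pred_rows.append(
                    {
                        "site_id": site.site_id,
                        "approach": pred.approach,
                        "accepted": pred.accepted,
                        "n_pairs": pred.n_pairs,
                        "max_bulge": pred.max_bulge,
                        "distance": pred.distance,
                        "ecs_start": pred.ecs_interval[0] + 1 if pred.ecs_interval else "",
                        "ecs_end": pred.ecs_interval[1] if pred.ecs_interval else "",
                        "edit_start": pred.edit_interval[0] + 1 if pred.edit_interval else "",
                        "edit_end": pred.edit_interval[1] if pred.edit_interval else "",
                        "reject_reason": pred.reject_reason or "",
                    }
                )
                if pred.structure is not None:
                    dot_lines.append(f">{site.site_id} {pred.approach}")
                    dot_lines.append(pred.structure.sequence)
                    dot_lines.append(pred.structure.to_dotbracket())
        paths["ecs_predictions"] = outdir / "ecs_predictions.tsv"
        with open(paths["ecs_predictions"], "w") as fh:
            fh.write(cfg.header("predict-ecs"))
            pd.DataFrame(pred_rows).to_csv(fh, sep="\t", index=False)
        paths["ecs_dotbracket"] = outdir / "ecs_predictions.dbn"
        paths["ecs_dotbracket"].write_text(
            cfg.header("predict-ecs") + "\n".join(dot_lines) + "\n"
        )
        accepted_preds = [p for p in predictions.values() if p.accepted]
        score, _tbl = ecs.enrichment_score(accepted_preds, matrix.sites, contig_lengths)
        log.append(
            {
                "stage": "predict-ecs",
                "n_predicted": len(predictions),
                "n_accepted": len(accepted_preds),
                "enrichment_score": None if math.isnan(score) else score,
            }
        )
    except Exception as exc:
        raise PipelineError("predict-ecs", exc) from exc

    # ---- qtl-structure ----
    try:
        vt = genotypes.variants.set_index("variant_id")
        comp_rows = []
        qtl_paired = []
        qtl_dgs = []
        for e in mapping.edqtls:
            pred = predictions.get(e.site_id)
            vpos = int(vt.loc[e.variant_id, "pos"])
            loc = qs.classify_variant_location(vpos, pred)
            row = {
                "variant_id": e.variant_id,
                "site_id": e.site_id,
                "location_class": loc,
                "is_base_paired": "",
                "delta_g": "",
                "signed_position": "",
                "effect_size": round(e.effect_size, 6),
                "passes_effect_gate": e.effect_size >= cfg.effect_size_gate,
            }
            if loc == qs.WITHIN_DUPLEX:
                comp = qs.compare_alleles(
                    e.variant_id,
                    genotypes,
                    pred,
                    genome[pred.site.chrom],
                    matrix.level[matrix.site_index(e.site_id)],
                    effect_gate=cfg.effect_size_gate,
                )
                row["is_base_paired"] = comp.is_base_paired
                row["delta_g"] = round(comp.delta_g, 4)
                row["signed_position"] = comp.signed_position
                if comp.passes_effect_gate:
                    qtl_paired.append(bool(comp.is_base_paired))
                    qtl_dgs.append(comp.delta_g)
            comp_rows.append(row)
        controls = qs.select_control_variants(
            genotypes,
            mapping.edqtls,
            predictions,
            mode="duplex",
            r2_max=cfg.ld_r2_max,
            seed=cfg.seed,
        )
        ctrl_paired = []
        ctrl_dgs = []
        for var_id in controls:
            # a control's duplex: the prediction whose intervals contain it
            vpos = int(vt.loc[var_id, "pos"])
            pred = next(
                (
                    p
                    for p in predictions.values()
                    if p.accepted
                    and qs.classify_variant_location(vpos, p) == qs.WITHIN_DUPLEX
                ),
                None,
            )
            if pred is None:
                continue
            comp = qs.compare_alleles(
                var_id,
                genotypes,
                pred,
                genome[pred.site.chrom],
                matrix.level[matrix.site_index(pred.site.site_id)],
                effect_gate=cfg.effect_size_gate,
            )
            ctrl_paired.append(bool(comp.is_base_paired))
            ctrl_dgs.append(comp.delta_g)
        tests: Dict[str, object] = {"n_qtl": len(qtl_dgs), "n_control": len(ctrl_dgs)}
        if qtl_paired and ctrl_paired:
            odds, p_f = qs.pairing_enrichment_test(qtl_paired, ctrl_paired)
            tests["pairing_fisher"] = {"odds_ratio": odds, "p": p_f}
        if qtl_dgs and ctrl_dgs:
            u, p_u = qs.delta_g_test(qtl_dgs, ctrl_dgs)
            tests["delta_g_mannwhitney"] = {"U": u, "p": p_u}
        paths["structural_comparisons"] = outdir / "structural_comparisons.tsv"
        with open(paths["structural_comparisons"], "w") as fh:
            fh.write(cfg.header("qtl-structure"))
            pd.DataFrame(comp_rows).to_csv(fh, sep="\t", index=False)
        paths["structure_tests"] = outdir / "structure_tests.json"
        paths["structure_tests"].write_text(
            json.dumps(tests, indent=1, sort_keys=True, default=float) + "\n"
        )
        log.append({"stage": "qtl-structure", "n_controls": len(controls), **tests})
    except Exception as exc:
        raise PipelineError("qtl-structure", exc) from exc

    # ---- distal-stems ----
    try:
        stem_rows = []
        for e in mapping.edqtls:
            pred = predictions.get(e.site_id)
            vpos = int(vt.loc[e.variant_id, "pos"])
            if qs.classify_variant_location(vpos, pred) != qs.DISTAL:
                continue
            exclude = [pred.edit_interval, pred.ecs_interval]
            site = matrix.sites[matrix.site_index(e.site_id)]
            for ss in qs.find_distal_stems(
                e.variant_id,
                vpos,
                genome[site.chrom],
                site_pos=site.pos,
                window=cfg.window,
                min_pairs=cfg.min_stem_pairs,
                max_bulge=cfg.max_bulge,
                exclude_intervals=[iv for iv in exclude if iv],
            ):
                stem_rows.append(
                    {
                        "variant_id": ss.variant_id,
                        "site_id": e.site_id,
                        "n_pairs": ss.n_pairs,
                        "max_bulge": ss.max_bulge,
                        "left_start": ss.left_interval[0] + 1,
                        "left_end": ss.left_interval[1],
                        "right_start": ss.right_interval[0] + 1,
                        "right_end": ss.right_interval[1],
                        "distance_to_site": ss.distance_to_editing_site,
                    }
                )
        paths["secondary_stems"] = outdir / "secondary_stems.tsv"
        with open(paths["secondary_stems"], "w") as fh:
            fh.write(cfg.header("distal-stems"))
            pd.DataFrame(stem_rows).to_csv(fh, sep="\t", index=False)
        log.append({"stage": "distal-stems", "n_stems": len(stem_rows)})
    except Exception as exc:
        raise PipelineError("distal-stems", exc) from exc

    paths["run_metadata"] = outdir / "run_metadata.json"
    paths["run_metadata"].write_text(
        json.dumps(
            {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": log},
            indent=1,
            sort_keys=True,
            default=str,
        )
        + "\n"
    )
    return paths
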