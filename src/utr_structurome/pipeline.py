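"""Glue: pileups -> reactivities -> windowed Gini -> gene table -> statistics.

:func:`analyze_dataset` is the in-memory backbone used by the numbered
analysis drivers, the tests, and the acceptance script; :func:`run_pipeline`
wraps it with file IO and a machine-readable manifest.
"""
from __future__ import annotations

import json
import logging
import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import association as assoc
from .config import RunConfig
from .metrics import window_gini
from .reactivity import NormalizationError, reactivity_pipeline
from .types import GiniWindowSet, PileupProfile, ReactivityProfile, TranscriptModel

log = logging.getLogger("utr_structurome")


def slice_pileup(p: PileupProfile, start: int, end: int) -> PileupProfile:
    sel = (p.positions >= start) & (p.positions < end)
    return PileupProfile(
        transcript_id=p.transcript_id,
        positions=p.positions[sel],
        ref_base=p.ref_base[sel],
        coverage=p.coverage[sel],
        mismatch=p.mismatch[sel],
        sample_label=p.sample_label,
        replicate=p.replicate,
    )


def score_transcripts(
    transcripts: list[TranscriptModel],
    treated: Mapping[str, PileupProfile],
    untreated: Optional[Mapping[str, PileupProfile]],
    cfg: RunConfig,
) -> tuple[dict[str, ReactivityProfile], dict[str, GiniWindowSet], pd.DataFrame, dict]:
    """Per-transcript normalized UTR reactivity, window Gini, and gene table.

    Genes that cannot be normalized (too few covered positions) or have no
    passed window are dropped from the gene table; the counts dict records
    every filter so "N genes used" is always recoverable.
    """
    profiles: dict[str, ReactivityProfile] = {}
    windows: dict[str, GiniWindowSet] = {}
    counts = {
        "n_input": len(transcripts),
        "n_normalization_failed": 0,
        "n_no_passed_window": 0,
        "n_scored": 0,
    }
    rows = []
    for t in transcripts:
        tp = treated[t.id]
        up = untreated.get(t.id) if untreated is not None else None
        try:
            prof = reactivity_pipeline(
                tp,
                up,
                min_coverage=cfg.min_coverage,
                top_fraction=cfg.top_fraction,
                background_method=cfg.background_method,
                region=t.utr3_interval,
            )
        except NormalizationError:
            counts["n_normalization_failed"] += 1
            continue
        profiles[t.id] = prof
        ws = window_gini(
            prof,
            slice_pileup(tp, *t.utr3_interval),
            window_size=cfg.window_size,
            step=cfg.step,
            mismatch_threshold=cfg.mismatch_threshold,
            ac_only=cfg.ac_only,
        )
        windows[t.id] = ws
        if np.isnan(ws.avg_gini):
            counts["n_no_passed_window"] += 1
            continue
        counts["n_scored"] += 1
        rows.append(
            {
                "transcript_id": t.id,
                "avg_gini": ws.avg_gini,
                "n_windows_passed": ws.n_passed,
            }
        )
    gene_table = pd.DataFrame(rows, columns=["transcript_id", "avg_gini", "n_windows_passed"])
    return profiles, windows, gene_table, counts


def associate_genes(gene_table: pd.DataFrame, covariates: pd.DataFrame, cfg: RunConfig) -> dict:
    """Decile classification and the expression / stability statistics."""
    merged = gene_table.merge(covariates, on="transcript_id", how="inner")
    merged = assoc.classify_deciles(
        merged, "avg_gini", q=cfg.q, labels=("high", "low", "mid")
    )
    merged = assoc.classify_deciles(
        merged, "half_life", q=cfg.q, labels=("long", "short", "mid")
    )
    expr = assoc.group_compare(merged, "avg_gini_class", "rpkm", test="ranksum")
    r, r_p, _ = assoc.correlate(merged, "avg_gini", "rpkm", log_y=True)
    ks = assoc.group_compare(
        merged, "half_life_class", "avg_gini", test="ks", groups=("long", "short")
    )
    stats = {
        "n_genes": len(merged),
        "expression_ranksum_p": expr.pvalue,
        "expression_medians": dict(
            zip(expr.summaries["group"], expr.summaries["median"])
        ),
        "gini_logrpkm_pearson_r": r,
        "gini_logrpkm_pearson_p": r_p,
        "halflife_ks_p": ks.pvalue,
        "halflife_ks_stat": ks.statistic,
    }
    extras: dict = {"expression_compare": expr, "halflife_compare": ks}
    for cov in ("gc_content", "polyA_len"):
        if cov in merged.columns:
            strat = assoc.stratified_confounder(merged, cov)
            stats[f"stratified_{cov}"] = {
                name: (None if res is None else res.pvalue) for name, res in strat.items()
            }
    if "mirna_target" in merged.columns:
        mir = assoc.mirna_overlap_summary(merged)
        stats["mirna_fractions"] = mir["fractions"]
        stats["mirna_p"] = mir["pvalue"]
    if "pairing_level" in merged.columns:
        levels = sorted(merged["pairing_level"].unique())
        stats["high_class_enrichment_top_level"] = assoc.level_enrichment(
            merged, "pairing_level", levels[-1]
        )
    return {"gene_table": merged, "stats": stats, "results": extras}


def analyze_dataset(
    transcripts: list[TranscriptModel],
    treated: Mapping[str, PileupProfile],
    untreated: Optional[Mapping[str, PileupProfile]],
    covariates: pd.DataFrame,
    cfg: Optional[RunConfig] = None,
) -> dict:
    """End-to-end in-memory analysis; returns gene table, stats, and counts."""
    cfg = cfg or RunConfig()
    profiles, windows, gene_table, counts = score_transcripts(
        transcripts, treated, untreated, cfg
    )
    if gene_table.empty:
        raise ValueError("no transcript survived scoring; nothing to associate")
    out = associate_genes(gene_table, covariates, cfg)
    out.update(profiles=profiles, windows=windows, counts=counts)
    out["stats"]["counts"] = counts
    return out


def run_pipeline(cfg: RunConfig) -> str:
    """File-based pipeline over a simulated-layout input directory.

    Expects ``transcripts.fa``, ``utr3.bed``, ``pileup_treated.tsv``,
    ``pileup_untreated.tsv`` (optional), ``covariates.tsv`` under
    ``cfg.input_dir``; writes reactivity/window/gene tables, the association
    report, and a manifest under ``cfg.output_dir``. Deterministic given the
    config.
    """
    from . import __version__
    from .io import (
        read_annotations,
        read_covariates_tsv,
        read_fasta,
        read_pileup_tsv,
        write_gene_tsv,
        write_reactivity_tsv,
        write_window_tsv,
    )

    if cfg.input_dir is None or cfg.output_dir is None:
        raise ValueError("run_pipeline needs input_dir and output_dir")
    ind = cfg.input_dir
    seqs = read_fasta(os.path.join(ind, "transcripts.fa"))
    if not seqs:
        raise ValueError(f"{ind}: no transcripts found")
    ann = read_annotations(
        os.path.join(ind, "utr3.bed"), {k: len(v) for k, v in seqs.items()}
    )
    transcripts = []
    for rec in ann.itertuples(index=False):
        tid = rec.transcript_id
        if tid not in seqs:
            raise ValueError(f"annotation references unknown transcript {tid}")
        transcripts.append(
            TranscriptModel(
                id=tid,
                sequence=seqs[tid],
                cds_interval=(0, int(rec.utr_start)),
                utr3_interval=(int(rec.utr_start), int(rec.utr_end)),
            )
        )
    treated = read_pileup_tsv(os.path.join(ind, "pileup_treated.tsv"))
    untreated_path = os.path.join(ind, "pileup_untreated.tsv")
    untreated = read_pileup_tsv(untreated_path) if os.path.exists(untreated_path) else None
    covariates = read_covariates_tsv(os.path.join(ind, "covariates.tsv"))

    result = analyze_dataset(transcripts, treated, untreated, covariates, cfg)

    os.makedirs(cfg.output_dir, exist_ok=True)
    write_reactivity_tsv(result["profiles"].values(), os.path.join(cfg.output_dir, "reactivity.tsv"))
    write_window_tsv(result["windows"].values(), os.path.join(cfg.output_dir, "windows.tsv"))
    write_gene_tsv(result["gene_table"], os.path.join(cfg.output_dir, "genes.tsv"))
    manifest = {
        "version": __version__,
        "parameters": cfg.to_dict(),
        "counts": result["counts"],
        "statistics": result["stats"],
    }
    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    log.info(
        "pipeline done: %d/%d transcripts scored",
        result["counts"]["n_scored"],
        result["counts"]["n_input"],
    )
    return cfg.output_dir
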