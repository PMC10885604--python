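"""Mismatch pileups -> normalized per-base DMS reactivity.

The chain is: count mismatches (from aligned reads or a pileup table),
raw reactivity = mismatch / coverage, background correction against the
untreated sample (subtraction floored at 0 by default; a division mode is
available), then 2-8 %-style normalization: divide by the median of the top
5 % of values and cap at 1.0.

The top-5 % set is computed on background-corrected values; the pipeline
order is fixed as correct -> normalize.
"""
from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import PileupProfile, ReactivityProfile


class NormalizationError(ValueError):
    """Too few usable positions to compute a normalization factor."""


def count_mismatches_bam(
    path: str,
    references: Mapping[str, str],
    sample_label: str = "",
) -> dict[str, PileupProfile]:
    """Per-base coverage/mismatch counts from a BAM/SAM of transcript alignments.

    Only primary, uniquely mapped records are counted (secondary and
    supplementary alignments are dropped; multi-mappers are recognized by an
    NH tag > 1 when present, otherwise by MAPQ 0). Coverage counts aligned
    read bases only — deletions do not contribute — and ambiguous bases (N)
    on either side are excluded from both coverage and mismatches.
    """
    import pysam

    profiles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        for tid in fh.references:
            if tid not in references:
                raise ValueError(f"no reference sequence for transcript {tid}")
            L = fh.get_reference_length(tid)
            if L != len(references[tid]):
                raise ValueError(
                    f"{tid}: alignment reference length {L} != sequence length "
                    f"{len(references[tid])}"
                )
            profiles[tid] = (np.zeros(L, dtype=np.int64), np.zeros(L, dtype=np.int64))
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.has_tag("NH") and read.get_tag("NH") > 1:
                continue
            if not read.has_tag("NH") and read.mapping_quality == 0:
                continue
            tid = read.reference_name
            cov, mism = profiles[tid]
            ref = references[tid].upper().replace("T", "U")
            qseq = read.query_sequence
            if qseq is None:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                q = qseq[qpos].upper().replace("T", "U")
                r = ref[rpos]
                if q == "N" or r == "N":
                    continue
                cov[rpos] += 1
                if q != r:
                    mism[rpos] += 1
    out = {}
    for tid, (cov, mism) in profiles.items():
        seq = references[tid].upper().replace("T", "U")
        out[tid] = PileupProfile(
            transcript_id=tid,
            positions=np.arange(len(seq)),
            ref_base=np.array(list(seq)),
            coverage=cov,
            mismatch=mism,
            sample_label=sample_label,
        )
    return out


def count_mismatches(
    source,
    references: Optional[Mapping[str, str]] = None,
    sample_label: str = "",
) -> dict[str, PileupProfile]:
    """Dispatch: pileup TSV path / DataFrame, or BAM/SAM path with references."""
    if isinstance(source, pd.DataFrame):
        from .io import pileups_from_frame

        return pileups_from_frame(source)
    if isinstance(source, str) and source.endswith((".bam", ".sam")):
        if references is None:
            raise ValueError("BAM/SAM input needs reference sequences")
        return count_mismatches_bam(source, references, sample_label)
    from .io import read_pileup_tsv

    return read_pileup_tsv(source)


def mismatch_bed(p: PileupProfile) -> pd.DataFrame:
    """BED-compatible mismatch table (chrom, start, end, name, score=mismatch)."""
    return pd.DataFrame(
        {
            "chrom": p.transcript_id,
            "start": p.positions,
            "end": p.positions + 1,
            "name": p.ref_base,
            "score": p.mismatch,
        }
    )


def merge_replicates(replicates: Iterable[PileupProfile]) -> PileupProfile:
    """Merge biological replicates by summing coverage and mismatch counts."""
    reps = list(replicates)
    first = reps[0]
    cov = first.coverage.copy()
    mism = first.mismatch.copy()
    for r in reps[1:]:
        if r.transcript_id != first.transcript_id or len(r) != len(first):
            raise ValueError("replicates must cover the same transcript")
        cov += r.coverage
        mism += r.mismatch
    return PileupProfile(
        transcript_id=first.transcript_id,
        positions=first.positions.copy(),
        ref_base=first.ref_base.copy(),
        coverage=cov,
        mismatch=mism,
        sample_label=first.sample_label,
    )


def raw_reactivity(p: PileupProfile, min_coverage: int = 20) -> ReactivityProfile:
    """Raw reactivity = mismatch / coverage; positions below ``min_coverage`` masked."""
    ok = p.coverage >= max(min_coverage, 1)
    raw = np.full(len(p), np.nan)
    raw[ok] = p.mismatch[ok] / p.coverage[ok]
    return ReactivityProfile(
        transcript_id=p.transcript_id,
        positions=p.positions.copy(),
        ref_base=p.ref_base.copy(),
        raw=raw,
        mask=~ok,
        mask_reason=np.where(~ok, "low_coverage", ""),
    )


def subtract_background(
    treated: ReactivityProfile,
    untreated: ReactivityProfile,
    method: str = "subtract",
) -> ReactivityProfile:
    """Background-correct treated reactivities against the untreated control.

    ``method='subtract'`` (default): r' = max(0, r_t - r_u).
    ``method='divide'``: r' = r_t / r_u, masked where r_u = 0.
    A position masked on either side stays masked.
    """
    if treated.transcript_id != untreated.transcript_id:
        raise ValueError(
            f"transcript mismatch: {treated.transcript_id} vs {untreated.transcript_id}"
        )
    if len(treated) != len(untreated):
        raise ValueError(f"{treated.transcript_id}: profile lengths differ")
    mask = treated.mask | untreated.mask
    reason = np.where(treated.mask, treated.mask_reason, untreated.mask_reason)
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "subtract":
            corrected = np.maximum(0.0, treated.raw - untreated.raw)
        elif method == "divide":
            corrected = treated.raw / untreated.raw
            bad = ~mask & ~np.isfinite(corrected)
            mask = mask | bad
            reason = np.where(bad, "zero_untreated", reason)
        else:
            raise ValueError(f"unknown background method {method!r}")
    corrected = np.where(mask, np.nan, corrected)
    return ReactivityProfile(
        transcript_id=treated.transcript_id,
        positions=treated.positions.copy(),
        ref_base=treated.ref_base.copy(),
        raw=treated.raw.copy(),
        corrected=corrected,
        mask=mask,
        mask_reason=reason.astype("U32"),
    )


def normalization_factor(values: np.ndarray, top_fraction: float = 0.05) -> float:
    """Median of the top ``ceil(top_fraction * n)`` finite values."""
    vals = values[np.isfinite(values)]
    n = len(vals)
    k = max(1, math.ceil(top_fraction * n))
    top = np.sort(vals)[-k:]
    return float(np.median(top))

def normalize_reactivity(
    profile: ReactivityProfile,
    top_fraction: float = 0.05,
    min_positions: int = 20,
) -> ReactivityProfile:
    """Divide corrected reactivities by the top-5 %-median and cap at 1.0.

    Requires at least ``min_positions`` unmasked positions. If the
    normalization factor is 0 (no signal at all) every value becomes 0 and a
    warning is emitted.
    """
    corrected = profile.corrected if profile.corrected is not None else profile.raw
    finite = np.isfinite(corrected) & ~profile.mask
    n = int(finite.sum())
    if n < min_positions:
        raise NormalizationError(
            f"{profile.transcript_id}: only {n} unmasked positions "
            f"(need >= {min_positions}) for normalization"
        )
    s = normalization_factor(corrected[finite], top_fraction)
    normalized = np.full(len(profile), np.nan)
    if s == 0.0:
        warnings.warn(
            f"{profile.transcript_id}: zero normalization factor; "
            "all normalized reactivities set to 0",
            stacklevel=2,
        )
        normalized[finite] = 0.0
    else:
        normalized[finite] = np.minimum(1.0, corrected[finite] / s)
    return ReactivityProfile(
        transcript_id=profile.transcript_id,
        positions=profile.positions.copy(),
        ref_base=profile.ref_base.copy(),
        raw=profile.raw.copy(),
        corrected=corrected.copy(),
        normalized=normalized,
        mask=profile.mask.copy(),
        mask_reason=profile.mask_reason.copy(),
    )


def reactivity_pipeline(
    treated: PileupProfile,
    untreated: Optional[PileupProfile] = None,
    min_coverage: int = 20,
    top_fraction: float = 0.05,
    background_method: str = "subtract",
    min_positions: int = 20,
    region: Optional[tuple[int, int]] = None,
) -> ReactivityProfile:
    """Full chain pileup -> raw -> corrected -> normalized for one transcript.

    If ``region`` is given (e.g. the 3' UTR interval) the profile is sliced
    to it *before* normalization, so the top-5 % scaling is local to that
    region — the per-transcript 3'-end scope used for transcriptome-wide data.
    """
    t = raw_reactivity(treated, min_coverage)
    if untreated is not None:
        u = raw_reactivity(untreated, min_coverage)
        prof = subtract_background(t, u, method=background_method)
    else:
        prof = t
    if region is not None:
        prof = prof.slice(*region)
    return normalize_reactivity(prof, top_fraction, min_positions)
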