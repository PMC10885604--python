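"""Structure statistics: windowed Gini index, meta-gene stop-codon profile,
codon-position reactivity, pairing fraction, and constraint-file export.

The Gini index of a reactivity window measures how unevenly the DMS signal
is distributed: a structured stretch concentrates reactivity on the few
unpaired A/C bases (high Gini), an open stretch spreads it evenly (low
Gini). Windows are 50 nt with a 25-nt step by default, and only windows
averaging more than 20 raw mismatches are trusted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    DMS_BASES,
    GiniWindowSet,
    PileupProfile,
    ReactivityProfile,
    TranscriptModel,
)


def gini(values: Sequence[float]) -> float:
    """Gini index G = sum_ij |x_i - x_j| / (2 n^2 xbar) of non-negative values.

    Computed via the sorted-rank identity, which is O(n log n) and equal to
    the pairwise formula to floating-point precision. Requires n >= 2,
    x_i >= 0 and a positive mean; otherwise a ValueError is raised (callers
    skip such windows).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("Gini undefined for fewer than 2 values")
    if np.any(x < 0):
        raise ValueError("Gini undefined for negative values")
    total = x.sum()
    if total <= 0:
        raise ValueError("Gini undefined for zero-mean values")
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(2.0 * np.sum(i * xs) / (n * total) - (n + 1) / n)


def pairing_fraction(dotbracket: str) -> float:
    """(#'(' + #')') / length of a balanced dot-bracket string."""
    from .simulate import pair_table

    pair_table(dotbracket)  # validates balance
    n = len(dotbracket)
    if n == 0:
        raise ValueError("empty dot-bracket")
    return (dotbracket.count("(") + dotbracket.count(")")) / n


def n_windows(length: int, window_size: int = 50, step: int = 25) -> int:
    """Number of full sliding windows: floor((L - size) / step) + 1, or 0."""
    if length < window_size:
        return 0
    return (length - window_size) // step + 1


def window_gini(
    reactivity: ReactivityProfile,
    pileup: PileupProfile,
    window_size: int = 50,
    step: int = 25,
    mismatch_threshold: float = 20.0,
    ac_only: bool = True,
) -> GiniWindowSet:
    """Sliding-window Gini of normalized reactivities over one region.

    ``reactivity`` and ``pileup`` must cover the same positions (typically a
    3' UTR). The Gini of each window is computed on the normalized values of
    its included positions — unmasked, and A/C only by default since G/U
    carry no DMS signal. ``mean_mismatch`` averages the raw mismatch counts
    of *all* window positions; a window passes iff it exceeds
    ``mismatch_threshold``. Windows whose included values are all zero (or
    fewer than 2) get a NaN Gini and never contribute to the average.
    """
    if len(reactivity) != len(pileup) or not np.array_equal(
        reactivity.positions, pileup.positions
    ):
        raise ValueError(
            f"{reactivity.transcript_id}: reactivity and pileup cover different positions"
        )
    vals = reactivity.values
    included = ~reactivity.mask & np.isfinite(vals)
    if ac_only:
        included &= np.isin(reactivity.ref_base, list(DMS_BASES))
    L = len(reactivity)
    rows = []
    for w in range(n_windows(L, window_size, step)):
        s = w * step
        e = s + window_size
        mean_mism = float(pileup.mismatch[s:e].mean())
        sel = included[s:e]
        win_vals = vals[s:e][sel]
        try:
            g = gini(win_vals)
        except ValueError:
            g = float("nan")
        rows.append(
            {
                "start0": s,
                "end0": e,
                "gini": g,
                "mean_mismatch": mean_mism,
                "n_used_positions": int(sel.sum()),
                "passed": mean_mism > mismatch_threshold,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["start0", "end0", "gini", "mean_mismatch", "n_used_positions", "passed"],
    )
    return GiniWindowSet(
        transcript_id=reactivity.transcript_id,
        windows=frame,
        window_size=window_size,
        step=step,
    )


@dataclass
class MetageneResult:
    """Aligned stop-codon meta-profile over many transcripts.

    Positions run from -flank (CDS side) through the 3 stop-codon bases
    (offsets 0..2) to +flank (3' UTR side). ``mean_reactivity`` averages
    unmasked normalized values per position; ``nt_freq`` columns A/C/G/U sum
    to 1 per position.
    """

    offsets: np.ndarray
    mean_reactivity: np.ndarray
    nt_freq: pd.DataFrame
    cds_means: np.ndarray     # per-transcript mean over the CDS flank
    utr_means: np.ndarray     # per-transcript mean over the UTR flank
    ranksum_stat: float
    ranksum_p: float
    n_used: int
    n_skipped: int

    def frame(self) -> pd.DataFrame:
        out = self.nt_freq.copy()
        out.insert(0, "offset", self.offsets)
        out["mean_reactivity"] = self.mean_reactivity
        return out


def _metagene_offsets(flank: int) -> np.ndarray:
    # -flank..-1 (CDS), 0..2 (stop codon), 3..flank+2 relabelled 1..flank (UTR)
    return np.concatenate(
        [np.arange(-flank, 0), np.array([0, 1, 2]), np.arange(1, flank + 1) + 2]
    )


def metagene_stop_profile(
    profiles: Iterable[ReactivityProfile],
    transcripts: dict[str, TranscriptModel],
    flank: int = 100,
) -> MetageneResult:
    """Mean reactivity and nucleotide frequency around stop codons.

    Transcripts need >= flank nt of CDS before the stop codon and >= flank nt
    of 3' UTR after it; others are skipped and counted. The stop codon's own
    3 positions belong to neither flank mean. The CDS-vs-UTR comparison is a
    two-sided rank-sum test on the per-transcript flank means.
    """
    width = 2 * flank + 3
    mat_rows: list[np.ndarray] = []
    base_rows: list[np.ndarray] = []
    n_skipped = 0
    for prof in profiles:
        t = transcripts.get(prof.transcript_id)
        if t is None:
            n_skipped += 1
            continue
        stop = t.stop_codon_start
        utr_len = t.utr3_interval[1] - (stop + 3)
        if stop < flank or utr_len < flank:
            n_skipped += 1
            continue
        lo, hi = stop - flank, stop + 3 + flank
        sel = (prof.positions >= lo) & (prof.positions < hi)
        if int(sel.sum()) != width:
            n_skipped += 1
            continue
        vals = np.where(prof.mask[sel], np.nan, prof.values[sel])
        mat_rows.append(vals)
        base_rows.append(prof.ref_base[sel])
    if not mat_rows:
        raise ValueError("no transcript satisfies the flank requirement")
    mat = np.vstack(mat_rows)
    bases = np.vstack(base_rows)
    with np.errstate(invalid="ignore"):
        mean_reactivity = np.nanmean(mat, axis=0)
    freq = pd.DataFrame(
        {b: (bases == b).mean(axis=0) for b in "ACGU"}
    )
    cds_means = np.nanmean(mat[:, :flank], axis=1)
    utr_means = np.nanmean(mat[:, flank + 3:], axis=1)
    ok = np.isfinite(cds_means) & np.isfinite(utr_means)
    if mat.shape[0] == 1 or not ok.any():
        stat, p = float("nan"), float("nan")
    else:
        stat, p = stats.ranksums(cds_means[ok], utr_means[ok])
    return MetageneResult(
        offsets=_metagene_offsets(flank),
        mean_reactivity=mean_reactivity,
        nt_freq=freq,
        cds_means=cds_means,
        utr_means=utr_means,
        ranksum_stat=float(stat),
        ranksum_p=float(p),
        n_used=mat.shape[0],
        n_skipped=n_skipped,
    )


def codon_position_reactivity(
    profiles: Iterable[ReactivityProfile],
    transcripts: dict[str, TranscriptModel],
    flank: int = 100,
) -> pd.DataFrame:
    """Mean reactivity at codon positions 1-3, CDS side and 3' UTR side.

    The CDS reading frame is anchored at the stop codon (codons counted
    backwards from it, within the flank); the UTR side is framed from the
    first base just downstream of the stop codon. Returns a 2x3 table
    (index 'cds'/'utr', columns 1/2/3); a side with no usable values is NaN.
    """
    buckets: dict[tuple[str, int], list[float]] = {
        (side, k): [] for side in ("cds", "utr") for k in (1, 2, 3)
    }
    for prof in profiles:
        t = transcripts.get(prof.transcript_id)
        if t is None:
            continue
        stop = t.stop_codon_start
        utr_start = stop + 3
        vals = prof.values
        usable = ~prof.mask & np.isfinite(vals)
        for idx in range(len(prof)):
            pos = int(prof.positions[idx])
            if not usable[idx]:
                continue
            if stop - flank <= pos < stop:
                frame = (pos - stop) % 3  # 0 => codon position 1
                buckets[("cds", frame + 1)].append(float(vals[idx]))
            elif utr_start <= pos < min(utr_start + flank, t.utr3_interval[1]):
                frame = (pos - utr_start) % 3
                buckets[("utr", frame + 1)].append(float(vals[idx]))
    data = {
        side: [
            float(np.mean(buckets[(side, k)])) if buckets[(side, k)] else float("nan")
            for k in (1, 2, 3)
        ]
        for side in ("cds", "utr")
    }
    return pd.DataFrame(data, index=[1, 2, 3]).T


def export_constraints(
    profile: ReactivityProfile,
    region: Optional[tuple[int, int]] = None,
) -> pd.DataFrame:
    """SHAPE-style constraint table for an external folding engine.

    Two columns: 1-based position within ``region`` and the reactivity;
    masked positions and G/U bases (DMS-uninformative) are written as -999.
    """
    if region is None:
        region = (int(profile.positions.min()), int(profile.positions.max()) + 1)
    start, end = region
    sel = (profile.positions >= start) & (profile.positions < end)
    if int(sel.sum()) != end - start:
        raise ValueError(
            f"{profile.transcript_id}: region [{start}, {end}) not fully covered"
        )
    vals = profile.values[sel]
    informative = (
        ~profile.mask[sel]
        & np.isfinite(vals)
        & np.isin(profile.ref_base[sel], list(DMS_BASES))
    )
    out = np.where(informative, vals, -999.0)
    return pd.DataFrame({"position": np.arange(1, end - start + 1), "reactivity": out})
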