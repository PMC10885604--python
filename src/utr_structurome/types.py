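"""Core containers shared by the simulation, reactivity, and scoring stages.

All coordinates are 0-based, half-open, on the transcript (not the genome).
Sequences are RNA strings over {A, C, G, U}; dot-bracket strings use the
Vienna convention with '.' for unpaired and matched '(' / ')' for base pairs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

RNA_BASES = ("A", "C", "G", "U")
DMS_BASES = frozenset({"A", "C"})  # DMS methylates unpaired adenosine / cytosine


@dataclass
class TranscriptModel:
    """A transcript with an annotated CDS end and 3' UTR.

    ``dotbracket`` is the ground-truth secondary structure of the 3' UTR
    (aligned to ``utr3_interval``); ``cds_dotbracket`` optionally carries a
    structure for the CDS so treated pileups can be simulated upstream of the
    stop codon as well (the coding region of real mRNAs is itself partly
    paired).
    """

    id: str
    sequence: str
    cds_interval: tuple[int, int]
    utr3_interval: tuple[int, int]
    polya_site: Optional[int] = None
    dotbracket: Optional[str] = None
    cds_dotbracket: Optional[str] = None

    def __post_init__(self) -> None:
        cs, ce = self.cds_interval
        us, ue = self.utr3_interval
        if us != ce:
            raise ValueError(
                f"{self.id}: 3' UTR must begin at the CDS end ({us} != {ce})"
            )
        if ue > len(self.sequence):
            raise ValueError(f"{self.id}: 3' UTR extends past the sequence end")
        if self.dotbracket is not None and len(self.dotbracket) != ue - us:
            raise ValueError(
                f"{self.id}: dot-bracket length {len(self.dotbracket)} does not "
                f"match 3' UTR length {ue - us}"
            )

    @property
    def stop_codon_start(self) -> int:
        """0-based index of the first stop-codon base (CDS includes the stop)."""
        return self.cds_interval[1] - 3

    @property
    def utr3_length(self) -> int:
        return self.utr3_interval[1] - self.utr3_interval[0]

    @property
    def utr3_sequence(self) -> str:
        return self.sequence[self.utr3_interval[0]: self.utr3_interval[1]]

    @property
    def pairing_fraction(self) -> Optional[float]:
        """Fraction of paired bases in the 3' UTR, or None without a structure."""
        if self.dotbracket is None:
            return None
        n = len(self.dotbracket)
        return (self.dotbracket.count("(") + self.dotbracket.count(")")) / n


@dataclass
class PileupProfile:
    """Per-base coverage and mismatch counts for one sample over one transcript."""

    transcript_id: str
    positions: np.ndarray  # 0-based
    ref_base: np.ndarray   # unicode 'A'/'C'/'G'/'U'
    coverage: np.ndarray   # int
    mismatch: np.ndarray   # int
    sample_label: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_base = np.asarray(self.ref_base, dtype="U1")
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.mismatch = np.asarray(self.mismatch, dtype=np.int64)
        n = len(self.positions)
        if not (len(self.ref_base) == len(self.coverage) == len(self.mismatch) == n):
            raise ValueError(f"{self.transcript_id}: pileup arrays differ in length")
        if np.any(self.mismatch > self.coverage):
            raise ValueError(f"{self.transcript_id}: mismatch count exceeds coverage")
        if np.any(self.coverage < 0):
            raise ValueError(f"{self.transcript_id}: negative coverage")

    def __len__(self) -> int:
        return len(self.positions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PileupProfile):
            return NotImplemented
        return (
            self.transcript_id == other.transcript_id
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref_base, other.ref_base)
            and np.array_equal(self.coverage, other.coverage)
            and np.array_equal(self.mismatch, other.mismatch)
        )


@dataclass
class ReactivityProfile:
    """Raw, background-corrected, and normalized DMS reactivities per base.

    ``mask`` is True where a position is excluded (low coverage, missing
    counterpart in the untreated sample, ...); ``mask_reason`` says why.
    Normalized values lie in [0, 1] wherever defined.
    """

    transcript_id: str
    positions: np.ndarray
    ref_base: np.ndarray
    raw: np.ndarray                        # NaN where masked
    corrected: Optional[np.ndarray] = None
    normalized: Optional[np.ndarray] = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask_reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_base = np.asarray(self.ref_base, dtype="U1")
        self.raw = np.asarray(self.raw, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.raw)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask_reason is None:
            self.mask_reason = np.where(self.mask, "low_coverage", "")
        self.mask_reason = np.asarray(self.mask_reason, dtype="U32")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def values(self) -> np.ndarray:
        """The most processed reactivity available (normalized > corrected > raw)."""
        if self.normalized is not None:
            return self.normalized
        if self.corrected is not None:
            return self.corrected
        return self.raw

    def slice(self, start: int, end: int) -> "ReactivityProfile":
        """Sub-profile over transcript positions [start, end) (0-based half-open)."""
        sel = (self.positions >= start) & (self.positions < end)
        return ReactivityProfile(
            transcript_id=self.transcript_id,
            positions=self.positions[sel],
            ref_base=self.ref_base[sel],
            raw=self.raw[sel],
            corrected=None if self.corrected is None else self.corrected[sel],
            normalized=None if self.normalized is None else self.normalized[sel],
            mask=self.mask[sel],
            mask_reason=self.mask_reason[sel],
        )


@dataclass
class GiniWindowSet:
    """Sliding-window Gini values for one transcript's 3' UTR.

    ``windows`` has columns start0, end0, gini, mean_mismatch, n_used_positions,
    passed. ``passed`` records the per-window mean-mismatch filter; the
    per-transcript average uses passed windows with a defined Gini.
    """

    transcript_id: str
    windows: pd.DataFrame
    window_size: int = 50
    step: int = 25

    def _usable(self) -> np.ndarray:
        if len(self.windows) == 0:
            return np.zeros(0, dtype=bool)
        return (
            self.windows["passed"].to_numpy(dtype=bool)
            & np.isfinite(self.windows["gini"].to_numpy(dtype=float))
        )

    @property
    def avg_gini(self) -> float:
        """Unweighted mean Gini over passed windows; NaN if none passed."""
        ok = self._usable()
        if not ok.any():
            return float("nan")
        return float(self.windows.loc[ok, "gini"].mean())

    @property
    def n_passed(self) -> int:
        return int(self._usable().sum())


@dataclass
class DecayCurve:
    """A reference-normalized decay time course for one gene."""

    gene_id: str
    timepoints: np.ndarray       # hours
    relative_abundance: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.relative_abundance = np.asarray(self.relative_abundance, dtype=float)
        if len(self.timepoints) != len(self.relative_abundance):
            raise ValueError(f"{self.gene_id}: timepoints/abundance length mismatch")


def records_to_frame(records: list[dict]) -> pd.DataFrame:
    """Convenience: list of per-gene dicts -> gene table."""
    return pd.DataFrame.from_records(records)


def asdict(obj) -> dict:
    return dataclasses.asdict(obj)
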