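"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA (Biopython), BED6 and GFF3 annotations (gffutils), Vienna dot-bracket
files, pileup / reactivity / covariate / window TSVs, SHAPE-style constraint
files, and decay time-course tables. Every exported table starts with a
comment declaring its coordinate convention; all internal coordinates are
0-based half-open, constraint files are 1-based per the SHAPE convention.
"""
from __future__ import annotations

import os
import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import DecayCurve, GiniWindowSet, PileupProfile, ReactivityProfile

_COORD_HEADER = "# coordinates: 0-based, half-open\n"

PILEUP_COLUMNS = ["transcript_id", "pos0", "ref_base", "coverage", "mismatch_count", "sample"]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper().replace("T", "U") for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# Dot-bracket (Vienna style: >header / sequence / structure)

def write_dotbracket(entries: Mapping[str, tuple[str, str]], path: str) -> None:
    """``entries`` maps id -> (sequence, dotbracket)."""
    with open(path, "w") as fh:
        for name, (seq, db) in entries.items():
            fh.write(f">{name}\n{seq}\n{db}\n")


def read_dotbracket(path: str) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}")
        name = lines[i][1:].split()[0]
        seq, db = lines[i + 1], lines[i + 2]
        if len(seq) != len(db):
            raise ValueError(f"{path}:{name}: sequence/structure length mismatch")
        out[name] = (seq, db)
        i += 3
    return out


# ---------------------------------------------------------------------------
# Annotations (BED6 / GFF3) -> transcript intervals

def write_utr_bed(intervals: Mapping[str, tuple[int, int]], path: str) -> None:
    """BED6 of 3' UTR intervals on transcript coordinates (plus strand)."""
    with open(path, "w") as fh:
        for name, (start, end) in intervals.items():
            fh.write(f"{name}\t{start}\t{end}\t{name}\t0\t+\n")


def _flip(start: int, end: int, length: int) -> tuple[int, int]:
    return length - end, length - start


def read_annotations(
    path: str, seq_lengths: Optional[Mapping[str, int]] = None
) -> pd.DataFrame:
    """Normalize BED6 or GFF3 annotations to transcript-coordinate intervals.

    Returns a frame with transcript_id, utr_start, utr_end, stop_codon_start,
    strand (0-based half-open, transcript orientation). Minus-strand features
    are flipped into transcript coordinates, which requires ``seq_lengths``.
    GFF3 input uses ``three_prime_UTR`` and ``stop_codon`` features grouped by
    Parent (or transcript_id/ID); a transcript with a UTR but no stop codon is
    skipped with a warning. BED input infers the stop codon as the 3 nt
    upstream of the UTR.
    """
    if path.endswith((".gff", ".gff3")):
        return _read_gff3(path, seq_lengths)
    return _read_bed(path, seq_lengths)


def _read_bed(path: str, seq_lengths) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    rows = []
    for rec in bed.itertuples(index=False):
        start, end, strand = int(rec.start), int(rec.end), str(rec.strand)
        if strand == "-":
            if seq_lengths is None or rec.chrom not in seq_lengths:
                raise ValueError(f"{rec.name}: minus-strand record needs a sequence length")
            start, end = _flip(start, end, seq_lengths[rec.chrom])
        rows.append(
            {
                "transcript_id": rec.name,
                "utr_start": start,
                "utr_end": end,
                "stop_codon_start": start - 3,
                "strand": strand,
            }
        )
    return pd.DataFrame(rows)


def _read_gff3(path: str, seq_lengths) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    def parent_of(feature) -> str:
        for key in ("Parent", "transcript_id", "ID"):
            if key in feature.attributes:
                return feature.attributes[key][0]
        return feature.seqid

    utrs: dict[str, list] = {}
    stops: dict[str, list] = {}
    for feat in db.features_of_type("three_prime_UTR"):
        utrs.setdefault(parent_of(feat), []).append(feat)
    for feat in db.features_of_type("stop_codon"):
        stops.setdefault(parent_of(feat), []).append(feat)

    rows = []
    for tid, feats in sorted(utrs.items()):
        if tid not in stops:
            warnings.warn(f"{tid}: no stop_codon feature; transcript skipped", stacklevel=2)
            continue
        feat = feats[0]
        stop = stops[tid][0]
        # GFF3 is 1-based inclusive
        start, end = feat.start - 1, feat.end
        s_start, s_end = stop.start - 1, stop.end
        strand = feat.strand
        if strand == "-":
            if seq_lengths is None or feat.seqid not in seq_lengths:
                raise ValueError(f"{tid}: minus-strand record needs a sequence length")
            L = seq_lengths[feat.seqid]
            start, end = _flip(start, end, L)
            s_start, s_end = _flip(s_start, s_end, L)
        rows.append(
            {
                "transcript_id": tid,
                "utr_start": start,
                "utr_end": end,
                "stop_codon_start": s_start,
                "strand": strand,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pileup TSV

def write_pileup_tsv(profiles: Iterable[PileupProfile], path: str) -> None:
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": p.transcript_id,
                    "pos0": p.positions,
                    "ref_base": p.ref_base,
                    "coverage": p.coverage,
                    "mismatch_count": p.mismatch,
                    "sample": p.sample_label,
                }
            )
        )
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)


def pileups_from_frame(frame: pd.DataFrame) -> dict[str, PileupProfile]:
    out = {}
    for tid, grp in frame.groupby("transcript_id", sort=True):
        grp = grp.sort_values("pos0")
        out[str(tid)] = PileupProfile(
            transcript_id=str(tid),
            positions=grp["pos0"].to_numpy(),
            ref_base=grp["ref_base"].to_numpy(dtype="U1"),
            coverage=grp["coverage"].to_numpy(),
            mismatch=grp["mismatch_count"].to_numpy(),
            sample_label=str(grp["sample"].iloc[0]) if "sample" in grp else "",
        )
    return out


def read_pileup_tsv(path: str) -> dict[str, PileupProfile]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PILEUP_COLUMNS[:-1]) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing pileup columns {sorted(missing)}")
    return pileups_from_frame(frame)


# ---------------------------------------------------------------------------
# Reactivity TSV

def write_reactivity_tsv(profiles: Iterable[ReactivityProfile], path: str) -> None:
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": p.transcript_id,
                    "pos0": p.positions,
                    "ref_base": p.ref_base,
                    "raw": p.raw,
                    "corrected": p.corrected if p.corrected is not None else np.nan,
                    "normalized": p.normalized if p.normalized is not None else np.nan,
                    "mask_reason": p.mask_reason,
                }
            )
        )
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)


def read_reactivity_tsv(path: str) -> dict[str, ReactivityProfile]:
    frame = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                        na_values=[""], dtype={"mask_reason": str})
    out = {}
    for tid, grp in frame.groupby("transcript_id", sort=True):
        grp = grp.sort_values("pos0")
        reason = grp["mask_reason"].fillna("").to_numpy(dtype="U32")
        out[str(tid)] = ReactivityProfile(
            transcript_id=str(tid),
            positions=grp["pos0"].to_numpy(),
            ref_base=grp["ref_base"].to_numpy(dtype="U1"),
            raw=grp["raw"].to_numpy(dtype=float),
            corrected=grp["corrected"].to_numpy(dtype=float),
            normalized=grp["normalized"].to_numpy(dtype=float),
            mask=reason != "",
            mask_reason=reason,
        )
    return out


# ---------------------------------------------------------------------------
# Window / gene tables

def write_window_tsv(window_sets: Iterable[GiniWindowSet], path: str) -> None:
    frames = []
    for ws in window_sets:
        f = ws.windows.copy()
        f.insert(0, "transcript_id", ws.transcript_id)
        frames.append(f)
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)


def write_gene_tsv(gene_table: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        gene_table.to_csv(fh, sep="\t", index=False)


def read_gene_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# SHAPE-style constraints (1-based positions, -999 = no data)

def write_constraints(constraints: pd.DataFrame, path: str) -> None:
    constraints.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


def read_constraints(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, names=["position", "reactivity"])
    frame["position"] = frame["position"].astype(int)
    return frame


# ---------------------------------------------------------------------------
# Covariates & decay curves

def write_covariates_tsv(covariates: pd.DataFrame, path: str) -> None:
    covariates.to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_decay_tsv(path: str) -> list[DecayCurve]:
    """Decay table with columns gene_id, time_h, relative_abundance."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    curves = []
    for gid, grp in frame.groupby("gene_id", sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            DecayCurve(
                gene_id=str(gid),
                timepoints=grp["time_h"].to_numpy(),
                relative_abundance=grp["relative_abundance"].to_numpy(),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Simulated dataset round trip

def write_simulated_dataset(ds, outdir: str) -> None:
    """Write a SimulatedDataset as FASTA + BED + dot-bracket + pileup/covariate TSVs."""
    os.makedirs(outdir, exist_ok=True)
    write_fasta({t.id: t.sequence for t in ds.transcripts}, os.path.join(outdir, "transcripts.fa"))
    write_utr_bed(
        {t.id: t.utr3_interval for t in ds.transcripts}, os.path.join(outdir, "utr3.bed")
    )
    write_dotbracket(
        {t.id: (t.utr3_sequence, t.dotbracket) for t in ds.transcripts if t.dotbracket},
        os.path.join(outdir, "utr3_structures.db"),
    )
    write_pileup_tsv(ds.treated.values(), os.path.join(outdir, "pileup_treated.tsv"))
    write_pileup_tsv(ds.untreated.values(), os.path.join(outdir, "pileup_untreated.tsv"))
    write_covariates_tsv(ds.covariates, os.path.join(outdir, "covariates.tsv"))
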