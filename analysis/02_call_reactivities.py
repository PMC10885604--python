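#!/usr/bin/env python
"""Call per-base DMS reactivities for every simulated transcript.

Reads the pileups from results/sim/, runs the chain raw -> background-
subtracted -> top-5%-median normalized over each 3' UTR, and writes
results/reactivity.tsv. Reports how many transcripts were normalizable.
"""
import pathlib
import sys

from utr_structurome import RunConfig
from utr_structurome.io import (
    read_annotations,
    read_fasta,
    read_pileup_tsv,
    write_reactivity_tsv,
)
from utr_structurome.reactivity import NormalizationError, reactivity_pipeline

BASE = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sim = BASE / "sim"
    if not sim.exists():
        sys.exit("run 01_simulate_probing_data.py first")
    cfg = RunConfig(mode="genomewide")
    seqs = read_fasta(str(sim / "transcripts.fa"))
    ann = read_annotations(str(sim / "utr3.bed")).set_index("transcript_id")
    treated = read_pileup_tsv(str(sim / "pileup_treated.tsv"))
    untreated = read_pileup_tsv(str(sim / "pileup_untreated.tsv"))
    profiles, failed = [], 0
    for tid in sorted(seqs):
        region = (int(ann.loc[tid, "utr_start"]), int(ann.loc[tid, "utr_end"]))
        try:
            profiles.append(
                reactivity_pipeline(
                    treated[tid], untreated[tid],
                    min_coverage=cfg.min_coverage, region=region,
                )
            )
        except NormalizationError:
            failed += 1
    out = BASE / "reactivity.tsv"
    write_reactivity_tsv(profiles, str(out))
    print(f"normalized {len(profiles)} 3' UTR profiles ({failed} failed) -> {out}")


if __name__ == "__main__":
    main()
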