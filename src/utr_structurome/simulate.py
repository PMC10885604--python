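"""Synthetic chemical-probing data generator.

Emulates the statistical structure of a 3'-end DMS mutational-profiling
experiment over a transcriptome whose 3' UTR structure is coupled to
expression and stability:

* 3' UTR secondary structures are *constructed* (hairpin stems placed in an
  unpaired scaffold), not folded thermodynamically: the downstream analysis
  consumes reactivities, never energies.
* DMS modification hits unpaired A/C at ``dms_rate_unpaired``, leaks onto
  paired A/C at ``dms_rate_paired``, and every base carries a small
  ``background_error`` mismatch rate (also the only signal in untreated
  samples).
* Coverage rises toward the 3' end as c(i) = mean_coverage * ((i+1)/L)**bias,
  mimicking a 3'-anchored library; bias = 0 recovers uniform coverage.
* Expression (RPKM) and half-life are log-linear in the 3' UTR pairing
  fraction with negative slopes (the structure-mediated-decay assumption)
  plus lognormal noise.

Everything is deterministic given a :class:`SimConfig` and its seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import DMS_BASES, PileupProfile, TranscriptModel

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class StructureTargetError(ValueError):
    """Requested pairing fraction is unreachable for the given length."""


@dataclass
class ExpressionModel:
    """log(RPKM) = baseline + slope * pairing_fraction + Normal(0, sd)."""

    baseline: float = 4.0   # natural-log RPKM at pairing fraction 0 (~55 RPKM)
    slope: float = -2.0     # <= 0: structure suppresses expression
    sd: float = 0.5         # lognormal noise


@dataclass
class HalfLifeModel:
    """log(t1/2) = log(baseline) + slope * pairing_fraction + Normal(0, sd)."""

    baseline: float = 4.0   # hours at pairing fraction 0
    slope: float = -1.0     # <= 0: structured UTRs decay faster
    sd: float = 0.3


@dataclass
class SimConfig:
    """Study conditions for the synthetic probing experiment."""

    n_genes: int = 300
    utr_length_range: tuple[int, int] = (150, 300)
    cds_length_range: tuple[int, int] = (150, 300)
    pairing_fraction_levels: tuple[float, ...] = (0.1, 0.7)
    cds_pairing_fraction: float = 0.7
    dms_rate_unpaired: float = 0.05
    dms_rate_paired: float = 0.005
    background_error: float = 0.002
    mean_coverage: float = 3000.0
    three_prime_bias: float = 0.5
    min_stem: int = 4
    max_stem: int = 8
    min_loop: int = 3
    polya_median: float = 80.0     # nt; lognormal median of tail length
    polya_log_sd: float = 0.4
    polya_slope: float = 0.0       # optional coupling of tail length to structure
    mirna_target_rate: float = 0.3
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)
    halflife_model: HalfLifeModel = field(default_factory=HalfLifeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("dms_rate_unpaired", "dms_rate_paired", "background_error"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not self.dms_rate_unpaired > self.dms_rate_paired >= self.background_error:
            raise ValueError(
                "require dms_rate_unpaired > dms_rate_paired >= background_error"
            )
        for lvl in self.pairing_fraction_levels:
            if not 0.0 <= lvl <= 0.95:
                raise ValueError(f"pairing fraction level {lvl} outside [0, 0.95]")
        if self.expression_model.slope > 0 or self.halflife_model.slope > 0:
            raise ValueError(
                "expression/half-life slopes must be <= 0 (structure suppresses "
                "expression and shortens half-life; 0 disables the coupling)"
            )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def max_pairing_fraction(
    length: int, min_stem: int = 4, max_stem: int = 8, min_loop: int = 3
) -> float:
    """Largest pairing fraction reachable by packing hairpins into ``length`` nt."""
    unit = 2 * max_stem + min_loop
    k = length // unit
    rem = length - k * unit
    extra = 0
    if rem >= 2 * min_stem + min_loop:
        extra = min(max_stem, (rem - min_loop) // 2)
    return 2 * (k * max_stem + extra) / length


def _stem_decomposition(n_pairs: int, min_stem: int, max_stem: int) -> list[int]:
    """Express n_pairs as a sum of stem lengths in [min_stem, max_stem]."""
    stems: list[int] = []
    r = n_pairs
    while r > 0:
        if min_stem <= r <= max_stem:
            stems.append(r)
            r = 0
        elif r > max_stem:
            s = max_stem
            if 0 < r - s < min_stem:
                s = r - min_stem  # leave a legal remainder
            stems.append(s)
            r -= s
        else:  # 0 < r < min_stem: round to the nearer of 0 / min_stem
            break
    if 0 < r < min_stem and (min_stem - r) <= r:
        stems.append(min_stem)
    return stems


def simulate_structure(
    length: int,
    target_pairing_fraction: float,
    seed: int,
    min_stem: int = 4,
    max_stem: int = 8,
    min_loop: int = 3,
) -> str:
    """Construct a balanced dot-bracket of ``length`` nt near a target pairing level.

    Hairpin stems (``min_stem``..``max_stem`` pairs, loops >= ``min_loop`` nt)
    are placed at seed-determined positions in an unpaired scaffold until the
    achieved pairing fraction lies within +/-0.05 of the target.

    Raises
    ------
    StructureTargetError
        If no stem packing can reach the target; the message names the
        maximum achievable fraction.
    """
    if length < 20:
        raise ValueError(f"length {length} < 20")
    if not 0.0 <= target_pairing_fraction <= 0.95:
        raise ValueError("target pairing fraction must lie in [0, 0.95]")
    rng = np.random.default_rng(seed)

    n_pairs = int(round(target_pairing_fraction * length)) // 2
    stems = _stem_decomposition(n_pairs, min_stem, max_stem)
    consumed = sum(2 * s + min_loop for s in stems)
    achieved = 2 * sum(stems) / length
    if consumed > length or abs(achieved - target_pairing_fraction) > 0.05 + 1e-9:
        max_frac = max_pairing_fraction(length, min_stem, max_stem, min_loop)
        raise StructureTargetError(
            f"target pairing fraction {target_pairing_fraction} unreachable at "
            f"length {length} (max achievable {max_frac:.3f} with stems of "
            f"{min_stem}-{max_stem} pairs and loops >= {min_loop} nt)"
        )

    slack = length - consumed
    k = len(stems)
    # distribute the unpaired slack into the k+1 gaps around the hairpins
    if k == 0:
        return "." * length
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    gaps = np.diff(np.concatenate(([0], cuts, [slack])))
    order = rng.permutation(k)
    parts: list[str] = []
    for i, stem_idx in enumerate(order):
        s = stems[stem_idx]
        parts.append("." * int(gaps[i]))
        parts.append("(" * s + "." * min_loop + ")" * s)
    parts.append("." * int(gaps[k]))
    db = "".join(parts)
    assert len(db) == length
    return db


def pair_table(dotbracket: str) -> dict[int, int]:
    """Map each paired position to its partner; raises on unbalanced input."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unclosed '('")
    return pairs


def _structured_sequence(dotbracket: str, rng: np.random.Generator) -> str:
    """Random RNA sequence whose paired positions carry complementary bases."""
    bases = list(rng.choice(list("ACGU"), size=len(dotbracket)))
    for i, j in pair_table(dotbracket).items():
        if i < j:
            bases[j] = COMPLEMENT[bases[i]]
    return "".join(bases)


def simulate_transcript(
    gene_index: int,
    pairing_level: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> TranscriptModel:
    """One transcript: CDS (own constructed structure) + structured 3' UTR."""
    utr_len = int(rng.integers(cfg.utr_length_range[0], cfg.utr_length_range[1] + 1))
    cds_len = int(rng.integers(cfg.cds_length_range[0], cfg.cds_length_range[1] + 1))
    cds_len -= cds_len % 3  # whole codons
    struct_seed = int(rng.integers(0, 2**31 - 1))
    utr_db = simulate_structure(
        utr_len, pairing_level, struct_seed,
        cfg.min_stem, cfg.max_stem, cfg.min_loop,
    )
    cds_db = simulate_structure(
        cds_len, cfg.cds_pairing_fraction, struct_seed + 1,
        cfg.min_stem, cfg.max_stem, cfg.min_loop,
    )
    # keep the stop codon itself unpaired so we can pin its sequence
    cds_list = list(cds_db)
    ptab = pair_table(cds_db)
    for i in range(cds_len - 3, cds_len):
        if cds_list[i] != ".":
            cds_list[ptab[i]] = "."
            cds_list[i] = "."
    cds_db = "".join(cds_list)

    seq = _structured_sequence(cds_db + utr_db, rng)
    seq = seq[: cds_len - 3] + "UAA" + seq[cds_len:]
    return TranscriptModel(
        id=f"g{gene_index:05d}",
        sequence=seq,
        cds_interval=(0, cds_len),
        utr3_interval=(cds_len, cds_len + utr_len),
        polya_site=cds_len + utr_len,
        dotbracket=utr_db,
        cds_dotbracket=cds_db,
    )


def _paired_mask(t: TranscriptModel) -> np.ndarray:
    """Boolean per-base paired status over the whole transcript."""
    L = len(t.sequence)
    mask = np.zeros(L, dtype=bool)
    if t.cds_dotbracket is not None:
        cs, ce = t.cds_interval
        mask[cs:ce] = np.frombuffer(t.cds_dotbracket.encode(), dtype="S1") != b"."
    if t.dotbracket is not None:
        us, ue = t.utr3_interval
        mask[us:ue] = np.frombuffer(t.dotbracket.encode(), dtype="S1") != b"."
    return mask


def modification_probabilities(t: TranscriptModel, cfg: SimConfig, treated: bool) -> np.ndarray:
    """Per-base mismatch probability under the generative model."""
    L = len(t.sequence)
    p = np.full(L, cfg.background_error)
    if treated:
        base = np.frombuffer(t.sequence.encode(), dtype="S1")
        is_ac = (base == b"A") | (base == b"C")
        paired = _paired_mask(t)
        p = p + np.where(is_ac & ~paired, cfg.dms_rate_unpaired, 0.0)
        p = p + np.where(is_ac & paired, cfg.dms_rate_paired, 0.0)
    return np.clip(p, 0.0, 1.0)


def coverage_profile(length: int, cfg: SimConfig) -> np.ndarray:
    """Deterministic 3'-biased coverage: c(i) = mean * ((i+1)/L)**bias."""
    i = np.arange(length, dtype=float)
    return np.rint(
        cfg.mean_coverage * ((i + 1.0) / length) ** cfg.three_prime_bias
    ).astype(np.int64)


def simulate_pileup(
    t: TranscriptModel, cfg: SimConfig, treated: bool, seed: int
) -> PileupProfile:
    """Binomial mismatch pileup for one sample over one transcript."""
    if treated and t.dotbracket is None:
        raise ValueError(f"{t.id}: treated pileup needs a ground-truth structure")
    rng = np.random.default_rng(seed)
    L = len(t.sequence)
    cov = coverage_profile(L, cfg)
    p = modification_probabilities(t, cfg, treated)
    mism = rng.binomial(cov, p)
    return PileupProfile(
        transcript_id=t.id,
        positions=np.arange(L),
        ref_base=np.array(list(t.sequence)),
        coverage=cov,
        mismatch=mism,
        sample_label="treated" if treated else "untreated",
    )


def simulate_covariates(
    t: TranscriptModel, cfg: SimConfig, seed: int
) -> dict[str, float | bool | str]:
    """Expression, half-life, poly(A) length, and miRNA-target flag for one gene."""
    pf = t.pairing_fraction
    if pf is None:
        raise ValueError(f"{t.id}: covariates need a pairing fraction")
    rng = np.random.default_rng(seed)
    em, hm = cfg.expression_model, cfg.halflife_model
    log_rpkm = em.baseline + em.slope * pf + rng.normal(0.0, em.sd)
    log_t12 = np.log(hm.baseline) + hm.slope * pf + rng.normal(0.0, hm.sd)
    polya = np.exp(
        np.log(cfg.polya_median) + cfg.polya_slope * pf
        + rng.normal(0.0, cfg.polya_log_sd)
    )
    utr = t.utr3_sequence
    gc = 100.0 * (utr.count("G") + utr.count("C")) / len(utr)
    return {
        "transcript_id": t.id,
        "pairing_fraction": pf,
        "rpkm": float(np.exp(log_rpkm)),
        "half_life": float(np.exp(log_t12)),   # hours
        "polyA_len": float(np.rint(polya)),
        "mirna_target": bool(rng.random() < cfg.mirna_target_rate),
        "gc_content": gc,
        "utr_len": t.utr3_length,
    }


@dataclass
class SimulatedDataset:
    transcripts: list[TranscriptModel]
    treated: dict[str, PileupProfile]
    untreated: dict[str, PileupProfile]
    covariates: pd.DataFrame


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full synthetic experiment: transcripts, treated/untreated pileups, covariates.

    Genes are assigned to the configured pairing-fraction levels in equal
    proportion (round-robin), so two levels with n_genes = 300 yield 150 each.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_genes)
    levels = cfg.pairing_fraction_levels
    transcripts: list[TranscriptModel] = []
    treated: dict[str, PileupProfile] = {}
    untreated: dict[str, PileupProfile] = {}
    rows = []
    for g, child in enumerate(children):
        rng = np.random.default_rng(child)
        level = levels[g % len(levels)]
        t = simulate_transcript(g, level, cfg, rng)
        sub = [int(x) for x in rng.integers(0, 2**31 - 1, size=3)]
        treated[t.id] = simulate_pileup(t, cfg, treated=True, seed=sub[0])
        untreated[t.id] = simulate_pileup(t, cfg, treated=False, seed=sub[1])
        row = simulate_covariates(t, cfg, seed=sub[2])
        row["pairing_level"] = level  # the requested design level
        rows.append(row)
        transcripts.append(t)
    return SimulatedDataset(
        transcripts=transcripts,
        treated=treated,
        untreated=untreated,
        covariates=pd.DataFrame(rows),
    )
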