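"""Structure metrics: Gini, windowing, meta-gene profile, constraint export."""
import numpy as np
import pandas as pd
import pytest

from utr_structurome import (
    PileupProfile,
    ReactivityProfile,
    SimConfig,
    TranscriptModel,
    codon_position_reactivity,
    export_constraints,
    gini,
    metagene_stop_profile,
    n_windows,
    pairing_fraction,
    reactivity_pipeline,
    simulate_dataset,
    window_gini,
)
from utr_structurome.io import read_constraints, write_constraints
from utr_structurome.metrics import MetageneResult

from conftest import brute_force_gini


class TestGini:
    def test_constant_vector_is_zero(self):
        assert gini([3.0, 3.0, 3.0, 3.0]) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("n", [2, 4, 10])
    def test_one_hot_closed_form(self, n):
        x = np.zeros(n)
        x[-1] = 1.0
        assert gini(x) == pytest.approx((n - 1) / n)

    def test_matches_pairwise_brute_force(self, rng):
        for _ in range(50):
            x = rng.exponential(1.0, size=50)
            x[rng.random(50) < 0.3] = 0.0
            assert abs(gini(x) - brute_force_gini(x)) < 1e-12

    def test_scale_invariance(self, rng):
        x = rng.random(40)
        assert gini(5.5 * x) == pytest.approx(gini(x), abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            g = gini(rng.exponential(1.0, size=30))
            assert 0.0 <= g < 1.0

    @pytest.mark.parametrize("bad", [[1.0], [0.0, 0.0], [-1.0, 2.0]])
    def test_undefined_inputs_raise(self, bad):
        with pytest.raises(ValueError):
            gini(bad)


class TestPairingFraction:
    @pytest.mark.parametrize(
        "db,expected",
        [(".....", 0.0), ("((((....))))", 8 / 12)],
    )
    def test_examples(self, db, expected):
        assert pairing_fraction(db) == pytest.approx(expected)

    def test_matches_independent_scan(self, small_dataset):
        for t in small_dataset.transcripts[:10]:
            by_scan = sum(1 for c in t.dotbracket if c in "()") / len(t.dotbracket)
            assert pairing_fraction(t.dotbracket) == pytest.approx(by_scan)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            pairing_fraction("(((..")


def _profile_and_pileup(values, mismatch, bases=None, tid="t1"):
    values = np.asarray(values, dtype=float)
    n = len(values)
    if bases is None:
        bases = np.array(["A"] * n)
    prof = ReactivityProfile(
        transcript_id=tid,
        positions=np.arange(n),
        ref_base=bases,
        raw=values.copy(),
        normalized=values.copy(),
        mask=~np.isfinite(values),
    )
    pile = PileupProfile(
        transcript_id=tid,
        positions=np.arange(n),
        ref_base=bases,
        coverage=np.full(n, 10_000),
        mismatch=np.asarray(mismatch),
    )
    return prof, pile


class TestWindowGini:
    def test_tiling_for_211_nt(self, rng):
        vals = rng.random(211)
        prof, pile = _profile_and_pileup(vals, rng.integers(30, 60, 211))
        ws = window_gini(prof, pile)
        assert len(ws.windows) == 7
        assert list(ws.windows["start0"]) == [0, 25, 50, 75, 100, 125, 150]

    def test_window_count_formula_on_random_lengths(self, rng):
        for L in rng.integers(50, 501, size=25):
            L = int(L)
            prof, pile = _profile_and_pileup(rng.random(L), rng.integers(0, 90, L))
            ws = window_gini(prof, pile)
            # independent enumeration of full windows
            starts = [s for s in range(0, L + 1, 25) if s + 50 <= L]
            assert len(ws.windows) == len(starts) == n_windows(L)

    def test_all_windows_failing_filter_gives_missing_average(self, rng):
        prof, pile = _profile_and_pileup(rng.random(100), np.full(100, 5))
        ws = window_gini(prof, pile, mismatch_threshold=20)
        assert not ws.windows["passed"].any()
        assert np.isnan(ws.avg_gini)

    def test_uniform_reactivity_gives_zero_average(self):
        prof, pile = _profile_and_pileup(np.full(100, 0.4), np.full(100, 50))
        ws = window_gini(prof, pile)
        assert ws.windows["passed"].all()
        assert ws.avg_gini == pytest.approx(0.0, abs=1e-12)

    def test_short_utr_yields_empty_window_set(self, rng):
        prof, pile = _profile_and_pileup(rng.random(40), np.full(40, 50))
        ws = window_gini(prof, pile)
        assert len(ws.windows) == 0
        assert np.isnan(ws.avg_gini)

    def test_gini_uses_ac_positions_only_by_default(self, rng):
        n = 50
        bases = np.array(["A", "G"] * (n // 2))
        vals = np.where(bases == "A", 0.5, 0.0)  # G zeros would inflate Gini
        prof, pile = _profile_and_pileup(vals, np.full(n, 50), bases=bases)
        assert window_gini(prof, pile).avg_gini == pytest.approx(0.0, abs=1e-12)
        all_base = window_gini(prof, pile, ac_only=False)
        assert all_base.avg_gini > 0.4

    def test_structure_raises_window_gini(self, small_analysis):
        """Paired 3' UTRs concentrate signal on fewer bases => higher Gini."""
        gt = small_analysis["gene_table"]
        means = gt.groupby("pairing_level")["avg_gini"].mean()
        assert means[0.7] > means[0.1] + 0.2

    def test_lowering_coverage_empties_filter_without_error(self):
        counts = []
        for cov in (2000, 200, 20):
            cfg = SimConfig(n_genes=4, mean_coverage=cov, seed=8)
            ds = simulate_dataset(cfg)
            passed = 0
            for t in ds.transcripts:
                prof = reactivity_pipeline(
                    ds.treated[t.id], ds.untreated[t.id],
                    min_coverage=1, region=t.utr3_interval,
                )
                from utr_structurome.pipeline import slice_pileup

                ws = window_gini(prof, slice_pileup(ds.treated[t.id], *t.utr3_interval))
                passed += int(ws.windows["passed"].sum())
            counts.append(passed)
        assert counts[0] > 0
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[2] == 0


def _metagene_transcripts(n=6, flank=100, utr_reactivity=0.5, cds_reactivity=0.5):
    """Hand-built profiles: constant reactivity, CDS 110 nt + stop + UTR 110 nt."""
    transcripts = {}
    profiles = []
    for i in range(n):
        cds_len = 113 + i  # stop codon start varies
        utr_len = 110
        L = cds_len + utr_len
        seq = "A" * (cds_len - 3) + "UAA" + "AC" * (utr_len // 2)
        t = TranscriptModel(
            id=f"m{i}",
            sequence=seq[:L],
            cds_interval=(0, cds_len),
            utr3_interval=(cds_len, L),
        )
        vals = np.full(L, np.nan)
        stop = t.stop_codon_start
        vals[stop - flank: stop] = cds_reactivity
        vals[stop: stop + 3] = 0.2
        vals[stop + 3: stop + 3 + flank] = utr_reactivity
        profiles.append(
            ReactivityProfile(
                transcript_id=t.id,
                positions=np.arange(L),
                ref_base=np.array(list(t.sequence[:L])),
                raw=vals.copy(),
                normalized=vals.copy(),
                mask=~np.isfinite(vals),
            )
        )
        transcripts[t.id] = t
    return profiles, transcripts


class TestMetagene:
    def test_flat_reactivity_gives_flat_profile(self):
        profiles, transcripts = _metagene_transcripts()
        res = metagene_stop_profile(profiles, transcripts)
        assert res.n_used == len(profiles)
        flanks = np.concatenate([res.mean_reactivity[:100], res.mean_reactivity[103:]])
        np.testing.assert_allclose(flanks, 0.5)
        np.testing.assert_allclose(res.mean_reactivity[100:103], 0.2)
        # nucleotide frequencies are proper distributions
        np.testing.assert_allclose(res.nt_freq.sum(axis=1), 1.0)

    def test_single_transcript_profile_is_identity(self):
        profiles, transcripts = _metagene_transcripts(n=1)
        res = metagene_stop_profile(profiles[:1], transcripts)
        t = transcripts["m0"]
        stop = t.stop_codon_start
        prof = profiles[0]
        np.testing.assert_allclose(
            res.mean_reactivity, prof.normalized[stop - 100: stop + 103]
        )

    def test_structured_cds_open_utr_contrast(self):
        """Paired CDS flank vs unpaired UTR: UTR more reactive, rank-sum p < 0.05."""
        cfg = SimConfig(
            n_genes=16,
            pairing_fraction_levels=(0.0,),
            cds_pairing_fraction=0.8,
            cds_length_range=(150, 200),
            utr_length_range=(150, 200),
            three_prime_bias=0.0,
            seed=21,
        )
        ds = simulate_dataset(cfg)
        profiles = [
            reactivity_pipeline(ds.treated[t.id], ds.untreated[t.id], min_coverage=20)
            for t in ds.transcripts
        ]
        res = metagene_stop_profile(profiles, {t.id: t for t in ds.transcripts})
        assert np.nanmean(res.utr_means) > np.nanmean(res.cds_means)
        assert res.ranksum_p < 0.05

    def test_short_flank_transcripts_are_skipped(self):
        profiles, transcripts = _metagene_transcripts(n=3)
        # shrink one CDS below the flank requirement
        t = transcripts["m0"]
        transcripts["m0"] = TranscriptModel(
            id="m0",
            sequence=t.sequence[:90] + t.sequence[t.cds_interval[1] - 3:],
            cds_interval=(0, 90),
            utr3_interval=(90, 90 + t.utr3_length),
        )
        res = metagene_stop_profile(profiles, transcripts)
        assert res.n_used == 2
        assert res.n_skipped == 1


class TestCodonPositionReactivity:
    def test_uniform_reactivity_equalizes_all_six_means(self):
        profiles, transcripts = _metagene_transcripts()
        table = codon_position_reactivity(profiles, transcripts)
        np.testing.assert_allclose(table.loc["cds"], 0.5)
        np.testing.assert_allclose(table.loc["utr"], 0.5)

    def test_periodic_cds_signal_detected_on_cds_side_only(self):
        profiles, transcripts = _metagene_transcripts()
        for prof, t in zip(profiles, transcripts.values()):
            stop = t.stop_codon_start
            for pos in range(stop - 99, stop, 3):  # codon position 3 boosted
                # pos such that (pos - stop) % 3 == 2
                prof.normalized[pos + ((2 - (pos - stop)) % 3)] = 0.9
        table = codon_position_reactivity(profiles, transcripts)
        assert table.loc["cds", 3] > table.loc["cds", 1]
        assert table.loc["cds", 3] > table.loc["cds", 2]
        assert np.allclose(table.loc["utr"], table.loc["utr", 1])

    def test_fully_masked_utr_reports_missing_means(self):
        profiles, transcripts = _metagene_transcripts(n=2)
        for prof, t in zip(profiles, transcripts.values()):
            utr = slice(t.utr3_interval[0], t.utr3_interval[1])
            prof.mask[utr] = True
        table = codon_position_reactivity(profiles, transcripts)
        assert table.loc["utr"].isna().all()
        assert table.loc["cds"].notna().all()


class TestExportConstraints:
    def _profile(self):
        bases = np.array(list("ACGUACGUAC"))
        vals = np.array([0.1, 0.2, 0.3, 0.4, np.nan, 0.6, 0.7, 0.8, 0.9, 1.0])
        return ReactivityProfile(
            transcript_id="t1",
            positions=np.arange(10),
            ref_base=bases,
            raw=vals.copy(),
            normalized=vals.copy(),
            mask=~np.isfinite(vals),
        )

    def test_masked_and_gu_positions_are_no_data(self):
        table = export_constraints(self._profile())
        # positions are 1-based; G (pos 3), U (pos 4) and the masked A (pos 5)
        by_pos = dict(zip(table["position"], table["reactivity"]))
        assert by_pos[3] == -999.0 and by_pos[4] == -999.0
        assert by_pos[5] == -999.0
        assert by_pos[1] == pytest.approx(0.1)

    def test_round_trip_preserves_informative_values(self, tmp_path):
        table = export_constraints(self._profile())
        path = tmp_path / "c.shape"
        write_constraints(table, str(path))
        back = read_constraints(str(path))
        np.testing.assert_allclose(back["reactivity"], table["reactivity"], atol=1e-9)
        assert list(back["position"]) == list(range(1, 11))

    def test_region_outside_profile_rejected(self):
        with pytest.raises(ValueError, match="region"):
            export_constraints(self._profile(), region=(5, 20))
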