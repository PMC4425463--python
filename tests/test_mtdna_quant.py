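import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from somamark import mtdna_quant as mq
from somamark import synthetic_data as sd
from somamark.exceptions import NoSignalError
from somamark.readset import AlignedReadSet
from somamark.stats_assoc import inverse_normal


def make_reads(rows):
    """rows: (flag, pos, mapq, length) on MT."""
    flags, poss, mapqs, lengths = zip(*rows) if rows else ((), (), (), ())
    return AlignedReadSet.from_columns(
        name=[f"r{i}" for i in range(len(rows))],
        flag=flags, ref=["MT"] * len(rows), pos=poss, mapq=mapqs,
        length=lengths)


class TestFilterReads:
    @pytest.mark.parametrize("flag,mapq,kept", [
        (1024, 60, False),   # duplicate bit is in the mask
        (99, 58, False),     # below the MAPQ floor
        (99, 60, True),      # clean read passes both
        (512, 60, False),    # QC-fail bit
        (256, 60, False),    # secondary alignment
        (2048, 60, True),    # supplementary is not excluded
    ])
    def test_predicate(self, flag, mapq, kept):
        reads = make_reads([(flag, 0, mapq, 100)])
        assert len(mq.filter_reads(reads)) == (1 if kept else 0)

    def test_idempotent_and_matches_bruteforce(self, small_reads):
        once = mq.filter_reads(small_reads)
        twice = mq.filter_reads(once)
        assert len(once) == len(twice)
        # brute-force evaluation of the predicate on every read
        expected = sum(
            1 for row in small_reads.frame.itertuples()
            if row.mapq >= 59 and (row.flag & 1804) == 0)
        assert len(once) == expected

    def test_empty_input(self):
        assert len(mq.filter_reads(make_reads([]))) == 0


class TestDepthProfile:
    def test_single_read_covers_first_segment(self):
        reads = make_reads([(99, 0, 60, 100)])
        profile = mq.depth_profile(reads, reads, mito_length=1000)
        assert profile.unfiltered[0] == 1.0
        assert np.all(profile.unfiltered[1:] == 0.0)

    def test_no_reads_all_zero(self):
        profile = mq.depth_profile(make_reads([]), make_reads([]), 1000)
        assert np.all(profile.unfiltered == 0)
        assert np.all(profile.filtered == 0)

    def test_partial_final_segment_normalized_by_true_length(self):
        # reference of 250 bp: segments of 100, 100, 50
        reads = make_reads([(99, 200, 60, 50)])
        profile = mq.depth_profile(reads, reads, mito_length=250)
        assert profile.n_segments == 3
        assert profile.unfiltered[2] == 1.0

    def test_read_beyond_reference_clipped_with_warning(self):
        reads = make_reads([(99, 950, 60, 100)])
        with pytest.warns(UserWarning, match="clipped"):
            profile = mq.depth_profile(reads, reads, mito_length=1000)
        assert profile.unfiltered[9] == 0.5

    def test_matches_per_base_pileup_oracle(self, rng):
        """Randomised read set against a brute-force per-base pileup."""
        mito_length = 730
        n = 50
        pos = rng.integers(0, mito_length - 40, n)
        length = rng.integers(20, 40, n)
        reads = make_reads(list(zip([99] * n, pos, [60] * n, length)))
        profile = mq.depth_profile(reads, reads, mito_length)
        pileup = np.zeros(mito_length)
        for p, ln in zip(pos, length):
            pileup[p:p + ln] += 1
        for k in range(profile.n_segments):
            lo, hi = 100 * k, min(100 * (k + 1), mito_length)
            assert profile.unfiltered[k] == pytest.approx(
                pileup[lo:hi].sum() / (hi - lo))


class TestNumtMask:
    @pytest.mark.parametrize("d_filt,d_unf,retained", [
        (100.0, 106.0, False),  # 6 > 5% of 100
        (100.0, 104.0, True),   # 4 <= 5% of 100
        (0.0, 3.0, False),      # no filtered signal
        (0.0, 0.0, False),      # empty segment
    ])
    def test_rule(self, d_filt, d_unf, retained):
        profile = mq.DepthProfile(np.array([d_unf]), np.array([d_filt]),
                                  reference_length=100)
        assert mq.numt_mask(profile)[0] == retained

    def test_matches_exhaustive_oracle_on_enumerated_profiles(self):
        """Every length-2 profile with integer depths in {0..5} (and
        unfiltered >= filtered), plus the per-segment oracle."""
        depths = range(6)
        for df0, df1, du0, du1 in itertools.product(depths, repeat=4):
            if du0 < df0 or du1 < df1:
                continue
            profile = mq.DepthProfile(
                np.array([du0, du1], dtype=float),
                np.array([df0, df1], dtype=float), reference_length=200)
            mask = mq.numt_mask(profile, rel_threshold=0.05)
            for k, (df, du) in enumerate(((df0, du0), (df1, du1))):
                oracle = df > 0 and (du - df) <= 0.05 * df
                assert mask[k] == oracle


class TestCopyNumber:
    def test_mean_over_retained(self):
        profile = mq.DepthProfile(np.array([8.0, 12.0]),
                                  np.array([8.0, 12.0]),
                                  reference_length=200)
        assert mq.copy_number_raw(profile) == pytest.approx(10.0)

    def test_all_excluded_raises(self):
        profile = mq.DepthProfile(np.array([10.0]), np.array([0.0]),
                                  reference_length=100)
        with pytest.raises(NoSignalError):
            mq.copy_number_raw(profile)

    def test_doubling_copies_doubles_raw_depth(self):
        ests = []
        for copies in (100.0, 200.0):
            cfg = sd.ReadSimConfig(mtdna_copies_per_cell=copies,
                                   nuclear_proxy_length=50_000,
                                   emit_sequences=False, seed=21)
            reads = sd.simulate_reads(cfg)
            est = mq.quantify_sample(reads, nuclear_length=50_000)
            ests.append(est.raw_mean_depth)
        assert ests[1] / ests[0] == pytest.approx(2.0, rel=0.05)

    def test_contaminants_contribute_no_filtered_depth(self):
        cfg = sd.ReadSimConfig(contamination_fraction=0.3,
                               nuclear_proxy_length=50_000,
                               numt_definitions=(),
                               emit_sequences=False, seed=17)
        reads = sd.simulate_reads(cfg)
        filtered = mq.filter_reads(reads)
        assert (filtered.frame["origin"] == "contaminant").sum() == 0
        # the filtered depth profile is bit-identical to a clean run
        clean = sd.simulate_reads(sd.ReadSimConfig(
            contamination_fraction=0.0, nuclear_proxy_length=50_000,
            numt_definitions=(), emit_sequences=False, seed=17))
        prof_contam = mq.depth_profile(reads, filtered, cfg.mito_genome_length)
        prof_clean = mq.depth_profile(clean, mq.filter_reads(clean),
                                      cfg.mito_genome_length)
        np.testing.assert_array_equal(prof_contam.filtered,
                                      prof_clean.filtered)

    def test_estimators_never_read_truth_tags(self, small_reads):
        shuffled = AlignedReadSet(small_reads.frame.assign(
            origin=np.random.default_rng(0).permutation(
                small_reads.frame["origin"].to_numpy())))
        a = mq.quantify_sample(small_reads, nuclear_length=200_000)
        b = mq.quantify_sample(shuffled, nuclear_length=200_000)
        assert a == b


class TestNormalizeMarker:
    def test_orthogonal_covariates_reduce_to_rank_transform(self, rng):
        raw = rng.standard_normal(200)
        with pytest.warns(UserWarning, match="constant covariate"):
            scores = mq.normalize_marker(raw, batch=["b1"] * 200,
                                         age=np.full(200, 50.0),
                                         chr20_depth=np.full(200, 1.7))
        expected = inverse_normal(raw - raw.mean())
        np.testing.assert_allclose(scores, expected)

    def test_output_standardized(self, rng):
        n = 1000
        raw = rng.gamma(2.0, 2.0, n)
        scores = mq.normalize_marker(
            raw, batch=rng.integers(0, 4, n), age=rng.integers(30, 60, n),
            chr20_depth=rng.uniform(1.5, 1.9, n))
        assert abs(scores.mean()) < 0.05
        assert scores.std() == pytest.approx(1.0, abs=0.05)

    def test_invariant_to_uniform_depth_rescaling(self, rng):
        n = 300
        chr20 = rng.uniform(1.4, 2.0, n)
        raw = 60.0 * chr20 * rng.lognormal(0.0, 0.3, n)
        batch = rng.integers(0, 3, n)
        age = rng.integers(30, 60, n)
        a = mq.normalize_marker(raw, batch, age, chr20)
        b = mq.normalize_marker(2.0 * raw, batch, age, 2.0 * chr20)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_constant_covariate_dropped_with_warning(self, rng):
        raw = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="constant covariate"):
            mq.normalize_marker(raw, batch=["b"] * 50,
                                age=np.full(50, 40.0),
                                chr20_depth=rng.uniform(1, 2, 50))
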