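"""HMM caller: decoding correctness against path enumeration, fragment
merging, quality scoring and parental-evidence vetting."""

import numpy as np
import pandas as pd
import pytest

from rarecnv import CnvCall, IntensityPanel, SnpManifest
from rarecnv.hmm import (HmmParams, call_cnvs, log_emissions,
                         log_transition_matrices, merge_fragments,
                         parent_state_evidence, state_posteriors,
                         _forward_backward, _viterbi_paths)
from tests._oracles import enumerate_hmm


def _manifest(pos, chrom="chr1", pfb=0.3):
    pos = np.asarray(pos)
    return SnpManifest(pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(pos))], "chrom": chrom,
        "pos_bp": pos, "gc_fraction": 0.5, "pfb": pfb}))


def _cn1_baf(rng, pfb, n):
    k = rng.binomial(1, pfb, size=n)
    return np.clip(k + rng.normal(0, 0.04, n), 0, 1)


def _cn2_baf(rng, pfb, n):
    k = rng.binomial(2, np.full(n, pfb))
    return np.clip(k / 2 + rng.normal(0, 0.04, n), 0, 1)


class TestTransitions:
    def test_rows_sum_to_one_for_random_distances(self):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.integers(1, 10**6, size=50))
        logA = log_transition_matrices(pos, HmmParams())
        rows = np.exp(logA).sum(axis=2)
        np.testing.assert_allclose(rows, 1.0, atol=1e-12)

    def test_distant_markers_revert_to_prior(self):
        p = HmmParams()
        logA = log_transition_matrices(np.array([1, 10**9]), p)
        np.testing.assert_allclose(np.exp(logA[0])[0, 1:],
                                   p.pi[1:], rtol=1e-6)


class TestDecoding:
    def test_all_diploid_sample_yields_no_calls(self):
        rng = np.random.default_rng(1)
        n = 500
        man = _manifest(np.arange(1, n + 1) * 20_000)
        lrr = rng.normal(0, 0.16, size=(1, n))
        baf = _cn2_baf(rng, 0.3, n)[None, :]
        panel = IntensityPanel(["s"], man, lrr, baf,
                               np.zeros((1, n), dtype=np.int8))
        assert call_cnvs(panel) == []

    def test_planted_deletion_boundaries_within_two_snps(self):
        """A 50-SNP copy-1 run is recovered with both boundaries within
        +-2 SNPs of truth in >= 95% of 200 replicates."""
        rng = np.random.default_rng(2)
        n, a, b = 150, 50, 99        # truth: SNP indices 50..99
        reps = 200
        man = _manifest(np.arange(1, n + 1) * 20_000)
        lrr = rng.normal(0, 0.16, size=(reps, n))
        lrr[:, a:b + 1] += -0.67
        baf = np.stack([_cn2_baf(rng, 0.3, n) for _ in range(reps)])
        for r in range(reps):
            baf[r, a:b + 1] = _cn1_baf(rng, 0.3, b - a + 1)
        panel = IntensityPanel([f"r{i}" for i in range(reps)], man, lrr, baf,
                               np.zeros((reps, n), dtype=np.int8))
        calls = call_cnvs(panel)
        by_sample = {}
        for c in calls:
            by_sample.setdefault(c.sample_id, []).append(c)
        pos = man.pos_bp
        good = 0
        for i in range(reps):
            cn1 = [c for c in by_sample.get(f"r{i}", []) if c.copy_number == 1]
            if len(cn1) == 1 \
                    and abs(np.searchsorted(pos, cn1[0].start_bp) - a) <= 2 \
                    and abs(np.searchsorted(pos, cn1[0].end_bp) - b) <= 2:
                good += 1
        assert good / reps >= 0.95

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        n = 60
        man = _manifest(np.arange(1, n + 1) * 30_000)
        post = state_posteriors(rng.normal(0, 0.2, n), rng.uniform(0, 1, n),
                                man.pos_bp, man.pfb)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("n_snps,seed", [(4, 10), (6, 11), (8, 12)])
    def test_posteriors_match_path_enumeration(self, n_snps, seed):
        """Forward-backward equals brute-force enumeration over all 5^n
        paths (1e-9), and the Viterbi path's log-probability is maximal."""
        rng = np.random.default_rng(seed)
        params = HmmParams()
        pos = np.cumsum(rng.integers(10_000, 200_000, size=n_snps))
        pfb = rng.uniform(0.05, 0.95, size=n_snps)
        lrr = rng.normal(0, 0.5, size=(1, n_snps))
        baf = rng.uniform(0, 1, size=(1, n_snps))
        logE = log_emissions(lrr, baf, pfb, params)
        logA = log_transition_matrices(pos, params)
        logpi = np.log(params.pi)
        post = _forward_backward(logE, logA, logpi)[0]
        path = _viterbi_paths(logE, logA, logpi)[0]
        post_ref, best_ref, best_lp = enumerate_hmm(logE[0], logA, logpi)
        np.testing.assert_allclose(post, post_ref, atol=1e-9)
        lp = logpi[path[0]] + logE[0, 0, path[0]] + sum(
            logA[t - 1, path[t - 1], path[t]] + logE[0, t, path[t]]
            for t in range(1, n_snps))
        assert lp >= best_lp - 1e-9

    def test_overwhelming_evidence_saturates_posterior(self):
        """LRR pinned to the copy-1 mean over 50 SNPs drives the interior
        CN1 posterior above 0.999."""
        n = 50
        man = _manifest(np.arange(1, n + 1) * 20_000)
        lrr = np.full(n, -0.67)
        baf = np.zeros(n)      # homozygous band, consistent with CN1
        post = state_posteriors(lrr, baf, man.pos_bp, man.pfb)
        assert np.all(post[5:-5, 1] > 0.999)

    def test_tie_breaks_prefer_lower_copy_number(self):
        """With completely uninformative emissions every state ties and the
        decoder must deterministically emit the lowest-index path."""
        params = HmmParams(pi=np.full(5, 0.2))
        n = 2
        logE = np.zeros((1, n, 5))
        logA = np.log(np.full((n - 1, 5, 5), 0.2))
        path = _viterbi_paths(logE, logA, np.log(np.full(5, 0.2)))[0]
        assert list(path) == [0, 0]

    def test_unsorted_manifest_rejected(self):
        df = pd.DataFrame({"snp_id": ["a", "b"], "chrom": "chr1",
                           "pos_bp": [100, 50], "gc_fraction": 0.5, "pfb": 0.3})
        man = SnpManifest(df)      # sorts on construction
        assert list(man.pos_bp) == [50, 100]


class TestMerge:
    def _man(self):
        # SNPs every 10 kb across 300 kb
        return _manifest(np.arange(1, 31) * 10_000)

    def test_short_gap_merges(self):
        man = self._man()
        a = CnvCall("s", "chr1", 1, 100_000, 1, 10, 0.99)
        b = CnvCall("s", "chr1", 140_001, 240_000, 1, 10, 0.97)
        merged = merge_fragments([a, b], man)          # gap 40k / total 240k
        assert len(merged) == 1
        m = merged[0]
        assert (m.start_bp, m.end_bp, m.copy_number) == (1, 240_000, 1)
        assert m.n_snps == man.n_snps_in("chr1", 1, 240_000)

    def test_boundary_ratio_not_merged(self):
        man = self._man()
        a = CnvCall("s", "chr1", 1, 100_000, 1, 10, 0.99)
        b = CnvCall("s", "chr1", 150_001, 250_000, 1, 10, 0.97)
        assert len(merge_fragments([a, b], man)) == 2   # 50k/250k = 0.2, strict <

    def test_different_copy_numbers_never_merge(self):
        man = self._man()
        a = CnvCall("s", "chr1", 1, 100_000, 1, 10, 0.99)
        b = CnvCall("s", "chr1", 110_001, 210_000, 3, 10, 0.97)
        assert len(merge_fragments([a, b], man)) == 2

    def test_iterates_to_fixed_point_and_never_shrinks(self):
        man = _manifest(np.arange(1, 101) * 10_000)
        calls = [CnvCall("s", "chr1", 1 + i * 120_000, 100_000 + i * 120_000,
                         1, 8, 0.9) for i in range(5)]
        merged = merge_fragments(calls, man)
        again = merge_fragments(merged, man)
        assert merged == again
        assert sum(c.length_bp for c in merged) >= sum(c.length_bp for c in calls)

    def test_overlapping_calls_rejected(self):
        man = self._man()
        a = CnvCall("s", "chr1", 1, 100_000, 1, 10, 0.99)
        b = CnvCall("s", "chr1", 50_000, 150_000, 1, 10, 0.97)
        with pytest.raises(ValueError, match="overlap"):
            merge_fragments([a, b], man)


class TestQuality:
    def test_unit_posteriors_give_quality_one(self):
        from rarecnv.hmm import score_quality
        call = CnvCall("s", "chr1", 1, 3, 1, 3, 0.5)
        post = np.zeros((3, 5))
        post[:, 1] = 1.0
        assert score_quality(call, post, np.arange(3)) == 1.0

    def test_quality_equals_forward_backward_oracle(self):
        """On a 5-SNP window the emitted quality equals the enumeration
        oracle's mean posterior of the called state (1e-9)."""
        rng = np.random.default_rng(20)
        n = 5
        man = _manifest(np.arange(1, n + 1) * 50_000)
        params = HmmParams()
        lrr = rng.normal(-0.67, 0.1, size=(1, n))
        baf = np.round(rng.uniform(0, 1, size=(1, n)))    # 0/1 bands
        panel = IntensityPanel(["s"], man, lrr, baf,
                               np.zeros((1, n), dtype=np.int8))
        calls = call_cnvs(panel)
        assert len(calls) == 1 and calls[0].copy_number == 1
        logE = log_emissions(lrr, baf, man.pfb, params)
        logA = log_transition_matrices(man.pos_bp, params)
        post_ref, _, _ = enumerate_hmm(logE[0], logA, np.log(params.pi))
        assert calls[0].quality == pytest.approx(post_ref[:, 1].mean(), abs=1e-9)

    def test_quality_decreases_with_noise(self):
        """Median call quality over 100 replicates strictly decreases as
        emission noise grows."""
        medians = []
        for sd in (0.16, 0.30, 0.45):
            rng = np.random.default_rng(21)
            n, reps = 80, 100
            man = _manifest(np.arange(1, n + 1) * 20_000)
            lrr = rng.normal(0, sd, size=(reps, n))
            lrr[:, 20:60] += -0.67
            baf = np.stack([_cn2_baf(rng, 0.3, n) for _ in range(reps)])
            for r in range(reps):
                baf[r, 20:60] = _cn1_baf(rng, 0.3, 40)
            panel = IntensityPanel([f"r{i}" for i in range(reps)], man, lrr,
                                   baf, np.zeros((reps, n), dtype=np.int8))
            quals = [c.quality for c in call_cnvs(panel) if c.copy_number == 1]
            medians.append(np.median(quals))
        assert medians[0] > medians[1] > medians[2]


class TestParentEvidence:
    def _setup(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        man = _manifest(np.arange(1, n + 1) * 20_000)
        call = CnvCall("child", "chr1", int(man.pos_bp[0]),
                       int(man.pos_bp[-1]), 1, n, 0.99)
        return rng, n, man, call

    def test_carrier_parent_supported(self):
        rng, n, man, call = self._setup(30)
        hits = 0
        for _ in range(200):
            lrr = rng.normal(-0.67, 0.28, size=n)
            baf = _cn1_baf(rng, 0.3, n)
            hits += parent_state_evidence(call, lrr, baf, man.pfb) == "supported"
        assert hits / 200 >= 0.99

    def test_diploid_parent_unsupported(self):
        rng, n, man, call = self._setup(31)
        hits = 0
        for _ in range(200):
            lrr = rng.normal(0.0, 0.16, size=n)
            baf = _cn2_baf(rng, 0.3, n)
            hits += parent_state_evidence(call, lrr, baf, man.pfb) == "unsupported"
        assert hits / 200 >= 0.95

    def test_all_missing_is_unknown(self):
        _, n, man, call = self._setup(32)
        verdict = parent_state_evidence(call, np.full(n, np.nan),
                                        np.full(n, np.nan), man.pfb)
        assert verdict == "unknown"
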