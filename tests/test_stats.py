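"""Shuffling null, fold-changes, empirical p-values, FDR and get_periodicity."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import kmerperiod as kp
from kmerperiod import stats


def dinuc_counts(bases):
    return Counter(zip(bases, bases[1:]))


class TestShuffle:
    def test_mono_preserves_letter_multiset(self):
        rng = np.random.default_rng(0)
        for seq in kp.make_random_sequences(20, 80, seed=3):
            out = kp.shuffle_sequence(seq, rng, "mono")
            assert sorted(out.bases) == sorted(seq.bases)
            assert len(out.bases) == len(seq.bases)

    def test_mono_single_letter_identity(self):
        rng = np.random.default_rng(0)
        assert kp.shuffle_sequence(kp.DnaSequence("s", "AAAA"), rng, "mono").bases == "AAAA"

    @pytest.mark.parametrize("bases", ["ATATAT", "ACGTACGTTGCA", "AATTCCGGNAAT"])
    def test_di_preserves_dinucleotide_counts(self, bases):
        rng = np.random.default_rng(1)
        out = kp.shuffle_sequence(kp.DnaSequence("s", bases), rng, "di")
        assert dinuc_counts(out.bases) == dinuc_counts(bases)

    def test_di_preserves_dinucleotides_on_random_sequences(self):
        rng = np.random.default_rng(2)
        for seq in kp.make_random_sequences(50, 60, seed=4):
            out = kp.shuffle_sequence(seq, rng, "di")
            assert dinuc_counts(out.bases) == dinuc_counts(seq.bases)

    def test_di_actually_permutes(self):
        rng = np.random.default_rng(5)
        seq = kp.make_random_sequences(1, 500, seed=6)[0]
        outs = {kp.shuffle_sequence(seq, rng, "di").bases for _ in range(5)}
        assert len(outs) > 1

    def test_unknown_order_rejected(self):
        with pytest.raises(ValueError):
            kp.shuffle_sequence(kp.DnaSequence("s", "ACGT"), np.random.default_rng(0), "tri")


class TestNullDistribution:
    def test_seeded_determinism(self, random_seqs):
        a = kp.null_distribution(random_seqs[:5], "WW", n_shuffling=3, seed=9)
        b = kp.null_distribution(random_seqs[:5], "WW", n_shuffling=3, seed=9)
        assert (a.psd_matrix == b.psd_matrix).all()

    def test_all_g_sequences_give_zero_matrix(self):
        seqs = [kp.DnaSequence("g", "G" * 100)]
        null = kp.null_distribution(seqs, "WW", n_shuffling=4, seed=0, max_distance=50)
        assert not null.psd_matrix.any()

    def test_matrix_shape(self, random_seqs):
        null = kp.null_distribution(random_seqs[:3], "WW", n_shuffling=5, seed=1, max_distance=60)
        assert null.psd_matrix.shape == (5, 30)


class TestLog2FoldChange:
    def test_basic(self):
        assert kp.log2_fold_change(4.0, np.array([2.0, 2.0, 2.0])) == 1.0
        assert kp.log2_fold_change(2.0, np.array([2.0, 2.0, 2.0])) == 0.0
        assert kp.log2_fold_change(1.0, np.array([8.0, 8.0, 8.0])) == -3.0

    def test_sentinels(self):
        assert kp.log2_fold_change(1.0, np.zeros(3)) == np.inf
        assert np.isnan(kp.log2_fold_change(0.0, np.zeros(3)))
        assert kp.log2_fold_change(0.0, np.ones(3)) == -np.inf


class TestEmpiricalPvalue:
    def test_floor_at_n500(self):
        null = np.arange(500, dtype=float)
        p = kp.empirical_pvalue(1000.0, null)
        assert p == 1 / 501
        assert f"{p:.2e}" == "2.00e-03"

    def test_ceiling(self):
        assert kp.empirical_pvalue(-1.0, np.arange(500, dtype=float)) == 1.0

    def test_small_n(self):
        # n=4, exactly 2 null values >= obs -> (2+1)/5
        assert kp.empirical_pvalue(3.0, np.array([1.0, 2.0, 3.0, 4.0])) == 0.6

    @given(st.floats(0, 10), st.lists(st.floats(0, 10), min_size=1, max_size=50))
    def test_bounds(self, obs, null):
        p = kp.empirical_pvalue(obs, np.array(null))
        n = len(null)
        assert 1 / (n + 1) <= p <= 1.0


class TestBhFdr:
    def test_single_pvalue_identity(self):
        assert kp.bh_fdr(np.array([0.05])).tolist() == [0.05]

    def test_hand_computed(self):
        got = kp.bh_fdr(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(got, [0.03, 0.03, 0.03])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    def test_never_decreases(self, pvals):
        p = np.array(pvals)
        assert (kp.bh_fdr(p) >= p - 1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            kp.bh_fdr(np.array([0.0, 0.5]))


class TestGetPeriodicity:
    def test_planted_period_recovery(self, planted_seqs):
        seqs, _ = planted_seqs
        res = kp.get_periodicity(seqs, "WW", n_shuffling=100, seed=42)
        m = res.metrics
        top = m.loc[m["l2fc"].idxmax()]
        assert top["period"] == 10.0
        assert top["pval"] == 1 / 101
        assert m["freq"].is_monotonic_increasing

    def test_absent_motif_degenerate(self, planted_seqs):
        seqs, _ = planted_seqs
        gg_free = [kp.DnaSequence(s.id, s.bases.replace("G", "A")) for s in seqs[:5]]
        with pytest.warns(UserWarning):
            res = kp.get_periodicity(gg_free, "GG", n_shuffling=5, seed=0)
        assert res.degenerate
        assert (res.metrics["psd_observed"] == 0).all()
        assert res.metrics["pval"].isna().all()
        assert res.metrics["fdr"].isna().all()

    def test_bit_identical_reruns(self, random_seqs):
        a = kp.get_periodicity(random_seqs[:10], "WW", n_shuffling=20, seed=5)
        b = kp.get_periodicity(random_seqs[:10], "WW", n_shuffling=20, seed=5)
        assert a.metrics.equals(b.metrics)
        assert (a.null.psd_matrix == b.null.psd_matrix).all()

    def test_pvalue_floor_reached_when_observed_beats_all_nulls(self, planted_seqs):
        seqs, _ = planted_seqs
        res = kp.get_periodicity(seqs, "WW", n_shuffling=50, seed=3)
        assert res.metrics["pval"].min() == 1 / 51

    def test_scale_invariance_via_rescaled_spectral_backend(self, random_seqs, monkeypatch):
        """l2FC, pval and fdr are unchanged when every PSD is rescaled by c>0."""
        seqs = random_seqs[:8]
        base = kp.get_periodicity(seqs, "WW", n_shuffling=15, seed=2)

        true_compute_psd = stats.spectral.compute_psd

        def rescaled(signal):
            spec = true_compute_psd(signal)
            return type(spec)(freqs=spec.freqs, periods=spec.periods, psd=spec.psd * 737.0)

        monkeypatch.setattr(stats.spectral, "compute_psd", rescaled)
        scaled = kp.get_periodicity(seqs, "WW", n_shuffling=15, seed=2)
        for col in ["l2fc", "pval", "fdr"]:
            assert np.allclose(scaled.metrics[col], base.metrics[col], rtol=1e-9)

    def test_config_recorded(self, random_seqs):
        res = kp.get_periodicity(random_seqs[:3], "WW", n_shuffling=2, seed=8, order="di")
        assert res.config["shuffle_order"] == "di"
        assert res.config["n_shuffling"] == 2
        assert res.config["seed"] == 8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kp.get_periodicity([], "WW", n_shuffling=2, seed=0)


def test_tsv_export_layout(tmp_path, random_seqs):
    res = kp.get_periodicity(random_seqs[:5], "WW", n_shuffling=10, seed=1)
    out = tmp_path / "metrics.tsv"
    res.to_tsv(out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == ["Freq", "Period", "PSD_observed", "l2FC", "pval", "fdr"]
    assert len(lines) == 1 + 100
    assert lines[1].startswith("0.005\t200.000\t")
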