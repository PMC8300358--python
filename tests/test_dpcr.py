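"""Digital-PCR Poisson quantification, genotype calling and simulation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from breedvar.datasets import load_dpcr_panel
from breedvar.dpcr import (
    DEFAULT_PARTITION_VOLUME_UL,
    DPCRConfig,
    Genotype,
    WellCounts,
    calibrate_partition_volume,
    call_genotype,
    channel_ratio,
    panel_accuracy,
    poisson_lambda,
    simulate_wells,
)


def wells(ch1, ch2, valid=18000, sid="s", label=""):
    return WellCounts(
        sample_id=sid,
        label=label,
        total_wells=valid,
        valid_wells=valid,
        ch1_pos=ch1,
        ch1_neg=valid - ch1,
        ch2_pos=ch2,
        ch2_neg=valid - ch2,
    )


class TestPoissonLambda:
    def test_zero_positives(self):
        assert poisson_lambda(0, 1000) == 0.0

    def test_half_positive_is_ln2(self):
        assert poisson_lambda(500, 1000) == pytest.approx(math.log(2))

    def test_saturation_and_degenerate_errors(self):
        with pytest.raises(ValueError, match="saturat"):
            poisson_lambda(1000, 1000)
        with pytest.raises(ValueError):
            poisson_lambda(0, 0)
        with pytest.raises(ValueError):
            poisson_lambda(-1, 1000)

    def test_strictly_monotone_in_positives(self):
        lams = [poisson_lambda(p, 5000) for p in range(0, 4999, 50)]
        assert all(b > a for a, b in zip(lams, lams[1:]))

    @given(
        valid=st.integers(min_value=2, max_value=50_000),
        data=st.data(),
    )
    def test_lambda_inverts_negative_fraction(self, valid, data):
        """lambda is non-negative, finite and inverts exactly to pos/valid."""
        pos = data.draw(st.integers(min_value=0, max_value=valid - 1))
        lam = poisson_lambda(pos, valid)
        assert lam >= 0 and math.isfinite(lam)
        assert (1 - math.exp(-lam)) * valid == pytest.approx(pos, abs=1e-6)


class TestChannelRatio:
    def test_symmetric_counts_give_unity(self):
        assert channel_ratio(wells(300, 300)) == pytest.approx(1.0)

    def test_absent_channel_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            channel_ratio(wells(300, 0))

    def test_partition_volume_cancels(self):
        w = wells(258, 255, valid=17790)
        r = channel_ratio(w)
        for vol in (1e-4, 7.3e-4):
            cfg = DPCRConfig(partition_volume=vol)
            call = call_genotype(w, cfg)
            assert call.conc1 / call.conc2 == pytest.approx(r)


class TestCallGenotype:
    def test_four_branches(self):
        assert call_genotype(wells(653, 0)).call is Genotype.TARGET_A
        assert call_genotype(wells(0, 655)).call is Genotype.TARGET_B
        assert call_genotype(wells(258, 255)).call is Genotype.HETEROZYGOTE
        assert call_genotype(wells(2, 3)).call is Genotype.NO_CALL

    def test_het_ratio_band_flag(self):
        ok = call_genotype(wells(300, 290))
        assert ok.ratio_in_band
        skew = call_genotype(wells(900, 100))
        assert skew.call is Genotype.HETEROZYGOTE and not skew.ratio_in_band

    def test_concentration_scaling(self):
        call = call_genotype(wells(653, 0, valid=18781))
        assert call.conc1 == pytest.approx(call.lambda1 / DEFAULT_PARTITION_VOLUME_UL)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="pos \\+ neg"):
            WellCounts("s", "", 100, 100, 10, 80, 0, 100)


class TestPanelAccuracy:
    def test_all_correct(self):
        calls = [call_genotype(wells(653, 0)), call_genotype(wells(0, 655))]
        labels = ["Jeju horse", "Thoroughbred"]
        assert panel_accuracy(calls, labels) == 1.0

    def test_heterozygote_counts_against(self):
        calls = [call_genotype(wells(258, 255))]
        assert panel_accuracy(calls, ["Jeju horse"]) == 0.0

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            panel_accuracy([], [])

    def test_randomized_labels_near_chance(self):
        """Shuffled labels on a balanced simulated panel score ~50%."""
        rng = np.random.default_rng(0)
        calls = [call_genotype(wells(500, 0)) for _ in range(20)] + [
            call_genotype(wells(0, 500)) for _ in range(20)
        ]
        accs = []
        for _ in range(200):
            labels = rng.permutation(["Jeju horse"] * 20 + ["Thoroughbred"] * 20)
            accs.append(panel_accuracy(calls, list(labels)))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)


class TestSimulateWells:
    def test_zero_concentration_always_negative(self):
        w = simulate_wells(0.0, 0.0, 18000, seed=1)
        assert w.ch1_pos == 0 and w.ch2_pos == 0

    def test_seed_reproducibility(self):
        w1 = simulate_wells(300.0, 120.0, 18000, seed=42)
        w2 = simulate_wells(300.0, 120.0, 18000, seed=42)
        assert (w1.ch1_pos, w1.ch2_pos) == (w2.ch1_pos, w2.ch2_pos)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_wells(-1.0, 0.0, 100)

    def test_estimator_recovery_across_lambda_range(self):
        """Round-trip lambda estimates within 5% of truth, averaged over seeds."""
        cfg = DPCRConfig()
        valid = 18000
        for lam_true in (0.01, 0.1, 0.5, 1.0):
            conc = lam_true / cfg.partition_volume
            est = []
            for seed in range(100):
                w = simulate_wells(conc, 0.0, valid, cfg, seed=seed)
                est.append(poisson_lambda(w.ch1_pos, valid))
            assert np.mean(est) == pytest.approx(lam_true, rel=0.05)

    def test_round_trip_bias_small_in_assay_regime(self):
        """Relative bias < 1% at lambda = 0.035 (the panel's regime), 1000 seeds."""
        cfg = DPCRConfig()
        lam_true = 0.035
        conc = lam_true / cfg.partition_volume
        est = [
            poisson_lambda(simulate_wells(conc, 0.0, 18000, cfg, seed=s).ch1_pos, 18000)
            for s in range(1000)
        ]
        assert abs(np.mean(est) - lam_true) / lam_true < 0.01

    def test_saturation_path_exercised(self):
        w = simulate_wells(1e9, 0.0, 1000, seed=0)
        assert w.ch1_pos == 1000
        with pytest.raises(ValueError, match="saturat"):
            poisson_lambda(w.ch1_pos, w.valid_wells)


def test_partition_volume_calibration_matches_published_concentrations():
    """Fitted per-well volume reproduces every printed concentration within 1%."""
    counts, df = load_dpcr_panel()
    lams, concs = [], []
    for w, row in zip(counts, df.itertuples()):
        for pos, conc in ((w.ch1_pos, row.ch1_conc), (w.ch2_pos, row.ch2_conc)):
            if conc > 0:
                lams.append(poisson_lambda(pos, w.valid_wells))
                concs.append(conc)
    vol = calibrate_partition_volume(lams, concs)
    assert vol == pytest.approx(DEFAULT_PARTITION_VOLUME_UL, rel=1e-3)
    for lam, conc in zip(lams, concs):
        assert lam / vol == pytest.approx(conc, rel=0.01)
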