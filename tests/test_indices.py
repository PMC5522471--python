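"""Wash-out and retention index computation."""

import dataclasses

import numpy as np
import pytest

import mibiquant as mq
from mibiquant import IndexMethod, RoiLabel

from conftest import random_valid_kinetics


def stats(mean, label, t, n=10):
    return mq.RoiStats(
        mean_counts_per_pixel=mean,
        n_pixels=n,
        total_counts=mean * n,
        t_acq_min=t,
        label=label,
    )


def wo_stats(ne, be, nl, bl, t_early=10.0, t_late=60.0):
    return (
        stats(ne, RoiLabel.NODULE, t_early),
        stats(be, RoiLabel.MIRROR_BACKGROUND, t_early),
        stats(nl, RoiLabel.NODULE, t_late),
        stats(bl, RoiLabel.MIRROR_BACKGROUND, t_late),
    )


def ri_stats(ne, ce, te, nl, cl, tl, t_early=10.0, t_late=60.0):
    return (
        stats(ne, RoiLabel.NODULE, t_early),
        stats(ce, RoiLabel.CONTRALATERAL, t_early),
        stats(te, RoiLabel.THORAX_BACKGROUND, t_early),
        stats(nl, RoiLabel.NODULE, t_late),
        stats(cl, RoiLabel.CONTRALATERAL, t_late),
        stats(tl, RoiLabel.THORAX_BACKGROUND, t_late),
    )


class TestWashoutIndex:
    def test_direct_formula_arithmetic(self):
        res = mq.washout_index(*wo_stats(200, 100, 180, 100))
        assert res.er == 100.0
        assert res.late_term == 80.0
        assert res.value == pytest.approx(-20.0)
        assert res.method is IndexMethod.WOIND
        assert not res.decay_corrected

    def test_no_net_change_is_zero(self):
        res = mq.washout_index(*wo_stats(150, 50, 150, 50))
        assert res.value == pytest.approx(0.0)

    def test_nonpositive_early_uptake_raises(self):
        with pytest.raises(mq.NonPositiveNetUptakeError):
            mq.washout_index(*wo_stats(100, 100, 80, 50))

    def test_late_below_background_is_flagged_not_fatal(self):
        res = mq.washout_index(*wo_stats(200, 100, 40, 50))
        assert res.value < -100.0
        assert "late_below_background" in res.flags

    def test_wrong_label_is_rejected(self):
        ne, be, nl, bl = wo_stats(200, 100, 180, 100)
        with pytest.raises(ValueError, match="label"):
            mq.washout_index(ne, ne, nl, bl)

    def test_monotone_in_late_nodule_counts(self):
        values = [
            mq.washout_index(*wo_stats(200, 100, nl, 100)).value
            for nl in np.linspace(100, 250, 16)
        ]
        assert np.all(np.diff(values) > 0)


class TestRetentionIndex:
    def test_fixed_point_and_direct_arithmetic(self):
        # DR == ER -> 0
        res = mq.retention_index(*ri_stats(30, 20, 10, 30, 20, 10))
        assert res.value == pytest.approx(0.0)
        # ER 1.0, DR 1.5 -> 50
        res = mq.retention_index(*ri_stats(30, 30, 10, 40, 30, 10))
        assert (res.er, res.late_term) == (1.0, 1.5)
        assert res.value == pytest.approx(50.0)
        # ER 2.0, DR 1.0 -> -50
        res = mq.retention_index(*ri_stats(50, 30, 10, 30, 30, 10))
        assert res.value == pytest.approx(-50.0)

    def test_degenerate_denominator_raises(self):
        with pytest.raises(mq.DegenerateRatioError):
            mq.retention_index(*ri_stats(30, 10, 10, 30, 20, 10))

    def test_monotone_in_delayed_ratio(self):
        values = [
            mq.retention_index(*ri_stats(30, 30, 10, nl, 30, 10)).value
            for nl in np.linspace(15, 60, 16)
        ]
        assert np.all(np.diff(values) > 0)


class TestDecayBehaviour:
    def test_ri_exactly_invariant_to_decay_correction(self, rng):
        for _ in range(100):
            te, tl = rng.uniform(0, 20, 2)
            args = ri_stats(
                te + rng.uniform(5, 300),
                te + rng.uniform(1, 100),
                te,
                tl + rng.uniform(5, 300),
                tl + rng.uniform(1, 100),
                tl,
            )
            raw = mq.retention_index(*args)
            corr = mq.retention_index(*args, decay=mq.DecaySpec(enabled=True))
            assert corr.value == pytest.approx(raw.value, rel=1e-12)

    def test_woind_decay_shift_closed_form(self, rng):
        half_life = 360.4
        for _ in range(100):
            t_early = float(rng.uniform(5, 15))
            t_late = t_early + float(rng.uniform(30, 60))
            be, bl = rng.uniform(0, 50, 2)
            args = wo_stats(
                be + rng.uniform(5, 300), be, bl + rng.uniform(0, 300), bl,
                t_early=t_early, t_late=t_late,
            )
            raw = mq.washout_index(*args)
            corr = mq.washout_index(
                *args, decay=mq.DecaySpec(enabled=True, half_life_min=half_life)
            )
            shift = 2.0 ** ((t_late - t_early) / half_life)
            assert corr.value / 100.0 + 1.0 == pytest.approx(
                (raw.value / 100.0 + 1.0) * shift, rel=1e-9
            )


class TestAgainstStraightLineOracle:
    """Both index chains vs a literal reimplementation of the formulas."""

    @staticmethod
    def _oracle_woind(ne, be, nl, bl):
        er = ne - be
        lr = nl - bl
        return lr / er * 100 - 100

    @staticmethod
    def _oracle_ri(ne, ce, te, nl, cl, tl):
        er = (ne - te) / (ce - te)
        dr = (nl - tl) / (cl - tl)
        return (dr - er) * 100 / er

    def test_thousand_random_tuples(self, rng):
        for _ in range(1000):
            be, bl = rng.uniform(0, 50, 2)
            ne = be + rng.uniform(0.5, 300)
            nl = rng.uniform(0, 350)
            res = mq.washout_index(*wo_stats(ne, be, nl, bl))
            assert res.value == pytest.approx(
                self._oracle_woind(ne, be, nl, bl), rel=1e-9, abs=1e-9
            )

            te, tl = rng.uniform(0, 20, 2)
            ce = te + rng.uniform(0.5, 100)
            cl = tl + rng.uniform(0.5, 100)
            ne2 = te + rng.uniform(0.5, 300)
            nl2 = rng.uniform(0, 350)
            res = mq.retention_index(*ri_stats(ne2, ce, te, nl2, cl, tl))
            assert res.value == pytest.approx(
                self._oracle_ri(ne2, ce, te, nl2, cl, tl), rel=1e-9, abs=1e-9
            )


class TestQuantifyStudy:
    def test_static_tracer_gives_zero_indices(self):
        kinetics = mq.KineticParams(
            f_nodule=1.0, f_parenchyma=1.0, f_background=1.0,
            require_parenchyma_faster=False,
        )
        ph = mq.build_phantom(kinetics=kinetics, noise="none")
        wo, ri = mq.quantify_study(ph.study)
        assert wo.value == pytest.approx(0.0, abs=1e-9)
        assert ri.value == pytest.approx(0.0, abs=1e-9)

    def test_benign_default_signs_and_value(self, noiseless_phantom):
        wo, ri = mq.quantify_study(noiseless_phantom.study)
        # parenchyma clears faster than the nodule: contrast rises, uptake falls
        assert ri.value > 0
        assert wo.value < 0
        assert wo.value == pytest.approx(
            mq.analytic_index(noiseless_phantom.kinetics, IndexMethod.WOIND),
            rel=1e-9,
        )
        assert wo.value == pytest.approx(-30.0, rel=1e-9)

    def test_missing_roi_is_named(self, noiseless_phantom):
        rois = dict(noiseless_phantom.study.rois)
        del rois[RoiLabel.THORAX_BACKGROUND]
        study = mq.StudyBundle(
            early=noiseless_phantom.study.early,
            late=noiseless_phantom.study.late,
            rois=rois,
        )
        with pytest.raises(ValueError, match="thorax_background"):
            mq.quantify_study(study)

    def test_zero_contrast_phantom_raises_downstream(self):
        kinetics = mq.KineticParams(
            a0_nodule=0.02, a0_parenchyma=0.12, a0_body_background=0.02
        )
        ph = mq.build_phantom(kinetics=kinetics, noise="none")
        with pytest.raises(mq.NonPositiveNetUptakeError):
            mq.quantify_study(ph.study)

    def test_random_kinetics_match_analytic_oracle(self, rng):
        for _ in range(10):
            k = random_valid_kinetics(rng)
            ph = mq.build_phantom(kinetics=k, noise="none")
            wo, ri = mq.quantify_study(ph.study)
            assert wo.value == pytest.approx(
                mq.analytic_index(k, IndexMethod.WOIND), rel=1e-9
            )
            assert ri.value == pytest.approx(
                mq.analytic_index(k, IndexMethod.RI), rel=1e-9
            )
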