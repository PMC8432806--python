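"""Forward predictions, the squared-error objective, and multistart fits."""

import numpy as np
import pytest

from phenoswitch.datasets import AssayDesign, generate
from phenoswitch.fitting import (
    GrowthAssayDataset, classify_strategy, fit, predicted_total, read_datasets,
    refit_drug, sse, write_datasets,
)
from phenoswitch.model import GrowthLaw, SwitchingStrategy
from conftest import make_params

STUDY_STRAT_B = SwitchingStrategy(0.0, 0.9, 0.01)


def study_truth(d_A_max=0.12, strat_B=(0.0, 0.9)):
    """Frozen truth of the synthetic recovery experiments."""
    return make_params(r_A=0.05, r_B=0.03, d_A=0.015, d_B=0.015,
                       d_A_max=d_A_max, strat_A=(0.0, 0.95, 0.01),
                       strat_B=(*strat_B, 0.01))


class TestPredictedTotal:
    def test_no_switching_closed_form(self):
        p = make_params(strat_A=(1.0, 1.0, 0.01), strat_B=(1.0, 1.0, 0.01),
                        r_A=0.05, d_A=0.01, r_B=0.02, d_B=0.03)
        ds = GrowthAssayDataset((0.0, 24.0, 96.0), (1000.0, 1000.0, 1000.0))
        pred = predicted_total(p, ds)
        assert pred == pytest.approx(1000.0 * np.exp(0.04 * np.array([0, 24, 96])),
                                     rel=1e-8)

    def test_pretreatment_segment_matches_untreated(self):
        p = study_truth()
        t = (24.0, 48.0, 72.0, 120.0)
        unt = predicted_total(p, GrowthAssayDataset(t, (1e3,) * 4, "untreated"))
        drug = predicted_total(p, GrowthAssayDataset(t, (1e3,) * 4, "drug",
                                                     "docetaxel", 72.0))
        assert drug[:3] == pytest.approx(unt[:3], rel=1e-9)
        assert drug[3] < unt[3]

    def test_fall_then_rebound_shape(self):
        p = study_truth()  # tolerant pool grows under the bath
        t = tuple(np.arange(24.0, 24.0 * 11, 24.0))
        pred = predicted_total(p, GrowthAssayDataset(t, (1e3,) * len(t), "drug",
                                                     "docetaxel", 72.0))
        post = pred[np.array(t) >= 72.0]
        trough = int(np.argmin(post))
        assert 0 < trough < len(post) - 1   # fall after the bath, then rebound
        assert post[-1] > post[trough]


class TestSse:
    def test_arithmetic(self, monkeypatch):
        # predictions (10, 20) against data (12, 18) -> 4 + 4 = 8
        import phenoswitch.fitting as mod

        monkeypatch.setattr(mod, "predicted_total",
                            lambda p, ds, structure=None: np.array([10.0, 20.0]))
        ds = GrowthAssayDataset((1.0, 2.0), (12.0, 18.0))
        assert mod.sse(make_params(), [ds]) == pytest.approx(8.0)

    def test_noiseless_data_zero_objective(self):
        p = study_truth()
        data = generate(p, AssayDesign(noise="none"), seed=0)
        assert sse(p, data) < 1e-12

    def test_invariant_under_dataset_order(self):
        p = study_truth()
        data = generate(p, AssayDesign(cv=0.1), seed=3)
        assert sse(p, data) == pytest.approx(sse(p, data[::-1]))

    def test_additional_dataset_never_decreases(self):
        p = study_truth()
        data = generate(p, AssayDesign(cv=0.1), seed=4)
        assert sse(p, data) >= sse(p, data[:1])


class TestFit:
    def test_noiseless_recovery_under_study_conditions(self):
        """With the strategy and death rate known, a noiseless sorted-
        plating assay identifies the remaining parameters exactly."""
        p = study_truth()
        data = generate(p, AssayDesign(noise="none", init="sensitive"), seed=0)
        res = fit(data, fixed={"strategy_B": STUDY_STRAT_B, "d_A": p.d_A},
                  seed=1, n_starts=6)
        total_sq = sum(c ** 2 for d in data for c in d.counts)
        assert res.sse < 1e-6 * total_sq
        assert res.estimates["lambda_A"] == pytest.approx(p.lambda_A, rel=0.01)

    def test_noisy_recovery_small_replicate_study(self):
        """3-replicate assays at 10% noise keep the growth-rate estimate
        within a few percent (subset of the acceptance-scale study)."""
        p = study_truth()
        fx = {"strategy_B": STUDY_STRAT_B, "d_A": p.d_A}
        errs = []
        for rep in range(4):
            noisy = generate(p, AssayDesign(cv=0.10, n_replicates=3),
                             seed=700 + rep)
            r = fit(noisy, fixed=fx, seed=800 + rep, n_starts=4)
            errs.append(abs(r.estimates["lambda_A"] - p.lambda_A) / p.lambda_A)
        assert np.median(errs) < 0.10

    def test_untreated_only_strategy_indistinguishable(self):
        """Without treatment the two retention strategies fit equally well
        — the practical non-identifiability of the untreated assay."""
        p = study_truth()
        data = generate(p, AssayDesign(cv=0.1, conditions=("untreated",)),
                        seed=42)
        fits = {lab: fit(data, fixed={"strategy_B": SwitchingStrategy(*s, 0.01)},
                         seed=7, n_starts=5)
                for lab, s in (("switch", (0.0, 0.9)), ("stay", (0.95, 1.0)))}
        lo = min(f.sse for f in fits.values())
        hi = max(f.sse for f in fits.values())
        assert (hi - lo) <= 0.01 * max(lo, 1e-300)

    def test_treated_predictions_of_untreated_equivalent_fits_diverge(self):
        """Parameter sets that explain the untreated data equally well under
        different strategies make clearly distinct treated predictions —
        the reason treatment data carries strategy information at all."""
        p = study_truth(strat_B=(0.95, 1.0))
        unt = generate(p, AssayDesign(noise="none", conditions=("untreated",)),
                       seed=0)
        fits = {lab: fit(unt, fixed={"strategy_B": SwitchingStrategy(*s, 0.01),
                                     "d_A_max": p.d_A_max},
                         seed=11, n_starts=5)
                for lab, s in (("switch", (0.0, 0.9)), ("stay", (0.95, 1.0)))}
        t = (24.0, 72.0, 120.0, 168.0)
        treated = {lab: predicted_total(
            f.params, GrowthAssayDataset(t, (1e3,) * 4, "drug", "x", 72.0))
            for lab, f in fits.items()}
        rel = np.abs(treated["switch"] - treated["stay"]) / treated["stay"]
        assert rel[-1] > 0.2  # > 20% divergence at the final observation

    def test_all_starts_logged(self):
        p = study_truth()
        data = generate(p, AssayDesign(cv=0.1), seed=5)
        res = fit(data, fixed={"strategy_B": STUDY_STRAT_B, "d_A": p.d_A},
                  seed=6, n_starts=3)
        assert len(res.start_sses) == 3 and len(res.converged) == 3
        assert res.sse == min(res.start_sses)


class TestRefitDrug:
    def test_growth_parameters_frozen_bit_identical(self):
        p = study_truth()
        data = generate(p, AssayDesign(cv=0.05), seed=8)
        base = fit(data, fixed={"strategy_B": STUDY_STRAT_B, "d_A": p.d_A},
                   seed=9, n_starts=4)
        other = generate(p.replace(d_A_max=0.18),
                         AssayDesign(cv=0.05), seed=10)
        res = refit_drug(other, base, seed=11, n_starts=4)
        for key in ("r_A", "r_B", "d_A", "d_B"):
            assert res.estimates[key] == base.estimates[key]

    def test_recovers_stronger_drug_ordering(self):
        p = study_truth(d_A_max=0.08)
        data = generate(p, AssayDesign(cv=0.02), seed=12)
        base = fit(data, fixed={"strategy_B": STUDY_STRAT_B, "d_A": p.d_A},
                   seed=13, n_starts=4)
        stronger = generate(p.replace(d_A_max=0.16),
                            AssayDesign(cv=0.02), seed=14)
        res = refit_drug(stronger, base, seed=15, n_starts=6)
        assert res.estimates["d_A_max"] > base.estimates["d_A_max"]


class TestClassifyStrategy:
    def test_reports_both_fits_and_gap(self):
        p = study_truth()
        data = generate(p, AssayDesign(cv=0.1), seed=16)
        out = classify_strategy(data, seed=17, n_starts=3,
                                fixed={"d_A": p.d_A})
        assert out["label"] in ("switch", "stay")
        assert out["relative_gap"] >= 0
        assert {"switch", "stay"} <= set(out)


class TestIo:
    def test_csv_roundtrip(self, tmp_path):
        p = study_truth()
        data = generate(p, AssayDesign(cv=0.1), seed=20)
        path = tmp_path / "assay.csv"
        write_datasets(data, path)
        back = read_datasets(path)
        assert len(back) == len(data)
        for a, b in zip(sorted(data, key=lambda d: d.condition),
                        sorted(back, key=lambda d: d.condition)):
            assert a.times == b.times
            assert np.allclose(a.counts, b.counts)
            assert a.condition == b.condition and a.init == b.init
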