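import numpy as np
import pytest

from dwiaspects.phantoms import EffectModel, generate_cohort
from dwiaspects.scoring import score_mask
from dwiaspects.severity import (SeverityError, deduction_frequency,
                                 derive_thresholds, dichotomize,
                                 normalized_frequency_map,
                                 region_association_tests, severity_from_nihss)


class TestNihssBands:
    @pytest.mark.parametrize("nihss,expected", [
        (0, "mild"), (5, "mild"), (7, "mild"),
        (8, "moderate"), (16, "moderate"),
        (17, "severe"), (42, "severe"),
    ])
    def test_band_mapping(self, nihss, expected):
        assert severity_from_nihss(nihss) == expected

    @pytest.mark.parametrize("bad", [-1, 43])
    def test_out_of_range(self, bad):
        with pytest.raises(SeverityError):
            severity_from_nihss(bad)

    def test_dichotomization_merges_moderate_and_severe(self):
        assert dichotomize("mild") == 0
        assert dichotomize("moderate") == 1
        assert dichotomize("severe") == 1


def _fake_result(atlas, deductions, hemisphere="left", volume=5.0):
    import numpy as np

    from dwiaspects.volume_io import LabeledVolume
    res = score_mask(
        LabeledVolume(np.zeros(atlas.labels.shape, np.uint8),
                      atlas.labels.affine.copy()), atlas)
    res.deductions = set(deductions)
    res.reported_score = 10 - len([d for d in deductions if d[1] == hemisphere])
    res.core_volume_mL = volume
    return res


class TestDeductionFrequency:
    def test_uniform_single_region(self, atlas64):
        results = [( _fake_result(atlas64, {("CA", "left")}), "mild")
                   for _ in range(5)]
        results += [(_fake_result(atlas64, {("CA", "left")}), "severe")
                    for _ in range(3)]
        table = deduction_frequency(results)
        for sev in ("mild", "severe"):
            assert table.frequency("CA", "left", sev) == 1.0
            assert table.frequency("M1", "left", sev) == 0.0
        assert table.class_sizes == {"mild": 5, "severe": 3}

    def test_absent_class_has_no_rows(self, atlas64):
        results = [(_fake_result(atlas64, set()), "mild")]
        table = deduction_frequency(results)
        assert "severe" not in set(table.rows.severity)
        assert not table.rows.frequency.isna().any()

    def test_matches_independent_tally(self, atlas_cohort):
        subs = generate_cohort(atlas_cohort, 50, (0.4, 0.3, 0.3), seed=3)
        scored = [(score_mask(s.truth_mask, atlas_cohort), s.severity)
                  for s in subs]
        table = deduction_frequency(scored)
        # brute-force recount
        for _, row in table.rows.iterrows():
            n = 0
            for res, sev in scored:
                if sev != row.severity:
                    continue
                if row.hemisphere == "both":
                    hit = any((row.code, h) in res.deductions
                              for h in ("left", "right"))
                else:
                    hit = (row.code, row.hemisphere) in res.deductions
                n += hit
            assert row["count"] == n
            assert row.frequency == pytest.approx(
                n / table.class_sizes[row.severity])

    def test_empty_cohort_rejected(self):
        with pytest.raises(SeverityError):
            deduction_frequency([])


class TestNormalizedMap:
    def test_min_max_arithmetic(self, atlas64):
        results = (
            [(_fake_result(atlas64, {("CA", "left")}), "mild")] * 3
            + [(_fake_result(atlas64, {("CA", "left"), ("M1", "left")}), "mild")] * 3
            + [(_fake_result(atlas64, set()), "mild")] * 4
        )
        table = deduction_frequency(results)
        norm = normalized_frequency_map(table)
        mild = norm[norm.severity == "mild"]
        ca = mild[(mild.code == "CA") & (mild.hemisphere == "left")]
        assert ca.normalized.iloc[0] == 1.0  # the most frequent region
        assert mild.normalized.min() == 0.0

    def test_constant_class_maps_to_zero(self, atlas64):
        results = [(_fake_result(atlas64, set()), "mild")] * 4
        norm = normalized_frequency_map(deduction_frequency(results))
        assert (norm.normalized == 0).all()

    def test_rank_order_preserved(self, atlas_cohort):
        subs = generate_cohort(atlas_cohort, 40, (0.4, 0.3, 0.3), seed=5)
        scored = [(score_mask(s.truth_mask, atlas_cohort), s.severity)
                  for s in subs]
        table = deduction_frequency(scored)
        norm = normalized_frequency_map(table)
        for _, grp in norm.groupby("severity"):
            f = grp.frequency.to_numpy()
            n = grp.normalized.to_numpy()
            order = np.argsort(f)
            assert (np.diff(n[order]) >= -1e-12).all()


class TestAssociations:
    def test_strong_severity_association_detected(self, atlas64):
        results = []
        for i in range(100):  # 90% of severe deduct M1-left, 5% of mild
            results.append((_fake_result(
                atlas64, {("M1", "left")} if i < 90 else set()), "severe"))
            results.append((_fake_result(
                atlas64, {("M1", "left")} if i < 5 else set()), "mild"))
        df = region_association_tests(results)
        row = df[(df.code == "M1") & (df.hemisphere == "left")].iloc[0]
        assert row.p < 0.001

    def test_never_deducted_region_flagged(self, atlas64):
        results = [(_fake_result(atlas64, {("CA", "left")}), s)
                   for s in ("mild", "severe") for _ in range(5)]
        df = region_association_tests(results)
        m5 = df[(df.code == "M5") & (df.hemisphere == "right")].iloc[0]
        assert m5.test == "non-testable"
        assert np.isnan(m5.p)

    def test_no_association_gives_large_p(self, atlas64):
        rng = np.random.default_rng(0)
        results = []
        for sev in ("mild", "moderate", "severe"):
            for _ in range(60):
                ded = {("M2", "left")} if rng.random() < 0.5 else set()
                results.append((_fake_result(atlas64, ded), sev))
        df = region_association_tests(results)
        row = df[(df.code == "M2") & (df.hemisphere == "left")].iloc[0]
        assert row.p > 0.05


class TestThresholds:
    def test_perfect_separation(self, atlas64):
        cohort = [(_fake_result(atlas64, set(), volume=5.0), "mild")
                  for _ in range(20)]
        for i in range(20):
            r = _fake_result(atlas64, {("M1", "left"), ("M2", "left"),
                                       ("M5", "left"), ("CA", "left"),
                                       ("IN", "left")}, volume=60.0)
            cohort.append((r, "severe"))
        out = derive_thresholds(cohort)
        assert out["aspects"].auc == 1.0
        assert out["volume"].auc == 1.0
        assert 5.0 < out["volume"].threshold <= 60.0

    def test_aspects_marker_uses_low_tail(self, atlas64):
        from dwiaspects.stats import roc_youden
        cohort = []
        rng = np.random.default_rng(1)
        for _ in range(40):
            mild = _fake_result(atlas64, set())
            mild.reported_score = int(rng.integers(7, 11))
            cohort.append((mild, "mild"))
            sev = _fake_result(atlas64, set())
            sev.reported_score = int(rng.integers(0, 8))
            cohort.append((sev, "severe"))
        out = derive_thresholds(cohort)
        scores = np.array([r.reported_score for r, _ in cohort], float)
        labels = np.array([dichotomize(s) for _, s in cohort])
        flipped = roc_youden(scores, labels, direction="high")
        assert out["aspects"].direction == "low"
        assert flipped.auc == pytest.approx(1.0 - out["aspects"].auc)

    def test_single_class_rejected(self, atlas64):
        from dwiaspects.stats import StatsError
        cohort = [(_fake_result(atlas64, set()), "mild")] * 5
        with pytest.raises(StatsError):
            derive_thresholds(cohort)
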