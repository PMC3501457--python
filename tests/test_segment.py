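"""Inflection detection, segment line fits and per-tissue line families."""

import numpy as np
import pytest

from conftest import as_curve
from voltfp.errors import (DegenerateFamilyError, NoInflectionError,
                           ParameterError)
from voltfp.segment import (SegmentFit, correlate_alpha_with_level,
                            find_inflection, fit_curve_segment, fit_families,
                            fit_line_at_inflection, fit_tissue_family)
from voltfp.synthetic import (DatasetSpec, generate_dataset,
                              make_tissue_profiles)


class TestFindInflection:
    def test_cubic_inflection_found_at_centre(self):
        i = np.arange(101, dtype=float)
        y = 0.5 * (i - 50) + 1e-3 * (i - 50) ** 3
        assert find_inflection(as_curve(-y), (10, 90)) == 50

    def test_convex_segment_has_no_inflection(self):
        y = (np.arange(101, dtype=float) - 50) ** 2
        with pytest.raises(NoInflectionError):
            find_inflection(as_curve(y), (10, 90))

    def test_noise_free_synthetic_curve_hits_designed_pivot(self, profiles):
        from voltfp.synthetic import generate_voltammogram
        for p in profiles:
            cur = generate_voltammogram(
                p, rng=np.random.default_rng(0), replicate_noise_sd=0.0,
                family_noise_frac=0.0, replicate_gain_sd=0.0,
                shape_noise_sd=0.0)
            fit = fit_curve_segment(cur)
            assert abs(fit.inflection_index - p.pivot_index) <= 2

    def test_invalid_interval(self):
        with pytest.raises(ParameterError):
            find_inflection(as_curve(np.zeros(50)), (30, 10))


class TestFitLine:
    def test_exact_line_recovered(self):
        pots = np.linspace(-0.7, -1.8, 101)
        cur = as_curve(2.0 * pots + 3.0)
        fit = fit_line_at_inflection(cur, 50, halfwidth=5)
        assert fit.k == pytest.approx(2.0, abs=1e-10)
        assert fit.q == pytest.approx(3.0, abs=1e-10)
        assert fit.m == 11

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=101)
        cur = as_curve(y)
        fit = fit_line_at_inflection(cur, 40, halfwidth=5)
        e = cur.potentials[35:46]
        v = y[35:46]
        k = (np.sum(e * v) - 11 * e.mean() * v.mean()) / \
            (np.sum(e * e) - 11 * e.mean() ** 2)
        q = v.mean() - k * e.mean()
        assert fit.k == pytest.approx(k, rel=1e-9)
        assert fit.q == pytest.approx(q, rel=1e-9)

    def test_window_out_of_bounds(self):
        with pytest.raises(ParameterError):
            fit_line_at_inflection(as_curve(np.zeros(20)), 2, halfwidth=5)


def fabricate_fits(alpha, beta, ks, tissue="liver"):
    return [SegmentFit(0, -1.5, k, alpha * k + beta, 11, 0.0, tissue, 1, i)
            for i, k in enumerate(ks)]


class TestTissueFamily:
    def test_exact_line_recovery(self):
        fam = fit_tissue_family(fabricate_fits(0.5, 2.0, [1.0, 2.0, 3.0]))
        assert fam.alpha == pytest.approx(0.5)
        assert fam.beta == pytest.approx(2.0)
        assert fam.intersection == pytest.approx((-0.5, 2.0))

    def test_too_few_fits(self):
        with pytest.raises(ParameterError):
            fit_tissue_family(fabricate_fits(0.5, 2.0, [1.0, 2.0]))

    def test_degenerate_family(self):
        with pytest.raises(DegenerateFamilyError):
            fit_tissue_family(fabricate_fits(0.5, 2.0, [1.0, 1.0, 1.0]))

    def test_zero_noise_lines_share_intersection_exactly(
            self, profiles, zero_noise_dataset):
        """With family noise off, every line passes through (-alpha, beta)."""
        by_tissue = {p.tissue_name: p for p in profiles}
        families, fits = fit_families(zero_noise_dataset)
        assert len(fits) == len(zero_noise_dataset)
        for fit in fits:
            p = by_tissue[fit.tissue]
            resid = fit.q - (p.segment_alpha * fit.k + p.segment_beta)
            assert abs(resid) < 1e-8
        for fam in families:
            p = by_tissue[fam.tissue]
            assert fam.alpha == pytest.approx(p.segment_alpha, abs=1e-8)
            assert fam.beta == pytest.approx(p.segment_beta, abs=1e-8)

    def test_default_noise_parameter_recovery(self):
        """alpha and beta recovered within 5% at the default noise levels."""
        errs_a, errs_b = [], []
        for seed in (0, 1, 2):
            profs = make_tissue_profiles(seed)
            ds = generate_dataset(DatasetSpec(seed=seed), profs)
            by_tissue = {p.tissue_name: p for p in profs}
            families, _ = fit_families(ds)
            for fam in families:
                p = by_tissue[fam.tissue]
                errs_a.append(abs(fam.alpha - p.segment_alpha) / abs(p.segment_alpha))
                errs_b.append(abs(fam.beta - p.segment_beta) / abs(p.segment_beta))
        assert max(errs_a) < 0.05
        assert max(errs_b) < 0.05


class TestCorrelation:
    def test_proportional_levels_give_full_correlation(self):
        fams = [fit_tissue_family(fabricate_fits(-a, 1.0, [1, 2, 3]), t)
                for t, a in [("a", 1.0), ("b", 2.0), ("c", 3.0), ("d", 4.0)]]
        levels = {"a": 10.0, "b": 20.0, "c": 30.0, "d": 40.0}
        assert correlate_alpha_with_level(fams, levels) == pytest.approx(100.0)

    def test_shuffled_levels_decorrelate(self):
        rng = np.random.default_rng(0)
        alphas = rng.normal(1.5, 0.02, size=40)
        fams = [fit_tissue_family(fabricate_fits(a, 1.0, [1, 2, 3]), f"t{i}")
                for i, a in enumerate(alphas)]
        levels = {f"t{i}": v for i, v in enumerate(rng.permutation(alphas))}
        assert abs(correlate_alpha_with_level(fams, levels)) < 50.0

    def test_too_few_tissues(self):
        fams = [fit_tissue_family(fabricate_fits(1.0, 1.0, [1, 2, 3]), t)
                for t in ("a", "b")]
        with pytest.raises(ParameterError):
            correlate_alpha_with_level(fams, {"a": 1.0, "b": 2.0})
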