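"""Hill turbidity fits, lacO FRAP, co-recruitment and dose-response grouping."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from globule import synthetic_data as sd
from globule.ensemble_stats import (
    corecruitment_ratio,
    fit_hill_turbidity,
    fit_laco_frap,
    group_by_percentiles,
    hill,
    segment_and_group,
)


class TestHill:
    def test_half_saturation_identity(self):
        assert hill(45.0, 1.0, 45.0, 2.0) == pytest.approx(0.5)

    def test_recovery_with_replicate_noise(self):
        df, truth = sd.gen_turbidity_table({"HP1a": (1.0, 45.0, 2.0)}, rng=1)
        sub = df[df.protein == "HP1a"]
        fits = fit_hill_turbidity(
            [(sub.conc_uM.to_numpy(), sub.od600.to_numpy(), truth["blank"])]
        )
        assert fits[0].c_sat == pytest.approx(45.0, rel=0.10)
        assert fits[0].c_sat_in_range

    def test_shared_plateau_joint_fit(self):
        df, truth = sd.gen_turbidity_table(
            {"HP1a": (1.0, 45.0, 2.0), "GFP-HP1a": (1.0, 23.0, 2.0)}, rng=1
        )
        datasets = [
            (s.conc_uM.to_numpy(), s.od600.to_numpy(), truth["blank"])
            for _, s in df.groupby("protein", sort=True)
        ]
        fits = fit_hill_turbidity(datasets, share_plateau=True)
        assert fits[0].a == pytest.approx(fits[1].a, rel=1e-9)  # shared plateau
        # groupby sorts: GFP-HP1a first, HP1a second
        assert fits[0].c_sat == pytest.approx(23.0, rel=0.10)
        assert fits[1].c_sat == pytest.approx(45.0, rel=0.10)

    def test_blank_only_data_rejected(self):
        conc = np.geomspace(2, 200, 8)
        blank = 0.05
        with pytest.raises(ValueError, match="no signal"):
            fit_hill_turbidity([(conc, np.full_like(conc, blank), blank)])

    def test_csat_invariant_under_turbidity_rescaling(self):
        df, truth = sd.gen_turbidity_table({"HP1a": (1.0, 45.0, 2.0)}, rng=6)
        sub = df[df.protein == "HP1a"]
        c, y = sub.conc_uM.to_numpy(), sub.od600.to_numpy() - truth["blank"]
        f1 = fit_hill_turbidity([(c, y, 0.0)])[0]
        f2 = fit_hill_turbidity([(c, 100.0 * y, 0.0)])[0]
        assert f2.a == pytest.approx(100.0 * f1.a, rel=1e-6)
        assert f2.c_sat == pytest.approx(f1.c_sat, rel=1e-6)
        assert f2.n == pytest.approx(f1.n, rel=1e-6)


class TestLacoFrap:
    def test_recovery_of_fraction_split(self):
        t = np.arange(0, 300, 2.0)
        rng = np.random.default_rng(3)
        y = 0.42 * (1 - np.exp(-t / 20.0)) + rng.normal(0, 0.02, t.size)
        fit = fit_laco_frap(t, y, tau2_fixed=5.0)
        assert fit.f_stable == pytest.approx(0.58, abs=0.05)
        assert fit.f_transient == pytest.approx(0.42, abs=0.05)

    def test_fully_recovering_curve_has_no_stable_fraction(self):
        t = np.arange(0, 300, 2.0)
        y = 1.0 - np.exp(-t / 15.0)
        fit = fit_laco_frap(t, y, tau2_fixed=5.0)
        assert fit.f_stable <= 0.02

    def test_fraction_partition_sums_to_one(self):
        t = np.arange(0, 300, 2.0)
        y = 0.3 * (1 - np.exp(-t / 25.0)) + 0.2 * (1 - np.exp(-t / 5.0))
        fit = fit_laco_frap(t, y, tau2_fixed=5.0)
        assert fit.f_stable + fit.f_transient + fit.f_fast == pytest.approx(1.0)
        assert fit.f_fast == pytest.approx(0.2, abs=0.03)


class TestCorecruitment:
    def test_control_equals_zero(self):
        assert corecruitment_ratio(100.0, 50.0, 2.0) == pytest.approx(0.0)

    def test_excess_ratio_convention(self):
        # normalized ratio 1.6 reports 0.6 co-recruited per tethered molecule
        assert corecruitment_ratio(160.0, 100.0, 1.0) == pytest.approx(0.6)

    def test_synthetic_double_indirect_layer(self, rng):
        """Array with a tethered layer plus 2x indirect accumulation reads 2.0."""
        tethered = 80.0
        n = 200
        cand = rng.normal(3.0 * tethered, 2.0, n)  # direct + 2x indirect
        tet = rng.normal(tethered, 2.0, n)
        vals = [corecruitment_ratio(c, t, 1.0) for c, t in zip(cand, tet)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.05)

    def test_invalid_control(self):
        with pytest.raises(ValueError):
            corecruitment_ratio(10.0, 5.0, 0.0)


class TestSegmentAndGroup:
    @staticmethod
    def _phantom(blob_level=200.0):
        ny = nx = 64
        yy, xx = np.mgrid[0:ny, 0:nx]
        nucleus = np.hypot(yy - 32, xx - 32) <= 26
        dapi = np.where(nucleus, 100.0, 4.0)
        blobs = np.zeros((ny, nx), dtype=bool)
        for cy, cx in [(20, 20), (20, 44), (44, 20), (44, 44)]:
            blobs |= np.hypot(yy - cy, xx - cx) <= 4
        blobs &= nucleus
        dapi[blobs] = blob_level
        hp1 = np.where(nucleus, 50.0, 2.0)
        marker = np.where(nucleus, 120.0, 1.0)
        return dapi, hp1, marker, blobs

    def test_chromocenter_threshold_rule(self):
        dapi, hp1, marker, blobs = self._phantom()
        df = segment_and_group(
            {"hp1": hp1, "dapi": dapi, "zsgreen": marker}, "hp1_overexpression"
        )
        assert len(df) == 1
        row = df.iloc[0]
        # threshold = 1.3 * median DAPI (median 100 -> 130); blobs at 200
        assert row.compartment_threshold == pytest.approx(130.0)
        assert row.compartment_area == pytest.approx(blobs.sum(), rel=0.02)

    def test_dcas9_threshold_rule(self):
        ny = nx = 64
        yy, xx = np.mgrid[0:ny, 0:nx]
        nucleus = np.hypot(yy - 32, xx - 32) <= 26
        dapi = np.where(nucleus, 100.0, 4.0)
        dcas9 = np.where(nucleus, 100.0, 1.0)
        sat = nucleus & (np.hypot(yy - 28, xx - 36) <= 5)
        dcas9[sat] = 300.0
        df = segment_and_group({"dapi": dapi, "dcas9": dcas9}, "dcas9")
        row = df.iloc[0]
        # median 100, max 300 -> threshold 120; only the satellite exceeds it
        assert row.compartment_threshold == pytest.approx(120.0)
        assert row.compartment_area == sat.sum()

    def test_empty_compartment_flagged(self):
        ny = nx = 48
        yy, xx = np.mgrid[0:ny, 0:nx]
        nucleus = np.hypot(yy - 24, xx - 24) <= 20
        dapi = np.where(nucleus, 100.0, 4.0)  # uniform: nothing above 1.3x median
        hp1 = np.where(nucleus, 50.0, 2.0)
        df = segment_and_group(
            {"hp1": hp1, "dapi": dapi, "zsgreen": hp1}, "hp1_overexpression"
        )
        assert df.iloc[0].compartment_area == 0
        assert np.isnan(df.iloc[0].dapi_compartment_mean)

    def test_buffering_regime_slopes(self):
        """Globule-like panels show flat area vs marker but rising internal
        intensity; droplet-like panels show the converse."""
        slopes = {}
        for pop in ("size_buffering", "concentration_buffering"):
            cells, _ = sd.gen_nuclei_panel(pop, n_cells=20, rng=3)
            rows = []
            for c in cells:
                df = segment_and_group(
                    {"hp1": c["hp1"], "dapi": c["dapi"], "zsgreen": c["zsgreen"]},
                    "hp1_overexpression",
                )
                rows.append(
                    (c["marker"], df.compartment_area.iloc[0],
                     df.hp1_compartment_mean.iloc[0])
                )
            arr = np.array(rows)
            x = np.log(arr[:, 0])
            slopes[pop] = (
                np.polyfit(x, arr[:, 1] / arr[:, 1].mean(), 1)[0],
                np.polyfit(x, arr[:, 2] / arr[:, 2].mean(), 1)[0],
            )
        area_slope, intensity_slope = slopes["size_buffering"]
        assert abs(area_slope) < 0.15
        assert intensity_slope > 0.2
        area_slope, intensity_slope = slopes["concentration_buffering"]
        assert area_slope > 0.2
        assert abs(intensity_slope) < 0.15


class TestGrouping:
    def test_hand_computed_group_sizes(self):
        groups = group_by_percentiles(np.arange(1, 11))
        counts = collections.Counter(groups)
        assert counts["low"] == 4 and counts["medium"] == 2 and counts["high"] == 4

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=5, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariance_and_monotone_means(self, values, rnd):
        values = np.asarray(values)
        perm = np.asarray(rnd.sample(range(values.size), values.size))
        g1 = group_by_percentiles(values)
        g2 = group_by_percentiles(values[perm])
        assert np.array_equal(g1[perm], g2)
        means = [values[g1 == lab].mean() for lab in ("low", "medium", "high")
                 if (g1 == lab).any()]
        assert np.all(np.diff(means) >= 0)
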