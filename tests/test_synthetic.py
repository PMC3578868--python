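"""Synthetic study generator: design lattice, latent hierarchy, rendering,
markers."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from scipy import stats

from osteomorph.config import (ConfigError, DesignConfig, LatentConfig,
                               MarkerConfig, RenderConfig, desk_config)
from osteomorph.synthetic import (LatentPotential, WellKey, build_design,
                                  cells_at_timepoint, render_field,
                                  sample_latents, sample_markers,
                                  simulate_markers_table, write_dataset)


def canonical_design():
    return build_design(DesignConfig())


class TestDesign:
    def test_canonical_counts(self):
        d = canonical_design()
        assert d.n_wells == 54                      # 3 lots x 2 cond x 3 pass x 3 wells
        assert d.n_retained_timepoints == 37
        assert d.n_slots == 54 * 5 * 37 == 9990

    def test_trivial_lattice(self):
        d = build_design(dict(n_lots=1, conditions=("induction",),
                              n_passages_per_lot=1, wells_per_condition=1,
                              fields_per_well=1, timepoints_scheduled=2,
                              timepoints_excluded=()))
        assert d.n_slots == 2
        assert len(list(d.iter_slots())) == 2

    def test_excluded_timepoints_shrink_retention(self):
        d = build_design(dict(timepoints_scheduled=10, timepoints_excluded=(0, 5)))
        assert d.retained_timepoints == (1, 2, 3, 4, 6, 7, 8, 9)

    @pytest.mark.parametrize("bad", [
        {"n_lots": 0},
        {"timepoints_excluded": (99,)},
        {"conditions": ("induction", "weird")},
        {"nonexistent_key": 1},
    ])
    def test_invalid_config_raises_named_error(self, bad):
        with pytest.raises(ConfigError):
            build_design(bad)


class TestLatents:
    def test_reproducible_given_seed(self):
        d = canonical_design()
        assert sample_latents(d, 7) == sample_latents(d, 7)
        assert sample_latents(d, 7) != sample_latents(d, 8)

    def test_induction_exceeds_control_in_expectation(self):
        d = canonical_design()
        lat = sample_latents(d, 0)
        ind = [l.potential_score for l in lat.values() if l.condition == "induction"]
        ctl = [l.potential_score for l in lat.values() if l.condition == "control"]
        assert np.mean(ind) > np.mean(ctl)

    def test_zero_lot_variance_collapses_lot_means(self):
        d = build_design(dict(n_lots=3, conditions=("control",),
                              n_passages_per_lot=2, wells_per_condition=50,
                              fields_per_well=1))
        cfg = LatentConfig(sd_lot=0.0, sd_passage=0.01, sd_well=0.01)
        lat = sample_latents(d, 3, cfg)
        means = pd.Series({w: l.potential_score for w, l in lat.items()})
        lots = pd.Series({w: w.lot for w in lat})
        lot_means = means.groupby(lots).mean()
        assert lot_means.max() - lot_means.min() < 0.02

    def test_variance_components_recovered(self):
        # nested method-of-moments ANOVA on a wide design recovers the
        # configured lot > passage > well variance decomposition
        cfg = LatentConfig(sd_lot=0.12, sd_passage=0.06, sd_well=0.03)
        d = build_design(dict(n_lots=120, conditions=("control",),
                              n_passages_per_lot=3, wells_per_condition=3,
                              fields_per_well=1))
        lat = sample_latents(d, 5, cfg)
        df = pd.DataFrame({
            "lot": [w.lot for w in lat], "passage": [w.passage for w in lat],
            "p": [l.potential_score for l in lat.values()]})
        # within-(lot,passage) variance estimates sd_well^2
        v_well = df.groupby(["lot", "passage"])["p"].var(ddof=1).mean()
        # between-passage-within-lot variance of cell means
        cell_means = df.groupby(["lot", "passage"])["p"].mean()
        n_wells = 3
        v_pass = cell_means.groupby("lot").var(ddof=1).mean() - v_well / n_wells
        lot_means = cell_means.groupby("lot").mean()
        n_pass = 3
        v_lot = lot_means.var(ddof=1) - v_pass / n_pass - v_well / (n_pass * n_wells)
        assert v_well == pytest.approx(cfg.sd_well ** 2, rel=0.15)
        assert v_pass == pytest.approx(cfg.sd_passage ** 2, rel=0.15)
        assert v_lot == pytest.approx(cfg.sd_lot ** 2, rel=0.15)


def _latent(potential, condition="induction", style=0.0, assay=0.0):
    return LatentPotential(
        well=WellKey(1, condition, 1, 1), lot_effect=0.0, passage_effect=0.0,
        well_effect=0.0, style=style, assay_offset=assay,
        potential_score=potential)


class TestRendering:
    def test_empty_field_is_pure_background(self):
        img, truth, n = render_field(_latent(0.5), 0, 0, 1,
                                     image_shape=(64, 64), n_timepoints=10)
        assert n == 0 and truth.max() == 0
        assert img.std() < 10  # noise + gradient only

    def test_bit_identical_for_same_seed(self):
        args = dict(image_shape=(96, 96), n_timepoints=10)
        a = render_field(_latent(0.6), 5, 8, 42, **args)
        b = render_field(_latent(0.6), 5, 8, 42, **args)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_truth_count_matches_labels(self):
        img, truth, n = render_field(_latent(0.4), 3, 12, 9,
                                     image_shape=(128, 128), n_timepoints=10)
        assert n == 12
        assert set(np.unique(truth)) == set(range(13))

    def test_overpacked_field_raises(self):
        with pytest.raises(RuntimeError):
            render_field(_latent(0.9), 9, 500, 0, image_shape=(48, 48),
                         n_timepoints=10)

    def test_induced_cells_rounder_than_control_at_final_timepoint(self):
        # aspect ratio measured on ground-truth masks, >= 100 cells per group
        def mean_aspect(latent):
            ratios = []
            seed = 0
            while len(ratios) < 100:
                _, truth, _ = render_field(latent, 9, 12, seed,
                                           image_shape=(192, 192), n_timepoints=10)
                for sl in ndi.find_objects(truth):
                    m = truth[sl] > 0
                    mu = np.array(np.nonzero(m), float)
                    cov = np.cov(mu - mu.mean(1, keepdims=True))
                    ev = np.linalg.eigvalsh(cov)
                    if ev[0] > 0:
                        ratios.append(np.sqrt(ev[1] / ev[0]))
                seed += 1
            return np.mean(ratios)

        induced = mean_aspect(_latent(0.8, "induction"))
        control = mean_aspect(_latent(0.2, "control"))
        assert induced < control

    def test_proliferation_monotone(self):
        cfg = RenderConfig()
        counts = [cells_at_timepoint(t, 12, cfg) for t in range(12)]
        assert counts == sorted(counts)
        assert counts[-1] > counts[0]


class TestMarkers:
    def test_noise_free_baseline_and_monotonicity(self):
        cfg = MarkerConfig()
        lo = sample_markers(_latent(0.0), 0, cfg, noise=False)
        assert lo.alp_rate == pytest.approx(cfg.alp_base)
        assert lo.ca_rate == pytest.approx(cfg.ca_base)
        hi = sample_markers(_latent(1.0), 0, cfg, noise=False)
        mid = sample_markers(_latent(0.5), 0, cfg, noise=False)
        assert lo.alp_rate < mid.alp_rate < hi.alp_rate
        assert lo.ca_rate < mid.ca_rate < hi.ca_rate

    def test_induction_vs_control_significant(self):
        # >= 500 wells; two-sample test on generated values, p < 0.01
        d = build_design(dict(n_lots=10, n_passages_per_lot=5,
                              wells_per_condition=5, fields_per_well=1))
        table = simulate_markers_table(d, 2)
        ind = table[table.condition == "induction"]
        ctl = table[table.condition == "control"]
        assert len(ind) >= 250 and len(ctl) >= 250
        for marker in ("alp_rate", "ca_rate"):
            p = stats.ttest_ind(ind[marker], ctl[marker], equal_var=False).pvalue
            assert p < 0.01

    def test_calcium_noisier_than_alp(self):
        d = build_design(dict(n_lots=10, n_passages_per_lot=5,
                              wells_per_condition=5, fields_per_well=1))
        table = simulate_markers_table(d, 4)
        ind = table[table.condition == "induction"]
        cv = lambda x: x.std() / x.mean()
        assert cv(ind["ca_rate"]) > cv(ind["alp_rate"])

    def test_induction_above_control_across_seed_replicates(self):
        d = build_design(dict(fields_per_well=1, timepoints_scheduled=2,
                              timepoints_excluded=()))
        wins = 0
        for seed in range(20):
            t = simulate_markers_table(d, seed)
            g = t.groupby("condition")[["alp_rate", "ca_rate"]].mean()
            wins += (g.loc["induction"] > g.loc["control"]).all()
        assert wins >= 19  # >= 95% of replicates


def test_write_dataset_layout(tmp_path):
    d = build_design(dict(n_lots=1, conditions=("induction",),
                          n_passages_per_lot=1, wells_per_condition=1,
                          fields_per_well=2, timepoints_scheduled=3,
                          timepoints_excluded=(0,), image_shape=(192, 192)))
    out = write_dataset(d, 0, tmp_path / "study")
    tifs = sorted(p.name for p in out.rglob("t*.tif"))
    assert len(tifs) == 8  # 2 fields x 2 timepoints x (image + truth)
    markers = pd.read_csv(out / "markers.csv")
    assert list(markers.columns) == ["well_id", "lot", "passage", "condition",
                                     "alp_rate", "ca_rate"]
    assert len(markers) == 1
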