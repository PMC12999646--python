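"""Volcano statistics, BH oracle equivalence, solvent comparison."""

import numpy as np
import pandas as pd
import pytest

from lipidmsi import differential
from lipidmsi.differential import (benjamini_hochberg, classify_effect,
                                   reflection_data, solvent_compare, volcano,
                                   whole_tissue_abundances)
from lipidmsi.msi_io import tic_image, tissue_mask
from lipidmsi.panel import (DEFAULT_MASS_GROUPS, default_panel, null_panel,
                            with_uniform_suppression)
from lipidmsi.synthetic import NoiseModel, PhantomConfig, generate_phantom


def bh_oracle(p):
    """Definitional step-up: adj_i = min_{j>=rank(i)} (m * p_(j) / j), <=1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBenjaminiHochberg:
    def test_equal_spacing_example(self):
        # p = (.01,.02,.03,.04), m=4: every adjusted value is 0.04
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_matches_step_up_oracle_random(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m)
            assert np.allclose(benjamini_hochberg(p), bh_oracle(p),
                               rtol=0, atol=1e-12)

    def test_monotone_in_p(self):
        p = np.array([0.001, 0.01, 0.3, 0.7])
        adj = benjamini_hochberg(p)
        assert (np.diff(adj[np.argsort(p)]) >= 0).all()
        assert (adj >= p).all()


def _abundance_frame(a_vals, b_vals, species="sp", cat="SP"):
    rows = []
    for i, v in enumerate(a_vals):
        rows.append({"species": species, "lmsd_category": cat,
                     "condition": "diseased", "replicate_id": f"d{i}",
                     "abundance": v})
    for i, v in enumerate(b_vals):
        rows.append({"species": species, "lmsd_category": cat,
                     "condition": "healthy", "replicate_id": f"h{i}",
                     "abundance": v})
    return pd.DataFrame(rows)


class TestVolcano:
    def test_identical_groups_null(self):
        df = _abundance_frame([10.0, 12.0, 9.0], [10.0, 12.0, 9.0])
        vt = volcano(df, "diseased", "healthy")
        assert vt["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert vt["p_value"].iloc[0] > 0.9
        assert not vt["significant"].iloc[0]

    def test_sign_flips_on_group_swap(self):
        df = _abundance_frame([40.0, 44.0, 38.0, 41.0], [10.0, 12.0, 9.0])
        a = volcano(df, "diseased", "healthy")
        b = volcano(df, "healthy", "diseased")
        assert a["log2fc"].iloc[0] == pytest.approx(-b["log2fc"].iloc[0])
        assert a["p_value"].iloc[0] == pytest.approx(b["p_value"].iloc[0])

    def test_requires_two_replicates(self):
        df = _abundance_frame([10.0], [10.0, 11.0])
        with pytest.raises(ValueError, match="2 replicates"):
            volcano(df, "diseased", "healthy")

    def test_nonpositive_excluded_with_warning(self):
        df = _abundance_frame([10.0, 0.0, 12.0, 11.0], [5.0, 6.0, 5.5])
        with pytest.warns(UserWarning, match="non-positive"):
            vt = volcano(df, "diseased", "healthy")
        want = np.log2([10.0, 12.0, 11.0]).mean() - np.log2([5.0, 6.0, 5.5]).mean()
        assert vt["log2fc"].iloc[0] == pytest.approx(want)

    @pytest.mark.parametrize("lfc,expected", [
        (0.3, "none"), (0.9, "small_moderate"), (-1.2, "small_moderate"),
        (1.7, "intermediate"), (2.5, "large"), (-3.0, "large"),
    ])
    def test_effect_bands(self, lfc, expected):
        assert classify_effect(lfc) == expected

    def test_mannwhitney_option(self):
        df = _abundance_frame([40.0, 44.0, 38.0, 41.0], [10.0, 12.0, 9.0])
        vt = volcano(df, "diseased", "healthy", test="mannwhitney")
        assert 0 < vt["p_value"].iloc[0] <= 1


class TestWholeTissue:
    def test_seven_values_per_species(self, default_cohort):
        ab = whole_tissue_abundances(default_cohort.images,
                                     default_cohort.config.panel)
        counts = ab.groupby("species")["abundance"].size()
        assert (counts == 7).all()

    def test_scales_with_baseline(self, noise):
        """Doubling the generator baseline doubles the measured mean."""
        from lipidmsi import chem
        from lipidmsi.panel import PanelEntry

        def one(baseline, seed):
            entry = PanelEntry(
                name="probe", formula=chem.parse_formula("C27H46O"),
                lmsd_category="ST",
                baseline_abundance={"default": baseline},
                adduct_fractions={"[M+H]+": 1.0})
            cfg = PhantomConfig(grid_shape=(60, 40), panel=[entry])
            img = generate_phantom(cfg, noise, "healthy", 0, seed,
                                   replicate_offset_log2=0.0)
            return whole_tissue_abundances([img], [entry])["abundance"].iloc[0]

        lo = np.mean([one(300.0, s) for s in range(3)])
        hi = np.mean([one(600.0, s) for s in range(3, 6)])
        assert hi / lo == pytest.approx(2.0, rel=0.1)

    def test_psychosine_recovered_as_large_effect(self, default_cohort):
        ab = whole_tissue_abundances(default_cohort.images,
                                     default_cohort.config.panel)
        vt = volcano(ab, "diseased", "healthy").set_index("species")
        assert abs(vt.loc["psychosine", "log2fc"]) > 2.0
        assert vt.loc["psychosine", "effect_class"] == "large"

    def test_fatty_acids_small_moderate(self, default_cohort):
        ab = whole_tissue_abundances(default_cohort.images,
                                     default_cohort.config.panel)
        vt = volcano(ab, "diseased", "healthy").set_index("species")
        bands = [vt.loc[sp, "effect_class"]
                 for sp in ("oleic acid", "DHA", "linoleic acid")]
        assert "large" not in bands


class TestRegionalVolcano:
    def test_single_replicate_region_rejected(self):
        rows = []
        for cond, rep in [("diseased", "d0"), ("healthy", "h0"),
                          ("healthy", "h1")]:
            rows.append({"condition": cond, "replicate_id": rep,
                         "region": "cerebrum", "roi_index": 0,
                         "species": "sp", "mean_abundance": 1.0,
                         "log_abundance": 0.0})
        table = pd.DataFrame(rows)
        with pytest.raises(ValueError, match="fewer than 2"):
            differential.regional_volcano(table, "cerebrum",
                                          "diseased", "healthy")

    def test_unknown_region_rejected(self):
        table = pd.DataFrame({"region": ["cerebrum"], "species": ["sp"],
                              "condition": ["healthy"],
                              "replicate_id": ["h0"],
                              "mean_abundance": [1.0]})
        with pytest.raises(ValueError, match="no rows"):
            differential.regional_volcano(table, "thalamus",
                                          "diseased", "healthy")


@pytest.fixture(scope="module")
def solvent_pair(noise):
    panel = with_uniform_suppression(null_panel(), -1.0)
    kw = dict(grid_shape=(90, 60), spatial_resolution=150.0,
              scan_range=(200.0, 1000.0), panel=panel)
    cfg_s = PhantomConfig(solvent="standard", **kw)
    cfg_d = PhantomConfig(solvent="doped", **kw)
    img_s = generate_phantom(cfg_s, noise, "diseased", 0, 31,
                             replicate_offset_log2=0.0)
    img_d = generate_phantom(cfg_d, noise, "diseased", 0, 32,
                             replicate_offset_log2=0.0)
    return img_s, img_d, panel


class TestSolventComparison:
    def test_identical_images_zero_ratios(self, noise):
        panel = null_panel()
        cfg = PhantomConfig(grid_shape=(60, 40), panel=panel)
        img = generate_phantom(cfg, noise, "diseased", 0, 33)
        comp = solvent_compare(img, img, panel)
        defined = comp.per_species[comp.per_species["defined"]]
        assert np.allclose(defined["log2_ratio"], 0.0)
        assert np.allclose(comp.per_category["mean"], 0.0)
        assert comp.preference_fraction == 0.0   # ties are not preferences

    def test_uniform_suppression_recovered(self, solvent_pair):
        img_s, img_d, panel = solvent_pair
        comp = solvent_compare(img_s, img_d, panel)
        # detection-floor censoring hits the suppressed (doped) side harder,
        # so category means can overshoot -1 slightly
        assert np.allclose(comp.per_category["mean"], -1.0, atol=0.25)
        assert comp.preference_fraction == pytest.approx(1.0)

    def test_fourteen_member_ions(self, solvent_pair):
        img_s, img_d, panel = solvent_pair
        comp = solvent_compare(img_s, img_d, panel)
        assert len(comp.per_ion) == 14
        assert comp.mass_groups.set_index("group")["n_members"].to_dict() == \
            {"lower": 3, "central": 2, "upper": 9}

    def test_group_fold_ratio_reflects_suppression(self, solvent_pair):
        img_s, img_d, panel = solvent_pair
        comp = solvent_compare(img_s, img_d, panel)
        assert comp.mass_groups["fold_standard_over_doped"].between(
            1.7, 2.3).all()


class TestReflection:
    def test_mirror_symmetric_for_identical_inputs(self, noise):
        cfg = PhantomConfig(grid_shape=(60, 40))
        img = generate_phantom(cfg, noise, "diseased", 0, 35)
        df = reflection_data(img, img, bin_width=1.0)
        assert np.allclose(df["mean_a"], df["mean_b"])

    def test_single_peak_lands_in_one_bin(self):
        from conftest import make_image

        img = make_image({(0, 0): [(462.3425, 100.0)],
                          (1, 0): [(462.3425, 90.0)]}, grid_shape=(2, 1))
        df = reflection_data(img, img, bin_width=1.0, mask_method="fraction")
        assert (df["mean_a"] > 0).sum() == 1
        assert df.loc[df["mean_a"] > 0, "mz_low"].iloc[0] == 462.0

    def test_bin_integral_equals_mean_tic(self, noise):
        cfg = PhantomConfig(grid_shape=(60, 40))
        img = generate_phantom(cfg, noise, "diseased", 0, 36)
        df = reflection_data(img, img, bin_width=2.0)
        mask = tissue_mask(tic_image(img))
        tic = tic_image(img)
        mean_tic = tic.values[mask].mean()
        assert df["mean_a"].sum() == pytest.approx(mean_tic, rel=1e-9)
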