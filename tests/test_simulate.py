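"""Synthetic study-shaped data generator."""

import numpy as np
import pandas as pd
import pytest
import yaml

import wingmorph as wm
from wingmorph.errors import ConfigError
from wingmorph.gpa import _center_scale


class TestReferenceMeans:
    def test_zero_separation_collapses(self):
        means = wm.make_reference_means(19, 0.0, seed=1, n_groups=4)
        arr = np.stack(list(means.values()))
        assert np.abs(arr - arr[0]).max() < 1e-12

    def test_landmark_count(self):
        means = wm.make_reference_means(19, 0.05, seed=1, n_groups=4)
        assert all(m.shape == (19, 2) for m in means.values())

    def test_unit_centroid_size(self):
        for m in wm.make_reference_means(10, 0.1, seed=2).values():
            assert np.sqrt((m**2).sum()) == pytest.approx(1.0)

    def test_separation_monotone(self):
        """Pairwise Procrustes distances between means grow with the
        separation parameter."""
        def mean_pairwise(sep):
            means = list(wm.make_reference_means(12, sep, seed=3).values())
            ds = [
                wm.procrustes_fit(a, b)[1]
                for i, a in enumerate(means) for b in means[i + 1:]
            ]
            return np.mean(ds)

        seps = [0.01, 0.03, 0.06, 0.12]
        vals = [mean_pairwise(s) for s in seps]
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))


class TestSamplePopulation:
    def test_pure_population_no_noise(self):
        """sigma_w -> 0, pure weights, no nuisance: every specimen is the
        group mean up to the size factor."""
        cfg = wm.SimulationConfig(seed=5, sigma_w=1e-12, nuisance=False)
        means = wm.make_reference_means(cfg.k, cfg.separation, seed=5,
                                        names=["A"])
        rng = np.random.default_rng(0)
        configs = wm.sample_population(
            cfg, "popA", 5, {"A": 1.0}, cfg.altitude_range, means, rng
        )
        for c in configs:
            np.testing.assert_allclose(
                _center_scale(c.coords), means["A"], atol=1e-9
            )

    def test_weights_must_sum_to_one(self):
        cfg = wm.SimulationConfig(seed=1)
        means = wm.make_reference_means(cfg.k, 0.05, seed=1, names=["A", "B"])
        with pytest.raises(ConfigError, match="sum"):
            wm.sample_population(
                cfg, "p", 3, {"A": 0.6, "B": 0.6}, cfg.altitude_range,
                means, np.random.default_rng(0),
            )

    def test_altitude_size_correlation_single_draw(self):
        """One n=750 draw lands near the target correlation."""
        cfg = wm.SimulationConfig(seed=9)
        means = wm.make_reference_means(cfg.k, cfg.separation, seed=9,
                                        names=["A"])
        configs = wm.sample_population(
            cfg, "p", 750, {"A": 1.0}, cfg.altitude_range, means,
            np.random.default_rng(9),
        )
        cs = np.array([wm.centroid_size(c.coords) for c in configs])
        alt = np.array([c.metadata["altitude_masl"] for c in configs])
        res = wm.size_covariate_correlation(cs, alt)
        assert res.r == pytest.approx(-0.32, abs=0.1)


class TestStudySimulation:
    def test_study_shape(self):
        """Full default design: 750 study wings in 15 apiaries, 4
        reference panels of 50, plus the placebo outgroup."""
        sim = wm.simulate_study(wm.SimulationConfig(seed=0))
        meta = sim.metadata
        queries = meta[meta["group_label"].isna()]
        assert len(queries) == 750
        assert queries["apiary"].nunique() == 15
        assert queries.groupby("apiary").size().eq(50).all()
        refs = meta[meta["group_label"].notna() & (meta["group_label"] != "placebo")]
        assert refs.groupby("group_label").size().eq(50).all()
        assert len(refs) == 200
        assert (meta["group_label"] == "placebo").sum() == 10
        assert sim.dataset.k == 19

    def test_altitudes_cover_floors(self):
        sim = wm.simulate_study(wm.SimulationConfig(seed=1))
        meta = sim.metadata
        floors = meta.loc[meta["group_label"].isna(), "floor"]
        assert floors.notna().all()
        assert floors.nunique() == 3

    def test_seed_determinism(self):
        cfg = dict(seed=3, n_apiaries=3, colonies_per_apiary=2,
                   wings_per_colony=3, n_per_reference=5)
        s1 = wm.simulate_study(wm.SimulationConfig(**cfg))
        s2 = wm.simulate_study(wm.SimulationConfig(**cfg))
        np.testing.assert_array_equal(
            s1.dataset.coords_array(), s2.dataset.coords_array()
        )

    def test_gpa_recovers_noise_model(self, small_sim, small_gpa):
        """After undoing the nuisance transforms, reference-group tangent
        residuals match the isotropic noise model: mean ~ 0 and
        per-coordinate SD ~ sigma_w."""
        meta = small_gpa.metadata
        mask = (meta["group_label"] == small_sim.config.reference_names[0]).to_numpy()
        t = small_gpa.tangent[mask]
        resid = t - t.mean(axis=0)
        sd = resid.std()
        assert sd == pytest.approx(small_sim.config.sigma_w, rel=0.35)
        assert np.abs(t.mean(axis=0)).max() < 5 * small_sim.config.sigma_w

    def test_hybrid_fraction_monotone_in_lambda(self):
        """The fraction of a simulated population classified to the
        scutellata-like reference is non-decreasing in lambda."""
        fractions = []
        for lam in (0.0, 0.5, 1.0):
            cfg = wm.SimulationConfig(
                seed=17, hybrid_lambda=lam, n_apiaries=2,
                colonies_per_apiary=2, wings_per_colony=5, n_per_reference=10,
                include_placebo=False,
            )
            sim = wm.simulate_study(cfg)
            res = wm.GeneralizedProcrustes(sim.dataset).fit()
            labels = res.metadata["group_label"]
            lda = wm.LinearDiscriminant(
                res.tangent, labels, provenance=res.provenance
            ).fit()
            q = labels.isna().to_numpy()
            out = lda.classify(res.tangent[q], provenance=res.provenance)
            fractions.append(
                (out.assigned == "A. m. scutellata").mean()
            )
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[2] > fractions[0]


class TestWriteStudy:
    def test_files_round_trip(self, tmp_path):
        cfg = wm.SimulationConfig(seed=2, n_apiaries=2, colonies_per_apiary=1,
                                  wings_per_colony=3, n_per_reference=4,
                                  include_placebo=False)
        sim = wm.simulate_study(cfg)
        paths = wm.write_study(sim, tmp_path)
        ds = wm.read_tps(paths["tps"])
        ds = wm.attach_metadata(ds, paths["metadata"])
        assert len(ds) == len(sim.dataset)
        meta = ds.metadata_frame()
        assert meta["altitude_masl"].notna().sum() == len(ds)
        with open(paths["config"]) as fh:
            stored = yaml.safe_load(fh)
        assert stored["seed"] == 2 and stored["k"] == 19

    def test_sequence_mutation_rates(self):
        panel = wm.make_haplotype_panel(n_haplotypes=3, length=500, seed=4)
        same = wm.mutate_sequences(panel, rate=0.0, n_per_haplotype=1, seed=4)
        assert all(q.seq == e.record.seq for (q, _), e in zip(same, panel))
        mutated = wm.mutate_sequences(panel, rate=0.03, n_per_haplotype=4, seed=4)
        idents = [
            wm.global_align_identity(q, next(e.record for e in panel
                                             if e.haplotype == truth))
            for q, truth in mutated
        ]
        assert np.mean(idents) == pytest.approx(97.0, abs=0.8)
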