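"""Latent-threshold generator: feasibility bounds, inversion, sampling, rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import symptomics as sy
from symptomics.synthetic import (
    CorpusProfile,
    GeneratorConfig,
    build_latent_model,
    default_profile,
    feasible_phi_bounds,
    phi_from_latent,
    phi_to_latent_correlation,
    render_narratives,
    sample_binary_matrix,
    simulate_corpus,
    DEFAULT_FILLERS,
)


class TestFeasiblePhiBounds:
    def test_symmetric_half_margins_attain_extremes(self):
        lo, hi = feasible_phi_bounds(0.5, 0.5)
        assert lo == pytest.approx(-1.0)
        assert hi == pytest.approx(1.0)

    def test_skewed_margins_extreme_table(self):
        _, hi = feasible_phi_bounds(0.9, 0.1)
        assert hi == pytest.approx((0.1 - 0.09) / math.sqrt(0.9 * 0.1 * 0.1 * 0.9))

    def test_equal_low_margins_max_is_one(self):
        _, hi = feasible_phi_bounds(0.057, 0.057)
        assert hi == pytest.approx(1.0)

    @given(st.floats(0.02, 0.98), st.floats(0.02, 0.98))
    @settings(max_examples=100, deadline=None)
    def test_bounds_come_from_extreme_tables(self, p1, p2):
        """Oracle: phi of the Frechet-extreme 2x2 tables equals the bounds."""
        lo, hi = feasible_phi_bounds(p1, p2)
        denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        assert hi == pytest.approx((min(p1, p2) - p1 * p2) / denom, rel=1e-12)
        assert lo == pytest.approx((max(0.0, p1 + p2 - 1) - p1 * p2) / denom, rel=1e-12)
        assert lo < 0 < hi


class TestLatentInversion:
    def test_zero_phi_maps_to_zero_rho(self):
        assert phi_to_latent_correlation(0.3, 0.7, 0.0) == 0.0

    def test_half_margins_closed_form(self):
        # at p1 = p2 = 1/2: phi = (2/pi) arcsin(rho), so rho = sin(pi phi / 2)
        rho = phi_to_latent_correlation(0.5, 0.5, 0.5)
        assert rho == pytest.approx(math.sin(math.pi * 0.5 / 2), abs=1e-6)

    def test_boundary_phi_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            phi_to_latent_correlation(0.5, 0.5, 1.0)

    def test_round_trip_within_tolerance(self):
        for p1, p2, phi in [(0.061, 0.05, 0.26), (0.2, 0.7, -0.15), (0.1, 0.1, 0.4)]:
            rho = phi_to_latent_correlation(p1, p2, phi)
            assert phi_from_latent(p1, p2, rho) == pytest.approx(phi, abs=1e-6)

    def test_monotone_in_phi(self):
        phis = [-0.05, 0.0, 0.05, 0.15, 0.25]  # all inside the Frechet range
        rhos = [phi_to_latent_correlation(0.06, 0.1, f) for f in phis]
        assert rhos == sorted(rhos)
        assert all(b > a for a, b in zip(rhos, rhos[1:]))

    def test_monte_carlo_cross_check(self):
        """Thresholded bivariate normal draws reproduce the solved-for phi."""
        p1, p2, phi = 0.5, 0.5, 0.5
        rho = phi_to_latent_correlation(p1, p2, phi)
        rng = np.random.default_rng(11)
        z1 = rng.standard_normal(1_000_000)
        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(1_000_000)
        x = (z1 > stats.norm.isf(p1)).astype(int)
        y = (z2 > stats.norm.isf(p2)).astype(int)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(phi, abs=0.003)


class TestGeneratorConfig:
    def test_phi_target_for_unknown_symptom_rejected(self):
        with pytest.raises(ValueError, match="unknown symptom"):
            GeneratorConfig.create(10, {"a": 0.5}, {("a", "b"): 0.1})

    def test_infeasible_phi_target_rejected(self):
        with pytest.raises(ValueError, match="feasible"):
            GeneratorConfig.create(10, {"a": 0.9, "b": 0.1}, {("a", "b"): 0.5})

    def test_non_psd_joint_targets_fail_loudly(self):
        cfg = GeneratorConfig.create(
            100,
            {"i": 0.06, "a": 0.06, "b": 0.06},
            {("i", "a"): 0.8, ("i", "b"): 0.8, ("a", "b"): -0.03},
        )
        with pytest.raises(ValueError, match="infeasible"):
            build_latent_model(cfg)
        # explicit repair is allowed but warns
        with pytest.warns(UserWarning, match="PSD"):
            model = build_latent_model(cfg, nearest_psd=True)
        assert np.linalg.eigvalsh(model.latent_correlations).min() >= -1e-10


class TestSampleBinaryMatrix:
    def test_planted_phi_recovered_within_sampling_error(self):
        # phi-hat at rare margins has heavier noise than the 1/sqrt(n) rule of
        # thumb, so the check averages a few seeds before applying the bound
        vals = []
        for seed in range(5):
            cfg = GeneratorConfig.create(
                10_000, {"A": 0.057, "B": 0.06}, {("A", "B"): 0.26}, seed=seed
            )
            vals.append(sy.phi_correlation(*sample_binary_matrix(cfg).T.to_numpy()))
        assert np.mean(vals) == pytest.approx(
            0.26, abs=3 * math.sqrt((1 - 0.26**2) / 10_000)
        )

    def test_unspecified_pairs_independent(self):
        cfg = GeneratorConfig.create(
            10_000, {"A": 0.3, "B": 0.4, "C": 0.2}, seed=2
        )
        m = sample_binary_matrix(cfg)
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert abs(sy.phi_correlation(m[a], m[b])) < 0.03

    def test_marginal_prevalences_converge(self):
        cfg = GeneratorConfig.create(20_000, {"A": 0.057, "B": 0.5}, seed=3)
        m = sample_binary_matrix(cfg)
        assert m["A"].mean() == pytest.approx(0.057, abs=0.006)
        assert m["B"].mean() == pytest.approx(0.5, abs=0.012)

    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig.create(500, {"A": 0.2, "B": 0.3}, seed=9)
        assert sample_binary_matrix(cfg).equals(sample_binary_matrix(cfg))


class TestRendering:
    def small_config(self, seed=0):
        return GeneratorConfig.create(
            200,
            {"auditory hallucination": 0.2, "lack of sleep": 0.4, "pain": 0.3,
             "low mood": 0.25},
            {("auditory hallucination", "lack of sleep"): 0.2},
            seed=seed,
            repeat_mention_rate=1.0,
        )

    def test_round_trip_exact(self, lex):
        cfg = self.small_config()
        m = sample_binary_matrix(cfg)
        records = render_narratives(m, lex, cfg)
        sets = sy.extract_corpus(records, lex)
        rebuilt = sy.build_matrix(sets, lex, all_columns=True)[list(m.columns)]
        assert rebuilt.equals(m)

    def test_zero_row_renders_fillers_only(self, lex):
        import pandas as pd

        cfg = self.small_config()
        m = pd.DataFrame(
            np.zeros((3, 4), dtype=np.int8),
            index=pd.Index(["a", "b", "c"], name="patient_id"),
            columns=list(dict(cfg.prevalences)),
        )
        records = render_narratives(m, lex, cfg)
        assert all(r.text for r in records)
        for ss in sy.extract_corpus(records, lex):
            assert ss.symptoms == frozenset()

    def test_repeat_mentions_still_encode_to_one(self, lex):
        import pandas as pd

        cfg = GeneratorConfig.create(
            1, {"anxiety": 0.5}, repeat_mention_rate=10.0, seed=4
        )
        m = pd.DataFrame(
            [[1]], index=pd.Index(["a"], name="patient_id"), columns=["anxiety"]
        )
        records = render_narratives(m, lex, cfg)
        assert records[0].text.count("anxi") >= 2  # several mentions rendered
        rebuilt = sy.build_matrix(sy.extract_corpus(records, lex), lex)
        assert rebuilt.loc["a", "anxiety"] == 1

    def test_deterministic_given_seed(self, lex):
        cfg = self.small_config(seed=7)
        m = sample_binary_matrix(cfg)
        assert render_narratives(m, lex, cfg) == render_narratives(m, lex, cfg)

    def test_fillers_disjoint_from_surface_tokens(self, lex):
        assert not set(DEFAULT_FILLERS) & lex.surface_tokens


class TestSimulateCorpus:
    def test_small_profile_counts_and_cleaning(self, lex):
        cfg = GeneratorConfig.create(
            300, {"pain": 0.3, "anxiety": 0.4, "fear": 0.2}, seed=5
        )
        records, truth, manifest = simulate_corpus(
            cfg, lex, CorpusProfile(n_zero_symptom=20, n_duplicates=1)
        )
        assert len(records) == 300
        assert manifest["expected_rows_after_cleaning"] == 279
        sets = sy.extract_corpus(records, lex)
        matrix = sy.build_matrix(sets, lex)
        cleaned, report = sy.clean_matrix(matrix, lex, raw_records=records)
        assert report.n_zero_symptom_rows_removed == 20
        assert report.n_duplicate_rows_removed == 1
        assert report.n_output_rows == 279

    def test_duplicate_has_identical_text_distinct_id(self, lex):
        cfg = GeneratorConfig.create(50, {"pain": 0.5, "anxiety": 0.5}, seed=6)
        records, _, _ = simulate_corpus(
            cfg, lex, CorpusProfile(n_zero_symptom=0, n_duplicates=1)
        )
        texts = [r.text for r in records]
        ids = [r.patient_id for r in records]
        assert len(set(ids)) == len(ids)
        assert len(set(texts)) == len(texts) - 1

    def test_byte_identical_given_seed(self, lex, tmp_path):
        cfg = GeneratorConfig.create(120, {"pain": 0.4, "fear": 0.3}, seed=8)
        for name in ("a", "b"):
            records, matrix, _ = simulate_corpus(
                cfg, lex, CorpusProfile(n_zero_symptom=5, n_duplicates=1)
            )
            sy.write_corpus(records, tmp_path / f"{name}.tsv")
            sy.write_matrix(matrix, tmp_path / f"{name}.csv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_empty_corpus_valid(self, lex):
        cfg = GeneratorConfig.create(0, {"pain": 0.5})
        records, matrix, manifest = simulate_corpus(cfg, lex)
        assert records == [] and matrix.shape[0] == 0
        assert manifest["n_records"] == 0


class TestDefaultProfile:
    def test_study_shape(self):
        config, profile, lexicon = default_profile(seed=0)
        assert config.n_patients == 10_933
        assert profile.n_zero_symptom == 704
        assert profile.n_duplicates == 1
        prev = config.prevalence_map
        assert prev["auditory hallucination"] == pytest.approx(0.061)
        phis = config.phi_map
        assert phis[("auditory hallucination", "visual hallucination")] == 0.26
        for s in ("dissociation", "obsession", "compulsion"):
            assert phis[tuple(sorted(("auditory hallucination", s)))] == 0.0

    def test_joint_targets_are_psd(self):
        config, _, _ = default_profile(seed=0)
        model = build_latent_model(config)
        assert np.linalg.eigvalsh(model.latent_correlations).min() >= -1e-10
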