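"""Synthetic cohort generator: determinism, planted structure, recovery."""

import numpy as np
import pytest

from scfc.containers import ValidationError
from scfc.construct import sc_from_streamlines
from scfc.metrics import degree
from scfc.richclub import classify_edges, consensus_mean_degree, select_hubs
from scfc.synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_covariates_and_scores,
    generate_functional_connectome,
    generate_structural_cohort,
    generate_structural_connectome,
    planted_hub_set,
)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(p_rich=1.5)
        with pytest.raises(ValidationError):
            GeneratorConfig(n_hubs=246)
        with pytest.raises(ValidationError):
            GeneratorConfig(group_sizes={"NC": 0})
        with pytest.raises(ValidationError):
            GeneratorConfig(coupling_strength={"NC": 1.0, "MCI": 0.4, "AD": 0.5})

    def test_roundtrip_through_dict(self):
        cfg = GeneratorConfig(seed=9, p_rich=0.2)
        again = GeneratorConfig.from_dict(cfg.to_dict())
        assert again.to_dict() == cfg.to_dict()

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            GeneratorConfig.from_dict({"nope": 1})


class TestStructuralGenerator:
    def test_degenerate_probabilities_fill_only_hub_block(self):
        cfg = GeneratorConfig(p_rich=1.0, p_feeder=0.0, p_local=0.0)
        m = generate_structural_connectome(cfg, "NC", np.random.default_rng(0))
        h = cfg.n_hubs
        hub_block = m.counts[:h, :h]
        off = np.triu_indices(h, 1)
        assert np.all(hub_block[off] >= 3)  # fully connected hub block
        assert m.counts[h:, :].sum() == 0

    def test_counts_at_least_three_and_symmetric(self):
        cfg = GeneratorConfig()
        m = generate_structural_connectome(cfg, "AD", np.random.default_rng(1))
        present = m.counts[m.counts > 0]
        assert present.min() >= 3
        np.testing.assert_array_equal(m.counts, m.counts.T)
        assert np.all(np.diagonal(m.counts) == 0)

    def test_unknown_group_errors(self):
        with pytest.raises(ValidationError, match="group"):
            generate_structural_connectome(
                GeneratorConfig(), "XX", np.random.default_rng(0)
            )

    def test_hub_pair_edge_fraction_matches_binomial_expectation(self):
        """Empirical hub-pair edge fraction within 3 SE of p_rich (block mean)."""
        cfg = GeneratorConfig()
        rng = np.random.default_rng(2)
        h = cfg.n_hubs
        iu = np.triu_indices(h, 1)
        n_pairs = len(iu[0])
        reps = 200
        frac = np.empty(reps)
        for r in range(reps):
            m = generate_structural_connectome(cfg, "NC", rng)
            frac[r] = (m.counts[:h, :h][iu] > 0).mean()
        # block-average probability is p_rich; an upper bound on the SE is
        # the binomial SE at p_rich (per-pair heterogeneity only shrinks it)
        se = np.sqrt(cfg.p_rich * (1 - cfg.p_rich) / (n_pairs * reps))
        assert abs(frac.mean() - cfg.p_rich) < 3 * se

    def test_feeder_thinning_ratio_matches_keep_fraction(self):
        """AD/NC mean feeder edge count ratio tracks the planted 0.8 keep."""
        base = GeneratorConfig().to_dict()
        base["degradation"]["AD"] = {
            "feeder_keep": 0.8, "local_keep": 1.0, "rich_keep": 1.0
        }
        cfg = GeneratorConfig.from_dict(base)
        rng = np.random.default_rng(3)
        h = cfg.n_hubs

        def feeder_count(group):
            m = generate_structural_connectome(cfg, group, rng)
            return (m.counts[:h, h:] > 0).sum()

        reps = 60
        nc = np.mean([feeder_count("NC") for _ in range(reps)])
        ad = np.mean([feeder_count("AD") for _ in range(reps)])
        assert ad / nc == pytest.approx(0.8, abs=0.03)

    def test_degradation_monotone_in_keep_fraction(self):
        """Feeder density decreases stochastically as feeder_keep shrinks."""
        rng = np.random.default_rng(4)
        keeps = [0.6, 0.8, 1.0]
        means = []
        for keep in keeps:
            d = GeneratorConfig().to_dict()
            d["degradation"]["NC"] = {
                "feeder_keep": keep, "local_keep": 1.0, "rich_keep": 1.0
            }
            cfg = GeneratorConfig.from_dict(d)
            hubs = planted_hub_set(cfg)
            dens = [
                classify_edges(
                    sc_from_streamlines(
                        generate_structural_connectome(cfg, "NC", rng)
                    ),
                    hubs,
                ).densities["feeder"]
                for _ in range(20)
            ]
            means.append(np.mean(dens))
        slope = np.polyfit(keeps, means, 1)[0]
        assert slope > 0
        assert means[0] < means[1] < means[2]


class TestFunctionalGenerator:
    def test_fc_invariants_on_generated_subjects(self, tiny_cohort):
        for s in tiny_cohort:
            w = s.fc.weights
            np.testing.assert_allclose(w, w.T)
            assert np.all(np.diagonal(w) == 0)
            assert w.min() >= 0 and w.max() <= 1
            np.testing.assert_allclose(s.sc.weights, s.sc.weights.T)

    def test_zero_frac_zeroes_connected_pairs(self):
        cfg = GeneratorConfig(seed=11)
        sc = sc_from_streamlines(
            generate_structural_connectome(cfg, "NC", np.random.default_rng(11))
        )
        fc = generate_functional_connectome(
            sc, 0.4, rng=np.random.default_rng(12), zero_frac=0.5
        )
        iu, ju = np.triu_indices(sc.n_nodes, 1)
        conn = sc.weights[iu, ju] > 0
        zero_rate = (fc.weights[iu, ju][conn] == 0).mean()
        assert zero_rate == pytest.approx(0.5, abs=0.06)

    def test_invalid_rho_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="rho"):
            generate_functional_connectome(
                tiny_cohort.subjects[0].sc, 1.0, rng=np.random.default_rng(0)
            )


class TestCovariatesAndScores:
    def test_zero_loadings_zero_noise_hit_group_means_exactly(self):
        d = GeneratorConfig().to_dict()
        for s in d["score_model"].values():
            s["b_feeder"] = 0.0
            s["b_coupling"] = 0.0
            s["sds"] = {g: 0.0 for g in s["sds"]}
        cfg = GeneratorConfig.from_dict(d)
        _, _, _, scores = generate_covariates_and_scores(
            cfg, "NC", {"feeder_density": 0.01, "coupling": 0.3},
            np.random.default_rng(0),
        )
        assert scores["MMSE"] == 29.24
        assert scores["CDR"] == 0.03

    def test_degenerate_variance_still_returns_finite_scores(self):
        d = GeneratorConfig().to_dict()
        for s in d["score_model"].values():
            s["b_feeder"] = 0.0
            s["b_coupling"] = 0.0
            s["sds"] = {g: 0.0 for g in s["sds"]}
        cfg = GeneratorConfig.from_dict(d)
        for g in ("NC", "MCI", "AD"):
            _, _, _, scores = generate_covariates_and_scores(
                cfg, g, {"feeder_density": 0.01, "coupling": float("nan")},
                np.random.default_rng(1),
            )
            assert all(np.isfinite(v) for v in scores.values())

    def test_group_means_recovered_in_expectation(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(2)
        exp_fd = cfg.expected_class_density("MCI")["feeder"]
        exp_cp = cfg.expected_coupling("MCI")
        draws = [
            generate_covariates_and_scores(
                cfg, "MCI", {"feeder_density": exp_fd, "coupling": exp_cp}, rng
            )[3]["MMSE"]
            for _ in range(400)
        ]
        se = cfg.score_model["MMSE"]["sds"]["MCI"] / np.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(27.90, abs=4 * se)


class TestCohort:
    def test_same_seed_identical_cohorts(self, tiny_config):
        a = generate_cohort(tiny_config)
        b = generate_cohort(tiny_config)
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            np.testing.assert_array_equal(sa.sc_counts.counts, sb.sc_counts.counts)
            np.testing.assert_array_equal(sa.fc.weights, sb.fc.weights)
            assert sa.scores == sb.scores and sa.age == sb.age

    def test_different_seed_differs(self, tiny_config, tiny_cohort):
        other = GeneratorConfig.from_dict({**tiny_config.to_dict(), "seed": 43})
        b = generate_cohort(other)
        assert not np.array_equal(
            tiny_cohort.subjects[0].sc_counts.counts, b.subjects[0].sc_counts.counts
        )

    def test_group_sizes_and_invariants(self, tiny_cohort, tiny_config):
        for g, n in tiny_config.group_sizes.items():
            assert len(tiny_cohort.by_group(g)) == n
        ids = [s.subject_id for s in tiny_cohort]
        assert len(set(ids)) == len(ids)

    def test_planted_hubs_recovered_by_consensus_selection(self):
        """Across seeds, top-fraction selection recovers >= 90% of planted hubs."""
        hits = []
        for seed in range(50):
            cfg = GeneratorConfig(
                group_sizes={"NC": 12}, seed=seed
            )
            nets = generate_structural_cohort(cfg)
            degs = np.mean([degree(net.binary) for _, _, net in nets], axis=0)
            import pandas as pd

            md = pd.Series(degs, index=cfg.node_labels())
            hubs = select_hubs(
                md, {"mode": "top_fraction", "fraction": cfg.n_hubs / cfg.n_nodes}
            )
            planted = set(cfg.hub_labels())
            hits.append(len(set(hubs.hub_labels) & planted) / cfg.n_hubs)
        assert np.mean(hits) >= 0.9

    def test_hub_mean_degree_exceeds_nonhub(self, tiny_cohort, tiny_config):
        md = consensus_mean_degree(tiny_cohort)
        planted = tiny_config.hub_labels()
        rest = [lab for lab in md.index if lab not in planted]
        assert md[planted].mean() > md[rest].mean()
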