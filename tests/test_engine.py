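import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from madeconv.data import CellLinePanel, Dataset, make_records
from madeconv.encoding import AllelePseudoSequence
from madeconv.engine import (
    DegenerateDistributionError,
    PanelLookupError,
    RescalingStats,
    Schedule,
    annotate_ma,
    blend_stats,
    blend_weight,
    estimate_score_distribution,
    fit_trimmed_normal,
    motif_from_annotated,
    out_of_fold_scores,
    run_nnalign_ma,
    train_sa_ensemble,
)
from madeconv.metrics import motif_pcc
from madeconv.network import Ensemble, TrainConfig, init_network


class TestBlendWeight:
    def test_midpoint_exact(self):
        assert blend_weight(75, Schedule()) == 0.5

    def test_after_pretraining_close_to_one(self):
        assert blend_weight(20, Schedule()) > 0.99

    def test_converged_to_zero(self):
        # direct evaluation: 1 / (1 + e^7.5)
        assert blend_weight(150, Schedule()) == \
            pytest.approx(1.0 / (1.0 + np.exp(7.5)), abs=1e-12)
        assert blend_weight(150, Schedule()) < 0.001

    @given(st.floats(0, 300), st.floats(0.01, 300))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing(self, x, dx):
        s = Schedule()
        assert blend_weight(x + dx, s) < blend_weight(x, s)

    def test_negative_iteration_rejected(self):
        with pytest.raises(ValueError):
            blend_weight(-1, Schedule())


class TestBlendStats:
    def _stats(self):
        return {"A": RescalingStats("A", p_bar=0.2, sigma=0.02),
                "B": RescalingStats("B", p_bar=0.4, sigma=0.06)}

    def test_w_one_limit(self):
        out = blend_stats(self._stats(), x=0, schedule=Schedule(shift=75,
                                                               scale=1e-9))
        assert out["A"].p_prime == pytest.approx(0.2)
        assert out["A"].sigma_prime == pytest.approx(0.02)

    def test_w_zero_limit(self):
        out = blend_stats(self._stats(), x=150, schedule=Schedule(shift=75,
                                                                  scale=1e-9))
        assert out["A"].p_prime == pytest.approx(0.3)   # uniform average
        assert out["A"].sigma_prime == pytest.approx(0.04)

    def test_halfway_arithmetic(self):
        out = blend_stats({"A": RescalingStats("A", 0.2, 0.02),
                           "B": RescalingStats("B", 0.4, 0.06)},
                          x=75, schedule=Schedule())
        # w = 0.5: p' = 0.5*0.2 + 0.5*0.3 = 0.25
        assert out["A"].p_prime == pytest.approx(0.25)

    @given(st.floats(0, 200))
    @settings(max_examples=40, deadline=None)
    def test_convex_hull_property(self, x):
        out = blend_stats(self._stats(), x=x, schedule=Schedule())
        for s in out.values():
            lo, hi = sorted((s.p_bar, s.p_bar_u))
            assert lo - 1e-12 <= s.p_prime <= hi + 1e-12
            lo, hi = sorted((s.sigma, s.sigma_u))
            assert lo - 1e-12 <= s.sigma_prime <= hi + 1e-12


class TestTrimmedNormal:
    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0.30, 0.05, size=10000)
        mu, sd = fit_trimmed_normal(scores)
        assert mu == pytest.approx(0.30, rel=0.05)
        assert sd == pytest.approx(0.05, rel=0.05)

    def test_robust_to_injected_outliers(self):
        rng = np.random.default_rng(1)
        clean = rng.normal(0.30, 0.05, size=10000)
        mu0, sd0 = fit_trimmed_normal(clean)
        spiked = clean.copy()
        idx = rng.choice(10000, size=100, replace=False)
        spiked[idx] = 0.30 + 10 * 0.05
        mu1, sd1 = fit_trimmed_normal(spiked)
        assert abs(mu1 - mu0) / mu0 < 0.05
        assert abs(sd1 - sd0) / sd0 < 0.05

    def test_constant_scores_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            fit_trimmed_normal(np.full(100, 0.5))

    def test_fixpoint_no_exclusions(self):
        scores = np.array([0.1, 0.2, 0.3, 0.4])
        mu, sd = fit_trimmed_normal(scores)
        assert mu == pytest.approx(scores.mean())
        assert sd == pytest.approx(scores.std())


class TestEstimateScoreDistribution:
    def test_constant_scorer_degenerate(self, enc, tiny_trained_run):
        world, _, run = tiny_trained_run
        ens = run.ensemble
        dead = init_network(ens.layout, 4, (0,))
        for w in (dead.wpt, dead.wat, dead.bh, dead.wo, dead.bo):
            w[...] = 0.0
        flat = Ensemble(members=[dead], layout=ens.layout, enc=ens.enc,
                        pseudo_table=ens.pseudo_table, config=ens.config)
        with pytest.raises(DegenerateDistributionError):
            estimate_score_distribution(flat, world.allele_names[0],
                                        world.proteome, n_random=500, seed=0)

    def test_deterministic(self, tiny_trained_run):
        world, _, run = tiny_trained_run
        a = estimate_score_distribution(run.ensemble, world.allele_names[0],
                                        world.proteome, n_random=1000, seed=3)
        b = estimate_score_distribution(run.ensemble, world.allele_names[0],
                                        world.proteome, n_random=1000, seed=3)
        assert a == b


class TestAnnotateMa:
    def _ma(self, peptides, label="CL-X"):
        df = make_records(peptides, np.ones(len(peptides)), label, "EL", "MA")
        return Dataset(df, (9, 9))

    def test_single_allele_panel(self, tiny_trained_run):
        world, bundle, run = tiny_trained_run
        only = world.allele_names[1]
        panels = {"CL-X": CellLinePanel("CL-X", (only,))}
        ma = self._ma(["AAAAKAAAA", "WWWWKWWWW", "CCCCKCCCC"])
        ann = annotate_ma(run.ensemble, ma, panels, None, iteration=99)
        assert (ann["annotation"] == only).all()

    def test_tie_breaks_lexicographically(self, tiny_trained_run):
        world, _, run = tiny_trained_run
        ens = run.ensemble
        a1 = world.allele_names[0]
        twin_name = "AAA-TWIN"
        twin = AllelePseudoSequence(twin_name, ens.pseudo_table[a1].residues)
        ens2 = Ensemble(members=ens.members, layout=ens.layout, enc=ens.enc,
                        pseudo_table={**ens.pseudo_table, twin_name: twin},
                        config=ens.config)
        panels = {"CL-X": CellLinePanel("CL-X", (a1, twin_name))}
        ma = self._ma(["AAAAKAAAA", "WWWWKWWWW"])
        ann = annotate_ma(ens2, ma, panels, None, iteration=99)
        # identical pseudo-sequences give identical scores -> exact tie
        assert (ann["annotation"] == twin_name).all()

    def test_missing_panel_errors(self, tiny_trained_run):
        world, _, run = tiny_trained_run
        ma = self._ma(["AAAAKAAAA"], label="UNKNOWN-CL")
        with pytest.raises(PanelLookupError):
            annotate_ma(run.ensemble, ma, {}, None, iteration=99)

    def test_trained_two_allele_panel_recovers_source(self, tiny_trained_run):
        """Positives generated from one allele of a two-allele panel are
        annotated back to it >= 95% of the time."""
        world, bundle, run = tiny_trained_run
        ann = run.annotation
        pos = ann[ann["target"] > 0]
        truth = bundle.ma.records.loc[pos.index, "true_allele"]
        two_allele = pos["label"] == "CL-01"
        acc = (pos["annotation"][two_allele] == truth[two_allele]).mean()
        assert acc >= 0.95

    def test_negatives_annotated_within_panel(self, tiny_trained_run):
        world, bundle, run = tiny_trained_run
        ann = run.annotation
        negs = ann[ann["target"] == 0]
        for label, grp in negs.groupby("label"):
            assert set(grp["annotation"]) <= set(world.panels[label].alleles)


class TestRunLoop:
    def test_annotation_conservation(self, tiny_trained_run):
        world, bundle, run = tiny_trained_run
        ann = run.annotation
        assert len(ann) == len(bundle.ma)
        pos = ann[ann["target"] > 0]
        for label, grp in pos.groupby("label"):
            panel = set(world.panels[label].alleles)
            assert set(grp["annotation"]) <= panel
            assert (grp["annotation"] != "").all()
        # every post-burn-in iteration logged annotated counts
        for entry in run.history:
            if entry["annotating"]:
                assert sum(entry["n_annotated"].values()) == len(pos)

    def test_missing_allele_fails_before_training(self, tiny_trained_run):
        world, bundle, _ = tiny_trained_run
        config = TrainConfig(hidden_sizes=(4,), seeds_per_size=1,
                             n_iterations=5, burn_in=2,
                             length_bounds=(9, 9))
        bad_pseudo = {k: v for k, v in world.pseudo_table.items()
                      if k != world.allele_names[0]}
        with pytest.raises((KeyError, ValueError)):
            run_nnalign_ma(bundle.sa, bundle.ma, world.panels, bad_pseudo,
                           world.proteome, config, seed=0)

    def test_ma_only_allele_motif_recovered(self, tiny_trained_run):
        world, bundle, run = tiny_trained_run
        for name in world.allele_names:
            m = motif_from_annotated(run, name)
            assert motif_pcc(m, world.alleles[name].pssm) >= 0.8

    def test_out_of_fold_scores_structure(self, tiny_trained_run):
        world, bundle, run = tiny_trained_run
        df = out_of_fold_scores(run, world.panels, "EL")
        assert df["score"].notna().all()
        assert (df["score"] > 0).all() and (df["score"] < 1).all()
        # MA score equals max over the panel alleles, checked brute force
        arrays = run.arrays
        ma_rows = df[df["origin"] == "MA"].head(10)
        for idx, row in ma_rows.iterrows():
            fold = int(row["partition"])
            members = run.ensemble.fold_members(fold)
            brute = max(
                np.mean([m_ for m_ in
                         [run.ensemble.batch_predict(
                             arrays, np.array([idx]), a, "EL",
                             members=members)[0]]])
                for a in world.panels[row["label"]].alleles)
            assert row["score"] == pytest.approx(brute, abs=1e-12)


class TestVariedLengthWorld:
    def test_end_to_end_with_indel_cores(self):
        """Full pipeline on an 8-11mer world: insertion/deletion cores are
        exercised in training, annotation and evaluation."""
        from madeconv.simulate import (build_training_bundle, make_world,
                                       varied_length_spec)

        spec = varied_length_spec()
        world = make_world(spec, 17)
        bundle = build_training_bundle(world, 17)
        config = TrainConfig(hidden_sizes=(10,), seeds_per_size=1,
                             n_partitions=5, n_iterations=30, burn_in=10,
                             early_stopping=False,
                             length_bounds=spec.length_bounds,
                             n_rescale_peptides=1000, rescale_shift=50.0)
        run = run_nnalign_ma(bundle.sa, bundle.ma, world.panels,
                             world.pseudo_table, world.proteome, config,
                             seed=17)
        pos = run.annotation[run.annotation["target"] > 0]
        assert sorted(pos["peptide"].str.len().unique()) == [8, 9, 10, 11]
        truth = bundle.ma.records.loc[pos.index, "true_allele"]
        assert (pos["annotation"] == truth).mean() >= 0.7
        df = out_of_fold_scores(run, world.panels, "EL")
        assert df["score"].notna().all()


class TestDegenerateLoop:
    def test_sa_only_trajectory_bit_identical(self):
        from madeconv.simulate import (FixtureSpec, build_training_bundle,
                                       make_world)
        from dataclasses import replace

        spec = FixtureSpec(n_alleles=3, panel_layout=((0, 1), (0, 2)),
                           ma_only=(0,), low_abundance=(),
                           n_ma_per_panel=40, n_sa_el=50, n_sa_ba=20,
                           n_background_sa=2, n_sa_el_background=40,
                           max_motif_pcc=0.3)
        world = make_world(spec, 31)
        bundle = build_training_bundle(world, 31)
        config = TrainConfig(hidden_sizes=(5,), seeds_per_size=2,
                             n_partitions=5, n_iterations=8, burn_in=3,
                             early_stopping=True, length_bounds=(9, 9))
        loop = run_nnalign_ma(bundle.sa, None, {}, world.pseudo_table,
                              world.proteome, config, seed=13)
        plain = train_sa_ensemble(bundle.sa, world.pseudo_table, config,
                                  seed=13)
        assert len(loop.ensemble.members) == len(plain.ensemble.members) == 50 // 5
        for a, b in zip(loop.ensemble.members, plain.ensemble.members):
            assert a.seed_key == b.seed_key
            for wa, wb in zip(a.copy_weights(), b.copy_weights()):
                assert np.array_equal(wa, wb)
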