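"""Fold splitting, the CV-score formula, relative scores and the protocol."""

import math

import numpy as np
import pytest

from phylocv.alignment import Alignment
from phylocv.crossval import (
    CVReport,
    cv_score,
    cv_score_from_site_log_likelihoods,
    per_site_ratio,
    relative_scores,
    run_protocol,
    split_fold,
    split_kfold,
)
from phylocv.crossval import testing_set_size as held_out_size
from phylocv.mcmc import ModelSpec, run_chain
from phylocv.report import read_cv_report, write_cv_report
from phylocv.simulate import sample_random_model, simulate_alignment
from phylocv.tree import random_tree


def constant_alignment(n_sites, n_taxa=2):
    seqs = np.full((n_taxa, n_sites), "A", dtype="U1")
    return Alignment([f"t{i}" for i in range(n_taxa)], seqs)


class TestSplitFold:
    def test_counts_and_disjointness(self):
        aln = constant_alignment(100)
        fold = split_fold(aln, seed=3)
        assert fold.testing.n_sites == 20
        assert fold.learning.n_sites == 80
        assert not set(fold.testing.site_ids) & set(fold.learning.site_ids)
        union = set(fold.testing.site_ids) | set(fold.learning.site_ids)
        assert union == set(range(100))

    def test_same_seed_same_split(self):
        aln = constant_alignment(50)
        f1 = split_fold(aln, seed=11)
        f2 = split_fold(aln, seed=11)
        assert (f1.testing.site_ids == f2.testing.site_ids).all()
        assert f1.split_id == f2.split_id

    def test_remainder_convention_on_arthropod_sized_alignment(self):
        # 41976 sites: testing round-half-even(41976/5 = 8395.2) = 8395
        assert held_out_size(41976) == 8395
        aln = constant_alignment(41976)
        fold = split_fold(aln, seed=1)
        assert fold.testing.n_sites == 8395
        assert fold.learning.n_sites == 33581

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            split_fold(constant_alignment(4))

    def test_kfold_partition_is_disjoint_cover(self):
        aln = constant_alignment(103)
        folds = split_kfold(aln, seed=5)
        all_test = np.concatenate([f.testing.site_ids for f in folds])
        assert len(all_test) == 103
        assert len(set(all_test.tolist())) == 103


class TestCVScoreFormula:
    def test_single_draw_single_site_collapse(self):
        assert cv_score_from_site_log_likelihoods([[-2.0]]) == pytest.approx(-2.0)

    def test_identical_draws_average_is_noop(self):
        logl = np.array([-1.3, -0.7, -2.2])
        table = np.tile(logl, (5, 1))
        assert cv_score_from_site_log_likelihoods(table) == pytest.approx(
            logl.sum(), abs=1e-12)

    def test_tabulated_three_sites_four_draws_oracle(self):
        rng = np.random.default_rng(99)
        probs = rng.uniform(0.01, 0.9, size=(4, 3))
        expected = sum(math.log(probs[:, n].mean()) for n in range(3))
        got = cv_score_from_site_log_likelihoods(np.log(probs))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_permutations(self):
        rng = np.random.default_rng(7)
        table = rng.normal(-3, 1, size=(6, 10))
        base = cv_score_from_site_log_likelihoods(table)
        assert cv_score_from_site_log_likelihoods(table[::-1]) == pytest.approx(base)
        assert cv_score_from_site_log_likelihoods(table[:, ::-1]) == pytest.approx(base)

    def test_duplicated_draw_changes_score_through_average_only(self):
        rng = np.random.default_rng(8)
        table = rng.normal(-3, 1, size=(4, 6))
        extended = np.vstack([table, table[-1:]])
        got = cv_score_from_site_log_likelihoods(extended)
        probs = np.exp(table)
        expected = sum(
            math.log((probs[:, n].sum() + probs[-1, n]) / 5.0) for n in range(6)
        )
        assert got == pytest.approx(expected, abs=1e-12)


def test_cv_score_integration_with_identical_snapshots(rng):
    # all K snapshots identical => score equals the plain sitewise sum
    from phylocv.likelihood import sitewise_log_likelihoods

    tree = random_tree(["a", "b", "c", "d"], rng)
    model = sample_random_model("single", seed=61, gamma=False)
    aln, _ = simulate_alignment(tree, model, 50, seed=62)
    spec = ModelSpec(kind="single", gamma=False)
    samples = run_chain(aln, tree, spec, cycles=12, burnin=10, seed=5)
    samples.samples = [samples.samples[-1]] * 4
    score = cv_score(aln, samples, tree)
    st = samples.samples[-1]
    direct = sitewise_log_likelihoods(
        aln, tree.with_branch_lengths(st.branch_lengths), st.mixture_model(spec)
    ).total
    assert score == pytest.approx(direct, abs=1e-10)


class TestRelativeScores:
    def test_reference_vs_itself_is_zero(self):
        out = relative_scores({"ref": np.array([1.0, 2.0, 3.0])}, "ref")
        assert out["ref"]["delta_mean"] == 0.0
        assert out["ref"]["delta_sd"] == 0.0

    def test_constant_offset(self):
        ref = np.array([-10.0, -12.0, -9.0, -11.0, -10.5])
        out = relative_scores({"ref": ref, "m": ref + 3.0}, "ref")
        assert out["m"]["delta_mean"] == pytest.approx(3.0)
        assert out["m"]["delta_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_spreadsheet_style_mean_sd(self):
        rng = np.random.default_rng(12)
        ref = rng.normal(-100, 5, 5)
        m = rng.normal(-95, 5, 5)
        out = relative_scores({"ref": ref, "m": m}, "ref")
        d = m - ref
        assert out["m"]["delta_mean"] == pytest.approx(d.mean())
        assert out["m"]["delta_sd"] == pytest.approx(d.std(ddof=1))

    def test_different_splits_rejected(self):
        scores = {"ref": np.zeros(2), "m": np.ones(2)}
        ids = {"ref": ["aa", "bb"], "m": ["aa", "cc"]}
        with pytest.raises(ValueError, match="different splits"):
            relative_scores(scores, "ref", split_ids=ids)


class TestPerSiteRatio:
    def test_printed_worked_example(self):
        per_site, ratio = per_site_ratio(18941, 41976)
        assert round(per_site, 3) == 0.451
        assert round(ratio, 2) == 1.57

    def test_zero_delta(self):
        assert per_site_ratio(0.0, 1234) == (0.0, 1.0)

    def test_sign_symmetry(self):
        per_site, ratio = per_site_ratio(-500, 500)
        assert per_site == pytest.approx(-1.0)
        assert ratio == pytest.approx(math.exp(-1.0))


@pytest.fixture(scope="module")
def tiny_data():
    rng = np.random.default_rng(77)
    tree = random_tree([f"t{i}" for i in range(6)], rng)
    model = sample_random_model("single", seed=78, gamma=False,
                                free_exchangeabilities=False)
    aln, _ = simulate_alignment(tree, model, 200, seed=79)
    return aln, tree


class TestRunProtocol:
    def test_single_model_all_deltas_zero(self, tiny_data):
        aln, tree = tiny_data
        spec = ModelSpec(kind="single", gamma=False, free_exchangeabilities=False)
        report = run_protocol(aln, tree, [spec], replicates=2, cycles=30,
                              burnin=10, seed=5)
        deltas = report.deltas()[spec.label]
        assert (deltas == 0).all()

    def test_two_models_two_replicates_plumbing(self, tiny_data, tmp_path):
        aln, tree = tiny_data
        specs = [ModelSpec(kind="single", gamma=False, free_exchangeabilities=False),
                 ModelSpec(kind="single", gamma=False, free_exchangeabilities=True)]
        report = run_protocol(aln, tree, specs, replicates=2, cycles=40,
                              burnin=15, seed=6, checkpoint_dir=tmp_path)
        assert sorted(report.models) == sorted(s.label for s in specs)
        for scores in report.scores.values():
            assert scores.shape == (2,)
            assert np.isfinite(scores).all()
        assert len(report.split_ids) == 2
        # checkpointed re-run returns identical scores without re-fitting
        again = run_protocol(aln, tree, specs, replicates=2, cycles=40,
                             burnin=15, seed=6, checkpoint_dir=tmp_path)
        for m in report.models:
            assert np.allclose(report.scores[m], again.scores[m])

    def test_splits_shared_across_models(self, tiny_data):
        # the paired design: one split per replicate for every model
        aln, tree = tiny_data
        f1 = split_fold(aln, seed=123)
        f2 = split_fold(aln, seed=123)
        assert (f1.testing.site_ids == f2.testing.site_ids).all()


class TestReportIO:
    def make_report(self):
        return CVReport(scores={"GTR+G": np.array([-10.1, -11.2, -9.9, -10.4, -10.0]),
                                "CATf=3-GTR+G": np.array([-9.0, -10.1, -9.2, -9.3, -9.1])},
                        reference="GTR+G", split_ids=["a1", "b2", "c3", "d4", "e5"])

    def test_row_counts(self, tmp_path):
        report = self.make_report()
        path = tmp_path / "report.tsv"
        write_cv_report(report, path)
        lines = [ln for ln in path.read_text().splitlines()
                 if ln and not ln.startswith("#")]
        assert len(lines) == 1 + 10 + 2  # header, details, summaries

    def test_round_trip_to_12_significant_digits(self, tmp_path):
        report = self.make_report()
        report.scores["GTR+G"] += np.pi * 1e-7  # exercise full precision
        path = tmp_path / "report.tsv"
        write_cv_report(report, path)
        back = read_cv_report(path)
        assert back.reference == "GTR+G"
        for m in report.models:
            a, b = report.scores[m], back.scores[m]
            assert np.abs((a - b) / a).max() < 1e-12

    def test_empty_report_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_cv_report(CVReport(scores={}, reference=""), path)
        lines = [ln for ln in path.read_text().splitlines()
                 if ln and not ln.startswith("#")]
        assert len(lines) == 1
        back = read_cv_report(path)
        assert back.models == []
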