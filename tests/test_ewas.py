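"""EWAS pipeline: I/O, site-wise fitting, FDR adjustment, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from rcgmeth import (MethylationDataset, adjust_fdr, build_design,
                     read_dataset, run_sitewise, sample_covariates,
                     sample_rcg_beta)
from rcgmeth.cli import main as cli_main


class TestReadDataset:
    def test_toy_fixture_shape(self, toy_dataset_files):
        beta_path, covar_path, betas, cov = toy_dataset_files
        ds = read_dataset(beta_path, covar_path)
        assert ds.n_sites == 3 and len(ds.samples) == 60
        np.testing.assert_allclose(ds.betas, betas.to_numpy())

    def test_intensity_matrices_with_offset(self, tmp_path):
        samples = [f"s{i}" for i in range(8)]
        m = pd.DataFrame(100.0, index=["cg1"], columns=samples)
        u = pd.DataFrame(100.0, index=["cg1"], columns=samples)
        cov = pd.DataFrame({"gender": np.arange(8) % 2}, index=samples)
        mp, up, cp = tmp_path / "m.tsv", tmp_path / "u.tsv", tmp_path / "c.tsv"
        m.to_csv(mp, sep="\t"); u.to_csv(up, sep="\t"); cov.to_csv(cp, sep="\t")
        ds = read_dataset(None, cp, m_path=mp, u_path=up, offset=100.0)
        np.testing.assert_allclose(ds.betas, 1.0 / 3.0)

    def test_missing_sample_dropped_with_warning(self, toy_dataset_files, caplog):
        beta_path, covar_path, _, cov = toy_dataset_files
        cov2 = cov.iloc[:-1]
        p = covar_path.parent / "c2.tsv"
        cov2.to_csv(p, sep="\t")
        with caplog.at_level("WARNING", logger="rcgmeth"):
            ds = read_dataset(beta_path, p)
        assert len(ds.samples) == 59
        assert any("unmatched" in r.message for r in caplog.records)

    def test_too_many_unmatched_fails(self, toy_dataset_files):
        beta_path, covar_path, _, cov = toy_dataset_files
        p = covar_path.parent / "c3.tsv"
        cov.iloc[:20].to_csv(p, sep="\t")
        with pytest.raises(ValueError, match="unmatched"):
            read_dataset(beta_path, p)

    def test_non_numeric_cell_reported(self, toy_dataset_files, tmp_path):
        beta_path, covar_path, betas, _ = toy_dataset_files
        txt = beta_path.read_text().replace(
            f"{betas.iloc[1, 2]}", "oops", 1)
        p = tmp_path / "bad.tsv"
        p.write_text(txt)
        with pytest.raises(ValueError, match="non-numeric"):
            read_dataset(p, covar_path)

    def test_excess_missingness_rejected(self):
        samples = [f"s{i}" for i in range(10)]
        betas = np.full((1, 10), 0.5)
        betas[0, :2] = np.nan  # 20% missing at the site
        cov = pd.DataFrame({"x": np.arange(10.0)}, index=samples)
        with pytest.raises(ValueError, match="missing"):
            MethylationDataset(["cg1"], samples, betas, cov)


class TestAdjustFdr:
    def test_bh_hand_computed(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03], "BH"),
                                   [0.03, 0.03, 0.03])

    def test_by_harmonic_factor(self):
        c = 1.0 + 0.5 + 1.0 / 3.0
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03], "BY"),
                                   np.minimum(np.array([0.03, 0.03, 0.03]) * c, 1.0))

    def test_single_p_unchanged_under_bh(self):
        np.testing.assert_allclose(adjust_fdr([0.2], "BH"), [0.2])

    def test_empty_input(self):
        assert adjust_fdr([], "BH").size == 0

    @pytest.mark.parametrize("method", ["BH", "BY"])
    def test_matches_reference_implementation(self, method):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(33)
        sm_name = {"BH": "fdr_bh", "BY": "fdr_by"}[method]
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 50))
            ours = adjust_fdr(p, method)
            ref = multipletests(p, method=sm_name)[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])


@pytest.fixture(scope="module")
def sim_dataset():
    rng = np.random.default_rng(34)
    n = 200
    cov = sample_covariates(n, seed=35)
    cov.index = [f"s{i}" for i in range(n)]
    X, _ = build_design(cov)
    n_sites, n_true = 40, 8
    gammas = np.zeros(n_sites)
    gammas[:n_true] = 0.3
    betas = np.vstack([
        sample_rcg_beta(n, 5.84, 0.93,
                        np.exp(X @ np.array([-1.0, g, 0, 0, 0, 0])), rng)
        for g in gammas])
    sites = [f"cg{i:03d}" for i in range(n_sites)]
    return MethylationDataset(sites, list(cov.index), betas, cov), n_true


class TestRunSitewise:
    def test_true_sites_enriched_in_small_pvalues(self, sim_dataset):
        ds, n_true = sim_dataset
        out = run_sitewise(ds, model="rcg", test="gender")
        ranks = out["p"].rank()
        true_ranks = ranks.iloc[:n_true]
        null_ranks = ranks.iloc[n_true:]
        from scipy.stats import mannwhitneyu
        assert mannwhitneyu(true_ranks, null_ranks,
                            alternative="less").pvalue < 1e-4

    def test_single_site_equals_direct_fit(self, sim_dataset):
        from rcgmeth import fit_rcg, wald_test
        ds, _ = sim_dataset
        one = MethylationDataset(ds.sites[:1], ds.samples, ds.betas[:1],
                                 ds.covariates)
        out = run_sitewise(one, model="rcg", test="gender")
        X, names = build_design(ds.covariates)
        t = wald_test(fit_rcg(ds.betas[0], X, coef_names=names),
                      names.index("gender"))
        assert out["p"].iloc[0] == pytest.approx(t.p, rel=1e-9)
        assert out["q_bh"].iloc[0] == pytest.approx(t.p, rel=1e-9)

    def test_site_order_invariance(self, sim_dataset):
        ds, _ = sim_dataset
        perm = np.random.default_rng(36).permutation(ds.n_sites)
        shuffled = MethylationDataset([ds.sites[i] for i in perm], ds.samples,
                                      ds.betas[perm], ds.covariates)
        out1 = run_sitewise(ds, model="mvalue", test="gender").set_index("site")
        out2 = run_sitewise(shuffled, model="mvalue", test="gender").set_index("site")
        pd.testing.assert_frame_equal(out1.sort_index(), out2.sort_index())

    def test_permuted_covariate_null_uniform(self):
        rng = np.random.default_rng(37)
        n = 150
        cov = sample_covariates(n, seed=38)
        cov.index = [f"s{i}" for i in range(n)]
        X, _ = build_design(cov)
        betas = np.vstack([
            sample_rcg_beta(n, 5.0, 0.5, np.exp(X @ np.array([-1.0, 0, 0, 0, 0, 0])), rng)
            for _ in range(300)])
        ds = MethylationDataset([f"cg{i}" for i in range(300)],
                                list(cov.index), betas, cov)
        out = run_sitewise(ds, model="mvalue", test="gender")
        from scipy.stats import kstest
        assert kstest(out["p"], "uniform").pvalue > 0.01


class TestCli:
    def test_ewas_command_and_determinism(self, toy_dataset_files):
        beta_path, covar_path, _, _ = toy_dataset_files
        runner = CliRunner()
        args = ["ewas", "--model", "mvalue", "--betas", str(beta_path),
                "--covars", str(covar_path), "--test", "gender"]
        r1 = runner.invoke(cli_main, args)
        r2 = runner.invoke(cli_main, args)
        assert r1.exit_code == 0
        assert r1.output == r2.output
        assert r1.output.splitlines()[0].startswith("site\tcoef")
        assert len(r1.output.strip().splitlines()) == 4

    def test_simulate_command_writes_rejection_column(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim.csv"
        r = runner.invoke(cli_main, [
            "simulate", "--design", "part1_null", "--rho", "0.5",
            "--replicates", "4", "--n", "250", "--seed", "1",
            "--out", str(out)])
        assert r.exit_code == 0
        df = pd.read_csv(out)
        assert "rejection_rate" in df.columns and len(df) == 1

    def test_fit_command(self, toy_dataset_files):
        beta_path, covar_path, _, _ = toy_dataset_files
        runner = CliRunner()
        r = runner.invoke(cli_main, ["fit", "--betas", str(beta_path),
                                     "--covars", str(covar_path),
                                     "--model", "rcg", "--site", "cg03"])
        assert r.exit_code == 0
        assert "alpha" in r.output and "gender" in r.output

    def test_usage_error_nonzero_exit(self):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["ewas", "--betas", "/nonexistent"])
        assert r.exit_code != 0
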