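import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from phenocopy.core_io import AnalysisConfig
from phenocopy.diffexp import (
    ContrastSpec,
    adjust_fdr,
    contrast_from_groups,
    estimate_variance_prior,
    fit_contrast,
    volcano_classify,
)
from phenocopy.simdata import SimConfig, generate_study


def bh_step_up_oracle(p):
    """Independent step-up implementation: rank-wise minimum from the top."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestPooledT:
    def test_textbook_two_sample_example(self):
        table = contrast_from_groups(
            np.array([[0.0, 1.0]]), np.array([[2.0, 3.0]]), ["g"], moderation=False
        )
        row = table.iloc[0]
        assert row["lr"] == pytest.approx(-2.0)
        assert abs(row["t"]) == pytest.approx(2.828, abs=1e-3)
        assert row["p_raw"] == pytest.approx(0.1056, abs=1e-3)

    def test_identical_groups_yield_null_call(self):
        x = np.array([[1.0, 2.0, 3.0]])
        table = contrast_from_groups(x, x.copy(), ["g"], moderation=False)
        assert table.iloc[0]["lr"] == 0.0
        assert table.iloc[0]["call"] == "none"

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            contrast_from_groups(np.array([[1.0]]), np.array([[1.0, 2.0]]), ["g"])

    def test_all_zero_variance_without_moderation_advises(self):
        a = np.ones((3, 2))
        b = np.zeros((3, 2))
        with pytest.raises(ValueError, match="moderation"):
            contrast_from_groups(a, b, ["g1", "g2", "g3"], moderation=False)

    def test_zero_variance_with_moderation_is_decisive(self):
        a = np.tile([[2.0], [0.0]], (1, 3))
        b = np.zeros((2, 3))
        table = contrast_from_groups(a, b, ["hit", "flat"], moderation=True, lr_min=1.0)
        assert table.loc["hit", "p_raw"] == 0.0 and table.loc["hit", "call"] == "up"
        assert table.loc["flat", "p_raw"] == 1.0 and table.loc["flat", "call"] == "none"


class TestModeration:
    def test_equal_variances_drive_prior_df_to_infinity(self):
        rng = np.random.default_rng(0)
        # all genes share one true variance and identical sample variance
        s_sq = np.full(200, 0.25)
        prior = estimate_variance_prior(s_sq, df=4)
        assert np.isinf(prior.d0)
        # with infinite prior df every gene is tested against the common scale
        a = rng.normal(size=(200, 3))
        b = rng.normal(size=(200, 3))
        table = contrast_from_groups(a, b, [f"g{i}" for i in range(200)], moderation=True)
        assert np.all(np.isfinite(table["t"]))

    def test_moderated_matches_unmoderated_at_large_n(self):
        # heteroscedastic genes: the prior stays weak (small d0), and with 50
        # samples per group the data term dominates the posterior variance
        rng = np.random.default_rng(1)
        sd = rng.lognormal(mean=-1.0, sigma=0.8, size=(300, 1))
        a = rng.normal(0, 1, size=(300, 50)) * sd
        b = rng.normal(0, 1, size=(300, 50)) * sd
        genes = [f"g{i}" for i in range(300)]
        mod = contrast_from_groups(a, b, genes, moderation=True)
        raw = contrast_from_groups(a, b, genes, moderation=False)
        rel = np.abs(mod["t"] - raw["t"]) / np.maximum(np.abs(raw["t"]), 1e-3)
        assert np.median(rel) < 0.01

    def test_agrees_with_bioconductor_limma(self, tmp_path):
        """Dual-route check: moderated t / p and the variance prior must match
        the reference empirical-Bayes implementation (limma::eBayes)."""
        rng = np.random.default_rng(42)
        n_genes, n = 300, 3
        sd = rng.gamma(40, 0.3 / 40, n_genes)
        mu = rng.uniform(5, 10, n_genes)
        eff = np.where(rng.random(n_genes) < 0.1, rng.normal(0, 1.5, n_genes), 0.0)
        a = mu[:, None] + eff[:, None] + rng.normal(size=(n_genes, n)) * sd[:, None]
        b = mu[:, None] + rng.normal(size=(n_genes, n)) * sd[:, None]
        genes = [f"g{i}" for i in range(n_genes)]
        table = contrast_from_groups(a, b, genes, moderation=True)

        mat = pd.DataFrame(np.hstack([a, b]), index=genes)
        mat.to_csv(tmp_path / "mat.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            mat <- as.matrix(read.delim("mat.tsv", row.names=1))
            design <- cbind(Intercept=1, groupA=c(rep(1,3), rep(0,3)))
            fit <- eBayes(lmFit(mat, design))
            out <- data.frame(t=fit$t[,"groupA"], p=fit$p.value[,"groupA"])
            write.table(out, "r.tsv", sep="\\t", quote=FALSE)
            """
        )
        (tmp_path / "check.R").write_text(script)
        subprocess.run(
            ["Rscript", "check.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "r.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(table["t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(table["p_raw"], ref["p"], rtol=1e-6)


class TestBH:
    def test_worked_example(self):
        out = adjust_fdr(np.array([0.005, 0.01, 0.03, 0.04]))
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_constant_vector_unchanged(self):
        out = adjust_fdr(np.full(5, 0.2))
        assert np.allclose(out, 0.2)

    def test_single_p_unchanged(self):
        assert adjust_fdr(np.array([0.7]))[0] == pytest.approx(0.7)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            assert np.allclose(adjust_fdr(p), bh_step_up_oracle(p), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=500)
        assert np.all(adjust_fdr(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr(np.array([0.5, 1.2]))


@pytest.mark.parametrize(
    "p_adj,lr,expected",
    [
        (0.005, 1.2, "up"),
        (0.005, 0.9, "none"),
        (0.02, 2.0, "none"),
        (0.005, -1.2, "down"),
        (0.005, -0.9, "none"),
    ],
)
def test_volcano_call_rule(p_adj, lr, expected):
    table = pd.DataFrame({"lr": [lr], "p_adj": [p_adj]}, index=["g"])
    assert volcano_classify(table, alpha=0.01, lr_min=1.0).iloc[0] == expected


def test_fit_contrast_selectors_and_overlap_guard(tiny_study):
    spec = ContrastSpec("stim", {"stimulated": True}, {"stimulated": False})
    table = fit_contrast(tiny_study, spec, moderation=True, alpha=0.01, lr_min=0.0)
    assert table.loc["G1", "lr"] == pytest.approx(2.0, abs=0.2)
    assert table.loc["G2", "lr"] == pytest.approx(-1.5, abs=0.2)
    bad = ContrastSpec("overlap", {"stimulated": True}, {"vehicle": "dmso"})
    with pytest.raises(ValueError, match="overlap"):
        fit_contrast(tiny_study, bad)


def test_global_null_false_positive_control():
    """All-null simulation: BH keeps the realized false-positive fraction at
    p_adj < 0.05 within binomial slack of the nominal level."""
    sim = SimConfig(
        n_genes=2000,
        seed=55,
        class_proportions={"null": 1.0},
        times_h=(2.0,),
    )
    study, _ = generate_study(sim)
    config = AnalysisConfig(seed=1)
    from phenocopy.signatures import stimulation_contrast

    table = stimulation_contrast(study, 2.0, config)
    frac = float((table["p_adj"] < 0.05).mean())
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 2000)
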