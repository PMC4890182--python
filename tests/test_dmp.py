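import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from dmpipe import (
    ModerationPrior,
    bh_fdr,
    call_dmps,
    cellline_delta_dmps,
    group_dmp_table,
    heterogeneity_summary,
    moderated_paired_test,
    paired_differences,
)

from conftest import make_dataset


def _hetero_diffs(seed=7, n_probes=300, n_pairs=8):
    """Null paired differences with probe-to-probe variance spread."""
    rng = np.random.default_rng(seed)
    sd = np.exp(rng.normal(-3, 0.6, n_probes))
    x = rng.normal(0, sd[:, None], (n_probes, n_pairs))
    return pd.DataFrame(x, index=[f"cg{i:05d}" for i in range(n_probes)])


class TestPairedDifferences:
    def test_equal_sites_give_zero(self):
        beta = np.tile(np.linspace(0.1, 0.9, 5)[:, None], (1, 8))
        ds = make_dataset(beta)
        diffs = paired_differences(ds, "MUT")
        assert (diffs.to_numpy() == 0).all()

    def test_constant_shift(self):
        beta = np.full((4, 6), 0.4)
        beta[:, ::2] += 0.05  # fimbrial columns
        ds = make_dataset(beta)
        diffs = paired_differences(ds, "MUT")
        np.testing.assert_allclose(diffs.to_numpy(), 0.05)

    def test_matches_direct_subtraction(self, small_sim):
        _, dataset, _, _ = small_sim
        diffs = paired_differences(dataset, "MUT")
        for subject in diffs.columns[:3]:
            fimb = dataset.beta[dataset.sample_id_for(subject, "fimbrial")]
            prox = dataset.beta[dataset.sample_id_for(subject, "proximal")]
            np.testing.assert_array_equal(diffs[subject].to_numpy(), (fimb - prox).to_numpy())

    def test_fewer_than_three_pairs_rejected(self):
        ds = make_dataset(np.full((3, 4), 0.5))
        with pytest.raises(ValueError, match="complete pairs"):
            paired_differences(ds, "MUT")


class TestModeratedTest:
    def test_vanishing_prior_recovers_ordinary_t(self):
        diffs = _hetero_diffs()
        t_mod, _, _ = moderated_paired_test(
            diffs, prior=ModerationPrior(d0=1e-12, s0_sq=1.0)
        )
        x = diffs.to_numpy()
        n = x.shape[1]
        t_ref = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(n))
        np.testing.assert_allclose(t_mod.to_numpy(), t_ref, rtol=1e-8)

    def test_equal_variances_leave_nothing_to_shrink(self):
        # every probe is a shifted copy of the same base vector, so all
        # sample variances equal sigma^2; with the prior centred on that
        # shared value the posterior variance is sigma^2 for every probe
        # and the moderated t coincides with the ordinary paired t at any
        # prior strength
        base = np.array([0.01, -0.02, 0.005, 0.03, -0.015, 0.0, 0.02, -0.01])
        shifts = np.linspace(-0.05, 0.05, 40)
        diffs = pd.DataFrame(base[None, :] + shifts[:, None])
        x = diffs.to_numpy()
        sigma_sq = float(np.var(x[0], ddof=1))
        t_ref = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(x.shape[1]))
        for d0 in (0.5, 4.0, 50.0):
            t_mod, _, _ = moderated_paired_test(
                diffs, prior=ModerationPrior(d0=d0, s0_sq=sigma_sq)
            )
            np.testing.assert_allclose(t_mod.to_numpy(), t_ref, rtol=1e-10)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(42)
        diffs = pd.DataFrame(rng.normal(0, 0.05, (2000, 10)))
        _, p, _ = moderated_paired_test(diffs)
        stat = stats.kstest(p.to_numpy(), "uniform")
        assert stat.pvalue > 0.01

    def test_matches_independent_closed_form_reimplementation(self):
        """Per-probe loop re-deriving the shrinkage from scratch."""
        diffs = _hetero_diffs(seed=9)
        t_mod, p_mod, prior = moderated_paired_test(diffs)
        x = diffs.to_numpy()
        n = x.shape[1]
        df = n - 1
        # prior from scratch: moment-match log variances
        s2 = [float(np.var(row, ddof=1)) for row in x]
        e = [math.log(v) - special.digamma(df / 2) + math.log(df / 2) for v in s2]
        emean = sum(e) / len(e)
        evar = sum((ei - emean) ** 2 for ei in e) / (len(e) - 1)
        target = evar - float(special.polygamma(1, df / 2))
        assert target > 0  # heterogeneous fixture keeps d0 finite
        y = 0.5 + 1.0 / target
        for _ in range(100):
            tri = float(special.polygamma(1, y))
            y += tri * (1 - tri / target) / float(special.polygamma(2, y))
        d0 = 2 * y
        s0_sq = math.exp(emean + special.digamma(d0 / 2) - math.log(d0 / 2))
        assert prior.d0 == pytest.approx(d0, rel=1e-8)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=1e-8)
        for g in range(x.shape[0]):
            s2_post = (d0 * s0_sq + df * s2[g]) / (d0 + df)
            t_ref = float(np.mean(x[g])) / math.sqrt(s2_post / n)
            p_ref = 2 * stats.t.sf(abs(t_ref), d0 + df)
            assert t_mod.iloc[g] == pytest.approx(t_ref, abs=1e-10 * max(1, abs(t_ref)))
            assert p_mod.iloc[g] == pytest.approx(p_ref, abs=1e-10)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_reference(self, tmp_path):
        """Cross-check against the Bioconductor reference implementation."""
        diffs = _hetero_diffs(seed=5, n_probes=200)
        diffs.to_csv(tmp_path / "diffs.tsv", sep="\t", float_format="%.17g")
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            'x <- as.matrix(read.delim("diffs.tsv", row.names=1))\n'
            'fit <- eBayes(lmFit(x, design=matrix(1, ncol(x), 1)))\n'
            'write.table(data.frame(t=fit$t, p=fit$p.value), "ref.tsv",'
            ' sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", "check.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
        t_mod, p_mod, _ = moderated_paired_test(diffs)
        np.testing.assert_allclose(t_mod.to_numpy(), ref.iloc[:, 0].to_numpy(), atol=1e-10)
        np.testing.assert_allclose(p_mod.to_numpy(), ref.iloc[:, 1].to_numpy(), atol=1e-10)

    def test_constant_matrix_is_degenerate(self):
        diffs = pd.DataFrame(np.full((10, 5), 0.2))
        with pytest.raises(ValueError, match="degenerate variance"):
            moderated_paired_test(diffs)


class TestBHFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_identity(self):
        assert bh_fdr(np.array([0.5]))[0] == pytest.approx(0.5)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr(np.ones(7)), np.ones(7))

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, np.nan]))


def _tables_from_q(q_mut, q_ctrl, median_mut):
    idx = [f"cg{i:05d}" for i in range(len(q_mut))]
    base = dict(n_pairs=5, mean_diff=0.0, s2=0.01, t=0.0, p=0.01)
    mut = pd.DataFrame({**base, "q": q_mut, "median_delta": median_mut}, index=idx)
    ctrl = pd.DataFrame({**base, "q": q_ctrl, "median_delta": 0.0}, index=idx)
    return mut, ctrl


class TestCallDMPs:
    def test_shared_significance_cancels(self):
        mut, ctrl = _tables_from_q([0.001] * 4, [0.001] * 4, [0.1] * 4)
        out = call_dmps(mut, ctrl)
        assert not out["mut_not_ctrl"].any()
        assert not out["dmp"].any()

    def test_definition_of_a_retained_hyper_dmp(self):
        mut, ctrl = _tables_from_q([0.01], [0.60], [0.05])
        out = call_dmps(mut, ctrl)
        assert out["dmp"].all()
        assert out["direction"].iloc[0] == "hyper"

    def test_median_threshold_is_strict(self):
        mut, ctrl = _tables_from_q([0.01, 0.01], [0.6, 0.6], [0.03, 0.0300001])
        out = call_dmps(mut, ctrl, delta_threshold=0.03)
        assert list(out["dmp"]) == [False, True]

    def test_probe_universe_mismatch_rejected(self):
        mut, ctrl = _tables_from_q([0.01, 0.01], [0.6, 0.6], [0.05, 0.05])
        with pytest.raises(ValueError, match="symmetric difference"):
            call_dmps(mut, ctrl.iloc[:1])

    def test_raising_delta_threshold_never_enlarges_calls(self):
        rng = np.random.default_rng(12)
        n = 200
        mut, ctrl = _tables_from_q(
            rng.random(n) * 0.1, rng.random(n), rng.normal(0, 0.05, n)
        )
        called = None
        for thr in (0.0, 0.02, 0.04, 0.08):
            out = call_dmps(mut, ctrl, delta_threshold=thr)
            now = set(out.index[out["dmp"]])
            if called is not None:
                assert now <= called
            called = now

    def test_site_label_swap_flips_every_sign(self, small_sim):
        _, dataset, _, _ = small_sim
        diffs_mut = paired_differences(dataset, "MUT")
        diffs_ctrl = paired_differences(dataset, "control")
        out = call_dmps(group_dmp_table(diffs_mut), group_dmp_table(diffs_ctrl))
        flipped = call_dmps(group_dmp_table(-diffs_mut), group_dmp_table(-diffs_ctrl))
        np.testing.assert_allclose(
            flipped["median_delta_mut"], -out["median_delta_mut"], atol=1e-15
        )
        pd.testing.assert_series_equal(flipped["dmp"], out["dmp"])
        hyper = out.index[out["dmp"] & (out["direction"] == "hyper")]
        hypo_flipped = flipped.index[flipped["dmp"] & (flipped["direction"] == "hypo")]
        assert set(hyper) == set(hypo_flipped)


class TestHeterogeneity:
    def _dmps(self, n, direction="hyper"):
        idx = [f"cg{i:05d}" for i in range(n)]
        return pd.DataFrame(
            {"dmp": True, "direction": direction, "median_delta_mut": 0.05}, index=idx
        )

    def test_small_changes_count_nowhere(self):
        diffs = pd.DataFrame(np.full((3, 6), 0.05), index=[f"cg{i:05d}" for i in range(3)])
        means, _ = heterogeneity_summary(diffs, self._dmps(3))
        assert means[0.1] == 0.0 and means[0.2] == 0.0

    def test_intermediate_changes_count_once(self):
        diffs = pd.DataFrame(np.full((3, 6), 0.15), index=[f"cg{i:05d}" for i in range(3)])
        means, _ = heterogeneity_summary(diffs, self._dmps(3))
        assert means[0.1] == 1.0 and means[0.2] == 0.0

    def test_direction_aware_counting(self):
        # hypo DMP: only decreases count
        diffs = pd.DataFrame([[-0.15, -0.3, 0.15, 0.0]], index=["cg00000"])
        means, _ = heterogeneity_summary(diffs, self._dmps(1, direction="hypo"))
        assert means[0.1] == pytest.approx(0.5)
        assert means[0.2] == pytest.approx(0.25)

    def test_matches_two_loop_count(self):
        rng = np.random.default_rng(3)
        n, m = 40, 9
        idx = [f"cg{i:05d}" for i in range(n)]
        diffs = pd.DataFrame(rng.normal(0, 0.15, (n, m)), index=idx)
        direction = rng.choice(["hyper", "hypo"], n)
        dmps = pd.DataFrame({"dmp": True, "direction": direction}, index=idx)
        means, per_probe = heterogeneity_summary(diffs, dmps)
        for theta in (0.1, 0.2):
            fracs = []
            for i in range(n):
                count = 0
                for j in range(m):
                    v = diffs.iloc[i, j]
                    if direction[i] == "hyper" and v > theta:
                        count += 1
                    if direction[i] == "hypo" and v < -theta:
                        count += 1
                fracs.append(count / m)
            assert means[theta] == pytest.approx(np.mean(fracs), abs=1e-12)

    def test_empty_dmps_rejected(self):
        diffs = pd.DataFrame(np.zeros((2, 4)), index=["a", "b"])
        dmps = pd.DataFrame({"dmp": [False, False], "direction": ["hyper", "hyper"]},
                            index=["a", "b"])
        with pytest.raises(ValueError):
            heterogeneity_summary(diffs, dmps)


class TestCelllineDeltas:
    def test_identical_arms_give_empty_lists(self):
        v = pd.Series([0.1, 0.5], index=["a", "b"])
        assert cellline_delta_dmps(v, v.copy(), 0.3) == ([], [])

    def test_threshold_strictness(self):
        treated = pd.Series([0.61, 0.60, 0.0], index=["a", "b", "c"])
        control = pd.Series([0.30, 0.30, 0.35], index=["a", "b", "c"])
        hyper, hypo = cellline_delta_dmps(treated, control, 0.3)
        assert hyper == ["a"]  # +0.31 passes, +0.30 does not
        assert hypo == ["c"]

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(8)
        idx = [f"cg{i:05d}" for i in range(500)]
        treated = pd.Series(rng.random(500), index=idx)
        control = pd.Series(rng.random(500), index=idx)
        hyper, hypo = cellline_delta_dmps(treated, control, 0.1)
        exp_hyper = sorted(i for i in idx if treated[i] - control[i] > 0.1)
        exp_hypo = sorted(i for i in idx if control[i] - treated[i] > 0.1)
        assert hyper == exp_hyper and hypo == exp_hypo

    def test_mismatched_probes_rejected(self):
        a = pd.Series([0.1], index=["a"])
        b = pd.Series([0.1], index=["b"])
        with pytest.raises(ValueError):
            cellline_delta_dmps(a, b, 0.1)
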