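import shutil
import subprocess

import numpy as np
import pytest

from sglife.normalize import (
    NormalizationError,
    apply_tmm,
    combat_adjust,
    scale_columns_to_mean,
    tmm_factors,
)
from sglife.quant import IntensityMatrix, ProteinRecord, SampleDesign

from conftest import make_matrix


class TestColumnScaling:
    def test_column_sums_equalized(self):
        m = IntensityMatrix(
            [ProteinRecord("P1", "A"), ProteinRecord("P2", "B")],
            [SampleDesign("a", "HS0", 1, "CAPRIN1"), SampleDesign("b", "HS10", 1, "CAPRIN1")],
            np.array([[4.0, 10.0], [6.0, 20.0]]),
        )
        out = scale_columns_to_mean(m)
        sums = out.values.sum(axis=0)
        assert np.allclose(sums, 20.0)

    def test_any_input_sums_equal(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(20, 2, size=(30, 9))
        m = make_matrix(prof, noise_sd=0.2, seed=1)
        out = scale_columns_to_mean(m)
        sums = np.nansum(out.values, axis=0)
        assert np.allclose(sums, sums[0], rtol=1e-9)

    def test_single_column_unchanged(self):
        m = IntensityMatrix(
            [ProteinRecord("P1", "A")],
            [SampleDesign("a", "HS0", 1, "CAPRIN1")],
            np.array([[5.0]]),
        )
        assert np.allclose(scale_columns_to_mean(m).values, m.values)

    def test_zero_sum_column_names_sample(self):
        m = IntensityMatrix(
            [ProteinRecord("P1", "A")],
            [SampleDesign("a", "HS0", 1, "CAPRIN1"), SampleDesign("bad", "HS10", 1, "CAPRIN1")],
            np.array([[5.0, 0.0]]),
        )
        with pytest.raises(NormalizationError, match="bad"):
            scale_columns_to_mean(m)


class TestComBat:
    def test_zero_batch_effect_is_identity(self):
        rng = np.random.default_rng(2)
        prof = rng.normal(20, 1.5, size=(80, 9)) + rng.normal(0, 0.3, size=(80, 9))
        m = make_matrix(prof, replicates=3, seed=2)  # replicate columns identical
        adj, _ = combat_adjust(m)
        assert np.max(np.abs(np.log2(adj.values) - np.log2(m.values))) < 1e-6

    def test_injected_shift_removed(self):
        # 200 flat proteins from the study-condition generator with a +0.8
        # log2 shift injected into replicate 2
        from sglife.simulate import SimulationConfig, simulate_timecourse

        cfg = SimulationConfig(n_early=0, n_late=0, n_invariable=200,
                               batch_shifts=(0.0, 0.8, 0.0), seed=5)
        _, m, _ = simulate_timecourse(cfg)
        adj, model = combat_adjust(m)
        lv = np.log2(adj.values)
        b1 = [j for j, s in enumerate(adj.samples) if s.replicate == 1]
        b2 = [j for j, s in enumerate(adj.samples) if s.replicate == 2]
        resid = np.abs(lv[:, b2].mean(axis=1) - lv[:, b1].mean(axis=1))
        assert np.median(resid) < 0.05
        # the location effect was seen by the model
        assert np.median(model.gamma_star[1] - model.gamma_star[0]) == pytest.approx(0.8, abs=0.1)

    def test_gamma_recovery_correlates_with_truth(self):
        rng = np.random.default_rng(6)
        n = 500
        true_shift = rng.normal(0.8, 0.4, n)
        base = rng.normal(20, 1.0, n)
        labels = ["HS0", "HS10", "HS20", "HS30", "HS60", "HS120", "HS180", "Re5", "Re10"]
        samples = [SampleDesign(f"c_{l}_r{b}", l, b, "CAPRIN1") for b in (1, 2) for l in labels]
        cols = [base + (true_shift if s.replicate == 2 else 0.0) + rng.normal(0, 0.3, n)
                for s in samples]
        m = IntensityMatrix([ProteinRecord(f"P{i}", f"G{i}") for i in range(n)],
                            samples, 2.0 ** np.column_stack(cols))
        _, model = combat_adjust(m)
        r = np.corrcoef(model.gamma_star[1] - model.gamma_star[0], true_shift)[0, 1]
        assert r > 0.9

    def test_shape_order_and_pooled_mean_preserved(self):
        rng = np.random.default_rng(7)
        prof = rng.normal(18, 1, size=(40, 9))
        m = make_matrix(prof, replicates=3, noise_sd=0.2, batch_shift=(0.3, -0.3, 0.0), seed=7)
        adj, _ = combat_adjust(m)
        assert adj.values.shape == m.values.shape
        assert adj.accessions == m.accessions
        # balanced groups: pooled log2 mean preserved up to the EB shrinkage
        # remainder (shrunk location effects need not sum to zero per protein)
        assert np.allclose(np.log2(adj.values).mean(axis=1),
                           np.log2(m.values).mean(axis=1), atol=0.05)

    def test_single_batch_errors(self):
        rng = np.random.default_rng(8)
        prof = rng.normal(20, 1, size=(10, 9))
        m = make_matrix(prof, replicates=1, seed=8)
        with pytest.raises(NormalizationError, match="2 batches"):
            combat_adjust(m)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_sva_combat_oracle(self, tmp_path):
        """Independent cross-check against Bioconductor sva's ComBat.

        Small expected discrepancy: the scale estimates use the mean squared
        deviation (ddof=0) so that zero batch effect is an exact identity.
        """
        from sglife.simulate import SimulationConfig, simulate_timecourse

        cfg = SimulationConfig(n_early=0, n_late=0, n_invariable=60,
                               batch_shifts=(0.0, 0.5, -0.5), seed=1)
        _, cap, _ = simulate_timecourse(cfg)
        logv = np.log2(cap.values)
        np.savetxt(tmp_path / "mat.tsv", logv, delimiter="\t")
        with open(tmp_path / "meta.tsv", "w") as f:
            f.write("batch\tgroup\n")
            for s in cap.samples:
                f.write(f"{s.replicate}\t{s.combat_group}\n")
        script = tmp_path / "combat.R"
        script.write_text(
            'suppressMessages(library(sva));'
            f'x <- as.matrix(read.table("{tmp_path}/mat.tsv", sep="\\t"));'
            f'meta <- read.table("{tmp_path}/meta.tsv", sep="\\t", header=TRUE);'
            'mod <- model.matrix(~ factor(group), data=meta);'
            'out <- ComBat(dat=x, batch=factor(meta$batch), mod=mod);'
            f'write.table(out, "{tmp_path}/out.tsv", sep="\\t", '
            'row.names=FALSE, col.names=FALSE)'
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             timeout=300)
        assert res.returncode == 0, res.stderr
        sva_out = np.loadtxt(tmp_path / "out.tsv", delimiter="\t")
        ours, _ = combat_adjust(cap)
        assert np.max(np.abs(np.log2(ours.values) - sva_out)) < 0.05

    def test_confounded_batch_errors(self):
        # batch 2 contains only early-group samples
        samples = [
            SampleDesign("a", "HS0", 1, "CAPRIN1"), SampleDesign("b", "HS60", 1, "CAPRIN1"),
            SampleDesign("c", "HS120", 1, "CAPRIN1"),
            SampleDesign("d", "HS0", 2, "CAPRIN1"), SampleDesign("e", "HS10", 2, "CAPRIN1"),
        ]
        rng = np.random.default_rng(9)
        m = IntensityMatrix(
            [ProteinRecord(f"P{i}", f"G{i}") for i in range(12)],
            samples, 2.0 ** rng.normal(20, 1, size=(12, 5)),
        )
        with pytest.raises(NormalizationError, match="confounded"):
            combat_adjust(m)


def _two_col(vals_a, vals_b):
    n = len(vals_a)
    return IntensityMatrix(
        [ProteinRecord(f"P{i}", f"G{i}") for i in range(n)],
        [SampleDesign("a", "HS0", 1, "CAPRIN1"), SampleDesign("b", "HS10", 1, "CAPRIN1")],
        np.column_stack([vals_a, vals_b]),
    )


class TestTMM:
    def test_identical_column_factor_one(self):
        rng = np.random.default_rng(1)
        ref = rng.lognormal(10, 1, 100)
        f = tmm_factors(_two_col(ref, ref.copy()), reference="a")
        assert f.factor_of_sample["b"] == pytest.approx(1.0, abs=1e-9)

    def test_uniform_doubling_factor_two(self):
        rng = np.random.default_rng(2)
        ref = rng.lognormal(10, 1, 100)
        f = tmm_factors(_two_col(ref, 2.0 * ref), reference="a")
        assert f.factor_of_sample["b"] == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_reciprocal_property(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.lognormal(10, 1, 120)
        x = ref * 1.3 * np.exp(rng.normal(0, 0.25, 120))
        f_fwd = tmm_factors(_two_col(ref, x), reference="a").factor_of_sample["b"]
        f_rev = tmm_factors(_two_col(x, ref), reference="a").factor_of_sample["b"]
        assert f_fwd * f_rev == pytest.approx(1.0, abs=1e-6)

    def test_too_few_pairs_errors(self):
        ref = np.array([1.0] * 5 + [0.0] * 20)
        x = np.ones(25)
        with pytest.raises(NormalizationError, match="10"):
            tmm_factors(_two_col(ref, x), reference="a")

    def test_apply_divides_columns(self):
        rng = np.random.default_rng(3)
        ref = rng.lognormal(10, 1, 50)
        m = _two_col(ref, 2.0 * ref)
        f = tmm_factors(m, reference="a")
        out = apply_tmm(m, f)
        assert np.allclose(out.values[:, 1], ref, rtol=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_edger_oracle(self, tmp_path):
        """Independent cross-check of the factors against edgeR's TMM."""
        rng = np.random.default_rng(4)
        counts = np.column_stack([
            rng.lognormal(8, 1, 300),
            rng.lognormal(8, 1, 300) * 1.6,
            rng.lognormal(8, 1, 300),
        ])
        # equal library sizes so raw-scale M-values match edgeR's proportion-based ones
        counts = counts / counts.sum(axis=0, keepdims=True) * 1e7
        np.savetxt(tmp_path / "counts.tsv", counts, delimiter="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR));'
            'x <- as.matrix(read.table("%s", sep="\\t"));'
            'f <- calcNormFactors(x, method="TMM", refColumn=1);'
            'cat(f, sep="\\n")' % (tmp_path / "counts.tsv")
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             timeout=300)
        assert res.returncode == 0, res.stderr
        edger = np.array([float(v) for v in res.stdout.split()])
        samples = [SampleDesign(s, "HS0", 1, "CAPRIN1") for s in ("a", "b", "c")]
        m = IntensityMatrix([ProteinRecord(f"P{i}", f"G{i}") for i in range(300)],
                            samples, counts)
        ours = tmm_factors(m, reference="a", recenter=True)
        mine = np.array([ours.factor_of_sample[s] for s in ("a", "b", "c")])
        assert np.allclose(mine, edger, rtol=0.02)
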