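import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ewaskit import harmonization, synthetic
from ewaskit.synthetic import CohortDesign

from conftest import make_manifest, make_sheet


def _uniform_beta(n_probes, n_samples, seed=0, lo=0.2, hi=0.8):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(lo, hi, size=(n_probes, n_samples)),
        index=pd.Index([f"cg{i}" for i in range(n_probes)], name="probe_id"),
        columns=[f"s{i}" for i in range(n_samples)],
    )


class TestFilterProbes:
    def _setup(self):
        n, m = 100, 10
        beta = _uniform_beta(n, m, seed=1)
        detp = pd.DataFrame(0.001, index=beta.index, columns=beta.columns)
        bc = pd.DataFrame(10, index=beta.index, columns=beta.columns)
        manifest = make_manifest(
            [(f"cg{i}", "1", 1000 + i, "", "intergenic", "OpenSea") for i in range(n)]
        )
        return beta, detp, bc, manifest

    def test_clean_input_is_identity(self):
        beta, detp, bc, manifest = self._setup()
        kept, report = harmonization.filter_probes(beta, detp, bc, manifest)
        assert report.n_retained == 100
        assert sum(report.n_removed_by_rule.values()) == 0
        pd.testing.assert_frame_equal(kept, beta)

    def test_planted_failures_counted(self):
        beta, detp, bc, manifest = self._setup()
        detp.iloc[0, 0] = 0.5
        detp.iloc[1, 3] = 0.02
        bc.iloc[2] = 1          # beadcount < 3 in all samples
        bc.iloc[3] = 1
        flags = {"no_cg": {"cg4"}, "snp_probe": {"cg5"}}
        manifest.loc["cg6", "chrom"] = "X"
        kept, report = harmonization.filter_probes(beta, detp, bc, manifest, flags=flags)
        assert report.n_retained == 93
        assert report.n_removed_by_rule == {
            "detection_p": 2, "beadcount": 2, "no_cg": 1, "snp_probe": 1,
            "multi_hit": 0, "xy": 1,
        }

    def test_first_rule_accounting(self):
        beta, detp, bc, manifest = self._setup()
        detp.iloc[0, 0] = 0.5
        bc.iloc[0] = 1          # same probe fails beadcount too
        _, report = harmonization.filter_probes(beta, detp, bc, manifest)
        assert report.n_removed_by_rule["detection_p"] == 1
        assert report.n_removed_by_rule["beadcount"] == 0

    def test_idempotent(self):
        beta, detp, bc, manifest = self._setup()
        detp.iloc[5, 2] = 0.9
        kept, _ = harmonization.filter_probes(beta, detp, bc, manifest)
        kept2, report2 = harmonization.filter_probes(
            kept, detp.loc[kept.index], bc.loc[kept.index], manifest
        )
        pd.testing.assert_frame_equal(kept, kept2)
        assert sum(report2.n_removed_by_rule.values()) == 0

    def test_shape_mismatch_rejected(self):
        beta, detp, bc, manifest = self._setup()
        with pytest.raises(ValueError, match="shape"):
            harmonization.filter_probes(beta, detp.iloc[:50], bc, manifest)


class TestIntersectCohorts:
    def test_partial_overlap(self):
        a = _uniform_beta(10, 3, seed=1)
        b = _uniform_beta(8, 4, seed=2)
        b.index = [f"cg{i}" for i in range(4, 12)]   # 6 shared: cg4..cg9
        ra, rb = harmonization.intersect_cohorts(a, b)
        assert ra.shape == (6, 3) and rb.shape == (6, 4)
        assert list(ra.index) == list(rb.index)

    def test_identical_sets_identity(self):
        a = _uniform_beta(5, 3, seed=3)
        ra, rb = harmonization.intersect_cohorts(a, a.copy())
        pd.testing.assert_frame_equal(ra, a)

    def test_disjoint_sets_error(self):
        a = _uniform_beta(5, 3, seed=4)
        b = _uniform_beta(5, 3, seed=5)
        b.index = [f"other{i}" for i in range(5)]
        with pytest.raises(ValueError, match="no probes"):
            harmonization.intersect_cohorts(a, b)


class TestSVDScreen:
    def test_planted_slide_shift_detected(self):
        d = CohortDesign(n_probes=400, batch_shift=0.5, seed=6)
        man = synthetic.generate_manifest(d)
        beta, sheet = synthetic.generate_cohort(man, d)
        screen = harmonization.svd_batch_screen(beta, sheet, covariates=["batch"])
        assert screen.min_p("batch") < 1e-3

    def test_variance_fractions_monotone(self):
        d = CohortDesign(n_probes=300, seed=7)
        man = synthetic.generate_manifest(d)
        beta, sheet = synthetic.generate_cohort(man, d)
        screen = harmonization.svd_batch_screen(beta, sheet)
        vf = screen.variance_fraction
        assert (np.diff(vf) <= 1e-12).all() and vf.sum() <= 1 + 1e-9

    def test_pure_noise_rarely_significant(self):
        hits = 0
        for seed in range(30):
            beta = _uniform_beta(200, 24, seed=seed)
            sheet = make_sheet(12, 12)
            sheet.index = beta.columns
            screen = harmonization.svd_batch_screen(
                beta, sheet, covariates=["batch", "group"]
            )
            if float(screen.association_p.min().min()) > 0.001:
                hits += 1
        assert hits >= 27  # >= 90% of null screens stay clean

    def test_singleton_batch_levels_untestable(self):
        beta = _uniform_beta(50, 4, seed=8)
        sheet = make_sheet(2, 2)
        sheet.index = beta.columns
        sheet["batch"] = [f"b{i}" for i in range(4)]
        with pytest.raises(ValueError, match="one sample per level"):
            harmonization.svd_batch_screen(beta, sheet, covariates=["batch"])


class TestCombat:
    def test_single_batch_identity(self):
        beta = _uniform_beta(60, 8, seed=9)
        sheet = make_sheet(4, 4)
        sheet.index = beta.columns
        sheet["batch"] = "only"
        out = harmonization.combat_adjust(beta, sheet)
        assert np.abs(out.to_numpy() - beta.to_numpy()).max() < 1e-10

    def test_batch_shift_removed(self):
        # the systematic slide shift is removed; what remains in the
        # per-probe batch-mean gap is the unshrunk half of sampling noise,
        # exactly as the parametric EB model prescribes
        d = CohortDesign(n_case=30, n_control=30, n_probes=300, batch_shift=0.4, seed=10)
        man = synthetic.generate_manifest(d)
        beta, sheet = synthetic.generate_cohort(man, d)
        out = harmonization.combat_adjust(beta, sheet)
        b1 = (sheet["batch"] == sheet["batch"].unique()[0]).to_numpy()
        gap = lambda m: (m.loc[:, b1].mean(axis=1) - m.loc[:, ~b1].mean(axis=1)).abs().mean()
        assert gap(out) < 0.3 * gap(beta)
        assert gap(out) < 0.02

    def test_group_effect_preserved(self):
        planted = (synthetic.PlantedDMR("G", "1", 1000, 1, 50, 0.15),)
        d = CohortDesign(n_case=20, n_control=20, n_probes=200,
                         planted_dmrs=planted, batch_shift=0.4, seed=12)
        man = synthetic.generate_manifest(d)
        beta, sheet = synthetic.generate_cohort(man, d)
        out = harmonization.combat_adjust(beta, sheet)
        case = (sheet["group"] == "case").to_numpy()
        probe = man.index[man["planted"]][0]
        before = beta.loc[probe, case].mean() - beta.loc[probe, ~case].mean()
        after = out.loc[probe, case].mean() - out.loc[probe, ~case].mean()
        assert abs(before - after) < 0.02

    def test_singleton_batch_rejected(self):
        beta = _uniform_beta(30, 5, seed=13)
        sheet = make_sheet(3, 2)
        sheet.index = beta.columns
        sheet["batch"] = ["a", "a", "a", "a", "b"]
        with pytest.raises(ValueError, match="singleton"):
            harmonization.combat_adjust(beta, sheet)

    def test_confounded_batch_rejected(self):
        beta = _uniform_beta(30, 6, seed=14)
        sheet = make_sheet(3, 3)
        sheet.index = beta.columns
        sheet["batch"] = np.where(sheet["group"] == "case", "a", "b")
        with pytest.raises(ValueError, match="confounded"):
            harmonization.combat_adjust(beta, sheet)

    def test_matches_reference_eb_implementation(self, tmp_path):
        """Cross-check against the R sva::ComBat oracle on a small fixture."""
        d = CohortDesign(n_case=8, n_control=8, n_probes=60, batch_shift=0.5, seed=3)
        man = synthetic.generate_manifest(d)
        beta, sheet = synthetic.generate_cohort(man, d)
        mine = harmonization.combat_adjust(beta, sheet)

        def logit(b):
            b = np.clip(b, 1e-6, 1 - 1e-6)
            return np.log(b / (1 - b))

        pd.DataFrame(logit(beta.to_numpy()), index=beta.index, columns=beta.columns).to_csv(
            tmp_path / "logit.csv"
        )
        sheet[["group", "batch"]].to_csv(tmp_path / "sheet.csv")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(sva))
            m <- as.matrix(read.csv('{tmp_path}/logit.csv', row.names=1, check.names=FALSE))
            sheet <- read.csv('{tmp_path}/sheet.csv', row.names=1)
            mod <- model.matrix(~group, data=sheet)
            out <- ComBat(dat=m, batch=sheet$batch, mod=mod, par.prior=TRUE)
            write.csv(out, '{tmp_path}/r_out.csv')
            """
        )
        (tmp_path / "check.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "check.R")], check=True, capture_output=True
        )
        r_out = pd.read_csv(tmp_path / "r_out.csv", index_col=0)
        diff = np.abs(logit(mine.to_numpy()) - r_out.to_numpy())
        # small residual from differing EB convergence tolerances
        assert diff.max() < 0.01
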