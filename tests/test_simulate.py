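"""Generator checks: determinism, manifest/annotation consistency, the
piecewise-Poisson fragment model, NB count moments, the null DE calibration
of simulated counts, and methylation separation."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from polyswitch.config import SimConfig
from polyswitch.expression import nb_two_group_test
from polyswitch.simulate import (GroundTruthManifest, SizingError,
                                 default_sample_sheet, simulate_chip_fragments,
                                 simulate_genome, simulate_methylation,
                                 simulate_rnaseq_counts, write_dataset)


def config(**kw) -> SimConfig:
    base = dict(n_chroms=1, chrom_length_bp=2_000_000, n_genes=50,
                n_common_domains=3, n_state_specific_domains=2,
                n_sensitive_genes=6, n_switch_genes=(2, 1),
                library_size=30_000, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestGenome:
    def test_nothing_planted_gives_only_common_domains(self):
        cfg = config(n_state_specific_domains=0, n_switch_genes=(0, 0))
        _, _, man = simulate_genome(cfg)
        assert all(d["kind"] == "common" for d in man.planted_domains)
        assert all(not v["silenced"] and not v["derepressed"]
                   for v in man.planted_switch_genes.values())

    def test_same_seed_identical_manifest(self):
        m1 = simulate_genome(config())[2].to_dict()
        m2 = simulate_genome(config())[2].to_dict()
        assert json.dumps(m1, sort_keys=True) == json.dumps(m2, sort_keys=True)

    def test_different_seed_differs(self):
        m1 = simulate_genome(config())[2].to_dict()
        m2 = simulate_genome(config(seed=6))[2].to_dict()
        assert json.dumps(m1) != json.dumps(m2)

    def test_switch_genes_have_declared_promoter_domains(self):
        cfg = config(n_switch_genes=(3, 0))
        _, annot, man = simulate_genome(cfg)
        tr = man.planted_switch_genes["TR"]
        assert len(tr["silenced"]) == 3
        tab = annot.table.set_index("gene")
        domains = {d["domain_id"]: d for d in man.planted_domains}
        for rec in tr["silenced"]:
            d = domains[rec["domain_id"]]
            assert d["states"] == ["TR"]
            tss = tab.loc[rec["gene"], "tss"]
            assert d["start"] <= tss < d["end"]   # domain overlaps TSS itself

    def test_genes_non_overlapping_and_in_bounds(self):
        cfg = config(n_genes=80)
        sizes, annot, man = simulate_genome(cfg)
        for chrom, grp in annot.table.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].values[1:] >= g["end"].values[:-1]).all()
            assert (g["end"] <= sizes[chrom]).all()
        for d in man.planted_domains:
            assert 0 <= d["start"] < d["end"] <= sizes[d["chrom"]]

    def test_infeasible_layout_raises_sizing_error(self):
        with pytest.raises(SizingError):
            simulate_genome(config(chrom_length_bp=100_000, n_genes=50))

    def test_manifest_json_round_trip(self, tmp_path):
        man = simulate_genome(config())[2]
        path = tmp_path / "m.json"
        path.write_text(json.dumps(man.to_dict()))
        back = GroundTruthManifest.from_dict(json.loads(path.read_text()))
        assert back.to_dict() == man.to_dict()


class TestChipFragments:
    def test_zero_library(self):
        cfg = config(library_size=0)
        man = simulate_genome(cfg)[2]
        fs = simulate_chip_fragments(man, "UT", "EZH2", 1, cfg)
        assert fs.library_size == 0

    def test_unknown_state_rejected(self):
        cfg = config()
        man = simulate_genome(cfg)[2]
        with pytest.raises(KeyError):
            simulate_chip_fragments(man, "XX", "EZH2", 1, cfg)

    def test_determinism_and_replicate_independence(self):
        cfg = config()
        man = simulate_genome(cfg)[2]
        a1 = simulate_chip_fragments(man, "UT", "EZH2", 1, cfg)
        a2 = simulate_chip_fragments(man, "UT", "EZH2", 1, cfg)
        b = simulate_chip_fragments(man, "UT", "EZH2", 2, cfg)
        assert np.array_equal(a1.fragments, a2.fragments)
        assert not np.array_equal(a1.fragments, b.fragments)

    def test_background_is_homogeneous_poisson(self):
        # no domains: window counts fit a homogeneous Poisson (chi-square GOF)
        cfg = config(n_common_domains=0, n_state_specific_domains=0,
                     n_switch_genes=(0, 0), n_sensitive_genes=0,
                     library_size=40_000)
        man = simulate_genome(cfg)[2]
        fs = simulate_chip_fragments(man, "UT", "EZH2", 1, cfg)
        w = 1000
        counts = np.zeros(cfg.chrom_length_bp // w, dtype=int)
        for _, s, e in fs.intervals():
            counts[((s + e) // 2) // w] += 1
        assert counts.size >= 1000
        lam = counts.mean()
        kmax = int(sps.poisson.ppf(0.999, lam))
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        exp = sps.poisson.pmf(np.arange(kmax + 1), lam)
        exp[-1] = sps.poisson.sf(kmax - 1, lam)
        exp = exp * counts.size
        keep = exp > 5
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        p = sps.chi2.sf(chi2, keep.sum() - 2)
        assert p > 0.01

    def test_domain_enrichment_matches_intensity_model(self):
        cfg = config(enrichment_factor=8.0, library_size=100_000,
                     library_jitter=0.0)
        man = simulate_genome(cfg)[2]
        fs = simulate_chip_fragments(man, "TR", "EZH2", 1, cfg)
        doms = man.domains_for("TR", "EZH2")
        total_w = sum(d["end"] - d["start"] for d in doms)
        genome = cfg.genome_length_bp
        dens = cfg.library_size / (genome + total_w * (cfg.enrichment_factor - 1))
        d = doms[0]
        expected = dens * cfg.enrichment_factor * (d["end"] - d["start"])
        n_in = sum(1 for _, s, e in fs.intervals()
                   if d["start"] <= (s + e) // 2 < d["end"])
        assert abs(n_in - expected) <= 4 * np.sqrt(expected)

    def test_fragment_length_and_bounds(self):
        cfg = config()
        man = simulate_genome(cfg)[2]
        fs = simulate_chip_fragments(man, "UT", "H3K27me3", 1, cfg)
        for chrom, s, e in fs.intervals():
            assert 0 <= s < e <= man.chrom_sizes[chrom]
            assert e - s <= cfg.fragment_length_bp


class TestRnaCounts:
    def test_identical_seed_identical_matrix(self):
        cfg = config()
        man = simulate_genome(cfg)[2]
        design = default_sample_sheet(cfg)
        c1 = simulate_rnaseq_counts(man, design, cfg)
        c2 = simulate_rnaseq_counts(man, design, cfg)
        pd.testing.assert_frame_equal(c1, c2)

    def test_bad_treatment_label_rejected(self):
        cfg = config()
        man = simulate_genome(cfg)[2]
        design = default_sample_sheet(cfg)
        design.loc[0, "treatment"] = "mock"
        with pytest.raises(ValueError):
            simulate_rnaseq_counts(man, design, cfg)

    def test_planted_effect_moment(self):
        # planted gene with base mean m and de_log2fc=2 -> EZH2i mean ~ 4m
        cfg = config(de_log2fc=2.0, rna_size_factor_jitter=0.0, rna_replicates=20)
        man = simulate_genome(cfg)[2]
        design = default_sample_sheet(cfg)
        counts = simulate_rnaseq_counts(man, design, cfg)
        state = "TR"
        sens = [g for g in man.planted_sensitive_genes[state]]
        veh = [s for s in counts.columns if s.startswith(f"{state}_vehicle")]
        trt = [s for s in counts.columns if s.startswith(f"{state}_EZH2i")]
        for g in sens:
            base = man.gene_base_mean[g]
            rep = 1.0
            for grp in man.planted_switch_genes.values():
                for rec in grp["silenced"] + grp["derepressed"]:
                    if rec["gene"] == g and state in rec["bound_states"]:
                        rep = 2.0 ** -cfg.switch_log2fc
            mu_v, mu_t = base * rep, base * rep * 4.0
            n = len(trt)
            sd_t = np.sqrt((mu_t + cfg.nb_dispersion * mu_t ** 2) / n)
            assert abs(counts.loc[g, trt].mean() - mu_t) <= 4.5 * sd_t
            sd_v = np.sqrt((mu_v + cfg.nb_dispersion * mu_v ** 2) / n)
            assert abs(counts.loc[g, veh].mean() - mu_v) <= 4.5 * sd_v

    def test_null_effect_gives_calibrated_downstream_test(self):
        cfg = config(de_log2fc=0.0, switch_log2fc=0.0, n_genes=300,
                     n_sensitive_genes=0, n_switch_genes=(0, 0),
                     chrom_length_bp=8_000_000)
        man = simulate_genome(cfg)[2]
        design = default_sample_sheet(cfg)
        counts = simulate_rnaseq_counts(man, design, cfg)
        veh = [s for s in counts.columns if s.startswith("UT_vehicle")]
        trt = [s for s in counts.columns if s.startswith("UT_EZH2i")]
        res = nb_two_group_test(counts, veh, trt)
        frac = (res.table["p_value"] < 0.05).mean()
        assert 0.0 <= frac <= 0.10   # MC band at 300 genes


class TestMethylation:
    def test_extreme_betas_separate(self):
        cfg = config(methylation_beta_params=((1, 99), (99, 1)))
        man = simulate_genome(cfg)[2]
        meth, _ = simulate_methylation(man, cfg)
        sens = meth.loc[meth["set"] == "sensitive", "promoter_methylation"]
        insens = meth.loc[meth["set"] == "insensitive", "promoter_methylation"]
        assert sens.mean() == pytest.approx(0.01, abs=0.02)
        assert insens.mean() == pytest.approx(0.99, abs=0.02)
        t, p = sps.ttest_ind(sens, insens)
        assert p < 1e-4

    def test_clone_matrix_moments_and_degenerate(self):
        cfg = config()
        man = simulate_genome(cfg)[2]
        genes = [g["gene"] for g in man.gene_annotation][:3]
        meth, clones = simulate_methylation(man, cfg, clone_genes=genes,
                                            n_clones=40, n_cpgs=25)
        fr = meth.set_index("gene")["promoter_methylation"]
        for g in genes:
            m = clones[g]
            assert m.shape == (40, 25)
            f = fr[g]
            se = np.sqrt(f * (1 - f) / m.size)
            assert abs(m.mean() - f) <= 4 * se + 1e-12

    def test_fractions_in_unit_interval(self):
        cfg = config()
        man = simulate_genome(cfg)[2]
        meth, _ = simulate_methylation(man, cfg)
        assert meth["promoter_methylation"].between(0, 1).all()


class TestWriteDataset:
    def test_outputs_byte_identical_across_runs(self, tmp_path):
        cfg = config()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(cfg, d1)
        write_dataset(cfg, d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_fragment_files_conserve_library_size(self, tmp_path):
        cfg = config()
        write_dataset(cfg, tmp_path / "d")
        man = simulate_genome(cfg)[2]
        fs = simulate_chip_fragments(man, "UT", "EZH2", 1, cfg)
        lines = (tmp_path / "d" / "UT_EZH2_rep1.bed").read_text().strip().splitlines()
        assert len(lines) == fs.library_size
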