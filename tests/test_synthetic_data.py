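"""Simulator: genome construction, selection arithmetic, sampling, reads."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sexfit import quant
from sexfit import synthetic_data as sd


class TestSimulateGenome:
    def test_genes_nonoverlapping_and_contained(self, small_spec, small_genome):
        genome, ann = small_genome
        genes = ann[ann.feature_type == "gene"]
        assert len(genes) == small_spec.n_genes
        assert set(genes.strand) <= {"+", "-"}
        for chrom, grp in genes.groupby("chrom"):
            grp = grp.sort_values("start")
            assert (grp.start >= 1).all()
            assert (grp.end <= len(genome[chrom])).all()
            assert (grp.start.values[1:] > grp.end.values[:-1]).all()

    def test_intervals_tile_genome(self, small_genome):
        genome, ann = small_genome
        for chrom, grp in ann.groupby("chrom"):
            grp = grp.sort_values("start")
            assert grp.start.iloc[0] == 1
            assert grp.end.iloc[-1] == len(genome[chrom])
            assert (grp.start.values[1:] == grp.end.values[:-1] + 1).all()

    def test_genic_fraction_near_target(self, small_spec, small_genome):
        _, ann = small_genome
        genes = ann[ann.feature_type == "gene"]
        genic = (genes.end - genes.start + 1).sum()
        total = sum(small_spec.chrom_lengths)
        assert abs(genic / total - (1 - small_spec.intergenic_fraction)) <= 0.10

    def test_deterministic_under_seed(self, small_spec):
        g1, a1 = sd.simulate_genome(small_spec)
        g2, a2 = sd.simulate_genome(small_spec)
        assert g1 == g2
        pd.testing.assert_frame_equal(a1, a2)

    def test_pigeonhole_error(self):
        spec = sd.SimGenomeSpec(
            chrom_lengths=(100_000,), n_genes=200, gene_length=(1_000, 1_000),
            intergenic_fraction=0.0, seed=0,
        )
        with pytest.raises(ValueError, match="cannot place genes"):
            sd.simulate_genome(spec)

    def test_inconsistent_intergenic_fraction_rejected(self):
        # 20 genes of ~1.5 kb on 100 kb is ~30% genic; asking for 10%
        # intergenic contradicts it
        spec = sd.SimGenomeSpec(
            chrom_lengths=(100_000,), n_genes=20, gene_length=(1_000, 2_000),
            intergenic_fraction=0.1, seed=0,
        )
        with pytest.raises(ValueError, match="cannot place genes"):
            sd.simulate_genome(spec)

    def test_gff_tsv_round_trip(self, small_genome, tmp_path):
        _, ann = small_genome
        sd.write_gff3(ann, tmp_path / "a.gff3")
        back = sd.read_annotation(tmp_path / "a.gff3")
        pd.testing.assert_frame_equal(
            back[["chrom", "start", "end", "feature_id", "feature_type"]],
            ann[["chrom", "start", "end", "feature_id", "feature_type"]],
        )


class TestSimulateLibrary:
    def test_neutral_selection_preserves_frequencies(self, small_truth):
        ab = small_truth.abundance
        for tp in ("T2", "T3", "T4"):
            np.testing.assert_allclose(ab[tp], ab["T1"], rtol=1e-12)

    def test_renormalization_conservation(self, small_truth):
        sums = small_truth.abundance.sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_sex_required_brute_force_renormalization(self, small_genome, small_config):
        """Pooled post-sex frequency of a selected gene's sites matches an
        independent renormalization over all clones."""
        genome, ann = small_genome
        genes = list(ann.loc[ann.feature_type == "gene", "feature_id"])
        target, factor = genes[0], 0.1
        effects = [
            sd.GeneEffectProfile.sex_required(g, factor) if g == target
            else sd.GeneEffectProfile.neutral(g)
            for g in genes
        ]
        truth = sd.simulate_library(genome, ann, effects, small_config)
        in_gene = truth.sites["feature"].str.split(";").apply(lambda f: target in f)
        t2 = truth.abundance["T2"].to_numpy()
        # brute-force oracle: multiply every clone by its own factor, renormalize
        oracle = t2 * np.where(in_gene, factor, 1.0)
        oracle = oracle / oracle.sum()
        np.testing.assert_allclose(truth.abundance["T3"], oracle, rtol=1e-12)
        mass2 = t2[in_gene].sum()
        expected_pool = factor * mass2 / (1 - mass2 + factor * mass2)
        assert truth.abundance.loc[in_gene.values, "T3"].sum() == pytest.approx(
            expected_pool
        )

    def test_essential_gene_absorbing_zero(self, small_genome, small_config):
        genome, ann = small_genome
        genes = list(ann.loc[ann.feature_type == "gene", "feature_id"])
        effects = [
            sd.GeneEffectProfile.essential(g) if g == genes[0]
            else sd.GeneEffectProfile.neutral(g)
            for g in genes
        ]
        truth = sd.simulate_library(genome, ann, effects, small_config)
        hit = truth.sites["feature"].str.split(";").apply(lambda f: genes[0] in f)
        assert hit.any()
        for tp in ("T2", "T3", "T4"):
            assert (truth.abundance.loc[hit.values, tp] == 0).all()

    def test_intergenic_sites_never_selected(self, small_genome, small_config):
        genome, ann = small_genome
        genes = list(ann.loc[ann.feature_type == "gene", "feature_id"])
        effects = [sd.GeneEffectProfile.sex_required(g, 0.01) for g in genes]
        truth = sd.simulate_library(genome, ann, effects, small_config)
        inter = (truth.sites["feature"] == "intergenic").to_numpy()
        t2, t3 = truth.abundance["T2"].to_numpy(), truth.abundance["T3"].to_numpy()
        # within the intergenic pool, relative frequencies are unchanged
        rel2 = t2[inter] / t2[inter].sum()
        rel3 = t3[inter] / t3[inter].sum()
        np.testing.assert_allclose(rel2, rel3, rtol=1e-12)

    def test_library_extinct(self, small_genome, small_config):
        genome, ann = small_genome
        genes = list(ann.loc[ann.feature_type == "gene", "feature_id"])
        effects = [sd.GeneEffectProfile.essential(g) for g in genes]
        cfg = sd.LibrarySimConfig(n_clones=30, seed=99)
        # with few clones it is possible all land in (essential) genes
        placed = sd.simulate_library(genome, ann,
                                     [sd.GeneEffectProfile.neutral(g) for g in genes],
                                     cfg)
        if (placed.sites["feature"] != "intergenic").all():
            with pytest.raises(ValueError, match="library extinct"):
                sd.simulate_library(genome, ann, effects, cfg)
        else:
            # force extinction deterministically via a single-gene genome
            spec = sd.SimGenomeSpec((10_000,), 1, (9_000, 9_000), 0.1, seed=1)
            g2, a2 = sd.simulate_genome(spec)
            gid = a2.loc[a2.feature_type == "gene", "feature_id"].iloc[0]
            small = sd.LibrarySimConfig(n_clones=5, seed=4, read_length=60)
            t = sd.simulate_library(
                g2, a2, [sd.GeneEffectProfile.neutral(gid)], small
            )
            if (t.sites["feature"] != "intergenic").all():
                with pytest.raises(ValueError, match="library extinct"):
                    sd.simulate_library(
                        g2, a2, [sd.GeneEffectProfile.essential(gid)], small
                    )

    def test_effects_must_cover_genes(self, small_genome, small_config):
        genome, ann = small_genome
        with pytest.raises(ValueError, match="cover genes"):
            sd.simulate_library(genome, ann, [], small_config)

    @settings(max_examples=20, deadline=None)
    @given(
        f_pre=st.floats(0.0, 2.0), f_sex=st.floats(0.0, 2.0),
        f_post=st.floats(0.0, 2.0),
    )
    def test_conservation_under_arbitrary_factors(self, small_genome, small_config,
                                                  f_pre, f_sex, f_post):
        genome, ann = small_genome
        genes = list(ann.loc[ann.feature_type == "gene", "feature_id"])
        effects = [
            sd.GeneEffectProfile(
                genes[0], "pleiotropic",
                {"vegetative_pre": f_pre, "sex": f_sex, "vegetative_post": f_post},
            )
        ] + [sd.GeneEffectProfile.neutral(g) for g in genes[1:]]
        truth = sd.simulate_library(genome, ann, effects, small_config)
        np.testing.assert_allclose(truth.abundance.sum(), 1.0, atol=1e-9)


class TestEffectProfiles:
    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            sd.GeneEffectProfile("g", "neutral", {"vegetative_pre": 0.5, "sex": 1.0,
                                                  "vegetative_post": 1.0})
        with pytest.raises(ValueError):
            sd.GeneEffectProfile("g", "essential", {"vegetative_pre": 1.0, "sex": 1.0,
                                                    "vegetative_post": 1.0})
        with pytest.raises(ValueError):
            sd.GeneEffectProfile.sex_required("g", 1.5)
        with pytest.raises(ValueError):
            sd.GeneEffectProfile("g", "no_such_class")


class TestSampleCounts:
    def test_zero_depth(self, small_truth, small_config):
        cfg = sd.LibrarySimConfig(
            n_clones=small_config.n_clones, depth=0, seed=small_config.seed
        )
        counts = sd.sample_counts(small_truth, cfg, "T1", rng=1)
        assert counts.sum() == 0

    def test_total_equals_depth(self, small_truth, small_config):
        counts = sd.sample_counts(small_truth, small_config, "T2", rng=5)
        assert counts.sum() == small_config.depth_for("T2")

    def test_binomial_moments_two_sites(self):
        """Two clones at 0.5/0.5 and depth 1e6: each count within 5 SD."""
        truth = sd.SimTruth(
            sites=pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "pos": [500, 900],
                 "strand": ["+", "+"], "feature": ["intergenic"] * 2}
            ),
            abundance=pd.DataFrame({tp: [0.5, 0.5] for tp in quant.TIMEPOINTS}),
            effects={},
        )
        cfg = sd.LibrarySimConfig(n_clones=2, depth=10**6, seed=0)
        counts = sd.sample_counts(truth, cfg, "T1", rng=13)
        sigma = np.sqrt(10**6 * 0.25)
        assert abs(counts[0] - 500_000) < 5 * sigma
        assert counts.sum() == 10**6

    def test_deterministic_under_seed(self, small_truth, small_config):
        c1 = sd.sample_counts(small_truth, small_config, "T3", rng=7)
        c2 = sd.sample_counts(small_truth, small_config, "T3", rng=7)
        np.testing.assert_array_equal(c1, c2)


class TestEmitReads:
    def test_pcr_constant_duplication_and_umis(self, small_genome, small_truth):
        genome, _ = small_genome
        cfg = sd.LibrarySimConfig(
            n_clones=1_500, pcr_mean_copies=2, pcr_model="constant", seed=3
        )
        counts = np.zeros(len(small_truth.sites), dtype=int)
        counts[0] = 3
        chunks, sidecar = sd.emit_reads(genome, small_truth, counts, cfg, "s", rng=5)
        assert len(sidecar) == 6  # 3 products x 2 copies
        assert sidecar["umi"].nunique() == 3

    def test_reads_are_deterministic(self, small_genome, small_truth, small_config):
        counts = sd.sample_counts(small_truth, small_config, "T1", rng=2)
        a, _ = sd.emit_reads(genome := small_genome[0], small_truth, counts,
                             small_config, "s", rng=9)
        b, _ = sd.emit_reads(genome, small_truth, counts, small_config, "s", rng=9)
        assert a == b

    def test_layout_infeasible(self):
        cfg = sd.LibrarySimConfig(read_length=30)  # < linker + UMI + end + 1
        with pytest.raises(ValueError, match="layout infeasible"):
            cfg.validate()

    def test_every_read_has_layout(self, small_genome, small_truth, small_config):
        genome, _ = small_genome
        counts = np.zeros(len(small_truth.sites), dtype=int)
        counts[:50] = 2
        chunks, sidecar = sd.emit_reads(genome, small_truth, counts, small_config,
                                        "s", rng=21)
        text = "".join(chunks)
        seqs = text.splitlines()[1::4]
        assert all(len(s) == small_config.read_length for s in seqs)
        assert all(s.startswith(small_config.linker) for s in seqs)
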