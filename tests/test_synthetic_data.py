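"""Generator contracts: planted islet, methylome, conversion, traces, qPCR."""

import math

import numpy as np
import pandas as pd
import pytest

from methylotrace import synthetic_data as sd
from methylotrace.cpg_island import find_cpg_islands
from methylotrace.methylation import ReferenceContext, align_read, call_methylation
from methylotrace.trace_io import call_bases


class TestMakePromoterSequence:
    def test_catalog_matches_direct_string_scan(self, promoter):
        seq, catalog = promoter
        scanned = [i + 1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"]
        assert list(catalog["abs_pos"]) == scanned
        assert list(catalog["cpg_id"]) == [f"CpG{k+1}" for k in range(len(scanned))]

    def test_cpg_counts_match_study_layout(self, promoter):
        seq, catalog = promoter
        assert len(seq) == 1080
        assert 24 <= len(catalog) <= 36  # ~30 CpGs over the region
        islet = catalog[(catalog["tss_rel"] >= -200) & (catalog["tss_rel"] <= -80)]
        assert len(islet) >= 7

    def test_islet_found_at_100_not_200(self, promoter):
        seq, _ = promoter
        assert find_cpg_islands(seq, minlen=200) == []
        calls = find_cpg_islands(seq, minlen=100)
        assert len(calls) == 1 and calls[0].klass == "islet"

    def test_same_seed_reproduces_sequence_and_catalog(self):
        s1, c1 = sd.make_promoter_sequence(seed=5)
        s2, c2 = sd.make_promoter_sequence(seed=5)
        assert s1 == s2
        pd.testing.assert_frame_equal(c1, c2)

    def test_contradictory_parameters_rejected(self):
        with pytest.raises(sd.ParameterError):
            sd.make_promoter_sequence(islet_gc=1.0, islet_oe=0.0)
        with pytest.raises(sd.ParameterError):
            sd.make_promoter_sequence(islet_gc=0.4)
        with pytest.raises(sd.ParameterError):
            sd.make_promoter_sequence(total_len=100, islet_span=(-200, -81))

    def test_planted_site_embedded(self, promoter):
        seq, _ = promoter
        assert "GTAGGCA" in seq


class TestSimulateMethylome:
    def test_zero_noise_gives_exact_region_means(self, promoter):
        _, catalog = promoter
        design = sd.CohortDesign(animal_sd=0.0)
        region_map = dict(zip(catalog["cpg_id"], catalog["region_id"]))
        truth = sd.simulate_methylome(catalog, design, region_map, seed=1)
        for row in truth.itertuples():
            assert row.true_fraction == design.region_means[(row.stage, row.region_id)]

    def test_mean_stage_difference_recovers_planted_effect(self, promoter):
        # 50 animals/stage at sd=0.01: the 5 pp region-2 effect is
        # estimated to well under half a point of Monte-Carlo error
        _, catalog = promoter
        design = sd.CohortDesign(animals_per_stage=50, animal_sd=0.01)
        region_map = dict(zip(catalog["cpg_id"], catalog["region_id"]))
        truth = sd.simulate_methylome(catalog, design, region_map, seed=2)
        r2 = truth[truth["region_id"] == 2]
        means = r2.groupby("stage")["true_fraction"].mean()
        assert means["PND35"] - means["PND14"] == pytest.approx(0.05, abs=0.005)

    def test_fractions_always_inside_unit_interval(self, promoter):
        _, catalog = promoter
        design = sd.CohortDesign(animals_per_stage=30, animal_sd=0.5)
        region_map = dict(zip(catalog["cpg_id"], catalog["region_id"]))
        truth = sd.simulate_methylome(catalog, design, region_map, seed=3)
        assert truth["true_fraction"].between(0, 1).all()

    def test_unassigned_cpg_rejected(self, promoter):
        _, catalog = promoter
        design = sd.CohortDesign()
        region_map = dict(zip(catalog["cpg_id"][1:], catalog["region_id"][1:]))
        with pytest.raises(sd.ParameterError, match="region"):
            sd.simulate_methylome(catalog, design, region_map, seed=0)


class TestCohortDesign:
    def test_invalid_designs_rejected(self):
        with pytest.raises(sd.ParameterError):
            sd.CohortDesign(animals_per_stage=0)
        with pytest.raises(sd.ParameterError):
            sd.CohortDesign(region_means={("PND14", 1): 1.2})
        with pytest.raises(sd.ParameterError):
            sd.CohortDesign(expression_fold={"PND14": 0.5, "PND35": 1, "PND56": 1})


class TestBisulfiteConvertPool:
    REF = "ACGTCCGATCGC"  # CpGs at 2, 6, 10; non-CpG Cs at 5, 9?, 12

    def test_full_methylation_protects_cpg_only(self):
        meth = {2: 1.0, 6: 1.0, 10: 1.0}
        pool = sd.bisulfite_convert_pool(self.REF, meth, n_molecules=50,
                                         conversion_rate=1.0, seed=0)
        for seq, _ in pool.variants:
            assert seq == "ACGTTCGATCGT"

    def test_no_methylation_full_conversion_removes_all_c(self):
        meth = {2: 0.0, 6: 0.0, 10: 0.0}
        pool = sd.bisulfite_convert_pool(self.REF, meth, n_molecules=50,
                                         conversion_rate=1.0, seed=0)
        for seq, _ in pool.variants:
            assert "C" not in seq

    def test_intermediate_methylation_is_binomial(self):
        meth = {2: 0.3, 6: 1.0, 10: 1.0}
        pool = sd.bisulfite_convert_pool(self.REF, meth, n_molecules=10_000,
                                         conversion_rate=1.0, seed=1)
        frac_c = pool.base_frequencies()[1, 1]  # 0-based position of CpG at 2
        assert frac_c == pytest.approx(0.30, abs=0.01)

    def test_length_and_non_c_bases_conserved(self):
        pool = sd.bisulfite_convert_pool(self.REF, {2: 0.5, 6: 0.5, 10: 0.5},
                                         n_molecules=200, conversion_rate=0.8,
                                         seed=2)
        for seq, _ in pool.variants:
            assert len(seq) == len(self.REF)
            for i, b in enumerate(self.REF):
                if b != "C":
                    assert seq[i] == b
                else:
                    assert seq[i] in "CT"

    def test_non_c_position_rejected_in_map(self):
        with pytest.raises(sd.ParameterError):
            sd.bisulfite_convert_pool(self.REF, {1: 0.5}, n_molecules=10)


class TestRenderTrace:
    def test_single_molecule_pool_is_pure(self):
        pool = sd.bisulfite_convert_pool("ACGTACGT", {2: 1.0, 6: 1.0},
                                         n_molecules=1, conversion_rate=1.0, seed=0)
        chrom = sd.render_trace(pool, noise_sd=0.0, seed=0)
        amps = chrom.channels[chrom.peak_locations]
        assert (np.count_nonzero(amps, axis=1) == 1).all()

    def test_even_mixture_gives_equal_c_t_peaks(self):
        pool = sd.bisulfite_convert_pool("ACGT", {2: 0.5}, n_molecules=10_000,
                                         conversion_rate=1.0, seed=3)
        chrom = sd.render_trace(pool, noise_sd=0.0, seed=0)
        amps = chrom.channels[chrom.peak_locations]
        i_c, i_t = amps[1, 1], amps[1, 3]
        assert i_c / (i_c + i_t) == pytest.approx(0.5, abs=0.02)

    def test_amplitude_sums_constant_before_noise(self):
        pool = sd.bisulfite_convert_pool("ACGTACGTCC", {2: 0.4, 6: 0.7},
                                         n_molecules=500, conversion_rate=0.95,
                                         seed=4)
        chrom = sd.render_trace(pool, noise_sd=0.0, seed=0)
        sums = chrom.channels[chrom.peak_locations].sum(axis=1)
        assert np.allclose(sums, sums[0], rtol=1e-6)

    def test_empty_pool_rejected(self):
        pool = sd.MoleculePool(matrix=np.zeros((0, 4), dtype=np.uint8),
                               source_reference="ACGT", true_methylation={},
                               conversion_rate=1.0)
        with pytest.raises(sd.ParameterError):
            sd.render_trace(pool)

    def test_end_to_end_ratio_recovers_methylation(self, promoter):
        # pooled conversion -> trace -> base call -> align -> C/(C+T)
        seq, catalog = promoter
        target = catalog["abs_pos"].iloc[10]
        meth = {int(p): 0.7 if p == target else 0.5 for p in catalog["abs_pos"]}
        pool = sd.bisulfite_convert_pool(seq, meth, n_molecules=4000, seed=5)
        chrom = sd.render_trace(pool, noise_sd=2.0, seed=6)
        calls = call_bases(chrom)
        ctx = ReferenceContext.from_catalog(seq, 842, catalog)
        cmap = align_read(calls.primary, ctx)
        profile = call_methylation(calls, cmap, ctx, sample_id="x", stage="PND14")
        row = profile.sites[profile.sites["cpg_id"] == catalog["cpg_id"].iloc[10]]
        assert row["percent"].iloc[0] == pytest.approx(70.0, abs=5.0)


class TestSimulateQpcr:
    def test_uniform_fold_zero_noise_gives_equal_dct(self):
        design = sd.CohortDesign(expression_fold={s: 1.0 for s in sd.STAGES})
        ct = sd.simulate_qpcr(design, ct_noise_sd=0.0, seed=0)
        mean_ct = ct.groupby(["sample", "gene"])["ct"].mean().unstack()
        dct = mean_ct["Mkrn3"] - mean_ct["Actb"]
        assert np.allclose(dct, dct.iloc[0])

    def test_fold_change_encodes_exact_ddct(self):
        design = sd.CohortDesign(
            expression_fold={"PND14": 1.0, "PND35": 0.3, "PND56": 0.3})
        ct = sd.simulate_qpcr(design, ct_noise_sd=0.0, seed=0)
        mean_ct = ct.groupby(["sample", "gene"])["ct"].mean().unstack()
        dct = (mean_ct["Mkrn3"] - mean_ct["Actb"])
        stage = {s: st for st, s in design.sample_ids}
        ddct = (dct[[s for s in dct.index if stage[s] == "PND35"]].mean()
                - dct[[s for s in dct.index if stage[s] == "PND14"]].mean())
        assert ddct == pytest.approx(math.log2(1 / 0.3), abs=1e-9)

    def test_same_seed_identical_table(self):
        design = sd.CohortDesign()
        t1 = sd.simulate_qpcr(design, seed=9)
        t2 = sd.simulate_qpcr(design, seed=9)
        pd.testing.assert_frame_equal(t1, t2)


class TestCoordinates:
    @pytest.mark.parametrize("abs_pos,rel", [(842, 1), (841, -1), (1, -841),
                                             (1080, 239), (843, 2)])
    def test_tss_relative_has_no_zero(self, abs_pos, rel):
        assert sd.tss_relative(abs_pos, 842) == rel
        assert sd.tss_absolute(rel, 842) == abs_pos

    def test_zero_is_rejected(self):
        with pytest.raises(sd.ParameterError):
            sd.tss_absolute(0, 842)
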