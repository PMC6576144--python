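"""Shared polymorphisms across species: mapping, co-occurrence, coding
effects, and the slope-divergent filter."""

import numpy as np
import pandas as pd
import pytest

from canyonpool import stats, transspecies
from canyonpool.io import GeneModel
from oracles import fisher_two_sided_enum


def _sites(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "p_nfs", "p_sfs"]
    )


class TestMapSharedSites:
    def test_identical_allele_pair_is_shared(self):
        a = _sites([("2R", 100, "A", "G", 0.3, 0.4)])
        b = _sites([("2R", 100, "A", "G", 0.2, 0.5)])
        assert len(transspecies.map_shared_sites(a, b)) == 1

    def test_different_allele_pair_is_not_shared(self):
        a = _sites([("2R", 100, "A", "G", 0.3, 0.4)])
        b = _sites([("2R", 100, "A", "T", 0.2, 0.5)])
        assert len(transspecies.map_shared_sites(a, b)) == 0

    def test_swapped_ref_alt_orientation_normalized(self):
        a = _sites([("2R", 100, "A", "G", 0.3, 0.4)])
        b = _sites([("2R", 100, "G", "A", 0.2, 0.5)])
        m = transspecies.map_shared_sites(a, b)
        assert len(m) == 1
        assert m.loc[0, "pb_nfs"] == pytest.approx(0.8)

    def test_symmetric_in_species_order(self, small_cohort):
        sa = stats.slope_site_frequencies(small_cohort.tables, small_cohort.slopes)
        sb = stats.slope_site_frequencies(
            small_cohort.species_b_tables, small_cohort.species_b_slopes
        )
        ab = transspecies.map_shared_sites(sa, sb)
        ba = transspecies.map_shared_sites(sb, sa)
        assert set(zip(ab["chrom_a"], ab["pos_a"])) == set(
            zip(ba["chrom_a"], ba["pos_a"])
        )

    def test_many_to_one_map_rejected(self):
        a = _sites([("2R", 100, "A", "G", 0.3, 0.4), ("2R", 200, "A", "G", 0.3, 0.4)])
        b = _sites([("2R", 100, "A", "G", 0.2, 0.5)])
        cmap = pd.DataFrame(
            {
                "chrom_a": ["2R", "2R"],
                "pos_a": [100, 200],
                "chrom_b": ["2R", "2R"],
                "pos_b": [100, 100],
                "strand": "+",
            }
        )
        with pytest.raises(ValueError):
            transspecies.map_shared_sites(a, b, cmap)


class TestCooccurrence:
    def _frame(self, pa, pb):
        return pd.DataFrame(
            {
                "pa_nfs": pa, "pa_sfs": pa,
                "pb_nfs": pb, "pb_sfs": pb,
            }
        )

    def test_copied_frequencies_give_strong_enrichment(self, rng):
        pa = np.where(rng.random(500) < 0.8, 0.2, 0.8)
        shared = self._frame(pa, pa)
        bg = _sites([("2R", i, "A", "G", 0.2, 0.2) for i in range(1, 201)])
        bg.loc[:99, ["p_nfs", "p_sfs"]] = 0.8  # half alt-major
        out = transspecies.major_allele_cooccurrence(shared, bg, bg)
        overall = out[out["stratum"] == "overall"].iloc[0]
        assert overall["observed"] == pytest.approx(1.0)
        assert overall["fold"] > 1.5

    def test_independent_major_alleles_give_fold_near_one(self, rng):
        n = 4000
        pa = np.where(rng.random(n) < 0.5, 0.2, 0.8)
        pb = np.where(rng.random(n) < 0.5, 0.2, 0.8)
        shared = self._frame(pa, pb)
        bg_rows = [
            ("2R", i, "A", "G", 0.2 if rng.random() < 0.5 else 0.8, 0.5)
            for i in range(1, 2001)
        ]
        bg = _sites(bg_rows)
        bg["p_sfs"] = bg["p_nfs"]
        out = transspecies.major_allele_cooccurrence(shared, bg, bg)
        overall = out[out["stratum"] == "overall"].iloc[0]
        assert overall["fold"] == pytest.approx(1.0, abs=0.12)

    def test_planted_ratio_recovered_from_generator(self, small_cohort):
        """Generator plants co-occurrence 0.85 against background 0.34:
        the recovered fold enrichment is ~2.5."""
        sa = stats.slope_site_frequencies(small_cohort.tables, small_cohort.slopes)
        sb = stats.slope_site_frequencies(
            small_cohort.species_b_tables, small_cohort.species_b_slopes
        )
        shared = transspecies.map_shared_sites(sa, sb)
        key = set(zip(shared["chrom_a"], shared["pos_a"]))
        bg_a = sa[~sa["pos"].isin({p for _, p in key})]
        bg_b = sb[~sb["pos"].isin({p for _, p in key})]
        out = transspecies.major_allele_cooccurrence(shared, bg_a, bg_b)
        fold = out[out["stratum"] == "overall"].iloc[0]["fold"]
        assert 2.0 <= fold <= 3.0


class TestInterslopeDiffCorrelation:
    def test_identical_differences_give_one(self):
        d = np.linspace(-0.4, 0.4, 50)
        shared = pd.DataFrame(
            {"pa_nfs": 0.5 + d / 2, "pa_sfs": 0.5 - d / 2,
             "pb_nfs": 0.5 + d / 2, "pb_sfs": 0.5 - d / 2}
        )
        out = transspecies.interslope_diff_correlation(shared)
        assert out[out["stratum"] == "overall"].iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_differences_near_zero(self, rng):
        n = 1000
        shared = pd.DataFrame(
            {
                "pa_nfs": rng.uniform(0.3, 0.7, n),
                "pa_sfs": rng.uniform(0.3, 0.7, n),
                "pb_nfs": rng.uniform(0.3, 0.7, n),
                "pb_sfs": rng.uniform(0.3, 0.7, n),
            }
        )
        out = transspecies.interslope_diff_correlation(shared)
        assert abs(out[out["stratum"] == "overall"].iloc[0]["r"]) < 0.1

    def test_planted_convergent_fraction_recovered(self, small_cohort, small_config):
        """30% of shared sites copy the interslope difference; the Spearman
        r between species recovers that fraction within 0.1."""
        sa = stats.slope_site_frequencies(small_cohort.tables, small_cohort.slopes)
        sb = stats.slope_site_frequencies(
            small_cohort.species_b_tables, small_cohort.species_b_slopes
        )
        shared = transspecies.map_shared_sites(sa, sb)
        out = transspecies.interslope_diff_correlation(shared)
        r = out[out["stratum"] == "overall"].iloc[0]["r"]
        assert r == pytest.approx(
            small_config.species_convergent_fraction, abs=0.15
        )


def _one_gene_annotator(seq: str, strand: str = "+"):
    gene = GeneModel(
        gene_id="g1", chrom="2R", start=1, end=len(seq), strand=strand,
        transcripts={"g1.t1": [(1, len(seq), 0)]},
    )
    return transspecies.EffectAnnotator([gene], {"2R": seq})


class TestEffectAnnotation:
    def test_third_position_synonymous(self):
        ann = _one_gene_annotator("TTTAAA")
        assert ann.annotate("2R", 3, "T", "C") == "synonymous"  # TTT -> TTC (Phe)

    def test_serine_to_phenylalanine_nonsynonymous(self):
        ann = _one_gene_annotator("TCTAAA")
        assert ann.annotate("2R", 2, "C", "T") == "nonsynonymous"  # TCT -> TTT

    def test_site_outside_cds_noncoding(self):
        ann = _one_gene_annotator("TTTAAA")
        assert ann.annotate("2R", 100, "A", "G") == "noncoding"

    def test_minus_strand_codon(self):
        # genome AAAGAA read on minus strand: TTC TTT; genomic pos 6 is the
        # first codon base (T); A->G at pos 6 means T->C: TTC -> CTC, Phe -> Leu
        ann = _one_gene_annotator("AAAGAA", strand="-")
        assert ann.annotate("2R", 6, "A", "G") == "nonsynonymous"
        # pos 4 is third base of first codon TTC; G->A means C->T: TTC -> TTT
        assert ann.annotate("2R", 4, "G", "A") == "synonymous"

    def test_reference_mismatch_flagged(self):
        ann = _one_gene_annotator("TTTAAA")
        with pytest.raises(ValueError, match="mismatch"):
            ann.annotate("2R", 1, "G", "A")


class TestSlopeDivergentFilter:
    def _shared(self, pa_n, pa_s, pb_n, pb_s, effect="nonsynonymous"):
        return pd.DataFrame(
            {
                "chrom_a": ["2R"], "pos_a": [100],
                "chrom_b": ["2R"], "pos_b": [100],
                "ref": ["C"], "alt": ["T"],
                "pa_nfs": [pa_n], "pa_sfs": [pa_s],
                "pb_nfs": [pb_n], "pb_sfs": [pb_s],
                "effect": [effect],
            }
        )

    def test_concordant_divergent_case_passes(self):
        # the same allele near-fixed in NFS of both species, minor in SFS
        out = transspecies.slope_divergent_filter(
            self._shared(1.00, 0.35, 0.59, 0.30)
        )
        assert len(out) == 1
        assert out.loc[0, "fisher_p_a"] < 0.001

    def test_discordant_slopes_fail(self):
        out = transspecies.slope_divergent_filter(
            self._shared(1.00, 0.35, 0.30, 0.59)
        )
        assert len(out) == 0

    def test_synonymous_site_fails(self):
        out = transspecies.slope_divergent_filter(
            self._shared(1.00, 0.35, 0.59, 0.30, effect="synonymous")
        )
        assert len(out) == 0

    def test_fisher_counts_match_enumeration_oracle(self):
        out = transspecies.slope_divergent_filter(
            self._shared(1.00, 0.35, 0.59, 0.30), n_lines_per_slope=9
        )
        # species A: alt counts round(1.0*18)=18 vs round(0.35*18)=6
        expected = fisher_two_sided_enum(18, 0, 6, 12)
        assert out.loc[0, "fisher_p_a"] == pytest.approx(expected, rel=1e-9)
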