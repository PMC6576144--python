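"""TE insertion sharing, abundance tests, densities and divergence scores."""

import pandas as pd
import pytest

from canyonpool import te
from canyonpool.config import SimulationConfig, TEFamily
from canyonpool.io import GeneModel
from canyonpool.simulate import simulate_cohort
from oracles import fisher_two_sided_enum


def _records(rows):
    return pd.DataFrame(rows, columns=["family", "chrom", "pos", "line", "slope"])


class TestCollapseSites:
    def test_same_position_across_lines_is_one_site(self):
        rec = _records(
            [
                ("roo", "2R", 100, "NFS_1", "NFS"),
                ("roo", "2R", 100, "NFS_2", "NFS"),
                ("roo", "2R", 100, "SFS_1", "SFS"),
            ]
        )
        sites = te.collapse_sites(rec)
        assert len(sites) == 1
        assert (sites.loc[0, "n_nfs"], sites.loc[0, "n_sfs"]) == (2, 1)

    def test_window_zero_keeps_positions_apart(self):
        rec = _records(
            [("roo", "2R", 100, "NFS_1", "NFS"), ("roo", "2R", 150, "NFS_2", "NFS")]
        )
        assert len(te.collapse_sites(rec, merge_window=0)) == 2

    def test_window_merges_nearby_positions(self):
        rec = _records(
            [("roo", "2R", 100, "NFS_1", "NFS"), ("roo", "2R", 150, "NFS_2", "NFS")]
        )
        sites = te.collapse_sites(rec, merge_window=100)
        assert len(sites) == 1 and sites.loc[0, "pos"] == 100

    def test_duplicate_records_rejected(self):
        rec = _records(
            [("roo", "2R", 100, "NFS_1", "NFS"), ("roo", "2R", 100, "NFS_1", "NFS")]
        )
        with pytest.raises(ValueError):
            te.collapse_sites(rec)


def _family_matrix(family, n_shared, n_total):
    """n_total sites of a family; the first n_shared carried on both slopes,
    the rest NFS-only."""
    rows = []
    for i in range(n_total):
        pos = 1000 + i * 10
        rows.append((family, "2R", pos, "NFS_1", "NFS"))
        if i < n_shared:
            rows.append((family, "2R", pos, "SFS_1", "SFS"))
    return _records(rows)


class TestFamilySharing:
    @pytest.mark.parametrize(
        "family,shared,total,pct",
        [
            ("P-element", 37, 584, 6),
            ("INE-1", 908, 1030, 88),
            ("412", 19, 309, 6),
        ],
    )
    def test_printed_sharing_percentages(self, family, shared, total, pct):
        stat = te.family_sharing(_family_matrix(family, shared, total), family)
        assert stat.n_sites_shared == shared
        assert stat.n_sites_total == total
        assert round(stat.pct_shared) == pct

    def test_single_slope_family_has_zero_sharing(self):
        stat = te.family_sharing(_family_matrix("roo", 0, 10), "roo")
        assert stat.pct_shared == 0.0

    def test_unknown_family_raises(self):
        with pytest.raises(KeyError):
            te.family_sharing(_family_matrix("roo", 0, 10), "jockey")


class TestAbundanceTest:
    def test_roo_counts_reproduce_printed_p(self):
        assert te.abundance_test(610, 554, 9036, 9182) == pytest.approx(
            0.049, abs=5e-4
        )

    def test_mariner_counts_reproduce_printed_p(self):
        assert te.abundance_test(69, 93, 9036, 9182) == pytest.approx(0.08, abs=5e-3)

    def test_identical_proportions_give_one(self):
        assert te.abundance_test(10, 10, 100, 100) == pytest.approx(1.0)

    def test_degenerate_margin_gives_one(self):
        assert te.abundance_test(0, 0, 100, 100) == 1.0


class TestSharingTest:
    def test_family_at_background_rate_is_unremarkable(self):
        assert te.sharing_test(10, 100, 100, 1000) > 0.9

    def test_fully_shared_family_matches_enumeration(self):
        t, bg_s, bg_t = 50, 50 + 495, 5000
        got = te.sharing_test(50, t, bg_s, bg_t)
        expected = fisher_two_sided_enum(50, 0, bg_s - 50, (bg_t - t) - (bg_s - 50))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_low_sharing_family_minimizes_p(self):
        cfg = SimulationConfig(
            genome_length=400_000,
            seed=17,
            sweep_intervals=[],
            te_families=[
                TEFamily("quiet", 200, 0.9),
                TEFamily("calm", 200, 0.85),
                TEFamily("restless", 200, 0.1),
            ],
        )
        cohort = simulate_cohort(cfg)
        table = te.family_table(cohort.te_calls)
        worst = table.loc[table["fisher_p_sharing"].idxmin(), "family"]
        assert worst == "restless"


class TestFamilyTable:
    def test_abundances_sum_to_slope_totals(self, small_cohort):
        table = te.family_table(small_cohort.te_calls)
        rec = small_cohort.te_calls
        assert table["abundance_nfs"].sum() == (rec["slope"] == "NFS").sum()
        assert table["abundance_sfs"].sum() == (rec["slope"] == "SFS").sum()

    def test_sharing_matches_planted_truth(self, small_cohort):
        truth = small_cohort.truth.te_truth
        table = te.family_table(small_cohort.te_calls).set_index("family")
        for fam, sub in truth.groupby("family"):
            shared = int(((sub["n_nfs"] > 0) & (sub["n_sfs"] > 0)).sum())
            assert table.loc[fam, "n_sites_shared"] == shared


class TestDensity:
    def test_counts_conserved_across_windows(self, small_cohort):
        density = te.te_density(
            small_cohort.te_calls, small_cohort.chrom_lengths, window=10_000
        )
        sites = te.collapse_sites(small_cohort.te_calls)
        assert density["n_sites_nfs"].sum() == (sites["n_nfs"] > 0).sum()
        assert density["n_sites_sfs"].sum() == (sites["n_sfs"] > 0).sum()

    def test_single_window_counts(self):
        rows = [("roo", "2R", 1 + i * 100, "NFS_1", "NFS") for i in range(24)]
        density = te.te_density(_records(rows), {"2R": 100_000}, window=100_000)
        assert density.loc[0, "n_sites_nfs"] == 24
        assert density.loc[0, "n_sites_sfs"] == 0


class TestCdsDisruption:
    def _gene(self, start, end, gid="gX"):
        return GeneModel(
            gene_id=gid, chrom="2R", start=start - 50, end=end + 50, strand="+",
            transcripts={f"{gid}.t": [(start, end, 0)]},
        )

    def test_boundary_base_included_and_intron_excluded(self):
        gene = GeneModel(
            gene_id="g", chrom="2R", start=100, end=400, strand="+",
            transcripts={"g.t": [(100, 199, 0), (300, 400, 0)]},
        )
        rec = _records(
            [
                ("P-element", "2R", 199, "NFS_1", "NFS"),  # CDS boundary
                ("P-element", "2R", 250, "NFS_2", "NFS"),  # intron
            ]
        )
        out = te.cds_disruption(rec, [gene])
        assert out["pos"].tolist() == [199]

    def test_matches_quadratic_scan_oracle(self, rng):
        genes = [
            self._gene(int(s), int(s) + 99, gid=f"g{i}")
            for i, s in enumerate(rng.integers(100, 50_000, 50))
        ]
        rec = _records(
            [
                ("roo", "2R", int(p), "NFS_1", "NFS")
                for p in rng.integers(1, 50_200, 1000)
            ]
        )
        rec = rec.drop_duplicates(subset=["family", "chrom", "pos", "line"])
        out = te.cds_disruption(rec, genes)
        # one row per (record, overlapping gene) pair, by quadratic scan
        brute_pairs = sum(
            1
            for p in rec["pos"]
            for g in genes
            for s, e in g.cds_intervals()
            if s <= p <= e
        )
        assert len(out) == brute_pairs


class TestDivergenceScore:
    def test_sphinx2_like_pattern_scores_minus_eight(self):
        rows = [("INE-1", "2R", 500, f"SFS_{i}", "SFS") for i in range(1, 10)]
        rows.append(("INE-1", "2R", 500, "NFS_1", "NFS"))
        sites = te.te_divergence_score(te.collapse_sites(_records(rows)))
        assert sites.loc[0, "score"] == -8

    def test_all_lines_site_scores_zero(self):
        rows = [("INE-1", "2R", 500, f"{s}_{i}", s)
                for s in ("NFS", "SFS") for i in range(1, 10)]
        sites = te.te_divergence_score(te.collapse_sites(_records(rows)))
        assert sites.loc[0, "score"] == 0

    def test_slope_swap_negates_score(self):
        rows = [("roo", "2R", 500, f"NFS_{i}", "NFS") for i in range(1, 6)]
        rows += [("roo", "2R", 500, "SFS_1", "SFS")]
        rec = _records(rows)
        swapped = rec.copy()
        swapped["slope"] = swapped["slope"].map({"NFS": "SFS", "SFS": "NFS"})
        a = te.te_divergence_score(te.collapse_sites(rec)).loc[0, "score"]
        b = te.te_divergence_score(te.collapse_sites(swapped)).loc[0, "score"]
        assert a == -b


class TestFisherAgainstEnumeration:
    def test_random_tables_match_oracle(self, rng):
        for _ in range(150):
            total = int(rng.integers(4, 301))
            a = int(rng.integers(0, total + 1))
            b = int(rng.integers(0, total - a + 1))
            c = int(rng.integers(0, total - a - b + 1))
            d = total - a - b - c
            got = te.abundance_test(a, c, a + b, c + d)
            expected = fisher_two_sided_enum(a, b, c, d)
            assert got == pytest.approx(expected, rel=1e-7, abs=1e-12)
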