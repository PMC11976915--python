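import numpy as np
import pandas as pd
import pytest

from synapa import sites
from synapa.sites import BlacklistParams, ClusterParams

from conftest import brute_force_clusters, brute_force_counts, make_reads

XRIP = sites.blacklist_params_for_mode("xrip")
SYNAPTO = sites.blacklist_params_for_mode("synaptosome")

NO_ENDS = pd.DataFrame(columns=["chrom", "pos", "strand"])


def _mask(seq: str, params: BlacklistParams, ends=NO_ENDS):
    return sites.compute_blacklist({"chr1": seq}, ends, params)


class TestModePresets:
    def test_xrip_preset(self):
        assert (XRIP.run_len, XRIP.window_hits, XRIP.window_len, XRIP.downstream_limit) == (6, 7, 10, 500)

    def test_synaptosome_preset(self):
        assert (SYNAPTO.run_len, SYNAPTO.window_hits, SYNAPTO.window_len, SYNAPTO.downstream_limit) == (4, 6, 8, 2000)

    def test_exempt_radius_25_everywhere(self):
        assert XRIP.exempt_radius == SYNAPTO.exempt_radius == 25

    def test_override(self):
        p = sites.blacklist_params_for_mode("xrip", downstream_limit=1000)
        assert p.downstream_limit == 1000 and p.run_len == 6

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown mode"):
            sites.blacklist_params_for_mode("nope")

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            BlacklistParams(window_hits=11, window_len=10)
        with pytest.raises(ValueError):
            ClusterParams(seed_depth=0)


class TestComputeBlacklist:
    def test_a_run_of_six_blacklists_base(self):
        # base 0 followed by AAAAAA, nowhere near an annotated end
        masks = _mask("C" + "AAAAAA" + "C" * 60, XRIP)
        assert masks[("chr1", "+")][0]

    def test_a_run_of_five_does_not(self):
        masks = _mask("C" + "AAAAA" + "C" * 60, XRIP)
        assert not masks[("chr1", "+")][0]

    def test_annotated_end_within_25_exempts(self):
        ends = pd.DataFrame([("chr1", 10, "+")], columns=["chrom", "pos", "strand"])
        masks = _mask("C" + "AAAAAA" + "C" * 60, XRIP, ends)
        assert not masks[("chr1", "+")][0]

    def test_annotated_end_on_other_strand_does_not_exempt(self):
        ends = pd.DataFrame([("chr1", 10, "-")], columns=["chrom", "pos", "strand"])
        masks = _mask("C" + "AAAAAA" + "C" * 60, XRIP, ends)
        assert masks[("chr1", "+")][0]

    def test_annotated_end_beyond_25_does_not_exempt(self):
        ends = pd.DataFrame([("chr1", 26, "+")], columns=["chrom", "pos", "strand"])
        masks = _mask("C" + "AAAAAA" + "C" * 60, XRIP, ends)
        assert masks[("chr1", "+")][0]

    def test_density_window_rules_counted_by_hand(self):
        # downstream bases AATAAGACAA: 7 A of 10 -> xrip window rule fires;
        # first 8 are AATAAGAC (5 A of 8) and the max A-run is 2, so the
        # synaptosome rules both fail
        masks_x = _mask("C" + "AATAAGACAA" + "C" * 60, XRIP)
        masks_s = _mask("C" + "AATAAGACAA" + "C" * 60, SYNAPTO)
        assert masks_x[("chr1", "+")][0]
        assert not masks_s[("chr1", "+")][0]

    def test_six_a_of_ten_fails_xrip_window_rule(self):
        # AATAAAGCCA has 6 A of 10 -> neither xrip rule fires
        masks = _mask("C" + "AATAAAGCCA" + "C" * 60, XRIP)
        assert not masks[("chr1", "+")][0]

    def test_minus_strand_uses_reverse_complement(self):
        # transcribed-strand downstream of base 6 on '-' is leftward; A on
        # the transcript = T on the reference
        seq = "TTTTTT" + "C" + "G" * 60
        masks = sites.compute_blacklist({"chr1": seq}, NO_ENDS, XRIP)
        assert masks[("chr1", "-")][6]
        assert not masks[("chr1", "+")][6]

    def test_run_rule_needs_full_run_available_at_contig_end(self):
        # only 4 As before the contig ends: xrip run rule (6) cannot fire,
        # window rule sees 4 hits < 7 -> clean; synaptosome run rule (4) fires
        seq = "C" * 60 + "C" + "AAAA"
        masks_x = _mask(seq, XRIP)
        masks_s = _mask(seq, SYNAPTO)
        b = 60
        assert not masks_x[("chr1", "+")][b]
        assert masks_s[("chr1", "+")][b]

    def test_apply_blacklist_drops_only_masked(self):
        reads = make_reads({0: 3, 20: 2})
        masks = _mask("C" + "AAAAAA" + "C" * 60, XRIP)
        out = sites.apply_blacklist(reads, masks)
        assert len(out) == 2 and (out["pos"] == 20).all()


class TestGeneWindows:
    GENES = pd.DataFrame(
        [
            dict(gene_id="gA", chrom="chr1", start=1000, end=2000, strand="+", utr_start=1500),
            dict(gene_id="gB", chrom="chr1", start=5000, end=6000, strand="-", utr_start=5500),
        ]
    )

    def test_downstream_100nt_kept_xrip(self):
        reads = make_reads({2099: 1})
        out = sites.restrict_to_gene_windows(reads, self.GENES, XRIP)
        assert len(out) == 1

    def test_downstream_1500nt_dropped_xrip_kept_synaptosome(self):
        reads = make_reads({3499: 1})
        assert len(sites.restrict_to_gene_windows(reads, self.GENES, XRIP)) == 0
        assert len(sites.restrict_to_gene_windows(reads, self.GENES, SYNAPTO)) == 1

    def test_opposite_strand_read_in_body_dropped(self):
        reads = make_reads({1500: 1}, strand="-")
        assert len(sites.restrict_to_gene_windows(reads, self.GENES, XRIP)) == 0

    def test_minus_strand_downstream_is_leftward(self):
        kept = make_reads({4600: 1}, strand="-")  # 400 nt downstream of gB
        dropped = make_reads({6100: 1}, strand="-")  # upstream of gB
        assert len(sites.restrict_to_gene_windows(kept, self.GENES, XRIP)) == 1
        assert len(sites.restrict_to_gene_windows(dropped, self.GENES, XRIP)) == 0

    def test_empty_output_allowed(self):
        reads = make_reads({100: 5})
        out = sites.restrict_to_gene_windows(reads, self.GENES, XRIP)
        assert len(out) == 0


class TestCallClusters:
    def test_worked_example_merging(self):
        reads = make_reads({100: 7, 103: 2, 130: 6, 160: 3})
        cl = sites.call_clusters(reads, None, ClusterParams())
        assert len(cl) == 1
        row = cl.iloc[0]
        assert (row.start, row.end, row.summit) == (85, 146, 100)

    def test_seed_at_exact_depth_six(self):
        cl = sites.call_clusters(make_reads({100: 6}), None, ClusterParams())
        assert len(cl) == 1
        assert cl.iloc[0].end - cl.iloc[0].start == 31

    def test_depth_split_across_samples_is_no_seed(self):
        reads = pd.concat([make_reads({100: 4}, sample="s1"), make_reads({100: 3}, sample="s2")])
        assert len(sites.call_clusters(reads, None, ClusterParams())) == 0

    def test_same_position_single_sample_is_seed(self):
        reads = make_reads({100: 7}, sample="s1")
        assert len(sites.call_clusters(reads, None, ClusterParams())) == 1

    def test_blacklisted_positions_contribute_no_depth(self):
        reads = make_reads({0: 10, 50: 7})
        masks = {("chr1", "+"): np.zeros(200, dtype=bool)}
        masks[("chr1", "+")][0] = True
        cl = sites.call_clusters(reads, masks, ClusterParams())
        assert len(cl) == 1 and cl.iloc[0].summit == 50

    def test_summit_tie_breaks_leftmost(self):
        reads = make_reads({100: 6, 101: 6})
        cl = sites.call_clusters(reads, None, ClusterParams())
        assert cl.iloc[0].summit == 100

    def test_abutting_intervals_merge(self):
        # seeds 31 apart -> [s-15, s+16) abut exactly
        reads = make_reads({100: 6, 131: 6})
        cl = sites.call_clusters(reads, None, ClusterParams())
        assert len(cl) == 1 and (cl.iloc[0].start, cl.iloc[0].end) == (85, 147)

    def test_strands_do_not_merge(self):
        reads = pd.concat([make_reads({100: 6}), make_reads({100: 6}, strand="-")])
        assert len(sites.call_clusters(reads, None, ClusterParams())) == 2

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for rep in range(50):
            n_pos = rng.integers(1, 60)
            positions = rng.integers(0, 500, size=n_pos)
            depths = rng.integers(1, 12, size=n_pos)
            sample_ids = rng.integers(0, 3, size=n_pos)
            rows = [
                ("chr1", int(p), "+", f"s{s}")
                for p, d, s in zip(positions, depths, sample_ids)
                for _ in range(d)
            ]
            reads = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "sample"])
            cl = sites.call_clusters(reads, None, ClusterParams())
            ref = brute_force_clusters(reads, 6, 15)
            got = [tuple(r) for r in cl[["chrom", "strand", "start", "end", "summit"]].to_numpy()]
            assert got == ref, f"rep {rep}"

    def test_lowering_seed_depth_grows_coverage_monotonically(self):
        # the raw cluster count is not monotone in seed_depth (extra seeds
        # can bridge two clusters into one); the covered positions are
        rng = np.random.default_rng(7)
        reads = pd.DataFrame(
            [("chr1", int(p), "+", "s1") for p in rng.integers(0, 400, size=600)],
            columns=["chrom", "pos", "strand", "sample"],
        )

        def covered(depth):
            cl = sites.call_clusters(reads, None, ClusterParams(seed_depth=depth))
            return {p for r in cl.itertuples(index=False) for p in range(r.start, r.end)}

        prev = None
        for depth in (12, 9, 6, 3, 1):
            cov = covered(depth)
            if prev is not None:
                assert cov >= prev
            prev = cov

    def test_widening_extension_never_increases_clusters(self):
        rng = np.random.default_rng(8)
        reads = pd.DataFrame(
            [("chr1", int(p), "+", "s1") for p in rng.integers(0, 400, size=800)],
            columns=["chrom", "pos", "strand", "sample"],
        )
        n_prev = None
        for ext in (2, 5, 15, 40):
            n = len(sites.call_clusters(reads, None, ClusterParams(extension=ext)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_no_seeds_gives_empty_frame(self):
        cl = sites.call_clusters(make_reads({100: 2}), None, ClusterParams())
        assert len(cl) == 0


class TestCountClusters:
    def test_counts_inside_only(self):
        reads = pd.concat([make_reads({90: 10}), make_reads({200: 2})])
        clusters = pd.DataFrame([dict(chrom="chr1", strand="+", start=85, end=116, summit=90)])
        out = sites.count_clusters(reads, clusters)
        assert out["s1"].iloc[0] == 10

    def test_read_at_end_not_counted(self):
        reads = make_reads({116: 1})
        clusters = pd.DataFrame([dict(chrom="chr1", strand="+", start=85, end=116, summit=90)])
        assert sites.count_clusters(reads, clusters)["s1"].iloc[0] == 0

    def test_read_at_start_counted(self):
        reads = make_reads({85: 1})
        clusters = pd.DataFrame([dict(chrom="chr1", strand="+", start=85, end=116, summit=90)])
        assert sites.count_clusters(reads, clusters)["s1"].iloc[0] == 1

    def test_overlapping_clusters_rejected(self):
        clusters = pd.DataFrame(
            [
                dict(chrom="chr1", strand="+", start=85, end=116, summit=90),
                dict(chrom="chr1", strand="+", start=100, end=140, summit=120),
            ]
        )
        with pytest.raises(ValueError, match="overlapping"):
            sites.count_clusters(make_reads({90: 1}), clusters)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(13)
        for rep in range(30):
            reads = pd.DataFrame(
                [
                    ("chr1", int(p), rng.choice(["+", "-"]), f"s{rng.integers(0, 3)}")
                    for p in rng.integers(0, 300, size=rng.integers(5, 80))
                ],
                columns=["chrom", "pos", "strand", "sample"],
            )
            cl = sites.call_clusters(reads, None, ClusterParams(seed_depth=2))
            if cl.empty:
                continue
            counted = sites.count_clusters(reads, cl)
            got = counted[sorted(reads["sample"].unique())].to_numpy()
            assert (got == brute_force_counts(reads, cl)).all(), f"rep {rep}"


class TestValidateClusters:
    CLUSTER = pd.DataFrame([dict(chrom="chr1", strand="+", start=85, end=146, summit=100)])

    @staticmethod
    def _v(pos, strand="+"):
        return pd.DataFrame([("chr1", pos, strand)], columns=["chrom", "pos", "strand"])

    def test_distant_end_removes_cluster(self):
        out = sites.validate_clusters(self.CLUSTER, self._v(200), ClusterParams())
        assert len(out) == 0

    def test_end_at_150_window_overlaps(self):
        # window [125, 176) intersects [85, 146)
        out = sites.validate_clusters(self.CLUSTER, self._v(150), ClusterParams())
        assert len(out) == 1 and bool(out["validated"].iloc[0])

    def test_touching_window_edge_removed_half_open(self):
        # validated end 171 -> window [146, 197); cluster ends at 146
        out = sites.validate_clusters(self.CLUSTER, self._v(171), ClusterParams())
        assert len(out) == 0

    def test_one_inside_window_edge_kept(self):
        out = sites.validate_clusters(self.CLUSTER, self._v(170), ClusterParams())
        assert len(out) == 1

    def test_strand_mismatch_removed(self):
        out = sites.validate_clusters(self.CLUSTER, self._v(100, "-"), ClusterParams())
        assert len(out) == 0

    def test_empty_validated_set_removes_all(self):
        empty = pd.DataFrame(columns=["chrom", "pos", "strand"])
        out = sites.validate_clusters(self.CLUSTER, empty, ClusterParams())
        assert len(out) == 0

    def test_idempotent(self):
        once = sites.validate_clusters(self.CLUSTER, self._v(150), ClusterParams())
        twice = sites.validate_clusters(once, self._v(150), ClusterParams())
        pd.testing.assert_frame_equal(once, twice)


class TestAssignClustersToGenes:
    GENES = pd.DataFrame(
        [
            dict(gene_id="gA", chrom="chr1", start=0, end=1000, strand="+", utr_start=500),
            dict(gene_id="gB", chrom="chr1", start=1040, end=1400, strand="+", utr_start=1200),
        ]
    )

    @staticmethod
    def _cluster(summit):
        return pd.DataFrame(
            [dict(chrom="chr1", strand="+", start=summit - 5, end=summit + 5, summit=summit, validated=True)]
        )

    def test_single_downstream_window(self):
        out = sites.assign_clusters_to_genes(self._cluster(1430), self.GENES, XRIP)
        assert out["gene"].iloc[0] == "gB"

    def test_nearest_three_prime_boundary_wins(self):
        # summit 1040: 41 bases from gA's 3' boundary (999), 359 from gB's (1399)
        out = sites.assign_clusters_to_genes(self._cluster(1040), self.GENES, XRIP)
        assert out["gene"].iloc[0] == "gA"

    def test_far_downstream_goes_to_downstream_window_owner(self):
        out = sites.assign_clusters_to_genes(self._cluster(1399), self.GENES, XRIP)
        assert out["gene"].iloc[0] == "gB"

    def test_unassignable_upstream_cluster_dropped(self):
        genes = self.GENES[self.GENES.gene_id == "gB"]
        out = sites.assign_clusters_to_genes(self._cluster(100), genes, XRIP)
        assert len(out) == 0


class TestFilterEfficacyOnTruth:
    def test_blacklist_removes_decoys_keeps_true_sites(self, small_dataset):
        reads = small_dataset["reads"]
        truth = small_dataset["truth"]
        ann_ends = truth.isoforms[["chrom", "end_pos", "strand"]].rename(columns={"end_pos": "pos"})
        masks = sites.compute_blacklist(small_dataset["genome"], ann_ends, XRIP)
        out = sites.apply_blacklist(reads, masks)
        decoy_before = (reads["origin"] == "decoy").sum()
        decoy_after = (out["origin"] == "decoy").sum()
        true_before = (reads["origin"] == "site").sum()
        true_after = (out["origin"] == "site").sum()
        assert 1 - decoy_after / decoy_before >= 0.95
        assert 1 - true_after / true_before <= 0.01
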