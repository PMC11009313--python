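"""Boundary windows, tag assignment, strength stratification, Fisher
enrichment and composition contrasts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clipsplice import diffbind, io, maxent, stratify
from clipsplice.crosslink import CrosslinkTag
from clipsplice.stratify import BoundarySite


def _toy_gtf(strand="+"):
    """One 2-exon gene: exon1 1-based 101-200, exon2 301-400 on a 500-nt
    contig."""
    rows = []
    for start, end in ((101, 200), (301, 400)):
        rows.append({
            "contig": "chr1", "source": "t", "feature": "exon",
            "start": start, "end": end, "score": ".", "strand": strand,
            "frame": ".", "gene_id": "g1", "transcript_id": "t1",
        })
    return pd.DataFrame(rows, columns=io.GTF_COLUMNS)


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(55)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=500))}


class TestExtractWindows:
    def test_plus_strand_windows_match_hand_slicing(self, toy_genome):
        sites = stratify.extract_boundary_windows(_toy_gtf("+"), toy_genome)
        seq = toy_genome["chr1"]
        by_side = {s.side: s for s in sites}
        assert set(by_side) == {"donor", "acceptor"}
        # donor: last 3 exonic (198-200) + first 6 intronic (201-206), 1-based
        assert by_side["donor"].window == seq[197:206]
        # acceptor: last 20 intronic (281-300) + first 3 exonic (301-303)
        assert by_side["acceptor"].window == seq[280:303]
        assert by_side["donor"].boundary == 199   # 0-based last exonic nt
        assert by_side["acceptor"].boundary == 300

    def test_minus_strand_windows_are_reverse_complemented(self, toy_genome):
        seq = toy_genome["chr1"]
        sites = {s.side: s for s in
                 stratify.extract_boundary_windows(_toy_gtf("-"), toy_genome)}
        # minus-strand donor sits at the genomic start of the right exon
        assert sites["donor"].window == io.reverse_complement(seq[294:303])
        assert sites["acceptor"].window == io.reverse_complement(seq[197:220])

    def test_window_relocates_to_recorded_coordinates(self, toy_annotation):
        """Round-trip: every extracted window re-slices from the genome at
        its recorded boundary coordinate (strand-aware)."""
        sites = stratify.extract_boundary_windows(toy_annotation.gtf, toy_annotation.genome)
        assert sites, "no windows extracted"
        seq = toy_annotation.genome["chrSim"]
        for s in sites:
            b = s.boundary
            if s.side == "donor":
                expected = (seq[b - 2:b + 7] if s.strand == "+"
                            else io.reverse_complement(seq[b - 6:b + 3]))
            else:
                expected = (seq[b - 20:b + 3] if s.strand == "+"
                            else io.reverse_complement(seq[b - 2:b + 21]))
            assert s.window == expected

    def test_short_intron_skipped_with_warning(self, toy_genome, caplog):
        gtf = _toy_gtf("+")
        gtf.loc[1, "start"] = 215  # intron 201-214: too short for acceptor 23-mer
        gtf.loc[1, "end"] = 320
        with caplog.at_level("WARNING"):
            sites = stratify.extract_boundary_windows(gtf, toy_genome)
        assert {s.side for s in sites} == {"donor"}
        assert "skipped" in caplog.text

    def test_overlapping_exons_rejected(self, toy_genome):
        gtf = _toy_gtf("+")
        gtf.loc[1, "start"] = 150
        with pytest.raises(ValueError, match="overlapping"):
            stratify.extract_boundary_windows(gtf, toy_genome)


class TestAssignTags:
    def _boundaries(self):
        return [
            BoundarySite("g1", "t1", "chr1", "donor", "+", 199, "N" * 9),
            BoundarySite("g1", "t1", "chr1", "acceptor", "+", 300, "N" * 23),
        ]

    def test_tag_at_junction_assigned(self):
        bs = self._boundaries()
        stats_ = stratify.assign_tags_to_boundaries(
            [CrosslinkTag("chr1", 199, "truncation", "s")], bs
        )
        assert stats_.n_assigned == 1 and bs[0].tag_counts == {"s": 1}

    def test_tag_just_outside_flank_unassigned(self):
        bs = self._boundaries()
        stats_ = stratify.assign_tags_to_boundaries(
            [CrosslinkTag("chr1", 199 + 11, "truncation", "s")], bs, flank=10
        )
        assert stats_.n_assigned == 0 and stats_.n_unassigned == 1

    def test_equidistant_tag_assigned_to_both(self):
        bs = [
            BoundarySite("g", "t", "chr1", "donor", "+", 100, "N" * 9),
            BoundarySite("g", "t", "chr1", "donor", "+", 110, "N" * 9),
        ]
        stats_ = stratify.assign_tags_to_boundaries(
            [CrosslinkTag("chr1", 105, "truncation", "s")], bs, flank=10
        )
        assert stats_.n_double_assigned == 1
        assert bs[0].tag_counts == {"s": 1} and bs[1].tag_counts == {"s": 1}

    def test_uniform_tags_assigned_at_flank_coverage_rate(self):
        """Uniform random tags hit the +/-flank neighbourhoods at roughly
        the fraction of the contig those windows cover."""
        rng = np.random.default_rng(8)
        L, flank = 100_000, 10
        bounds = [BoundarySite("g", "t", "chr1", "donor", "+", int(b), "N" * 9)
                  for b in np.linspace(1000, L - 1000, 40)]
        tags = [CrosslinkTag("chr1", int(p), "truncation", "s")
                for p in rng.integers(0, L, size=20_000)]
        res = stratify.assign_tags_to_boundaries(tags, bounds, flank=flank)
        expected = 40 * (2 * flank + 1) / L
        observed = res.n_assigned / res.n_tags
        assert abs(observed - expected) < 3 * np.sqrt(expected * (1 - expected) / 20_000)


class TestStratifiedFoldChanges:
    def _boundary(self, i, category, case, control):
        b = BoundarySite("g%d" % i, "t%d" % i, "chr1", "donor", "+", 100 + i, "N" * 9)
        b.category = category
        b.score = {"weak": 1.0, "intermediate": 5.0, "strong": 9.0}[category]
        b.tag_counts = {"case": case, "control": control}
        return b

    def test_all_intermediate_leaves_other_categories_empty(self):
        bs = [self._boundary(i, "intermediate", 20, 20) for i in range(5)]
        table, summaries = stratify.stratified_fold_changes(bs, "case", "control")
        assert (table["category"] == "intermediate").all()
        assert summaries["weak"] is None and summaries["strong"] is None

    def test_partition_conserves_boundary_count(self):
        rng = np.random.default_rng(5)
        cats = ["weak", "intermediate", "strong"]
        bs = [self._boundary(i, cats[i % 3], int(rng.integers(10, 50)),
                             int(rng.integers(10, 50))) for i in range(30)]
        table, _ = stratify.stratified_fold_changes(bs, "case", "control")
        assert len(table) == 30
        assert table.groupby("category")["site"].count().sum() == 30

    def test_planted_weak_enrichment_right_shifts_weak_category(self):
        """Case-enriched weak donors produce a weak-category fold-change
        distribution right-shifted against the strong category."""
        rng = np.random.default_rng(6)
        bs = []
        for i in range(40):
            base = int(rng.integers(40, 60))
            bs.append(self._boundary(i, "weak", base * 3, base))
        for i in range(40, 80):
            base = int(rng.integers(40, 60))
            bs.append(self._boundary(i, "strong", base, base))
        table, _ = stratify.stratified_fold_changes(bs, "case", "control")
        means = table.groupby("category")["log2fc"].mean()
        assert means["weak"] - means["strong"] > 1.0

    def test_order_invariance(self):
        bs = [self._boundary(i, "weak", 30 + i, 20) for i in range(6)]
        t1, _ = stratify.stratified_fold_changes(bs, "case", "control")
        t2, _ = stratify.stratified_fold_changes(list(reversed(bs)), "case", "control")
        assert sorted(t1["log2fc"]) == pytest.approx(sorted(t2["log2fc"]))


class TestFisherEnrichment:
    def test_matches_hypergeometric_enumeration(self):
        """2x2 table (5,5,5,85): two-sided p equals the sum of hypergeometric
        point masses no larger than the observed one."""
        selected = {f"s{i}" for i in range(10)}
        background = selected | {f"b{i}" for i in range(90)}
        gene_set = {f"s{i}" for i in range(5)} | {f"b{i}" for i in range(5)}
        res = stratify.fisher_enrichment(selected, background, {"gs": gene_set})[0]
        assert res.table == (5, 5, 5, 85)
        # independent oracle: enumerate the hypergeometric support
        N, K, n = 100, 10, 10  # universe, set size, selected size
        probs = [sps.hypergeom.pmf(k, N, K, n) for k in range(0, min(K, n) + 1)]
        observed = sps.hypergeom.pmf(5, N, K, n)
        p_oracle = sum(p for p in probs if p <= observed * (1 + 1e-9))
        assert res.p == pytest.approx(p_oracle, rel=1e-9)

    def test_null_pvalues_roughly_uniform(self):
        """Selected genes drawn uniformly from the background give p-values
        passing a KS uniformity check at alpha = 0.01."""
        rng = np.random.default_rng(10)
        background = {f"g{i}" for i in range(2000)}
        gene_set = {f"g{i}" for i in range(200)}
        pvals = []
        for _ in range(200):
            selected = set(rng.choice(sorted(background), size=200, replace=False))
            res = stratify.fisher_enrichment(selected, background, {"gs": gene_set})
            pvals.append(res[0].p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_selected_equals_gene_set_is_extreme(self):
        selected = {f"s{i}" for i in range(20)}
        background = selected | {f"b{i}" for i in range(480)}
        res = stratify.fisher_enrichment(selected, background, {"gs": set(selected)})[0]
        assert res.p < 1e-10 and res.odds_ratio > 1

    def test_bh_adjustment_across_sets(self):
        selected = {f"s{i}" for i in range(10)}
        background = selected | {f"b{i}" for i in range(190)}
        sets = {"hit": set(selected), "miss1": {"b1", "b2"}, "miss2": {"b3", "b4"}}
        results = {r.gene_set: r for r in
                   stratify.fisher_enrichment(selected, background, sets)}
        assert all(r.p_adj >= r.p for r in results.values())

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="empty background"):
            stratify.fisher_enrichment(set(), set(), {})
        with pytest.raises(ValueError, match="subset"):
            stratify.fisher_enrichment({"x"}, {"y"}, {})


class TestCompositionContrast:
    def test_identical_sets_no_difference(self):
        seqs = ["ACGTACGTA", "TTGCATGCA"]
        res = stratify.composition_contrast(seqs, seqs, n_boot=50)
        assert (res.per_position["diff"] == 0).all()
        assert (res.aggregate["diff"] == 0).all()

    def test_extreme_t_versus_c_sets(self):
        res = stratify.composition_contrast(["TTTT"] * 5, ["CCCC"] * 5, n_boot=50)
        agg = res.aggregate.set_index("base")
        assert agg.loc["T", "diff"] == pytest.approx(1.0)
        assert agg.loc["C", "diff"] == pytest.approx(-1.0)

    def test_planted_thymidine_excess_recovered_within_ci(self):
        """A planted 10% T excess in the up set falls inside the bootstrap
        CI of the aggregate T-fraction difference."""
        rng = np.random.default_rng(14)
        def draw(p_t, n):
            probs = [(1 - p_t) / 3] * 3 + [p_t]
            return ["".join(rng.choice(list("ACGT"), size=50, p=probs))
                    for _ in range(n)]
        up, down = draw(0.35, 200), draw(0.25, 200)
        res = stratify.composition_contrast(up, down, n_boot=500, seed=3)
        t_row = res.aggregate.set_index("base").loc["T"]
        assert t_row["ci_low"] <= 0.10 <= t_row["ci_high"]

    def test_unequal_lengths_skip_per_position_only(self):
        res = stratify.composition_contrast(["ACGT", "ACGTA"], ["TTTT"], n_boot=20)
        assert res.per_position is None
        assert not res.aggregate.empty

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            stratify.composition_contrast([], ["ACGT"])


class TestScoreBoundaries:
    def test_scores_and_categories_attached_per_side(self, donor_sets, toy_annotation):
        signal, decoy = donor_sets
        donor_model = maxent.fit_maxent(signal)
        sites = stratify.extract_boundary_windows(toy_annotation.gtf, toy_annotation.genome)
        scored = stratify.score_boundaries(sites, donor_model=donor_model)
        donors = [s for s in scored if s.side == "donor"]
        acceptors = [s for s in scored if s.side == "acceptor"]
        assert donors and all(s.score is not None and s.category is not None
                              for s in donors)
        assert all(s.score is None for s in acceptors)  # no acceptor model given
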