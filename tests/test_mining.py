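"""Window expansion, locus classification, group assignment, count tables."""

import numpy as np
import pytest

from retromine import simulate
from retromine.mining import (
    INDIVIDUAL_RNH,
    LTR_RT,
    NONLTR_RT,
    CandidateLocus,
    assign_group,
    classify_locus,
    count_table,
    expand_window,
    merge_anchor_windows,
    mine_fmrnh,
    mine_genome,
    render_count_tsv,
)
from retromine.profiles import DomainHit


def make_anchor(start, end, score=100.0, frame=1, profile="aRNH", target="g"):
    return DomainHit(
        profile_name=profile, target_id=target, frame=frame,
        protein_start=0, protein_end=(end - start) // 3, score=score,
        genome_start=start, genome_end=end,
    )


def background(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestExpandWindow:
    def test_interior_anchor_gets_full_flanks(self):
        assert expand_window(make_anchor(12_000, 12_450), 30_000) == (2_000, 22_450)

    def test_left_clamp(self):
        assert expand_window(make_anchor(500, 800), 30_000) == (0, 10_800)

    def test_double_clamp_on_short_contig(self):
        assert expand_window(make_anchor(100, 200), 250) == (0, 250)


class TestMergeAnchorWindows:
    def _locus(self, anchor, genome_length=50_000):
        return CandidateLocus("g", anchor, expand_window(anchor, genome_length))

    def test_nearby_but_distinct_anchors_stay_separate(self):
        a = self._locus(make_anchor(10_000, 10_450))
        b = self._locus(make_anchor(10_550, 11_000))
        assert len(merge_anchor_windows([a, b])) == 2

    def test_duplicate_anchor_across_frames_collapses(self):
        a = self._locus(make_anchor(10_000, 10_450, score=90.0, frame=1))
        b = self._locus(make_anchor(10_001, 10_451, score=95.0, frame=2))
        merged = merge_anchor_windows([a, b])
        assert len(merged) == 1
        assert merged[0].anchor.score == 95.0

    def test_empty_input(self):
        assert merge_anchor_windows([]) == []

    def test_anchor_contained_in_window(self):
        for locus in merge_anchor_windows([self._locus(make_anchor(3_000, 3_450))]):
            ws, we = locus.window
            gs, ge = locus.anchor.genome_interval()
            assert ws <= gs and ge <= we


@pytest.fixture(scope="module")
def coding():
    rng = np.random.default_rng(11)
    dom = simulate.default_domain_templates()
    return {
        name: simulate.backtranslate(rng, dom[name].protein)
        for name in ("RT_LTR_Chronos", "RT_nonLTR_L1", "aRNH_cellular")
    }


@pytest.fixture(scope="module")
def references():
    return simulate.group_references()


@pytest.fixture(scope="module")
def mined(profiles):
    plan = [
        simulate.PlantSpec("Chronos", 1, 0.05),
        simulate.PlantSpec("L1", 1, 0.05),
        simulate.PlantSpec("aRNH_gene", 1, 0.05),
    ]
    seq, truth = simulate.build_genome(plan, 60_000, seed=99, genome_id="g")
    loci = mine_genome(
        "g", seq, profiles["aRNH"], profiles["RT_LTR"], profiles["RT_nonLTR"],
        simulate.group_references(), chd_profile=profiles["CHD"],
    )
    return loci, truth


class TestClassifyLocus:
    def test_ltr_rt_window(self, profiles, coding, rng):
        window = background(rng, 2_000) + coding["RT_LTR_Chronos"] + background(rng, 2_000)
        label, hits = classify_locus(window, profiles["RT_LTR"], profiles["RT_nonLTR"])
        assert label == LTR_RT
        assert hits and hits[0].profile_name == "RT_LTR"

    def test_nonltr_rt_window(self, profiles, coding, rng):
        window = background(rng, 2_000) + coding["RT_nonLTR_L1"] + background(rng, 2_000)
        label, hits = classify_locus(window, profiles["RT_LTR"], profiles["RT_nonLTR"])
        assert label == NONLTR_RT
        assert hits and hits[0].profile_name == "RT_nonLTR"

    def test_rt_free_window_is_individual(self, profiles, coding, rng):
        window = background(rng, 2_000) + coding["aRNH_cellular"] + background(rng, 2_000)
        label, hits = classify_locus(window, profiles["RT_LTR"], profiles["RT_nonLTR"])
        assert label == INDIVIDUAL_RNH
        assert hits == []


class TestAssignGroup:
    def test_diverged_chronos_copy_assigned(self, references, rng):
        protein = simulate._variant(rng, references["Chronos"], 0.05)
        assert assign_group(protein, references, chd_present=True) == "Chronos"

    def test_chd_absence_flips_to_archon(self, references, rng):
        protein = simulate._variant(rng, references["Archon"], 0.05)
        assert assign_group(protein, references, chd_present=False) == "Archon"

    def test_utopia_copy_assigned(self, references, rng):
        protein = simulate._variant(rng, references["Utopia"], 0.05)
        assert assign_group(protein, references) == "Utopia"

    def test_background_orf_unassigned(self, references, rng):
        from retromine.profiles import AMINO_ACIDS, BACKGROUND

        decoy = "".join(rng.choice(list(AMINO_ACIDS), size=400, p=BACKGROUND))
        assert assign_group(decoy, references) == "unassigned"

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            assign_group("MKV", {})


class TestMineFmrnh:
    def test_planted_gene_recovered_with_1kb_flanks(self, profiles, rng):
        gene = simulate.default_element_templates()["fmRNH_gene"].nt
        genome = background(rng, 20_000)
        genome = genome[:8_000] + gene + genome[8_000:]
        loci = mine_fmrnh("g", genome, profiles["fmRNH"])
        assert len(loci) == 1
        locus = loci[0]
        assert locus.classification == INDIVIDUAL_RNH
        assert locus.group == "fmRNH"
        gs, ge = locus.anchor.genome_interval()
        assert locus.window == (gs - 1_000, ge + 1_000)

    def test_genome_without_fmrnh_is_empty(self, profiles, rng):
        assert mine_fmrnh("g", background(rng, 15_000), profiles["fmRNH"]) == []

    def test_flank_clamped_at_contig_edge(self, profiles, rng):
        gene = simulate.default_element_templates()["fmRNH_gene"].nt
        genome = gene + background(rng, 5_000)
        loci = mine_fmrnh("g", genome, profiles["fmRNH"])
        assert len(loci) == 1
        assert loci[0].window[0] == 0


class TestCountTable:
    def _loci(self, spec):
        """spec: list of (genome, classification, group)"""
        out = []
        for i, (gid, cls, group) in enumerate(spec):
            anchor = make_anchor(1_000 * (i + 1), 1_000 * (i + 1) + 450, target=gid)
            out.append(
                CandidateLocus(gid, anchor, (anchor.genome_start - 100,
                                             anchor.genome_end + 100),
                               classification=cls, group=group)
            )
        return out

    def test_counts_match_planted_composition(self):
        loci = self._loci(
            [("g1", LTR_RT, "Chronos")] * 3
            + [("g1", NONLTR_RT, "L1")] * 2
            + [("g1", INDIVIDUAL_RNH, "fmRNH")]
        )
        table = count_table(loci)
        assert table.at["g1", "Chronos"] == 3
        assert table.at["g1", "L1"] == 2
        assert table.at["g1", "fmRNH"] == 1
        assert table.at["g1", "Archon"] == 0

    def test_row_sums_equal_locus_counts(self):
        loci = self._loci(
            [("g1", LTR_RT, "Archon")] * 2 + [("g2", INDIVIDUAL_RNH, "aRNH-novel-1")]
        )
        table = count_table(loci)
        assert table.loc["g1"].sum() == 2
        assert table.loc["g2"].sum() == 1

    def test_empty_loci_preserve_genome_rows(self):
        table = count_table([], genome_ids=["g1", "g2"])
        assert list(table.index) == ["g1", "g2"]
        assert (table.to_numpy() == 0).all()

    def test_disjoint_plants_give_block_counts(self):
        loci = self._loci(
            [("g1", LTR_RT, "Chronos")] * 2 + [("g2", NONLTR_RT, "Utopia")] * 3
        )
        table = count_table(loci)
        assert table.at["g1", "Chronos"] == 2 and table.at["g1", "Utopia"] == 0
        assert table.at["g2", "Utopia"] == 3 and table.at["g2", "Chronos"] == 0

    def test_independent_recount(self):
        spec = (
            [("g1", LTR_RT, "Chronos")] * 2
            + [("g1", NONLTR_RT, "L1")]
            + [("g2", INDIVIDUAL_RNH, "fmRNH")] * 2
        )
        loci = self._loci(spec)
        table = count_table(loci)
        for gid in table.index:
            for cat in table.columns:
                expected = sum(1 for g, _, grp in spec if g == gid and grp == cat)
                assert table.at[gid, cat] == expected

    def test_tsv_renders_zero_as_dash(self, tmp_path):
        loci = self._loci([("g1", LTR_RT, "Chronos")])
        path = tmp_path / "counts.tsv"
        render_count_tsv(count_table(loci), path)
        body = path.read_text().splitlines()[1]
        assert "\t-" in body and "\t1" in body


class TestMineGenomeInvariants:
    """Partition/exclusivity invariants on a compact simulated genome."""

    def test_every_anchor_in_exactly_one_locus(self, mined):
        loci, truth = mined
        assert len(loci) == len(truth)

    def test_individual_iff_no_rt_hits(self, mined):
        loci, _ = mined
        for locus in loci:
            assert (locus.classification == INDIVIDUAL_RNH) == (not locus.rt_hits)

    def test_classifications_match_planted_groups(self, mined):
        loci, truth = mined
        expected = {
            "Chronos": LTR_RT, "L1": NONLTR_RT, "aRNH_gene": INDIVIDUAL_RNH,
        }
        by_pos = sorted(loci, key=lambda l: l.anchor.genome_start)
        truth_sorted = sorted(truth, key=lambda t: t.start)
        for locus, rec in zip(by_pos, truth_sorted):
            assert locus.classification == expected[rec.group]
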