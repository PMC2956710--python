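"""Tag extraction, filter cascade, accounting and tag-to-gene mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sagekit import synth, tagproc
from sagekit.tagproc import (
    ANCHOR,
    DitagRead,
    LibraryComposition,
    TagCountTable,
    TagObservation,
    build_tag_map,
    canonical_tag,
    classify_tag_mapping,
    count_duplicate_ditags,
    extract_tags,
    filter_bad_tags,
    normalize_cpm,
    phred_qf,
    quality_filter,
    remove_ldts,
    revcomp,
)

TAG_A = "ACGTACGTACGTACGTA"
TAG_B = "TTTTCCCCGGGGAAAAT"


def make_ditag_read(tag1, tag2, q=40, read_id="d0", lib="L1"):
    seq = ANCHOR + tag1 + revcomp(tag2) + ANCHOR
    return DitagRead(read_id, seq, [q] * len(seq), lib)


class TestExtractTags:
    def test_one_ditag_yields_two_oriented_tags(self):
        obs, ledger = extract_tags([make_ditag_read(TAG_A, TAG_B)])
        assert [o.tag for o in obs] == [TAG_A, TAG_B]
        assert sum(ledger.values()) == 1

    def test_short_read_skipped_not_fatal(self):
        short = DitagRead("s", ANCHOR + "ACGT", [40] * 8, "L1")
        obs, _ = extract_tags([short, make_ditag_read(TAG_A, TAG_B)])
        assert len(obs) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            extract_tags([])

    def test_duplicate_ledger_counts_exact_repeats(self):
        reads = [make_ditag_read(TAG_A, TAG_B, read_id=f"d{i}") for i in range(10)]
        uniq = [
            make_ditag_read(TAG_A, t, read_id=f"u{i}")
            for i, t in enumerate(_random_tags(90))
        ]
        _, ledger = extract_tags(reads + uniq)
        n_dup, _ = count_duplicate_ditags(ledger)
        assert n_dup == 9  # 10 copies of one ditag = 9 beyond the first

    def test_five_copies_count_four_duplicates(self):
        n_dup, _ = count_duplicate_ditags({"X" * 34: 5})
        assert n_dup == 4

    def test_all_distinct_is_zero(self):
        reads = [
            make_ditag_read(TAG_A, t, read_id=f"u{i}")
            for i, t in enumerate(_random_tags(20))
        ]
        _, ledger = extract_tags(reads)
        assert count_duplicate_ditags(ledger) == (0, 0.0)


def _random_tags(n, seed=0):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list("ACGT"), 17)) for _ in range(n)]


class TestFilters:
    def test_bad_tag_rule(self):
        clean = TagObservation(TAG_A, 1.0, "d0")
        bad = TagObservation("ACGTNCGTACGTACGTA", 1.0, "d1")
        kept, removed = filter_bad_tags([clean, bad])
        assert [o.tag for o in kept] == [TAG_A] and removed == 1

    def test_qf_closed_forms(self):
        # 17 bases at Q=40: (1 - 1e-4)^17 ~ 0.99830 -> kept
        hi = TagObservation(TAG_A, phred_qf([40] * 17), "d0")
        # 17 bases at Q=20: 0.99^17 ~ 0.84294 -> removed
        lo = TagObservation(TAG_B, phred_qf([20] * 17), "d1")
        assert hi.qf == pytest.approx((1 - 1e-4) ** 17, rel=1e-12)
        assert lo.qf == pytest.approx(0.99**17, rel=1e-12)
        kept, removed, mean_qf = quality_filter([hi, lo], threshold=0.95)
        assert [o.tag for o in kept] == [TAG_A] and removed == 1
        assert mean_qf == pytest.approx((hi.qf + lo.qf) / 2)

    @settings(derandomize=True, max_examples=50)
    @given(
        quals=st.lists(st.integers(2, 40), min_size=17, max_size=17),
        pos=st.integers(0, 16),
        drop=st.integers(1, 10),
    )
    def test_qf_monotone_in_per_base_quality(self, quals, pos, drop):
        lowered = list(quals)
        lowered[pos] = max(lowered[pos] - drop, 0)
        assert phred_qf(lowered) <= phred_qf(quals) + 1e-15

    def test_ldt_removal_counts_by_type(self):
        linker1, linker2 = "A" * 17, "C" * 17
        table = TagCountTable("L1", {TAG_A: 10, linker1: 3, linker2: 2})
        cleaned, n1, n2 = remove_ldts(table, {linker1}, {linker2})
        assert (n1, n2) == (3, 2)
        assert cleaned.counts == {TAG_A: 10}

    def test_ldt_no_match_unchanged(self):
        table = TagCountTable("L1", {TAG_A: 10})
        cleaned, n1, n2 = remove_ldts(table, {"G" * 17}, {"T" * 17})
        assert cleaned.counts == table.counts and (n1, n2) == (0, 0)


class TestComposition:
    def test_accounting_identity_from_stage_counts(self):
        comp = LibraryComposition.from_stage_counts(
            "L", unfiltered_total=1000, n_bad=10, n_duplicate_ditags=50,
            n_below_qf=200, n_ldt_type1=5, n_ldt_type2=5,
        )
        assert comp.total_minus_bad == 990
        assert comp.total_q95 == 790
        assert comp.final_total == 780
        assert comp.unfiltered_total == (
            comp.final_total + comp.n_bad + comp.n_below_qf
            + comp.n_ldt_type1 + comp.n_ldt_type2
        )

    def test_inconsistent_stage_outputs_rejected(self):
        table = TagCountTable("L", {TAG_A: 5})
        with pytest.raises(ValueError):
            tagproc.build_library_composition(
                "L", unfiltered_total=100, n_bad=0, post_bad=table,
                n_duplicate_ditags=0, n_below_qf=0, mean_qf=1.0,
                post_qf=table, n_ldt_type1=0, n_ldt_type2=0, final=table,
            )

    def test_zero_contaminant_round_trip(self, clean_read_atlas):
        """Contamination-free reads reproduce the generating counts exactly."""
        reads, _ = synth.generate_raw_ditags(clean_read_atlas)
        for (rep, stage), table in clean_read_atlas.libraries.items():
            final, comp = tagproc.process_library(reads[table.library_id], table.library_id)
            assert final.counts == table.counts
            assert comp.final_total == comp.unfiltered_total == clean_read_atlas.config.library_size
            assert comp.n_bad == comp.n_below_qf == 0

    def test_filter_order_stability(self):
        """Bad-tag, QF and LDT criteria are per-observation, so applying
        QF before the bad-tag filter passes the same joint survivor set."""
        rng = np.random.default_rng(5)
        obs = []
        for i, tag in enumerate(_random_tags(50, seed=1)):
            if rng.random() < 0.2:
                tag = tag[:8] + "N" + tag[9:]
            q = [int(rng.integers(15, 41)) for _ in range(17)]
            obs.append(TagObservation(tag, phred_qf(q), f"d{i}"))
        a, _ = filter_bad_tags(obs)
        a, _, _ = quality_filter(a)
        b, _, _ = quality_filter(obs)
        b, _ = filter_bad_tags(b)
        assert [o.tag for o in a] == [o.tag for o in b]


class TestCpm:
    def test_arithmetic(self):
        table = TagCountTable("L", {TAG_A: 100, TAG_B: 249_900})
        cpm = normalize_cpm(table)
        assert cpm[TAG_A] == pytest.approx(400.0)
        assert sum(cpm.values()) == pytest.approx(1e6)

    def test_single_tag_gets_everything(self):
        assert normalize_cpm(TagCountTable("L", {TAG_A: 7}))[TAG_A] == 1e6

    def test_round_trip_to_integers(self):
        table = TagCountTable("L", {t: c for t, c in zip(_random_tags(5), (1, 10, 100, 7, 82))})
        cpm = normalize_cpm(table)
        total = table.total_tags
        for t, c in table.counts.items():
            assert round(cpm[t] * total / 1e6) == c

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            normalize_cpm(TagCountTable("L", {}))


class TestTagMap:
    def test_canonical_tag_after_rightmost_anchor(self):
        assert canonical_tag("AAACATG" + "T" * 17 + "G") == "T" * 17
        assert canonical_tag("CATG" + "A" * 17 + "CATG" + "C" * 17) == "C" * 17
        # 3'-most site without 17 downstream bases falls back to the previous one
        assert canonical_tag("CATG" + "A" * 17 + "CATGGG") == "A" * 17
        assert canonical_tag("ACGTACGT") is None

    def test_ambiguous_and_host_classes(self):
        shared = "G" * 17
        human = [("GENE1", "AAT" + ANCHOR + shared), ("GENE2", "TTA" + ANCHOR + shared)]
        host_only = "ACACACACACACACACA"
        tmap = build_tag_map(human, host_transcripts=[("mGene", "CCT" + ANCHOR + host_only)])
        assert tmap.class_of(shared) == "ambiguous"
        assert tmap.class_of(host_only) == "host"

    def test_unique_sense_and_antisense(self):
        tmap = build_tag_map([("GENE1", "TTA" + ANCHOR + TAG_A)])
        assert tmap.class_of(TAG_A) == "unique_sense"
        assert tmap.gene_of(TAG_A) == "GENE1"
        anti = canonical_tag(revcomp("TTA" + ANCHOR + TAG_A))
        if anti is not None:
            assert tmap.class_of(anti) in ("antisense", "unique_sense")

    def test_synthetic_transcripts_recover_planted_classes(self, balanced_atlas):
        human, host = synth.generate_transcripts(balanced_atlas)
        rebuilt = build_tag_map(human, host_transcripts=host)
        truth = balanced_atlas.tag_map
        checked = 0
        for tag, cls in truth.mapping_class.items():
            if cls in ("unique_sense", "ambiguous", "host"):
                assert rebuilt.class_of(tag) == cls, tag
                checked += 1
        assert checked > 50

    def test_funnel_summary(self):
        tmap = build_tag_map(
            [("GENE1", "TTA" + ANCHOR + TAG_A), ("GENE2", "AAT" + ANCHOR + TAG_B)]
        )
        unseen = "ATATATATATATATATA"
        classes, funnel = classify_tag_mapping([TAG_A, TAG_B, unseen], tmap)
        assert classes[unseen] == "no_map"
        assert funnel["n_relevant"] == 3          # no_map is still relevant
        assert funnel["n_candidate_genes"] == 2   # but contributes no gene

    def test_empty_funnel(self):
        _, funnel = classify_tag_mapping([], build_tag_map([("G", "T" + ANCHOR + TAG_A)]))
        assert funnel["n_input"] == 0 and funnel["n_candidate_genes"] == 0


def test_fastq_round_trip(tmp_path):
    reads = [make_ditag_read(TAG_A, TAG_B, q=33, read_id="r1")]
    synth.write_fastq(reads, tmp_path / "x.fastq")
    back = tagproc.read_fastq(tmp_path / "x.fastq", "L1")
    assert back[0].sequence == reads[0].sequence
    assert list(back[0].qualities) == list(reads[0].qualities)
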