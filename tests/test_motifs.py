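"""Motif annotation, IUPAC rescanning and the motif/non-motif position test."""

import numpy as np
import pandas as pd
import pytest

from corepromoter.motifs import (
    MotifDef,
    annotate_motifs,
    default_catalogue,
    iupac_match,
    motif_distribution_test,
    read_catalogue,
    rescan_motif,
    scan_consensus,
    write_catalogue,
)
from corepromoter.variants import CohortVariant, VariantKey


def mut(rel_pos, ref="A", alt="G", gene="g1", carriers=2, var_class="somatic", pos=None):
    return CohortVariant(
        key=VariantKey("chr1", pos or (1000 + rel_pos), ref, alt),
        gene_id=gene,
        rel_pos=rel_pos,
        carriers=frozenset(f"S{i}" for i in range(carriers)),
        db_flags={},
        var_class=var_class,
    )


def by_name(catalogue, name):
    return next(m for m in catalogue if m.name == name)


class TestCatalogue:
    def test_default_names_are_the_standard_vocabulary(self):
        names = {m.name for m in default_catalogue()}
        assert {"TATA box", "BREu", "BREd", "Inr", "DPE", "MTE_box1",
                "MTE_box2", "DCE_box1", "DCE_box2", "DCE_box3", "TCT",
                "XCPE1", "XCPE2", "Ets", "SP1", "E-Box", "TCF", "DTIE"} == names

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "cat.tsv"
        write_catalogue(default_catalogue(), path)
        assert read_catalogue(path) == default_catalogue()

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            MotifDef("bad", 10, 5)
        with pytest.raises(ValueError, match="IUPAC"):
            MotifDef("bad", 1, 5, "AXG")


class TestIupac:
    @pytest.mark.parametrize(
        "consensus,seq,expected",
        [
            ("RGWYV", "AGATG", True),
            ("RGWYV", "AGGTG", False),  # W excludes G
            ("CANNTG", "CACGTG", True),
            ("TATAWAWR", "TATAAAAG", True),
        ],
    )
    def test_match(self, consensus, seq, expected):
        assert iupac_match(consensus, seq) is expected

    def test_scan_finds_all_offsets(self):
        assert scan_consensus("ANT", "AATACTGAGT") == [0, 3, 7]


class TestAnnotate:
    def test_variant_in_dpe_window(self):
        hits, table = annotate_motifs([mut(28)], default_catalogue())
        assert "DPE" in {h.motif_name for h in hits}
        assert table.set_index("motif").loc["DPE", "somatic_count"] == 1

    def test_variant_hits_custom_bred_window(self):
        cat = [MotifDef("BREd", -45, -38, "")]
        hits, _ = annotate_motifs([mut(-41)], cat)
        assert [h.motif_name for h in hits] == ["BREd"]

    def test_position_without_motif_has_no_hit(self):
        hits, table = annotate_motifs([mut(90)], default_catalogue())
        assert hits == []
        assert (table.somatic_count == 0).all()

    def test_count_table_zero_filled_per_motif(self):
        _, table = annotate_motifs([mut(28)], default_catalogue())
        assert len(table) == len(default_catalogue())

    def test_deletion_interval_spans_ref_allele(self):
        # deletion anchored at +25 whose ref spans into the DPE window (+28..+32)
        deletion = mut(25, ref="ACTG", alt="A")
        hits, _ = annotate_motifs([deletion], default_catalogue())
        assert "DPE" in {h.motif_name for h in hits}

    def test_insertion_affects_anchor_only(self):
        insertion = mut(25, ref="A", alt="ACTGG")
        hits, _ = annotate_motifs([insertion], default_catalogue())
        assert "DPE" not in {h.motif_name for h in hits}

    def test_order_independent(self):
        muts = [mut(28), mut(-30, gene="g2"), mut(2, gene="g3")]
        _, t1 = annotate_motifs(muts, default_catalogue())
        _, t2 = annotate_motifs(muts[::-1], default_catalogue())
        pd.testing.assert_frame_equal(t1, t2)

    def test_recurrence_mode_weights_by_carriers(self):
        muts = [mut(28, carriers=5)]
        _, pair = annotate_motifs(muts, default_catalogue(), count_mode="pair")
        _, rec = annotate_motifs(muts, default_catalogue(), count_mode="recurrence")
        assert pair.set_index("motif").loc["DPE", "somatic_count"] == 1
        assert rec.set_index("motif").loc["DPE", "somatic_count"] == 5

    def test_consensus_scan_motif_needs_sequence(self):
        seq = "T" * 94 + "GGGCGG" + "T" * 101  # SP1 word ending just before TSS
        hits, _ = annotate_motifs(
            [mut(-3, gene="g1")], default_catalogue(), sequences={"g1": seq}
        )
        assert "SP1" in {h.motif_name for h in hits}
        hits_noseq, _ = annotate_motifs([mut(-3, gene="g1")], default_catalogue())
        assert "SP1" not in {h.motif_name for h in hits_noseq}

    def test_empty_catalogue_is_error(self):
        with pytest.raises(ValueError):
            annotate_motifs([mut(28)], [])


class TestRescan:
    def test_identity_sequences_return_null(self):
        dpe = by_name(default_catalogue(), "DPE")
        seq = "ACGT" * 51
        assert rescan_motif(seq[:201], seq[:201], dpe) is None

    def test_no_match_anywhere_returns_null(self):
        dpe = by_name(default_catalogue(), "DPE")
        ref = "C" * 201
        alt = "C" * 100 + "T" + "C" * 100
        assert rescan_motif(ref, alt, dpe) is None

    def test_dpe_shift_from_fixture(self, fixture_dir):
        sdf = pd.read_csv(fixture_dir["dpe_sequences"], sep="\t")
        seqs = dict(zip(sdf.gene_id, sdf.sequence))
        dpe = by_name(default_catalogue(), "DPE")
        change = rescan_motif(seqs["FTH1L_ref"], seqs["FTH1L_alt"], dpe, gene_id="FTH1L")
        assert change is not None
        assert (change.kind, change.ref_rel_pos, change.alt_rel_pos) == ("shifted", 30, 26)

    def test_abolished_and_created(self):
        dpe = by_name(default_catalogue(), "DPE")
        with_match = "C" * 129 + "AGATG" + "C" * 67  # match at +30 (index 129)
        without = "C" * 201
        gone = rescan_motif(with_match, without, dpe)
        assert gone.kind == "abolished" and gone.ref_rel_pos == 30
        born = rescan_motif(without, with_match, dpe)
        assert born.kind == "created" and born.alt_rel_pos == 30

    def test_rescan_requires_consensus(self):
        with pytest.raises(ValueError, match="consensus"):
            rescan_motif("A" * 201, "C" * 201, MotifDef("TCT", -2, 6, ""))


class TestDistributionTest:
    def test_identical_counts_give_p_one(self):
        muts = []
        t, p = motif_distribution_test(muts, default_catalogue())
        assert t == 0.0 and p == 1.0

    def test_motif_concentration_is_significant(self):
        # pile mutations onto motif positions (DPE +28..+32), none elsewhere,
        # with spread between positions so variances are nonzero
        cat = [MotifDef("DPE", 28, 32, "RGWYV")]
        muts = [
            mut(rel, gene=f"g{i}", pos=1000 + i)
            for i, rel in enumerate([28, 29, 30, 31, 32] * 20 + [28] * 10)
        ]
        t, p = motif_distribution_test(muts, cat)
        assert t > 0 and p < 0.05

    def test_single_group_is_error(self):
        whole_window = [MotifDef("all", -100, 101, "")]
        with pytest.raises(ValueError):
            motif_distribution_test([], whole_window)
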