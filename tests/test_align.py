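"""Trimming, placement, classification, naming and counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import random_dna, tiered_hits
from tsrnakit.align import (ConfigError, CoordinateError, FragmentAligner,
                            NamingError, TsrnaIdError, aggregate_counts,
                            align_fragment, call_species, classify_subtype,
                            name_tsrna, parse_tsrna_id, profile_fastqs,
                            trim_adapter)

ADAPTER = "AGATCGGAAGAGCACACGTCT"


class TestTrimAdapter:
    def test_returns_insert_before_adapter(self):
        insert = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        read = (insert + ADAPTER + "TTTTTTTTT")[:50]
        assert trim_adapter(read, ADAPTER) == (insert, "ok")

    def test_read_without_adapter_rejected(self):
        assert trim_adapter("A" * 50, ADAPTER) == (None, "no_adapter")

    def test_insert_length_bounds_enforced(self):
        short = ("ACGTACGTACGTA" + ADAPTER + "A" * 30)[:50]   # 13 nt insert
        assert trim_adapter(short, ADAPTER)[1] == "insert_length"
        long = ("A" * 41 + ADAPTER)[:50]
        assert trim_adapter(long, ADAPTER)[1] == "insert_length"

    def test_short_adapter_is_config_error(self):
        with pytest.raises(ConfigError):
            trim_adapter("A" * 50, "ACGTA")

    def test_leftmost_adapter_occurrence_wins(self):
        key = ADAPTER[:8]
        read = ("T" * 20 + key + "C" * 5 + key + "G" * 40)[:50]
        assert trim_adapter(read, ADAPTER) == ("T" * 20, "ok")


class TestAlignFragment:
    def test_exact_prefix_maps_at_start(self, pro_agg_family):
        refs = pro_agg_family
        insert = refs.matures["Pro-AGG-1"].seq[:22]
        hits = align_fragment(insert, refs)
        assert {(h.start, h.end, h.mismatches, h.source) for h in hits} \
            == {(1, 22, 0, "mature")}
        assert len(hits) == 4  # all four identical isodecoders

    def test_one_mismatch_tier_used_when_no_exact(self, pro_agg_family):
        refs = pro_agg_family
        insert = list(refs.matures["Pro-AGG-1"].seq[:22])
        insert[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[insert[10]]
        hits = align_fragment("".join(insert), refs)
        assert hits and all(h.mismatches == 1 for h in hits)

    def test_trailer_fragment_maps_to_precursor(self, pro_agg_family):
        refs = pro_agg_family
        pre = refs.precursors["Pro-AGG-1"]
        b1 = pre.body_span[1]
        frag = pre.seq[b1 : b1 + 16]
        hits = align_fragment(frag, refs)
        assert all(h.source == "precursor" and h.region == "trailer"
                   for h in hits)

    def test_matches_bruteforce_tiered_scan(self, sim_refs):
        rng = np.random.default_rng(17)
        matures = {g.gene_id: sim_refs.matures[g.gene_id].seq
                   for g in sim_refs.genes}
        precursors = {g.gene_id: sim_refs.precursors[g.gene_id].seq
                      for g in sim_refs.genes}
        aligner = FragmentAligner(sim_refs)
        gene_ids = list(matures)
        for trial in range(150):
            mode = trial % 3
            k = int(rng.integers(14, 41))
            if mode == 0:
                insert = random_dna(rng, k)
            else:
                src = matures if mode == 1 else precursors
                seq = src[gene_ids[int(rng.integers(len(gene_ids)))]]
                if len(seq) < k:
                    continue
                off = int(rng.integers(0, len(seq) - k + 1))
                frag = list(seq[off : off + k])
                for _ in range(int(rng.integers(0, 3))):  # 0-2 mutations
                    p = int(rng.integers(k))
                    frag[p] = "ACGT"[int(rng.integers(4))]
                insert = "".join(frag)
            got = {(h.gene_id, h.start, h.end, h.mismatches, h.source)
                   for h in aligner.align(insert)}
            want = set(tiered_hits(insert, matures, precursors))
            assert got == want, f"trial {trial}: {insert}"

    def test_empty_reference_rejected(self):
        from tsrnakit.reference import ReferenceError, ReferenceSet
        with pytest.raises(ReferenceError):
            ReferenceSet(genes=[])


class TestClassifySubtype:
    @pytest.mark.parametrize("start,end,L,expected", [
        (1, 31, 75, "tRF-5c"),
        (1, 34, 75, "tiRNA-5"),
        (59, 75, 75, "tRF-3a"),
        (1, 14, 75, "tRF-5a"),
        (1, 22, 75, "tRF-5b"),
        (69, 86, 86, "tRF-3a"),
        (50, 75, 75, "tRF-3b"),
        (40, 75, 75, "tiRNA-3"),
        (10, 30, 75, "tRF-other"),
    ])
    def test_published_and_band_examples(self, start, end, L, expected):
        assert classify_subtype(start, end, L) == expected

    def test_precursor_regions(self):
        assert classify_subtype(80, 95, 0, "precursor", "trailer") == "tRF-1"
        assert classify_subtype(1, 15, 0, "precursor", "leader") == "tRF-other"
        assert classify_subtype(30, 50, 0, "precursor", "body") == "tRF-other"

    def test_coordinate_errors(self):
        with pytest.raises(CoordinateError):
            classify_subtype(10, 5, 75)
        with pytest.raises(CoordinateError):
            classify_subtype(60, 80, 75)
        with pytest.raises(CoordinateError):
            classify_subtype(1, 13, 75)  # below minimum fragment length

    @given(length=st.integers(14, 40))
    @settings(derandomize=True, max_examples=27)
    def test_length_bands_partition_both_ends(self, length):
        """Each length falls in exactly one 5' bin and one 3' bin."""
        L = 100
        five = classify_subtype(1, length, L)
        assert five in {"tRF-5a", "tRF-5b", "tRF-5c", "tiRNA-5"}
        three = classify_subtype(L - length + 1, L, L)
        assert three in {"tRF-3a", "tRF-3b", "tiRNA-3"}


class TestNaming:
    def test_multimapping_isodecoders_get_m_suffix(self, pro_agg_family):
        refs = pro_agg_family
        insert = refs.matures["Pro-AGG-1"].seq[57:75]  # 58..75, 18 nt
        hits = align_fragment(insert, refs)
        subtype = classify_subtype(58, 75, 75)
        assert subtype == "tRF-3a"
        assert name_tsrna(hits, subtype, refs) == "tRF-58:75-Pro-AGG-1-M4"

    def test_singleton_has_no_m_suffix(self, pro_agg_family):
        refs = pro_agg_family
        hits = [h for h in align_fragment(refs.matures["Pro-AGG-2"].seq[:14],
                                          refs) if h.gene_id == "Pro-AGG-2"]
        assert name_tsrna(hits, "tRF-5a", refs) == "tRF-1:14-Pro-AGG-2"

    def test_mixed_coordinates_raise(self, pro_agg_family):
        refs = pro_agg_family
        a = align_fragment(refs.matures["Pro-AGG-1"].seq[:14], refs)
        b = align_fragment(refs.matures["Pro-AGG-1"].seq[:15], refs)
        with pytest.raises(NamingError):
            name_tsrna(a + b, "tRF-5a", refs)

    @pytest.mark.parametrize("tsrna_id,length,n", [
        ("tRF-59:75-Pro-AGG-1-M4", 17, 4),
        ("tiRNA-1:34-Glu-TTC-3", 34, 1),
        ("tRF-1:22-Ser-AGA-1-M3", 22, 3),
        ("tRF-69:86-Leu-CAA-1-M5", 18, 5),
    ])
    def test_parse_published_ids(self, tsrna_id, length, n):
        p = parse_tsrna_id(tsrna_id)
        assert p["length"] == length
        assert p["n_genes"] == n

    @pytest.mark.parametrize("bad", [
        "tXF-1:22-Ser-AGA-1", "tRF-22-Ser-AGA-1", "tRF-1:22-Serine-AGA-1",
        "tRF-1:22-Ser-AGU-1", "tRF-1:22-Ser-AGA", "tRF-22:1-Ser-AGA-1",
    ])
    def test_malformed_ids_rejected_with_position(self, bad):
        with pytest.raises(TsrnaIdError):
            parse_tsrna_id(bad)

    @given(prefix=st.sampled_from(["tRF", "tiRNA"]),
           start=st.integers(1, 60), length=st.integers(14, 40),
           aa=st.sampled_from(["Gly", "Pro", "Glu", "Ser"]),
           anticodon=st.text("ACGT", min_size=3, max_size=3),
           iso=st.integers(1, 30), n=st.integers(1, 9))
    @settings(derandomize=True, max_examples=200)
    def test_name_parse_roundtrip(self, prefix, start, length, aa,
                                  anticodon, iso, n):
        name = f"{prefix}-{start}:{start + length - 1}-{aa}-{anticodon}-{iso}"
        if n >= 2:
            name += f"-M{n}"
        p = parse_tsrna_id(name)
        assert (p["prefix"], p["start"], p["length"], p["amino_acid"],
                p["anticodon"], p["isodecoder"], p["n_genes"]) == \
            (prefix, start, length, aa, anticodon, iso, n if n >= 2 else 1)


class TestCounting:
    def test_identical_reads_counted_once_per_read(self, pro_agg_family):
        refs = pro_agg_family
        aligner = FragmentAligner(refs)
        call = call_species(refs.matures["Pro-AGG-1"].seq[:20], aligner)
        table = aggregate_counts([[call] * 10, [call] * 3], ["A", "B"])
        assert table.loc[call.tsrna_id].tolist() == [10, 3]

    def test_multimapping_read_contributes_once(self, pro_agg_family):
        refs = pro_agg_family
        aligner = FragmentAligner(refs)
        call = call_species(refs.matures["Pro-AGG-1"].seq[:20], aligner)
        assert len(call.supporting_genes) == 4
        table = aggregate_counts([[call]], ["A"])
        assert table["A"].sum() == 1

    def test_empty_fastq_yields_empty_table(self, tmp_path, pro_agg_family):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        res = profile_fastqs([fq], ["S1"], pro_agg_family, ADAPTER)
        assert res.counts.empty
        assert res.log["samples"]["S1"]["reads"] == 0
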