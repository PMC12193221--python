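"""Primer screening, pair enumeration and in-silico PCR."""

import numpy as np
import pytest

from hrmid import (
    PrimerConstraints,
    SynthPanelSpec,
    check_primer,
    conservation_profile,
    enumerate_pairs,
    find_regions,
    gc_content,
    in_silico_pcr,
    revcomp,
    synth_barcodes,
)
from hrmid import panels

COX2_F = "TGGAACCCCTGGACGACTTA"   # published forward, 20-mer
COX2_R = "ACTGTGATTAGCTCCGCAAA"   # published reverse, 20-mer
COI_1502_F = "AGCGGGAATAGTGGGAA"  # published 17-mer (below length window)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0),
        ("ATAT", 0.0),
        # hand count on the published forward primer: 11 G+C of 20
        (COX2_F, 0.55),
    ])
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_ambiguity_excluded_from_both_sides(self):
        assert gc_content("GCNN") == 1.0
        assert gc_content("ATNN") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestCheckPrimer:
    def test_published_cox2_forward_passes(self):
        assert check_primer(COX2_F) == ()

    def test_short_literature_primer_fails_length(self):
        verdict = check_primer(COI_1502_F)
        assert len(COI_1502_F) == 17
        assert any(v.startswith("length") for v in verdict)

    def test_all_gc_fails_gc_window(self):
        verdict = check_primer("G" * 20)
        assert any(v.startswith("gc") for v in verdict)

    def test_all_failures_reported_not_just_first(self):
        # 8-mer, all G: fails both length and GC
        verdict = check_primer("GGGGGGGG")
        kinds = {v.split(":")[0] for v in verdict}
        assert {"length", "gc"} <= kinds

    def test_case_invariant(self):
        assert check_primer(COX2_F.lower()) == check_primer(COX2_F)

    def test_degenerate_bases_rejected(self):
        verdict = check_primer("TGGAACCCCTGGACGACTTN")
        assert any(v.startswith("degenerate") for v in verdict)

    def test_hairpin_detected(self):
        # GCGC stem ... loop ... GCGC revcomp stem
        seq = "GCGCAAAAAAAAAAGCGC" + "AT"
        verdict = check_primer(seq)
        assert any(v.startswith("hairpin") for v in verdict)

    def test_self_dimer_detected(self):
        # 8-base self-complementary run in the middle
        seq = "TTCTT" + "AACCGGTT" + "CTTCTTA"
        c = PrimerConstraints(dimer_max_run=8)
        verdict = check_primer(seq, c)
        assert any("dimer" in v for v in verdict)


@pytest.fixture(scope="module")
def panel():
    # seed chosen so both full flanks pass the GC/structure screens
    for seed in range(100):
        spec = SynthPanelSpec(n_species=5, flank_len=20, core_len=57,
                              core_divergence=0.3, seed=seed)
        records = synth_barcodes(spec)
        f5 = records[0].sequence[:20]
        f3 = records[0].sequence[-20:]
        if check_primer(f5) == () and check_primer(revcomp(f3)) == ():
            return records
    raise RuntimeError("no suitable seed found")


class TestEnumeratePairs:
    def test_full_flank_pair_present(self, panel):
        regions = find_regions(conservation_profile(panel))
        pairs = enumerate_pairs(panel, regions)
        assert any(p.product_len == 97 and p.fwd_start == 0 and p.rev_end == 97
                   for p in pairs)

    def test_product_max_excludes_long_products(self, panel):
        regions = find_regions(conservation_profile(panel))
        pairs = enumerate_pairs(panel, regions,
                                PrimerConstraints(product_max=50))
        assert all(p.product_len <= 50 for p in pairs)
        assert not any(p.product_len == 97 for p in pairs)

    def test_no_variable_region_no_pairs(self):
        records = synth_barcodes(
            SynthPanelSpec(n_species=3, flank_len=30, core_len=1,
                           core_divergence=0.0, seed=4)
        )
        regions = find_regions(conservation_profile(records))
        # fully conserved alignment: one region, no variable columns
        assert enumerate_pairs(records, regions) == []

    def test_pairs_repass_screen_and_reproduce_product(self, panel):
        from hrmid.align import consensus_sequence

        regions = find_regions(conservation_profile(panel))
        pairs = enumerate_pairs(panel, regions)
        consensus = consensus_sequence(panel)
        for p in pairs[:10]:
            assert check_primer(p.fwd) == ()
            assert check_primer(p.rev) == ()
            amps = in_silico_pcr(p.fwd, p.rev, consensus, max_mismatch=0)
            assert p.product_len in {len(a) for a in amps}

    def test_sorted_by_product_len(self, panel):
        regions = find_regions(conservation_profile(panel))
        pairs = enumerate_pairs(panel, regions)
        lens = [p.product_len for p in pairs]
        assert lens == sorted(lens)


class TestInSilicoPcr:
    def test_constructed_template_single_product(self):
        rng = np.random.default_rng(0)
        core = "".join(rng.choice(list("ACGT"), 57))
        template = COX2_F + core + revcomp(COX2_R)
        amps = in_silico_pcr(COX2_F, COX2_R, template)
        assert len(amps) == 1
        assert len(amps[0]) == 97
        assert amps[0].sequence == template

    def test_missing_reverse_site_no_product(self):
        rng = np.random.default_rng(1)
        template = COX2_F + "".join(rng.choice(list("ACGT"), 100))
        assert in_silico_pcr(COX2_F, COX2_R, template) == []

    def test_synthetic_coxii_template_yields_97bp(self):
        """The bundled synthetic COXII-like template (published primer
        footprints at the published spacing) amplifies one 97 bp product."""
        tpl = panels.synthetic_coxii_template()
        amps = in_silico_pcr(COX2_F, COX2_R, tpl, max_mismatch=3,
                             three_prime_exact=5)
        assert len(amps) == 1
        assert len(amps[0]) == 97
        # gene coordinates: forward 5' at position 519 (1-based)
        assert amps[0].start == 518

    def test_exact_mode_agrees_with_string_search_oracle(self):
        """Exhaustive comparison with a naive find-all-occurrences oracle
        on random 1 kb templates."""
        rng = np.random.default_rng(99)
        for trial in range(20):
            template = "".join(rng.choice(list("ACGT"), 1000))
            i = int(rng.integers(0, 400))
            j = int(rng.integers(i + 100, 900))
            fwd = template[i:i + 20]
            rev = revcomp(template[j:j + 20])
            amps = in_silico_pcr(fwd, rev, template, max_mismatch=0)

            # oracle: all exact occurrences via str.find
            def occurrences(pat, s):
                out, k = [], s.find(pat)
                while k != -1:
                    out.append(k)
                    k = s.find(pat, k + 1)
                return out

            f_sites = occurrences(fwd, template)
            r_sites = occurrences(revcomp(rev), template)
            expected = sorted(
                (fi, rj + 20)
                for fi in f_sites for rj in r_sites
                if fi + 19 < rj
            )
            assert sorted((a.start, a.end) for a in amps) == expected

    def test_mismatch_budget_and_three_prime_seed(self):
        rng = np.random.default_rng(5)
        core = "".join(rng.choice(list("ACGT"), 57))
        # two mismatches in the forward footprint, away from the 3' seed
        fwd_site = list(COX2_F)
        fwd_site[2] = "A" if fwd_site[2] != "A" else "C"
        fwd_site[5] = "A" if fwd_site[5] != "A" else "C"
        template = "".join(fwd_site) + core + revcomp(COX2_R)
        assert in_silico_pcr(COX2_F, COX2_R, template, max_mismatch=1) == []
        amps = in_silico_pcr(COX2_F, COX2_R, template, max_mismatch=2)
        assert len(amps) == 1 and amps[0].fwd_mismatches == 2

        # a mismatch inside the 3'-terminal seed kills the site
        bad = list(COX2_F)
        bad[-2] = "A" if bad[-2] != "A" else "C"
        template2 = "".join(bad) + core + revcomp(COX2_R)
        assert in_silico_pcr(COX2_F, COX2_R, template2, max_mismatch=3,
                             three_prime_exact=5) == []

    def test_gapped_template_rejected(self):
        with pytest.raises(ValueError):
            in_silico_pcr(COX2_F, COX2_R, "ACGT-ACGT")
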