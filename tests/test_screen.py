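"""Marker discovery: diagnostic indels, presence-marker design and the
het-male/hom-female SNP screen."""
import copy

import numpy as np
import pytest

from figmark.align import splice_map
from figmark.models import DiagnosticIndel, Panel, Sample
from figmark.pcr import amplify
from figmark.screen import (
    design_presence_marker,
    find_diagnostic_indels,
    screen_snp_sites,
    sites_in_amplicon,
)


def _mini_panel(ref, male_seq, n_male=3, n_female=3, locus="X"):
    samples = [
        Sample(f"m{i}", "male", {locus: (male_seq,)}) for i in range(n_male)
    ] + [
        Sample(f"f{i}", "female", {locus: (ref,)}) for i in range(n_female)
    ]
    return Panel(samples=samples, name="mini")


class TestFindDiagnosticIndels:
    def test_recovers_the_15bp_male_insertion(self, cultivar_panel):
        found = find_diagnostic_indels(cultivar_panel, "AG")
        assert len(found) == 1
        d = found[0]
        assert (d.length, d.sequence, d.present_in) == (15, "CAGGAGGAGGAAGCT", "male")

    def test_identical_loci_yield_nothing(self):
        seq = "ATG" + "ACGTAC" * 30 + "TAA"
        assert find_diagnostic_indels(_mini_panel(seq, seq), "X") == []

    def test_planted_7bp_male_insertion(self):
        rng = np.random.default_rng(9)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        male = ref[:140] + "TTCCGGA" + ref[140:]
        found = find_diagnostic_indels(_mini_panel(ref, male), "X")
        assert [(d.length, d.present_in) for d in found] == [(7, "male")]

    def test_missing_locus_raises(self, cultivar_panel):
        with pytest.raises(KeyError):
            find_diagnostic_indels(cultivar_panel, "NO_SUCH_LOCUS")

    def test_shuffled_labels_destroy_the_partition(self, cultivar_panel):
        rng = np.random.default_rng(0)
        sexes = [s.true_sex for s in cultivar_panel.samples]
        for _ in range(20):
            shuffled = copy.deepcopy(cultivar_panel)
            perm = rng.permutation(len(sexes))
            for sample, k in zip(shuffled.samples, perm):
                sample.true_sex = sexes[int(k)]
            if [s.true_sex for s in shuffled.samples] == sexes:
                continue  # permutation happened to preserve the labelling
            assert find_diagnostic_indels(shuffled, "AG") == []


class TestDesignPresenceMarker:
    def test_reproduces_published_marker(self, cultivar_panel, ag_models):
        indel = find_diagnostic_indels(cultivar_panel, "AG")[0]
        pair = design_presence_marker(indel, ag_models["male_ag2"])
        assert pair.forward.seq == "CAGGAGGAGGAAGCT"
        assert pair.reverse.seq == "TTACACTAATTGGAGGGCCA"
        assert pair.expected_length == 146

    def test_absent_indel_rejected(self, cultivar_panel, ag_models):
        indel = find_diagnostic_indels(cultivar_panel, "AG")[0]
        with pytest.raises(ValueError, match="absent"):
            design_presence_marker(indel, ag_models["female"])

    def test_expected_length_matches_amplification(self, cultivar_panel, ag_models):
        # cross-module consistency: the designed length equals what the
        # PCR engine produces on the same template
        indel = find_diagnostic_indels(cultivar_panel, "AG")[0]
        for allele in ("male_ag2", "male_ag3"):
            pair = design_presence_marker(indel, ag_models[allele])
            for template in (ag_models[allele].cds_seq, ag_models[allele].genomic_seq):
                amps = amplify(template, pair)
                assert [a.length for a in amps] == [pair.expected_length]

    def test_planted_indel_length_arithmetic(self):
        cds = "ATG" + "GCT" * 40 + "TTCCGGATT" + "GCA" * 30 + "TAA"
        model = splice_map(cds, cds, name="toy")
        indel = DiagnosticIndel("TTCCGGATT", 9, "male", "X", 123)
        pair = design_presence_marker(indel, model)
        assert pair.expected_length == len(cds) - cds.find("TTCCGGATT")
        assert [a.length for a in amplify(cds, pair)] == [pair.expected_length]


class TestScreenSnpSites:
    def test_cultivar_screen_verdicts(self, cultivar_panel, ran1):
        verdicts = screen_snp_sites(cultivar_panel, ran1["sites"])
        by_label = {v.site_label: v for v in verdicts}
        assert [v.site_label for v in verdicts] == [s.label for s in ran1["sites"]]
        invalid = sorted(l for l, v in by_label.items() if v.verdict == "invalid")
        assert invalid == ["seq000259_10377", "seq000259_9823", "seq000259_9855"]
        assert sum(v.verdict == "discriminating" for v in verdicts) == 12
        for v in verdicts:
            if v.verdict == "invalid":
                assert v.counterexamples

    def test_verdicts_invariant_under_sample_order(self, cultivar_panel, ran1):
        reversed_panel = Panel(samples=list(reversed(cultivar_panel.samples)), name="rev")
        a = screen_snp_sites(cultivar_panel, ran1["sites"])
        b = screen_snp_sites(reversed_panel, ran1["sites"])
        assert [(v.site_label, v.verdict) for v in a] == [
            (v.site_label, v.verdict) for v in b
        ]

    def test_single_male_panel_is_vacuously_discriminating(self, cultivar_panel, ran1):
        one_male = Panel(samples=[cultivar_panel.by_sex("male")[0]], name="one")
        with pytest.warns(UserWarning, match="single-sex"):
            verdicts = screen_snp_sites(one_male, ran1["sites"])
        disc_sites = [s for s in ran1["sites"] if s.validity == "discriminating"]
        by_label = {v.site_label: v for v in verdicts}
        assert all(by_label[s.label].verdict == "discriminating" for s in disc_sites)

    def test_planted_hom_male_counterexample(self, cultivar_panel, ran1):
        site = next(s for s in ran1["sites"] if s.validity == "discriminating")
        broken = copy.deepcopy(cultivar_panel)
        culprit = broken.by_sex("male")[0]
        cons = list(culprit.consensus("RAN1"))
        cons[site.genomic_pos] = site.female_base
        culprit.locus_seqs["RAN1"] = ("".join(cons),)
        verdicts = {v.site_label: v for v in screen_snp_sites(broken, ran1["sites"])}
        v = verdicts[site.label]
        assert v.verdict == "invalid"
        assert (culprit.sample_id, f"male hom({site.female_base})") in v.counterexamples

    def test_out_of_range_site_raises(self, cultivar_panel, ran1):
        import dataclasses

        far = dataclasses.replace(ran1["sites"][0], genomic_pos=10**7)
        with pytest.raises(IndexError):
            screen_snp_sites(cultivar_panel, [far])


class TestSitesInAmplicon:
    def test_marker_covers_six_discriminating_sites(self, ran1, primer_pairs):
        amp = amplify(ran1["gene"].genomic_seq, primer_pairs["RAN1-Marker"])[0]
        assert sites_in_amplicon(ran1["sites"], amp, "discriminating").count == 6

    @pytest.mark.parametrize("pair_name,n_covered", [("1-SNP", 1), ("2-SNP", 2), ("6SNP-2", 6)])
    def test_snp_detection_amplicons(self, ran1, primer_pairs, pair_name, n_covered):
        amp = amplify(ran1["gene"].genomic_seq, primer_pairs[pair_name])[0]
        assert sites_in_amplicon(ran1["sites"], amp).count == n_covered

    def test_zero_length_window(self, ran1, primer_pairs):
        amp = amplify(ran1["gene"].genomic_seq, primer_pairs["RAN1-Marker"])[0]
        import dataclasses

        empty = dataclasses.replace(amp, end=amp.start, product_seq="")
        assert sites_in_amplicon(ran1["sites"], empty).count == 0
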