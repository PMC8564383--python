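"""Synthetic-locus generator: structural invariants, determinism,
panel composition and fixture round-trips."""
import numpy as np
import pytest

from figmark import forge
from figmark.align import translate
from figmark.forge import (
    INVALID_SITE_LABELS,
    build_cultivar_panel,
    build_f1_population,
    validate_primer_uniqueness,
    _build_all,
    _intended_hits,
)
from figmark.models import ConstraintError, het_code_for
from figmark.pcr import find_primer_sites


class TestGeneModels:
    def test_ag_dimensions(self, ag_models):
        female = ag_models["female"]
        assert len(female.genomic_seq) == 5230
        assert len(female.cds_seq) == 744
        assert female.n_exons == 7
        for allele in ("male_ag2", "male_ag3"):
            assert len(ag_models[allele].cds_seq) == 759
            assert ag_models[allele].n_exons == 7

    def test_male_cds_is_female_plus_insertion(self, ag_models):
        f = ag_models["female"].cds_seq
        m = ag_models["male_ag2"].cds_seq
        pos = forge.AG_INSERTION_CDS_POS
        assert m == f[:pos] + forge.AG_MARKER_INSERTION + f[pos:]

    def test_translations_are_stop_free(self, ag_models, ran1):
        assert len(translate(ag_models["female"].cds_seq)) == 247
        assert len(translate(ag_models["male_ag2"].cds_seq)) == 252
        assert len(translate(ran1["gene"].cds_seq)) == 3015 // 3 - 1

    def test_introns_are_gt_ag(self, ag_models, ran1):
        for model in (*ag_models.values(), ran1["gene"]):
            for s, e in model.introns:
                assert e - s >= 60
                assert model.genomic_seq[s : s + 2] == "GT"
                assert model.genomic_seq[e - 2 : e] == "AG"

    def test_ran1_dimensions(self, ran1):
        gene = ran1["gene"]
        assert len(gene.cds_seq) == 3015
        assert gene.n_exons == 9
        ws, we = ran1["marker_window"]
        assert we - ws == 608
        # the marker window sits wholly inside exon 2
        e2 = gene.exons[1]
        assert e2[0] <= ws and we <= e2[1]


class TestSnpCatalogue:
    def test_site_counts_and_invalid_labels(self, ran1):
        sites = ran1["sites"]
        assert len(sites) == 15
        assert sum(s.validity == "discriminating" for s in sites) == 12
        assert sorted(s.label for s in sites if s.validity == "invalid") == sorted(
            INVALID_SITE_LABELS
        )

    def test_six_discriminating_sites_in_marker_window(self, ran1):
        ws, we = ran1["marker_window"]
        inside = [
            s
            for s in ran1["sites"]
            if ws <= s.genomic_pos < we and s.validity == "discriminating"
        ]
        assert len(inside) == 6

    def test_het_codes_and_genomic_positions(self, ran1):
        gene = ran1["gene"]
        for s in ran1["sites"]:
            assert s.het_code == het_code_for(s.female_base, s.male_alt_base)
            assert gene.genomic_seq[s.genomic_pos] == s.female_base
            assert gene.cds_to_genomic(s.cds_pos) == s.genomic_pos

    def test_effects_verify_under_translation(self, ran1):
        gene = ran1["gene"]
        ref = translate(gene.cds_seq)
        for s in ran1["sites"]:
            mutated = list(gene.cds_seq)
            mutated[s.cds_pos] = s.male_alt_base
            alt = translate("".join(mutated))
            changed = sum(a != b for a, b in zip(ref, alt))
            assert changed == (1 if s.effect == "missense" else 0), s.label

    def test_12722_switch_flips_effect(self):
        default = forge.build_ran1_model(1)
        alt = forge.build_ran1_model(1, snp12722_effect="synonymous")
        eff = {m: {s.label: s.effect for s in m2["sites"]} for m, m2 in
               (("d", default), ("s", alt))}
        assert eff["d"]["seq000259_12722"] == "missense"
        assert eff["s"]["seq000259_12722"] == "synonymous"


class TestPrimerUniqueness:
    def test_no_unintended_primer_sites(self, ag_models, ran1):
        built = _build_all(1)
        seqs = {
            ag_models["female"].name: ag_models["female"].genomic_seq,
            ag_models["male_ag2"].name: ag_models["male_ag2"].genomic_seq,
            ag_models["male_ag3"].name: ag_models["male_ag3"].genomic_seq,
            "FcRAN1": ran1["gene"].genomic_seq,
            "Actin": built["actin"],
        }
        validate_primer_uniqueness(seqs, _intended_hits(built))

    def test_marker_forward_absent_from_all_female_sequences(self, cultivar_panel):
        for sample in cultivar_panel.by_sex("female"):
            for seqs in sample.locus_seqs.values():
                for seq in seqs:
                    assert not find_primer_sites(seq, forge.AG_MARKER_INSERTION)


class TestPanels:
    def test_cultivar_composition(self, cultivar_panel):
        assert len(cultivar_panel) == 51
        assert len(cultivar_panel.by_sex("male")) == 27
        assert len(cultivar_panel.by_sex("female")) == 24

    def test_males_het_at_all_discriminating_sites(self, cultivar_panel, ran1):
        disc = [s for s in ran1["sites"] if s.validity == "discriminating"]
        for sample in cultivar_panel.by_sex("male"):
            cons = sample.consensus("RAN1")
            assert all(cons[s.genomic_pos] == s.het_code for s in disc)
        for sample in cultivar_panel.by_sex("female"):
            cons = sample.consensus("RAN1")
            assert all(cons[s.genomic_pos] == s.female_base for s in disc)

    def test_invalid_sites_violated_by_both_sexes(self, cultivar_panel, ran1):
        invalid = [s for s in ran1["sites"] if s.validity == "invalid"]
        for site in invalid:
            male_hom = any(
                s.consensus("RAN1")[site.genomic_pos] != site.het_code
                for s in cultivar_panel.by_sex("male")
            )
            female_het = any(
                s.consensus("RAN1")[site.genomic_pos] == site.het_code
                for s in cultivar_panel.by_sex("female")
            )
            assert male_hom and female_het, site.label

    def test_f1_fixed_counts(self, pop1, pop2):
        assert len(pop1) == 242 and len(pop1.by_sex("male")) == 132
        assert len(pop2) == 85 and len(pop2.by_sex("male")) == 36

    def test_f1_fixed_counts_must_sum(self):
        with pytest.raises(ValueError):
            build_f1_population(n=100, seed=1, fixed_counts=(10, 20))

    def test_f1_bernoulli_male_fraction_in_binomial_bounds(self):
        panel = build_f1_population(n=200, seed=7)
        m = len(panel.by_sex("male"))
        # 99% binomial interval around 100 for n=200, p=0.5
        assert 82 <= m <= 118

    def test_determinism(self):
        a = build_cultivar_panel(seed=3)
        b = build_cultivar_panel(seed=3)
        assert a == b
        assert build_f1_population(n=50, seed=3) == build_f1_population(n=50, seed=3)

    def test_different_seeds_differ(self):
        assert (
            forge.build_ag_models(1)["female"].genomic_seq
            != forge.build_ag_models(2)["female"].genomic_seq
        )


class TestFixtureRoundTrip:
    def test_panel_round_trip_identity(self, tmp_path, cultivar_panel, ran1):
        built = _build_all(1)
        forge.write_fixtures(
            cultivar_panel, tmp_path / "cv", seed=1, models=built, sites=ran1["sites"]
        )
        again = forge.read_fixtures(tmp_path / "cv")
        assert again == cultivar_panel

    def test_rewrite_is_byte_identical(self, tmp_path, pop2):
        forge.write_fixtures(pop2, tmp_path / "a", seed=1)
        forge.write_fixtures(forge.read_fixtures(tmp_path / "a"), tmp_path / "b", seed=1)
        for name in ("samples.fasta", "truth.tsv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_fixture_contents(self, tmp_path, pop1, ran1):
        forge.write_fixtures(pop1, tmp_path / "p1", seed=1, sites=ran1["sites"])
        truth = (tmp_path / "p1" / "truth.tsv").read_text().splitlines()
        assert len(truth) == 243  # header + 242 samples
        sites = (tmp_path / "p1" / "snp_sites.tsv").read_text().splitlines()
        assert len(sites) == 16  # header + 15 sites
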