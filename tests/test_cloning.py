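"""BioBrick cloning: affixes, digestion algebra, ligation, back-translation."""

import numpy as np
import pytest
from Bio.Restriction import NotI as BioNotI
from Bio.Seq import Seq

from selenopep import (
    BIOBRICK_PREFIX, BIOBRICK_SUFFIX, NOT_I, Construct, DNAPart, Fragment,
    add_affixes, assemble_insert, back_translate, concatenate,
    default_codon_table, digest_and_ligate, ligate, parse_peptide,
    serialize_construct, translate, virtual_digest,
)
from selenopep.cloning import CloningError, read_construct
from selenopep.properties import PeptideSequence


def rand_dna(rng, n, forbid_site=True):
    while True:
        s = "".join(rng.choice(list("ACGT"), size=n))
        if not forbid_site or NOT_I.recognition not in s:
            return s


@pytest.fixture()
def dna_rng():
    return np.random.default_rng(2024)


class TestAffixes:
    def test_printed_affix_lengths(self):
        assert len(BIOBRICK_PREFIX) == 20
        assert len(BIOBRICK_SUFFIX) == 21

    def test_each_affix_carries_exactly_one_noti_site(self):
        assert BIOBRICK_PREFIX.count(NOT_I.recognition) == 1
        assert BIOBRICK_SUFFIX.count(NOT_I.recognition) == 1

    @pytest.mark.parametrize(
        "which,delta", [("prefix_only", 20), ("suffix_only", 21), ("both", 41)]
    )
    def test_length_deltas(self, dna_rng, which, delta):
        part = DNAPart(id="x", role="cds", sequence=rand_dna(dna_rng, 60))
        assert len(add_affixes(part, which=which)) == len(part) + delta

    def test_circular_input_rejected(self, dna_rng):
        part = DNAPart(
            id="x", role="backbone", sequence=rand_dna(dna_rng, 60),
            topology="circular",
        )
        with pytest.raises(CloningError):
            add_affixes(part)


class TestAssembleConcatenate:
    def test_assembled_length_is_sum(self, dna_rng):
        parts = [
            DNAPart(id=f"p{i}", role=r, sequence=rand_dna(dna_rng, n))
            for i, (r, n) in enumerate(
                [("promoter", 40), ("rbs", 15), ("cds", 90), ("terminator", 50)]
            )
        ]
        insert = assemble_insert(parts)
        assert len(insert) == sum(len(p) for p in parts)
        assert insert.secis_note is None  # no order warnings

    def test_strict_mode_rejects_terminator_before_cds(self, dna_rng):
        parts = [
            DNAPart(id="t", role="terminator", sequence=rand_dna(dna_rng, 50)),
            DNAPart(id="c", role="cds", sequence=rand_dna(dna_rng, 90)),
        ]
        with pytest.raises(CloningError, match="terminator"):
            assemble_insert(parts, strict=True)
        # non-strict: surfaced as a warning note
        assert "violation" in assemble_insert(parts).secis_note

    def test_concatenate_identity_and_associativity(self, dna_rng):
        a = DNAPart(id="a", role="other", sequence=rand_dna(dna_rng, 30))
        b = DNAPart(id="b", role="other", sequence=rand_dna(dna_rng, 40))
        c = DNAPart(id="c", role="other", sequence=rand_dna(dna_rng, 50))
        ab_c = concatenate(concatenate(a, b), c)
        a_bc = concatenate(a, concatenate(b, c))
        assert ab_c.sequence == a_bc.sequence
        assert len(ab_c) == 120


class TestDigestion:
    def test_linear_one_site_two_fragments(self, dna_rng):
        seq = rand_dna(dna_rng, 100) + NOT_I.recognition + rand_dna(dna_rng, 60)
        part = DNAPart(id="x", role="other", sequence=seq)
        frags = virtual_digest(part, NOT_I)
        assert len(frags) == 2
        assert sum(len(f) for f in frags) == len(seq)
        assert frags[1].five_prime_overhang == "GGCC"
        assert frags[0].three_prime_overhang == "GGCC"

    def test_no_site_returns_single_uncut_fragment(self, dna_rng):
        part = DNAPart(id="x", role="other", sequence=rand_dna(dna_rng, 80))
        frags = virtual_digest(part, NOT_I)
        assert len(frags) == 1
        assert frags[0].five_prime_overhang == ""

    def test_affixed_cassette_gives_three_fragments(self, dna_rng):
        core = DNAPart(id="core", role="cds", sequence=rand_dna(dna_rng, 120))
        cassette = add_affixes(core)
        frags = virtual_digest(cassette, NOT_I)
        assert len(frags) == 3
        assert sum(len(f) for f in frags) == len(cassette)

    def test_circular_k_sites_k_fragments(self, dna_rng):
        pieces = [rand_dna(dna_rng, int(n)) for n in (50, 70, 90)]
        seq = "".join(p + NOT_I.recognition for p in pieces)
        circ = DNAPart(id="c", role="other", sequence=seq, topology="circular")
        frags = virtual_digest(circ, NOT_I)
        assert len(frags) == 3
        assert sum(len(f) for f in frags) == len(seq)

    def test_site_positions_agree_with_biopython(self, dna_rng):
        # independent oracle: Biopython's NotI search on the same molecules
        for _ in range(25):
            seq = rand_dna(dna_rng, 200, forbid_site=False)
            seq = (
                seq[:50] + NOT_I.recognition + seq[50:130]
                + NOT_I.recognition + seq[130:]
            )
            ours = NOT_I.sites(seq)
            # Bio.Restriction reports 1-based positions after the top cut
            theirs = [p - NOT_I.cut_offset_top for p in BioNotI.search(Seq(seq))]
            assert ours == theirs

    def test_overhang_geometry_matches_biopython(self):
        assert NOT_I.overhang_length == 4
        assert BioNotI.ovhg == -4  # 5' overhang of 4 nt
        assert NOT_I.is_palindromic


class TestLigation:
    def test_blunt_into_sticky_refused(self, dna_rng):
        sticky = Fragment(
            sequence=rand_dna(dna_rng, 40), five_prime_overhang="GGCC",
            three_prime_overhang="GGCC",
        )
        blunt = Fragment(sequence=rand_dna(dna_rng, 40))
        with pytest.raises(CloningError, match="junction"):
            ligate([blunt, sticky])

    def test_self_ligation_circularizes(self, dna_rng):
        frag = Fragment(
            sequence="GGCC" + rand_dna(dna_rng, 60), five_prime_overhang="GGCC",
            three_prime_overhang="GGCC",
        )
        construct = ligate([frag], require_circular=True)
        assert construct.topology == "circular"
        assert len(construct) == len(frag)

    def test_digest_then_ligate_reconstitutes_circle(self, dna_rng):
        pieces = [rand_dna(dna_rng, int(n)) for n in (80, 120)]
        seq = "".join(p + NOT_I.recognition for p in pieces)
        circ = DNAPart(id="c", role="other", sequence=seq, topology="circular")
        frags = virtual_digest(circ, NOT_I)
        rebuilt = ligate(frags, require_circular=True)
        assert len(rebuilt) == len(seq)
        original = Construct(id="o", parts=(circ,), topology="circular")
        assert rebuilt.same_molecule(original)

    def test_backbone_plus_cassette_published_arithmetic(self, dna_rng):
        """Synthetic parts with the published architecture reproduce the
        printed insert/cassette/plasmid lengths and NotI behavior."""
        sel2 = "MADUSERLHHSAHKKGUWAACTNFSRCTRKU"
        from selenopep import load_default_table

        table = load_default_table()
        cds = back_translate(parse_peptide(sel2, table, id="Selera-2"))
        i1_parts = [
            DNAPart(id=f"p{i}", role=r, sequence=rand_dna(dna_rng, n))
            for i, (r, n) in enumerate(
                [("promoter", 715), ("rbs", 20), ("cds", 1392),
                 ("cds", 1845), ("cds", 95), ("cds", 2652),
                 ("terminator", 100)]
            )
        ]
        insert1 = add_affixes(
            assemble_insert(i1_parts, id="insert1"), which="prefix_only"
        )
        i2_parts = [
            DNAPart(id="t7p", role="promoter", sequence=rand_dna(dna_rng, 23)),
            DNAPart(id="g10", role="rbs", sequence=rand_dna(dna_rng, 36)),
            DNAPart(id="cds2", role="cds", sequence=cds),
            DNAPart(id="t7t", role="terminator", sequence=rand_dna(dna_rng, 36)),
        ]
        insert2 = add_affixes(
            assemble_insert(i2_parts, id="insert2"), which="suffix_only"
        )
        assert len(insert1) == 6839
        assert len(insert2) == 212
        cassette = concatenate(insert1, insert2, id="cassette")
        assert len(cassette) == 7051
        backbone = Construct(
            id="bb",
            parts=(DNAPart(
                id="bb", role="backbone",
                sequence=rand_dna(dna_rng, 2038) + NOT_I.recognition,
            ),),
            topology="circular",
        )
        plasmid = digest_and_ligate(backbone, cassette, id="plasmid")
        assert plasmid.topology == "circular"
        assert len(plasmid) == 9078
        frags = virtual_digest(plasmid, NOT_I)
        assert len(frags) == 2
        assert sum(len(f) for f in frags) == 9078

    def test_no_internal_sites_survive_outside_junctions(self, dna_rng):
        core = DNAPart(id="core", role="cds", sequence=rand_dna(dna_rng, 150))
        cassette = add_affixes(core)
        backbone = Construct(
            id="bb",
            parts=(DNAPart(
                id="bb", role="backbone",
                sequence=rand_dna(dna_rng, 500) + NOT_I.recognition,
            ),),
            topology="circular",
        )
        plasmid = digest_and_ligate(backbone, cassette)
        # exactly the two reconstituted sites flanking the cassette
        assert len(NOT_I.sites(plasmid.sequence, "circular")) == 2


class TestBackTranslation:
    def test_selera2_cds_arithmetic(self, table):
        pep = parse_peptide("MADUSERLHHSAHKKGUWAACTNFSRCTRKU", table, id="S2")
        cds = back_translate(pep)
        assert len(cds) == 3 * (31 + 1)
        internal = [cds[i: i + 3] for i in range(0, len(cds) - 3, 3)]
        assert internal.count("TGA") == 3

    def test_argmax_deterministic_weighted_seeded(self, table):
        pep = parse_peptide("MKUWACDEFGHIKLMNPQRSTVWYU", table, id="p")
        ct = default_codon_table()
        assert back_translate(pep, ct) == back_translate(pep, ct)
        w1 = back_translate(pep, ct, mode="seeded_weighted", seed=5)
        w2 = back_translate(pep, ct, mode="seeded_weighted", seed=5)
        w3 = back_translate(pep, ct, mode="seeded_weighted", seed=6)
        assert w1 == w2
        assert w1 != w3

    def test_unmapped_token_rejected(self, table):
        pep = PeptideSequence(id="p", tokens=("K", "dip", "K"))
        with pytest.raises(CloningError, match="dip"):
            back_translate(pep)

    def test_round_trip_identity(self, table, rng):
        from conftest import random_peptide_tokens

        ct = default_codon_table()
        for _ in range(50):
            n = int(rng.integers(1, 40))
            pep = PeptideSequence(
                id="r", tokens=random_peptide_tokens(rng, n)
            )
            for mode in ("argmax", "seeded_weighted"):
                cds = back_translate(pep, ct, mode=mode, seed=3)
                assert translate(cds, sec_aware=True).tokens == pep.tokens

    def test_translation_without_sec_awareness_truncates(self, table):
        pep = parse_peptide("MADUSER", table, id="p")
        cds = back_translate(pep)
        assert len(translate(cds, sec_aware=False)) == 3  # stops at U codon

    def test_non_codon_length_rejected(self):
        with pytest.raises(CloningError):
            translate("ATGC")


class TestSerialization:
    def _plasmid(self, dna_rng):
        parts = (
            DNAPart(id="lacP", role="promoter", sequence=rand_dna(dna_rng, 60)),
            DNAPart(id="rbs1", role="rbs", sequence=rand_dna(dna_rng, 15)),
            DNAPart(id="selA", role="cds", sequence=rand_dna(dna_rng, 300)),
            DNAPart(id="term", role="terminator", sequence=rand_dna(dna_rng, 45)),
            DNAPart(id="bb", role="backbone", sequence=rand_dna(dna_rng, 400)),
        )
        return Construct(id="mini", parts=parts, topology="circular")

    def test_genbank_round_trip(self, tmp_path, dna_rng):
        plasmid = self._plasmid(dna_rng)
        path = tmp_path / "mini.gb"
        serialize_construct(plasmid, path, "genbank")
        back = read_construct(path, "genbank")
        assert back.sequence == plasmid.sequence
        assert back.topology == "circular"
        assert [p.id for p in back.parts] == [p.id for p in plasmid.parts]
        assert [p.role for p in back.parts] == [p.role for p in plasmid.parts]

    def test_topology_encoded_in_locus_line(self, tmp_path, dna_rng):
        plasmid = self._plasmid(dna_rng)
        path = tmp_path / "mini.gb"
        serialize_construct(plasmid, path, "genbank")
        assert "circular" in path.read_text().splitlines()[0]

    def test_fasta_output(self, tmp_path, dna_rng):
        plasmid = self._plasmid(dna_rng)
        path = tmp_path / "mini.fasta"
        serialize_construct(plasmid, path, "fasta")
        body = "".join(path.read_text().splitlines()[1:])
        assert body == plasmid.sequence
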