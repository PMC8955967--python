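"""MBS construction, spacer search, insert assembly, and validation."""

import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circsponge.duplex_report import is_wc, is_wobble, pair_duplex
from circsponge.seq_core import (
    Alphabet,
    MiRNA,
    NucleotideSequence,
    reverse_complement,
    transcribe,
)
from circsponge.sponge_design import (
    DesignError,
    DesignParams,
    Feature,
    MismatchPolicy,
    SpacerPolicy,
    SpongeConstruct,
    assemble_insert,
    build_mbs,
    enzyme_by_name,
    make_spacer,
    validate_construct,
)

mirna_like = st.text(alphabet="ACGU", min_size=15, max_size=30)


def random_target(rng, n=22):
    """Random design-feasible miRNA (bulge disjoint from seed, clonable MBS)."""
    from circsponge.fixtures import FixtureSpec, random_design_target

    return random_design_target(
        rng, FixtureSpec(length_range=(n, n)), f"rand-{rng.random():.6f}"
    )


class TestEnzymes:
    def test_canonical_recognition_sequences(self):
        assert enzyme_by_name("EcoRV").recognition.residues == "GATATC"
        assert enzyme_by_name("SacII").recognition.residues == "CCGCGG"
        assert enzyme_by_name("HindIII").recognition.residues == "AAGCTT"
        assert enzyme_by_name("EcoRI").recognition.residues == "GAATTC"

    def test_defaults_are_palindromic(self):
        for name in ("EcoRV", "SacII", "HindIII", "EcoRI"):
            assert enzyme_by_name(name).is_palindromic

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(DesignError):
            enzyme_by_name("NotAnEnzyme123")


class TestBuildMbs:
    def test_default_mir21_mbs(self, mir21):
        mbs = build_mbs(mir21, DesignParams())
        assert mbs.seq.residues == "UCAACAUCACAGAGAUAAGCUA"
        # for a 22-nt miRNA, window 10-13 in miRNA coords is 10-13 in MBS coords
        assert mbs.bulge_positions_mbs == frozenset({10, 11, 12, 13})

    def test_empty_bulge_is_exact_reverse_complement(self, mir21):
        mbs = build_mbs(mir21, DesignParams(bulge_window=None))
        assert mbs.seq == reverse_complement(mir21.seq)

    def test_bulge_overlapping_seed_refused(self, mir21):
        with pytest.raises(DesignError):
            build_mbs(mir21, DesignParams(bulge_window=(5, 9)))

    def test_bulge_outside_mirna_refused(self, mir21):
        with pytest.raises(DesignError):
            build_mbs(mir21, DesignParams(bulge_window=(20, 25)))

    @given(mirna_like)
    @settings(max_examples=100)
    def test_identity_bulge_never_pairs_and_preserves_bases(self, s):
        m = MiRNA.from_string("rand", s)
        window = (10, min(13, len(s)))
        p = DesignParams(bulge_window=window)
        mbs = build_mbs(m, p)
        L = len(m)
        bulge = list(range(window[0], window[1] + 1))
        # multiset of bulge bases equals the miRNA's own bases there
        assert Counter(mbs.seq.residues[L - mp] for mp in bulge) == Counter(
            m.seq.residues[mp - 1] for mp in bulge
        )
        for mp in range(1, L + 1):
            x, y = m.seq.residues[mp - 1], mbs.seq.residues[L - mp]
            if mp in bulge:
                assert not is_wc(x, y) and not is_wobble(x, y)
            else:
                assert is_wc(x, y)

    def test_seeded_random_policy_avoids_pairing_and_is_deterministic(self, mir21):
        p = DesignParams(mismatch_policy=MismatchPolicy.SEEDED_RANDOM, rng_seed=9)
        a = build_mbs(mir21, p, random.Random(9))
        b = build_mbs(mir21, p, random.Random(9))
        assert a.seq == b.seq
        rep = pair_duplex(mir21, a.seq)
        assert rep.mismatch_positions() == {10, 11, 12, 13}
        assert rep.wobble_positions() == set()

    def test_duplex_mismatches_confined_to_bulge(self, mir21):
        mbs = build_mbs(mir21, DesignParams(bulge_window=(11, 12)))
        rep = pair_duplex(mir21, mbs.seq)
        assert rep.mismatch_positions() == {11, 12}


class TestMakeSpacer:
    def test_zero_length_spacer(self, mir21):
        mbs = build_mbs(mir21, DesignParams())
        p = DesignParams(spacer_len=0)
        assert len(make_spacer(mir21, p, mbs.seq, mbs.seq, random.Random(1))) == 0

    def test_deterministic_and_creates_no_new_sites(self, mir21):
        from circsponge.site_scanner import find_seed_matches

        mbs = build_mbs(mir21, DesignParams())
        p = DesignParams()
        s1 = make_spacer(mir21, p, mbs.seq, mbs.seq, random.Random(1))
        s2 = make_spacer(mir21, p, mbs.seq, mbs.seq, random.Random(1))
        assert s1.residues == s2.residues and len(s1) == 4
        joined = NucleotideSequence(
            mbs.seq.residues + s1.residues + mbs.seq.residues, Alphabet.RNA
        )
        lo, hi = 22, 26
        assert not any(
            h.start < hi and h.end > lo for h in find_seed_matches(joined, mir21)
        )


class TestAssembleInsert:
    def test_default_layout(self, mir21, default_construct):
        c = default_construct
        assert len(c.insert) == 190  # 6 + 7*22 + 6*4 + 6
        assert c.insert.residues[:6] == "GATATC"
        assert c.insert.residues[-6:] == "CCGCGG"
        kinds = [f.kind for f in c.features]
        assert kinds == ["flank5"] + ["MBS", "spacer"] * 6 + ["MBS", "flank3"]
        assert c.tiles_exactly()

    def test_single_mbs_length(self, mir21):
        c = assemble_insert(mir21, DesignParams(n_mbs=1))
        assert len(c.insert) == 34  # 6 + 22 + 6

    def test_deterministic_for_fixed_seed(self, mir21):
        a = assemble_insert(mir21, DesignParams(rng_seed=5))
        b = assemble_insert(mir21, DesignParams(rng_seed=5))
        assert a.insert == b.insert and a.features == b.features

    def test_seeded_search_policy_assembles_validly(self, mir21):
        c = assemble_insert(
            mir21, DesignParams(spacer_policy=SpacerPolicy.SEEDED_SEARCH, rng_seed=3)
        )
        assert len(c.insert) == 190 and c.tiles_exactly()

    def test_length_formula_over_random_mirnas(self):
        rng = random.Random(2024)
        for _ in range(100):
            n = rng.randint(15, 30)
            m = random_target(rng, n)
            n_mbs = rng.randint(1, 8)
            spacer = rng.randint(0, 6)
            hi = min(13, n)
            p = DesignParams(n_mbs=n_mbs, spacer_len=spacer, bulge_window=(10, hi))
            c = assemble_insert(m, p)
            expected = 6 + n_mbs * n + (n_mbs - 1) * spacer + 6
            assert len(c.insert) == expected
            assert sum(f.end - f.start for f in c.features) == expected


class TestValidateConstruct:
    def test_default_design_passes_all_checks(self, mir21, default_construct, decoy_panel):
        report = validate_construct(default_construct, mir21, decoy_panel)
        assert report.passed, report.to_tsv()
        assert {c.name for c in report.checks} == {
            "site_count",
            "mbs_duplexes",
            "forbidden_sites",
            "decoy_sites",
            "feature_tiling",
        }

    def test_corrupted_seed_pairing_fails(self, mir21, default_construct):
        c = default_construct
        res = list(c.insert.residues)
        mbs1 = c.features_of_kind("MBS")[0]
        # break a seed-pairing position (MBS position 18 faces miRNA position 5)
        q = mbs1.start + 17
        res[q] = "A" if res[q] != "A" else "G"
        corrupted = SpongeConstruct(
            NucleotideSequence("".join(res), Alphabet.DNA),
            c.features,
            c.params_used,
            c.target,
        )
        report = validate_construct(corrupted, mir21, [])
        failed = {ck.name for ck in report.checks if not ck.passed}
        assert "site_count" in failed or "mbs_duplexes" in failed

    def test_hindiii_inside_spacer_fails_naming_the_enzyme(self, mir21, default_construct):
        # a 6-nt spacer gives room to plant the full recognition sequence
        wide = assemble_insert(mir21, DesignParams(spacer_len=6))
        spacer = wide.features_of_kind("spacer")[0]
        res = list(wide.insert.residues)
        res[spacer.start : spacer.end] = "AAGCTT"
        corrupted = SpongeConstruct(
            NucleotideSequence("".join(res), Alphabet.DNA),
            wide.features,
            wide.params_used,
            wide.target,
        )
        report = validate_construct(corrupted, mir21, [])
        check = {c.name: c for c in report.checks}["forbidden_sites"]
        assert not check.passed and "HindIII" in check.detail

    def test_broken_tiling_detected(self, mir21, default_construct):
        c = default_construct
        gappy = SpongeConstruct(
            c.insert, c.features[:-1], c.params_used, c.target
        )
        report = validate_construct(gappy, mir21, [])
        assert not {ck.name: ck for ck in report.checks}["feature_tiling"].passed

    def test_fifty_seeded_random_designs_validate(self):
        rng = random.Random(123)
        for i in range(50):
            m = random_target(rng)
            p = DesignParams(rng_seed=i)
            c = assemble_insert(m, p)
            report = validate_construct(c, m, [])
            assert report.passed, (m.id, report.to_tsv())

    def test_report_serialization_round_trip_fields(self, mir21, default_construct):
        import json

        report = validate_construct(default_construct, mir21, [])
        data = json.loads(report.to_json())
        assert data["passed"] is True and len(data["checks"]) == 5
        tsv = report.to_tsv().splitlines()
        assert tsv[0] == "check\tpassed\tdetail" and len(tsv) == 6
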