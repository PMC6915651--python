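"""Species profiling, enzyme selection (incl. greedy vs exhaustive cover), assignment."""

from itertools import combinations

import pytest

from coibar.discriminate import (
    Assignment,
    ReferencePanel,
    assign_sample,
    builtin_reference_profiles,
    evaluate_enzyme,
    profile_species,
    select_enzymes,
)
from coibar.gel import make_pattern
from coibar.restriction import digest
from coibar.seqio import SeqRecord
from coibar.synth import make_clade_variant, make_panel

from conftest import polyA_with_sites


def _panel(records):
    return ReferencePanel.from_records(records)


@pytest.fixture(scope="module")
def synthetic_panel():
    return make_panel(seed=42)


class TestProfileSpecies:
    def test_identical_sequences_identical_single_variant(self, mboi, make_labeled_record):
        seq = "A" * 300 + "GATC" + "A" * 396
        panel = _panel([
            make_labeled_record("a1", seq, "spA"),
            make_labeled_record("b1", seq, "spB"),
        ])
        pa, pb = profile_species(panel, mboi)
        assert pa.n_variants == pb.n_variants == 1
        assert pa.variants[0][0].bands == pb.variants[0][0].bands

    def test_planted_site_gain_makes_second_variant(self, mboi, make_labeled_record):
        base = "A" * 300 + "GATC" + "A" * 396
        rec = make_labeled_record("a1", base, "spA")
        variant = make_clade_variant(rec, mboi, "add-site", seed=5)
        panel = _panel([
            rec,
            SeqRecord(id="a2", sequence=variant.sequence, declared_species="spA"),
        ])
        (profile,) = profile_species(panel, mboi)
        assert profile.n_variants == 2

    def test_variant_count_bounded_by_record_count(self, synthetic_panel, mboi):
        panel, _ = synthetic_panel
        for profile in profile_species(panel, mboi):
            assert profile.n_variants <= len(panel.species[profile.species])


class TestEvaluateEnzyme:
    def test_matching_species_not_discriminated(self, mboi, make_labeled_record):
        seq = "A" * 700
        panel = _panel([
            make_labeled_record("a1", seq, "spA"),
            make_labeled_record("b1", seq, "spB"),
        ])
        report = evaluate_enzyme(profile_species(panel, mboi))
        assert not report.discriminates_all

    def test_single_species_trivially_true_but_flagged(self, mboi, make_labeled_record):
        panel = _panel([make_labeled_record("a1", "A" * 700, "spA")])
        report = evaluate_enzyme(profile_species(panel, mboi))
        assert report.discriminates_all and report.flagged

    def test_permutation_invariant_in_species_order(self, synthetic_panel, mboi):
        panel, _ = synthetic_panel
        profiles = profile_species(panel, mboi)
        fwd = evaluate_enzyme(profiles)
        rev = evaluate_enzyme(list(reversed(profiles)))
        assert fwd.pairwise == rev.pairwise
        assert fwd.discriminates_all == rev.discriminates_all


class TestSelectEnzymes:
    def test_planted_enzyme_ranked_first_single_solution(self, synthetic_panel, enzymes):
        panel, truth = synthetic_panel
        reports, solution = select_enzymes(panel, list(enzymes.values()))
        assert reports[0].enzyme == truth.planted_enzyme
        assert reports[0].discriminates_all
        assert solution.feasible and solution.enzymes == (truth.planted_enzyme,)

    def _cover_panel(self, enzymes, make_labeled_record):
        """Three species where MboI separates only (A,B) and HpaII separates
        A and B from C: a two-enzyme cover is required."""
        # MboI cuts at 200/244/221 -> A vs B differ >10%, C sits within 10% of both
        seqs = {
            "spA": polyA_with_sites(700, {"MboI": [200], "HpaII": [350]}, enzymes),
            "spB": polyA_with_sites(700, {"MboI": [244], "HpaII": [350]}, enzymes),
            "spC": polyA_with_sites(700, {"MboI": [221], "HpaII": [170]}, enzymes),
        }
        return _panel([
            make_labeled_record(f"{sp}_1", seq, sp) for sp, seq in seqs.items()
        ])

    def test_greedy_cover_matches_exhaustive_minimum(self, enzymes, make_labeled_record):
        panel = self._cover_panel(enzymes, make_labeled_record)
        reports, solution = select_enzymes(panel, list(enzymes.values()))
        assert not reports[0].discriminates_all
        assert solution.feasible

        all_pairs = {tuple(sorted(p)) for p in combinations(panel.species, 2)}
        coverage = {r.enzyme: r.distinguished_pairs() for r in reports}
        exhaustive_min = min(
            (len(sub) for n in range(1, len(coverage) + 1)
             for sub in combinations(coverage, n)
             if set().union(*(coverage[e] for e in sub)) >= all_pairs),
        )
        assert len(solution.enzymes) == exhaustive_min == 2
        covered = set().union(*(coverage[e] for e in solution.enzymes))
        assert covered >= all_pairs

    def test_infeasible_when_nothing_cuts(self, enzymes, make_labeled_record):
        panel = _panel([
            make_labeled_record("a1", "A" * 700, "spA"),
            make_labeled_record("b1", "A" * 700, "spB"),
        ])
        _, solution = select_enzymes(panel, list(enzymes.values()))
        assert not solution.feasible and solution.diagnostic


class TestAssignSample:
    def test_exact_reference_pattern_scores_one(self, synthetic_panel, mboi):
        panel, truth = synthetic_panel
        profiles = profile_species(panel, mboi)
        for sp, recs in panel.species.items():
            result = assign_sample(recs[0], profiles, mboi)
            assert result == Assignment(
                status="assigned", species=sp,
                variant_index=result.variant_index, score=1.0,
                matched_record_ids=result.matched_record_ids,
            )

    def test_unknown_pattern_unassigned(self, synthetic_panel, mboi):
        panel, _ = synthetic_panel
        profiles = profile_species(panel, mboi)
        result = assign_sample(make_pattern([999]), profiles, mboi)
        assert result.status == "unassigned"

    def test_ambiguous_when_two_species_tie(self, mboi, make_labeled_record):
        seq = "A" * 300 + "GATC" + "A" * 396
        panel = _panel([
            make_labeled_record("a1", seq, "spA"),
            make_labeled_record("b1", seq, "spB"),
        ])
        profiles = profile_species(panel, mboi)
        observed = make_pattern(digest(seq, mboi))
        assert assign_sample(observed, profiles, mboi).status == "ambiguous"

    def test_empty_profiles_error(self, mboi):
        with pytest.raises(ValueError):
            assign_sample(make_pattern([510]), [], mboi)


class TestBuiltinReferenceProfiles:
    """The bundled MboI gel patterns of the five market species."""

    def test_observed_band_assignments(self):
        profiles = builtin_reference_profiles()
        cases = {
            (510,): ("Oxynotus centrina", None),
            (400, 110): ("Prionace glauca", None),
            (400, 150): ("Scyliorhinus canicula", None),
            (390, 180, 120): ("Mustelus mustelus", None),
            (240, 220, 170): ("Xiphias gladius", "clade_I"),
            (280, 220, 170): ("Xiphias gladius", "clade_II"),
        }
        for bands, (species, clade) in cases.items():
            result = assign_sample(make_pattern(bands), profiles)
            assert result.status == "assigned" and result.species == species
            if clade:
                assert result.matched_record_ids == (clade,)

    def test_all_patterns_pairwise_distinct(self):
        profiles = builtin_reference_profiles()
        variants = [(p.species, v) for p in profiles for v, _ in p.variants]
        assert len(variants) == 6
        from coibar.gel import patterns_match

        for (_, a), (_, b) in combinations(variants, 2):
            assert not patterns_match(a, b, tolerance=0.10)
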