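"""Site mapping and the four screening filters."""

from collections import Counter

import pytest

from ubigain import (
    ModSite,
    OrthologAlignment,
    ScreenConfig,
    build_reference_index,
    map_site,
    screen_site,
    residue_profile,
)
from ubigain.alignments import ColumnProfile
from ubigain.screening import (
    EUARCHONTOGLIRES_K,
    LOW_CONSERVATION,
    MANY_NONPRIMATE_K,
    MULTI_COPY,
    NO_ALIGNMENT,
    PEPTIDE_MISMATCH,
    filter_conservation,
    filter_euarchontoglires,
    filter_multicopy,
    filter_nonprimate_lysines,
)
from ubigain.synthetic_data import SimConfig, simulate_gene


def profile_from(tree, overrides, default="Q"):
    """A full-roster single-column profile with the given species residues."""
    residues = {sp: default for sp in tree.species}
    residues.update(overrides)
    return ColumnProfile(column=0, residue_by_species=residues)


class TestMapSite:
    def test_position_and_context_agree(self, ercc2):
        aln, site = ercc2
        res = map_site(site, aln)
        assert res.ok and res.corrected_position is None
        assert aln.reference_row[res.column] == "K"

    def test_position_not_k_peptide_absent_is_mismatch(self):
        aln = OrthologAlignment("g", {"hg19": "A" * 30})
        site = ModSite("g", 10, "AAAAAAKAAAAAA")
        res = map_site(site, aln)
        assert not res.ok and res.failure == PEPTIDE_MISMATCH

    def test_context_disagreement_is_mismatch(self):
        ref = "AAAAAAAAAKKQQQQQQQ"
        aln = OrthologAlignment("g", {"hg19": ref})
        # position 10 holds K but the reported context does not occur there —
        # and the peptide matches nowhere else either
        site = ModSite("g", 10, "CCCCCCKCCCCCC")
        res = map_site(site, aln)
        assert not res.ok and res.failure == PEPTIDE_MISMATCH

    def test_unique_peptide_search_remaps_with_correction(self):
        # an upstream 3-residue indel shifted coordinates: reported position
        # holds Q, but the peptide occurs uniquely 3 residues downstream
        ref = "QQQ" + "AAAAAA" + "ESEETLKRIEQIA" + "AAAAAA"
        aln = OrthologAlignment("g", {"hg19": ref})
        site = ModSite("g", 13, "ESEETLKRIEQIA")  # true lysine is at 16
        res = map_site(site, aln)
        assert res.ok and res.corrected_position == 16
        assert aln.ungapped_reference[15] == "K"

    def test_multiple_peptide_hits_is_mismatch(self):
        ref = "ESEETLKRIEQIA" + "ESEETLKRIEQIA"
        aln = OrthologAlignment("g", {"hg19": ref})
        site = ModSite("g", 1, "ESEETLKRIEQIA")  # position 1 holds E
        assert map_site(site, aln).failure == PEPTIDE_MISMATCH

    def test_x_wildcard_matches_either_side(self):
        aln = OrthologAlignment("g", {"hg19": "AAAXAAKAAAAAA"})
        # 'X' in the reference (index 3) and in the peptide (index 9) both match
        site = ModSite("g", 7, "AAAQAAKAAXAAA")
        assert map_site(site, aln).ok

    def test_no_alignment(self):
        site = ModSite("g", 7, "AAAAAAKAAAAAA")
        assert map_site(site, None).failure == NO_ALIGNMENT


class TestFilterEuarchontoglires:
    def test_mouse_lysine_fails(self, tree):
        prof = profile_from(tree, {"hg19": "K", "mm9": "K"})
        assert not filter_euarchontoglires(prof, tree).passed

    def test_non_lysine_outgroup_passes(self, tree):
        prof = profile_from(tree, {"hg19": "K", "mm9": "R", "rn4": "Q", "tupBel1": None})
        assert filter_euarchontoglires(prof, tree).passed

    def test_all_missing_outgroup_passes_with_flag(self, tree):
        eua = [s for s, t in tree.major_clade.items() if t == "eua"]
        prof = profile_from(tree, {"hg19": "K", **{s: None for s in eua}})
        res = filter_euarchontoglires(prof, tree)
        assert res.passed and res.flag == "EUA_ALL_MISSING"

    def test_primate_lysines_never_trigger(self, tree):
        prof = profile_from(tree, {s: "K" for s in tree.primates})
        assert filter_euarchontoglires(prof, tree).passed


class TestFilterNonprimateLysines:
    def test_fraction_above_cap_fails(self, tree):
        nonpri = sorted(s for s, t in tree.major_clade.items() if t != "pri")
        prof = profile_from(tree, {s: "K" for s in nonpri[:10]})  # 10 of 26
        res = filter_nonprimate_lysines(prof, tree, ScreenConfig())
        assert not res.passed and res.value == pytest.approx(10 / 26)

    def test_zero_lysines_pass(self, tree):
        res = filter_nonprimate_lysines(profile_from(tree, {}), tree, ScreenConfig())
        assert res.passed and res.value == 0.0

    def test_missing_excluded_from_denominator(self, tree):
        nonpri = sorted(s for s, t in tree.major_clade.items() if t != "pri")
        overrides = {s: None for s in nonpri[:6]}  # 20 observed remain
        overrides[nonpri[6]] = "K"  # 1 of 20 = 0.05
        res = filter_nonprimate_lysines(profile_from(tree, overrides), tree, ScreenConfig())
        assert res.passed and res.value == pytest.approx(0.05)

    def test_all_missing_passes_with_flag(self, tree):
        nonpri = [s for s, t in tree.major_clade.items() if t != "pri"]
        prof = profile_from(tree, {s: None for s in nonpri})
        res = filter_nonprimate_lysines(prof, tree, ScreenConfig())
        assert res.passed and res.flag == "NONPRIMATE_ALL_MISSING"


class TestFilterConservation:
    def test_fully_conserved_window_passes(self, make_aln, tree):
        aln = make_aln(length=41, overrides={21: {"default": "Q", "hg19": "K"}})
        res = filter_conservation(aln, 20, tree, ScreenConfig())
        assert res.passed and res.value == pytest.approx(1.0)

    def test_half_matching_species_fail(self, species_order, tree):
        # half the non-human species differ from the reference everywhere
        half = set(species_order[1:19])
        rows = {
            sp: ("W" if sp in half else "A") * 41 for sp in species_order
        }
        rows["hg19"] = "A" * 20 + "K" + "A" * 20
        aln = OrthologAlignment("g", rows)
        res = filter_conservation(aln, 20, tree, ScreenConfig())
        assert not res.passed and res.value == pytest.approx(18 / 36)

    def test_two_species_70pct_passes_default(self, tree):
        # reference + one species matching at 14 of 20 window columns
        other = "A" * 7 + "W" * 3 + "A" * 3 + "K" + "A" * 4 + "W" * 3 + "A" * 20
        rows = {"hg19": "A" * 13 + "K" + "A" * 27, "panTro2": other[:41]}
        aln = OrthologAlignment("g", rows)
        res = filter_conservation(aln, 13, tree, ScreenConfig())
        assert res.value == pytest.approx(14 / 20)
        assert res.passed


class TestFilterMulticopy:
    def test_unique_sequence_passes(self, make_aln):
        aln = make_aln("g1", 40)
        assert filter_multicopy(aln, build_reference_index([aln])).passed

    def test_identical_human_rows_fail_both(self, make_aln):
        a, b = make_aln("g1", 40), make_aln("g2", 40)
        index = build_reference_index([a, b])
        assert not filter_multicopy(a, index).passed
        assert not filter_multicopy(b, index).passed

    def test_one_residue_difference_passes(self, make_aln):
        a = make_aln("g1", 40)
        b = make_aln("g2", 40, overrides={5: {"hg19": "W"}})
        index = build_reference_index([a, b])
        assert filter_multicopy(a, index).passed
        assert filter_multicopy(b, index).passed


class TestScreenSite:
    def test_clean_gain_retained(self, ercc2, tree):
        aln, site = ercc2
        call = screen_site(site, aln, tree, ScreenConfig(), build_reference_index([aln]))
        assert call.retained and call.reasons == []

    def test_all_failing_reasons_collected(self, species_order, tree):
        # mouse K at the site column AND an unconserved window
        half = set(species_order[1:19])
        rows = {sp: ("W" if sp in half else "A") * 41 for sp in species_order}
        rows["hg19"] = "A" * 20 + "K" + "A" * 20
        rows["mm9"] = rows["mm9"][:20] + "K" + rows["mm9"][21:]
        aln = OrthologAlignment("g", rows)
        site = ModSite("g", 21, "AAAAAAKAAAAAA")
        call = screen_site(site, aln, tree, ScreenConfig())
        assert call.status == "discarded"
        assert call.reasons == [EUARCHONTOGLIRES_K, LOW_CONSERVATION]

    def test_multicopy_reason(self, ercc2, tree):
        aln, site = ercc2
        index = Counter({aln.ungapped_reference: 2})
        call = screen_site(site, aln, tree, ScreenConfig(), index)
        assert call.reasons == [MULTI_COPY]

    def test_threshold_tightening_is_monotone(self, tree):
        loose = ScreenConfig(
            conservation_min_identity=0.5, nonprimate_lysine_max_fraction=0.3
        )
        strict = ScreenConfig(
            conservation_min_identity=0.8, nonprimate_lysine_max_fraction=0.05
        )
        retained_loose, retained_strict = set(), set()
        for i in range(30):
            cfg = SimConfig(tree=tree, substitution_rate=0.05, seed=100 + i)
            aln, site, _ = simulate_gene(cfg, i)
            if screen_site(site, aln, tree, loose).retained:
                retained_loose.add(aln.gene_id)
            if screen_site(site, aln, tree, strict).retained:
                retained_strict.add(aln.gene_id)
        assert retained_strict <= retained_loose

    def test_verdict_independent_of_filter_order(self, species_order, tree):
        # the reason set equals exactly the independently failing predicates
        half = set(species_order[1:19])
        rows = {sp: ("W" if sp in half else "A") * 41 for sp in species_order}
        rows["hg19"] = "A" * 20 + "K" + "A" * 20
        rows["mm9"] = rows["mm9"][:20] + "K" + rows["mm9"][21:]
        aln = OrthologAlignment("g", rows)
        site = ModSite("g", 21, "AAAAAAKAAAAAA")
        cfg = ScreenConfig()
        call = screen_site(site, aln, tree, cfg)
        prof = residue_profile(aln, 20, tree)
        independent = {
            EUARCHONTOGLIRES_K: not filter_euarchontoglires(prof, tree).passed,
            MANY_NONPRIMATE_K: not filter_nonprimate_lysines(prof, tree, cfg).passed,
            LOW_CONSERVATION: not filter_conservation(aln, 20, tree, cfg).passed,
        }
        assert set(call.reasons) == {k for k, failed in independent.items() if failed}
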