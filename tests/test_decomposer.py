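"""Neutral-loss decomposition, ladder prediction/matching, annotation."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pt_mass

from saponet import (AnnotationConfig, GeneratorConfig, Peak, Spectrum,
                     annotate, adduct_mz, decompose_mass, fixture_spectrum,
                     generate_dataset, generate_ladder, infer_neutral_mass,
                     match_ladder, monoisotopic_mass, primary_spectra)
from saponet.decompose import (Candidate, GlycanComposition, classify_skeleton,
                               parse_loss_label)

AGLYCONE_FORMULAS = {
    "diosgenin": "C27H42O3",
    "laxogenin": "C27H42O4",
    "sarsa/tigogenin": "C27H44O3",
    "27OH-sarsa/tigogenin": "C27H44O4",
    "sieboldigenin": "C27H42O5",
    "3,6,27-triOH-furostane": "C27H44O5",
}


def oracle_decompose(m, tol_ppm):
    """Independent brute-force enumeration using pyteomics masses."""
    glc = pt_mass.calculate_mass(formula="C6H10O5")
    ara = pt_mass.calculate_mass(formula="C5H8O4")
    water = pt_mass.calculate_mass(formula="H2O")
    out = set()
    for name, formula in AGLYCONE_FORMULAS.items():
        base = pt_mass.calculate_mass(formula=formula)
        for g in range(5):
            for a in range(3):
                for w in (0, 1):
                    theo = base + g * glc + a * ara + w * water
                    if abs((theo - m) / theo * 1e6) <= tol_ppm:
                        out.add((name, g, a, w))
    return out


def as_keys(candidates):
    return {(c.aglycone.name, c.glycan.n_glc, c.glycan.n_ara, c.extra_water)
            for c in candidates}


def make_candidate(aglycone_by_name, name, n_glc, n_ara, extra_water):
    agl = aglycone_by_name[name]
    glycan = GlycanComposition(n_glc, n_ara)
    theo = agl.mass + glycan.residue_mass + extra_water * monoisotopic_mass("H2O")
    return Candidate(agl, glycan, extra_water, theo, 0.0)


class TestDecompose:
    def test_reference_masses_decompose_as_published(self):
        assert ("laxogenin", 2, 1, 0) in as_keys(decompose_mass(886.4562))
        assert as_keys(decompose_mass(430.3083)) == {("laxogenin", 0, 0, 0)}
        keys = as_keys(decompose_mass(904.4668))
        assert ("laxogenin", 2, 1, 1) in keys
        # the exact formula degeneracy: laxogenin+H2O == the 27-OH furostane backbone
        assert ("3,6,27-triOH-furostane", 2, 1, 0) in keys

    def test_equals_bruteforce_oracle_on_random_masses(self):
        rng = random.Random(1234)
        for _ in range(200):
            m = rng.uniform(400.0, 1300.0)
            assert as_keys(decompose_mass(m, 5.0)) == oracle_decompose(m, 5.0), m

    def test_sorted_by_abs_ppm_and_errors(self):
        cands = decompose_mass(886.4560)
        ppms = [abs(c.ppm) for c in cands]
        assert ppms == sorted(ppms)
        with pytest.raises(ValueError):
            decompose_mass(-1.0)
        assert decompose_mass(600.0, 1.0) == []

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(400.0, 1300.0), st.floats(0.5, 5.0), st.floats(5.0, 25.0))
    def test_widening_tolerance_never_removes_candidates(self, m, tol_lo, tol_hi):
        assert as_keys(decompose_mass(m, tol_lo)) <= as_keys(decompose_mass(m, tol_hi))


class TestInferNeutralMass:
    def test_multi_species_corroboration(self):
        cands = infer_neutral_mass(
            [("negative", 723.3958), ("negative", 769.4012), ("positive", 725.4099)])
        top = cands[0]
        assert top.support == 3
        assert abs(top.mass - 724.4034) < 0.01
        species = {name for _, name, _ in top.assignments}
        assert species == {"[M-H]-", "[M+HCOO]-", "[M+H]+"}

    def test_single_positive_ion_yields_alternatives(self):
        cands = infer_neutral_mass([("positive", 431.3161)])
        masses = {round(c.mass, 4): c for c in cands}
        assert any(abs(m - 430.3088) < 1e-3 for m in masses)
        assert any(abs(c.mass - 98.99272) < 1e-4
                   for c in infer_neutral_mass([("positive", 100.0)]))

    def test_requires_at_least_one_ion(self):
        with pytest.raises(ValueError):
            infer_neutral_mass([])


class TestLadder:
    def test_laxogenin_triglycoside_ladder_values(self, aglycone_by_name):
        cand = make_candidate(aglycone_by_name, "laxogenin", 2, 1, 0)
        mzs = [ion.mz for ion in generate_ladder(cand)]
        for expected in (725.4107, 593.3682, 431.3156, 413.3050,
                         287.2006, 269.1900, 251.1795):
            assert any(abs(mz - expected) < 5e-4 for mz in mzs), expected

    def test_aglycone_only_ladder(self, aglycone_by_name):
        cand = make_candidate(aglycone_by_name, "laxogenin", 0, 0, 0)
        ladder = generate_ladder(cand)
        labels = {ion.label for ion in ladder}
        assert "[M+H]+" in labels and "[M+H-H2O]+" in labels
        assert any("C8H16O2" in lab for lab in labels)
        assert all(not ion.loss_counter.get("Glc") for ion in ladder)

    def test_27oh_classes_use_142_never_144(self, aglycone_by_name):
        for name in ("27OH-sarsa/tigogenin", "sieboldigenin"):
            cand = make_candidate(aglycone_by_name, name, 1, 1, 0)
            for ion in generate_ladder(cand):
                assert "EF144" not in ion.loss_counter
        # ...while the trihydroxy furostane class fragments via 144 after
        # shedding its extra hydroxyls as water
        cand = make_candidate(aglycone_by_name, "3,6,27-triOH-furostane", 3, 1, 1)
        assert any("EF144" in ion.loss_counter for ion in generate_ladder(cand))

    def test_ladder_closure(self, aglycone_by_name):
        """Every ladder ion m/z equals the adduct of (mass - losses)."""
        from saponet.masses import neutral_loss_mass
        cand = make_candidate(aglycone_by_name, "diosgenin", 3, 1, 1)
        for ion in generate_ladder(cand):
            lost = sum(neutral_loss_mass(k) * n for k, n in ion.losses)
            assert abs(ion.mz - adduct_mz(cand.theoretical_mass - lost, "[M+H]+")) < 1e-6

    def test_reference_fragment_labels_covered(self, records, aglycone_by_name):
        """For every printed fragment whose loss label is arithmetically
        consistent with its printed m/z, the generated ladder contains an
        ion within 0.02 Da with the identical loss multiset.  (A handful
        of printed labels contradict their own m/z and are excluded.)"""
        from saponet.masses import neutral_loss_mass
        n_checked = n_skipped = 0
        for rec in records:
            cand = make_candidate(aglycone_by_name, rec.aglycone,
                                  rec.n_glc, rec.n_ara, rec.extra_water)
            base = adduct_mz(cand.theoretical_mass, "[M+H]+")
            ladder = generate_ladder(cand)
            for mz, label in rec.fragments:
                losses = parse_loss_label(label)
                derived = base - sum(neutral_loss_mass(k) * n for k, n in losses.items())
                if abs(derived - mz) > 0.02:
                    n_skipped += 1
                    continue
                n_checked += 1
                hit = [ion for ion in ladder
                       if abs(ion.mz - mz) <= 0.02 and ion.loss_counter == losses]
                assert hit, (rec.number, mz, label)
        assert n_checked > 150
        assert n_skipped <= 20


class TestMatchLadder:
    def test_reference_triglycoside_matches_seven_fragments(
            self, records_by_no, aglycone_by_name):
        rec = records_by_no[4]
        spec = Spectrum(id="frags", precursor_mz=887.4646, polarity="positive",
                        peaks=[Peak(mz) for mz, _ in rec.fragments])
        cand = make_candidate(aglycone_by_name, "laxogenin", 2, 1, 0)
        matches = match_ladder(spec, generate_ladder(cand))
        assert len(matches) == 7

    def test_empty_peak_list(self, aglycone_by_name):
        spec = Spectrum(id="x", precursor_mz=500.0, polarity="positive", peaks=[])
        cand = make_candidate(aglycone_by_name, "laxogenin", 1, 0, 0)
        assert match_ladder(spec, generate_ladder(cand)) == []

    def test_noise_free_synthetic_ladder_fully_assigned(self, aglycone_by_name):
        truths, by_part = generate_dataset(GeneratorConfig(
            seed=8, n_compounds=20, ppm_sigma=0.0, decoy_rate=0.0,
            parts_profile={"root": 1.0}))
        for truth, spec in zip(truths, primary_spectra(truths, by_part)):
            cand = make_candidate(aglycone_by_name, truth.aglycone,
                                  truth.n_glc, truth.n_ara,
                                  1 if truth.skeleton == "furostane" else 0)
            matches = match_ladder(spec, generate_ladder(cand))
            n_ladder_peaks = sum(1 for _, _, kind in spec.metadata["true_peaks"]
                                 if kind == "ladder")
            assert len(matches) == n_ladder_peaks


class TestClassifyAndAnnotate:
    def test_skeleton_classification_examples(self, records_by_no, aglycone_by_name):
        # furostane triglycoside: dehydrated precursor, extra water required
        cand8 = make_candidate(aglycone_by_name, "laxogenin", 2, 1, 1)
        assert classify_skeleton(cand8, 887.4628) == ("furostane", True)
        # (iso)spirostane diglycoside: intact protonated precursor
        cand2 = make_candidate(aglycone_by_name, "laxogenin", 1, 1, 0)
        assert classify_skeleton(cand2, 725.4099) == ("(iso)spirostane", True)
        # free laxogenin is a spirostane sapogenin
        cand1 = make_candidate(aglycone_by_name, "laxogenin", 0, 0, 0)
        assert classify_skeleton(cand1, 431.3161) == ("(iso)spirostane", True)
        # conflicting evidence is flagged, not silently resolved
        assert classify_skeleton(cand2, 707.3993)[1] is False

    def test_all_reference_records_annotated_with_published_compositions(
            self, records, config):
        classes = set()
        for rec in records:
            result = annotate(fixture_spectrum(rec), config)
            assert result, rec.number
            top = result[0]
            assert (top.aglycone, top.glycan.n_glc, top.glycan.n_ara) == \
                (rec.aglycone, rec.n_glc, rec.n_ara), rec.number
            expected_skeleton = "furostane" if rec.extra_water else "(iso)spirostane"
            assert top.skeleton == expected_skeleton, rec.number
            assert abs(top.ppm) <= config.tol_ppm
            assert top.n_matched >= config.min_matched
            classes.add(top.aglycone)
        assert len(classes) == 6

    def test_decoy_spectrum_rejected(self, config):
        rng = np.random.default_rng(17)
        peaks = sorted(rng.uniform(100.0, 777.0, size=30))
        spec = Spectrum(id="decoy", precursor_mz=777.7770, polarity="positive",
                        peaks=[Peak(float(mz), 1.0) for mz in peaks])
        assert annotate(spec, config) == []

    def test_negative_mode_spectrum_not_annotated(self, config):
        spec = Spectrum(id="neg", precursor_mz=723.3958, polarity="negative",
                        peaks=[Peak(500.0, 1.0)])
        assert annotate(spec, config) == []


class TestConfig:
    def test_from_file_and_overrides(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text(
            "# comment\ntol_ppm = 8\nfrag_tol_da = 0.01\nmin_matched = 4\n"
            "max_glc = 3\nallow_extra_water = false\n")
        cfg = AnnotationConfig.from_file(path)
        assert (cfg.tol_ppm, cfg.frag_tol_da, cfg.min_matched) == (8.0, 0.01, 4)
        assert cfg.max_glc == 3 and cfg.allow_extra_water is False

    def test_from_file_rejects_unknown_key(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("tolppm = 5\n")
        with pytest.raises(ValueError, match="unknown key"):
            AnnotationConfig.from_file(path)

    def test_defaults_are_standard_parameters(self):
        cfg = AnnotationConfig()
        assert (cfg.tol_ppm, cfg.frag_tol_da, cfg.min_matched) == (5.0, 0.02, 3)
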