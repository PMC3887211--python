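"""b/y fragment prediction, spectrum annotation, and site localization."""

import numpy as np
import pytest

from autometh import (
    AMBIGUOUS,
    METHYL,
    METHYL_DELTA,
    PROTON,
    InputError,
    ModifiedPeptide,
    PeakList,
    SpectrumSimConfig,
    annotate,
    localize,
    peptide_neutral_mass,
    predict_fragments,
    simulate_msms,
)
from tests.conftest import GIGCYMFR, random_sequence


def frag_map(fragments):
    return {(f.series, f.index): f for f in fragments if f.charge == 1}


def ms2(mzs, precursor_mz=500.0, precursor_charge=2):
    mzs = np.asarray(mzs, dtype=float)
    return PeakList(
        mz=mzs,
        intensity=np.ones(len(mzs)),
        ms_level=2,
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
    )


class TestPredictFragments:
    def test_y1_of_arginine(self):
        frags = frag_map(predict_fragments(GIGCYMFR))
        assert frags[("y", 1)].mz == pytest.approx(175.119, abs=1e-3)

    def test_methyl_shift_pattern(self, methylated_peptide):
        """Methyl at position 4: b2/b3 unchanged; b4-b7 and y5-y7 shifted +14.0157."""
        unmod = frag_map(predict_fragments(GIGCYMFR))
        mod = frag_map(predict_fragments(methylated_peptide))
        for i in (2, 3):
            assert mod[("b", i)].mz == unmod[("b", i)].mz
            assert not mod[("b", i)].carries_mod
        for i in (4, 5, 6, 7):
            assert mod[("b", i)].mz - unmod[("b", i)].mz == pytest.approx(
                METHYL_DELTA, abs=1e-9
            )
            assert mod[("b", i)].carries_mod
        for j in (5, 6, 7):
            assert mod[("y", j)].mz - unmod[("y", j)].mz == pytest.approx(
                METHYL_DELTA, abs=1e-9
            )
        for j in (1, 2, 3, 4):
            assert mod[("y", j)].mz == unmod[("y", j)].mz

    def test_by_complementarity_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(2, 15)))
            n = len(seq)
            frags = frag_map(predict_fragments(seq))
            total = peptide_neutral_mass(seq) + 2 * PROTON
            for i in range(1, n):
                assert frags[("b", i)].mz + frags[("y", n - i)].mz == pytest.approx(
                    total, abs=1e-6
                )

    def test_length_one_rejected(self):
        with pytest.raises(InputError):
            predict_fragments("G")

    def test_higher_charges_requested(self):
        frags = predict_fragments(GIGCYMFR, charges=(1, 2))
        ones = [f for f in frags if f.charge == 1]
        twos = [f for f in frags if f.charge == 2]
        assert len(ones) == len(twos) == 14
        for f1, f2 in zip(ones, twos):
            assert f2.mz < f1.mz


class TestAnnotate:
    def test_full_ladder_annotated(self, methylated_peptide):
        frags = predict_fragments(methylated_peptide)
        spec = ms2([f.mz for f in frags])
        anns = annotate(spec, frags, tol=0.5)
        assert len(anns) == 14  # 7 b + 7 y
        assert {(a.fragment.series, a.fragment.index) for a in anns} == {
            (s, i) for s in "by" for i in range(1, 8)
        }

    def test_out_of_tolerance_peak_skipped(self, methylated_peptide):
        frags = predict_fragments(methylated_peptide)
        b4 = next(f for f in frags if (f.series, f.index) == ("b", 4))
        spec = ms2([b4.mz + 0.8])
        assert annotate(spec, frags, tol=0.5) == []

    def test_empty_spectrum(self, methylated_peptide):
        frags = predict_fragments(methylated_peptide)
        assert annotate(ms2([]), frags, tol=0.5) == []


def itemized_evidence_spectrum():
    """The decisive ion inventory: unshifted b2/b3 plus +14-shifted b4-b7, y5, y6."""
    unmod = frag_map(predict_fragments(GIGCYMFR))
    mzs = [unmod[("b", 2)].mz, unmod[("b", 3)].mz]
    mzs += [unmod[("b", i)].mz + METHYL_DELTA for i in (4, 5, 6, 7)]
    mzs += [unmod[("y", j)].mz + METHYL_DELTA for j in (5, 6)]
    precursor = (peptide_neutral_mass(GIGCYMFR) + METHYL_DELTA + 2 * PROTON) / 2
    return ms2(mzs, precursor_mz=precursor, precursor_charge=2)


class TestLocalize:
    def test_itemized_ions_localize_cys4(self):
        result = localize(
            itemized_evidence_spectrum(),
            GIGCYMFR,
            METHYL,
            tol=0.5,
            parent_offset=3745,
            peptide_start=135,
        )
        assert result.best_site == 4
        assert result.residue_label == "Cys3882"
        assert result.site_determining_matched > 0

    def test_any_site_scoring_still_unique(self):
        """Brute-force scoring over all 8 placements: b3/b4 bracket position 4."""
        result = localize(
            itemized_evidence_spectrum(), GIGCYMFR, METHYL, tol=0.5, any_site=True
        )
        assert result.best_site == 4
        best = {c.position: c.score for c in result.candidate_sites}
        assert all(best[4] > s for p, s in best.items() if p != 4)

    def test_non_site_determining_ions_are_ambiguous(self):
        unmod = frag_map(predict_fragments(GIGCYMFR))
        precursor = (peptide_neutral_mass(GIGCYMFR) + METHYL_DELTA + 2 * PROTON) / 2
        spec = ms2([unmod[("y", j)].mz for j in (1, 2, 3)], precursor_mz=precursor)
        result = localize(spec, GIGCYMFR, METHYL, tol=0.5, any_site=True)
        assert result.best_site == AMBIGUOUS

    def test_no_candidate_sites(self):
        spec = ms2([300.0])
        result = localize(spec, "GAGAVLTE", METHYL, tol=0.5)
        assert result.best_site is None and result.candidate_sites == []

    def test_precursor_inconsistency_warns_not_fatal(self):
        spec = itemized_evidence_spectrum()
        spec.precursor_mz += 3.0
        with pytest.warns(UserWarning, match="precursor"):
            result = localize(spec, GIGCYMFR, METHYL, tol=0.5)
        assert result.best_site == 4 and result.warnings

    def test_score_invariant_to_peak_order_and_intensity(self):
        spec = itemized_evidence_spectrum()
        shuffled = PeakList(
            mz=spec.mz[::-1].copy(),
            intensity=np.full(len(spec), 1e6),
            ms_level=2,
            precursor_mz=spec.precursor_mz,
            precursor_charge=2,
        )
        r1 = localize(spec, GIGCYMFR, METHYL, tol=0.5, any_site=True)
        r2 = localize(shuffled, GIGCYMFR, METHYL, tol=0.5, any_site=True)
        assert [c.score for c in r1.candidate_sites] == [c.score for c in r2.candidate_sites]


class TestLocalizationNeverSilentlyWrong:
    def test_simulated_spectra_correct_or_ambiguous(self):
        """Random decapeptides, one methyl site, dropout and jitter: the
        localizer either recovers the true site or flags ambiguity."""
        rng = np.random.default_rng(42)
        n_correct = n_ambiguous = 0
        for trial in range(150):
            seq = random_sequence(rng, 10)
            true_site = int(rng.integers(1, 11))
            # ground truth may sit on any residue: widen methyl's target set
            anywhere_methyl = type(METHYL)(
                METHYL.name, METHYL.delta_mass, frozenset(seq)
            )
            peptide = ModifiedPeptide(seq, ((true_site, anywhere_methyl),))
            cfg = SpectrumSimConfig(
                mz_sigma=0.2, dropout_p=0.3, seed=int(rng.integers(2**31))
            )
            spec = simulate_msms(peptide, cfg)
            result = localize(spec, seq, METHYL, tol=0.5, any_site=True)
            if result.best_site == AMBIGUOUS:
                n_ambiguous += 1
            else:
                assert result.best_site == true_site, (seq, true_site, trial)
                n_correct += 1
        assert n_correct > 0 and n_correct + n_ambiguous == 150
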