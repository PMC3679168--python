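"""Tryptic digestion, peak matching, coverage, and MOWSE scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as ptmass
from pyteomics import parser as ptparser

from heterospot.pmf import (
    MowseIndex,
    PMFResult,
    SearchParams,
    accept_identification,
    identify,
    match_masses,
    matchable_fragments,
    n_distinct_matched,
    peptide_mh,
    search_database,
    sequence_coverage,
    strip_autolysis,
    tryptic_digest,
)
from heterospot.simulate import AMINO_ACIDS

sequences = st.text(alphabet=AMINO_ACIDS, min_size=10, max_size=120)


class TestDigest:
    def test_cleaves_after_k_and_r(self):
        frags = tryptic_digest("AKLR", 0)
        assert [f.sequence for f in frags] == ["AK", "LR"]
        assert [(f.start, f.end) for f in frags] == [(1, 2), (3, 4)]

    def test_proline_blocks_cleavage(self):
        frags = tryptic_digest("AKPR", 0)
        assert [f.sequence for f in frags] == ["AKPR"]

    def test_missed_cleavage_fragments(self):
        frags = tryptic_digest("AKLRG", 1)
        assert {f.sequence for f in frags} == {"AK", "LR", "G", "AKLR", "LRG"}
        by_seq = {f.sequence: f.missed_cleavages for f in frags}
        assert by_seq["AKLR"] == 1 and by_seq["AK"] == 0

    def test_glycine_mh_mass(self):
        # residue 57.02146 + water 18.010565 + proton 1.007276
        frag = tryptic_digest("G", 0)[0]
        assert frag.mh_mass == pytest.approx(76.0393, abs=1e-4)

    @given(sequences)
    @settings(max_examples=60, deadline=None)
    def test_zero_missed_concatenation_reconstructs(self, seq):
        frags = [f for f in tryptic_digest(seq, 2) if f.missed_cleavages == 0]
        assert "".join(f.sequence for f in sorted(frags, key=lambda f: f.start)) == seq

    @given(sequences, st.integers(0, 2))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_pyteomics(self, seq, missed):
        # oracle: pyteomics cleave with the simple no-cleavage-before-P
        # trypsin rule (the full ExPASy rule adds W|K-P and M|R-P
        # exceptions this pipeline deliberately does not use)
        ours = {f.sequence for f in tryptic_digest(seq, missed)}
        theirs = ptparser.cleave(seq, r"[KR](?!P)", missed_cleavages=missed)
        assert ours == set(theirs)

    @given(sequences)
    @settings(max_examples=40, deadline=None)
    def test_mh_matches_pyteomics_fast_mass(self, seq):
        for f in tryptic_digest(seq, 1)[:5]:
            ref = ptmass.fast_mass(f.sequence, ion_type="M", charge=1)
            assert f.mh_mass == pytest.approx(ref, abs=1e-4)

    def test_nonstandard_residue_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            tryptic_digest("AKXLR", 0)

    def test_carbamidomethyl_shifts_cys_peptides(self):
        plain = peptide_mh("ACK")
        fixed = peptide_mh("ACK", carbamidomethyl_cys=True)
        assert fixed - plain == pytest.approx(57.02146, abs=1e-4)


class TestMatching:
    def _frag(self, mh, start=1, end=10):
        from heterospot.pmf import PeptideFragment

        return PeptideFragment("X" * (end - start + 1), start, end, 0, mh)

    def test_within_tolerance_matches(self):
        m = match_masses([1000.000], [self._frag(1000.020)], tol_ppm=25)
        assert len(m) == 1
        assert m[0].error_ppm == pytest.approx(-20.0, abs=0.01)

    def test_outside_tolerance_no_match(self):
        assert match_masses([1000.030], [self._frag(1000.000)], tol_ppm=25) == []

    def test_empty_peak_list(self):
        assert match_masses([], [self._frag(1000.0)]) == []

    def test_closest_fragment_wins(self):
        frags = [self._frag(999.995, 1, 5), self._frag(1000.010, 6, 10)]
        m = match_masses([1000.000], frags, tol_ppm=25)
        assert len(m) == 1 and m[0].fragment.start == 1

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_equals_bruteforce_oracle(self, data):
        # oracle: all-pairs ppm filter with per-peak nearest assignment
        theo = sorted(
            data.draw(
                st.lists(st.floats(500, 5000), min_size=1, max_size=40, unique=True)
            )
        )
        obs = data.draw(st.lists(st.floats(500, 5000), min_size=0, max_size=40))
        frags = [self._frag(m, i * 10 + 1, i * 10 + 5) for i, m in enumerate(theo)]
        got = {
            (m.observed_mz, m.fragment.mh_mass)
            for m in match_masses(obs, frags, tol_ppm=25)
        }
        expected = set()
        for mz in obs:
            best = None
            for f in frags:
                ppm = abs(mz - f.mh_mass) / f.mh_mass * 1e6
                if ppm <= 25 and (best is None or ppm < best[0]):
                    best = (ppm, f.mh_mass)
            if best is not None:
                expected.add((mz, best[1]))
        assert got == expected

    def test_uniform_shift_within_tolerance_preserved(self):
        rng = np.random.default_rng(0)
        theo = np.sort(rng.uniform(500, 5000, 30))
        frags = [self._frag(m, i * 10 + 1, i * 10 + 5) for i, m in enumerate(theo)]
        base = match_masses(theo, frags, tol_ppm=25)
        shifted = match_masses(theo * (1 + 10e-6), frags, tol_ppm=25)
        assert len(base) == len(shifted) == 30

    def test_strip_autolysis_removes_calibrants(self):
        peaks = np.array([800.0, 2163.333, 2273.434, 3000.0])
        out = strip_autolysis(peaks)
        assert list(out) == [800.0, 3000.0]


class TestCoverage:
    def _match(self, start, end):
        from heterospot.pmf import Match, PeptideFragment

        return Match(0.0, PeptideFragment("X" * (end - start + 1), start, end, 0, 0.0), 0.0)

    def test_single_fragment_fraction(self):
        assert sequence_coverage([self._match(1, 10)], 100) == pytest.approx(0.10)

    def test_duplicate_fragments_counted_once(self):
        one = sequence_coverage([self._match(5, 14)], 100)
        two = sequence_coverage([self._match(5, 14), self._match(5, 14)], 100)
        assert one == two

    @given(st.lists(st.tuples(st.integers(1, 90), st.integers(0, 15)), max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_equals_boolean_mask_oracle(self, spans):
        length = 100
        matches = [self._match(s, min(s + w, length)) for s, w in spans]
        mask = np.zeros(length, dtype=bool)
        for m in matches:
            mask[m.fragment.start - 1 : m.fragment.end] = True
        assert sequence_coverage(matches, length) == pytest.approx(mask.mean())

    @given(st.lists(st.tuples(st.integers(1, 90), st.integers(0, 15)), max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_match_set(self, spans):
        length = 100
        matches = [self._match(s, min(s + w, length)) for s, w in spans]
        cov = 0.0
        for k in range(len(matches) + 1):
            new = sequence_coverage(matches[:k], length)
            assert new >= cov - 1e-12
            cov = new


class TestMowse:
    def test_zero_matches_score_zero(self, protein_db):
        index = MowseIndex(protein_db, SearchParams(n_decoys=50))
        pid = next(iter(protein_db))
        assert index.score_matches([], index.intact_mass(pid)) == 0.0

    def test_additional_match_never_decreases_score(self, protein_db):
        index = MowseIndex(protein_db, SearchParams(n_decoys=50))
        rng = np.random.default_rng(2)
        for pid in list(protein_db)[:10]:
            frags = matchable_fragments(index.digest(pid))
            if len(frags) < 3:
                continue
            peaks = np.sort([f.mh_mass for f in frags])
            matches = match_masses(peaks, frags, tol_ppm=25)
            k = rng.integers(1, len(matches))
            subset_score = index.score_matches(matches[:k], index.intact_mass(pid))
            full_score = index.score_matches(matches, index.intact_mass(pid))
            assert full_score >= subset_score

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MowseIndex({})


class TestAcceptance:
    def _result(self, **kw):
        base = dict(
            protein_id="P", matches=[], n_matched=5, coverage=0.2,
            score=100.0, threshold=10.0, significant=True, accepted=False,
            intact_mass=20000.0,
        )
        base.update(kw)
        return PMFResult(**base)

    def test_all_criteria_met_accepted(self):
        res = self._result(n_matched=4, coverage=0.12)
        assert accept_identification(res, SearchParams())

    def test_three_peptides_rejected(self):
        assert not accept_identification(self._result(n_matched=3), SearchParams())

    def test_low_coverage_rejected(self):
        assert not accept_identification(self._result(coverage=0.08), SearchParams())

    def test_insignificant_score_rejected(self):
        assert not accept_identification(
            self._result(significant=False), SearchParams()
        )

    def test_parent_mass_window_enforced(self):
        res = self._result(intact_mass=20000.5)
        params = SearchParams()
        assert not accept_identification(res, params, observed_intact_mass=20000.0)
        assert accept_identification(res, params, observed_intact_mass=20000.4)

    def test_true_spectrum_identified_end_to_end(self, protein_db):
        from heterospot import SpectrumConfig, simulate_pmf_spectrum

        params = SearchParams(n_decoys=200)
        index = MowseIndex(protein_db, params)
        pid = list(protein_db)[4]
        spec = simulate_pmf_spectrum(protein_db[pid], SpectrumConfig(seed=33))
        res = identify(spec, pid, index, np.random.default_rng(1))
        assert res.accepted
        assert res.n_matched >= 4 and res.coverage > 0.10
        ranked = search_database(spec, index)
        assert ranked[0][0] == pid
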