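"""Peptide-mass-fingerprint protein identification.

A PMF search matches the observed peptide masses of a digested gel spot
against in-silico tryptic digests of a protein database. An identification
is accepted only when all of the classic acceptance criteria hold:

1. a MOWSE-style score above the 95% significance threshold (p < 0.05),
   here estimated empirically from shuffled-sequence decoys;
2. at least four distinct predicted peptide masses matched;
3. sequence coverage by the matching peptides above 10%;
4. a peptide mass tolerance of 25 ppm;
5. a parent (intact protein) mass tolerance of 0.2 Da, applied when an
   intact mass is supplied.

Monoisotopic residue masses come from the standard table (pyteomics);
cysteine is unmodified by default with an optional fixed
carbamidomethylation. Peptides shorter than 4 residues or with [M+H]+
outside 500-5000 Da are excluded from matching, as is standard in PMF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _ptmass

WATER_MONO = 18.010565
PROTON_MONO = 1.007276
CARBAMIDOMETHYL = 57.02146  # fixed Cys modification, optional

#: [M+H]+ window of peptides considered matchable.
MASS_RANGE_DA = (500.0, 5000.0)
MIN_PEPTIDE_LENGTH = 4

#: Trypsin autolysis [M+H]+ peaks used as internal calibrants; optionally
#: stripped from observed peak lists before matching.
TRYPSIN_AUTOLYSIS_MZ = (2163.333, 2273.434)

RESIDUE_MONO = {aa: _ptmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

MOWSE_PEPTIDE_BIN_DA = 100.0
MOWSE_PROTEIN_BIN_DA = 10_000.0
MOWSE_SCALE = 50_000.0


@dataclass(frozen=True)
class PeptideFragment:
    """One tryptic fragment with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    mh_mass: float


@dataclass(frozen=True)
class Match:
    """An observed peak assigned to a theoretical fragment."""

    observed_mz: float
    fragment: PeptideFragment
    error_ppm: float


@dataclass
class SearchParams:
    """Thresholds of the five PMF acceptance criteria."""

    tol_ppm: float = 25.0
    parent_tol_da: float = 0.2
    max_missed_cleavages: int = 1
    alpha: float = 0.05
    min_peptides: int = 4
    min_coverage: float = 0.10
    n_decoys: int = 1000
    carbamidomethyl_cys: bool = False

    def __post_init__(self):
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PMFResult:
    """Outcome of searching one peak list against one candidate protein."""

    protein_id: str
    matches: list[Match]
    n_matched: int
    coverage: float
    score: float
    threshold: float
    significant: bool
    accepted: bool
    intact_mass: float = float("nan")


def _check_sequence(sequence: str) -> str:
    for i, aa in enumerate(sequence):
        if aa not in RESIDUE_MONO:
            raise ValueError(
                f"non-standard residue {aa!r} at position {i + 1}"
            )
    return sequence


def peptide_mh(sequence: str, carbamidomethyl_cys: bool = False) -> float:
    """Monoisotopic [M+H]+ mass: residue masses + water + proton."""
    m = sum(RESIDUE_MONO[aa] for aa in _check_sequence(sequence))
    if carbamidomethyl_cys:
        m += CARBAMIDOMETHYL * sequence.count("C")
    return m + WATER_MONO + PROTON_MONO


def protein_mass(sequence: str, carbamidomethyl_cys: bool = False) -> float:
    """Monoisotopic neutral mass of an intact protein."""
    m = sum(RESIDUE_MONO[aa] for aa in _check_sequence(sequence))
    if carbamidomethyl_cys:
        m += CARBAMIDOMETHYL * sequence.count("C")
    return m + WATER_MONO


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions *after* which trypsin cuts: K/R not followed by P."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    sequence: str,
    max_missed_cleavages: int = 1,
    carbamidomethyl_cys: bool = False,
) -> list[PeptideFragment]:
    """In-silico tryptic digest with 0..max_missed_cleavages missed sites.

    Cleaves C-terminal to K or R unless the next residue is P. Returns every
    fragment with its coordinates, missed-cleavage count and [M+H]+ mass; no
    length or mass filtering is applied here (the 0-missed fragments
    concatenate back to the input sequence).
    """
    _check_sequence(sequence)
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    # segment boundaries: [0, site+1 ..., len]
    bounds = [0] + [s + 1 for s in cleavage_sites(sequence)] + [len(sequence)]
    fragments = []
    n_seg = len(bounds) - 1
    for i in range(n_seg):
        for missed in range(max_missed_cleavages + 1):
            j = i + missed + 1
            if j > n_seg:
                break
            start, end = bounds[i], bounds[j]
            seq = sequence[start:end]
            fragments.append(
                PeptideFragment(
                    sequence=seq,
                    start=start + 1,
                    end=end,
                    missed_cleavages=missed,
                    mh_mass=peptide_mh(seq, carbamidomethyl_cys),
                )
            )
    return fragments


def matchable_fragments(fragments) -> list[PeptideFragment]:
    """Fragments inside the standard PMF search space (length and mass)."""
    lo, hi = MASS_RANGE_DA
    return [
        f
        for f in fragments
        if len(f.sequence) >= MIN_PEPTIDE_LENGTH and lo <= f.mh_mass <= hi
    ]


def strip_autolysis(peaks: np.ndarray, tol_ppm: float = 25.0) -> np.ndarray:
    """Remove trypsin autolysis calibrant peaks from an m/z vector."""
    mz = np.asarray(peaks, dtype=float)
    keep = np.ones(mz.shape[0], dtype=bool)
    for cal in TRYPSIN_AUTOLYSIS_MZ:
        col = mz if mz.ndim == 1 else mz[:, 0]
        keep &= np.abs(col - cal) / cal * 1e6 > tol_ppm
    return mz[keep]


def match_masses(observed, theoretical, tol_ppm: float = 25.0) -> list[Match]:
    """Assign observed peaks to theoretical fragments within a ppm window.

    Each observed peak matches at most one fragment — the one with the
    smallest |relative error|, ties broken toward the lower-mass fragment.
    A peak with no fragment within tol_ppm is unmatched. An empty peak list
    yields an empty match list.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim == 2:  # (m/z, intensity) peak list
        obs = obs[:, 0]
    frags = sorted(theoretical, key=lambda f: f.mh_mass)
    if obs.size == 0 or not frags:
        return []
    theo = np.array([f.mh_mass for f in frags])
    idx = np.searchsorted(theo, obs)
    matches = []
    for mz, i in zip(obs, idx):
        best = None
        for j in (i - 1, i):
            if 0 <= j < theo.size:
                ppm = (mz - theo[j]) / theo[j] * 1e6
                if abs(ppm) <= tol_ppm:
                    # tie toward the lower-mass fragment: strict < keeps j-1
                    if best is None or abs(ppm) < abs(best[1]):
                        best = (j, ppm)
        if best is not None:
            j, ppm = best
            matches.append(Match(float(mz), frags[j], float(ppm)))
    return matches


def n_distinct_matched(matches) -> int:
    """Distinct predicted peptides matched (a fragment counts once)."""
    return len({(m.fragment.start, m.fragment.end) for m in matches})


def sequence_coverage(matches, protein_length: int) -> float:
    """Fraction of parent residues covered by the union of matched fragments."""
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    ivals = sorted((m.fragment.start, m.fragment.end) for m in matches)
    covered = 0
    cur_start = cur_end = None
    for start, end in ivals:
        if cur_end is None or start > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered / protein_length


class MowseIndex:
    """Database-wide peptide-mass frequency matrix for MOWSE scoring.

    Fragment counts are binned by 100 Da peptide [M+H]+ mass and 10 kDa
    intact-protein mass, then normalized within each protein-mass column so
    each cell is the frequency of that peptide-mass bin among the column's
    fragments. A matched peptide contributes weight 1/frequency: matches to
    rare mass bins carry more evidence. The raw score is
    ``50000 / (product of matched-cell frequencies x intact mass in Da)``.
    """

    def __init__(self, database: dict[str, str], params: SearchParams | None = None):
        if not database:
            raise ValueError("protein database is empty")
        self.params = params or SearchParams()
        self.database = dict(database)
        self._digests: dict[str, list[PeptideFragment]] = {}
        self._masses: dict[str, float] = {}
        counts: dict[int, dict[int, int]] = {}
        for pid, seq in self.database.items():
            frags = matchable_fragments(
                tryptic_digest(
                    seq,
                    self.params.max_missed_cleavages,
                    self.params.carbamidomethyl_cys,
                )
            )
            self._digests[pid] = frags
            pmass = protein_mass(seq, self.params.carbamidomethyl_cys)
            self._masses[pid] = pmass
            col = int(pmass // MOWSE_PROTEIN_BIN_DA)
            cdict = counts.setdefault(col, {})
            for f in frags:
                row = int(f.mh_mass // MOWSE_PEPTIDE_BIN_DA)
                cdict[row] = cdict.get(row, 0) + 1
        # column-sum normalization: cell -> frequency within its column
        self._freq: dict[int, dict[int, float]] = {}
        self._floor: dict[int, float] = {}
        for col, cdict in counts.items():
            total = sum(cdict.values())
            self._freq[col] = {row: n / total for row, n in cdict.items()}
            # unseen cells get a sub-minimal pseudo-frequency
            self._floor[col] = 1.0 / (total + 1)

    def digest(self, protein_id: str) -> list[PeptideFragment]:
        return self._digests[protein_id]

    def intact_mass(self, protein_id: str) -> float:
        return self._masses[protein_id]

    def cell_frequency(self, peptide_mh: float, intact_mass: float) -> float:
        col = int(intact_mass // MOWSE_PROTEIN_BIN_DA)
        row = int(peptide_mh // MOWSE_PEPTIDE_BIN_DA)
        colfreq = self._freq.get(col)
        if colfreq is None:
            # no database protein in this mass class; fall back to global floor
            return min(self._floor.values())
        return colfreq.get(row, self._floor[col])

    def score_matches(self, matches, intact_mass: float) -> float:
        """MOWSE-style score of a match set against a candidate mass."""
        distinct = {}
        for m in matches:
            distinct[(m.fragment.start, m.fragment.end)] = m
        if not distinct:
            return 0.0
        product = 1.0
        for m in distinct.values():
            product *= self.cell_frequency(m.fragment.mh_mass, intact_mass)
        return MOWSE_SCALE / (product * intact_mass)


def mowse_score(
    matches,
    candidate_sequence: str,
    index: MowseIndex,
    peaks=None,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, bool, float]:
    """Score a match set and test significance against shuffled decoys.

    Returns ``(score, significant, threshold)``. The significance threshold
    is the (1 - alpha) quantile of scores obtained by matching the same
    peak list against ``n_decoys`` shuffles of the candidate sequence
    (shuffling preserves composition, hence intact mass). When ``peaks`` is
    None no decoy test is run and ``significant`` is False unless the score
    is positive and n_decoys == 0.
    """
    params = index.params
    cmass = protein_mass(candidate_sequence, params.carbamidomethyl_cys)
    score = index.score_matches(matches, cmass)
    if peaks is None or params.n_decoys == 0:
        return score, False, float("inf")
    threshold = decoy_score_threshold(peaks, candidate_sequence, index, rng)
    return score, bool(score > threshold), threshold


def _decoy_fragment_masses(
    residue_masses: np.ndarray,
    is_site_base: np.ndarray,
    not_proline: np.ndarray,
    max_missed: int,
    water_proton: float,
):
    """Matchable fragment [M+H]+ masses of one (shuffled) residue order.

    ``is_site_base`` flags K/R residues, ``not_proline`` flags non-P
    residues; both are aligned with ``residue_masses``. Vectorized
    equivalent of tryptic_digest + matchable_fragments for mass-only use.
    """
    n = residue_masses.size
    sites = np.flatnonzero(is_site_base[:-1] & not_proline[1:])
    bounds = np.concatenate(([0], sites + 1, [n]))
    csum = np.concatenate(([0.0], np.cumsum(residue_masses)))
    out = []
    n_seg = bounds.size - 1
    for missed in range(max_missed + 1):
        i = np.arange(n_seg - missed)
        start, end = bounds[i], bounds[i + missed + 1]
        mass = csum[end] - csum[start] + water_proton
        length = end - start
        lo, hi = MASS_RANGE_DA
        ok = (length >= MIN_PEPTIDE_LENGTH) & (mass >= lo) & (mass <= hi)
        out.append(np.column_stack([mass[ok], start[ok], end[ok]]))
    return np.concatenate(out) if out else np.empty((0, 3))


def decoy_score_threshold(
    peaks,
    candidate_sequence: str,
    index: MowseIndex,
    rng: np.random.Generator | int | None = None,
) -> float:
    """(1 - alpha) quantile of decoy scores for a peak list.

    Decoys are residue shuffles of the candidate; each is digested, matched
    against the same peaks at the same tolerance, and scored with the same
    frequency matrix. Shuffling preserves residue composition, so every
    decoy shares the candidate's intact mass.
    """
    params = index.params
    rng = np.random.default_rng(rng)
    obs = np.asarray(peaks, dtype=float)
    if obs.ndim == 2:
        obs = obs[:, 0]
    obs = np.sort(obs)
    _check_sequence(candidate_sequence)
    res_m = np.array([RESIDUE_MONO[aa] for aa in candidate_sequence])
    if params.carbamidomethyl_cys:
        res_m = res_m + CARBAMIDOMETHYL * np.array(
            [aa == "C" for aa in candidate_sequence]
        )
    is_site = np.array([aa in "KR" for aa in candidate_sequence])
    not_pro = np.array([aa != "P" for aa in candidate_sequence])
    cmass = float(res_m.sum() + WATER_MONO)
    wp = WATER_MONO + PROTON_MONO
    tol = params.tol_ppm * 1e-6
    scores = np.empty(params.n_decoys)
    for d in range(params.n_decoys):
        order = rng.permutation(res_m.size)
        frag = _decoy_fragment_masses(
            res_m[order], is_site[order], not_pro[order],
            params.max_missed_cleavages, wp,
        )
        if frag.shape[0] == 0 or obs.size == 0:
            scores[d] = 0.0
            continue
        theo = frag[:, 0]
        srt = np.argsort(theo)
        theo_s, start_s, end_s = theo[srt], frag[srt, 1], frag[srt, 2]
        idx = np.searchsorted(theo_s, obs)
        lo_j = np.clip(idx - 1, 0, theo_s.size - 1)
        hi_j = np.clip(idx, 0, theo_s.size - 1)
        err_lo = np.abs(obs - theo_s[lo_j]) / theo_s[lo_j]
        err_hi = np.abs(obs - theo_s[hi_j]) / theo_s[hi_j]
        pick = np.where(err_lo <= err_hi, lo_j, hi_j)
        err = np.minimum(err_lo, err_hi)
        hit = err <= tol
        if not hit.any():
            scores[d] = 0.0
            continue
        # dedupe matched fragments by coordinates, then score
        coords = {
            (int(start_s[j]), int(end_s[j])): theo_s[j] for j in pick[hit]
        }
        product = 1.0
        for mh in coords.values():
            product *= index.cell_frequency(float(mh), cmass)
        scores[d] = MOWSE_SCALE / (product * cmass)
    return float(np.quantile(scores, 1.0 - params.alpha))


def accept_identification(
    result: PMFResult,
    params: SearchParams,
    observed_intact_mass: float | None = None,
) -> bool:
    """Conjunction of the five acceptance criteria for one PMF result."""
    if not result.significant:
        return False
    if result.n_matched < params.min_peptides:
        return False
    if not result.coverage > params.min_coverage:
        return False
    if any(abs(m.error_ppm) > params.tol_ppm for m in result.matches):
        return False
    if observed_intact_mass is not None:
        if abs(result.intact_mass - observed_intact_mass) > params.parent_tol_da:
            return False
    return True


def identify(
    peaks,
    candidate_id: str,
    index: MowseIndex,
    rng: np.random.Generator | int | None = None,
    observed_intact_mass: float | None = None,
) -> PMFResult:
    """Full PMF verdict for one candidate protein against one peak list."""
    params = index.params
    seq = index.database[candidate_id]
    matches = match_masses(peaks, index.digest(candidate_id), params.tol_ppm)
    score, significant, threshold = mowse_score(matches, seq, index, peaks, rng)
    result = PMFResult(
        protein_id=candidate_id,
        matches=matches,
        n_matched=n_distinct_matched(matches),
        coverage=sequence_coverage(matches, len(seq)),
        score=score,
        threshold=threshold,
        significant=significant,
        accepted=False,
        intact_mass=index.intact_mass(candidate_id),
    )
    result.accepted = accept_identification(result, params, observed_intact_mass)
    return result


def search_database(peaks, index: MowseIndex) -> list[tuple[str, float]]:
    """Score every database protein against a peak list, best first.

    Returns (protein_id, score) pairs sorted by descending score; no decoy
    significance testing is performed here.
    """
    params = index.params
    out = []
    for pid in index.database:
        matches = match_masses(peaks, index.digest(pid), params.tol_ppm)
        out.append((pid, index.score_matches(matches, index.intact_mass(pid))))
    out.sort(key=lambda t: t[1], reverse=True)
    return out
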