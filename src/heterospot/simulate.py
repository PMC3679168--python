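"""Synthetic 2-DE experiments and PMF spectra with planted ground truth.

The spot simulator emulates the design of a hybrid/parent embryo proteomics
experiment: two inbred parents (P1, P2) and their F1 hybrid (H), each run on
three replicate gels at two developmental stages (dry seed and 24 h after
imbibition). Each simulated spot is planted with an inheritance mode; the
genotype means implement that mode, replicate gels add log-normal noise, and
per-gel detection dropout feeds the reproducibility filter. The PMF
simulator emits peak lists of true tryptic peptide masses with ppm-scale
mass error plus contaminant peaks.

Defaults reflect the reference experiment: mode proportions shaped like the
dry-seed mode table (most spots not differential), a 3-fold planted effect,
10% replicate coefficient of variation, and triplicate gels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modes import ALL_MODES, MODE_ADDITIVE, MODE_NOT_DIFFERENTIAL
from .pmf import MASS_RANGE_DA, tryptic_digest

STAGES = ("DS", "24HAI")

#: Mode proportions shaped like the dry-seed reference table: 134 of 1140
#: displayed spots differential, split 71 additive / 63 nonadditive.
DEFAULT_MODE_PROPORTIONS = {
    "not_differential": 1006 / 1140,
    "additive": 71 / 1140,
    "++": 6 / 1140,
    "+": 12 / 1140,
    "+/-": 2 / 1140,
    "D": 1 / 1140,
    "-": 8 / 1140,
    "--": 34 / 1140,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Parameters of a planted-mode spot-volume simulation.

    cv is the replicate coefficient of variation on the natural scale; the
    log-scale sd of the log-normal noise is sqrt(ln(1 + cv^2)).
    effect_fold is the planted fold separation between genotype means for
    non-null modes. dropout_rate is the per-gel probability that a spot
    fails detection on an individual gel.
    """

    n_spots: int = 1000
    mode_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_PROPORTIONS)
    )
    n_replicates: int = 3
    cv: float = 0.1
    effect_fold: float = 3.0
    dropout_rate: float = 0.05
    dynamic_range: float = 1e3
    partial_dominance_q: float = 0.25
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    def __post_init__(self):
        if self.n_spots < 1:
            raise ValueError("n_spots must be a positive integer")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        unknown = set(self.mode_proportions) - set(ALL_MODES)
        if unknown:
            raise ValueError(
                f"mode_proportions contains unknown mode codes: {sorted(unknown)}"
            )
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mode_proportions must sum to 1 (got {total!r})"
            )
        if any(v < 0 for v in self.mode_proportions.values()):
            raise ValueError("mode_proportions entries must be non-negative")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.effect_fold <= 1:
            raise ValueError("effect_fold must be > 1")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if not 0 < self.partial_dominance_q < 1:
            raise ValueError("partial_dominance_q must be in (0, 1)")
        if self.dynamic_range < 1:
            raise ValueError("dynamic_range must be >= 1")


def _planted_means(
    mode: str, base: float, f: float, q: float, rng: np.random.Generator
):
    """Genotype means (P1, P2, H) implementing a planted mode.

    For modes requiring distinguishable parents the parents sit ``f``-fold
    apart, with the high parent assigned to P1 or P2 at random — except the
    dominance modes (+, -, +/-), whose parents sit ``f**2`` apart: a
    dominance hybrid coincides with (or lies between) the parents, so its
    ratio to the midparent is capped below 2 and is governed by the parent
    separation, not by the hybrid's own offset. Mode "D" uses equal parents
    with the hybrid at f x midparent; "+/-" places the hybrid at the
    q-quantile point between the parent means.
    """
    swap = bool(rng.integers(2))
    sep = f * f if mode in ("+", "-", "+/-") else f
    lo, hi = base, base * sep
    if mode == MODE_NOT_DIFFERENTIAL:
        return base, base, base
    if mode == "D":
        return base, base, base * f
    if mode == MODE_ADDITIVE:
        h = (lo + hi) / 2
    elif mode == "++":
        h = hi * f
    elif mode == "--":
        h = lo / f
    elif mode == "+":
        h = hi
    elif mode == "-":
        h = lo
    elif mode == "+/-":
        h = lo + q * (hi - lo)
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown mode {mode!r}")
    p1, p2 = (hi, lo) if swap else (lo, hi)
    return p1, p2, h


def simulate_spot_experiment(config: SimulationConfig):
    """Simulate a spot-volume table with planted inheritance modes.

    Returns ``(table, truth)``: the long-format spot table over 3 genotypes
    x n_replicates gels x the configured stages, and the truth table mapping
    each spot and stage to its planted mode code. Replicate volumes are
    log-normal around the planted genotype mean with the configured cv
    (mean-preserving); each gel observation independently drops out with
    probability dropout_rate (volume withheld, detected=False).
    """
    rng = np.random.default_rng(config.seed)
    codes = list(config.mode_proportions)
    probs = np.array([config.mode_proportions[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    sd_log = np.sqrt(np.log1p(config.cv**2))

    width = max(4, len(str(config.n_spots)))
    spot_ids = [f"S{i:0{width}d}" for i in range(1, config.n_spots + 1)]

    truth_rows = []
    rows = []
    for stage in config.stages:
        modes = rng.choice(codes, size=config.n_spots, p=probs)
        bases = config.dynamic_range ** rng.uniform(0, 1, size=config.n_spots)
        for sid, mode, base in zip(spot_ids, modes, bases):
            truth_rows.append({"spot_id": sid, "stage": stage, "mode": mode})
            means = _planted_means(
                mode, base, config.effect_fold, config.partial_dominance_q, rng
            )
            for genotype, mean in zip(("P1", "P2", "H"), means):
                noise = rng.normal(0.0, sd_log, size=config.n_replicates)
                vols = mean * np.exp(noise - sd_log**2 / 2)
                dropped = rng.uniform(size=config.n_replicates) < config.dropout_rate
                for rep in range(config.n_replicates):
                    rows.append(
                        {
                            "spot_id": sid,
                            "stage": stage,
                            "genotype": genotype,
                            "replicate": rep + 1,
                            "volume": np.nan if dropped[rep] else vols[rep],
                            "detected": not dropped[rep],
                        }
                    )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return table, truth


def simulate_protein_db(
    n_proteins: int, length_range: tuple[int, int] = (100, 400), seed: int = 0
) -> dict[str, str]:
    """Random protein sequences over the 20 standard amino acids.

    Returns an ordered mapping of unique identifiers to sequences, suitable
    for writing as FASTA. Lengths are drawn uniformly over
    ``length_range`` (inclusive).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 10 or hi < lo:
        raise ValueError(
            f"degenerate length_range {length_range!r}: need 10 <= lo <= hi"
        )
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_proteins)))
    aa = np.array(list(AMINO_ACIDS))
    db = {}
    for i in range(1, n_proteins + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aa, size=length))
        db[f"SYN{i:0{width}d}"] = seq
    return db


@dataclass
class SpectrumConfig:
    """Parameters of a synthetic peptide-mass-fingerprint spectrum.

    mass_error_ppm_sd is the sd of the Gaussian relative mass error in ppm;
    peptide_detection_prob is the chance each theoretical peptide mass shows
    up as a peak; contaminant peaks are uniform decoy masses over the
    matchable window.
    """

    max_missed_cleavages: int = 1
    mass_error_ppm_sd: float = 5.0
    peptide_detection_prob: float = 0.7
    n_contaminant_peaks: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.mass_error_ppm_sd < 0:
            raise ValueError("mass_error_ppm_sd must be >= 0")
        if not 0 <= self.peptide_detection_prob <= 1:
            raise ValueError("peptide_detection_prob must be in [0, 1]")
        if self.n_contaminant_peaks < 0:
            raise ValueError("n_contaminant_peaks must be >= 0")


def simulate_pmf_spectrum(sequence: str, config: SpectrumConfig) -> np.ndarray:
    """Synthetic PMF peak list for one protein: (n, 2) array of m/z, intensity.

    The unique theoretical [M+H]+ masses of the protein's tryptic fragments
    (up to max_missed_cleavages) are each kept with peptide_detection_prob
    and perturbed by a Gaussian relative mass error of mass_error_ppm_sd
    ppm; n_contaminant_peaks uniform decoy masses over the matchable mass
    window are added. Peaks are sorted ascending by m/z.
    """
    rng = np.random.default_rng(config.seed)
    frags = tryptic_digest(sequence, config.max_missed_cleavages)
    masses = np.unique([f.mh_mass for f in frags])
    keep = rng.uniform(size=masses.size) < config.peptide_detection_prob
    true_mz = masses[keep]
    if config.mass_error_ppm_sd > 0 and true_mz.size:
        err = rng.normal(0.0, config.mass_error_ppm_sd, size=true_mz.size)
        true_mz = true_mz * (1.0 + err * 1e-6)
    lo, hi = MASS_RANGE_DA
    contam = rng.uniform(lo, hi, size=config.n_contaminant_peaks)
    mz = np.concatenate([true_mz, contam])
    intensity = rng.lognormal(mean=0.0, sigma=1.0, size=mz.size)
    order = np.argsort(mz)
    return np.column_stack([mz[order], intensity[order]])
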