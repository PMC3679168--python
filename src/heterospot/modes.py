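"""Midparent differential testing and inheritance-mode classification.

For each spot the hybrid (H) is compared against the midparent value MP —
the per-replicate average of the two inbred parents P1 and P2, which is the
expectation under purely additive gene action. A spot is *differentially
expressed* between hybrid and parents when at least one of the pairwise
genotype contrasts (H vs P1, H vs P2, P1 vs P2) passes the dual criterion
fold change > 1.5 and p < 0.05. Differential spots whose hybrid level is
statistically indistinguishable from MP are *additive*; the rest are
assigned one of six nonadditive modes following the standard scheme for
hybrid/parent expression surveys:

``++``  above high parent (overdominance): H significantly above both parents
``--``  below low parent (underdominance): H significantly below both parents
``+``   high parent dominance: H at the high parent, distinct from the low
``-``   low parent dominance: H at the low parent, distinct from the high
``+/-`` partial dominance: H significantly between the two parents
``D``   different: nonadditive but fitting none of the classes above

Within the mode table the parent-wise calls use the t-test p-value alone;
the fold-change criterion applies to the differential and midparent calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODE_ADDITIVE = "additive"
MODE_NOT_DIFFERENTIAL = "not_differential"
#: The six nonadditive codes, in the conventional display order.
NONADDITIVE_CODES = ("++", "+", "+/-", "D", "-", "--")
ALL_MODES = (MODE_ADDITIVE,) + NONADDITIVE_CODES + (MODE_NOT_DIFFERENTIAL,)

#: Human-readable names for the mode codes.
MODE_LABELS = {
    "additive": "additive expression",
    "++": "above high parent expression",
    "+": "high parent expression",
    "+/-": "partial dominance expression",
    "D": "different from additivity, not belonging to any other class",
    "-": "low parent expression",
    "--": "below low parent expression",
    "not_differential": "not differentially expressed",
}

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison of replicate spot volumes.

    ``fold_change`` is the ratio of the larger group mean to the smaller
    (always >= 1); ``significant`` applies the dual rule
    fold_change > fc_threshold AND p_value < alpha.
    """

    mean_a: float
    mean_b: float
    fold_change: float
    p_value: float
    significant: bool


@dataclass
class DifferentialResult:
    """Per-spot contrasts and the assigned expression mode."""

    spot_id: str
    stage: str
    contrasts: dict[str, Contrast] = field(default_factory=dict)
    mode: str = MODE_NOT_DIFFERENTIAL


def midparent_profile(p1_reps, p2_reps) -> np.ndarray:
    """Element-wise midparent value: the mean of paired parental replicates."""
    p1 = np.asarray(p1_reps, dtype=float)
    p2 = np.asarray(p2_reps, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError(
            f"parental replicate vectors differ in length: {p1.shape} vs {p2.shape}"
        )
    return (p1 + p2) / 2.0


def _welch_p(a: np.ndarray, b: np.ndarray, axis: int = -1, pooled: bool = False):
    """Two-sided two-sample t-test p-values with a zero-variance sentinel.

    When both groups have zero within-group variance the t statistic is
    undefined; p is reported as 1 for equal means and 0 for unequal means.
    """
    import warnings

    with warnings.catch_warnings():
        # near-identical replicate vectors trip scipy's precision warning;
        # the degenerate zero-variance cases are handled explicitly below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = stats.ttest_ind(a, b, axis=axis, equal_var=pooled)
    p = np.asarray(res.pvalue, dtype=float)
    var_a = np.var(a, axis=axis)
    var_b = np.var(b, axis=axis)
    degenerate = (var_a == 0) & (var_b == 0)
    if np.any(degenerate):
        equal = np.isclose(np.mean(a, axis=axis), np.mean(b, axis=axis))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    return p


def _fold_change(mean_a, mean_b):
    """Symmetric fold change: larger mean over smaller mean (>= 1)."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    hi = np.maximum(mean_a, mean_b)
    lo = np.minimum(mean_a, mean_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(lo > 0, hi / lo, np.inf)
    return np.where(hi == lo, 1.0, fc)


def pairwise_contrast(
    a_reps,
    b_reps,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    ttest: str = "welch",
) -> Contrast:
    """Compare two replicate groups: fold change, t-test p, dual significance.

    ``ttest`` selects Welch's unequal-variance test (default) or the
    pooled-variance test.
    """
    a = np.asarray(a_reps, dtype=float)
    b = np.asarray(b_reps, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates for a t-test")
    if ttest not in ("welch", "pooled"):
        raise ValueError(f"unknown ttest flavor: {ttest!r}")
    p = float(_welch_p(a, b, pooled=(ttest == "pooled")))
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fc = float(_fold_change(mean_a, mean_b))
    return Contrast(
        mean_a=mean_a,
        mean_b=mean_b,
        fold_change=fc,
        p_value=p,
        significant=bool(fc > fc_threshold and p < alpha),
    )


def _classify_arrays(
    h: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    fc_threshold: float,
    alpha: float,
    ttest: str,
    log: bool,
):
    """Vectorized mode classification over a (n_spots, n_replicates) stack.

    Returns a DataFrame with the four contrasts (fold change + p-value each)
    and the assigned mode code per spot.
    """
    pooled = ttest == "pooled"
    mp = (p1 + p2) / 2.0
    th, tp1, tp2, tmp = (np.log(x) if log else x for x in (h, p1, p2, mp))

    p_mp = _welch_p(th, tmp, pooled=pooled)
    p_p1 = _welch_p(th, tp1, pooled=pooled)
    p_p2 = _welch_p(th, tp2, pooled=pooled)
    p_pp = _welch_p(tp1, tp2, pooled=pooled)

    h_m, p1_m, p2_m, mp_m = (x.mean(axis=-1) for x in (h, p1, p2, mp))
    fc_mp = _fold_change(h_m, mp_m)
    fc_p1 = _fold_change(h_m, p1_m)
    fc_p2 = _fold_change(h_m, p2_m)
    fc_pp = _fold_change(p1_m, p2_m)

    dual = lambda fc, p: (fc > fc_threshold) & (p < alpha)
    differential = dual(fc_p1, p_p1) | dual(fc_p2, p_p2) | dual(fc_pp, p_pp)
    nonadditive = dual(fc_mp, p_mp)

    hi_is_p1 = p1_m >= p2_m
    hi_m = np.where(hi_is_p1, p1_m, p2_m)
    lo_m = np.where(hi_is_p1, p2_m, p1_m)
    sig_hi = np.where(hi_is_p1, p_p1, p_p2) < alpha
    sig_lo = np.where(hi_is_p1, p_p2, p_p1) < alpha

    mode = np.select(
        [
            ~differential,
            ~nonadditive,
            (h_m > hi_m) & (h_m > lo_m) & sig_hi & sig_lo,
            (h_m < hi_m) & (h_m < lo_m) & sig_hi & sig_lo,
            ~sig_hi & sig_lo,
            ~sig_lo & sig_hi,
            (h_m > lo_m) & (h_m < hi_m) & sig_hi & sig_lo,
        ],
        [MODE_NOT_DIFFERENTIAL, MODE_ADDITIVE, "++", "--", "+", "-", "+/-"],
        default="D",
    )
    return pd.DataFrame(
        {
            "fc_mp": fc_mp, "p_mp": p_mp,
            "fc_p1": fc_p1, "p_p1": p_p1,
            "fc_p2": fc_p2, "p_p2": p_p2,
            "fc_pp": fc_pp, "p_pp": p_pp,
            "mode": mode,
        }
    )


def classify_mode(
    h_reps,
    p1_reps,
    p2_reps,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    ttest: str = "welch",
    log: bool = False,
    spot_id: str = "",
    stage: str = "",
) -> DifferentialResult:
    """Classify one spot's expression mode from its replicate volumes.

    The decision table, evaluated in order:

    1. not differential unless >= 1 of H-vs-P1, H-vs-P2, P1-vs-P2 passes the
       dual criterion (FC > fc_threshold and p < alpha);
    2. additive if H vs MP fails the dual criterion;
    3. otherwise one of the six nonadditive codes from the hybrid mean's
       position relative to the parents and the parent-wise p-values.
    """
    h = np.atleast_2d(np.asarray(h_reps, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1_reps, dtype=float))
    p2 = np.atleast_2d(np.asarray(p2_reps, dtype=float))
    if not (h.shape == p1.shape == p2.shape):
        raise ValueError("all three genotypes need equal replicate counts")
    if h.shape[-1] < 2:
        raise ValueError("need at least 2 replicates per genotype")
    row = _classify_arrays(h, p1, p2, fc_threshold, alpha, ttest, log).iloc[0]
    mk = lambda ma, mb, fc, p: Contrast(
        float(ma), float(mb), float(fc), float(p),
        bool((fc > fc_threshold) and (p < alpha)),
    )
    mp_m = float((p1 + p2).mean() / 2)
    contrasts = {
        "H_vs_MP": mk(h.mean(), mp_m, row.fc_mp, row.p_mp),
        "H_vs_P1": mk(h.mean(), p1.mean(), row.fc_p1, row.p_p1),
        "H_vs_P2": mk(h.mean(), p2.mean(), row.fc_p2, row.p_p2),
        "P1_vs_P2": mk(p1.mean(), p2.mean(), row.fc_pp, row.p_pp),
    }
    return DifferentialResult(
        spot_id=spot_id, stage=stage, contrasts=contrasts, mode=str(row["mode"])
    )


def classify_table(
    table: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    ttest: str = "welch",
    log: bool = False,
    retained: set | None = None,
) -> pd.DataFrame:
    """Classify every spot of a (normalized) table retained in all genotypes.

    Spots not retained by the reproducibility filter in all three genotypes
    at a stage are skipped for that stage. Returns one row per classified
    spot and stage with the four contrasts and the mode code.
    """
    from .quant import GENOTYPES, reproducibility_filter, validate_table

    validate_table(table)
    if retained is None:
        retained = reproducibility_filter(table)

    frames = []
    det = table[table["detected"].astype(bool)]
    for stage, sub in det.groupby("stage", sort=True):
        wide = sub.pivot_table(
            index="spot_id", columns=["genotype", "replicate"], values="volume"
        )
        spot_ids = [
            s
            for s in wide.index
            if all((s, stage, g) in retained for g in GENOTYPES)
        ]
        if not spot_ids:
            continue
        reps = sorted({r for (_, r) in wide.columns})
        stack = {
            g: wide.loc[spot_ids, [(g, r) for r in reps]].to_numpy()
            for g in GENOTYPES
        }
        res = _classify_arrays(
            stack["H"], stack["P1"], stack["P2"],
            fc_threshold, alpha, ttest, log,
        )
        res.insert(0, "stage", stage)
        res.insert(0, "spot_id", spot_ids)
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["spot_id", "stage", "fc_mp", "p_mp", "fc_p1", "p_p1",
                     "fc_p2", "p_p2", "fc_pp", "p_pp", "mode"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class ModeSummary:
    """Count/percentage summary of expression modes at one stage.

    ``pct_nonadditive`` is nonadditive spots over differential spots;
    ``pct_differential`` is differential spots over all displayed spots.
    Percentages are rounded to two decimals.
    """

    stage: str
    displayed_spots: int
    additive: int
    counts: dict[str, int]  # per nonadditive code

    @property
    def nonadditive_sum(self) -> int:
        return sum(self.counts.values())

    @property
    def differential_total(self) -> int:
        return self.additive + self.nonadditive_sum

    @property
    def pct_nonadditive(self) -> float:
        if self.differential_total == 0:
            return 0.0
        return round(100.0 * self.nonadditive_sum / self.differential_total, 2)

    @property
    def pct_additive(self) -> float:
        if self.differential_total == 0:
            return 0.0
        return round(100.0 * self.additive / self.differential_total, 2)

    @property
    def pct_differential(self) -> float:
        if self.displayed_spots == 0:
            return 0.0
        return round(100.0 * self.differential_total / self.displayed_spots, 2)

    @property
    def higher_parent_pct(self) -> float:
        """Percent of nonadditive spots at or above the high parent (++ and +)."""
        if self.nonadditive_sum == 0:
            return 0.0
        up = self.counts.get("++", 0) + self.counts.get("+", 0)
        return round(100.0 * up / self.nonadditive_sum, 2)

    @property
    def lower_parent_pct(self) -> float:
        """Percent of nonadditive spots at or below the low parent (- and --)."""
        if self.nonadditive_sum == 0:
            return 0.0
        down = self.counts.get("-", 0) + self.counts.get("--", 0)
        return round(100.0 * down / self.nonadditive_sum, 2)

    @classmethod
    def from_counts(
        cls, stage: str, displayed_spots: int, additive: int, **code_counts: int
    ) -> "ModeSummary":
        """Build a summary from explicit per-code counts.

        Keyword names use spelled-out aliases for the symbolic codes:
        ``above_high``, ``high``, ``partial``, ``different``, ``low``,
        ``below_low``.
        """
        alias = {
            "above_high": "++", "high": "+", "partial": "+/-",
            "different": "D", "low": "-", "below_low": "--",
        }
        counts = {code: 0 for code in NONADDITIVE_CODES}
        for name, n in code_counts.items():
            code = alias.get(name, name)
            if code not in counts:
                raise ValueError(f"unknown mode code {name!r}")
            counts[code] = int(n)
        return cls(stage=stage, displayed_spots=int(displayed_spots),
                   additive=int(additive), counts=counts)

    def to_frame(self) -> pd.DataFrame:
        row = {
            "stage": self.stage,
            "displayed_spots": self.displayed_spots,
            "additive": self.additive,
            **{code: self.counts[code] for code in NONADDITIVE_CODES},
            "nonadditive_sum": self.nonadditive_sum,
            "differential_total": self.differential_total,
            "pct_differential": self.pct_differential,
            "pct_nonadditive": self.pct_nonadditive,
        }
        return pd.DataFrame([row])


def summarize_modes(
    results, stage: str, displayed_spots: int | None = None
) -> ModeSummary:
    """Tally classified spots of one stage into a ModeSummary.

    ``results`` is a list of :class:`DifferentialResult` or a DataFrame with
    ``stage`` and ``mode`` columns. ``displayed_spots`` defaults to the
    number of classified spots at the stage (differential or not).
    """
    if isinstance(results, pd.DataFrame):
        sub = results[results["stage"] == stage]
        mode_list = list(sub["mode"])
    else:
        mode_list = [r.mode for r in results if r.stage == stage]
    bad = set(mode_list) - set(ALL_MODES)
    if bad:
        raise ValueError(f"unknown mode codes in results: {sorted(bad)}")
    if displayed_spots is None:
        displayed_spots = len(mode_list)
    counts = {code: mode_list.count(code) for code in NONADDITIVE_CODES}
    return ModeSummary(
        stage=stage,
        displayed_spots=int(displayed_spots),
        additive=mode_list.count(MODE_ADDITIVE),
        counts=counts,
    )
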