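"""Dry-seed vs imbibed-embryo comparisons and cross-stage mode reconciliation.

Two kinds of question are answered here. Within a genotype: which spots
appear, disappear, or change abundance between the dry-seed (DS) stage and
24 h after imbibition (24HAI)? Across the differential analyses of the two
stages: for spots differential at both stages, do the inheritance-mode
calls agree? Spot numbering differs between the two stages' gel sets, so
cross-stage identity is an explicit externally supplied id mapping (manual
gel matching), never inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .modes import (
    DEFAULT_ALPHA,
    DEFAULT_FC_THRESHOLD,
    MODE_NOT_DIFFERENTIAL,
    DifferentialResult,
    pairwise_contrast,
)
from .quant import reproducibility_filter, validate_table

logger = logging.getLogger(__name__)

STATUS_VALUES = ("newly_detected", "lost", "changed", "unchanged")


@dataclass
class StageChange:
    """One spot's behavior between two stages within one genotype."""

    spot_id: str
    genotype: str
    status: str
    fold_change: float = float("nan")
    p_value: float = float("nan")


@dataclass
class OverlapRecord:
    """Mode calls of one physical spot identified at both stages."""

    ds_id: str
    hai_id: str
    mode_ds: str
    mode_24hai: str

    @property
    def same_pattern(self) -> bool:
        return self.mode_ds == self.mode_24hai

    @property
    def pattern(self) -> str:
        """Display encoding, e.g. ``+/D`` for high-parent at DS, D at 24HAI."""
        return f"{self.mode_ds}/{self.mode_24hai}"


def stage_differential(
    genotype: str,
    ds_table: pd.DataFrame,
    hai_table: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    ttest: str = "welch",
) -> list[StageChange]:
    """Classify each spot of one genotype across two stages.

    Both tables must be normalized; the reproducibility filter is applied
    within each. A spot retained only in ``hai_table`` is newly detected,
    only in ``ds_table`` is lost; a spot retained in both is compared with
    the dual fold-change/p-value rule (changed vs unchanged). The returned
    statuses partition the union of retained spots of the genotype.
    """
    for name, tab in (("ds_table", ds_table), ("hai_table", hai_table)):
        validate_table(tab)
        if genotype not in set(tab["genotype"]):
            raise ValueError(f"genotype {genotype!r} absent from {name}")

    def retained_spots(tab):
        return {s for (s, _stage, g) in reproducibility_filter(tab) if g == genotype}

    ds_spots = retained_spots(ds_table)
    hai_spots = retained_spots(hai_table)

    def reps(tab, spot):
        sub = tab[
            (tab["spot_id"] == spot)
            & (tab["genotype"] == genotype)
            & tab["detected"].astype(bool)
        ]
        return sub.sort_values("replicate")["volume"].to_numpy()

    changes = []
    for spot in sorted(hai_spots - ds_spots):
        changes.append(StageChange(spot, genotype, "newly_detected"))
    for spot in sorted(ds_spots - hai_spots):
        changes.append(StageChange(spot, genotype, "lost"))
    for spot in sorted(ds_spots & hai_spots):
        c = pairwise_contrast(
            reps(ds_table, spot), reps(hai_table, spot),
            fc_threshold=fc_threshold, alpha=alpha, ttest=ttest,
        )
        status = "changed" if c.significant else "unchanged"
        changes.append(
            StageChange(spot, genotype, status, c.fold_change, c.p_value)
        )
    return changes


def _as_mode_map(results) -> dict[str, str]:
    """Accept DifferentialResult lists, DataFrames, or plain mappings."""
    if isinstance(results, dict):
        return dict(results)
    if isinstance(results, pd.DataFrame):
        return dict(zip(results["spot_id"], results["mode"]))
    out = {}
    for r in results:
        if not isinstance(r, DifferentialResult):
            raise TypeError(f"cannot interpret {type(r).__name__} as a mode call")
        out[r.spot_id] = r.mode
    return out


def overlap_patterns(
    ds_results, hai_results, id_pairs
) -> tuple[list[OverlapRecord], int, int]:
    """Reconcile mode calls for spots differential at both stages.

    ``id_pairs`` is an iterable of (DS spot id, 24HAI spot id) giving the
    externally established cross-stage correspondences. One record is
    produced per pair whose members are both differential (any mode other
    than not_differential). Pairs referencing an id missing from either
    result set are logged and skipped. Returns
    ``(records, n_overlap, n_same_pattern)``.
    """
    ds_modes = _as_mode_map(ds_results)
    hai_modes = _as_mode_map(hai_results)
    records = []
    for ds_id, hai_id in id_pairs:
        if ds_id not in ds_modes or hai_id not in hai_modes:
            logger.warning(
                "skipping dangling spot pair (%s, %s): id not in results",
                ds_id, hai_id,
            )
            continue
        mode_ds, mode_hai = ds_modes[ds_id], hai_modes[hai_id]
        if mode_ds == MODE_NOT_DIFFERENTIAL or mode_hai == MODE_NOT_DIFFERENTIAL:
            continue
        records.append(OverlapRecord(ds_id, hai_id, mode_ds, mode_hai))
    n_overlap = len(records)
    n_same = sum(r.same_pattern for r in records)
    return records, n_overlap, n_same
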