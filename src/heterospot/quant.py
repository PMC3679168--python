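"""Per-gel spot-volume normalization and replicate reproducibility rules.

A 2-DE experiment is a long table of spot volumes: one row per
(spot, stage, genotype, replicate gel). Volumes from different gels are not
directly comparable because staining intensity and protein load vary, so
each spot is expressed as its fraction of the total detected volume on its
own gel (the %Vol convention of gel-analysis software). A spot is only
trusted for a genotype/stage if it was detected on every replicate gel.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

#: Required columns of a spot-volume table.
TABLE_COLUMNS = ("spot_id", "stage", "genotype", "replicate", "volume", "detected")

#: Genotype labels: the two inbred parents and their F1 hybrid.
GENOTYPES = ("P1", "P2", "H")

#: A gel is one physical 2-D gel: a stage x genotype x replicate combination.
GEL_KEY = ["stage", "genotype", "replicate"]

PRESENCE_LABELS = (
    "all",
    "parent1_dominant",
    "parent2_dominant",
    "hybrid_only",
    "parent_only",
    "other",
)


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the spot-volume table schema and its invariants.

    Returns the table unchanged. Raises ``ValueError`` on missing columns,
    duplicated (spot, stage, genotype, replicate) keys, or non-positive
    volumes on rows flagged as detected.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spot table is missing columns: {missing}")
    key = ["spot_id", "stage", "genotype", "replicate"]
    if table.duplicated(subset=key).any():
        dup = table[table.duplicated(subset=key)].iloc[0]
        raise ValueError(
            "duplicate spot record: "
            f"spot_id={dup.spot_id!r} stage={dup.stage!r} "
            f"genotype={dup.genotype!r} replicate={dup.replicate!r}"
        )
    detected = table[table["detected"].astype(bool)]
    if not (detected["volume"] > 0).all():
        bad = detected[~(detected["volume"] > 0)].iloc[0]
        raise ValueError(
            f"detected spot {bad.spot_id!r} on gel "
            f"({bad.stage}, {bad.genotype}, rep {bad.replicate}) "
            "has non-positive volume"
        )
    return table


def normalize_volumes(raw: pd.DataFrame) -> pd.DataFrame:
    """Normalize each detected spot volume against its gel's total volume.

    Every detected volume is divided by the summed detected volume on the
    same gel (stage x genotype x replicate), so normalized volumes on each
    gel sum to exactly 1. Undetected entries are left untouched. The total
    is taken over detected spots only: a spot missing from a gel contributes
    nothing to that gel's total.

    Raises ``ValueError`` if any gel has no detected spot, naming the gel.
    """
    validate_table(raw)
    out = raw.copy()
    det = out["detected"].astype(bool)
    totals = out.loc[det].groupby(GEL_KEY)["volume"].sum()
    # every gel present in the table must have at least one detected spot
    all_gels = out[GEL_KEY].drop_duplicates()
    for _, gel in all_gels.iterrows():
        key = (gel["stage"], gel["genotype"], gel["replicate"])
        if key not in totals.index:
            raise ValueError(
                f"gel (stage={key[0]}, genotype={key[1]}, replicate={key[2]}) "
                "has no detected spots; cannot normalize"
            )
    gel_total = out.set_index(GEL_KEY).index.map(totals)
    out.loc[det, "volume"] = out.loc[det, "volume"] / pd.Series(
        gel_total, index=out.index
    )[det]
    return out


def _replicate_counts(table: pd.DataFrame) -> int:
    """Number of replicate gels, enforced equal across genotype/stage groups."""
    counts = table.groupby(["stage", "genotype"])["replicate"].nunique()
    if counts.nunique() != 1:
        raise ValueError(
            f"inconsistent replicate counts across gels: {counts.to_dict()}"
        )
    return int(counts.iloc[0])


def reproducibility_filter(
    table: pd.DataFrame, n_replicates: int | None = None
) -> set[tuple[str, str, str]]:
    """Spots retained per genotype/stage: detected on *all* replicate gels.

    Returns the set of (spot_id, stage, genotype) triples whose spot was
    detected in every one of the ``n_replicates`` gels for that genotype and
    stage. When ``n_replicates`` is None it is inferred from the table and
    must be consistent across all genotype/stage groups.
    """
    validate_table(table)
    if n_replicates is None:
        n_replicates = _replicate_counts(table)
    det = table[table["detected"].astype(bool)]
    counts = det.groupby(["spot_id", "stage", "genotype"])["replicate"].nunique()
    return {key for key, n in counts.items() if n == n_replicates}


def annotate_retained(
    table: pd.DataFrame, retained: set[tuple[str, str, str]]
) -> pd.DataFrame:
    """Return a copy of the table with a boolean ``retained`` column."""
    out = table.copy()
    keys = list(zip(out["spot_id"], out["stage"], out["genotype"]))
    out["retained"] = [k in retained for k in keys]
    return out


def presence_label(detected_in: Iterable[str]) -> str:
    """Map the set of genotypes a spot is retained in to a presence label.

    A spot seen in one parent and the hybrid but not the other parent is the
    classic presence signature of dominant inheritance.
    """
    s = frozenset(detected_in)
    if not s <= set(GENOTYPES):
        raise ValueError(f"unknown genotypes in presence set: {sorted(s)}")
    if s == {"P1", "P2", "H"}:
        return "all"
    if s == {"P1", "H"}:
        return "parent1_dominant"
    if s == {"P2", "H"}:
        return "parent2_dominant"
    if s == {"H"}:
        return "hybrid_only"
    if s in ({"P1"}, {"P2"}):
        return "parent_only"
    if not s:
        raise ValueError("spot retained in no genotype; absent, not classifiable")
    return "other"


def presence_pattern(
    table: pd.DataFrame,
    spot_id: str,
    stage: str,
    retained: set[tuple[str, str, str]] | None = None,
):
    """Presence pattern of one spot at one stage, after reproducibility filtering.

    Returns a ``(spot_id, stage, detected_in, label)`` named tuple. Raises
    ``ValueError`` if the spot is retained in no genotype at this stage.
    """
    from collections import namedtuple

    if retained is None:
        retained = reproducibility_filter(table)
    detected_in = frozenset(
        g for g in GENOTYPES if (spot_id, stage, g) in retained
    )
    if not detected_in:
        raise ValueError(
            f"spot {spot_id!r} at stage {stage!r} retained in no genotype"
        )
    PresencePattern = namedtuple(
        "PresencePattern", ["spot_id", "stage", "detected_in", "label"]
    )
    return PresencePattern(spot_id, stage, detected_in, presence_label(detected_in))
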