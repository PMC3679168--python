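"""Packaged reference tables from a published maize embryo heterosis survey.

Three small tables transcribed from a maize hybrid (Zong3/87-1) vs parents
2-DE study of dry and 24 h imbibed seed embryos: the per-stage expression-
mode counts, the cross-stage overlap of differential spots, and the
hundred-grain-weight trait summaries. They serve as ground truth for the
summary arithmetic and reconciliation logic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .modes import ModeSummary, NONADDITIVE_CODES


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("heterospot.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype={"stage": str})


def load_mode_counts() -> pd.DataFrame:
    """Per-stage displayed-spot and mode counts of the reference survey."""
    return _read("maize_embryo_mode_counts.tsv")


def mode_summary(stage: str) -> ModeSummary:
    """Reference counts of one stage as a :class:`ModeSummary`."""
    counts = load_mode_counts().set_index("stage")
    if stage not in counts.index:
        raise ValueError(f"unknown stage {stage!r}; have {list(counts.index)}")
    row = counts.loc[stage]
    return ModeSummary(
        stage=stage,
        displayed_spots=int(row["displayed_spots"]),
        additive=int(row["additive"]),
        counts={code: int(row[code]) for code in NONADDITIVE_CODES},
    )


def load_stage_overlap() -> pd.DataFrame:
    """Cross-stage spot pairs with the mode call at each stage."""
    return _read("maize_embryo_stage_overlap.tsv").astype(
        {"ds_id": str, "hai_id": str}
    )


def load_grain_weight() -> pd.DataFrame:
    """Hundred-grain-weight summaries (mean, dispersion, n) per genotype."""
    return _read("maize_grain_weight.tsv")
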