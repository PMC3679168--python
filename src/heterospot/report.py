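"""End-to-end pipeline orchestration, report tables, and trait t-tests.

``run_pipeline`` wires the stages together: simulate (or load) raw spot
volumes, normalize per gel, apply the reproducibility filter, classify
inheritance modes per stage, summarize counts, reconcile modes across
stages, and optionally run a PMF identification round on a simulated
protein database. Every output TSV carries a comment line with version and
parameters; a JSON manifest records all seeds and thresholds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .io import read_id_pairs, read_spot_table, write_spot_table, write_tsv
from .modes import (
    DEFAULT_ALPHA,
    DEFAULT_FC_THRESHOLD,
    classify_table,
    summarize_modes,
)
from .overlap import overlap_patterns
from .pmf import MowseIndex, SearchParams, identify
from .quant import normalize_volumes, reproducibility_filter
from .simulate import (
    SimulationConfig,
    SpectrumConfig,
    simulate_pmf_spectrum,
    simulate_protein_db,
    simulate_spot_experiment,
)

logger = logging.getLogger(__name__)


@dataclass
class TraitSummary:
    """A group's trait summary: mean +/- dispersion over n measurements.

    ``dispersion_is_se`` says whether the +/- value is a standard error
    rather than a standard deviation.
    """

    label: str
    mean: float
    dispersion: float
    n: int
    dispersion_is_se: bool = False

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2 for testing")

    @property
    def sd(self) -> float:
        if self.dispersion_is_se:
            return self.dispersion * np.sqrt(self.n)
        return self.dispersion


def two_group_ttest(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test from raw vectors or trait summaries.

    Accepts raw replicate vectors or :class:`TraitSummary` objects (mixing
    is allowed by converting vectors to summaries). Returns ``(t, p)``.
    """
    def as_summary(x, label):
        if isinstance(x, TraitSummary):
            return x
        arr = np.asarray(x, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label} needs n >= 2")
        return TraitSummary(label, float(arr.mean()), float(arr.std(ddof=1)), arr.size)

    sa, sb = as_summary(a, "a"), as_summary(b, "b")
    res = stats.ttest_ind_from_stats(
        sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n, equal_var=equal_var
    )
    return float(res.statistic), float(res.pvalue)


def tally_functional_classes(annotations: pd.DataFrame) -> pd.Series:
    """Count externally supplied functional-class labels per class.

    ``annotations`` maps spot ids to class labels (columns ``spot_id``,
    ``functional_class``). The tally sums to the number of annotated spots.
    """
    if "functional_class" not in annotations.columns:
        raise ValueError("annotations need a 'functional_class' column")
    return annotations["functional_class"].value_counts().sort_index()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, outdir=None) -> dict:
    """Run the full analysis described by a config mapping or YAML file.

    The config names either a ``simulation`` block (SimulationConfig
    fields) or an ``inputs`` block with a ``spot_table`` path (and optional
    ``id_pairs`` path); a ``thresholds`` block overrides fc_threshold,
    alpha, ttest flavor and log transform; an optional ``pmf`` block
    (n_proteins, n_spectra, seed, spectrum/search settings) adds a PMF
    identification round on a simulated database. Writes all report TSVs
    plus ``manifest.json`` into the output directory and returns the main
    objects in a dict.
    """
    cfg = _load_config(config)
    if outdir is None:
        outdir = cfg.get("outdir")
    if outdir is None:
        raise ValueError("no output directory: pass outdir or set it in the config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    thresholds = {
        "fc_threshold": DEFAULT_FC_THRESHOLD,
        "alpha": DEFAULT_ALPHA,
        "ttest": "welch",
        "log": False,
    }
    thresholds.update(cfg.get("thresholds", {}))

    manifest: dict = {"version": __version__, "thresholds": thresholds}
    tag = f"heterospot {__version__}; " + "; ".join(
        f"{k}={v}" for k, v in thresholds.items()
    )

    truth = None
    id_pairs = None
    if "simulation" in cfg:
        sim_cfg = SimulationConfig(**cfg["simulation"])
        manifest["simulation"] = {**cfg["simulation"], "seed": sim_cfg.seed}
        raw, truth = simulate_spot_experiment(sim_cfg)
        write_tsv(truth, outdir / "truth_table.tsv", tag)
        # simulated spots keep the same id at both stages
        id_pairs = [(s, s) for s in truth["spot_id"].unique()]
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        if "spot_table" not in inputs:
            raise FileNotFoundError("config inputs block names no spot_table")
        path = Path(inputs["spot_table"])
        if not path.exists():
            raise FileNotFoundError(f"missing input: {path}")
        raw = read_spot_table(path)
        if "id_pairs" in inputs:
            pair_path = Path(inputs["id_pairs"])
            if not pair_path.exists():
                raise FileNotFoundError(f"missing input: {pair_path}")
            id_pairs = read_id_pairs(pair_path)
        manifest["inputs"] = {k: str(v) for k, v in inputs.items()}
    else:
        raise ValueError("config needs a 'simulation' or 'inputs' block")

    normalized = normalize_volumes(raw)
    write_spot_table(normalized, outdir / "normalized_volumes.tsv")
    retained = reproducibility_filter(normalized)
    results = classify_table(
        normalized,
        fc_threshold=thresholds["fc_threshold"],
        alpha=thresholds["alpha"],
        ttest=thresholds["ttest"],
        log=thresholds["log"],
        retained=retained,
    )
    write_tsv(results, outdir / "differential_results.tsv", tag)

    stages = sorted(results["stage"].unique())
    summaries = {s: summarize_modes(results, s) for s in stages}
    summary_frame = pd.concat([summaries[s].to_frame() for s in stages],
                              ignore_index=True) if stages else pd.DataFrame()
    write_tsv(summary_frame, outdir / "mode_summary.tsv", tag)

    overlap_out = None
    if id_pairs is not None and len(stages) == 2:
        ds, hai = stages[0], stages[1]
        records, n_overlap, n_same = overlap_patterns(
            results[results["stage"] == ds],
            results[results["stage"] == hai],
            id_pairs,
        )
        overlap_frame = pd.DataFrame(
            [
                {
                    "ds_id": r.ds_id, "hai_id": r.hai_id,
                    "pattern": r.pattern, "same_pattern": r.same_pattern,
                }
                for r in records
            ]
        )
        write_tsv(overlap_frame, outdir / "overlap_records.tsv", tag)
        manifest["overlap"] = {"n_overlap": n_overlap, "n_same_pattern": n_same}
        overlap_out = (records, n_overlap, n_same)

    pmf_results = None
    if "pmf" in cfg:
        pmf_cfg = dict(cfg["pmf"])
        n_proteins = int(pmf_cfg.get("n_proteins", 50))
        n_spectra = int(pmf_cfg.get("n_spectra", 5))
        seed = int(pmf_cfg.get("seed", 0))
        params = SearchParams(**pmf_cfg.get("search", {}))
        db = simulate_protein_db(n_proteins, seed=seed)
        index = MowseIndex(db, params)
        rng = np.random.default_rng(seed + 1)
        rows = []
        for k, pid in enumerate(list(db)[:n_spectra]):
            spec_cfg = SpectrumConfig(
                **{**pmf_cfg.get("spectrum", {}), "seed": seed + 100 + k}
            )
            peaks = simulate_pmf_spectrum(db[pid], spec_cfg)
            res = identify(peaks, pid, index, rng)
            rows.append(
                {
                    "protein_id": res.protein_id,
                    "n_matched": res.n_matched,
                    "coverage": round(res.coverage, 4),
                    "score": res.score,
                    "threshold": res.threshold,
                    "significant": res.significant,
                    "accepted": res.accepted,
                }
            )
        pmf_results = pd.DataFrame(rows)
        write_tsv(pmf_results, outdir / "pmf_results.tsv", tag)
        manifest["pmf"] = {
            "n_proteins": n_proteins, "n_spectra": n_spectra, "seed": seed,
            "search": {
                "tol_ppm": params.tol_ppm,
                "parent_tol_da": params.parent_tol_da,
                "max_missed_cleavages": params.max_missed_cleavages,
                "alpha": params.alpha,
                "min_peptides": params.min_peptides,
                "min_coverage": params.min_coverage,
                "n_decoys": params.n_decoys,
            },
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; reports in %s", outdir)
    return {
        "normalized": normalized,
        "retained": retained,
        "results": results,
        "summaries": summaries,
        "truth": truth,
        "overlap": overlap_out,
        "pmf": pmf_results,
        "manifest": manifest,
    }
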