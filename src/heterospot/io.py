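"""Readers and writers for the pipeline's on-disk formats.

Spot-volume tables, truth tables, classification results and summaries
travel as TSV; protein collections as FASTA (Biopython); peak lists as
two-column m/z / intensity text or MGF (pyteomics).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf

from .quant import validate_table


def write_spot_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.to_csv(path, sep="\t", index=False)


def read_spot_table(path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", dtype={"spot_id": str, "stage": str, "genotype": str}
    )
    table["detected"] = table["detected"].astype(bool)
    return validate_table(table)


def write_tsv(frame: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a TSV with an optional leading ``#`` provenance comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_id_pairs(path) -> list[tuple[str, str]]:
    """Two-column TSV of cross-stage spot id correspondences."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"id-pair file {path} needs two columns")
    return list(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_fasta(database: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in database.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_peak_list(peaks: np.ndarray, path) -> None:
    """Two-column text peak list: m/z <TAB> intensity."""
    arr = np.asarray(peaks, dtype=float)
    if arr.ndim == 1:
        arr = np.column_stack([arr, np.ones_like(arr)])
    np.savetxt(path, arr, delimiter="\t", fmt="%.6f")


def read_peak_list(path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    return arr[np.argsort(arr[:, 0])]


def write_mgf(peaks: np.ndarray, path, title: str = "spectrum") -> None:
    arr = np.asarray(peaks, dtype=float)
    spectra = [
        {
            "m/z array": arr[:, 0],
            "intensity array": arr[:, 1],
            "params": {"title": title},
        }
    ]
    mgf.write(spectra, output=str(path), file_mode="w")


def read_mgf(path) -> list[np.ndarray]:
    out = []
    with mgf.read(str(path)) as reader:
        for spec in reader:
            out.append(
                np.column_stack([spec["m/z array"], spec["intensity array"]])
            )
    return out
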