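"""Shared readers/writers and run reporting.

All tabular files are TSV with a header row, UTF-8, '.' decimal, missing
values written as "NA".  Clone sets are FASTA with the reference as the
first record (id "REF") unless a separate reference file is supplied.
Every writer's output round-trips through the matching reader.
"""

from __future__ import annotations

import json
import platform
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .assays import FluctuationExperiment
from .bioid import BAITS, SpectralCountMatrix
from .chip import QpcrRun
from .shm import CloneSet

NA = "NA"

__all__ = [
    "read_spectral_counts",
    "write_spectral_counts",
    "read_fasta",
    "write_fasta",
    "read_fluctuation",
    "write_fluctuation",
    "read_qpcr_plate",
    "write_qpcr_plate",
    "write_table",
    "write_run_report",
]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index=index)


def write_spectral_counts(
    m: SpectralCountMatrix, counts_path: str | Path, meta_path: str | Path
) -> None:
    counts = m.counts.copy()
    counts.index.name = "prey_id"
    write_table(counts, counts_path)
    write_table(m.samples, meta_path)


def read_spectral_counts(
    counts_path: str | Path,
    meta_path: str | Path,
    birA_prey_id: str = "BIRA_STAR",
) -> SpectralCountMatrix:
    """Read a prey x sample count TSV plus sample metadata TSV.

    Strict integer coercion; duplicate preys, unknown baits, negative
    counts and samples missing from the metadata are hard errors.
    """
    raw = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    prey_col = raw.columns[0]
    dupes = raw[prey_col][raw[prey_col].str.strip().str.lower().duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate prey row(s): {sorted(set(dupes))}")
    counts = raw.set_index(prey_col)
    counts.index.name = "prey_id"
    try:
        as_float = counts.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric spectral counts: {exc}") from exc
    if not (as_float.to_numpy() == as_float.to_numpy().round()).all():
        raise ValueError("non-integer spectral counts")
    counts = as_float.astype(int)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative spectral counts")

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError("metadata needs a sample_id column")
    meta = meta.set_index("sample_id")
    unknown = set(meta["bait"]) - set(BAITS)
    if unknown:
        raise ValueError(f"unknown bait labels: {sorted(unknown)}")
    missing = set(counts.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    return SpectralCountMatrix(
        counts=counts, samples=meta.loc[list(counts.columns)],
        birA_prey_id=birA_prey_id,
    )


def write_fasta(clone_set: CloneSet, path: str | Path) -> None:
    records = [SeqRecord(Seq(clone_set.reference), id="REF", description="")]
    records += [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in clone_set.clones
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, ref_path: str | Path | None = None) -> CloneSet:
    """Read clones from FASTA; the reference is the record with id "REF"
    or the single record of ``ref_path`` when given."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA: {path}")
    reference = None
    clones = []
    if ref_path is not None:
        refs = list(SeqIO.parse(str(ref_path), "fasta"))
        if not refs:
            raise ValueError(f"empty reference FASTA: {ref_path}")
        reference = str(refs[0].seq).upper()
    for rec in records:
        if rec.id == "REF" and ref_path is None:
            reference = str(rec.seq).upper()
        else:
            clones.append((rec.id, str(rec.seq).upper()))
    if reference is None:
        raise ValueError('no reference: expected a record with id "REF"')
    return CloneSet(reference=reference, clones=clones)


def write_fluctuation(exps: list[FluctuationExperiment], path: str | Path) -> None:
    rows = [
        {
            "construct": e.construct,
            "experiment": e.experiment_id,
            "culture": i + 1,
            "rifR": rif,
            "ampR": amp,
        }
        for e in exps
        for i, (rif, amp) in enumerate(e.cultures)
    ]
    write_table(pd.DataFrame(rows), path, index=False)


def read_fluctuation(path: str | Path) -> list[FluctuationExperiment]:
    df = pd.read_csv(path, sep="\t")
    required = {"construct", "experiment", "rifR", "ampR"}
    if not required <= set(df.columns):
        raise ValueError(f"fluctuation table needs columns {sorted(required)}")
    exps = []
    for (construct, exp_id), grp in df.groupby(
        ["construct", "experiment"], sort=False
    ):
        exps.append(
            FluctuationExperiment(
                construct=str(construct),
                cultures=list(zip(grp["rifR"].astype(int),
                                  grp["ampR"].astype(int))),
                experiment_id=str(exp_id),
            )
        )
    return exps


def write_qpcr_plate(run: QpcrRun, path: str | Path) -> None:
    write_table(run.measurements, path, index=False)


def read_qpcr_plate(path: str | Path, input_fraction: float) -> QpcrRun:
    df = pd.read_csv(path, sep="\t")
    return QpcrRun(measurements=df, input_fraction=input_fraction)


def write_run_report(
    out_dir: str | Path,
    command: str,
    parameters: dict,
    warnings_seen: list[str],
    outputs: list[str],
    seed: int | None = None,
) -> Path:
    """JSON run report: versions, seed, parameters, warnings, outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {
        "command": command,
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "parameters": parameters,
        "warnings": warnings_seen,
        "outputs": outputs,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "argv": sys.argv,
    }
    path = out_dir / "run_report.json"
    path.write_text(json.dumps(report, indent=2, default=str))
    return path
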