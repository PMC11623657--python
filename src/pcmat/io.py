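"""Readers and writers for the package's on-disk formats.

Repertoires travel as AIRR-Rearrangement-style TSV (tab-separated, one row
per chain, standard column names plus ``c_``-prefixed custom columns);
germlines as FASTA keyed by v_call; serum and event logs as CSV.  Output is
byte-deterministic: fixed column order, fixed float formatting, ``\\n``
line endings.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .germline import GERMLINES

FLOAT_FORMAT = "%.8g"


def write_table(df: pd.DataFrame, path: str, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_repertoire(df: pd.DataFrame, path: str) -> None:
    """Write an AIRR-style repertoire TSV."""
    write_table(df, path, sep="\t")


def read_repertoire(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "c_animal": str})
    required = {"cell_id", "locus", "v_call", "sequence_alignment", "germline_alignment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"repertoire TSV missing columns: {sorted(missing)}")
    return df


def write_serum_csv(serum_df: pd.DataFrame, path: str) -> None:
    write_table(serum_df, path, sep=",")


def read_serum_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_event_log(event_df: pd.DataFrame, path: str) -> None:
    write_table(event_df, path, sep=",")


def write_germline_fasta(path: str, germlines: dict[str, str] | None = None) -> None:
    """Write the germline V registry (or a custom mapping) as FASTA."""
    germlines = germlines if germlines is not None else GERMLINES
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in germlines.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_germline_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_output_bundle(output, out_dir: str) -> dict[str, str]:
    """Write every table of a SimulationOutput under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "repertoire": os.path.join(out_dir, "repertoire.tsv"),
        "serum": os.path.join(out_dir, "serum.csv"),
        "events": os.path.join(out_dir, "events.csv"),
        "germlines": os.path.join(out_dir, "germlines.fasta"),
    }
    write_repertoire(output.repertoire, paths["repertoire"])
    write_serum_csv(output.serum_df, paths["serum"])
    write_event_log(output.event_log, paths["events"])
    write_germline_fasta(paths["germlines"])
    return paths
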