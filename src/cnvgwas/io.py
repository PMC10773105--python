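"""Readers and writers for the tab-delimited artifacts.

All tables are plain TSV. The CNV call table follows a PennCNV-like dialect
(sample_id, chrom, start, end, type in {DUP, DEL}, copy_number, qs with qs
in [-1, 1], sign encoding the CNV type); coordinates are 1-based inclusive
throughout, including in emitted BED-like region tables (noted in their
header).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "type", "copy_number", "qs"]
PROBE_COLUMNS = ["probe_id", "chrom", "pos"]

SUMSTATS_COLUMNS = [
    "disease", "model", "probe_id", "chrom", "pos", "beta", "se", "p",
    "or", "ci_low", "ci_high", "firth", "n_case", "n_control",
    "n_case_carrier",
]


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns {sorted(missing)}")
    if not df["type"].isin(["DUP", "DEL"]).all():
        raise ValueError("call type must be DUP or DEL")
    if ((df["qs"] < -1) | (df["qs"] > 1)).any():
        raise ValueError("qs outside [-1, 1]")
    return df[CALL_COLUMNS]


def write_calls(df: pd.DataFrame, path) -> None:
    df[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_probes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe map missing columns {sorted(missing)}")
    return df[PROBE_COLUMNS]


def write_probes(df: pd.DataFrame, path) -> None:
    df[PROBE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_intervals(path) -> pd.DataFrame:
    """BED-like interval file (chrom, start, end [, extra columns])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"interval file missing column {col!r}")
    return df


def write_cnvr_table(cnvrs, path) -> None:
    """Emit merged regions as a BED-like TSV (1-based inclusive)."""
    rows = []
    for k, r in enumerate(cnvrs):
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "name": f"cnvr_{k + 1}",
                "tier": r.tier if r.tier is not None else "",
                "models": ",".join(r.models),
                "diseases": ",".join(r.diseases),
                "gene_count": r.gene_count if r.gene_count is not None else "",
            }
        )
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "name", "tier", "models",
                     "diseases", "gene_count"],
        ).to_csv(fh, sep="\t", index=False)
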