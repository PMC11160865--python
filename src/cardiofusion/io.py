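"""Flat-file formats: TSV tables, minimal VCF panel input, Newick, JSON report.

All tables are tab-separated with a header row, UTF-8, '.' decimal, no
quoting.  Coordinates are 1-based inclusive (VCF convention) throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

COUNTS_COLUMNS = ["cell_id", "site_id", "depth", "alt_count", "mean_base_error"]
SITES_COLUMNS = ["site_id", "chrom", "pos", "ref", "alt"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: counts.tsv missing columns {sorted(missing)}")
    return df


def read_sites(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(SITES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sites.tsv missing columns {sorted(missing)}")
    return df


def read_panel_vcf(path: str | Path) -> pd.DataFrame:
    """Read a site panel from a minimal VCF 4.2 file (CHROM POS ID REF ALT)."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            alt = rec.alts[0] if rec.alts else "."
            rows.append(
                {
                    "site_id": rec.id if rec.id not in (None, ".") else f"s{i:04d}",
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                }
            )
    df = pd.DataFrame(rows, columns=SITES_COLUMNS)
    bad = df[(df["ref"].str.len() != 1) | (df["alt"].str.len() != 1)]
    if len(bad):
        raise ValueError(f"{path}: panel must contain single-nucleotide alleles only")
    return df


def write_panel_vcf(panel: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = list(dict.fromkeys(panel["chrom"]))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in panel.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['site_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\n"
            )


def write_config_echo(config: dict, path: str | Path) -> None:
    """Flat key=value echo of the effective configuration."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in sorted(_flatten(config).items()):
            fh.write(f"{k}={v}\n")


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, cls=_NumpyEncoder, allow_nan=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
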