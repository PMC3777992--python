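"""Readers and writers for the package's plain-text interchange formats.

Annotations travel as BED (0-based, half-open) plus a TSV arm table;
probe signal as a pair of bedGraph tracks (ChIP, input) plus a 5-column
TSV carrying uniqueness flags; bin tracks as bedGraph plus a TSV with
probe counts; reports as TSV and JSON. All writers are deterministic
(fixed column order, fixed float formatting, sorted JSON keys).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .errors import DataError
from .genome_partition import FeatureSet
from .signal_enrichment import BinTrack

FLOAT_FMT = "%.6g"


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_annotation(features: FeatureSet, outdir: str | Path) -> dict[str, Path]:
    """Write arms.tsv, te_instances.bed, pirna_clusters.bed; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arms = pd.DataFrame(
        [
            {
                "name": a.name,
                "length": a.length,
                "telomere_at_start": a.telomere_at_start,
                "pericentric_border": a.pericentric_border,
                "is_chr4": a.is_chr4,
            }
            for a in (features.arms[n] for n in sorted(features.arms))
        ]
    )
    paths = {"arms": outdir / "arms.tsv"}
    write_tsv(arms, paths["arms"])
    paths["te"] = outdir / "te_instances.bed"
    features.te_instances.to_csv(
        paths["te"], sep="\t", index=False, header=False,
        columns=["chrom", "start", "end", "family"],
    )
    paths["clusters"] = outdir / "pirna_clusters.bed"
    features.pirna_clusters.to_csv(
        paths["clusters"], sep="\t", index=False, header=False,
        columns=["chrom", "start", "end", "cluster"],
    )
    return paths


def write_probe_signal(probes: pd.DataFrame, outdir: str | Path, prefix: str) -> dict[str, Path]:
    """Write <prefix>_chip/input.bedGraph plus <prefix>_probes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for channel in ("chip", "input"):
        p = outdir / f"{prefix}_{channel}.bedGraph"
        bg = pd.DataFrame(
            {
                "chrom": probes["chrom"],
                "start": probes["pos"],
                "end": probes["pos"] + 1,
                "value": probes[channel],
            }
        )
        bg.to_csv(p, sep="\t", index=False, header=False, float_format=FLOAT_FMT)
        paths[channel] = p
    p = outdir / f"{prefix}_probes.tsv"
    write_tsv(probes[["chrom", "pos", "chip", "input", "unique"]], p)
    paths["probes"] = p
    return paths


def read_probe_tsv(path: str | Path) -> pd.DataFrame:
    """Read a 5-column probe TSV (chrom, pos, chip, input, unique)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "chip", "input", "unique"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing probe columns {sorted(missing)}")
    df["unique"] = df["unique"].astype(bool)
    return df


def write_bin_track(bins: BinTrack, outdir: str | Path, prefix: str) -> dict[str, Path]:
    """Write <prefix>_bins.bedGraph (mean M) and <prefix>_bins.tsv (with counts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bg = pd.DataFrame(
        {
            "chrom": bins.df["chrom"],
            "start": bins.df["start"],
            "end": bins.df["start"] + bins.bin_width,
            "mean_m": bins.df["mean_m"],
        }
    )
    paths = {"bedgraph": Path(outdir) / f"{prefix}_bins.bedGraph"}
    bg.to_csv(paths["bedgraph"], sep="\t", index=False, header=False, float_format=FLOAT_FMT)
    paths["tsv"] = Path(outdir) / f"{prefix}_bins.tsv"
    write_tsv(bins.df, paths["tsv"])
    return paths


def read_csv_table(path: str | Path, required: set[str]) -> pd.DataFrame:
    """Read an assay CSV and verify its header; row errors name row numbers."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"{path}: unreadable CSV ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df
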