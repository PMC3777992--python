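"""Per-probe M values, per-sample normalization, and fixed-width binning.

The enrichment statistic throughout is the M value: the log2 ratio of
ChIP signal intensity to input signal intensity at a probe. Tracks are
median-centered per sample over uniquely mapping probes (the convention
that typical background probes sit at M = 0), then averaged into
fixed-width genomic bins (default 500 bp) for all downstream class
summaries. Non-unique probes are kept in the track but excluded from
bins by default, so only signal attributable to a single genomic
position contributes to class averages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import DataError

PROBE_COLUMNS = ["chrom", "pos", "chip", "input", "unique"]


class ProbeRecord(NamedTuple):
    """One probe: genomic midpoint plus paired two-channel intensities."""

    chrom: str
    pos: int
    chip: float
    input: float
    unique: bool = True


def probes_to_frame(probes) -> pd.DataFrame:
    """Coerce a probe DataFrame or iterable of ProbeRecord to a DataFrame."""
    if isinstance(probes, pd.DataFrame):
        missing = set(PROBE_COLUMNS) - set(probes.columns)
        if missing:
            raise DataError(f"probe table missing columns {sorted(missing)}")
        return probes.reset_index(drop=True)
    return pd.DataFrame(list(probes), columns=PROBE_COLUMNS)


@dataclass
class MTrack:
    """Per-probe M values (chrom, pos, m, unique) and a normalization flag."""

    df: pd.DataFrame
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class BinTrack:
    """Fixed-width bin means: (chrom, start, mean_m, n_probes).

    Bins are half-open [start, start + bin_width), aligned to multiples
    of bin_width from coordinate 0. Bins with no probes are omitted.
    """

    bin_width: int
    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)


def compute_m_values(probes: pd.DataFrame | Iterable[ProbeRecord]) -> MTrack:
    """M = log2(chip / input) per probe; order and uniqueness flags kept.

    Intensities must be strictly positive; a non-positive value raises
    :class:`DataError` identifying the offending probe rather than being
    silently log-transformed.
    """
    df = probes_to_frame(probes)
    chip = df["chip"].to_numpy(dtype=float)
    inp = df["input"].to_numpy(dtype=float)
    bad = np.flatnonzero(~((chip > 0) & (inp > 0)))
    if bad.size:
        i = int(bad[0])
        raise DataError(
            f"non-positive intensity at probe {i} "
            f"({df['chrom'].iat[i]}:{df['pos'].iat[i]}: chip={chip[i]}, input={inp[i]})"
        )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "m": np.log2(chip / inp),
            "unique": df["unique"].to_numpy(dtype=bool),
        }
    )
    return MTrack(df=out, normalized=False)


def normalize_track(track: MTrack) -> MTrack:
    """Median-center M over unique probes; returns a new track.

    The median of unique-probe M values is subtracted from every probe,
    so after normalization the unique-probe median is 0. When
    heterochromatic probes make up a sizeable minority, the global
    median sits slightly above the euchromatic background; the pipeline
    corrects for this after class assignment by recentering bin means
    on annotated euchromatin (see
    :func:`hetprofile.class_profiles.recenter_on_background`).
    """
    if track.normalized:
        raise DataError("track is already normalized")
    if len(track) == 0:
        raise DataError("cannot normalize an empty track")
    uniq = track.df.loc[track.df["unique"], "m"]
    if uniq.empty:
        raise DataError("no unique probes to define the normalization median")
    med = float(np.median(uniq.to_numpy()))
    df = track.df.copy()
    df["m"] = df["m"] - med
    return replace(track, df=df, normalized=True)


def bin_track(track: MTrack, bin_width: int = 500, include_nonunique: bool = False) -> BinTrack:
    """Average probe M values into fixed-width bins.

    A probe at position ``pos`` falls in bin ``floor(pos / bin_width)``.
    Non-unique probes are excluded unless ``include_nonunique``. Empty
    bins are omitted, never zero-filled.
    """
    if bin_width <= 0:
        raise DataError("bin_width must be > 0")
    df = track.df if include_nonunique else track.df[track.df["unique"]]
    if df.empty:
        return BinTrack(bin_width=bin_width, df=pd.DataFrame(columns=["chrom", "start", "mean_m", "n_probes"]))
    start = (df["pos"].to_numpy() // bin_width) * bin_width
    grouped = (
        pd.DataFrame({"chrom": df["chrom"].to_numpy(), "start": start, "m": df["m"].to_numpy()})
        .groupby(["chrom", "start"], sort=True)["m"]
        .agg(mean_m="mean", n_probes="size")
        .reset_index()
    )
    grouped["start"] = grouped["start"].astype(int)
    grouped["n_probes"] = grouped["n_probes"].astype(int)
    return BinTrack(bin_width=bin_width, df=grouped)
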