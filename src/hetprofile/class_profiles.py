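"""Per-class enrichment summaries and wild-type-vs-mutant differentials.

Bins labeled by :func:`~hetprofile.genome_partition.assign_bins` are
averaged per class label (pericentric, chromosome4, per-TE-family,
per-cluster, subtelomere, euchromatin) plus two aggregate labels:
``te`` over all TE-labeled bins and ``cluster`` over all cluster-labeled
bins. Differentials report the percent decrease of the class mean M,
100 x (mean_wt - mean_mut) / mean_wt, guarded by an ``m_floor`` on the
reference mean so near-zero classes (roo-like TE families) report only
the absolute change delta_m; direction counts tally families/clusters
whose mean M dropped in the mutant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .genome_partition import (
    CLUSTER_PREFIX,
    EUCHROMATIN,
    TE_PREFIX,
    BinMembership,
)
from .signal_enrichment import BinTrack

TE_AGGREGATE = "te"
CLUSTER_AGGREGATE = "cluster"


@dataclass
class EnrichmentProfile:
    """Per-label mean M with bin counts and standard errors."""

    condition: str
    table: pd.DataFrame  # label, mean_m, n_bins, se
    uncovered: list[str] = field(default_factory=list)

    def mean(self, label: str) -> float:
        rows = self.table[self.table["label"] == label]
        if rows.empty:
            raise KeyError(label)
        return float(rows["mean_m"].iloc[0])


@dataclass
class DifferentialReport:
    """Wild-type-vs-mutant changes per label plus direction counts."""

    table: pd.DataFrame
    te_direction_counts: tuple[int, int]  # (n_decreased, n_total)
    cluster_direction_counts: tuple[int, int]
    m_floor: float
    min_bins: int

    def percent_decrease(self, label: str) -> float:
        rows = self.table[self.table["label"] == label]
        if rows.empty:
            raise KeyError(label)
        return float(rows["percent_decrease"].iloc[0])

    def delta(self, label: str) -> float:
        rows = self.table[self.table["label"] == label]
        if rows.empty:
            raise KeyError(label)
        return float(rows["delta_m"].iloc[0])


@dataclass
class CorrelationReport:
    """Cross-profile agreement of per-family means."""

    pairs: pd.DataFrame  # label, mean_a, mean_b
    r_squared: float
    n_families: int
    fold_level_r: float | None = None  # corr of supplied per-family deltas vs level in b


@dataclass
class SubtelomereProfile:
    """Ordered bin series per arm, telomere -> centromere."""

    series: dict[str, pd.DataFrame]
    empty_arms: list[str] = field(default_factory=list)


def recenter_on_background(
    bins: BinTrack, membership: BinMembership, label: str = EUCHROMATIN
) -> BinTrack:
    """Shift all bin means so the background class averages 0.

    Per-sample median normalization leaves a small positive offset when
    heterochromatic probes are a non-negligible minority (the global
    median sits above the euchromatic peak), which would inflate every
    percent-decrease denominator. Subtracting the probe-weighted mean M
    of background-labeled bins pins enrichment to the euchromatic
    baseline instead. A no-op (offset 0) on noiseless background.
    """
    mask = np.asarray(membership.mask_for(label))
    if not mask.any():
        raise DataError(f"no bins labeled {label!r} to define the background level")
    sub = bins.df.loc[mask]
    weights = sub["n_probes"].to_numpy(dtype=float)
    offset = float(np.average(sub["mean_m"].to_numpy(), weights=weights))
    df = bins.df.copy()
    df["mean_m"] = df["mean_m"] - offset
    return BinTrack(bin_width=bins.bin_width, df=df)


def class_mean_profile(
    bins: BinTrack, membership: BinMembership, condition: str
) -> EnrichmentProfile:
    """Arithmetic mean of member-bin mean_m per label, with n and SE.

    SE is the sd of member-bin means over sqrt(n_bins) (0 for singleton
    labels). Labels with no member bins are listed as uncovered.
    """
    if len(membership.labels) != len(bins):
        raise DataError("membership is not aligned with the bin track")
    values: dict[str, list[float]] = {}
    m = bins.df["mean_m"].to_numpy()
    for i, labels in enumerate(membership.labels):
        seen_te = False
        seen_cl = False
        for lbl in labels:
            values.setdefault(lbl, []).append(m[i])
            if lbl.startswith(TE_PREFIX):
                seen_te = True
            elif lbl.startswith(CLUSTER_PREFIX):
                seen_cl = True
        if seen_te:
            values.setdefault(TE_AGGREGATE, []).append(m[i])
        if seen_cl:
            values.setdefault(CLUSTER_AGGREGATE, []).append(m[i])
    rows = []
    for lbl in sorted(values):
        arr = np.asarray(values[lbl])
        n = len(arr)
        se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append({"label": lbl, "mean_m": float(arr.mean()), "n_bins": n, "se": se})
    return EnrichmentProfile(
        condition=condition,
        table=pd.DataFrame(rows, columns=["label", "mean_m", "n_bins", "se"]),
        uncovered=[],
    )


def differential_profile(
    wt: EnrichmentProfile,
    mut: EnrichmentProfile,
    m_floor: float = 0.1,
    min_bins: int = 5,
) -> DifferentialReport:
    """Per-label change between two conditions plus direction counts.

    delta_m = mean_mut - mean_wt is always reported; percent_decrease =
    100 x (mean_wt - mean_mut) / mean_wt only where mean_wt > m_floor
    (NaN and ``floored`` flag otherwise). Direction counts cover TE
    families and piRNA clusters with >= min_bins bins in both profiles;
    "decreased" means delta_m < 0 strictly, exact ties are unchanged.
    """
    wt_idx = wt.table.set_index("label")
    mut_idx = mut.table.set_index("label")
    shared = [lbl for lbl in wt_idx.index if lbl in mut_idx.index]
    if not shared:
        raise DataError("profiles share no labels")
    rows = []
    for lbl in shared:
        a, b = wt_idx.loc[lbl], mut_idx.loc[lbl]
        mean_wt, mean_mut = float(a["mean_m"]), float(b["mean_m"])
        delta = mean_mut - mean_wt
        se_delta = math.sqrt(float(a["se"]) ** 2 + float(b["se"]) ** 2)
        floored = not (mean_wt > m_floor)
        if floored:
            # below the floor the ratio is unreliable; exact equality is
            # still an unambiguous 0% change
            pct = 0.0 if delta == 0 else float("nan")
            pct_se = float("nan")
        else:
            pct = 100.0 * (mean_wt - mean_mut) / mean_wt
            # first-order propagation of the ratio mean_mut / mean_wt
            pct_se = (100.0 / mean_wt) * math.sqrt(
                float(b["se"]) ** 2 + (mean_mut / mean_wt) ** 2 * float(a["se"]) ** 2
            )
        if delta < 0:
            direction = "decreased"
        elif delta > 0:
            direction = "increased"
        else:
            direction = "unchanged"
        rows.append(
            {
                "label": lbl,
                "mean_wt": mean_wt,
                "mean_mut": mean_mut,
                "delta_m": delta,
                "se_delta": se_delta,
                "percent_decrease": pct,
                "percent_decrease_se": pct_se,
                "floored": floored,
                "direction": direction,
                "n_bins_wt": int(a["n_bins"]),
                "n_bins_mut": int(b["n_bins"]),
            }
        )
    table = pd.DataFrame(rows)

    def counts(prefix: str) -> tuple[int, int]:
        sub = table[
            table["label"].str.startswith(prefix)
            & (table["n_bins_wt"] >= min_bins)
            & (table["n_bins_mut"] >= min_bins)
        ]
        return int((sub["direction"] == "decreased").sum()), int(len(sub))

    return DifferentialReport(
        table=table,
        te_direction_counts=counts(TE_PREFIX),
        cluster_direction_counts=counts(CLUSTER_PREFIX),
        m_floor=m_floor,
        min_bins=min_bins,
    )


def cross_condition_correlation(
    a: EnrichmentProfile,
    b: EnrichmentProfile,
    label_prefix: str = TE_PREFIX,
    deltas: dict[str, float] | None = None,
) -> CorrelationReport:
    """Squared Pearson correlation of per-family means across two profiles.

    With ``deltas`` (per-family delta_m from a differential, e.g. the
    mutant effect in one tissue), also reports the plain Pearson r of
    those deltas against the family's enrichment level in profile ``b``
    (a fold-change-vs-level check).
    """
    a_idx = a.table.set_index("label")["mean_m"]
    b_idx = b.table.set_index("label")["mean_m"]
    shared = sorted(
        lbl for lbl in a_idx.index if lbl.startswith(label_prefix) and lbl in b_idx.index
    )
    if len(shared) < 3:
        raise DataError(f"need >=3 shared {label_prefix!r} labels, got {len(shared)}")
    xa = a_idx.loc[shared].to_numpy(dtype=float)
    xb = b_idx.loc[shared].to_numpy(dtype=float)
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise DataError("correlation undefined: a profile has zero variance across families")
    r = float(np.corrcoef(xa, xb)[0, 1])
    fold_level_r = None
    if deltas is not None:
        common = [lbl for lbl in shared if lbl in deltas]
        if len(common) >= 3:
            d = np.array([deltas[lbl] for lbl in common], dtype=float)
            lvl = b_idx.loc[common].to_numpy(dtype=float)
            fold_level_r = float(np.corrcoef(d, lvl)[0, 1])
    return CorrelationReport(
        pairs=pd.DataFrame({"label": shared, "mean_a": xa, "mean_b": xb}),
        r_squared=r * r,
        n_families=len(shared),
        fold_level_r=fold_level_r,
    )


def subtelomere_profile(
    bins: BinTrack,
    windows: dict[str, tuple[int, int]],
    telomere_at_start: dict[str, bool] | None = None,
) -> SubtelomereProfile:
    """Bin series inside each arm's terminal window, telomere first.

    Orientation uses ``telomere_at_start`` when given; otherwise a
    window starting at 0 is taken as telomere-at-start. Arms whose
    window holds no covered bins are flagged empty.
    """
    series: dict[str, pd.DataFrame] = {}
    empty: list[str] = []
    for arm, (lo, hi) in sorted(windows.items()):
        sub = bins.df[
            (bins.df["chrom"] == arm) & (bins.df["start"] >= lo) & (bins.df["start"] < hi)
        ].copy()
        if sub.empty:
            empty.append(arm)
            series[arm] = sub.reset_index(drop=True)
            continue
        at_start = telomere_at_start[arm] if telomere_at_start is not None else lo == 0
        sub = sub.sort_values("start", ascending=at_start)
        series[arm] = sub.reset_index(drop=True)
    return SubtelomereProfile(series=series, empty_arms=empty)
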