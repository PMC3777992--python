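"""Genome annotation model and bin-to-feature-class assignment.

A genome is a set of chromosome arms. Each arm carries a pericentric
border (centromere-proximal of the border is heterochromatin), an
orientation flag saying which end holds the telomere, and an ``is_chr4``
flag for small arms treated as entirely heterochromatic ("chromosome 4"
class). On top of the arms sit interval features: transposable-element
(TE) instances labeled by family, and piRNA clusters labeled by id.

Bins from a :class:`~hetprofile.signal_enrichment.BinTrack` are assigned
class labels by midpoint containment. Labels are *sets*, not a
partition: a bin inside a TE copy that lies in pericentric
heterochromatin carries both ``TE:<family>`` and ``pericentric``.
``euchromatin`` is the absence of any heterochromatic label
(subtelomere labels do not count as heterochromatic).

Coordinates are 0-based, half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError

PERICENTRIC = "pericentric"
CHROMOSOME4 = "chromosome4"
EUCHROMATIN = "euchromatin"
TE_PREFIX = "TE:"
CLUSTER_PREFIX = "cluster:"
SUBTEL_PREFIX = "subtelomere:"

#: Labels that make a bin heterochromatic (prefix match for TE/cluster).
_HET_EXACT = {PERICENTRIC, CHROMOSOME4}
_HET_PREFIXES = (TE_PREFIX, CLUSTER_PREFIX)


@dataclass(frozen=True)
class ChromosomeArm:
    """One chromosome arm with its heterochromatin geometry.

    ``pericentric_border`` is the coordinate separating euchromatin from
    pericentric heterochromatin; which side is heterochromatic follows
    from ``telomere_at_start`` (the centromere sits at the opposite end
    of the telomere). Arms flagged ``is_chr4`` are treated as entirely
    heterochromatic, as class "chromosome 4", and carry no pericentric
    label.
    """

    name: str
    length: int
    telomere_at_start: bool
    pericentric_border: int
    is_chr4: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise DataError(f"arm {self.name!r}: length must be > 0")
        if not (0 < self.pericentric_border <= self.length):
            raise DataError(
                f"arm {self.name!r}: pericentric_border must satisfy "
                f"0 < border <= length (got {self.pericentric_border})"
            )

    def pericentric_span(self) -> tuple[int, int] | None:
        """Half-open interval of pericentric heterochromatin, or None for chr4."""
        if self.is_chr4:
            return None
        if self.telomere_at_start:
            return (self.pericentric_border, self.length)
        return (0, self.pericentric_border)

    def is_pericentric(self, pos: float) -> bool:
        span = self.pericentric_span()
        if span is None:
            return False
        return span[0] <= pos < span[1]


@dataclass
class FeatureSet:
    """Arms plus labeled interval features.

    ``te_instances`` columns: chrom, start, end, family.
    ``pirna_clusters`` columns: chrom, start, end, cluster.
    ``reporter_loci`` (optional) columns: chrom, pos, name.
    """

    arms: dict[str, ChromosomeArm]
    te_instances: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "family"])
    )
    pirna_clusters: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "cluster"])
    )
    reporter_loci: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.arms:
            raise DataError("FeatureSet requires at least one chromosome arm")
        self.validate()

    def validate(self) -> None:
        for df, id_col, what in (
            (self.te_instances, "family", "TE instance"),
            (self.pirna_clusters, "cluster", "piRNA cluster"),
        ):
            for idx, row in df.iterrows():
                if row["chrom"] not in self.arms:
                    raise DataError(f"{what} {idx}: unknown chrom {row['chrom']!r}")
                if not row["end"] > row["start"] >= 0:
                    raise DataError(
                        f"{what} {idx}: invalid interval [{row['start']}, {row['end']})"
                    )
                if row["end"] > self.arms[row["chrom"]].length:
                    raise DataError(
                        f"{what} {idx}: end {row['end']} beyond arm "
                        f"{row['chrom']!r} length {self.arms[row['chrom']].length}"
                    )
                if not str(row[id_col]):
                    raise DataError(f"{what} {idx}: empty {id_col} id")

    @property
    def te_families(self) -> list[str]:
        return sorted(self.te_instances["family"].unique())

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.pirna_clusters["cluster"].astype(str).unique())


@dataclass
class BinMembership:
    """Per-bin label sets, row-aligned with the originating BinTrack."""

    labels: list[frozenset[str]]

    def all_labels(self) -> set[str]:
        out: set[str] = set()
        for s in self.labels:
            out |= s
        return out

    def mask_for(self, label: str) -> list[bool]:
        return [label in s for s in self.labels]

    def mask_for_prefix(self, prefix: str) -> list[bool]:
        return [any(lbl.startswith(prefix) for lbl in s) for s in self.labels]


def _is_heterochromatic(label: str) -> bool:
    return label in _HET_EXACT or label.startswith(_HET_PREFIXES)


def load_annotation(
    arm_table: str,
    te_bed: str | None = None,
    cluster_bed: str | None = None,
    reporter_bed: str | None = None,
) -> FeatureSet:
    """Read an arm table (TSV) and BED feature files into a FeatureSet.

    Arm table columns: name, length, telomere_at_start, pericentric_border,
    is_chr4. BED files are 4-column (chrom, start, end, name); the name
    field is the TE family or cluster id. Malformed lines raise
    :class:`DataError` naming the file and 1-based line number.
    """
    arm_df = pd.read_csv(arm_table, sep="\t")
    required = {"name", "length", "telomere_at_start", "pericentric_border", "is_chr4"}
    missing = required - set(arm_df.columns)
    if missing:
        raise DataError(f"{arm_table}: missing arm-table columns {sorted(missing)}")
    arms = {
        str(r["name"]): ChromosomeArm(
            name=str(r["name"]),
            length=int(r["length"]),
            telomere_at_start=bool(r["telomere_at_start"]),
            pericentric_border=int(r["pericentric_border"]),
            is_chr4=bool(r["is_chr4"]),
        )
        for _, r in arm_df.iterrows()
    }

    def read_bed(path: str, id_col: str) -> pd.DataFrame:
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise DataError(f"{path} line {lineno}: expected 4 BED columns")
                chrom, start_s, end_s, name = parts[:4]
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise DataError(f"{path} line {lineno}: non-integer coordinates")
                if chrom not in arms:
                    raise DataError(f"{path} line {lineno}: unknown chrom {chrom!r}")
                if end <= start:
                    raise DataError(f"{path} line {lineno}: end <= start")
                if end > arms[chrom].length:
                    raise DataError(
                        f"{path} line {lineno}: interval end {end} beyond arm length"
                    )
                if not name:
                    raise DataError(f"{path} line {lineno}: missing {id_col} id")
                rows.append({"chrom": chrom, "start": start, "end": end, id_col: name})
        return pd.DataFrame(rows, columns=["chrom", "start", "end", id_col])

    te = read_bed(te_bed, "family") if te_bed else None
    clusters = read_bed(cluster_bed, "cluster") if cluster_bed else None
    reporters = None
    if reporter_bed:
        rep = read_bed(reporter_bed, "name")
        reporters = pd.DataFrame(
            {"chrom": rep["chrom"], "pos": (rep["start"] + rep["end"]) // 2, "name": rep["name"]}
        )
    kwargs = {}
    if te is not None:
        kwargs["te_instances"] = te
    if clusters is not None:
        kwargs["pirna_clusters"] = clusters
    return FeatureSet(arms=arms, reporter_loci=reporters, **kwargs)


def subtelomeric_windows(features: FeatureSet, window: int = 50_000) -> dict[str, tuple[int, int]]:
    """Per-arm half-open window of the assembly end nearest the telomere.

    Arms shorter than ``window`` yield the whole arm.
    """
    if window <= 0:
        raise DataError("subtelomere window must be > 0")
    out: dict[str, tuple[int, int]] = {}
    for name, arm in features.arms.items():
        w = min(window, arm.length)
        if arm.telomere_at_start:
            out[name] = (0, w)
        else:
            out[name] = (arm.length - w, arm.length)
    return out


def assign_bins(bins, features: FeatureSet, subtelomere_window: int = 50_000) -> BinMembership:
    """Label each bin of a BinTrack by midpoint containment.

    A bin belongs to an interval feature iff its midpoint
    (start + bin_width/2) lies inside the feature. Pericentric and
    subtelomere labels use the same midpoint rule against the arm
    geometry; chr4-like arms label every bin ``chromosome4``.
    ``euchromatin`` is added iff no heterochromatic label applies.
    """
    trees_te: dict[str, IntervalTree] = {}
    for _, row in features.te_instances.iterrows():
        trees_te.setdefault(row["chrom"], IntervalTree()).addi(
            row["start"], row["end"], TE_PREFIX + str(row["family"])
        )
    trees_cl: dict[str, IntervalTree] = {}
    for _, row in features.pirna_clusters.iterrows():
        trees_cl.setdefault(row["chrom"], IntervalTree()).addi(
            row["start"], row["end"], CLUSTER_PREFIX + str(row["cluster"])
        )
    subtel = subtelomeric_windows(features, subtelomere_window)

    half = bins.bin_width / 2.0
    labels: list[frozenset[str]] = []
    for chrom, start in zip(bins.df["chrom"], bins.df["start"]):
        if chrom not in features.arms:
            raise DataError(f"bin on unknown arm {chrom!r}")
        arm = features.arms[chrom]
        mid = start + half
        s: set[str] = set()
        if arm.is_chr4:
            s.add(CHROMOSOME4)
        elif arm.is_pericentric(mid):
            s.add(PERICENTRIC)
        lo, hi = subtel[chrom]
        if lo <= mid < hi:
            s.add(SUBTEL_PREFIX + chrom)
        if chrom in trees_te:
            for iv in trees_te[chrom].at(mid):
                s.add(iv.data)
        if chrom in trees_cl:
            for iv in trees_cl[chrom].at(mid):
                s.add(iv.data)
        if not any(_is_heterochromatic(lbl) for lbl in s):
            s.add(EUCHROMATIN)
        labels.append(frozenset(s))
    return BinMembership(labels=labels)
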