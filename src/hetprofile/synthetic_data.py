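"""Synthetic tiling-array, qPCR, and reporter-assay data with known truth.

Every downstream stage of the pipeline is exercised against data whose
ground truth is planted by construction:

* a small multi-arm genome with pericentric borders, a chr4-like arm,
  TE instances grouped by family, and piRNA clusters;
* two-channel probe intensities in which ChIP = input x 2^(true M +
  noise), with the true M at a position set by the most specific
  containing feature (TE family > piRNA cluster > pericentric / chr4 >
  euchromatin at 0) and a condition-dependent shift for the mutant;
* qPCR plates with input-dilution series and IP wells generated from a
  per-locus amplification efficiency and a true fold enrichment;
* replicate beta-galactosidase time series and pigment endpoints per
  genotype class with lognormal between-replicate noise.

Default parameters emulate a piwi-mutant HP1a profiling experiment:
TE family baselines range from near 0 (roo-like families with little
HP1a) to M > 2 (gypsy5-like families); the mutant condition lowers the
M value of Piwi-sensitive territory multiplicatively, by 13.4% at
sensitive TEs, 6.7% in pericentric background, 5.7% on the chr4-like
arm, and 8.7% in piRNA clusters, with a minority of families and
clusters insensitive (shift 0) and one cluster gaining enrichment.

All randomness flows from ``config.seed`` (or an explicit ``seed``
argument) through per-purpose ``numpy`` generator streams, so identical
configuration and seed reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigError
from .genome_partition import ChromosomeArm, FeatureSet, subtelomeric_windows

WILD_TYPE = "wild_type"
MUTANT = "mutant"
CONDITIONS = (WILD_TYPE, MUTANT)

# rng stream ids, one per sampling purpose, combined with the base seed
_STREAM_LAYOUT = 1
_STREAM_UNIQUE = 2
_STREAM_SIGNAL = {WILD_TYPE: 3, MUTANT: 4}
_STREAM_QPCR = {WILD_TYPE: 5, MUTANT: 6}
_STREAM_ASSAY = 7
_STREAM_EXPRESSION = 8


@dataclass(frozen=True)
class Shift:
    """Condition effect on true M: relative (fractional) or additive (log2)."""

    mode: str  # "relative" | "additive"
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "additive"):
            raise ConfigError(f"unknown shift mode {self.mode!r}")

    def apply(self, m: float | np.ndarray):
        if self.mode == "relative":
            return m * (1.0 + self.value)
        return m + self.value


NO_SHIFT = Shift("additive", 0.0)


@dataclass(frozen=True)
class ArmSpec:
    name: str
    length: int
    telomere_at_start: bool
    pericentric_border: int
    is_chr4: bool = False


@dataclass(frozen=True)
class TeFamilySpec:
    name: str
    n_instances: int
    length_range: tuple[int, int]
    baseline_m: float
    placement: str = "uniform"  # "uniform" | "subtelomeric"
    shift: Shift | None = None  # None -> class-level "te" shift


@dataclass(frozen=True)
class ClusterGroupSpec:
    prefix: str
    count: int
    length_range: tuple[int, int]
    baseline_m: float
    shift: Shift | None = None  # None -> class-level "cluster" shift


@dataclass(frozen=True)
class QpcrLocusTruth:
    """True fold enrichment over the control locus, per condition."""

    fold_enrichment: Mapping[str, float]
    efficiency: float = 1.0  # fraction; amplification base b = 1 + efficiency
    ct_noise_sd: float = 0.0


@dataclass(frozen=True)
class AssayClassTruth:
    mean: float
    lognormal_sd: float
    n_replicates: int


def _default_te_families() -> tuple[TeFamilySpec, ...]:
    # Family names follow well-known Drosophila TE families. Baselines span
    # near-zero (roo-like) to M > 2 (gypsy5-like); eight low-enrichment
    # families are Piwi-insensitive (shift 0), mirroring the minority of
    # families whose HP1a level does not respond to Piwi depletion.
    sensitive_mid = [
        ("Bari1", 1.6), ("Invader1", 1.5), ("mdg1", 1.7), ("blood", 1.2),
        ("gypsy", 1.4), ("copia", 1.0), ("jockey", 1.1), ("F-element", 0.9),
        ("Doc", 1.3), ("412", 1.35), ("297", 1.25), ("1731", 0.95),
        ("mdg3", 1.45), ("Burdock", 1.55), ("Transpac", 1.05),
        ("springer", 1.15), ("Ine-1", 0.85),
    ]
    high = [("gypsy5", 2.4), ("invader3", 2.2), ("DIVER2", 2.1)]
    telomeric = [("HeT-A", 1.8), ("TART", 1.9)]
    insensitive = [
        ("roo", 0.05), ("DMRP1", 0.10), ("XDMR", 0.15), ("Rt1b", 0.20),
        ("Cr1a", 0.25), ("baggins", 0.12), ("G-element", 0.18), ("hopper", 0.22),
    ]
    specs: list[TeFamilySpec] = []
    for name, m in sensitive_mid + high:
        specs.append(TeFamilySpec(name, 6, (800, 2000), m))
    for name, m in telomeric:
        specs.append(TeFamilySpec(name, 6, (800, 2000), m, placement="subtelomeric"))
    for name, m in insensitive:
        specs.append(TeFamilySpec(name, 6, (800, 2000), m, shift=NO_SHIFT))
    return tuple(specs)


def _default_clusters() -> tuple[ClusterGroupSpec, ...]:
    # 14 of 20 clusters respond to the mutant condition, five are inert and
    # one (42AB-like) gains enrichment: with the inert clusters splitting
    # ~50/50 on noise, the expected decreased fraction matches the ~5/6
    # of clusters that lose enrichment in the profiled data.
    return (
        ClusterGroupSpec("cluster", 14, (10_000, 30_000), 1.3),
        ClusterGroupSpec("inert", 5, (10_000, 30_000), 1.3, shift=NO_SHIFT),
        ClusterGroupSpec("gain42AB", 1, (20_000, 30_000), 1.3, shift=Shift("relative", 0.05)),
    )


def _default_class_shift() -> dict[str, Shift]:
    # Targets for the CLASS-MEAN decreases are 13.4% (TE), 6.7%
    # (pericentric), 5.7% (chr4), 8.7% (clusters). Because a minority of
    # families/clusters is insensitive (shift 0) yet still counted in the
    # class mean, the shift applied to the sensitive territory is scaled up
    # by the inverse of the sensitive fraction of total class weight
    # (baseline x expected bp), so the aggregate lands on the target.
    # Likewise the pericentric/chr4 background shifts are solved from the
    # expected admixture of TE (4.6% occupancy) and cluster (7.4%) territory,
    # which decreases more steeply than the background it sits in, and the
    # cluster territory shift accounts for embedded TEs and the 42AB-like
    # cluster's +5% gain.
    return {
        "te": Shift("relative", -0.139),
        "pericentric": Shift("relative", -0.063),
        "chromosome4": Shift("relative", -0.051),
        "cluster": Shift("relative", -0.128),
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults define the reference run."""

    arm_specs: tuple[ArmSpec, ...] = (
        ArmSpec("arm2L", 2_200_000, True, 1_800_000),
        ArmSpec("arm3R", 2_100_000, False, 350_000),
        # sized like the real assembled chromosome 4 (~1.2 Mb)
        ArmSpec("chr4", 1_200_000, True, 1_200_000, is_chr4=True),
    )
    te_family_specs: tuple[TeFamilySpec, ...] = field(default_factory=_default_te_families)
    cluster_specs: tuple[ClusterGroupSpec, ...] = field(default_factory=_default_clusters)
    class_shift: dict[str, Shift] = field(default_factory=_default_class_shift)
    pericentric_m: float = 1.5
    chr4_m: float = 1.2
    probe_spacing: int = 300
    probe_noise_sd: float = 0.3
    nonunique_fraction: float = 0.15
    input_mean_intensity: float = 1000.0
    input_lognormal_sd: float = 0.4
    subtelomere_window: int = 50_000
    # qPCR plate layout and truth
    qpcr_control_locus: str = "alpha_actinin"
    qpcr_input_dilutions: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001)
    qpcr_base_efficacy: float = 0.01  # control-locus pulldown efficacy (input fraction)
    qpcr_input_ct_at_full: float = 14.0
    qpcr_n_input_replicates: int = 2
    qpcr_n_ip_replicates: int = 4
    qpcr_truth: dict[str, QpcrLocusTruth] = field(
        default_factory=lambda: {
            "alpha_actinin": QpcrLocusTruth({WILD_TYPE: 1.0, MUTANT: 1.0}, 1.0, 0.15),
            "hsp70_reporter": QpcrLocusTruth({WILD_TYPE: 4.0, MUTANT: 2.0}, 1.0, 0.15),
            "HeT-A_promoter": QpcrLocusTruth({WILD_TYPE: 4.0, MUTANT: 2.0}, 1.0, 0.15),
        }
    )
    # RT-qPCR expression truth: sample -> fold change vs reference sample
    expression_truth: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "piwi_kd": 0.5}
    )
    expression_reference: str = "control"
    expression_target_locus: str = "piwi"
    expression_control_locus: str = "RPL32"
    expression_ct_noise_sd: float = 0.1
    expression_n_replicates: int = 4
    # PEV reporter assay truth per genotype class
    assay_truth: dict[str, dict[str, AssayClassTruth]] = field(
        default_factory=lambda: {
            "beta_gal": {
                "C": AssayClassTruth(8e-4, 0.2, 6),
                "M": AssayClassTruth(1.6e-3, 0.2, 6),
                "Z": AssayClassTruth(3.2e-3, 0.2, 6),
                "M+Z": AssayClassTruth(4.8e-3, 0.2, 6),
            },
            "pigment": {
                "C": AssayClassTruth(0.08, 0.2, 6),
                "M": AssayClassTruth(0.16, 0.2, 6),
                "Z": AssayClassTruth(0.32, 0.2, 6),
                "M+Z": AssayClassTruth(0.48, 0.2, 6),
            },
        }
    )
    assay_control_class: str = "C"
    beta_gal_times: tuple[float, ...] = (0, 15, 30, 45, 60, 75, 90, 105, 120)
    beta_gal_od0: float = 0.05
    flies_per_sample: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_spacing <= 0:
            raise ConfigError("probe_spacing must be > 0")
        if not (0 <= self.nonunique_fraction < 1):
            raise ConfigError("nonunique_fraction must be in [0, 1)")
        for spec in self.arm_specs:
            if spec.length <= 0:
                raise ConfigError(f"arm {spec.name!r}: length must be > 0")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _family_shift(config: SimConfig, spec: TeFamilySpec) -> Shift:
    if spec.shift is not None:
        return spec.shift
    return config.class_shift.get("te", NO_SHIFT)


def _cluster_shift(config: SimConfig, spec: ClusterGroupSpec) -> Shift:
    if spec.shift is not None:
        return spec.shift
    return config.class_shift.get("cluster", NO_SHIFT)


# ---------------------------------------------------------------------------
# annotation


def build_genome_annotation(config: SimConfig) -> FeatureSet:
    """Lay out arms, TE instances, and piRNA clusters at random positions.

    Placed intervals never overlap one another (overlap with pericentric
    territory is expected and allowed); placement is rejection-sampled,
    and a genome too small for the requested features raises
    :class:`CapacityError`.
    """
    arms = {
        s.name: ChromosomeArm(s.name, s.length, s.telomere_at_start, s.pericentric_border, s.is_chr4)
        for s in config.arm_specs
    }
    genome_bp = sum(a.length for a in arms.values())
    feature_bp = sum(
        s.n_instances * s.length_range[1] for s in config.te_family_specs
    ) + sum(s.count * s.length_range[1] for s in config.cluster_specs)
    if feature_bp > genome_bp:
        raise CapacityError(
            f"requested features need up to {feature_bp} bp but genome has {genome_bp} bp"
        )

    rng = _rng(config.seed, _STREAM_LAYOUT)
    arm_names = sorted(arms)
    weights = np.array([arms[n].length for n in arm_names], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in arm_names}

    def try_place(chrom: str, lo: int, hi: int, length: int) -> int | None:
        # uniform start in [lo, hi - length]; None if it cannot fit or collides
        if hi - lo < length:
            return None
        start = int(rng.integers(lo, hi - length + 1))
        end = start + length
        for s, e in placed[chrom]:
            if start < e and s < end:
                return None
        return start

    def place(length: int, placement: str) -> tuple[str, int]:
        subtel = subtelomeric_windows(FeatureSet(arms=arms), config.subtelomere_window)
        for _ in range(2000):
            if placement == "subtelomeric":
                # telomere-associated families live in the terminal windows
                chrom = arm_names[int(rng.choice(len(arm_names), p=weights))]
                lo, hi = subtel[chrom]
            else:
                chrom = arm_names[int(rng.choice(len(arm_names), p=weights))]
                lo, hi = 0, arms[chrom].length
            start = try_place(chrom, lo, hi, length)
            if start is not None:
                placed[chrom].append((start, start + length))
                return chrom, start
        raise CapacityError("could not place a feature after 2000 attempts")

    cluster_rows = []
    for spec in config.cluster_specs:
        for i in range(spec.count):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            chrom, start = place(length, "uniform")
            cluster_rows.append(
                {"chrom": chrom, "start": start, "end": start + length,
                 "cluster": f"{spec.prefix}_{i + 1}"}
            )
    te_rows = []
    for spec in config.te_family_specs:
        for _ in range(spec.n_instances):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            chrom, start = place(length, spec.placement)
            te_rows.append(
                {"chrom": chrom, "start": start, "end": start + length, "family": spec.name}
            )

    return FeatureSet(
        arms=arms,
        te_instances=pd.DataFrame(te_rows, columns=["chrom", "start", "end", "family"]),
        pirna_clusters=pd.DataFrame(cluster_rows, columns=["chrom", "start", "end", "cluster"]),
    )


# ---------------------------------------------------------------------------
# true M field


def true_m_at(
    annotation: FeatureSet, config: SimConfig, chrom: str, positions: np.ndarray, condition: str
) -> np.ndarray:
    """Vectorized noiseless true M at positions on one arm for a condition.

    Precedence (most specific wins): TE family > piRNA cluster >
    pericentric / chr4 background > euchromatin (0). The mutant shift of
    the governing feature is applied; a configured ``subtelomere`` shift
    (additive) is layered on top for positions inside the terminal
    windows.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    arm = annotation.arms[chrom]
    positions = np.asarray(positions)
    base = np.zeros(len(positions))
    shifted = np.zeros(len(positions))

    def paint(mask: np.ndarray, baseline: float, shift: Shift) -> None:
        base[mask] = baseline
        shifted[mask] = shift.apply(baseline)

    if arm.is_chr4:
        paint(np.ones(len(positions), dtype=bool), config.chr4_m,
              config.class_shift.get("chromosome4", NO_SHIFT))
    else:
        span = arm.pericentric_span()
        if span is not None:
            mask = (positions >= span[0]) & (positions < span[1])
            paint(mask, config.pericentric_m, config.class_shift.get("pericentric", NO_SHIFT))

    cluster_shifts = {}
    for spec in config.cluster_specs:
        for i in range(spec.count):
            cluster_shifts[f"{spec.prefix}_{i + 1}"] = (_cluster_shift(config, spec), spec.baseline_m)
    cl = annotation.pirna_clusters
    for _, row in cl[cl["chrom"] == chrom].iterrows():
        shift, baseline = cluster_shifts[str(row["cluster"])]
        mask = (positions >= row["start"]) & (positions < row["end"])
        paint(mask, baseline, shift)

    fam_specs = {s.name: s for s in config.te_family_specs}
    te = annotation.te_instances
    for _, row in te[te["chrom"] == chrom].iterrows():
        spec = fam_specs[str(row["family"])]
        mask = (positions >= row["start"]) & (positions < row["end"])
        paint(mask, spec.baseline_m, _family_shift(config, spec))

    out = base if condition == WILD_TYPE else shifted
    if condition == MUTANT and "subtelomere" in config.class_shift:
        sub = config.class_shift["subtelomere"]
        if sub.mode != "additive":
            raise ConfigError("subtelomere shift must be additive")
        lo, hi = subtelomeric_windows(annotation, config.subtelomere_window)[chrom]
        out = out.copy()
        out[(positions >= lo) & (positions < hi)] += sub.value
    return out


def simulate_probe_signal(
    annotation: FeatureSet, config: SimConfig, condition: str
) -> pd.DataFrame:
    """Probe table (chrom, pos, chip, input, unique) for one condition.

    Probes tile every ``probe_spacing`` bp. Input intensities are
    lognormal; ChIP = input x 2^(true M + N(0, probe_noise_sd)).
    Uniqueness flags are drawn once per probe position (independent of
    condition, as mappability is a property of the probe).
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng_sig = _rng(config.seed, _STREAM_SIGNAL[condition])
    rng_uni = _rng(config.seed, _STREAM_UNIQUE)
    frames = []
    for name in sorted(annotation.arms):
        arm = annotation.arms[name]
        pos = np.arange(0, arm.length, config.probe_spacing, dtype=int)
        m_true = true_m_at(annotation, config, name, pos, condition)
        inp = config.input_mean_intensity * np.exp(
            rng_sig.normal(0.0, config.input_lognormal_sd, len(pos))
        )
        noise = (
            rng_sig.normal(0.0, config.probe_noise_sd, len(pos))
            if config.probe_noise_sd > 0
            else np.zeros(len(pos))
        )
        chip = inp * np.exp2(m_true + noise)
        unique = rng_uni.random(len(pos)) >= config.nonunique_fraction
        frames.append(
            pd.DataFrame({"chrom": name, "pos": pos, "chip": chip, "input": inp, "unique": unique})
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# planted truth


@dataclass
class SimTruth:
    """Ground truth derivable from (config, annotation) alone.

    Class/family means come from the noiseless true-M field evaluated at
    the probe grid and aggregated exactly as the pipeline aggregates
    (500-bp bins, midpoint membership), so estimator recovery can be
    judged against the value the pipeline would see with zero noise.
    """

    class_means: dict[str, dict[str, float]]  # condition -> label -> mean M
    percent_decreases: dict[str, float]  # label -> 100 * (wt - mut) / wt
    delta_m: dict[str, float]  # label -> mut - wt
    qpcr_enrichment: dict[str, dict[str, float]]  # condition -> locus -> fold
    assay_fold_changes: dict[str, dict[str, float]]  # assay -> class -> fold vs control

    def to_dict(self) -> dict:
        return {
            "class_means": self.class_means,
            "percent_decreases": self.percent_decreases,
            "delta_m": self.delta_m,
            "qpcr_enrichment": self.qpcr_enrichment,
            "assay_fold_changes": self.assay_fold_changes,
        }


def compute_sim_truth(
    annotation: FeatureSet, config: SimConfig, bin_width: int = 500
) -> SimTruth:
    """Evaluate the noiseless true-M field through the binning/labeling path."""
    from .class_profiles import class_mean_profile, differential_profile
    from .genome_partition import assign_bins
    from .signal_enrichment import MTrack, bin_track

    profiles = {}
    for condition in CONDITIONS:
        frames = []
        for name in sorted(annotation.arms):
            arm = annotation.arms[name]
            pos = np.arange(0, arm.length, config.probe_spacing, dtype=int)
            m = true_m_at(annotation, config, name, pos, condition)
            frames.append(pd.DataFrame({"chrom": name, "pos": pos, "m": m, "unique": True}))
        track = MTrack(df=pd.concat(frames, ignore_index=True), normalized=True)
        bins = bin_track(track, bin_width=bin_width)
        membership = assign_bins(bins, annotation, config.subtelomere_window)
        profiles[condition] = class_mean_profile(bins, membership, condition)

    diff = differential_profile(profiles[WILD_TYPE], profiles[MUTANT])
    class_means = {
        cond: dict(zip(profiles[cond].table["label"], profiles[cond].table["mean_m"]))
        for cond in CONDITIONS
    }
    pct = {
        row["label"]: row["percent_decrease"]
        for _, row in diff.table.iterrows()
        if not np.isnan(row["percent_decrease"])
    }
    delta = dict(zip(diff.table["label"], diff.table["delta_m"]))

    qpcr = {
        cond: {locus: float(t.fold_enrichment[cond]) for locus, t in config.qpcr_truth.items()}
        for cond in CONDITIONS
    }
    assay = {}
    for assay_name, classes in config.assay_truth.items():
        ctrl = classes[config.assay_control_class].mean
        assay[assay_name] = {cls: t.mean / ctrl for cls, t in classes.items()}
    return SimTruth(
        class_means=class_means,
        percent_decreases=pct,
        delta_m=delta,
        qpcr_enrichment=qpcr,
        assay_fold_changes=assay,
    )


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr_plate(
    config: SimConfig, condition: str = WILD_TYPE, seed: int | None = None
) -> pd.DataFrame:
    """One ChIP-qPCR plate: input dilution series plus IP wells per locus.

    Columns: locus, role (input_dilution | ip), dilution_fraction (input
    wells only), ct, replicate, sample. Input-well Ct follows
    ``ct(f) = ct_full + slope * log10(f)`` with slope = -1/log10(1 + E);
    IP-well Ct is the curve evaluated at the locus's true pulldown
    efficacy (base efficacy x fold enrichment). Gaussian Ct noise is
    added per well.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")
    if config.qpcr_control_locus not in config.qpcr_truth:
        raise ConfigError(
            f"control locus {config.qpcr_control_locus!r} missing from qpcr_truth"
        )
    if len(config.qpcr_input_dilutions) < 3:
        raise ConfigError("need at least 3 input dilutions for a standard curve")
    base_seed = config.seed if seed is None else seed
    rng = _rng(base_seed, _STREAM_QPCR[condition])
    rows = []
    for locus in sorted(config.qpcr_truth):
        truth = config.qpcr_truth[locus]
        b = 1.0 + truth.efficiency
        if not (1.0 < b <= 2.5):
            raise ConfigError(f"locus {locus!r}: amplification base {b} outside (1, 2.5]")
        slope = -1.0 / np.log10(b)
        fold = float(truth.fold_enrichment[condition])
        efficacy = config.qpcr_base_efficacy * fold
        for f in config.qpcr_input_dilutions:
            for rep in range(1, config.qpcr_n_input_replicates + 1):
                ct = config.qpcr_input_ct_at_full + slope * np.log10(f)
                if truth.ct_noise_sd > 0:
                    ct += rng.normal(0.0, truth.ct_noise_sd)
                rows.append(
                    {"locus": locus, "role": "input_dilution", "dilution_fraction": f,
                     "ct": float(ct), "replicate": rep, "sample": condition}
                )
        for rep in range(1, config.qpcr_n_ip_replicates + 1):
            ct = config.qpcr_input_ct_at_full + slope * np.log10(efficacy)
            if truth.ct_noise_sd > 0:
                ct += rng.normal(0.0, truth.ct_noise_sd)
            rows.append(
                {"locus": locus, "role": "ip", "dilution_fraction": np.nan,
                 "ct": float(ct), "replicate": rep, "sample": condition}
            )
    return pd.DataFrame(rows)


def simulate_expression_table(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """RT-qPCR Ct table (sample, locus, ct, replicate) with planted folds.

    The target transcript's Ct is displaced by -log2(fold) relative to
    the reference sample at a fixed control-locus Ct, so ideal-doubling
    ddCt analysis recovers ``expression_truth`` exactly at zero noise.
    """
    base_seed = config.seed if seed is None else seed
    rng = _rng(base_seed, _STREAM_EXPRESSION)
    if config.expression_reference not in config.expression_truth:
        raise ConfigError("expression_truth must include the reference sample")
    rows = []
    control_ct = 16.0
    base_dct = 5.0  # target minus control Ct in the reference sample
    for sample in sorted(config.expression_truth):
        fold = config.expression_truth[sample]
        for rep in range(1, config.expression_n_replicates + 1):
            noise = (
                rng.normal(0.0, config.expression_ct_noise_sd, 2)
                if config.expression_ct_noise_sd > 0
                else np.zeros(2)
            )
            rows.append(
                {"sample": sample, "locus": config.expression_control_locus,
                 "ct": control_ct + noise[0], "replicate": rep}
            )
            rows.append(
                {"sample": sample, "locus": config.expression_target_locus,
                 "ct": control_ct + base_dct - np.log2(fold) + noise[1], "replicate": rep}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PEV reporter assays


@dataclass
class ReporterTables:
    """Long-format replicate tables for the two PEV readouts."""

    beta_gal: pd.DataFrame  # genotype_class, replicate, time_min, od574
    pigment: pd.DataFrame  # genotype_class, replicate, od480, flies_per_sample


def simulate_reporter_tables(config: SimConfig, seed: int | None = None) -> ReporterTables:
    """Replicate beta-gal time series and pigment endpoints per genotype.

    Each beta-gal replicate is an exact line od574(t) = od0 + a*t whose
    slope ``a`` is the class's true activity times lognormal noise;
    variability lives between replicates, as in extract-level assays.
    Pigment endpoints are the class mean times lognormal noise.
    """
    for assay_name, classes in config.assay_truth.items():
        if len(classes) < 2 or config.assay_control_class not in classes:
            raise ConfigError(f"{assay_name}: need >=2 genotype classes incl. the control")
        for cls, truth in classes.items():
            if truth.n_replicates < 2:
                raise ConfigError(f"{assay_name}/{cls}: n_replicates < 2 leaves SEM undefined")
    base_seed = config.seed if seed is None else seed
    rng = _rng(base_seed, _STREAM_ASSAY)
    times = np.asarray(config.beta_gal_times, dtype=float)

    bg_rows = []
    for cls in sorted(config.assay_truth["beta_gal"]):
        truth = config.assay_truth["beta_gal"][cls]
        for rep in range(1, truth.n_replicates + 1):
            noise = np.exp(rng.normal(0.0, truth.lognormal_sd)) if truth.lognormal_sd > 0 else 1.0
            slope = truth.mean * noise
            for t in times:
                bg_rows.append(
                    {"genotype_class": cls, "replicate": rep, "time_min": float(t),
                     "od574": config.beta_gal_od0 + slope * float(t)}
                )
    pg_rows = []
    for cls in sorted(config.assay_truth["pigment"]):
        truth = config.assay_truth["pigment"][cls]
        for rep in range(1, truth.n_replicates + 1):
            noise = np.exp(rng.normal(0.0, truth.lognormal_sd)) if truth.lognormal_sd > 0 else 1.0
            pg_rows.append(
                {"genotype_class": cls, "replicate": rep, "od480": truth.mean * noise,
                 "flies_per_sample": config.flies_per_sample}
            )
    return ReporterTables(beta_gal=pd.DataFrame(bg_rows), pigment=pd.DataFrame(pg_rows))


def null_config(**overrides) -> SimConfig:
    """A zero-baseline, zero-shift, zero-noise configuration.

    Useful as the end-to-end null: every probe has ChIP = input (M = 0)
    and every downstream fold change is exactly 1.
    """
    cfg = SimConfig(
        te_family_specs=tuple(
            replace(s, baseline_m=0.0, shift=NO_SHIFT) for s in _default_te_families()
        ),
        cluster_specs=tuple(
            replace(s, baseline_m=0.0, shift=NO_SHIFT) for s in _default_clusters()
        ),
        class_shift={},
        pericentric_m=0.0,
        chr4_m=0.0,
        probe_noise_sd=0.0,
        input_lognormal_sd=0.0,
        qpcr_truth={
            "alpha_actinin": QpcrLocusTruth({WILD_TYPE: 1.0, MUTANT: 1.0}, 1.0, 0.0),
            "hsp70_reporter": QpcrLocusTruth({WILD_TYPE: 1.0, MUTANT: 1.0}, 1.0, 0.0),
        },
        expression_truth={"control": 1.0, "piwi_kd": 1.0},
        expression_ct_noise_sd=0.0,
        assay_truth={
            "beta_gal": {cls: AssayClassTruth(1e-3, 0.0, 4) for cls in ("C", "M", "Z", "M+Z")},
            "pigment": {cls: AssayClassTruth(0.1, 0.0, 4) for cls in ("C", "M", "Z", "M+Z")},
        },
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg
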