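"""Wet-lab assay computations: ChIP-qPCR, ddCt expression, PEV readouts.

ChIP-qPCR enrichment follows the input-dilution standard-curve route:
for each locus, Ct is regressed on log10(dilution fraction); inverting
the fitted line at an IP well's Ct yields the pulldown efficacy (the
input-fraction equivalent of the immunoprecipitate), and relative
enrichment is the target locus's mean efficacy over the control locus's
(alpha-actinin by convention). The curve slope also yields the
amplification base b = 10^(-1/slope) and efficiency E = b - 1.

Relative expression uses the classic ddCt method with ideal doubling:
dCt = Ct_target - Ct_control per sample, ddCt vs a reference sample,
fold = 2^(-ddCt). An efficiency-corrected variant using a fitted base
is available but not the default.

Position-effect-variegation readouts: beta-galactosidase activity is
the least-squares slope of OD574 against time over a CPRG reaction
series; eye pigment is an OD480 endpoint summarized per genotype class.
Fold changes between genotype classes (C, M, Z, M+Z or WT, KD) are
ratios of class means with SEM propagated by the first-order delta
method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, FailedCurveError


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares fit of Ct vs log10(input dilution fraction)."""

    locus: str
    slope: float  # Ct per log10 dilution; negative for a working assay
    intercept: float  # Ct at dilution fraction 1
    r_squared: float
    ct_range: tuple[float, float]  # Ct span of the fitted dilution wells
    slope_stderr: float = 0.0
    intercept_stderr: float = 0.0
    x_mean: float = 0.0  # mean log10 dilution of the fitted wells

    @property
    def base(self) -> float:
        """Amplification base b = 10^(-1/slope) (2.0 at perfect efficiency)."""
        return 10.0 ** (-1.0 / self.slope)

    @property
    def efficiency(self) -> float:
        """Efficiency E = b - 1, as a fraction."""
        return self.base - 1.0

    def ct_at(self, fraction: float) -> float:
        return self.intercept + self.slope * math.log10(fraction)

    def efficacy_at(self, ct: float) -> float:
        """Invert the curve: the input fraction equivalent to a Ct."""
        return 10.0 ** ((ct - self.intercept) / self.slope)

    def log10_efficacy_var(self, ct: float) -> float:
        """First-order variance of log10(efficacy) from curve-fit noise.

        Uses the OLS parameter variances and the slope-intercept
        covariance cov(a, b) = -x_mean * var(b). This error is shared by
        every IP well inverted through the same curve, so it must be
        propagated separately from replicate scatter.
        """
        u = (ct - self.intercept) / self.slope
        var_b = self.slope_stderr**2
        var_a = self.intercept_stderr**2
        cov_ab = -self.x_mean * var_b
        return (var_a + u**2 * var_b + 2 * u * cov_ab) / self.slope**2


@dataclass
class EnrichmentResult:
    locus: str
    pulldown_efficacy: float  # mean over IP replicates
    efficacy_sem: float
    relative_enrichment: float  # target efficacy / control efficacy
    enrichment_sem: float
    n_replicates: int
    out_of_range: bool = False  # some IP Ct outside the calibrated dilution span


@dataclass
class ExpressionResult:
    target_locus: str
    control_locus: str
    reference_sample: str
    table: pd.DataFrame  # sample, delta_ct, ddct, fold_change, fold_sem, n

    def fold(self, sample: str) -> float:
        rows = self.table[self.table["sample"] == sample]
        if rows.empty:
            raise KeyError(sample)
        return float(rows["fold_change"].iloc[0])


@dataclass
class ActivityResult:
    activity: float  # delta OD574 per minute
    clamped: bool  # negative fitted slope clamped to 0
    n_points: int


@dataclass
class GenotypeSummary:
    control_class: str
    table: pd.DataFrame  # genotype_class, mean, sem, n, fold_change, fold_sem

    def fold(self, genotype_class: str) -> float:
        rows = self.table[self.table["genotype_class"] == genotype_class]
        if rows.empty:
            raise KeyError(genotype_class)
        return float(rows["fold_change"].iloc[0])


def fit_input_standard_curve(wells: pd.DataFrame, locus: str | None = None) -> StandardCurve:
    """Fit Ct ~ log10(dilution_fraction) over a locus's input wells.

    ``wells`` needs columns dilution_fraction and ct (rows with role
    other than ``input_dilution`` are ignored if a role column exists).
    Requires >= 3 distinct dilution fractions; a non-negative slope
    signals a failed curve.
    """
    df = wells
    if "role" in df.columns:
        df = df[df["role"] == "input_dilution"]
    if "locus" in df.columns:
        loci = df["locus"].unique()
        if locus is None:
            if len(loci) != 1:
                raise DataError(f"wells span several loci {sorted(loci)}; pass locus=")
            locus = str(loci[0])
        else:
            df = df[df["locus"] == locus]
    if locus is None:
        locus = "?"
    frac = df["dilution_fraction"].to_numpy(dtype=float)
    ct = df["ct"].to_numpy(dtype=float)
    if len(np.unique(frac)) < 3:
        raise DataError(f"locus {locus!r}: need >=3 distinct dilution fractions")
    if np.any(frac <= 0) or np.any(frac > 1):
        raise DataError(f"locus {locus!r}: dilution fractions must lie in (0, 1]")
    x = np.log10(frac)
    fit = stats.linregress(x, ct)
    if fit.slope >= 0:
        raise FailedCurveError(f"locus {locus!r}: non-negative slope {fit.slope:.3f}")
    return StandardCurve(
        locus=locus,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        ct_range=(float(ct.min()), float(ct.max())),
        slope_stderr=float(fit.stderr) if np.isfinite(fit.stderr) else 0.0,
        intercept_stderr=float(fit.intercept_stderr) if np.isfinite(fit.intercept_stderr) else 0.0,
        x_mean=float(x.mean()),
    )


def _ip_efficacies(ip_wells: pd.DataFrame, curve: StandardCurve) -> tuple[np.ndarray, bool]:
    df = ip_wells
    if "role" in df.columns:
        df = df[df["role"] == "ip"]
    if "locus" in df.columns and curve.locus != "?":
        df = df[df["locus"] == curve.locus]
    if df.empty:
        raise DataError(f"locus {curve.locus!r}: no IP wells")
    ct = df["ct"].to_numpy(dtype=float)
    lo, hi = curve.ct_range
    out_of_range = bool(np.any((ct < lo) | (ct > hi)))
    return np.array([curve.efficacy_at(c) for c in ct]), out_of_range


def chip_qpcr_enrichment(
    ip_wells: pd.DataFrame,
    curve_target: StandardCurve,
    curve_control: StandardCurve,
    control_ip_wells: pd.DataFrame,
) -> EnrichmentResult:
    """Relative enrichment: target pulldown efficacy over control's.

    Efficacies are averaged on the linear scale across IP replicates;
    SEM of the ratio comes from first-order propagation. IP Cts outside
    the Ct span of the fitted dilution wells set ``out_of_range``.
    """
    eff_t, oor_t = _ip_efficacies(ip_wells, curve_target)
    eff_c, oor_c = _ip_efficacies(control_ip_wells, curve_control)
    mean_t, mean_c = float(eff_t.mean()), float(eff_c.mean())
    sem_t = float(eff_t.std(ddof=1) / math.sqrt(len(eff_t))) if len(eff_t) > 1 else 0.0
    sem_c = float(eff_c.std(ddof=1) / math.sqrt(len(eff_c))) if len(eff_c) > 1 else 0.0
    if mean_c <= 0:
        raise DataError("control locus mean efficacy is non-positive")
    # curve-fit uncertainty is shared by every IP well inverted through the
    # same curve, so it adds to the replicate SEM rather than averaging out
    ln10 = math.log(10.0)
    curve_sd_t = mean_t * ln10 * math.sqrt(
        max(curve_target.log10_efficacy_var(curve_target.intercept
                                            + curve_target.slope * math.log10(mean_t)), 0.0)
    ) if mean_t > 0 else 0.0
    curve_sd_c = mean_c * ln10 * math.sqrt(
        max(curve_control.log10_efficacy_var(curve_control.intercept
                                             + curve_control.slope * math.log10(mean_c)), 0.0)
    )
    sem_t = math.sqrt(sem_t**2 + curve_sd_t**2)
    sem_c = math.sqrt(sem_c**2 + curve_sd_c**2)
    ratio = mean_t / mean_c
    ratio_sem = ratio * math.sqrt(
        (sem_t / mean_t) ** 2 + (sem_c / mean_c) ** 2
    ) if mean_t > 0 else float("nan")
    return EnrichmentResult(
        locus=curve_target.locus,
        pulldown_efficacy=mean_t,
        efficacy_sem=sem_t,
        relative_enrichment=ratio,
        enrichment_sem=ratio_sem,
        n_replicates=len(eff_t),
        out_of_range=oor_t or oor_c,
    )


def ddct_expression(
    wells: pd.DataFrame,
    target_locus: str,
    control_locus: str,
    reference_sample: str,
    base: float = 2.0,
) -> ExpressionResult:
    """Relative expression by the ddCt method.

    ``wells`` columns: sample, locus, ct, replicate. Per sample, dCt is
    the mean target Ct minus the mean control Ct; ddCt subtracts the
    reference sample's dCt; fold = base^(-ddCt) (base 2 = ideal
    doubling; pass a fitted amplification base for the
    efficiency-corrected variant). The reference sample's fold is 1 by
    construction. Fold SEM combines replicate dCt spread of sample and
    reference by the delta method.
    """
    samples = sorted(wells["sample"].unique())
    if reference_sample not in samples:
        raise DataError(f"reference sample {reference_sample!r} absent from table")
    per_sample: dict[str, tuple[float, float, int]] = {}
    for sample in samples:
        sub = wells[wells["sample"] == sample]
        tgt = sub[sub["locus"] == target_locus]["ct"].to_numpy(dtype=float)
        ctl = sub[sub["locus"] == control_locus]["ct"].to_numpy(dtype=float)
        if len(tgt) == 0 or len(ctl) == 0:
            raise DataError(f"sample {sample!r}: missing {target_locus!r} or {control_locus!r} wells")
        dct = float(tgt.mean() - ctl.mean())
        var = 0.0
        if len(tgt) > 1:
            var += float(tgt.var(ddof=1)) / len(tgt)
        if len(ctl) > 1:
            var += float(ctl.var(ddof=1)) / len(ctl)
        per_sample[sample] = (dct, math.sqrt(var), min(len(tgt), len(ctl)))
    ref_dct, ref_sem, _ = per_sample[reference_sample]
    log_base = math.log(base)
    rows = []
    for sample in samples:
        dct, sem, n = per_sample[sample]
        ddct = dct - ref_dct
        if sample == reference_sample:
            fold, fold_sem = 1.0, 0.0
        else:
            fold = base ** (-ddct)
            fold_sem = fold * log_base * math.sqrt(sem**2 + ref_sem**2)
        rows.append(
            {"sample": sample, "delta_ct": dct, "ddct": ddct,
             "fold_change": fold, "fold_sem": fold_sem, "n": n}
        )
    return ExpressionResult(
        target_locus=target_locus,
        control_locus=control_locus,
        reference_sample=reference_sample,
        table=pd.DataFrame(rows),
    )


def beta_gal_activity(
    series: pd.DataFrame, od_ceiling: float | None = None
) -> ActivityResult:
    """Activity = least-squares slope of OD574 against time (OD/min).

    ``series`` columns: time_min, od574 (>= 3 points). ``od_ceiling``
    optionally drops saturated readings above a ceiling before the fit
    (linear-range restriction). Negative fitted slopes are clamped to 0
    and flagged.
    """
    df = series
    if od_ceiling is not None:
        df = df[df["od574"] <= od_ceiling]
    t = df["time_min"].to_numpy(dtype=float)
    od = df["od574"].to_numpy(dtype=float)
    if len(t) < 3:
        raise DataError("beta-gal series needs >= 3 (retained) time points")
    if np.allclose(t, t[0]):
        raise DataError("degenerate time vector: all time points equal")
    slope = float(np.polyfit(t, od, 1)[0])
    clamped = slope < 0
    return ActivityResult(activity=max(slope, 0.0), clamped=clamped, n_points=len(t))


def pigment_summary(samples: pd.DataFrame, per_fly: bool = False) -> pd.DataFrame:
    """Per-genotype-class mean and SEM of OD480 endpoints.

    ``samples`` columns: genotype_class, od480 (+ flies_per_sample if
    ``per_fly``). Every class needs >= 2 replicates.
    """
    df = samples.copy()
    value = df["od480"].astype(float)
    if per_fly:
        value = value / df["flies_per_sample"].astype(float)
    df["_value"] = value
    rows = []
    for cls, sub in df.groupby("genotype_class", sort=True):
        vals = sub["_value"].to_numpy()
        if len(vals) < 2:
            raise DataError(f"genotype class {cls!r} has fewer than 2 replicates")
        rows.append(
            {"genotype_class": cls, "mean": float(vals.mean()),
             "sem": float(vals.std(ddof=1) / math.sqrt(len(vals))), "n": len(vals)}
        )
    return pd.DataFrame(rows)


def beta_gal_summary(table: pd.DataFrame, od_ceiling: float | None = None) -> pd.DataFrame:
    """Replicate activities per genotype class, summarized as mean/SEM.

    ``table`` columns: genotype_class, replicate, time_min, od574.
    """
    rows = []
    for (cls, _rep), sub in table.groupby(["genotype_class", "replicate"], sort=True):
        res = beta_gal_activity(sub, od_ceiling=od_ceiling)
        rows.append({"genotype_class": cls, "activity": res.activity})
    acts = pd.DataFrame(rows)
    out = []
    for cls, sub in acts.groupby("genotype_class", sort=True):
        vals = sub["activity"].to_numpy()
        if len(vals) < 2:
            raise DataError(f"genotype class {cls!r} has fewer than 2 replicates")
        out.append(
            {"genotype_class": cls, "mean": float(vals.mean()),
             "sem": float(vals.std(ddof=1) / math.sqrt(len(vals))), "n": len(vals)}
        )
    return pd.DataFrame(out)


def genotype_fold_changes(summary: pd.DataFrame, control_class: str) -> GenotypeSummary:
    """Fold change of each genotype class's mean over the control class.

    ``summary`` columns: genotype_class, mean, sem, n (as produced by
    :func:`pigment_summary` / :func:`beta_gal_summary`). SEM of the
    ratio uses the first-order delta method; the control class's fold
    is exactly 1 with SEM 0.
    """
    classes = list(summary["genotype_class"])
    if control_class not in classes:
        raise DataError(f"control class {control_class!r} absent")
    ctrl = summary[summary["genotype_class"] == control_class].iloc[0]
    if ctrl["mean"] == 0:
        raise DataError("control class mean is 0; fold changes undefined")
    rows = []
    for _, row in summary.iterrows():
        if row["genotype_class"] == control_class:
            fold, fold_sem = 1.0, 0.0
        else:
            fold = float(row["mean"]) / float(ctrl["mean"])
            fold_sem = abs(fold) * math.sqrt(
                (float(row["sem"]) / float(row["mean"])) ** 2
                + (float(ctrl["sem"]) / float(ctrl["mean"])) ** 2
            ) if row["mean"] != 0 else float("nan")
        rows.append(
            {"genotype_class": row["genotype_class"], "mean": float(row["mean"]),
             "sem": float(row["sem"]), "n": int(row["n"]),
             "fold_change": fold, "fold_sem": fold_sem}
        )
    return GenotypeSummary(control_class=control_class, table=pd.DataFrame(rows))
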