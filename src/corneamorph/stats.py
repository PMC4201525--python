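"""Diagnostic statistics over per-eye morphometric records.

The battery mirrors standard clinical-study practice for a two-group
(healthy vs keratoconus) cross-sectional design:

* per-variable normality screening (Kolmogorov-Smirnov with the
  Lilliefors correction, since location and scale are estimated);
* two-group comparison by Student's t when both groups screen normal,
  otherwise Mann-Whitney U (exact for small tie-free samples, tie-
  corrected normal approximation otherwise);
* severity-staged comparison by Kruskal-Wallis with Dunn's pairwise
  post-hoc z tests under Bonferroni correction, plus a pooled-SD effect
  size (normal mean minus stage mean over pooled SD) per stage;
* per-variable ROC analysis: Mann-Whitney (trapezoidal) AUC,
  Hanley-McNeil standard error, normal-approximation CI and p against
  the chance line, Youden-optimal cut-off with its sensitivity and
  specificity, and the accuracy ratio 2*AUC - 1 (Gini rescaling).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.diagnostic import lilliefors

STAGE_ORDER = ("normal", "I", "II", "III-IV")
ALPHA = 0.05


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

@dataclass
class NormalityResult:
    statistic: float
    p: float
    normal: bool


def normality_test(values) -> NormalityResult:
    """Lilliefors-corrected Kolmogorov-Smirnov test for normality.

    Verdict "normal" iff p > 0.05.  Requires n >= 4 and a non-constant
    sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise StatsError(f"normality test requires n >= 4, got {x.size}")
    if np.ptp(x) == 0:
        raise StatsError("normality test undefined for a constant sample")
    stat, p = lilliefors(x, dist="norm")
    return NormalityResult(float(stat), float(p), bool(p > ALPHA))


# ---------------------------------------------------------------------------
# two-group comparison
# ---------------------------------------------------------------------------

def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    m = float(x.mean())
    if x.size < 2 or x.std(ddof=1) == 0:
        return m, m, m
    half = sps.t.ppf(0.5 + level / 2, x.size - 1) * x.std(ddof=1) / math.sqrt(x.size)
    return m, m - half, m + half


def _mw_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal-approximation z for the Mann-Whitney U statistic."""
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = n1 + n2
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0
    return float((u - n1 * n2 / 2.0) / math.sqrt(var))


@dataclass
class GroupComparison:
    variable: str
    test: str                       # "t-test" or "Mann-Whitney"
    statistic: float
    z: float | None
    p: float
    mean_a: float
    ci_a: tuple[float, float]
    mean_b: float
    ci_b: tuple[float, float]
    normal_a: bool
    normal_b: bool


def compare_groups(values, labels, variable: str = "") -> GroupComparison:
    """Two-sided healthy-vs-diseased comparison, test chosen by normality.

    Student's t (equal-variance, as is conventional for this design) is
    used when both groups pass the Lilliefors screen; otherwise
    Mann-Whitney U, exact when both groups have n <= 10 and no ties.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise StatsError(f"expected exactly two groups, got {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if min(len(a), len(b)) < 2:
        raise StatsError("each group needs n >= 2")

    def screens_normal(x: np.ndarray) -> bool:
        if x.size < 4 or np.ptp(x) == 0:
            return False
        return normality_test(x).normal

    norm_a, norm_b = screens_normal(a), screens_normal(b)
    if norm_a and norm_b:
        stat, p = sps.ttest_ind(a, b)
        test, z = "t-test", None
    else:
        test = "Mann-Whitney"
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
        z = _mw_z(a, b)
    ma, loa, hia = _mean_ci(a)
    mb, lob, hib = _mean_ci(b)
    return GroupComparison(
        variable=variable, test=test, statistic=float(stat), z=z, p=float(p),
        mean_a=ma, ci_a=(loa, hia), mean_b=mb, ci_b=(lob, hib),
        normal_a=norm_a, normal_b=norm_b,
    )


# ---------------------------------------------------------------------------
# staged comparison
# ---------------------------------------------------------------------------

def pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled standard deviation of two samples."""
    n1, n2 = len(x), len(y)
    return math.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )


def effect_size(reference: np.ndarray, stage: np.ndarray) -> float:
    """Pooled-SD effect size (reference mean - stage mean) / pooled SD.

    Positive when the reference (normal) group exceeds the stage group.
    """
    return float((reference.mean() - stage.mean()) / pooled_sd(reference, stage))


@dataclass
class StagedComparison:
    variable: str
    stages: list[str]
    n_per_stage: dict[str, int]
    kw_h: float
    kw_p: float
    dunn_z: dict[tuple[str, str], float]
    dunn_p_adjusted: dict[tuple[str, str], float]
    effect_sizes: dict[str, float]              # each stage vs normal
    stage_means: dict[str, float]
    stage_ci: dict[str, tuple[float, float]]
    stage_range: dict[str, tuple[float, float]]


def staged_comparison(values, stages, variable: str = "") -> StagedComparison:
    """Kruskal-Wallis across severity strata with Dunn/Bonferroni post hoc."""
    values = np.asarray(values, dtype=float)
    stages = np.asarray(stages)
    present = []
    for s in STAGE_ORDER:
        n = int((stages == s).sum())
        if n == 0:
            warnings.warn(f"stage {s!r} has no observations and is dropped")
        else:
            present.append(s)
    for s in np.unique(stages):
        if s not in STAGE_ORDER:
            raise StatsError(f"unknown stage label {s!r}")
    if len(present) < 2:
        raise StatsError("staged comparison needs at least two non-empty stages")

    samples = {s: values[stages == s] for s in present}
    kw_h, kw_p = sps.kruskal(*samples.values())

    # Dunn's z on the joint ranking, tie-corrected
    joint = np.concatenate([samples[s] for s in present])
    ranks = sps.rankdata(joint)
    n_total = len(joint)
    mean_rank, sizes, start = {}, {}, 0
    for s in present:
        k = len(samples[s])
        mean_rank[s] = float(ranks[start:start + k].mean())
        sizes[s] = k
        start += k
    _, counts = np.unique(joint, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
    dunn_z, dunn_p = {}, {}
    for a, b in pairs:
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        dunn_z[(a, b)] = float(z)
        dunn_p[(a, b)] = float(min(1.0, p_raw * len(pairs)))

    es = {}
    if "normal" in present:
        for s in present:
            if s != "normal":
                es[s] = effect_size(samples["normal"], samples[s])

    means, cis, ranges = {}, {}, {}
    for s in present:
        m, lo, hi = _mean_ci(samples[s])
        means[s] = m
        cis[s] = (lo, hi)
        ranges[s] = (float(samples[s].min()), float(samples[s].max()))
    return StagedComparison(
        variable=variable, stages=present, n_per_stage=sizes,
        kw_h=float(kw_h), kw_p=float(kw_p),
        dunn_z=dunn_z, dunn_p_adjusted=dunn_p,
        effect_sizes=es, stage_means=means, stage_ci=cis, stage_range=ranges,
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def accuracy_ratio(auc: float) -> float:
    """Gini rescaling of an ROC area: 2 * AUC - 1."""
    return 2.0 * auc - 1.0


def auc_mann_whitney(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U (ties count half)."""
    pos = values[labels == 1]
    neg = values[labels == 0]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of the AUC (Hanley & McNeil exponential approximation)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


@dataclass
class RocResult:
    variable: str
    direction: str                  # "larger" or "smaller" is diseased
    auc: float
    se: float
    ci: tuple[float, float]
    p: float
    accuracy_ratio: float
    cutoff: float
    sensitivity: float
    specificity: float


def roc_analysis(values, labels, direction: str = "auto", variable: str = "") -> RocResult:
    """Single-variable ROC diagnostics.

    ``direction`` "larger" treats larger values as diseased (AUC may fall
    below 0.5, reported as-is, with a negative accuracy ratio);
    "smaller" treats smaller values as diseased; "auto" picks the
    orientation with AUC >= 0.5.  The cut-off maximizes Youden's J; with
    direction "larger" the rule is "positive if value >= cutoff",
    mirrored for "smaller".
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise StatsError("labels must contain both classes 0 and 1")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())

    auc_raw = auc_mann_whitney(values, labels)
    if direction == "auto":
        direction = "larger" if auc_raw >= 0.5 else "smaller"
    if direction not in ("larger", "smaller"):
        raise ValueError(f"unknown direction {direction!r}")
    auc = auc_raw if direction == "larger" else 1.0 - auc_raw

    se = hanley_mcneil_se(auc, n_pos, n_neg)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    if se > 0:
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0

    scores = values if direction == "larger" else -values
    fpr, tpr, thresh = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    k = int(np.argmax(j))
    cutoff = float(thresh[k]) if direction == "larger" else float(-thresh[k])
    return RocResult(
        variable=variable, direction=direction,
        auc=float(auc), se=float(se), ci=ci, p=p,
        accuracy_ratio=accuracy_ratio(auc),
        cutoff=cutoff,
        sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]),
    )


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

def cohort_report(records: pd.DataFrame, labels, stages=None) -> dict:
    """Run the full battery over a cohort table of morphometric variables.

    ``records`` holds one row per eye, one column per variable; ``labels``
    are 0/1 (healthy/keratoconus); ``stages`` the severity strata
    ("normal" for healthy eyes).  Returns per-variable comparison, staged
    and ROC tables (as DataFrames under keys "group", "staged", "roc").
    """
    labels = np.asarray(labels).astype(int)
    out_group, out_staged, out_roc = [], [], []
    for var in records.columns:
        v = records[var].to_numpy(dtype=float)
        gc = compare_groups(v, labels, variable=var)
        out_group.append({
            "variable": var, "test": gc.test, "p": gc.p,
            "mean_normal": gc.mean_a, "ci_normal_lo": gc.ci_a[0], "ci_normal_hi": gc.ci_a[1],
            "mean_kc": gc.mean_b, "ci_kc_lo": gc.ci_b[0], "ci_kc_hi": gc.ci_b[1],
            "z": gc.z if gc.z is not None else np.nan,
        })
        roc = roc_analysis(v, labels, direction="larger", variable=var)
        out_roc.append({
            "variable": var, "auc": roc.auc, "accuracy_ratio": roc.accuracy_ratio,
            "se": roc.se, "ci_lo": roc.ci[0], "ci_hi": roc.ci[1], "p": roc.p,
            "cutoff": roc.cutoff, "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        })
        if stages is not None:
            sc = staged_comparison(v, np.asarray(stages), variable=var)
            row = {"variable": var, "kw_h": sc.kw_h, "kw_p": sc.kw_p}
            for s in sc.stages:
                row[f"mean_{s}"] = sc.stage_means[s]
                row[f"range_{s}"] = sc.stage_range[s]
            for s, e in sc.effect_sizes.items():
                row[f"es_{s}"] = e
            out_staged.append(row)
    report = {
        "group": pd.DataFrame(out_group),
        "roc": pd.DataFrame(out_roc),
    }
    if stages is not None:
        report["staged"] = pd.DataFrame(out_staged)
    return report
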