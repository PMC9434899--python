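"""Group-level statistics: three-group comparison with rank-based post-hoc,
Pearson correlations, and ROC analysis of the VOSS index.

The three-group comparison follows the common clinical-neuroimaging recipe:
one-way ANOVA when every group passes a Shapiro-Wilk normality pre-test,
otherwise Kruskal-Wallis; pairwise post-hoc by Dunn's rank test with Holm
adjustment (default) or Tukey's HSD on rank-transformed data.  ROC analysis
treats INPH as the positive class with higher scores positive; the empirical
AUC is computed trapezoidally and cross-checked on every call against the
tie-corrected Mann-Whitney U identity AUC = U / (n1 n2).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "RocResult",
    "StatsError",
    "kruskal_wallis",
    "pearson_r",
    "roc_analysis",
    "cohort_analysis",
]


class StatsError(RuntimeError):
    pass


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    test: str
    pairwise: dict[str, float]  # adjusted p-values keyed "name1-name2"


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float


def _dunn_posthoc(samples: list[np.ndarray], names: list[str]) -> dict[str, float]:
    """Dunn's rank-based pairwise test with Holm adjustment."""
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start:start + s.size].mean())
        start += s.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    raw = []
    keys = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        se = np.sqrt(base_var * (1.0 / samples[i].size + 1.0 / samples[j].size))
        if se == 0:
            raise StatsError("degenerate post-hoc: zero rank variance (all values tied)")
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw.append(2.0 * sps.norm.sf(abs(z)))
        keys.append(f"{names[i]}-{names[j]}")
    adjusted = multipletests(raw, method="holm")[1]
    return dict(zip(keys, adjusted))


def _tukey_on_ranks(samples: list[np.ndarray], names: list[str]) -> dict[str, float]:
    """Tukey HSD applied to rank-transformed pooled data."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    labels = np.concatenate([[names[i]] * s.size for i, s in enumerate(samples)])
    res = pairwise_tukeyhsd(ranks, labels)
    out = {}
    for row, p in zip(res._results_table.data[1:], res.pvalues):
        out[f"{row[0]}-{row[1]}"] = float(p)
    # statsmodels orders pairs alphabetically; re-key in the input group order
    keyed = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        a, b = names[i], names[j]
        keyed[f"{a}-{b}"] = out.get(f"{a}-{b}", out.get(f"{b}-{a}"))
    return keyed


def kruskal_wallis(
    samples: list,
    names: list[str] | None = None,
    posthoc: str = "dunn",
) -> GroupComparison:
    """Kruskal-Wallis H test with tie correction and pairwise post-hoc.

    H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, tie-corrected; the
    p-value is chi-square with k-1 degrees of freedom.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(s.size < 1 for s in samples):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    if sum(s.size for s in samples) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        raise StatsError("degenerate input: all values identical")
    h, p = sps.kruskal(*samples)
    if names is None:
        names = [f"group{i}" for i in range(len(samples))]
    if posthoc == "dunn":
        pairwise = _dunn_posthoc(samples, names)
    elif posthoc == "tukey_ranks":
        pairwise = _tukey_on_ranks(samples, names)
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return GroupComparison(statistic=float(h), p_value=float(p), test="kruskal", pairwise=pairwise)


def anova_oneway(samples: list, names: list[str] | None = None) -> GroupComparison:
    """One-way ANOVA with Tukey HSD post-hoc (the normal-data branch)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    samples = [np.asarray(s, dtype=float) for s in samples]
    f, p = sps.f_oneway(*samples)
    if names is None:
        names = [f"group{i}" for i in range(len(samples))]
    pooled = np.concatenate(samples)
    labels = np.concatenate([[names[i]] * s.size for i, s in enumerate(samples)])
    res = pairwise_tukeyhsd(pooled, labels)
    pairwise = {}
    for row, pv in zip(res._results_table.data[1:], res.pvalues):
        pairwise[f"{row[0]}-{row[1]}"] = float(pv)
    return GroupComparison(statistic=float(f), p_value=float(p), test="anova", pairwise=pairwise)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance input to Pearson correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def roc_analysis(scores_pos, scores_neg) -> RocResult:
    """Empirical ROC with trapezoidal AUC and the Youden-optimal cutoff.

    Positive class = higher scores (INPH); a case is called positive when its
    score >= threshold.  Ties contribute half credit (the Mann-Whitney
    convention), which the trapezoidal rule over the empirical curve realizes
    automatically; the identity AUC = U/(n1 n2) is asserted on every call.
    The reported cutoff is the midpoint between the Youden-maximizing observed
    score and the next lower observed score.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise StatsError("both score groups must be non-empty")

    all_scores = np.unique(np.concatenate([pos, neg]))[::-1]  # descending
    thresholds = np.concatenate([[np.inf], all_scores, [-np.inf]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    # trapezoidal AUC over (FPR, TPR)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    u_stat = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc_u = float(u_stat) / (pos.size * neg.size)
    if abs(auc - auc_u) > 1e-12:
        raise StatsError(
            f"internal AUC cross-check failed: trapezoidal {auc} vs U-identity {auc_u}"
        )

    j = sens + spec - 1.0
    best = int(np.argmax(j))
    best_thr = thresholds[best]
    if np.isinf(best_thr):
        cutoff = float(all_scores[0] + 1.0)
    else:
        lower = all_scores[all_scores < best_thr]
        cutoff = float((best_thr + lower[0]) / 2.0) if lower.size else float(best_thr)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=cutoff,
        youden_j=float(j[best]),
    )


_REGION_COLUMNS = {"lv": "lv_norm", "hc": "hc_norm", "syl": "syl_norm"}


def cohort_analysis(
    table: pd.DataFrame,
    posthoc: str = "dunn",
    normality_alpha: float = 0.05,
) -> dict:
    """The full group-level report on a cohort table.

    Emits per-region group medians/IQRs, the three-group test (ANOVA if every
    group passes Shapiro-Wilk at ``normality_alpha``, else Kruskal-Wallis)
    with pairwise post-hoc, within-group Pearson correlations (LV vs
    high-convexity, LV vs Sylvian), VOSS mean +- SD for INPH and AD, and the
    ROC of the VOSS index for INPH (positive) vs AD (negative).
    """
    required = {"group", "lv_norm", "hc_norm", "syl_norm", "voss"}
    missing = required - set(table.columns)
    if missing:
        raise StatsError(f"cohort table missing columns: {sorted(missing)}")
    groups = [g for g in ("control", "INPH", "AD") if g in set(table["group"])]
    if len(groups) < 2:
        raise StatsError(f"need >= 2 groups, found {sorted(set(table['group']))}")

    report: dict = {"groups": {g: int((table["group"] == g).sum()) for g in groups}}

    regions = {}
    for region, col in _REGION_COLUMNS.items():
        samples = [table.loc[table["group"] == g, col].to_numpy() for g in groups]
        desc = {
            g: {
                "median": float(np.median(s)),
                "q1": float(np.percentile(s, 25)),
                "q3": float(np.percentile(s, 75)),
            }
            for g, s in zip(groups, samples)
        }
        def _passes_normality(s: np.ndarray) -> bool:
            if s.size < 3 or np.all(s == s[0]):
                return False
            return bool(sps.shapiro(s).pvalue > normality_alpha)

        normal = all(_passes_normality(s) for s in samples)
        comp = (
            anova_oneway(samples, names=groups)
            if normal
            else kruskal_wallis(samples, names=groups, posthoc=posthoc)
        )
        regions[region] = {
            "descriptives": desc,
            "test": comp.test,
            "statistic": comp.statistic,
            "p_value": comp.p_value,
            "pairwise": comp.pairwise,
        }
    report["regions"] = regions

    correlations = {}
    for g in groups:
        sub = table[table["group"] == g]
        if len(sub) >= 3:
            entry = {}
            for a, b in (("lv_norm", "hc_norm"), ("lv_norm", "syl_norm")):
                r, p = pearson_r(sub[a], sub[b])
                entry[f"{a.split('_')[0]}-{b.split('_')[0]}"] = {"r": r, "p": p}
            correlations[g] = entry
    report["correlations"] = correlations

    voss = {}
    for g in ("INPH", "AD"):
        if g in groups:
            v = table.loc[table["group"] == g, "voss"].to_numpy()
            voss[g] = {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
    report["voss"] = voss

    if "INPH" in groups and "AD" in groups:
        roc = roc_analysis(
            table.loc[table["group"] == "INPH", "voss"].to_numpy(),
            table.loc[table["group"] == "AD", "voss"].to_numpy(),
        )
        best = int(np.argmax(roc.sensitivity + roc.specificity - 1.0))
        report["roc"] = {
            "auc": roc.auc,
            "youden_cutoff": roc.youden_cutoff,
            "youden_j": roc.youden_j,
            "sensitivity_at_cutoff": float(roc.sensitivity[best]),
            "specificity_at_cutoff": float(roc.specificity[best]),
        }
    return report


def report_to_text(report: dict) -> str:
    """Human-readable rendering of the cohort report."""
    lines = ["CSF-space volumetry cohort report", "=" * 34]
    lines.append("Group sizes: " + ", ".join(f"{g} n={n}" for g, n in report["groups"].items()))
    names = {"lv": "Lateral ventricle", "hc": "High-convexity SAS", "syl": "Sylvian region"}
    for region, res in report["regions"].items():
        lines.append(f"\n{names[region]} (normalized volume)")
        for g, d in res["descriptives"].items():
            lines.append(f"  {g:8s} median {d['median']:.4f} (IQR {d['q1']:.4f}-{d['q3']:.4f})")
        lines.append(f"  {res['test']}: statistic {res['statistic']:.3f}, p {res['p_value']:.3g}")
        for pair, p in res["pairwise"].items():
            lines.append(f"    {pair}: p {p:.3g}")
    if report.get("correlations"):
        lines.append("\nWithin-group Pearson correlations")
        for g, entry in report["correlations"].items():
            for pair, d in entry.items():
                lines.append(f"  {g:8s} {pair}: r {d['r']:+.3f} (p {d['p']:.3g})")
    if report.get("voss"):
        lines.append("\nVOSS index (lateral ventricle / high-convexity SAS)")
        for g, d in report["voss"].items():
            lines.append(f"  {g:8s} mean {d['mean']:.3f} +- {d['sd']:.3f}")
    if "roc" in report:
        r = report["roc"]
        lines.append(
            f"\nROC (INPH vs AD, VOSS index): AUC {r['auc']:.3f}, "
            f"cutoff {r['youden_cutoff']:.3f} "
            f"(Se {r['sensitivity_at_cutoff']:.3f}, Sp {r['specificity_at_cutoff']:.3f})"
        )
    return "\n".join(lines) + "\n"


def save_report(report: dict, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(report_to_text(report))
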