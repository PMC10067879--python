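"""Evaluation statistics: segmentation overlap and diagnostic performance.

Overlap indices (Dice, Jaccard, Hausdorff) score predicted masks or contours
against ground truth; agreement (Bland-Altman, Pearson r) and 2x2
diagnostic-performance analytics score virtual FFR against a reference, with
ischemia defined as FFR <= 0.80.  Because lower vFFR means disease, the AUC
score convention is "higher score = more diseased": pass ``-vffr`` (or any
strictly decreasing transform of vFFR) as the score.

Confidence-interval choices: Clopper-Pearson exact intervals for
proportions, the log method for likelihood ratios, and DeLong's method for
the AUC — the defaults of the common clinical statistics packages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist

__all__ = [
    "dice",
    "jaccard",
    "hausdorff",
    "AgreementReport",
    "bland_altman",
    "DiagnosticReport",
    "diagnostic_performance",
    "roc_auc",
]


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A.B| / (|A|+|B|); two empty masks -> 1.0 with warning."""
    a, b = _as_bool(mask_a), _as_bool(mask_b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def jaccard(mask_a, mask_b) -> float:
    """Jaccard index |A.B| / |AuB|; two empty masks -> 1.0 with warning."""
    a, b = _as_bool(mask_a), _as_bool(mask_b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both masks empty; Jaccard defined as 1.0", stacklevel=2)
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def hausdorff(points_a, points_b) -> float:
    """Symmetric Hausdorff distance between two point sets (contours), in the
    units of the coordinates (mm when contours are in mm)."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("hausdorff undefined for an empty point set")
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman bias and limits of agreement, plus Pearson r of (x, y)."""

    bias: float  # mean(y - x)
    sd: float  # SD of differences
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    pearson_r: float  # nan when either series is constant
    n: int


def bland_altman(x, y) -> AgreementReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-D arrays with n >= 2")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant series; Pearson r undefined", stacklevel=2)
        r = float("nan")
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return AgreementReport(
        bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        pearson_r=r, n=len(x),
    )


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class DiagnosticReport:
    """2x2 diagnostic analytics; proportions in percent with exact 95% CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    plr: float
    plr_ci: tuple[float, float]
    nlr: float
    nlr_ci: tuple[float, float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "tp", "fp", "tn", "fn", "accuracy", "accuracy_ci", "sensitivity",
            "sensitivity_ci", "specificity", "specificity_ci", "ppv", "ppv_ci",
            "npv", "npv_ci", "plr", "plr_ci", "nlr", "nlr_ci",
        )}

    def to_markdown(self) -> str:
        def pct(v, ci):
            return f"{v:.1f} ({ci[0]:.1f}-{ci[1]:.1f})"

        def ratio(v, ci):
            return f"{v:.3g} ({ci[0]:.3g}-{ci[1]:.3g})"

        rows = [
            ("Accuracy, % (95% CI)", pct(self.accuracy, self.accuracy_ci)),
            ("Sensitivity, % (95% CI)", pct(self.sensitivity, self.sensitivity_ci)),
            ("Specificity, % (95% CI)", pct(self.specificity, self.specificity_ci)),
            ("Positive predictive value, % (95% CI)", pct(self.ppv, self.ppv_ci)),
            ("Negative predictive value, % (95% CI)", pct(self.npv, self.npv_ci)),
            ("Positive likelihood ratio (95% CI)", ratio(self.plr, self.plr_ci)),
            ("Negative likelihood ratio (95% CI)", ratio(self.nlr, self.nlr_ci)),
        ]
        width = max(len(r[0]) for r in rows)
        lines = ["| " + "Metric".ljust(width) + " | Value |",
                 "|" + "-" * (width + 2) + "|-------|"]
        lines += ["| " + name.ljust(width) + " | " + val + " |" for name, val in rows]
        return "\n".join(lines)


def _lr_ci(lr: float, a: int, m: int, b: int, n: int, z: float = 1.959963984540054):
    """Log-method CI for a likelihood ratio formed from proportions a/m, b/n."""
    if lr == 0 or not np.isfinite(lr) or a == 0 or b == 0:
        return (float("nan"), float("nan"))
    se = np.sqrt(1 / a - 1 / m + 1 / b - 1 / n)
    return (float(lr * np.exp(-z * se)), float(lr * np.exp(z * se)))


def diagnostic_performance(pred, truth) -> DiagnosticReport:
    """Standard 2x2 derivations from binary ischemia calls.

    ``pred`` and ``truth`` are boolean vectors (True = positive = ischemic,
    i.e. FFR <= 0.80).  Proportion CIs are Clopper-Pearson exact; likelihood
    ratio CIs use the log method.
    """
    p = _as_bool(pred).ravel()
    t = _as_bool(truth).ravel()
    if p.shape != t.shape or len(p) < 1:
        raise ValueError("pred and truth must be equal-length non-empty vectors")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    n = len(p)
    pos, neg = tp + fn, fp + tn

    def prop(k, m):
        if m == 0:
            return float("nan"), (float("nan"), float("nan"))
        lo, hi = _clopper_pearson(k, m)
        return 100.0 * k / m, (100.0 * lo, 100.0 * hi)

    acc, acc_ci = prop(tp + tn, n)
    sens, sens_ci = prop(tp, pos)
    spec, spec_ci = prop(tn, neg)
    ppv, ppv_ci = prop(tp, tp + fp)
    npv, npv_ci = prop(tn, tn + fn)

    se = sens / 100.0 if pos else float("nan")
    sp = spec / 100.0 if neg else float("nan")
    plr = se / (1 - sp) if neg and sp < 1 else float("inf") if neg else float("nan")
    nlr = (1 - se) / sp if neg and sp > 0 else float("nan")
    plr_ci = _lr_ci(plr, tp, pos, fp, neg) if np.isfinite(plr) else (float("nan"),) * 2
    nlr_ci = _lr_ci(nlr, fn, pos, tn, neg) if np.isfinite(nlr) and nlr > 0 else (float("nan"),) * 2

    return DiagnosticReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=acc, accuracy_ci=acc_ci,
        sensitivity=sens, sensitivity_ci=sens_ci,
        specificity=spec, specificity_ci=spec_ci,
        ppv=ppv, ppv_ci=ppv_ci, npv=npv, npv_ci=npv_ci,
        plr=plr, plr_ci=plr_ci, nlr=nlr, nlr_ci=nlr_ci,
    )


def _delong_variance(scores_pos: np.ndarray, scores_neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via placement values."""
    m, n = len(scores_pos), len(scores_neg)
    # placement of each positive among negatives and vice versa (ties = 1/2)
    v10 = np.array([(np.sum(sp > scores_neg) + 0.5 * np.sum(sp == scores_neg)) / n for sp in scores_pos])
    v01 = np.array([(np.sum(scores_pos > sn) + 0.5 * np.sum(scores_pos == sn)) / m for sn in scores_neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def roc_auc(scores, truth, *, ci_method: str = "delong", n_boot: int = 2000, seed: int = 0):
    """AUC by the Mann-Whitney statistic (ties counted 1/2) with a 95% CI.

    ``scores`` must increase with disease likelihood (use -vFFR).  CI by
    DeLong (default) or stratified bootstrap.
    Returns (auc, (ci_low, ci_high)).
    """
    s = np.asarray(scores, dtype=float)
    t = _as_bool(truth).ravel()
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    pos, neg = s[t], s[~t]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    auc, var = _delong_variance(pos, neg)
    if ci_method == "delong":
        z = 1.959963984540054
        half = z * np.sqrt(var)
        return auc, (max(0.0, auc - half), min(1.0, auc + half))
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for i in range(n_boot):
            bp = rng.choice(pos, size=len(pos))
            bn = rng.choice(neg, size=len(neg))
            vals[i], _ = _delong_variance(bp, bn)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return auc, (float(lo), float(hi))
    raise ValueError("ci_method must be 'delong' or 'bootstrap'")
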