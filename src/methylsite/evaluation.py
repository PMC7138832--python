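"""Performance metrics, normality-gated significance tests, and
positional composition-bias statistics.

Threshold metrics from a confusion table (TP, TN, FP, FN):

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    ACC = (TP+TN) / total        SEN = TP / (TP+FN)
    SPE = TN / (TN+FP)           PRE = TP / (TP+FP)
    CPRE = SEN / (SEN + r*(1-SPE))

where ``r`` is the expected negative:positive ratio in real-world data; when
``r`` equals the evaluated set's own N/P, CPRE reduces exactly to PRE.  Any
zero denominator propagates as NaN (rendered "Nan" in reports).  Ranking
metrics are the tie-aware ROC AUC (concordance probability) and the
step-rule precision-recall AUC.

Group differences are tested with a Shapiro-Wilk gate: normal-looking
samples get a t-test, otherwise a Wilcoxon test (signed-rank when paired,
rank-sum otherwise); a directional one-tailed test runs only when the
two-tailed test is significant.  Compositional bias between positive and
negative site windows is assessed per (position, amino acid) cell with a
two-proportion test and Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .datasets import STANDARD_AA

NAN = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricsReport:
    MCC: float = NAN
    ACC: float = NAN
    SEN: float = NAN
    SPE: float = NAN
    PRE: float = NAN
    CPRE: float = NAN
    AUC: float = NAN
    PRAUC: float = NAN
    r_used: float = NAN

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("MCC", "ACC", "SEN", "SPE", "PRE", "CPRE", "AUC",
                      "PRAUC", "r_used")
        }

    def formatted(self) -> dict:
        """Report values with NaN rendered as the string "Nan"."""
        return {
            k: ("Nan" if isinstance(v, float) and math.isnan(v) else round(v, 4))
            for k, v in self.as_dict().items()
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else NAN


def confusion_metrics(c: ConfusionCounts, r: float | None = None) -> MetricsReport:
    """Threshold metrics from a confusion table.

    ``r`` defaults to the evaluated set's own negative:positive ratio
    (N/P = (TN+FP)/(TP+FN)), under which CPRE == PRE exactly.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    if r is None:
        r = _safe_div(c.TN + c.FP, c.TP + c.FN)
    elif r <= 0:
        raise ValueError("r must be positive")
    mcc_den = math.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = _safe_div(c.TP * c.TN - c.FP * c.FN, mcc_den)
    acc = (c.TP + c.TN) / c.total
    sen = _safe_div(c.TP, c.TP + c.FN)
    spe = _safe_div(c.TN, c.TN + c.FP)
    pre = _safe_div(c.TP, c.TP + c.FP)
    if math.isnan(sen) or math.isnan(spe) or math.isnan(r):
        cpre = NAN
    else:
        cpre = _safe_div(sen, sen + r * (1.0 - spe))
    return MetricsReport(MCC=mcc, ACC=acc, SEN=sen, SPE=spe, PRE=pre,
                         CPRE=cpre, r_used=r)


def roc_pr_auc(scores, labels) -> tuple:
    """(ROC AUC, PR AUC) from continuous scores and 0/1 labels.

    ROC AUC is the tie-aware concordance probability; PR AUC uses the
    step-rule integration (precision at each achieved recall level).
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes for ranking metrics")
    scores = np.asarray(scores, dtype=float)
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def evaluate_scores(scores, labels, threshold: float = 0.5,
                    r: float | None = None) -> MetricsReport:
    """Full report: threshold metrics at ``threshold`` plus AUC/PRAUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    c = ConfusionCounts.from_predictions(labels, (scores >= threshold).astype(int))
    report = confusion_metrics(c, r)
    report.AUC, report.PRAUC = roc_pr_auc(scores, labels)
    return report


# ---------------------------------------------------------------------------
# Normality-gated difference testing


@dataclass
class TestResult:
    normality_p_a: float
    normality_p_b: float
    test_used: str  # "t" | "wilcoxon"
    p_two_tailed: float
    p_one_tailed: float | None
    direction: str  # "a>b" | "a<b" | "none"


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # constant sample: certainly not Gaussian-looking
    return float(stats.shapiro(x).pvalue)


def gated_difference_test(a, b, paired: bool = False,
                          alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk-gated two-sample comparison.

    Normal-looking data (all Shapiro p > alpha; for paired data the gate is
    on the differences) -> Student's t-test (paired or two-sample);
    otherwise Wilcoxon signed-rank (paired) or rank-sum (independent).
    The one-tailed test runs only when the two-tailed p < alpha, in the
    direction suggested by the means (t) or rank sums (Wilcoxon).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per sample")
    if paired and len(a) != len(b):
        raise ValueError("paired samples must have equal lengths")

    if paired:
        d = a - b
        if np.ptp(d) == 0:
            if d[0] == 0:
                # identical samples: no difference, trivially non-significant
                return TestResult(1.0, 1.0, "t", 1.0, None, "none")
            # constant non-zero shift: zero-variance differences, the paired
            # t statistic diverges — trivially significant
            direction = "a>b" if d[0] > 0 else "a<b"
            return TestResult(1.0, 1.0, "t", 0.0, 0.0, direction)
        p_norm = _shapiro_p(d)
        p_a = p_b = p_norm
        gaussian = p_norm > alpha
    else:
        p_a, p_b = _shapiro_p(a), _shapiro_p(b)
        gaussian = p_a > alpha and p_b > alpha

    if gaussian:
        test_used = "t"
        if paired:
            p_two = float(stats.ttest_rel(a, b).pvalue)
        else:
            p_two = float(stats.ttest_ind(a, b).pvalue)
        a_greater = float(np.mean(a)) > float(np.mean(b))
    else:
        test_used = "wilcoxon"
        if paired:
            res = stats.wilcoxon(a, b)
            p_two = float(res.pvalue)
            a_greater = float(np.mean(a - b)) > 0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            p_two = float(res.pvalue)
            # direction from rank sums (U statistic vs its null mean)
            a_greater = float(res.statistic) > len(a) * len(b) / 2.0
    if p_two >= alpha:
        return TestResult(p_a, p_b, test_used, p_two, None, "none")

    alternative = "greater" if a_greater else "less"
    if test_used == "t":
        if paired:
            p_one = float(stats.ttest_rel(a, b, alternative=alternative).pvalue)
        else:
            p_one = float(stats.ttest_ind(a, b, alternative=alternative).pvalue)
    else:
        if paired:
            p_one = float(stats.wilcoxon(a, b, alternative=alternative).pvalue)
        else:
            p_one = float(
                stats.mannwhitneyu(a, b, alternative=alternative).pvalue
            )
    direction = "a>b" if a_greater else "a<b"
    return TestResult(p_a, p_b, test_used, p_two, p_one, direction)


# ---------------------------------------------------------------------------
# Compositional bias (two-sample-logo-style statistics)


def composition_bias(pos_windows, neg_windows, alpha: float = 0.05,
                     correction: str = "bonferroni") -> pd.DataFrame:
    """Per (position, amino acid) enrichment of positives vs negatives.

    Windows should share one odd size (41 in the standard logo convention:
    20 upstream + site + 20 downstream).  Padding characters are excluded
    from the counts.  Each cell gets a two-proportion test — Fisher's exact
    when any expected count is below 5, else the normal approximation — with
    Bonferroni correction over all (position, amino acid) cells.

    Returns a DataFrame with columns position, aa, freq_pos, freq_neg,
    p_raw, p_adj, call (enriched/depleted/ns).
    """
    if not pos_windows or not neg_windows:
        raise ValueError("both window sets must be non-empty")
    ws = {w.w for w in pos_windows} | {w.w for w in neg_windows}
    if len(ws) != 1:
        raise ValueError("all windows must share one size")
    w = ws.pop()
    half = (w - 1) // 2
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")

    def counts(windows):
        # (position offset, aa) -> count over non-pad characters
        tot = np.zeros(w, dtype=int)
        cnt = np.zeros((w, 20), dtype=int)
        for win in windows:
            for i, c in enumerate(win.text):
                if c in STANDARD_AA:
                    tot[i] += 1
                    cnt[i, STANDARD_AA.index(c)] += 1
        return cnt, tot

    cnt_p, tot_p = counts(pos_windows)
    cnt_n, tot_n = counts(neg_windows)
    offsets = [o for o in range(-half, half + 1) if o != 0]
    n_cells = len(offsets) * 20
    rows = []
    for o in offsets:
        i = o + half
        np_, nn_ = int(tot_p[i]), int(tot_n[i])
        for ai, aa in enumerate(STANDARD_AA):
            kp, kn = int(cnt_p[i, ai]), int(cnt_n[i, ai])
            if np_ == 0 or nn_ == 0:
                p_raw = 1.0
                fp = fn = 0.0
            else:
                fp, fn = kp / np_, kn / nn_
                pooled = (kp + kn) / (np_ + nn_)
                expected = [
                    pooled * np_, (1 - pooled) * np_,
                    pooled * nn_, (1 - pooled) * nn_,
                ]
                if min(expected) < 5:
                    _, p_raw = stats.fisher_exact(
                        [[kp, np_ - kp], [kn, nn_ - kn]]
                    )
                else:
                    se = math.sqrt(
                        pooled * (1 - pooled) * (1 / np_ + 1 / nn_)
                    )
                    if se == 0:
                        p_raw = 1.0
                    else:
                        z = (fp - fn) / se
                        p_raw = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p_raw * n_cells)
            if p_adj < alpha:
                call = "enriched" if fp > fn else "depleted"
            else:
                call = "ns"
            rows.append(
                {
                    "position": o,
                    "aa": aa,
                    "freq_pos": fp,
                    "freq_neg": fn,
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                    "call": call,
                }
            )
    return pd.DataFrame(rows)


def write_metrics(report: MetricsReport, dest, fmt: str = "tsv") -> None:
    """Write a metrics report as TSV or JSON (NaN rendered "Nan")."""
    import json

    data = report.formatted()
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        close = True
    try:
        if fmt == "json":
            json.dump(data, dest, indent=2)
            dest.write("\n")
        else:
            dest.write("\t".join(data.keys()) + "\n")
            dest.write("\t".join(str(v) for v in data.values()) + "\n")
    finally:
        if close:
            dest.close()
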