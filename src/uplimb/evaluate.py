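"""Agreement statistics between angle-waveform sets: coefficient of multiple
correlation (CMC), RMSE, range of motion (ROM), angle at the point of target
achieved (PTA), Bland-Altman limits of agreement, and normality-gated paired
tests; plus report assembly over cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import AngleWaveform, CHANNELS, ValidationError


def cmc(waveforms, return_flag=False):
    """Kadaba-style within-group coefficient of multiple correlation.

    ``waveforms``: (G, T) array of G aligned waveforms of one channel.

        CMC = sqrt(1 - [sum_gt (Y_gt - Ybar_t)^2 / (G (T-1))]
                     / [sum_gt (Y_gt - Ybar)^2 / (G T - 1)])

    with Ybar_t the across-waveform mean at time t and Ybar the grand mean.
    The radicand is negative when the waveforms are more dissimilar than the
    grand-mean spread (a known property of the statistic); it is clamped to 0
    and flagged. Identical constant waveforms make the statistic 0/0 and
    return a flagged NaN.
    """
    Y = np.asarray(waveforms, dtype=float)
    if Y.ndim != 2:
        raise ValidationError("cmc expects a (G, T) array")
    G, T = Y.shape
    if G < 2 or T < 2:
        raise ValidationError("need G >= 2 waveforms of length T >= 2")
    mean_t = Y.mean(axis=0)
    grand = Y.mean()
    num = np.sum((Y - mean_t) ** 2) / (G * (T - 1))
    den = np.sum((Y - grand) ** 2) / (G * T - 1)
    if den == 0.0:
        value, flag = np.nan, True
    else:
        radicand = 1.0 - num / den
        if radicand < 0:
            value, flag = 0.0, True
        else:
            value, flag = float(np.sqrt(radicand)), False
    if return_flag:
        return value, flag
    return value


def rmse(a, b):
    """Root-mean-squared error between two equal-length channel waveforms."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rom(wf, channel=None):
    """Range of motion: max - min over the normalized waveform (degrees)."""
    x = _channel_values(wf, channel)
    return float(x.max() - x.min())


def pta(wf, channel=None):
    """Angle at the point of target achieved: the final (100%) sample.

    Each task's recording ends when the hand reaches the target, so the last
    normalized sample is the target-achievement angle.
    """
    x = _channel_values(wf, channel)
    return float(x[-1])


def _channel_values(wf, channel):
    if isinstance(wf, AngleWaveform):
        if not wf.normalized:
            raise ValidationError("ROM/PTA require a time-normalized waveform")
        return wf.values if channel is None else wf.channel(channel)
    x = np.asarray(wf, dtype=float)
    if channel is not None and x.ndim == 2:
        return x[:, CHANNELS.index(channel)]
    return x


def bland_altman(x, y):
    """Bland-Altman agreement of two paired parameter lists.

    Returns dict with mean_diff, loa_lower/upper (mean +/- 1.96 sample SD),
    and the per-pair means and differences for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need equal-length paired lists with n >= 2")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "loa_lower": mean_diff - 1.96 * sd,
        "loa_upper": mean_diff + 1.96 * sd,
        "means": (x + y) / 2.0,
        "diffs": d,
    }


def paired_comparison(x, y, alpha=0.05):
    """Normality-gated paired test on x vs y.

    Shapiro-Wilk on the paired differences selects a paired t-test (p > 0.05,
    normal) or the Wilcoxon signed-rank test otherwise. Returns
    ``(test_name, statistic, p_value)``; zero-variance differences yield
    ``("degenerate", nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need equal-length paired samples with n >= 3")
    d = x - y
    if np.allclose(d, d[0]):
        return ("degenerate", float("nan"), float("nan"))
    sw_p = stats.shapiro(d).pvalue
    if sw_p > alpha:
        res = stats.ttest_rel(x, y)
        return ("paired-t", float(res.statistic), float(res.pvalue))
    res = stats.wilcoxon(x, y)
    return ("wilcoxon", float(res.statistic), float(res.pvalue))


@dataclass
class AgreementReport:
    """Per task x channel agreement summary (dict-of-dicts payload)."""

    entries: dict

    def to_dict(self):
        return self.entries


def _subject_mean(values_by_subject):
    """Mean over trials within subject, then mean and SD across subjects."""
    per_subject = [np.nanmean(v) for v in values_by_subject.values() if len(v)]
    arr = np.asarray(per_subject, dtype=float)
    return float(np.nanmean(arr)), float(np.nanstd(arr, ddof=1)) if len(arr) > 1 else 0.0


def build_report(fold_results, alpha=0.05) -> AgreementReport:
    """Aggregate LOOCV fold results into the per-task, per-channel report.

    For every channel: CMC and RMSE mean (SD) across subjects (trials averaged
    within subject first), PTA and ROM per system with mean differences,
    Bland-Altman 95% limits of agreement on PTA/ROM, and the normality-gated
    paired test on the per-subject PTA/ROM values.
    """
    folds = list(fold_results)
    if not folds:
        raise ValidationError("no folds to report on")
    tasks = sorted({f.task for f in folds})
    entries = {}
    for task in tasks:
        tfolds = [f for f in folds if f.task == task]
        entries[task] = {}
        for ci, ch in enumerate(CHANNELS):
            cmc_b, cmc_a, rmse_b, rmse_a = {}, {}, {}, {}
            per_subject = {}
            for f in tfolds:
                sid = f.subject_id
                cmc_b[sid] = f.cmc_before[:, ci]
                cmc_a[sid] = f.cmc_after[:, ci]
                rmse_b[sid] = f.rmse_before[:, ci]
                rmse_a[sid] = f.rmse_after[:, ci]
                per_subject[sid] = {
                    "pta_ref": [pta(w.values[:, ci]) for w in f.targets],
                    "pta_raw": [pta(w.values[:, ci]) for w in f.inputs],
                    "pta_hat": [pta(w.values[:, ci]) for w in f.refined],
                    "rom_ref": [rom(w.values[:, ci]) for w in f.targets],
                    "rom_raw": [rom(w.values[:, ci]) for w in f.inputs],
                    "rom_hat": [rom(w.values[:, ci]) for w in f.refined],
                }
            subjects = sorted(per_subject)

            def smean(key):
                return np.array([np.mean(per_subject[s][key]) for s in subjects])

            entry = {
                "cmc": {"raw": _subject_mean(cmc_b), "refined": _subject_mean(cmc_a)},
                "rmse": {"raw": _subject_mean(rmse_b), "refined": _subject_mean(rmse_a)},
            }
            for param in ("pta", "rom"):
                ref = smean(f"{param}_ref")
                raw = smean(f"{param}_raw")
                hat = smean(f"{param}_hat")
                block = {}
                for label, vals in (("raw", raw), ("refined", hat)):
                    loa = [np.nan, np.nan]
                    if len(vals) >= 2:
                        ba = bland_altman(vals, ref)
                        loa = [ba["loa_lower"], ba["loa_upper"]]
                    test = (paired_comparison(vals, ref, alpha=alpha)
                            if len(vals) >= 3 else ("n/a", np.nan, np.nan))
                    block[label] = {
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                        "mean_diff": float((vals - ref).mean()),
                        "loa": loa,
                        "test": test[0], "statistic": test[1], "p_value": test[2],
                    }
                block["reference"] = {
                    "mean": float(ref.mean()),
                    "sd": float(ref.std(ddof=1)) if len(ref) > 1 else 0.0,
                }
                entry[param] = block
            entries[task][ch] = entry
    return AgreementReport(entries=entries)
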