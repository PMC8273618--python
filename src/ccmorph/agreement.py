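"""Method-agreement statistics: Dice overlap, Pearson r, Bland–Altman.

These are the validation statistics used to compare automated segmentations
against manual ones and thickness measurements between modalities: the Dice
score for mask overlap, a two-tailed Pearson correlation (p-value from the
t transform with n-2 degrees of freedom), and Bland–Altman bias with
1.96·SD limits of agreement (sample SD, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .grids import BinaryMask
from .thickness import local_thickness, summarize


@dataclass(frozen=True)
class AgreementResult:
    r: float
    p_two_tailed: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def _values(mask: BinaryMask | np.ndarray) -> np.ndarray:
    return mask.values if isinstance(mask, BinaryMask) else np.asarray(mask).astype(bool)


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice score 2|A∩B| / (|A|+|B|); two empty masks agree perfectly (1.0)."""
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError(f"mask shapes differ: {av.shape} vs {bv.shape}")
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((av & bv).sum()) / denom


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-tailed p-value.

    The p-value comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom. Requires n >= 3 and non-zero variance in both arguments.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson requires non-zero variance in both inputs")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementResult:
    """Bland–Altman agreement of paired measurements ``a`` and ``b``.

    Differences are ``a - b``; bias is their mean, sd_diff the sample SD
    (n-1), and the limits of agreement bias ± 1.96·sd_diff. Pearson r/p are
    filled when n >= 3 and both inputs vary, else reported as NaN.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("a and b must have equal length")
    if a.size < 2:
        raise ValueError("bland_altman requires n >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    r = p = float("nan")
    if a.size >= 3 and np.std(a) > 0 and np.std(b) > 0:
        r, p = pearson(a, b)
    return AgreementResult(
        r=r,
        p_two_tailed=p,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(a.size),
    )


def out_of_fold_report(
    predictions: dict[str, BinaryMask],
    truths: dict[str, BinaryMask],
    grouping: dict[str, str] | None = None,
    pixel_size_um: float | None = None,
) -> dict:
    """Per-sample Dice and predicted-vs-true mean thickness correlation.

    ``predictions`` and ``truths`` map sample ids to masks; every prediction
    must have a paired truth. ``grouping`` optionally maps sample id to a
    sample/subject label: per-image Dice is averaged within each group
    before the overall mean, mirroring per-sample averaging of multiple
    sections. Thickness correlation is reported when at least three groups
    have non-empty masks on both sides and the values vary; a constant
    thickness across groups is flagged instead.
    """
    missing = sorted(set(predictions) - set(truths))
    if missing:
        raise ValueError(f"predictions without a paired truth: {missing}")
    grouping = grouping or {sid: sid for sid in predictions}

    per_image = {sid: dice(predictions[sid], truths[sid]) for sid in predictions}
    groups = sorted({grouping[sid] for sid in predictions})
    per_group_dice = {
        g: float(np.mean([per_image[sid] for sid in predictions if grouping[sid] == g]))
        for g in groups
    }
    overall = float(np.mean(list(per_group_dice.values())))

    pred_th, true_th, th_groups = [], [], []
    for g in groups:
        sids = [sid for sid in predictions if grouping[sid] == g]
        pv, tv = [], []
        for sid in sids:
            if predictions[sid].values.any() and truths[sid].values.any():
                pv.append(summarize(local_thickness(predictions[sid]), pixel_size_um).mean_um)
                tv.append(summarize(local_thickness(truths[sid]), pixel_size_um).mean_um)
        if pv:
            pred_th.append(float(np.mean(pv)))
            true_th.append(float(np.mean(tv)))
            th_groups.append(g)

    report = {
        "per_image_dice": per_image,
        "per_sample_dice": per_group_dice,
        "mean_dice": overall,
        "thickness_pred_um": dict(zip(th_groups, pred_th)),
        "thickness_truth_um": dict(zip(th_groups, true_th)),
        "thickness_r": None,
        "thickness_p": None,
        "thickness_constant": False,
    }
    if len(pred_th) >= 3:
        if np.std(pred_th) == 0 or np.std(true_th) == 0:
            report["thickness_constant"] = True
        else:
            r, p = pearson(pred_th, true_th)
            report["thickness_r"] = r
            report["thickness_p"] = p
    return report
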