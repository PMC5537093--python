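"""Segmentation evaluation: overlap metrics, border distances, kidney
volumetry, Bland-Altman agreement, and cohort summaries.

Voxel-level agreement between a reference mask R and a predicted mask P is
tallied into TP/FP/FN/TN counts, from which

    Dice      = 2*TP / (2*TP + FP + FN)
    Jaccard   = TP / (TP + FP + FN)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)
    Precision   = TP / (TP + FP)

A metric whose denominator is zero is reported as NaN (explicitly
undefined), never silently 0.  Border agreement is summarized by D_mean:
the per-axial-slice symmetrized maximum border-to-border distance
(slice-wise Hausdorff distance, in mm) averaged over the slices where both
masks have a border; mean symmetric surface distance is emitted alongside
as a secondary statistic.  Total kidney volume is voxel count x voxel
volume; agreement of percent volume differences across a cohort is
assessed with Bland-Altman limits mean +/- 1.96 * sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import BinaryMask3D, check_same_geometry

__all__ = [
    "ConfusionCounts", "SegMetrics", "VolumeReport", "BlandAltmanResult",
    "confusion_counts", "dice", "jaccard", "sensitivity", "specificity",
    "precision", "boundary_distance_mean", "total_volume",
    "percent_volume_difference", "bland_altman", "evaluate_case",
    "evaluate_cohort", "CohortSummary",
]

LIMITS_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel tallies; TP+FP+FN+TN equals the total voxel count."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegMetrics:
    dice: float
    jaccard: float
    sensitivity: float
    specificity: float
    precision: float
    d_mean_mm: float
    mssd_mm: float  # mean symmetric surface distance, secondary


@dataclass(frozen=True)
class VolumeReport:
    tkv_ref_ml: float
    tkv_pred_ml: float
    pct_diff: float


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    n: int


def confusion_counts(ref: BinaryMask3D, pred: BinaryMask3D) -> ConfusionCounts:
    check_same_geometry(ref, pred, context=" in confusion_counts")
    r = ref.values.astype(bool)
    p = pred.values.astype(bool)
    tp = int(np.count_nonzero(r & p))
    fp = int(np.count_nonzero(~r & p))
    fn = int(np.count_nonzero(r & ~p))
    tn = int(np.count_nonzero(~r & ~p))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def dice(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def jaccard(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def _slice_border(slc: np.ndarray) -> np.ndarray:
    """Border voxels of a 2-D binary slice (4-connected erosion residue)."""
    return slc & ~ndimage.binary_erosion(slc, border_value=0)


def _directed_stats(a_pts: np.ndarray, b_pts: np.ndarray, spacing2d) -> tuple[float, float]:
    """(max, mean) over a of min-distance(a, B), in physical units."""
    diff = a_pts[:, None, :] - b_pts[None, :, :]
    d = np.sqrt(((diff * np.asarray(spacing2d)) ** 2).sum(-1)).min(axis=1)
    return float(d.max()), float(d.mean())


def boundary_distance_mean(ref: BinaryMask3D, pred: BinaryMask3D) -> tuple[float, float]:
    """Slice-wise border distance summaries ``(d_mean_mm, mssd_mm)``.

    For each axial slice on which both masks have foreground, the directed
    maximum distance from each border to the other is computed (physical
    in-plane units) and symmetrized by taking the larger of the two; these
    slice-wise Hausdorff distances are averaged over the involved slices.
    ``mssd_mm`` averages all point-to-border minimum distances instead.
    Returns ``(nan, nan)`` when either mask is empty or no slice has both.
    """
    check_same_geometry(ref, pred, context=" in boundary_distance_mean")
    if ref.voxel_count() == 0 or pred.voxel_count() == 0:
        return float("nan"), float("nan")
    spacing2d = ref.spacing_mm[:2]
    haus, mins = [], []
    for z in range(ref.shape[2]):
        r = ref.values[:, :, z].astype(bool)
        p = pred.values[:, :, z].astype(bool)
        if not (r.any() and p.any()):
            continue
        rb = np.argwhere(_slice_border(r))
        pb = np.argwhere(_slice_border(p))
        max_rp, mean_rp = _directed_stats(rb, pb, spacing2d)
        max_pr, mean_pr = _directed_stats(pb, rb, spacing2d)
        haus.append(max(max_rp, max_pr))
        mins.append(0.5 * (mean_rp + mean_pr))
    if not haus:
        return float("nan"), float("nan")
    return float(np.mean(haus)), float(np.mean(mins))


def total_volume(mask: BinaryMask3D) -> float:
    """Mask volume in millilitres: voxel count x voxel volume (mm^3) / 1000."""
    return mask.voxel_count() * mask.voxel_volume_mm3() / 1000.0


def percent_volume_difference(pred_ml: float, ref_ml: float) -> float:
    """Signed percent TKV error, 100*(pred - ref)/ref."""
    if ref_ml <= 0:
        raise ValueError("reference volume must be positive")
    return 100.0 * (pred_ml - ref_ml) / ref_ml


def bland_altman(diffs) -> BlandAltmanResult:
    """Limits of agreement mean +/- 1.96 * sample SD (n-1 denominator)."""
    diffs = np.asarray(list(diffs), dtype=np.float64)
    if diffs.size < 2:
        raise ValueError("Bland-Altman needs at least 2 values")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean, sd_diff=sd,
        lower_limit=mean - LIMITS_MULTIPLIER * sd,
        upper_limit=mean + LIMITS_MULTIPLIER * sd,
        n=int(diffs.size),
    )


def evaluate_case(ref: BinaryMask3D, pred: BinaryMask3D) -> tuple[SegMetrics, VolumeReport]:
    c = confusion_counts(ref, pred)
    d_mean, mssd = boundary_distance_mean(ref, pred)
    seg = SegMetrics(
        dice=dice(c), jaccard=jaccard(c), sensitivity=sensitivity(c),
        specificity=specificity(c), precision=precision(c),
        d_mean_mm=d_mean, mssd_mm=mssd,
    )
    ref_ml = total_volume(ref)
    pred_ml = total_volume(pred)
    pct = percent_volume_difference(pred_ml, ref_ml) if ref_ml > 0 else float("nan")
    return seg, VolumeReport(tkv_ref_ml=ref_ml, tkv_pred_ml=pred_ml, pct_diff=pct)


_SUMMARY_COLUMNS = [
    "dice", "jaccard", "sensitivity", "specificity", "precision",
    "d_mean_mm", "mssd_mm", "pct_diff",
]


@dataclass
class CohortSummary:
    """Per-case table, m +/- SD [min/max] summary, and Bland-Altman result."""

    per_case: pd.DataFrame
    summary: pd.DataFrame
    bland_altman: BlandAltmanResult | None

    def formatted(self) -> pd.Series:
        """Rows formatted in the conventional 'm ± SD [min/max]' style."""
        out = {}
        for stat, row in self.summary.iterrows():
            out[stat] = (
                f"{row['mean']:.2f} ± {row['sd']:.2f} "
                f"[{row['min']:.2f}/{row['max']:.2f}]"
            )
        return pd.Series(out, name="m ± SD [min/max]")


def evaluate_cohort(pairs, case_ids=None) -> CohortSummary:
    """Evaluate (reference, prediction) mask pairs across a cohort.

    Parameters
    ----------
    pairs : sequence of (BinaryMask3D, BinaryMask3D)
        Reference and predicted masks per case.
    case_ids : optional sequence of str

    Undefined per-case metrics propagate as NaN and are excluded from the
    summary statistics of that column only (never dropped silently: they
    remain visible in ``per_case``).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (ref, pred) pair")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(pairs))]
    rows = []
    for cid, (ref, pred) in zip(case_ids, pairs):
        seg, vol = evaluate_case(ref, pred)
        rows.append(
            dict(case_id=cid, dice=seg.dice, jaccard=seg.jaccard,
                 sensitivity=seg.sensitivity, specificity=seg.specificity,
                 precision=seg.precision, d_mean_mm=seg.d_mean_mm,
                 mssd_mm=seg.mssd_mm, tkv_ref_ml=vol.tkv_ref_ml,
                 tkv_pred_ml=vol.tkv_pred_ml, pct_diff=vol.pct_diff)
        )
    per_case = pd.DataFrame(rows).set_index("case_id")
    summary = pd.DataFrame(
        {
            "mean": per_case[_SUMMARY_COLUMNS].mean(),
            "sd": per_case[_SUMMARY_COLUMNS].std(ddof=1),
            "min": per_case[_SUMMARY_COLUMNS].min(),
            "max": per_case[_SUMMARY_COLUMNS].max(),
        }
    )
    diffs = per_case["pct_diff"].dropna()
    ba = bland_altman(diffs) if diffs.size >= 2 else None
    return CohortSummary(per_case=per_case, summary=summary, bland_altman=ba)


def bland_altman_plot(ref_volumes_ml, pct_diffs, out_path, title="Bland-Altman: TKV percent difference"):
    """Scatter of percent differences vs reference TKV with mean and limits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(pct_diffs)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ref_volumes_ml, pct_diffs, s=18, alpha=0.8)
    ax.axhline(ba.mean_diff, color="k", lw=1.5)
    for y in (ba.lower_limit, ba.upper_limit):
        ax.axhline(y, color="k", lw=1, ls=":")
    ax.set_xlabel("Reference TKV (ml)")
    ax.set_ylabel("TKV difference (%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return ba
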