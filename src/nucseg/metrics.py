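"""Instance-segmentation evaluation with dual IOU thresholds.

Conventional object-level F1 scores match ground-truth (GT) and predicted
objects at a single IOU threshold tau1, so a nucleus segmented with a small
inaccuracy (say IOU = 0.4) is double-counted as both a false positive and a
false negative.  The suite here adds a second, lower threshold tau2 and an
*inaccurate mask* (IA) category: a GT object whose single best partner lies
in (tau2, tau1] counts as one error, not two.  GT objects covered by several
partners in that band are *splits* (oversegmentation); predictions covering
several GT objects in that band are *merges* (undersegmentation).

Categories per GT object (mutually exclusive, precedence top-down):

====== ==========================================================
TP     some prediction overlaps with IOU > tau1
split  >1 predictions overlap with tau2 < IOU <= tau1
IA     exactly 1 prediction overlaps with tau2 < IOU <= tau1
FN     all overlaps <= tau2 (or none)
====== ==========================================================

FP counts predictions whose best IOU against any GT object is <= tau2.

Scores::

    conventional F1 = 2 TP / (2 TP + FP_conv + FN_conv + eps)
    adapted     F1 = 2 TP / (2 TP + FP + FN + IA + splits + eps)

with ``FP_conv = n_pred - TP`` and ``FN_conv = n_gt - TP`` (every unmatched
object is an error) while FP/FN in the adapted form use the tau2 rule.  The
adapted denominator never exceeds the conventional one, so adapted >=
conventional at equal tau1.  The headline summary "F1avg0.6" is the
unweighted image-wise mean of adapted F1 at tau1 = 0.6, tau2 = 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TAU1_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.5, 0.91, 0.05), 2))


@dataclass(frozen=True)
class MetricConfig:
    """Evaluation hyperparameters.

    tau1: IOU above which a match is a true positive (headline 0.6).
    tau2: lower IOU bound separating errors from non-overlaps (0.1).
    eps: additive stabiliser in both F1 denominators.
    pixel_size_um: micrometres per pixel, for the size-stratified IOU.
    size_cutoff_um2: object area (um^2) above which a nucleus is "large".
    """

    tau1: float = 0.6
    tau2: float = 0.1
    eps: float = 1e-8
    pixel_size_um: float | None = None
    size_cutoff_um2: float = 750.0

    def __post_init__(self) -> None:
        if not (0.0 < self.tau2 < self.tau1 < 1.0):
            raise ValueError(f"need 0 < tau2 < tau1 < 1, got tau2={self.tau2}, tau1={self.tau1}")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class IOUTable:
    """Sparse table of overlapping (gt_label, pred_label) object pairs."""

    gt_labels: np.ndarray          # int, one entry per overlapping pair
    pred_labels: np.ndarray
    intersection: np.ndarray       # pixel counts
    union: np.ndarray
    n_gt: int
    n_pred: int
    gt_areas: dict[int, int] = field(default_factory=dict)

    @property
    def iou(self) -> np.ndarray:
        return self.intersection / self.union

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gt_label": self.gt_labels,
                "pred_label": self.pred_labels,
                "intersection": self.intersection,
                "union": self.union,
                "iou": self.iou,
            }
        )


@dataclass
class MatchResult:
    """Per-image contingency under the dual-threshold matching rules."""

    tp: int
    fp: int
    fn: int
    ia: int
    splits: int
    merges: int
    n_gt: int
    n_pred: int
    gt_category: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.tp + self.fn + self.ia + self.splits == self.n_gt, (
            "GT partition violated: "
            f"TP={self.tp} FN={self.fn} IA={self.ia} splits={self.splits} n_gt={self.n_gt}"
        )


def pairwise_iou(gt: np.ndarray, pred: np.ndarray) -> IOUTable:
    """Exact per-object-pair intersection/union pixel counts.

    Pairs with zero overlap are omitted (their IOU is implicitly 0).
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")

    gt_ids, gt_counts = np.unique(gt[gt > 0], return_counts=True)
    pred_ids, pred_counts = np.unique(pred[pred > 0], return_counts=True)
    gt_area = dict(zip(gt_ids.tolist(), gt_counts.tolist()))
    pred_area = dict(zip(pred_ids.tolist(), pred_counts.tolist()))

    both = (gt > 0) & (pred > 0)
    if both.any():
        codes = gt[both].astype(np.int64) * (pred.max() + 1) + pred[both].astype(np.int64)
        pair_codes, inter = np.unique(codes, return_counts=True)
        g = pair_codes // (pred.max() + 1)
        p = pair_codes % (pred.max() + 1)
        union = np.array(
            [gt_area[int(gi)] + pred_area[int(pi)] for gi, pi in zip(g, p)], dtype=np.int64
        ) - inter
    else:
        g = p = inter = union = np.zeros(0, dtype=np.int64)

    return IOUTable(
        gt_labels=g.astype(np.int64),
        pred_labels=p.astype(np.int64),
        intersection=inter.astype(np.int64),
        union=union,
        n_gt=len(gt_ids),
        n_pred=len(pred_ids),
        gt_areas=gt_area,
    )


def match_objects(table: IOUTable, cfg: MetricConfig) -> MatchResult:
    """Categorise every object per the dual-threshold rules.

    For tau1 >= 0.5 at most one prediction can exceed tau1 per GT object
    (two sets cannot each share a strict majority of a third); this is
    asserted.  Below 0.5 uniqueness is no longer geometric and a greedy
    max-IOU assignment is applied with a warning.
    """
    tau1, tau2 = cfg.tau1, cfg.tau2
    greedy = tau1 < 0.5
    if greedy:
        warnings.warn(
            f"tau1={tau1} < 0.5: TP uniqueness not guaranteed; using greedy max-IOU",
            stacklevel=2,
        )

    iou = table.iou
    # group pair rows by GT object and by predicted object
    gt_rows: dict[int, list[int]] = {}
    pred_rows: dict[int, list[int]] = {}
    for idx in range(len(iou)):
        gt_rows.setdefault(int(table.gt_labels[idx]), []).append(idx)
        pred_rows.setdefault(int(table.pred_labels[idx]), []).append(idx)

    # gt_areas lists every GT label when the table came from pairwise_iou;
    # otherwise only labels with overlaps are known and the remainder are FN.
    all_gt = set(table.gt_areas) if table.gt_areas else set(gt_rows)

    category: dict[int, str] = {}
    tp = splits = ia = fn = 0
    for g in sorted(all_gt):
        rows = gt_rows.get(g, [])
        above1 = [r for r in rows if iou[r] > tau1]
        band = [r for r in rows if tau2 < iou[r] <= tau1]
        if above1:
            if not greedy:
                assert len(above1) == 1, f"multiple IOU>{tau1} partners for GT {g}"
            category[g] = "TP"
            tp += 1
        elif len(band) > 1:
            category[g] = "split"
            splits += 1
        elif len(band) == 1:
            category[g] = "IA"
            ia += 1
        else:
            category[g] = "FN"
            fn += 1
    # GT objects absent from the table entirely (no overlap with anything)
    n_unseen = table.n_gt - len(category)
    fn += n_unseen

    # FP: predictions whose best IOU <= tau2 (incl. zero-overlap predictions)
    fp = 0
    merges = 0
    seen_preds = set(pred_rows)
    for p in seen_preds:
        rows = pred_rows[p]
        best = max(iou[r] for r in rows)
        if best <= tau2:
            fp += 1
        band_gt = [r for r in rows if tau2 < iou[r] <= tau1]
        if len(band_gt) > 1:
            merges += 1
    fp += table.n_pred - len(seen_preds)

    return MatchResult(
        tp=tp, fp=fp, fn=fn, ia=ia, splits=splits, merges=merges,
        n_gt=table.n_gt, n_pred=table.n_pred, gt_category=category,
    )


def conventional_f1(match: MatchResult, eps: float = 1e-8) -> float:
    """Single-threshold F1: every object unmatched at tau1 is an error."""
    fn_conv = match.n_gt - match.tp
    fp_conv = match.n_pred - match.tp
    return 2.0 * match.tp / (2.0 * match.tp + fp_conv + fn_conv + eps)


def adapted_f1(match: MatchResult, eps: float = 1e-8) -> float:
    """Dual-threshold F1: IA and split GT objects count one error each."""
    ia_total = match.ia + match.splits
    return 2.0 * match.tp / (2.0 * match.tp + match.fp + match.fn + ia_total + eps)


def f1_curve(
    gt: np.ndarray,
    pred: np.ndarray,
    cfg: MetricConfig = MetricConfig(),
    tau1_grid: tuple[float, ...] = DEFAULT_TAU1_GRID,
) -> pd.DataFrame:
    """Both F1 variants over a tau1 grid (tau2 fixed) for one image pair."""
    table = pairwise_iou(gt, pred)
    rows = []
    for t1 in tau1_grid:
        m = match_objects(table, MetricConfig(tau1=t1, tau2=cfg.tau2, eps=cfg.eps))
        rows.append(
            {
                "tau1": t1,
                "adapted_f1": adapted_f1(m, cfg.eps),
                "conventional_f1": conventional_f1(m, cfg.eps),
            }
        )
    return pd.DataFrame(rows)


def dataset_score(
    per_image: list[MatchResult], mode: str = "avg", metric: str = "adapted_f1",
    eps: float = 1e-8,
) -> float:
    """Dataset-level score: image-wise average or aggregated contingencies.

    ``avg`` is the unweighted mean of image-wise scores (this is F1avg0.6
    when metric="adapted_f1" at tau1=0.6); ``agg`` sums the contingency
    tables over the dataset first and scores once.
    """
    if not per_image:
        raise ValueError("need at least one image")
    score_fn = {"adapted_f1": adapted_f1, "conventional_f1": conventional_f1}[metric]
    if mode == "avg":
        return float(np.mean([score_fn(m, eps) for m in per_image]))
    if mode == "agg":
        total = MatchResult(
            tp=sum(m.tp for m in per_image),
            fp=sum(m.fp for m in per_image),
            fn=sum(m.fn for m in per_image),
            ia=sum(m.ia for m in per_image),
            splits=sum(m.splits for m in per_image),
            merges=sum(m.merges for m in per_image),
            n_gt=sum(m.n_gt for m in per_image),
            n_pred=sum(m.n_pred for m in per_image),
        )
        return float(score_fn(total, eps))
    raise ValueError(f"unknown mode {mode!r}")


def split_merge_rate(
    per_image: list[MatchResult], per_n: int = 50
) -> dict[str, float | int]:
    """Over/under-segmentation rates per ``per_n`` nuclei, mean +/- sd.

    Per image: splits / n_gt * per_n (GT nuclei oversegmented) and
    merges / n_pred * per_n (detected nuclei that merge GT nuclei).
    Images with a zero denominator are excluded from the respective rate
    and their count reported.
    """
    split_rates = [m.splits / m.n_gt * per_n for m in per_image if m.n_gt > 0]
    merge_rates = [m.merges / m.n_pred * per_n for m in per_image if m.n_pred > 0]
    return {
        "split_rate_mean": float(np.mean(split_rates)) if split_rates else 0.0,
        "split_rate_sd": float(np.std(split_rates)) if split_rates else 0.0,
        "merge_rate_mean": float(np.mean(merge_rates)) if merge_rates else 0.0,
        "merge_rate_sd": float(np.std(merge_rates)) if merge_rates else 0.0,
        "excluded_split_images": sum(1 for m in per_image if m.n_gt == 0),
        "excluded_merge_images": sum(1 for m in per_image if m.n_pred == 0),
    }


def object_iou_by_size(
    gt: np.ndarray, pred: np.ndarray, cfg: MetricConfig
) -> dict[str, float]:
    """Image-wise mean best-partner IOU, stratified by physical object size.

    A GT object is *large* iff area_px * pixel_size^2 > cutoff (um^2); its
    IOU is the max over predicted partners, 0 when none overlaps.  Strata
    with no GT objects report NaN.
    """
    if cfg.pixel_size_um is None:
        raise ValueError("pixel_size_um must be set for size-stratified IOU")
    table = pairwise_iou(gt, pred)
    best: dict[int, float] = {}
    for g, i in zip(table.gt_labels, table.iou):
        gi = int(g)
        best[gi] = max(best.get(gi, 0.0), float(i))
    px_area = cfg.pixel_size_um**2
    large, small = [], []
    for g, area in table.gt_areas.items():
        iou = best.get(g, 0.0)
        (large if area * px_area > cfg.size_cutoff_um2 else small).append(iou)
    return {
        "large_mean_iou": float(np.mean(large)) if large else float("nan"),
        "small_mean_iou": float(np.mean(small)) if small else float("nan"),
        "n_large": len(large),
        "n_small": len(small),
    }


def evaluate_pair(gt: np.ndarray, pred: np.ndarray, cfg: MetricConfig = MetricConfig()) -> MatchResult:
    """Convenience: match one GT/pred mask pair at the configured thresholds."""
    return match_objects(pairwise_iou(gt, pred), cfg)


def evaluate_batch(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    cfg: MetricConfig = MetricConfig(),
    tau1_grid: tuple[float, ...] = DEFAULT_TAU1_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate many (gt, pred) mask pairs.

    Returns ``(per_image, summary)``: per-image contingencies and scores at
    the headline tau1, and a summary frame with avg and agg scores for every
    tau1 on the grid plus split/merge rates at the headline thresholds.
    """
    per_rows = []
    matches_by_tau: dict[float, list[MatchResult]] = {t: [] for t in tau1_grid}
    head_matches: list[MatchResult] = []
    for i, (gt, pred) in enumerate(pairs):
        table = pairwise_iou(gt, pred)
        m = match_objects(table, cfg)
        head_matches.append(m)
        per_rows.append(
            {
                "image": i,
                "n_gt": m.n_gt, "n_pred": m.n_pred,
                "tp": m.tp, "fp": m.fp, "fn": m.fn, "ia": m.ia,
                "splits": m.splits, "merges": m.merges,
                "adapted_f1": adapted_f1(m, cfg.eps),
                "conventional_f1": conventional_f1(m, cfg.eps),
                "empty_agreement": m.n_gt == 0 and m.n_pred == 0,
            }
        )
        for t1 in tau1_grid:
            matches_by_tau[t1].append(
                match_objects(table, MetricConfig(tau1=t1, tau2=cfg.tau2, eps=cfg.eps))
            )
    sum_rows = []
    for t1 in tau1_grid:
        ms = matches_by_tau[t1]
        sum_rows.append(
            {
                "tau1": t1,
                "adapted_f1_avg": dataset_score(ms, "avg", "adapted_f1", cfg.eps),
                "adapted_f1_agg": dataset_score(ms, "agg", "adapted_f1", cfg.eps),
                "conventional_f1_avg": dataset_score(ms, "avg", "conventional_f1", cfg.eps),
                "conventional_f1_agg": dataset_score(ms, "agg", "conventional_f1", cfg.eps),
            }
        )
    summary = pd.DataFrame(sum_rows)
    rates = split_merge_rate(head_matches)
    for k, v in rates.items():
        summary[k] = v
    return pd.DataFrame(per_rows), summary
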