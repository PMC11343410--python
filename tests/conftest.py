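import numpy as np
import pytest

from nucseg.synthetic import SyntheticConfig, generate_mask


@pytest.fixture(scope="session")
def small_mask() -> np.ndarray:
    """A deterministic sparse mask with a handful of cells."""
    return generate_mask(SyntheticConfig(image_size=128, n_cells=(4, 6), seed=11))


def random_label_pair(rng: np.random.Generator, size: int = 48, n: int = 4):
    """A (gt, pred) mask pair with random blobs and perturbed copies.

    Produces the full range of matching outcomes: exact matches, shifts of
    varying IOU, drops, spurious predictions, splits and merges.
    """
    from scipy import ndimage as ndi

    gt = np.zeros((size, size), dtype=np.int32)
    label = 0
    for _ in range(n):
        r = int(rng.integers(3, 9))
        cy, cx = rng.integers(r, size - r, 2)
        yy, xx = np.ogrid[:size, :size]
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        blob &= gt == 0
        if blob.sum() < 4:
            continue
        label += 1
        gt[blob] = label

    pred = np.zeros_like(gt)
    plabel = 0
    for g in range(1, label + 1):
        obj = gt == g
        u = rng.uniform()
        if u < 0.15:
            continue  # dropped -> FN
        dy, dx = rng.integers(-4, 5, 2)
        shifted = np.roll(np.roll(obj, dy, axis=0), dx, axis=1)
        if u < 0.75:
            plabel += 1
            pred[shifted & (pred == 0)] = plabel
        else:  # split the object into two pieces
            ys, xs = np.nonzero(shifted)
            if len(ys) < 6:
                plabel += 1
                pred[shifted & (pred == 0)] = plabel
                continue
            cut = int(np.median(ys))
            for sel in (ys <= cut, ys > cut):
                if sel.any():
                    plabel += 1
                    m = np.zeros_like(obj)
                    m[ys[sel], xs[sel]] = True
                    pred[m & (pred == 0)] = plabel
    # occasionally add a spurious prediction
    if rng.uniform() < 0.4:
        r = int(rng.integers(2, 5))
        cy, cx = rng.integers(r, size - r, 2)
        yy, xx = np.ogrid[:size, :size]
        blob = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2) & (pred == 0)
        if blob.sum() >= 3:
            plabel += 1
            pred[blob] = plabel
    # occasionally merge two predicted objects
    if plabel >= 2 and rng.uniform() < 0.3:
        a, b = rng.choice(np.arange(1, plabel + 1), 2, replace=False)
        pred[pred == b] = a
        grown_a = ndi.binary_dilation(pred == a, iterations=2)
        pred[grown_a & (pred == 0)] = a
    return gt, pred


def brute_force_contingency(gt, pred, tau1=0.6, tau2=0.1):
    """Literal rule application over exhaustive per-object pixel overlaps.

    Written directly from the category definitions with plain Python loops
    and boolean masks; shares no code with the package's vectorised path.
    """
    gt_labels = sorted(int(v) for v in np.unique(gt) if v > 0)
    pred_labels = sorted(int(v) for v in np.unique(pred) if v > 0)
    iou = {}
    for g in gt_labels:
        gm = gt == g
        for p in pred_labels:
            pm = pred == p
            inter = int(np.logical_and(gm, pm).sum())
            if inter > 0:
                iou[(g, p)] = inter / int(np.logical_or(gm, pm).sum())
    tp = fn = ia = splits = 0
    for g in gt_labels:
        partners = {p: v for (gg, p), v in iou.items() if gg == g}
        if any(v > tau1 for v in partners.values()):
            tp += 1
        else:
            band = [p for p, v in partners.items() if tau2 < v <= tau1]
            if len(band) > 1:
                splits += 1
            elif len(band) == 1:
                ia += 1
            else:
                fn += 1
    fp = merges = 0
    for p in pred_labels:
        partners = {g: v for (g, pp), v in iou.items() if pp == p}
        if not partners or max(partners.values()) <= tau2:
            fp += 1
        if sum(1 for v in partners.values() if tau2 < v <= tau1) > 1:
            merges += 1
    return dict(tp=tp, fp=fp, fn=fn, ia=ia, splits=splits, merges=merges,
                n_gt=len(gt_labels), n_pred=len(pred_labels))
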