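"""Synthetic low-magnification bright-field benchmark images.

Generates paired pseudo-bright-field images and ground-truth nucleus label
masks so segmentation, training, and evaluation can be exercised without any
microscope data.  The content emulates what low-magnification transmitted
light actually shows: round cells and more irregular cells with protruding
pseudopodia, cell areas spanning roughly an order of magnitude, a bright
refractive halo at object boundaries, weak interior contrast, additive
sensor noise, and a smooth multiplicative illumination gradient.  A dense
seeding mode emulates high cell-density fields where undersegmentation
(merging of touching nuclei) becomes the dominant failure mode.

The module also produces *controlled mask corruptions* (drop, shift, split,
merge, boundary jitter) together with the contingency outcome each one must
produce under the dual-threshold matching rules, computed here directly from
pixel overlaps.  These fixtures are the ground truth the evaluation suite is
tested against.

Determinism: one global integer seed drives a per-image stream derived as
``seed + image_index``, so a dataset can be extended without altering
already-generated images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

from .imgio import FileList, IntensityImage, write_file_list, write_mask


@dataclass(frozen=True)
class SyntheticConfig:
    """Rendering and placement parameters for one synthetic field of view.

    Radii default to (4, 14) px: the area ratio between the largest and
    smallest cells is then (14/4)^2 ~ 12, i.e. cell areas span an order of
    magnitude.  ``density_mode`` switches between tracking-style sparse
    fields and densely seeded fields (several-fold more cells, smaller
    placement margin).
    """

    image_size: int = 256
    n_cells: tuple[int, int] = (5, 12)
    radius_range: tuple[float, float] = (4.0, 14.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.7)
    lobe_amplitude: float = 0.25       # radial boundary perturbation (fraction of radius)
    pseudopodia_prob: float = 0.4      # chance a cell gets strong protrusions
    halo_strength: float = 0.35        # brightness of the refractive rim
    contrast: float = 0.18             # interior darkening vs background
    noise_sd: float = 0.03             # additive Gaussian noise (fraction of range)
    illumination_gradient: float = 0.15
    density_mode: str = "sparse"
    margin_px: int = 2                 # minimum gap between placed objects
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] < 2:
            raise ValueError("minimum radius must be >= 2 px")
        if self.density_mode not in ("sparse", "dense"):
            raise ValueError(f"unknown density_mode {self.density_mode!r}")


def _dense_variant(config: SyntheticConfig) -> SyntheticConfig:
    lo, hi = config.n_cells
    return replace(config, n_cells=(4 * lo, 4 * hi), margin_px=1)


def _cell_polygon(rng: np.random.Generator, cy: float, cx: float, r: float,
                  ecc: float, lobes: float, n_vertices: int = 48):
    """Radially perturbed ellipse: round cell or pseudopodia-bearing cell."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    b = r * np.sqrt(1 - ecc**2)
    # low-order Fourier perturbation of the radius -> lobes / protrusions
    n_modes = rng.integers(2, 6)
    pert = np.zeros_like(theta)
    for m in rng.choice(np.arange(2, 8), size=n_modes, replace=False):
        pert += rng.uniform(0, lobes) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
    pert = np.clip(1.0 + pert, 0.4, 2.0)
    phi = rng.uniform(0, np.pi)
    x0 = r * np.cos(theta) * pert
    y0 = b * np.sin(theta) * pert
    ys = cy + x0 * np.sin(phi) + y0 * np.cos(phi)
    xs = cx + x0 * np.cos(phi) - y0 * np.sin(phi)
    return ys, xs


def generate_mask(config: SyntheticConfig) -> np.ndarray:
    """Place pairwise non-overlapping labelled cells; labels 1..n contiguous.

    When a cell cannot be placed without violating the margin after a
    bounded number of retries it is skipped, so fewer objects than requested
    may be present (recorded via the returned label count).
    """
    cfg = _dense_variant(config) if config.density_mode == "dense" else config
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    mask = np.zeros((size, size), dtype=np.int32)
    occupied = np.zeros((size, size), dtype=bool)  # objects + margin
    n_target = int(rng.integers(cfg.n_cells[0], cfg.n_cells[1] + 1))
    label = 0
    for _ in range(n_target):
        placed = False
        for _attempt in range(60):
            r = np.exp(rng.uniform(np.log(cfg.radius_range[0]), np.log(cfg.radius_range[1])))
            ecc = rng.uniform(*cfg.eccentricity_range)
            lobes = cfg.lobe_amplitude
            if rng.uniform() < cfg.pseudopodia_prob:
                lobes *= 2.5
            pad = r * (1 + 2.5 * lobes) + cfg.margin_px + 1
            if 2 * pad >= size:
                continue
            cy = rng.uniform(pad, size - pad)
            cx = rng.uniform(pad, size - pad)
            ys, xs = _cell_polygon(rng, cy, cx, r, ecc, lobes)
            rr, cc = draw_polygon(ys, xs, shape=mask.shape)
            if rr.size < 4:
                continue
            cand = np.zeros_like(occupied)
            cand[rr, cc] = True
            if (cand & occupied).any():
                continue
            label += 1
            mask[rr, cc] = label
            occupied |= ndi.binary_dilation(cand, iterations=cfg.margin_px)
            placed = True
            break
        if not placed:
            continue
    return mask


def _illumination(size: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / max(size - 1, 1)
    gy, gx = rng.uniform(-1, 1, 2)
    field_ = 1.0 + strength * (gy * (yy - 0.5) + gx * (xx - 0.5))
    return field_


def render_brightfield(mask: np.ndarray, config: SyntheticConfig) -> IntensityImage:
    """Render a pseudo-bright-field image for a label mask.

    Background sits at mid-grey; object interiors are slightly darker with a
    smooth texture; a bright halo rings each object; additive Gaussian noise
    and a multiplicative illumination gradient complete the render.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    fg = mask > 0
    img = np.full(mask.shape, 0.55, dtype=np.float64)

    if fg.any():
        # interior darkening with smooth per-pixel texture
        texture = ndi.gaussian_filter(rng.normal(0, 1, mask.shape), 2.0)
        texture /= max(np.abs(texture).max(), 1e-9)
        img[fg] -= config.contrast * (0.7 + 0.3 * texture[fg])
        # bright refractive rim just outside each object
        rim = ndi.binary_dilation(fg, iterations=2) & ~fg
        img[rim] += config.halo_strength
        inner_rim = fg & ~ndi.binary_erosion(fg, iterations=1)
        img[inner_rim] += 0.3 * config.halo_strength

    img *= _illumination(mask.shape[0], config.illumination_gradient, rng)
    img += rng.normal(0, config.noise_sd, mask.shape)
    out = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
    return IntensityImage(pixels=out, bit_depth=8)


def render_nuclear_channel(mask: np.ndarray, config: SyntheticConfig) -> IntensityImage:
    """Render a high-contrast fluorescent-marker-style nuclear channel."""
    rng = np.random.default_rng(config.seed + 2_000_003)
    img = np.where(mask > 0, 0.75, 0.05).astype(np.float64)
    img += rng.normal(0, config.noise_sd, mask.shape)
    out = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
    return IntensityImage(pixels=out, bit_depth=8)


# ---------------------------------------------------------------------------
# Controlled corruptions with geometrically computed expected contingencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorruptionSpec:
    """One corruption op applied to listed labels of a ground-truth mask.

    op: "drop" | "shift" | "split" | "merge" | "boundary_jitter"
    labels: labels the op applies to (merge needs exactly two)
    dx, dy: shift offsets; axis: 0/1 split axis; amplitude: jitter push (px)
    """

    op: str
    labels: tuple[int, ...]
    dx: int = 0
    dy: int = 0
    axis: int = 0
    amplitude: int = 1
    seed: int = 0


def _expected_contingency(gt: np.ndarray, pred: np.ndarray,
                          tau1: float, tau2: float) -> dict[str, int]:
    """Literal rule application from raw pixel overlaps (plain Python loops).

    Independent of the vectorised evaluation path; used as its oracle.
    """
    gt_labels = [int(v) for v in np.unique(gt) if v > 0]
    pred_labels = [int(v) for v in np.unique(pred) if v > 0]
    ious: dict[tuple[int, int], float] = {}
    for g in gt_labels:
        gm = gt == g
        for p in pred_labels:
            pm = pred == p
            inter = int(np.count_nonzero(gm & pm))
            if inter:
                union = int(np.count_nonzero(gm | pm))
                ious[(g, p)] = inter / union
    tp = fn = ia = splits = 0
    for g in gt_labels:
        pair = {p: i for (gg, p), i in ious.items() if gg == g}
        if any(i > tau1 for i in pair.values()):
            tp += 1
        else:
            band = [p for p, i in pair.items() if tau2 < i <= tau1]
            if len(band) > 1:
                splits += 1
            elif len(band) == 1:
                ia += 1
            else:
                fn += 1
    fp = merges = 0
    for p in pred_labels:
        pair = {g: i for (g, pp), i in ious.items() if pp == p}
        if not pair or max(pair.values()) <= tau2:
            fp += 1
        if len([g for g, i in pair.items() if tau2 < i <= tau1]) > 1:
            merges += 1
    return {
        "tp": tp, "fp": fp, "fn": fn, "ia": ia,
        "splits": splits, "merges": merges,
        "n_gt": len(gt_labels), "n_pred": len(pred_labels),
    }


def corrupt_mask(
    mask: np.ndarray,
    spec: CorruptionSpec,
    tau1: float = 0.6,
    tau2: float = 0.1,
) -> tuple[np.ndarray, dict[str, int]]:
    """Apply one controlled corruption; return it with its expected outcome.

    The expected contingency treats the input mask as ground truth and the
    corrupted mask as the prediction, with categories derived directly from
    exhaustive pixel-overlap counts.
    """
    mask = np.asarray(mask)
    present = set(int(v) for v in np.unique(mask) if v > 0)
    for lbl in spec.labels:
        if lbl not in present:
            raise ValueError(f"label {lbl} not present in mask")
    out = mask.copy()
    next_label = int(mask.max()) + 1

    if spec.op == "drop":
        for lbl in spec.labels:
            out[out == lbl] = 0
    elif spec.op == "shift":
        for lbl in spec.labels:
            obj = mask == lbl
            out[obj] = 0
            shifted = np.roll(np.roll(obj, spec.dy, axis=0), spec.dx, axis=1)
            # roll wraps; clear wrapped slices
            if spec.dy > 0:
                shifted[: spec.dy, :] = False
            elif spec.dy < 0:
                shifted[spec.dy :, :] = False
            if spec.dx > 0:
                shifted[:, : spec.dx] = False
            elif spec.dx < 0:
                shifted[:, spec.dx :] = False
            out[shifted & (out == 0)] = lbl
    elif spec.op == "split":
        for lbl in spec.labels:
            ys, xs = np.nonzero(mask == lbl)
            cut = int(np.rint((ys if spec.axis == 0 else xs).mean()))
            coord = ys if spec.axis == 0 else xs
            out[ys[coord == cut], xs[coord == cut]] = 0       # 1-px gap
            sel = coord > cut
            out[ys[sel], xs[sel]] = next_label
            next_label += 1
    elif spec.op == "merge":
        if len(spec.labels) != 2:
            raise ValueError("merge needs exactly two labels")
        a, b = spec.labels
        out[out == b] = a
        # bridge the gap so the merged object is plausible as one component
        bridge = ndi.binary_dilation(mask == a, iterations=2) & ndi.binary_dilation(
            mask == b, iterations=2
        )
        out[bridge & (out == 0)] = a
    elif spec.op == "boundary_jitter":
        rng = np.random.default_rng(spec.seed)
        for lbl in spec.labels:
            obj = out == lbl
            if rng.uniform() < 0.5:
                grown = ndi.binary_dilation(obj, iterations=spec.amplitude)
                out[grown & (out == 0)] = lbl
            else:
                shrunk = ndi.binary_erosion(obj, iterations=spec.amplitude)
                out[obj & ~shrunk] = 0
    else:
        raise ValueError(f"unknown corruption op {spec.op!r}")

    expected = _expected_contingency(mask, out, tau1, tau2)
    return out, expected


def generate_dataset(
    n_images: int, config: SyntheticConfig, out_dir: str | Path,
    write_nuclear: bool = False,
) -> FileList:
    """Write ``n_images`` paired bright-field PNGs and mask PNGs plus a CSV.

    Image ``i`` is generated from ``config.seed + i`` so regenerating with
    the same seed is byte-identical and datasets extend without reshuffling.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[tuple[Path, Path | None]] = []
    for i in range(n_images):
        cfg_i = replace(config, seed=config.seed + i)
        mask = generate_mask(cfg_i)
        bf = render_brightfield(mask, cfg_i)
        img_path = out_dir / f"bf_{i:04d}.png"
        mask_path = out_dir / f"mask_{i:04d}.png"
        from imageio.v3 import imwrite

        imwrite(img_path, bf.pixels)
        write_mask(mask, mask_path)
        if write_nuclear:
            imwrite(out_dir / f"nuc_{i:04d}.png", render_nuclear_channel(mask, cfg_i).pixels)
        rows.append((img_path, mask_path))
    fl = FileList(rows=rows)
    write_file_list(fl, out_dir / "file_list.csv")
    return fl
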