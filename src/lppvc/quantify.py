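"""Figures of merit and statistics for lesion quantification.

Lesion-to-background ratios (LBR) come in three flavours: the maximum voxel
(LBR_max), the mean within the half-max isocontour adapted to the
background level (LBR_A50), and the plain mean over the segmentation mask
(LBR_mean).  The effect of a correction is summarized as the relative LBR
change

    dLBR (%) = (LBR_corrected - LBR_uncorrected) / LBR_uncorrected * 100.

Plaques are classified by their maximum CT density into non-calcified
(HU < 110), light (110-210), medium (210-550) and heavy (>= 550) classes,
and LBR/dLBR trends against volume or density are summarized by the
hyperbolic fit y = A/x + B together with Pearson/Spearman correlations and
a one-sided paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import ImageVolume

PLAQUE_CLASSES = ("non-calcified", "light", "medium", "heavy")


# ---------------------------------------------------------------------------
# LBR figures of merit

def _background_mean(img: ImageVolume, background_mask: np.ndarray) -> float:
    if not background_mask.any():
        raise ValueError("background mask is empty")
    m = float(img.values[background_mask].mean())
    if m <= 0:
        raise ValueError("background mean must be positive")
    return m


def lbr_max(img: ImageVolume, lesion_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Maximum voxel in the lesion over the mean of the background VOIs."""
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    return float(img.values[lesion_mask].max()) / _background_mean(img, background_mask)


def lbr_mean(img: ImageVolume, lesion_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Mean over the segmentation mask over the background mean."""
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    return float(img.values[lesion_mask].mean()) / _background_mean(img, background_mask)


def lbr_a50(img: ImageVolume, lesion_mask: np.ndarray, background_mean: float) -> float:
    """Mean within the 50%-of-max isocontour adapted to the background.

    The isocontour threshold is (max + background)/2; only voxels connected
    to the maximum count.  The maximum voxel is always included, so the
    contour is never empty.
    """
    if background_mean <= 0:
        raise ValueError("background mean must be positive")
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    masked = np.where(lesion_mask, img.values, -np.inf)
    peak = np.unravel_index(np.argmax(masked), img.shape)
    vmax = img.values[peak]
    thr = 0.5 * (vmax + background_mean)
    cand = img.values >= thr
    labels, _ = ndimage.label(cand)
    contour = labels == labels[peak]
    return float(img.values[contour].mean()) / background_mean


def delta_lbr(lbr_pvc: float, lbr_nopvc: float) -> float:
    """Relative LBR change in percent; sign preserved."""
    if lbr_nopvc <= 0:
        raise ValueError("uncorrected LBR must be positive")
    return (lbr_pvc - lbr_nopvc) / lbr_nopvc * 100.0


def classify_plaque(hu_max: float) -> str:
    """Four-class calcification taxonomy by maximum plaque density.

    Boundaries: <110 non-calcified; 110 (the calcification threshold) up to
    210 light; 210-550 medium; >=550 heavy.
    """
    if not np.isfinite(hu_max):
        raise ValueError("HU value must be finite")
    if hu_max < 110:
        return "non-calcified"
    if hu_max < 210:
        return "light"
    if hu_max < 550:
        return "medium"
    return "heavy"


@dataclass
class LesionQuant:
    """Per-lesion quantification record."""

    lesion_id: int
    method: str
    lbr_max: float | None = None
    lbr_a50: float | None = None
    lbr_mean: float | None = None
    delta_lbr_max: float | None = None
    delta_lbr_mean: float | None = None
    volume_mm3: float | None = None
    hu_max: float | None = None
    plaque_class: str | None = None


# ---------------------------------------------------------------------------
# trend fitting and association statistics

@dataclass
class HyperbolicFit:
    """Least-squares fit of y = A/x + B (linear regression of y on 1/x)."""

    A: float
    B: float
    A_stderr: float
    B_stderr: float
    pearson_r: float
    spearman_s: float
    n: int


def fit_hyperbolic(x, y) -> HyperbolicFit:
    """Fit y = A/x + B by ordinary least squares in the variable 1/x and
    report Pearson/Spearman correlations of (x, y) alongside."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0):
        raise ValueError("all x must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    reg = stats.linregress(1.0 / x, y)
    if np.ptp(y) > 0:
        pear = stats.pearsonr(x, y).statistic
        spear = stats.spearmanr(x, y).statistic
    else:
        pear = spear = np.nan
    return HyperbolicFit(A=float(reg.slope), B=float(reg.intercept),
                         A_stderr=float(reg.stderr), B_stderr=float(reg.intercept_stderr),
                         pearson_r=float(pear), spearman_s=float(spear), n=len(x))


def association_stats(corrected, uncorrected, alternative: str = "greater") -> dict:
    """Pearson, Spearman, and a one-sided paired t-test on two paired samples.

    The default alternative tests whether the corrected values exceed the
    uncorrected ones.  Identical pairs give t = 0, p = 0.5 by convention;
    zero-variance inputs are rejected for Pearson and the t-test.
    """
    a = np.asarray(corrected, dtype=float)
    b = np.asarray(uncorrected, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two paired 1D samples with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance sample: Pearson and t undefined")
    n = len(a)
    d = a - b
    if np.ptp(d) == 0 and d[0] == 0:
        t, p = 0.0, 0.5
    else:
        res = stats.ttest_rel(a, b, alternative=alternative)
        t, p = float(res.statistic), float(res.pvalue)
    return {
        "pearson": float(stats.pearsonr(a, b).statistic),
        "spearman": float(stats.spearmanr(a, b).statistic),
        "t": t,
        "p": p,
        "df": n - 1,
    }


# ---------------------------------------------------------------------------
# background sampling and experiment tables

def background_voi_mask(body_mask: np.ndarray, lesion_masks, voxel_size_mm,
                        n_vois: int = 3, diameter_mm: float = 15.0,
                        clearance_mm: float = 25.0,
                        edge_clearance_mm: float = 10.0,
                        target_depth_mm: float = 25.0) -> np.ndarray:
    """Spherical background VOIs in lesion-free uniform body regions.

    Deterministic placement: candidate centers on a coarse grid are ranked
    by closeness of their depth inside the uniform region to
    ``target_depth_mm``, then taken greedily with at least two VOI
    diameters of spacing, ``edge_clearance_mm`` beyond the VOI radius from
    any boundary and ``clearance_mm`` from every lesion.  Moderate depth
    avoids both spill-over at compartment boundaries and the centre of the
    body, where attenuation is strongest and low-count reconstructions are
    noisiest.
    """
    from .phantoms import rasterize_sphere
    from .volume import centered_grid

    shape = body_mask.shape
    origin = centered_grid(shape, voxel_size_mm)
    lesions = np.zeros(shape, dtype=bool)
    for m in lesion_masks:
        lesions |= m
    dist_lesion = (ndimage.distance_transform_edt(~lesions, sampling=voxel_size_mm)
                   if lesions.any() else np.full(shape, np.inf))
    dist_edge = ndimage.distance_transform_edt(body_mask, sampling=voxel_size_mm)
    r = diameter_mm / 2.0
    ok = (dist_edge >= r + edge_clearance_mm) & (dist_lesion >= clearance_mm + r)
    step = max(1, int(round(diameter_mm / min(voxel_size_mm))) // 2)
    cand = []
    for ix in range(step, shape[0] - step, step):
        for iy in range(step, shape[1] - step, step):
            for iz in range(step, shape[2] - step, step):
                if ok[ix, iy, iz]:
                    cand.append((abs(dist_edge[ix, iy, iz] - target_depth_mm), ix, iy, iz))
    cand.sort()
    out = np.zeros(shape, dtype=bool)
    centers_taken: list[np.ndarray] = []
    for _, ix, iy, iz in cand:
        if len(centers_taken) >= n_vois:
            break
        c_mm = np.array([origin[a] + (ix, iy, iz)[a] * voxel_size_mm[a] for a in range(3)])
        if any(np.linalg.norm(c_mm - t) < 2 * diameter_mm for t in centers_taken):
            continue
        occ = rasterize_sphere(c_mm, diameter_mm, (shape, voxel_size_mm), supersample=1)
        out |= occ.values > 0.5
        centers_taken.append(c_mm)
    if len(centers_taken) < n_vois:
        raise ValueError(f"could only place {len(centers_taken)}/{n_vois} background VOIs")
    return out


def evaluate_phantom_experiment(phantom, images: dict[str, ImageVolume],
                                lp_ratios: dict[str, dict[int, float]] | None = None,
                                lesion_masks: dict[int, np.ndarray] | None = None,
                                background_mask: np.ndarray | None = None,
                                uncorrected: str = "OSEM") -> pd.DataFrame:
    """Per-lesion, per-method quantification table.

    ``images`` maps method-arm names (e.g. ``"OSEM"``, ``"OSEM+PVC"``) to
    reconstructed images; ``lp_ratios`` maps LP arm names to per-lesion
    fitted activity ratios.  The EXP arm is the phantom's intended
    (pre-rasterization) lesion-to-background ratio.  Missing arms yield rows
    with missing values rather than fabricated ones.
    """
    if lesion_masks is None:
        lesion_masks = {lid: phantom.lesion_mask(lid) for lid in phantom.intended}
    if background_mask is None:
        # fall back to smaller VOIs on reduced grids
        for diam, clear, edge in ((15.0, 25.0, 10.0), (10.0, 15.0, 5.0), (8.0, 8.0, 3.0)):
            try:
                background_mask = background_voi_mask(
                    phantom.body_mask, list(lesion_masks.values()),
                    phantom.activity.voxel_size_mm, diameter_mm=diam,
                    clearance_mm=clear, edge_clearance_mm=edge,
                    target_depth_mm=min(25.0, clear))
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not place background VOIs; pass background_mask")
    rows = []
    base_lbr: dict[int, float] = {}
    ref_img = images.get(uncorrected)
    for lid, mask in lesion_masks.items():
        meta = phantom.intended.get(lid, {})
        if ref_img is not None:
            base_lbr[lid] = lbr_max(ref_img, mask, background_mask)
        for arm, img in images.items():
            bg = _background_mean(img, background_mask)
            q = LesionQuant(
                lesion_id=lid, method=arm,
                lbr_max=lbr_max(img, mask, background_mask),
                lbr_a50=lbr_a50(img, mask, bg),
                lbr_mean=lbr_mean(img, mask, background_mask),
                volume_mm3=meta.get("volume_mm3"),
                hu_max=meta.get("hu"),
                plaque_class=classify_plaque(meta["hu"]) if "hu" in meta else None,
            )
            if arm != uncorrected and lid in base_lbr:
                q.delta_lbr_max = delta_lbr(q.lbr_max, base_lbr[lid])
            rows.append(q)
        for arm, ratios in (lp_ratios or {}).items():
            q = LesionQuant(lesion_id=lid, method=arm,
                            lbr_max=ratios.get(lid), volume_mm3=meta.get("volume_mm3"),
                            hu_max=meta.get("hu"),
                            plaque_class=classify_plaque(meta["hu"]) if "hu" in meta else None)
            if q.lbr_max is not None and lid in base_lbr:
                q.delta_lbr_max = delta_lbr(q.lbr_max, base_lbr[lid])
            rows.append(q)
        rows.append(LesionQuant(lesion_id=lid, method="EXP",
                                lbr_max=meta.get("activity", np.nan) / phantom.background_activity,
                                volume_mm3=meta.get("volume_mm3"), hu_max=meta.get("hu")))
    return pd.DataFrame([vars(r) for r in rows])
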