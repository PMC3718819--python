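"""Dim-particle enhancement: iterative self-overlay and contrast stretch.

Very dim mRNA puncta (~1 intensity unit above background) are invisible in
raw kymographs.  Repeatedly compositing a 50%-transparent copy of the
kymograph onto itself with the standard *overlay* blend raises the
contrast-to-noise ratio of faint coherent ridges, after which a clipped
contrast stretch (or inversion) makes them visible.  A paired ROI /
background-ROI control verifies the chain does not manufacture particles
out of noise.

Compositing runs in floating point on the 8-bit intensity scale (M = 255)
with clamping; quantizing to integers after every overlay would annihilate
sub-quantum dim signals, so rounding happens only on output.  Note the
*normal* blend is an exact no-op when an image is composited with itself —
only a non-linear blend can change the CNR — and that the raw overlay
iterate is monotone toward 0 below mid-gray, so the chain's final stretch
is what restores a displayable image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kymo import Kymograph

__all__ = [
    "EnhancementConfig",
    "iterative_overlay",
    "contrast_stretch",
    "enhance_dim_particles",
    "local_enhancement_control",
    "contrast_to_noise",
]

M = 255.0


@dataclass(frozen=True)
class EnhancementConfig:
    n_overlays: int = 300
    opacity: float = 0.5
    blend_mode: str = "overlay"  # 'overlay' | 'normal'
    invert: bool = False
    clip_percentiles: tuple[float, float] = (0.5, 99.5)
    # display exponent per noise SD for the final tone mapping (see
    # enhance_dim_particles); 0.5 is conservative and never loses CNR
    display_gamma: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.opacity <= 1.0:
            raise ValueError("opacity must lie in (0, 1]")
        if self.n_overlays < 1:
            raise ValueError("n_overlays must be >= 1")
        if self.blend_mode not in ("overlay", "normal"):
            raise ValueError("blend_mode must be 'overlay' or 'normal'")


def _to_8bit_scale(matrix: np.ndarray) -> np.ndarray:
    """Working copy on the [0, 255] scale (affine rescale only if needed)."""
    out = np.asarray(matrix, dtype=float)
    lo, hi = out.min(), out.max()
    if hi > M or lo < 0:
        if hi == lo:
            return np.zeros_like(out)
        out = (out - lo) / (hi - lo) * M
    return out.copy()


def blend_overlay(base: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Standard overlay transfer: B(b, t) = (b/M)(b + (2t/M)(M - b))."""
    return np.clip((base / M) * (base + (2.0 * top / M) * (M - base)), 0.0, M)


def iterative_overlay(kymo: Kymograph, cfg: EnhancementConfig) -> Kymograph:
    """Composite n_overlays transparent copies of the kymograph onto itself.

    I_0 is the source (8-bit scale) and
    I_{k+1} = (1 - opacity) * I_k + opacity * B(I_k, I_0),
    with B the configured blend function.  For blend 'normal', B(b, t) = t
    and I_0 is an exact fixed point: self-averaging alone cannot change
    anything.  The returned matrix is the float iterate (clamped to
    [0, 255]); quantization is left to the contrast stretch.
    """
    base = _to_8bit_scale(kymo.matrix)
    if cfg.invert:
        base = M - base
    top = base.copy()
    cur = base
    if cfg.blend_mode == "normal":
        # (1-a) I_k + a I_0 with I_0 fixed point: closed form, no iteration
        result = cur
    else:
        for _ in range(cfg.n_overlays):
            cur = np.clip((1.0 - cfg.opacity) * cur + cfg.opacity * blend_overlay(cur, top), 0.0, M)
        result = cur
    return Kymograph(
        matrix=result,
        pixel_size=kymo.pixel_size,
        frame_interval=kymo.frame_interval,
        channel=kymo.channel,
        path=kymo.path,
    )


def contrast_stretch(kymo: Kymograph, clip_range: tuple[float, float]) -> Kymograph:
    """Affine rescale of [lo, hi] to the full 8-bit range, clamped."""
    lo, hi = clip_range
    if lo >= hi:
        raise ValueError(f"clip_range requires lo < hi, got ({lo}, {hi})")
    out = np.clip((np.asarray(kymo.matrix, dtype=float) - lo) / (hi - lo) * M, 0.0, M)
    return Kymograph(
        matrix=np.round(out),
        pixel_size=kymo.pixel_size,
        frame_interval=kymo.frame_interval,
        channel=kymo.channel,
        path=kymo.path,
    )


def enhance_dim_particles(kymo: Kymograph, cfg: EnhancementConfig | None = None) -> Kymograph:
    """Full enhancement chain: iterative overlay, tone mapping, stretch.

    Many overlay iterations make the composite approximately exponential
    in the underlying intensity, with an exponent that keeps growing: past
    ~e^1 per noise SD the brightest background outliers dominate the image
    variance and the composite's contrast-to-noise ratio degrades.  The
    chain therefore renormalizes the composite in log domain to a fixed
    display exponent (``display_gamma`` per noise SD, estimated as the log
    image's SD) before the clipped 8-bit stretch.  A mildly convex tone
    curve strictly gains ridge CNR on Gaussian noise — the gain of
    y = e^(g·x/σ) is (e^g − 1)/sqrt(e^(g²) − 1) > 1 for 0 < g < ~1.6 —
    while the bounded exponent keeps the result stable.
    """
    cfg = cfg or EnhancementConfig()
    over = iterative_overlay(kymo, cfg)
    if cfg.blend_mode == "overlay":
        log_img = np.log(np.maximum(over.matrix, 1e-300))
        scale = log_img.std()
        z = (log_img - np.median(log_img)) / (scale if scale > 0 else 1.0)
        mapped = np.exp(cfg.display_gamma * z)
    else:
        mapped = over.matrix
    lo, hi = np.percentile(mapped, cfg.clip_percentiles)
    if hi <= lo:
        hi = lo + 1.0
    toned = Kymograph(
        matrix=mapped,
        pixel_size=kymo.pixel_size,
        frame_interval=kymo.frame_interval,
        channel=kymo.channel,
        path=kymo.path,
    )
    return contrast_stretch(toned, (lo, hi))


def contrast_to_noise(
    matrix: np.ndarray, ridge_cols: slice | np.ndarray, background_cols: np.ndarray
) -> float:
    """(ridge mean - background mean) / background SD."""
    ridge = np.asarray(matrix, dtype=float)[:, ridge_cols]
    bg = np.asarray(matrix, dtype=float)[:, background_cols]
    sd = bg.std()
    if sd == 0:
        raise ValueError("background has zero variance; CNR undefined")
    return float((ridge.mean() - bg.mean()) / sd)


def _crop(kymo: Kymograph, roi: tuple[int, int, int, int]) -> Kymograph:
    r0, r1, c0, c1 = roi
    return Kymograph(
        matrix=kymo.matrix[r0:r1, c0:c1].copy(),
        pixel_size=kymo.pixel_size,
        frame_interval=kymo.frame_interval,
        channel=kymo.channel,
    )


def _rois_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]


def local_enhancement_control(
    kymo: Kymograph,
    roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int],
    cfg: EnhancementConfig | None = None,
    detection_cfg=None,
) -> dict[str, bool]:
    """False-positive control for local enhancement.

    Applies the identical enhancement chain to a candidate-particle ROI and
    a signal-free background ROI (both (row0, row1, col0, col1), half-open)
    and runs ridge detection + linking in each.  A valid configuration must
    not create a detection in the pure-noise region.
    """
    from .track import DetectionConfig, detect_peaks, link_trajectories

    if _rois_overlap(roi, background_roi):
        raise ValueError("roi and background_roi must be disjoint")
    cfg = cfg or EnhancementConfig()
    if detection_cfg is None:
        # thresholds for the stretched 8-bit domain; tight linking window
        # because candidate ridges in the control are near-vertical
        detection_cfg = DetectionConfig(
            min_prominence=100.0,
            min_separation=0.5,
            max_step=0.5,
            max_gap=1,
            min_track_len=10,
            smooth_sigma_px=1.0,
        )

    report = {}
    for name, region in (("roi_detected", roi), ("background_detected", background_roi)):
        sub = enhance_dim_particles(_crop(kymo, region), cfg)
        detections = detect_peaks(sub, detection_cfg)
        tracks = link_trajectories(detections, detection_cfg, frame_interval=kymo.frame_interval)
        report[name] = len(tracks) > 0
    return report
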