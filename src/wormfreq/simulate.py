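"""Synthetic dark-field worm videos with known locomotor frequency.

The simulated animal is a bright, tapered ribbon whose centerline carries a
traveling sinusoidal body wave of frequency ``f0`` (the undulation frequency
a swimming adult C. elegans exhibits, ~1.7 Hz), rigid-transformed by a
drifting heading and translation, on a dark background with static stray
light (so background subtraction is exercised).  The body carries a fixed
brightness texture — a dominant bright segment, small granules, a mild
dorsoventral bias — plus a posture-locked whole-body brightness modulation;
real dark-field worms show all of these, and without them the rendered
animal would be exactly mirror-symmetric half an undulation period apart.
Spatial/temporal downsampling and calibrated Gaussian noise reproduce
degraded recording conditions.

All randomness is owned by ``seed``; identical configs give bitwise-identical
videos.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .video import FrameStack

__all__ = ["WormSimConfig", "GroundTruth", "render_worm_video", "downsample", "add_noise"]


@dataclass
class WormSimConfig:
    """Simulation parameters.  Defaults emulate a freely swimming adult.

    f0: undulation frequency (Hz); wavelength/amplitude/thickness as fractions
    of body length; length_px: body length L in pixels; speed_px_s and
    heading_drift set the rigid drift; intensity: peak body brightness;
    background_frac: static background amplitude relative to body brightness.
    """

    f0: float = 1.7
    wavelength: float = 0.9
    amplitude: float = 0.12
    length_px: float = 60.0
    thickness: float = 0.06  # max half-width as a fraction of L
    speed_px_s: float = 20.0  # swimming adults translate ~1/3 body length per second
    heading_drift: float = 0.2  # rad/s
    fps: float = 30.0
    duration_s: float = 10.0
    image_hw: tuple[int, int] = (240, 240)
    intensity: float = 200.0
    background_frac: float = 0.1
    # body-fixed intensity texture (dark-field realism: a brightest body
    # segment, scattering granules, and dorsoventrally biased brightness;
    # without it the rendered animal is exactly mirror-symmetric half an
    # undulation period apart, which no real worm image is)
    texture_strength: float = 0.25  # along-body brightness modulation
    cross_asymmetry: float = 0.25  # linear brightness bias across the body
    bright_segment: float = 0.8  # amplitude of the dominant bright segment
    n_speckles: int = 6  # small bright body-fixed granules
    speckle_strength: float = 0.4
    # posture-locked whole-body brightness modulation: dark-field scattering
    # depends on the body's tilt, which cycles with the undulation, so overall
    # brightness oscillates at f0 (one bright and one dim phase per cycle)
    scatter_modulation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 < 0:
            raise ValueError("f0 must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.length_px < 4:
            raise ValueError("length_px must be >= 4")


@dataclass
class GroundTruth:
    f0: float
    centerlines: np.ndarray  # (T, S, 2) float, (row, col) per sample
    masks: np.ndarray  # (T, H, W) bool body-pixel masks


def _static_background(h: int, w: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Static stray-light pattern: a dim pedestal with a gentle gradient and
    one broad bump, as dark-field illumination leaves everywhere."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    gx, gy = rng.uniform(-1, 1, 2)
    plane = (gx * xx / max(w - 1, 1) + gy * yy / max(h - 1, 1) + 1.0) / 2.0
    cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
    sig = 0.4 * min(h, w)
    bump = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)))
    pattern = 0.55 + 0.45 * (0.5 * plane + 0.5 * bump)
    pattern /= max(pattern.max(), 1e-12)
    return amplitude * pattern


def render_worm_video(config: WormSimConfig) -> tuple[FrameStack, GroundTruth]:
    """Render the video and its ground truth (centerlines, body masks)."""
    h, w = config.image_hw
    ell = config.length_px
    amp = config.amplitude * ell
    w0 = config.thickness * ell
    # bounding radius of the body around its center
    radius = ell / 2.0 + amp + w0 + 2.0
    if 2 * radius >= min(h, w):
        raise ValueError(
            f"worm (extent ~{2 * radius:.0f} px) does not fit the {h}x{w} frame"
        )

    rng = np.random.default_rng(config.seed)
    t_count = max(1, int(round(config.duration_s * config.fps)))
    dt = 1.0 / config.fps

    phase0 = rng.uniform(0, 2 * np.pi)
    theta0 = rng.uniform(0, 2 * np.pi)
    lo = radius + 1.0
    cy = rng.uniform(lo, h - radius - 1.0)
    cx = rng.uniform(lo, w - radius - 1.0)
    heading_sign = rng.choice([-1.0, 1.0])

    n_s = max(64, int(2 * ell))
    s = np.linspace(0.0, 1.0, n_s)
    half_width = w0 * np.sqrt(np.clip(1.0 - (2 * s - 1.0) ** 2, 0.0, None))

    # body-fixed brightness texture, frozen at t=0 and carried by the body
    ridge = np.ones(n_s)
    for m in (1, 2, 3):
        ridge += rng.uniform(0, config.texture_strength / m) * np.cos(
            2 * np.pi * m * s + rng.uniform(0, 2 * np.pi)
        )
    ridge = np.clip(ridge, 0.2, None)
    # one dominant bright segment (anterior gut region) + small granules
    n_spk = config.n_speckles + 1
    spk_s = np.concatenate([[rng.uniform(0.2, 0.5)], rng.uniform(0.08, 0.92, config.n_speckles)])
    spk_d = np.concatenate(
        [[0.0], rng.uniform(-0.6, 0.6, config.n_speckles) * np.interp(spk_s[1:], s, half_width)]
    )
    spk_amp = np.concatenate(
        [[config.bright_segment], rng.uniform(0.3, 1.0, config.n_speckles) * config.speckle_strength]
    )
    spk_sig_s = np.concatenate([[0.08], np.full(config.n_speckles, 0.03)])  # body-length fraction
    spk_sig_d = np.concatenate(
        [[max(0.6 * w0, 1.0)], np.full(config.n_speckles, max(0.35 * w0, 0.8))]
    )  # px

    bg = _static_background(h, w, config.background_frac * config.intensity, rng)

    frames = np.empty((t_count, h, w), dtype=np.float64)
    masks = np.zeros((t_count, h, w), dtype=bool)
    centerlines = np.empty((t_count, n_s, 2), dtype=np.float64)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = theta0
    for ti in range(t_count):
        t = ti * dt
        # body-frame centerline: traveling wave
        bx = (s - 0.5) * ell
        by = amp * np.sin(2 * np.pi * s / config.wavelength - 2 * np.pi * config.f0 * t + phase0)
        ct, st = np.cos(theta), np.sin(theta)
        px = cx + ct * bx - st * by
        py = cy + st * bx + ct * by
        centerlines[ti, :, 0] = py
        centerlines[ti, :, 1] = px

        # render inside the bounding box only
        r0 = max(int(py.min() - w0 - 2), 0)
        r1 = min(int(py.max() + w0 + 3), h)
        c0 = max(int(px.min() - w0 - 2), 0)
        c1 = min(int(px.max() + w0 + 3), w)
        sub_y = yy[r0:r1, c0:c1].ravel()
        sub_x = xx[r0:r1, c0:c1].ravel()
        # distance from each pixel to the nearest centerline sample, with that
        # sample's half-width -> approximate signed distance to the body surface
        d2 = (sub_y[:, None] - py[None, :]) ** 2 + (sub_x[:, None] - px[None, :]) ** 2
        k = np.argmin(d2, axis=1)
        pick = np.arange(len(k))
        dist = np.sqrt(d2[pick, k])
        sd = dist - half_width[k]
        ramp = np.clip(0.5 - sd, 0.0, 1.0)

        # signed across-body offset via the local centerline normal
        tx = np.gradient(px)
        ty = np.gradient(py)
        tn = np.hypot(tx, ty)
        nx, ny = -ty / tn, tx / tn
        d_signed = (sub_y - py[k]) * ny[k] + (sub_x - px[k]) * nx[k]
        wk = np.maximum(half_width[k], 0.5)
        texture = ridge[k] * (1.0 + config.cross_asymmetry * np.clip(d_signed / wk, -1.2, 1.2))
        for j in range(n_spk):
            texture += spk_amp[j] * np.exp(
                -((s[k] - spk_s[j]) ** 2) / (2 * spk_sig_s[j] ** 2)
                - ((d_signed - spk_d[j]) ** 2) / (2 * spk_sig_d[j] ** 2)
            )
        glow = 1.0 + config.scatter_modulation * np.sin(2 * np.pi * config.f0 * t + phase0 + 0.7)
        body = config.intensity * glow * ramp * np.clip(texture, 0.0, None)
        frame = bg.copy()
        frame[r0:r1, c0:c1] += body.reshape(r1 - r0, c1 - c0)
        frames[ti] = frame
        masks[ti, r0:r1, c0:c1] = (sd < 0).reshape(r1 - r0, c1 - c0)

        # rigid drift with reflection at the borders
        theta += heading_sign * config.heading_drift * dt
        cx += config.speed_px_s * dt * np.cos(theta)
        cy += config.speed_px_s * dt * np.sin(theta)
        if cx < radius + 1 or cx > w - radius - 1:
            cx = np.clip(cx, radius + 1, w - radius - 1)
            theta = np.pi - theta
        if cy < radius + 1 or cy > h - radius - 1:
            cy = np.clip(cy, radius + 1, h - radius - 1)
            theta = -theta

    stack = FrameStack(frames, fps=config.fps)
    truth = GroundTruth(f0=config.f0, centerlines=centerlines, masks=masks)
    return stack, truth


def downsample(stack: FrameStack, spatial_factor: int = 1, temporal_factor: int = 1) -> FrameStack:
    """Block-average spatially and keep every k-th frame (fps divided by k)."""
    if spatial_factor < 1 or temporal_factor < 1:
        raise ValueError("downsampling factors must be >= 1")
    t, h, w = stack.shape
    if spatial_factor > min(h, w) or temporal_factor > t:
        raise ValueError("downsampling factor exceeds stack dimensions")
    frames = stack.frames
    if temporal_factor > 1:
        frames = frames[::temporal_factor]
    if spatial_factor > 1:
        hh = (h // spatial_factor) * spatial_factor
        ww = (w // spatial_factor) * spatial_factor
        f = frames[:, :hh, :ww]
        f = f.reshape(f.shape[0], hh // spatial_factor, spatial_factor, ww // spatial_factor, spatial_factor)
        frames = f.mean(axis=(2, 4))
    return FrameStack(frames, fps=stack.fps / temporal_factor, pixel_size=stack.pixel_size)


def add_noise(stack: FrameStack, snr_db: float, seed: int = 0) -> FrameStack:
    """Additive zero-mean Gaussian noise at a requested whole-frame SNR.

    sigma^2 = P_signal / 10^(snr_db/10) with P_signal the mean squared
    intensity over all frames; the result is clamped at zero.  An infinite
    ``snr_db`` is the identity.
    """
    if np.isinf(snr_db) and snr_db > 0:
        return FrameStack(stack.frames.copy(), fps=stack.fps, pixel_size=stack.pixel_size)
    p_signal = float(np.mean(stack.frames**2))
    if p_signal <= 0:
        raise ValueError("cannot set an SNR on an all-zero stack")
    sigma = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = stack.frames + rng.normal(0.0, sigma, size=stack.frames.shape)
    np.clip(noisy, 0.0, None, out=noisy)
    return FrameStack(noisy, fps=stack.fps, pixel_size=stack.pixel_size)
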