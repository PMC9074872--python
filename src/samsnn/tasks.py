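"""Seeded synthetic generators for every learning task.

All generators are pure functions of their seed (identical seeds give
bit-identical outputs) and produce class-balanced, validated spike rasters, so
the whole repository builds and tests without any external data:

* five-class noisy spike-pattern sets (Poisson templates + Gaussian timing
  jitter + random spike deletion),
* eight oriented-bar 27x27 images with noisy pixels, Bernoulli-rate encoded,
* the 40-channel store-recall working-memory stream,
* threshold-crossing sequential encoding of 28x28 grayscale images, with a
  synthetic seven-segment "digit-like" image generator standing in for
  handwritten digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .network import SpikeRaster

__all__ = [
    "PatternSet",
    "make_pattern_set",
    "make_feature_images",
    "encode_image_rates",
    "StoreRecallSample",
    "make_store_recall",
    "encode_sequential_image",
    "make_digit_like_images",
]


# --------------------------------------------------------------------------
# Noisy spike-pattern classification
# --------------------------------------------------------------------------

@dataclass
class PatternSet:
    """Per-class spike templates plus jittered/thinned labeled instances."""

    templates: List[SpikeRaster]
    samples: List[SpikeRaster]
    labels: np.ndarray
    n_classes: int
    jitter_std: float     # ms
    deletion_prob: float

    def dense(self) -> Tuple[np.ndarray, np.ndarray]:
        """Samples as a dense ``(N, T, n_in)`` float array with labels."""
        X = np.stack([s.to_dense() for s in self.samples]).astype(float)
        return X, self.labels


def jitter_spike_times(
    steps: np.ndarray,
    jitter_std: float,
    horizon: int,
    rng: np.random.Generator,
    dt: float = 1.0,
) -> np.ndarray:
    """Displace spike steps by rounded Gaussian noise of std ``jitter_std`` ms,
    clipping the results to ``[0, horizon)``."""
    if jitter_std <= 0 or steps.size == 0:
        return steps.copy()
    moved = steps + np.round(rng.normal(0.0, jitter_std / dt, steps.shape))
    return np.clip(moved, 0, horizon - 1).astype(np.int64)


def make_pattern_set(
    n_classes: int = 5,
    n_input: int = 80,
    horizon: int = 2000,
    jitter_std: float = 0.0,
    deletion: float = 0.0,
    n_per_class: int = 10,
    rate_hz: float = 50.0,
    seed: int = 0,
    dt: float = 1.0,
) -> PatternSet:
    """Generate a class-balanced noisy spike-pattern classification set.

    Templates are Poisson spike rasters (``rate_hz`` per channel) drawn once
    per class and fixed; each instance jitters every template spike by
    Gaussian noise of standard deviation ``jitter_std`` ms (times clipped to
    the horizon) and then deletes spikes independently with probability
    ``deletion``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if not 0.0 <= deletion < 1.0:
        raise ValueError("deletion must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = rate_hz * dt / 1000.0
    templates = [
        SpikeRaster.from_dense(rng.random((horizon, n_input)) < p)
        for _ in range(n_classes)
    ]
    samples: List[SpikeRaster] = []
    labels: List[int] = []
    for _ in range(n_per_class):
        for c in range(n_classes):
            ev = templates[c].events
            steps = jitter_spike_times(ev[:, 0], jitter_std, horizon, rng, dt)
            neurons = ev[:, 1]
            if deletion > 0 and ev.size:
                keep = rng.random(ev.shape[0]) >= deletion
                steps, neurons = steps[keep], neurons[keep]
            dense = np.zeros((horizon, n_input), dtype=np.int8)
            dense[steps, neurons] = 1  # collisions collapse to one event
            samples.append(SpikeRaster.from_dense(dense))
            labels.append(c)
    return PatternSet(
        templates=templates, samples=samples, labels=np.asarray(labels),
        n_classes=n_classes, jitter_std=jitter_std, deletion_prob=deletion,
    )


# --------------------------------------------------------------------------
# Oriented-bar feature detection
# --------------------------------------------------------------------------

ORIENTATIONS = tuple(22.5 * i for i in range(8))


def make_feature_images(
    seed: int = 0,
    size: int = 27,
    noise_frac: float = 0.1,
    noise_std: float = 0.5,
    bar_halfwidth: float = 1.5,
) -> np.ndarray:
    """Eight oriented-bar images (0, 22.5, ..., 157.5 degrees) with noisy pixels.

    Each ``size x size`` image shows a bar through the center (pixels within
    ``bar_halfwidth`` of the oriented line are lit); ``round(noise_frac *
    size**2)`` randomly chosen pixels then receive additive Gaussian noise,
    and intensities are clipped to [0, 1].  Returns shape ``(8, size, size)``.
    """
    rng = np.random.default_rng(seed)
    c = (size - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(size) - c, np.arange(size) - c, indexing="ij")
    images = np.zeros((len(ORIENTATIONS), size, size))
    n_noisy = int(round(noise_frac * size * size))
    for k, deg in enumerate(ORIENTATIONS):
        theta = np.deg2rad(deg)
        # distance from pixel center to the line through the origin at angle theta
        dist = np.abs(-np.sin(theta) * xx + np.cos(theta) * yy)
        img = (dist <= bar_halfwidth).astype(float)
        flat_idx = rng.choice(size * size, size=n_noisy, replace=False)
        noise = rng.normal(0.0, noise_std, n_noisy)
        img.ravel()[flat_idx] += noise
        images[k] = np.clip(img, 0.0, 1.0)
    return images


def encode_image_rates(
    images: np.ndarray,
    duration: int = 100,
    r_max: float = 100.0,
    seed: int = 0,
    dt: float = 1.0,
) -> List[SpikeRaster]:
    """Bernoulli-rate encode images: pixel intensity -> spike probability per step."""
    rng = np.random.default_rng(seed)
    rasters = []
    for img in images:
        p = np.clip(img.ravel() * r_max * dt / 1000.0, 0.0, 1.0)
        dense = rng.random((duration, p.size)) < p
        rasters.append(SpikeRaster.from_dense(dense))
    return rasters


# --------------------------------------------------------------------------
# Store-recall working memory
# --------------------------------------------------------------------------

@dataclass
class StoreRecallSample:
    """One store-recall trial: 40-channel input raster plus recall targets.

    Channels 0-9 carry stream #1, 10-19 stream #2 (each frame's active bits
    spike throughout the frame), channels 20-29 the store command and 30-39
    the recall command (synchronous volleys over the whole command frame).
    ``target_bits[f]`` holds the 20 bits present at the most recent store;
    ``recall_mask[f]`` marks the frames where the readout is scored.
    """

    raster: SpikeRaster
    frame_types: np.ndarray   # 0 = data only, 1 = store, 2 = recall
    frame_bits: np.ndarray    # (n_frames, 20)
    target_bits: np.ndarray   # (n_frames, 20); valid where recall_mask
    recall_mask: np.ndarray   # (n_frames,) bool
    frame_len: int


def make_store_recall(
    n_frames: int = 10,
    frame_len: int = 150,
    p_store: float = 0.1,
    p_recall: float = 0.1,
    n_samples: int = 1,
    seed: int = 0,
    spike_period: int = 3,
    max_tries: int = 1000,
) -> List[StoreRecallSample]:
    """Generate store-recall trials (40 input channels).

    Frame types are drawn independently (store with ``p_store``, recall with
    ``p_recall``), re-drawn wholesale until the trial contains at least one
    store, at least one recall, and no recall before the first store.  Active
    bit channels and command channels emit regular spike trains with one
    spike every ``spike_period`` steps for the whole frame (command volleys
    are synchronous across their ten neurons).
    """
    rng = np.random.default_rng(seed)
    samples: List[StoreRecallSample] = []
    for _ in range(n_samples):
        for _try in range(max_tries):
            u = rng.random(n_frames)
            types = np.where(u < p_store, 1, np.where(u < p_store + p_recall, 2, 0))
            stores = np.flatnonzero(types == 1)
            recalls = np.flatnonzero(types == 2)
            if stores.size and recalls.size and recalls.min() > stores.min():
                break
        else:
            raise RuntimeError("could not draw a valid store-recall trial")
        bits = (rng.random((n_frames, 20)) < 0.5).astype(np.int8)
        dense = np.zeros((n_frames * frame_len, 40), dtype=np.int8)
        target = np.zeros((n_frames, 20), dtype=np.int8)
        recall_mask = types == 2
        stored: Optional[np.ndarray] = None
        train = np.zeros(frame_len, dtype=np.int8)
        train[::spike_period] = 1
        for f in range(n_frames):
            sl = slice(f * frame_len, (f + 1) * frame_len)
            dense[sl, :20] = train[:, None] * bits[f]
            if types[f] == 1:
                dense[sl, 20:30] = train[:, None]
                stored = bits[f]
            elif types[f] == 2:
                dense[sl, 30:40] = train[:, None]
                target[f] = stored
        samples.append(StoreRecallSample(
            raster=SpikeRaster.from_dense(dense), frame_types=types, frame_bits=bits,
            target_bits=target, recall_mask=recall_mask, frame_len=frame_len,
        ))
    return samples


# --------------------------------------------------------------------------
# Sequential image encoding
# --------------------------------------------------------------------------

def encode_sequential_image(
    image: np.ndarray,
    n_levels: int = 80,
    steps_per_pixel: int = 1,
) -> SpikeRaster:
    """Threshold-crossing sequential code for a grayscale image in [0, 1].

    Pixels are presented in raster order, one per ``steps_per_pixel`` steps.
    Channel ``c`` (threshold level ``theta_c``, levels evenly spaced in the
    open interval (0, 1)) fires at a pixel's step when the intensity crosses
    ``theta_c`` between the previous pixel (baseline 0 before the first) and
    the current one, in either direction.  A final cue channel fires at the
    last step, marking the end of the presentation; the horizon is exactly
    ``n_pixels * steps_per_pixel``.
    """
    img = np.asarray(image, dtype=float).ravel()
    if img.min() < 0 or img.max() > 1:
        raise ValueError("pixel values must be normalized to [0, 1]")
    if steps_per_pixel < 1:
        raise ValueError("steps_per_pixel must be >= 1")
    thresholds = (np.arange(n_levels) + 1.0) / (n_levels + 1.0)
    prev = np.concatenate([[0.0], img[:-1]])
    lo = np.minimum(prev, img)[:, None]
    hi = np.maximum(prev, img)[:, None]
    crossed = (lo < thresholds) & (thresholds <= hi)      # (n_pixels, n_levels)

    n_pixels = img.size
    horizon = n_pixels * steps_per_pixel
    dense = np.zeros((horizon, n_levels + 1), dtype=np.int8)
    dense[::steps_per_pixel, :n_levels] = crossed
    dense[-1, n_levels] = 1                               # end-of-image cue
    return SpikeRaster.from_dense(dense)


# Seven-segment layout: which segments are lit for each digit 0-9.
_SEGMENTS = {
    0: "abcdef", 1: "bc", 2: "abged", 3: "abgcd", 4: "fgbc",
    5: "afgcd", 6: "afgedc", 7: "abc", 8: "abcdefg", 9: "abcfgd",
}


def make_digit_like_images(
    n_per_class: int = 10,
    seed: int = 0,
    size: int = 28,
    noise_std: float = 0.1,
    max_shift: int = 2,
) -> Tuple[np.ndarray, np.ndarray]:
    """Synthetic digit-like 28x28 images (seven-segment strokes + jitter + noise).

    A stand-in for handwritten digits so nothing is downloaded: each class is
    a seven-segment glyph, randomly shifted by up to ``max_shift`` pixels and
    corrupted with Gaussian pixel noise, clipped to [0, 1].  Returns
    ``(images, labels)`` with exact class balance.
    """
    rng = np.random.default_rng(seed)
    t, m, b = 4, size // 2, size - 5
    l, r = 8, size - 9
    seg_pixels = {
        "a": [(t, x) for x in range(l, r + 1)],
        "g": [(m, x) for x in range(l, r + 1)],
        "d": [(b, x) for x in range(l, r + 1)],
        "f": [(y, l) for y in range(t, m + 1)],
        "b": [(y, r) for y in range(t, m + 1)],
        "e": [(y, l) for y in range(m, b + 1)],
        "c": [(y, r) for y in range(m, b + 1)],
    }
    images, labels = [], []
    for _ in range(n_per_class):
        for digit in range(10):
            img = np.zeros((size, size))
            for seg in _SEGMENTS[digit]:
                for y, x in seg_pixels[seg]:
                    img[y, x] = 1.0
            dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
            img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
            img = np.clip(img + rng.normal(0.0, noise_std, img.shape), 0.0, 1.0)
            images.append(img)
            labels.append(digit)
    return np.stack(images), np.asarray(labels)
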