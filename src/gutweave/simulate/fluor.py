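"""Synthetic fluorescence fields: Gaussian blobs in and out of a gut ROI.

Emulates single-channel images of transgenic reporter larvae (green
neutrophils, red macrophages) where a gut region of interest is drawn by hand
and cells inside it are counted.  Blobs are isotropic Gaussians of known
amplitude on a noisy background; centres are placed by rejection sampling
with a minimum separation of twice the blob radius so connected-component
counting can recover the planted truth exactly at sufficient signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from matplotlib.path import Path
from scipy import ndimage

_MAX_RETRIES = 10_000


@dataclass
class FluorSimConfig:
    image_size: int = 256
    roi: Sequence[tuple] = ((40, 40), (40, 200), (200, 200), (200, 40))  # (x, y)
    counts_per_channel: Mapping[str, tuple] = field(
        default_factory=lambda: {"green": (7, 3), "red": (5, 2)}
    )  # channel -> (inside ROI, outside ROI)
    blob_radius: float = 4.0
    intensity: float = 100.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.roi) < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")
        if self.blob_radius <= 0:
            raise ValueError("blob_radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for ch, (n_in, n_out) in self.counts_per_channel.items():
            if n_in < 0 or n_out < 0:
                raise ValueError(f"negative blob count for channel {ch!r}")


def _roi_mask(roi, size: int) -> np.ndarray:
    path = Path(np.asarray(roi, dtype=float))
    xx, yy = np.meshgrid(np.arange(size), np.arange(size))
    pts = np.column_stack([xx.ravel(), yy.ravel()]) + 0.0
    return path.contains_points(pts).reshape(size, size)


def simulate_fluorescence(config: FluorSimConfig):
    """Return (images, roi_vertices, truth).

    images : dict channel → float64 image.
    truth : channel → {"inside": n, "outside": n, "centres": [(x, y, in_roi)]}.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    inside = _roi_mask(config.roi, size)
    margin = int(np.ceil(3 * config.blob_radius)) + 1
    # keep centres clear of the ROI boundary so a blob's bright core cannot
    # straddle it and leak a countable fragment onto the wrong side
    clearance = 2.0 * config.blob_radius
    dist_in = ndimage.distance_transform_edt(inside)
    dist_out = ndimage.distance_transform_edt(~inside)

    yy, xx = np.mgrid[0:size, 0:size]
    images = {}
    truth = {}
    for channel, (n_in, n_out) in config.counts_per_channel.items():
        img = rng.normal(0.0, config.noise_sd, size=(size, size))
        centres = []
        placed = []

        def place(n_wanted: int, want_inside: bool) -> None:
            placed_here = 0
            retries = 0
            while placed_here < n_wanted:
                if retries > _MAX_RETRIES:
                    raise RuntimeError("could not place blobs at requested packing")
                x = rng.uniform(margin, size - margin)
                y = rng.uniform(margin, size - margin)
                dist = dist_in if want_inside else dist_out
                if dist[int(round(y)), int(round(x))] < clearance:
                    retries += 1
                    continue
                if any(np.hypot(x - px, y - py) < 2 * config.blob_radius + 2 for px, py in placed):
                    retries += 1
                    continue
                placed.append((x, y))
                centres.append((x, y, want_inside))
                placed_here += 1

        place(n_in, True)
        place(n_out, False)
        for x, y, _ in centres:
            img += config.intensity * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * (config.blob_radius / 2.0) ** 2)
            )
        images[channel] = img
        truth[channel] = {"inside": n_in, "outside": n_out, "centres": centres}

    return images, [tuple(v) for v in config.roi], truth
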