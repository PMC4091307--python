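"""Expression detection: segment ISH signal above tissue background.

Each section gets a robust global threshold: the background level is the
median of in-tissue pixel intensities and its spread is the median absolute
deviation scaled to an SD equivalent (x 1.4826). A pixel is "expressing"
when it is in tissue and strictly above ``b + k * max(s, s_min)``; the floor
``s_min`` keeps the threshold meaningful on noise-free images where the MAD
collapses to zero. No morphological cleanup is applied: the mask is a pure
pointwise function of the image, so it is idempotent and easy to reason
about, and a swappable detector can replace it wholesale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import NoTissueError, RegistrationError
from .synthetic import SectionImage

DEFAULT_K = 3.0
DEFAULT_S_MIN = 2.0


@dataclass
class ExpressionMask:
    """Boolean expression mask co-registered with its section image."""

    detected: np.ndarray  # bool, same shape as the image
    background_level: float
    spread: float
    threshold: float

    def save(self, png_path: str | Path, json_path: str | Path | None = None) -> None:
        png_path = Path(png_path)
        Image.fromarray(self.detected.astype(np.uint8) * 255).save(png_path)
        record = {
            "background_level": self.background_level,
            "spread": self.spread,
            "threshold": self.threshold,
            "n_detected": int(self.detected.sum()),
        }
        if json_path is None:
            json_path = png_path.with_suffix(".json")
        Path(json_path).write_text(json.dumps(record, indent=1))

    @classmethod
    def load(cls, png_path: str | Path, json_path: str | Path | None = None) -> "ExpressionMask":
        png_path = Path(png_path)
        if json_path is None:
            json_path = png_path.with_suffix(".json")
        record = json.loads(Path(json_path).read_text())
        detected = np.asarray(Image.open(png_path)) > 0
        return cls(
            detected=detected,
            background_level=float(record["background_level"]),
            spread=float(record["spread"]),
            threshold=float(record["threshold"]),
        )


def estimate_background(image: SectionImage) -> tuple[float, float]:
    """Robust background level and spread of a section.

    Returns ``(b, s)`` with b the median of in-tissue intensities and s the
    MAD scaled by 1.4826. Raises :class:`NoTissueError` on tissue-free images.
    """
    vals = image.pixels[image.tissue].astype(np.float64)
    if vals.size == 0:
        raise NoTissueError("section has no in-tissue pixels")
    b = float(np.median(vals))
    s = 1.4826 * float(np.median(np.abs(vals - b)))
    return b, s


def detect_expression(
    image: SectionImage,
    b: float,
    s: float,
    k: float = DEFAULT_K,
    s_min: float = DEFAULT_S_MIN,
) -> ExpressionMask:
    """Threshold a section: detected iff in tissue and intensity > b + k*max(s, s_min)."""
    if k <= 0:
        raise ValueError(f"threshold multiplier k must be positive, got {k}")
    threshold = b + k * max(s, s_min)
    detected = image.tissue & (image.pixels.astype(np.float64) > threshold)
    return ExpressionMask(
        detected=detected, background_level=b, spread=s, threshold=threshold
    )


def segment_section(
    image: SectionImage, k: float = DEFAULT_K, s_min: float = DEFAULT_S_MIN
) -> ExpressionMask:
    """Convenience: estimate background then detect, per section."""
    b, s = estimate_background(image)
    return detect_expression(image, b, s, k=k, s_min=s_min)


def mask_summary(mask: ExpressionMask, image: SectionImage) -> tuple[int, int, float]:
    """(n_detected, n_tissue, sum of detected-pixel intensity) for one section."""
    if mask.detected.shape != image.pixels.shape:
        raise RegistrationError(
            f"mask shape {mask.detected.shape} != image shape {image.pixels.shape}"
        )
    n_detected = int(mask.detected.sum())
    n_total = int(image.tissue.sum())
    total = float(image.pixels.astype(np.float64)[mask.detected].sum())
    return n_detected, n_total, total
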