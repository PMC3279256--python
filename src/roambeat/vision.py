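"""Correlation-filter recognition of artifacts in grayscale frame series.

One filter per artifact.  A filter is trained from one or more reference
images of the artifact (e.g., small pose or rotation variants of its visual
tag): each reference is made zero-mean and unit-energy and the composite
template is the frequency-domain average of their spectra.  Applying the
filter to a scene frame computes the normalized cross-correlation surface
(via FFT, valid where the template fully overlaps the frame) and returns the
global peak -- a similarity score in [-1, 1] and the 0-based (row, column)
coordinates where the artifact best matches, origin at the top-left.

A score of 1.0 occurs exactly when a verbatim copy of a single-reference
template appears in the frame.  Thresholding the per-frame peak scores (in
:func:`roambeat.io_streams.discretize_scores`) turns a frame series into the
same binary presence signal the other technologies produce, and each
transition keeps its frame time so beats link back to frame indexes.

Occlusion is not handled here; when the artifact is hidden the score simply
drops, and recovering the episode is left to the other sensor technologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .io_streams import BinarySignal, RawStream, discretize_scores

__all__ = [
    "Frame",
    "CorrelationFilter",
    "CorrelationResult",
    "build_composite_filter",
    "correlate",
    "recognize_series",
    "embed_template",
]

_EPS = 1e-10


@dataclass
class Frame:
    """One grayscale frame with its capture time (seconds)."""

    pixels: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 3:
            # Color frames are luminance-converted on load (ITU-R 601 weights).
            self.pixels = (
                0.299 * self.pixels[..., 0]
                + 0.587 * self.pixels[..., 1]
                + 0.114 * self.pixels[..., 2]
            )
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class CorrelationFilter:
    """Composite correlation template for one artifact."""

    artifact_id: str
    template_spectrum: np.ndarray
    template_size: tuple
    normalization: float  # energy of the spatial composite template
    spatial: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class CorrelationResult:
    """Peak of one normalized correlation surface."""

    peak_value: float
    peak_x: int  # column (0-based, origin top-left)
    peak_y: int  # row
    t: float


def build_composite_filter(references: Sequence[Frame], artifact_id: str) -> CorrelationFilter:
    """Average the normalized spectra of the reference images into one filter.

    Each reference is centered (zero mean) and scaled to unit energy before
    its FFT is taken, so no single bright reference dominates the composite.
    With a single reference this reduces to a normalized matched filter;
    duplicated references change nothing.
    """
    if not references:
        raise ValueError("need at least one reference image")
    shapes = {ref.shape for ref in references}
    if len(shapes) > 1:
        raise ValueError(f"reference images must share one shape, got {sorted(shapes)}")
    spectra = []
    for ref in references:
        centered = ref.pixels - ref.pixels.mean()
        energy = np.sqrt(np.sum(centered**2))
        if energy < _EPS:
            raise ValueError("a flat reference image carries no pattern to match")
        spectra.append(np.fft.fft2(centered / energy))
    composite_spectrum = np.mean(spectra, axis=0)
    spatial = np.real(np.fft.ifft2(composite_spectrum))
    spatial = spatial - spatial.mean()
    energy = float(np.sqrt(np.sum(spatial**2)))
    if energy < _EPS:
        raise ValueError("reference images cancel out; composite template is flat")
    return CorrelationFilter(
        artifact_id=artifact_id,
        template_spectrum=composite_spectrum,
        template_size=next(iter(shapes)),
        normalization=energy,
        spatial=spatial,
    )


def correlate(filt: CorrelationFilter, frame: Frame) -> CorrelationResult:
    """Normalized cross-correlation peak of the filter against one frame.

    The correlation surface is computed in the frequency domain and is valid
    only where the template fully overlaps the frame; the reported (row,
    column) is the template's top-left corner at the best match.  Windows
    with (numerically) zero variance score 0.  The score is invariant to any
    affine rescaling a*frame + b (a > 0) of the intensities.
    """
    th, tw = filt.template_size
    fh, fw = frame.shape
    if fh < th or fw < tw:
        raise ValueError(
            f"frame {frame.shape} smaller than template {filt.template_size}"
        )
    surface = correlation_surface(filt, frame)
    idx = int(np.argmax(surface))
    row, col = np.unravel_index(idx, surface.shape)
    return CorrelationResult(
        peak_value=float(surface[row, col]),
        peak_x=int(col),
        peak_y=int(row),
        t=frame.t,
    )


def correlation_surface(filt: CorrelationFilter, frame: Frame) -> np.ndarray:
    """Full valid-mode normalized cross-correlation surface."""
    template = filt.spatial / filt.normalization  # zero mean, unit energy
    pixels = frame.pixels
    th, tw = template.shape
    n = th * tw
    # Numerator: window-centered frame against zero-mean template; the local
    # mean term vanishes because the template sums to zero.
    num = _sig.fftconvolve(pixels, template[::-1, ::-1], mode="valid")
    ones = np.ones_like(template)
    win_sum = _sig.fftconvolve(pixels, ones, mode="valid")
    win_sq = _sig.fftconvolve(pixels**2, ones, mode="valid")
    win_var = win_sq - win_sum**2 / n
    scale = max(float(np.max(win_sq)), 1.0)
    win_var = np.where(win_var > _EPS * scale, win_var, np.inf)
    surface = num / np.sqrt(win_var)
    return np.clip(surface, -1.0, 1.0)


def recognize_series(
    filt: CorrelationFilter,
    frames: Sequence[Frame],
    threshold: float,
) -> tuple:
    """Score every frame and threshold the scores into a presence signal.

    Returns ``(scores, signal)``: the per-frame peak scores as a vision
    :class:`RawStream` and the :class:`BinarySignal` obtained by applying
    ``threshold`` (each transition carries its frame's time, so beats link
    back to frame indexes through a frame clock).
    """
    prev = None
    for frame in frames:
        if prev is not None and frame.t <= prev:
            raise ValueError("frames must be strictly time-ordered")
        prev = frame.t
    samples = []
    for frame in frames:
        result = correlate(filt, frame)
        samples.append((frame.t, result.peak_value))
    stream = RawStream(artifact_id=filt.artifact_id, technology="vision", samples=samples)
    return stream, discretize_scores(stream, threshold)


def embed_template(
    canvas: np.ndarray,
    template: np.ndarray,
    row: int,
    col: int,
) -> np.ndarray:
    """Return a copy of ``canvas`` with ``template`` pasted at (row, col).

    Convenience for building synthetic test scenes; the pasted block must fit
    inside the canvas.
    """
    canvas = np.array(canvas, dtype=float, copy=True)
    th, tw = template.shape
    if row < 0 or col < 0 or row + th > canvas.shape[0] or col + tw > canvas.shape[1]:
        raise ValueError("template does not fit in the canvas at that position")
    canvas[row : row + th, col : col + tw] = template
    return canvas
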