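"""Independent brute-force per-pixel reference implementations.

Each oracle is written as a direct transcription of the operation's
definition (explicit loops, clamped indexing for edge replication, sorted
windows for order statistics) and shares no code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def _clamp(i: int, n: int) -> int:
    return 0 if i < 0 else (n - 1 if i >= n else i)


def _disc_offsets(radius: float) -> list[tuple[int, int]]:
    r = int(math.floor(radius))
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def median3x3(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            vals = sorted(
                img[_clamp(y + dy, h), _clamp(x + dx, w)]
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
            )
            out[y, x] = vals[4]
    return out


def disc_median(img: np.ndarray, radius: float) -> np.ndarray:
    offs = _disc_offsets(radius)
    k = len(offs) // 2  # upper-middle order statistic for even counts
    h, w = img.shape
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            vals = sorted(img[_clamp(y + dy, h), _clamp(x + dx, w)] for dy, dx in offs)
            out[y, x] = vals[k]
    return out


def remove_outliers_oracle(
    img: np.ndarray, radius: float, threshold: float, mode: str
) -> np.ndarray:
    med = disc_median(img, radius)
    out = img.copy()
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            dev = float(img[y, x]) - float(med[y, x])
            if mode == "bright" and dev > threshold:
                out[y, x] = med[y, x]
            elif mode == "dark" and -dev > threshold:
                out[y, x] = med[y, x]
    return out


def variance_oracle(img: np.ndarray, radius: float) -> np.ndarray:
    offs = _disc_offsets(radius)
    h, w = img.shape
    out = np.empty((h, w), dtype=np.float64)
    for y in range(h):
        for x in range(w):
            vals = [float(img[_clamp(y + dy, h), _clamp(x + dx, w)]) for dy, dx in offs]
            m = sum(vals) / len(vals)
            out[y, x] = sum((v - m) ** 2 for v in vals) / len(vals)
    return out


def threshold_oracle(img: np.ndarray, lo: int, hi: int) -> np.ndarray:
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            if lo <= img[y, x] <= hi:
                out[y, x] = 255
    return out


def dilate_oracle(mask: np.ndarray, iterations: int) -> np.ndarray:
    fg = mask > 0
    for _ in range(iterations):
        acc = np.zeros_like(fg)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                shifted = np.zeros_like(fg)
                ys = slice(max(dy, 0), fg.shape[0] + min(dy, 0))
                yd = slice(max(-dy, 0), fg.shape[0] + min(-dy, 0))
                xs = slice(max(dx, 0), fg.shape[1] + min(dx, 0))
                xd = slice(max(-dx, 0), fg.shape[1] + min(-dx, 0))
                shifted[yd, xd] = fg[ys, xs]
                acc |= shifted
        fg = acc
    return fg.astype(np.uint8) * 255


def fill_holes_oracle(mask: np.ndarray) -> np.ndarray:
    """Flood-fill the background from every border pixel (4-connectivity)."""
    h, w = mask.shape
    bg = mask == 0
    reached = np.zeros((h, w), dtype=bool)
    queue: deque[tuple[int, int]] = deque()
    for x in range(w):
        for y in (0, h - 1):
            if bg[y, x] and not reached[y, x]:
                reached[y, x] = True
                queue.append((y, x))
    for y in range(h):
        for x in (0, w - 1):
            if bg[y, x] and not reached[y, x]:
                reached[y, x] = True
                queue.append((y, x))
    while queue:
        y, x = queue.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and bg[ny, nx] and not reached[ny, nx]:
                reached[ny, nx] = True
                queue.append((ny, nx))
    out = np.where(bg & ~reached, 255, mask).astype(np.uint8)
    return out


def rid_oracle(img: np.ndarray, roi: np.ndarray) -> float:
    total = 0.0
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            if roi[y, x] > 0:
                total += float(img[y, x])
    return total


def edm_oracle(height: int, width: int, centroid: tuple[float, float]) -> np.ndarray:
    cx, cy = centroid
    out = np.empty((height, width), dtype=np.float64)
    for y in range(height):
        for x in range(width):
            out[y, x] = math.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    return out


def hsb_oracle_pixel(r: int, g: int, b: int) -> tuple[float, float, float]:
    """Closed-form hexcone conversion for one pixel on the 8-bit scales.

    Returns continuous (hue, saturation, brightness) before rounding.
    """
    v = max(r, g, b)
    mn = min(r, g, b)
    delta = v - mn
    if delta == 0:
        h_deg = 0.0
    elif v == r:
        h_deg = (60.0 * ((g - b) / delta)) % 360.0
    elif v == g:
        h_deg = 60.0 * ((b - r) / delta + 2.0)
    else:
        h_deg = 60.0 * ((r - g) / delta + 4.0)
    s = 0.0 if v == 0 else 255.0 * delta / v
    return h_deg * 255.0 / 360.0, s, float(v)
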