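"""Synthetic labelled glyph images, IDX container I/O, and batching.

The glyph generator is the package's desk-scale stand-in for a
handwritten-digit dataset: each class is a fixed binary seven-segment
glyph stamped onto a small grayscale canvas with integer translation
jitter and additive Gaussian pixel noise, clipped to [0, 1].  Class
templates are mutually distinct, so the classes are separable by a
nearest-template classifier on clean images.  Real digit datasets can be
read from IDX-format image/label files (the MNIST container format).
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

IDX_IMAGE_MAGIC = 2051
IDX_LABEL_MAGIC = 2049

# seven-segment encoding per class: A top, B upper-right, C lower-right,
# D bottom, E lower-left, F upper-left, G middle
_SEGMENTS = {
    0: "ABCDEF", 1: "BC", 2: "ABGED", 3: "ABGCD", 4: "FGBC",
    5: "AFGCD", 6: "AFGEDC", 7: "ABC", 8: "ABCDEFG", 9: "ABCDFG",
}
N_TEMPLATES = len(_SEGMENTS)


class FormatError(ValueError):
    """Raised for malformed IDX files."""


@dataclass
class GlyphDatasetSpec:
    """Parameters of the synthetic glyph dataset."""

    image_side: int = 12
    n_classes: int = 10
    n_examples: int = 1000
    noise_sd: float = 0.05
    jitter: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes > N_TEMPLATES:
            raise ValueError(f"n_classes {self.n_classes} exceeds the "
                             f"{N_TEMPLATES} available glyph templates")
        if self.n_classes < 1 or self.n_examples < 1:
            raise ValueError("n_classes and n_examples must be >= 1")
        if self.image_side < 8:
            raise ValueError("image_side must be >= 8 to fit a glyph")
        if self.jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise_sd must be >= 0")


def glyph_template(digit: int, image_side: int) -> np.ndarray:
    """Binary (image_side, image_side) canvas with the class glyph centred,
    leaving a margin so jitter never clips strokes."""
    margin = max(2, image_side // 6)
    bh = image_side - 2 * margin
    bw = max(3, bh - 2)
    box = np.zeros((bh, bw))
    mid = bh // 2
    segs = _SEGMENTS[digit]
    if "A" in segs:
        box[0, :] = 1
    if "G" in segs:
        box[mid, :] = 1
    if "D" in segs:
        box[-1, :] = 1
    if "F" in segs:
        box[: mid + 1, 0] = 1
    if "B" in segs:
        box[: mid + 1, -1] = 1
    if "E" in segs:
        box[mid:, 0] = 1
    if "C" in segs:
        box[mid:, -1] = 1
    canvas = np.zeros((image_side, image_side))
    r0 = (image_side - bh) // 2
    c0 = (image_side - bw) // 2
    canvas[r0:r0 + bh, c0:c0 + bw] = box
    return canvas


def make_glyph_dataset(spec: GlyphDatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render ``spec.n_examples`` flattened images plus integer labels.

    Classes are balanced up to rounding; output is deterministic given
    ``spec.seed``.  Returns (images (n, side^2) in [0,1], labels (n,)).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_examples
    side = spec.image_side
    labels = np.tile(np.arange(spec.n_classes), n // spec.n_classes + 1)[:n]
    labels = labels[rng.permutation(n)]
    templates = [glyph_template(d, side) for d in range(spec.n_classes)]
    shifts = rng.integers(-spec.jitter, spec.jitter + 1, size=(n, 2))
    noise = rng.normal(0.0, spec.noise_sd, size=(n, side, side)) if spec.noise_sd > 0 \
        else np.zeros((n, side, side))
    images = np.empty((n, side * side))
    for k in range(n):
        img = templates[labels[k]]
        if spec.jitter > 0:
            img = np.roll(img, tuple(shifts[k]), axis=(0, 1))
        images[k] = np.clip(img + noise[k], 0.0, 1.0).ravel()
    return images, labels.astype(np.int64)


# ---------------------------------------------------------------------------
# IDX container I/O (big-endian; images magic 2051, labels magic 2049)

def read_idx_images(path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(16)
        if len(header) < 16:
            raise FormatError("truncated IDX image header")
        magic, n, rows, cols = struct.unpack(">iiii", header)
        if magic != IDX_IMAGE_MAGIC:
            raise FormatError(f"bad IDX image magic {magic} (expected {IDX_IMAGE_MAGIC})")
        payload = fh.read()
    data = np.frombuffer(payload, dtype=np.uint8)
    if data.size != n * rows * cols:
        raise FormatError("truncated IDX image payload")
    return data.reshape(n, rows * cols).astype(float) / 255.0


def read_idx_labels(path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(8)
        if len(header) < 8:
            raise FormatError("truncated IDX label header")
        magic, n = struct.unpack(">ii", header)
        if magic != IDX_LABEL_MAGIC:
            raise FormatError(f"bad IDX label magic {magic} (expected {IDX_LABEL_MAGIC})")
        payload = fh.read()
    data = np.frombuffer(payload, dtype=np.uint8)
    if data.size != n:
        raise FormatError("truncated IDX label payload")
    return data.astype(np.int64)


def write_idx_images(path, images: np.ndarray, image_side: int) -> None:
    """Write [0,1] float images as byte-valued IDX (values rounded to 0-255)."""
    images = np.asarray(images)
    n = images.shape[0]
    raw = np.clip(np.round(images * 255.0), 0, 255).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">iiii", IDX_IMAGE_MAGIC, n, image_side, image_side))
        fh.write(raw.tobytes())


def write_idx_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels, dtype=np.int64)
    if np.any(labels < 0) or np.any(labels > 255):
        raise ValueError("IDX labels must fit in a byte")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">ii", IDX_LABEL_MAGIC, labels.size))
        fh.write(labels.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# batching and splitting

def batch_iterator(images: np.ndarray, labels: np.ndarray,
                   batch_size: int, seed: int = 0):
    """Seeded shuffle followed by contiguous batches; the final short
    batch is emitted."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    n = len(images)
    if n != len(labels):
        raise ValueError("image/label lengths disagree")
    order = np.random.default_rng(seed).permutation(n)
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        yield images[idx], labels[idx]


def split_by_label(images: np.ndarray, labels: np.ndarray,
                   label_sets: tuple) -> tuple:
    """Split into two sub-datasets whose labels fall in each set, order
    preserved.  Sets may overlap (e.g. the 0-5 / 5-9 split shares 5)."""
    out = []
    for s in label_sets:
        s = set(int(v) for v in s)
        mask = np.isin(labels, sorted(s)) if s else np.zeros(len(labels), bool)
        if not mask.any():
            logger.warning("split_by_label: empty split for label set %s", sorted(s))
        out.append((images[mask], labels[mask]))
    return tuple(out)
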