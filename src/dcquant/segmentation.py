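"""Nucleus and territory segmentation, volume fraction, mid-slice choice."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_mean, threshold_otsu

from .stacks import BinaryMask3D, VoxelStack

_THRESHOLDS = {"otsu": threshold_otsu, "mean": threshold_mean}


def _threshold(values: np.ndarray, method: str) -> float:
    try:
        fn = _THRESHOLDS[method]
    except KeyError:
        raise ValueError(f"unknown threshold method {method!r}; choose from {sorted(_THRESHOLDS)}")
    return float(fn(values))


def segment_nucleus(stack: VoxelStack, method: str = "otsu") -> BinaryMask3D:
    """Threshold the nuclear-stain channel and keep one solid nucleus.

    Global threshold on the whole-stack histogram, then the largest
    26-connected 3D component, then per-plane hole filling.  Dissected-nucleus
    fields contain a single nucleus by construction, so the largest-component
    rule is the automated stand-in for a hand-drawn 3D mask.
    """
    data = stack.data
    if data.max() == data.min():
        raise ValueError("no foreground: stack is constant")
    t = _threshold(data, method)
    fg = data > t
    if not fg.any():
        raise ValueError("no foreground above threshold")
    labels, n = ndi.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = labels == int(np.argmax(sizes))
    filled = np.stack([ndi.binary_fill_holes(fg[z]) for z in range(fg.shape[0])])
    return BinaryMask3D(filled, provenance="nucleus")


def segment_signal(stack: VoxelStack, nucleus: BinaryMask3D, method: str = "otsu") -> BinaryMask3D:
    """Threshold the signal channel inside the nucleus.

    The threshold is computed from nuclear voxels only and the resulting mask
    is intersected with the nucleus mask, so non-specific extranuclear
    staining never enters downstream quantification.  Territories may
    legitimately fragment, so no largest-component filter is applied.  A
    signal channel that is flat inside the nucleus yields an empty mask
    rather than an error.
    """
    if stack.shape != nucleus.shape:
        raise ValueError("stack and nucleus mask must be congruent")
    if nucleus.count() == 0:
        raise ValueError("empty nucleus mask")
    inside = stack.data[nucleus.data]
    if inside.max() == inside.min():
        # flat channel inside the nucleus: stain everywhere (positive level)
        # or nowhere (zero) — flagged by emptiness, never an error
        full = inside.max() > 0
        return BinaryMask3D(nucleus.data if full else np.zeros(stack.shape, dtype=bool), provenance="signal")
    t = _threshold(inside, method)
    return BinaryMask3D((stack.data > t) & nucleus.data, provenance="signal")


def restrict_to_nucleus(signal: BinaryMask3D, nucleus: BinaryMask3D) -> BinaryMask3D:
    """Clip a signal mask to the nuclear mask (idempotent for pipeline masks)."""
    if signal.shape != nucleus.shape:
        raise ValueError("masks must be congruent")
    return BinaryMask3D(signal.data & nucleus.data, provenance=signal.provenance)


def volume_fraction(signal: BinaryMask3D, nucleus: BinaryMask3D) -> float:
    """Territory volume over nuclear volume, counted in voxels.

    Pure voxel counting: with anisotropic voxels the same spacing enters
    numerator and denominator, so the ratio is spacing-independent.
    """
    if signal.shape != nucleus.shape:
        raise ValueError("masks must be congruent")
    n_nuc = nucleus.count()
    if n_nuc == 0:
        raise ValueError("empty nucleus mask")
    n_sig = int((signal.data & nucleus.data).sum())
    return n_sig / n_nuc


def select_mid_slice(signal_stack: VoxelStack, nucleus: BinaryMask3D) -> int:
    """Pick the most in-focus middle plane of the nucleus.

    Candidates are the middle third of nucleus-containing planes; the focus
    score is the normalized intensity variance (variance / mean) of the signal
    channel over nuclear pixels.  Ties resolve to the lowest z.
    """
    if signal_stack.shape != nucleus.shape:
        raise ValueError("stack and nucleus mask must be congruent")
    zs = np.flatnonzero(nucleus.data.any(axis=(1, 2)))
    if zs.size < 3:
        raise ValueError("nucleus must span at least 3 planes")
    third = zs.size // 3
    candidates = zs[third : zs.size - third]
    if candidates.size == 0:  # defensive; cannot occur for size >= 3
        candidates = zs
    best_z, best_score = int(candidates[0]), -np.inf
    for z in candidates:
        vals = signal_stack.data[z][nucleus.data[z]]
        if vals.size == 0:
            continue
        m = vals.mean()
        score = vals.var() / m if m > 0 else 0.0
        if score > best_score:  # strict: ties keep the lowest z
            best_score, best_z = score, int(z)
    return best_z
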