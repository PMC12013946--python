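"""Rolling-ball background subtraction.

The background under each z-plane is estimated by a grayscale morphological
opening with a paraboloid structuring element, the separable equivalent of
sliding a ball of the given radius beneath the intensity surface.  Near its
apex the paraboloid of curvature ``1/(2 r)`` coincides with a ball of radius
``r``, which is the classic ImageJ parameterization of this filter.

Because the quadratic structuring function separates over axes, the 2D
erosion/dilation are computed as exact sequential 1D passes; each 1D pass is
an exact min-plus (max-plus) convolution, no shrinking or approximation.
"""

from __future__ import annotations

import numpy as np

from .stacks import VoxelStack


def _parabolic_transform_axis(img: np.ndarray, c: float, axis: int, erode: bool) -> np.ndarray:
    """Exact 1D parabolic erosion/dilation along ``axis``.

    erosion:  out[x] = min_y img[y] + c (x - y)^2
    dilation: out[x] = max_y img[y] - c (x - y)^2
    """
    moved = np.moveaxis(img, axis, -1)
    n = moved.shape[-1]
    idx = np.arange(n, dtype=float)
    quad = c * (idx[:, None] - idx[None, :]) ** 2  # quad[y, x]
    if erode:
        out = (moved[..., :, None] + quad).min(axis=-2)
    else:
        out = (moved[..., :, None] - quad).max(axis=-2)
    return np.moveaxis(out, -1, axis)


def rolling_ball_background(plane: np.ndarray, radius: float) -> np.ndarray:
    """Background surface of one 2D plane (grayscale opening, paraboloid SE)."""
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError("expected a 2D plane")
    if radius < 1:
        raise ValueError("rolling-ball radius must be >= 1 pixel")
    if radius > min(plane.shape):
        raise ValueError(
            f"rolling-ball radius {radius} exceeds plane extent {min(plane.shape)}"
        )
    c = 1.0 / (2.0 * radius)
    eroded = _parabolic_transform_axis(plane, c, 0, erode=True)
    eroded = _parabolic_transform_axis(eroded, c, 1, erode=True)
    opened = _parabolic_transform_axis(eroded, c, 0, erode=False)
    opened = _parabolic_transform_axis(opened, c, 1, erode=False)
    return opened


def subtract_background(stack: VoxelStack, radius: float = 50.0) -> VoxelStack:
    """Subtract the rolling-ball background from every z-plane.

    Returns a new stack clipped at zero; spacing and channel label carry over.
    The default radius of 50 pixels matches the usual choice for ~10 um
    nuclei imaged at ~0.1 um/px.
    """
    planes = [
        np.clip(stack.plane(z) - rolling_ball_background(stack.plane(z), radius), 0.0, None)
        for z in range(stack.shape[0])
    ]
    return VoxelStack(np.stack(planes), spacing=stack.spacing, channel=stack.channel)
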