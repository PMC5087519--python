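"""Level-1 two-dimensional dual-tree complex wavelet transform.

A single decomposition level is computed with one symmetric biorthogonal
analysis pair (LeGall 5/3), filtered without decimation and with symmetric
boundary extension.  The four polyphase components of each highpass image
(even/odd rows crossed with even/odd columns) correspond to the four
combinations of the two wavelet trees — at level 1 the second tree is the
first delayed by one sample — and are combined quad-to-complex into six
oriented complex subbands at approximately +15, +45, +75, -75, -45 and -15
degrees.  Highpass filters sum to zero, so all six subbands vanish on a
constant image.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d

# LeGall 5/3 analysis filters (exact dyadic rationals), zero-centred.
_H0 = np.array([-1.0, 2.0, 6.0, 2.0, -1.0]) / 8.0  # lowpass, sums to 1
_H1 = np.array([-1.0, 2.0, -1.0]) / 2.0  # highpass, sums to 0

#: Nominal orientation (degrees) of each returned subband, in order.
ORIENTATIONS = (15, 45, 75, -75, -45, -15)


def _filt(x: np.ndarray, h: np.ndarray, axis: int) -> np.ndarray:
    return convolve1d(x, h, axis=axis, mode="mirror")


def _q2c(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Combine the four polyphase quads of ``y`` into two complex subbands."""
    w = np.sqrt(0.5)
    a = y[0::2, 0::2]
    b = y[0::2, 1::2]
    c = y[1::2, 0::2]
    d = y[1::2, 1::2]
    p = (a + 1j * b) * w
    q = (d - 1j * c) * w
    return p - q, p + q


def dtcwt_level1(image: np.ndarray) -> np.ndarray:
    """One-level 2-D DT-CWT of a grayscale image.

    Parameters
    ----------
    image : (H, W) array
        Grayscale input; H and W must be even (pad beforehand if needed).

    Returns
    -------
    (H/2, W/2, 6) complex array
        Oriented subbands in the order given by :data:`ORIENTATIONS`.
    """
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("dtcwt_level1 expects a 2-D grayscale image")
    if x.shape[0] % 2 or x.shape[1] % 2:
        raise ValueError("image dimensions must be even; pad first")

    lo = _filt(x, _H0, axis=0)  # lowpass along columns (vertical)
    hi = _filt(x, _H1, axis=0)  # highpass along columns
    band_15 = _filt(hi, _H0, axis=1)  # horizontal-ish detail
    band_75 = _filt(lo, _H1, axis=1)  # vertical-ish detail
    band_45 = _filt(hi, _H1, axis=1)  # diagonal detail

    out = np.empty((x.shape[0] // 2, x.shape[1] // 2, 6), dtype=np.complex128)
    out[:, :, 0], out[:, :, 5] = _q2c(band_15)  # +15, -15 degrees
    out[:, :, 1], out[:, :, 4] = _q2c(band_45)  # +45, -45 degrees
    out[:, :, 2], out[:, :, 3] = _q2c(band_75)  # +75, -75 degrees
    return out
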