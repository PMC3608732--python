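"""Translation-only registration of the time-lapse stack.

The window-chamber preparation is mechanically rigid: frame-to-frame motion
is a slow, essentially translational drift of the whole field.  Masks are
drawn once on (a projection of) the aligned series and applied to every
frame, so alignment only has to undo that translation.  Integer-pixel
accuracy is sufficient for the morphometry tolerances; no rotational or
deformable component is modelled.

The shift between two frames is the integer translation maximising their
normalized cross-correlation, found on an FFT cross-correlation surface of
the mean-subtracted frames and searched over at least +-10% of the frame
size.  Every frame is registered to the first frame of the series (the
pre-treatment baseline).
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateInputError
from .stack_io import ImageStack

__all__ = ["estimate_translation", "align_stack", "translate_frame"]


def translate_frame(frame: np.ndarray, shift: tuple[int, int], fill: float) -> np.ndarray:
    """Shift a frame by integer (dy, dx), filling exposed pixels with ``fill``."""
    dy, dx = int(shift[0]), int(shift[1])
    out = np.full_like(frame, fill)
    H, W = frame.shape
    ys = slice(max(dy, 0), min(H + dy, H))
    xs = slice(max(dx, 0), min(W + dx, W))
    ys_src = slice(max(-dy, 0), min(H - dy, H))
    xs_src = slice(max(-dx, 0), min(W - dx, W))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


def estimate_translation(
    reference: np.ndarray,
    moving: np.ndarray,
    max_shift: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Integer (dy, dx) by which ``moving`` is displaced relative to ``reference``.

    If ``moving`` equals ``reference`` shifted down by 3 and left by 2, the
    result is ``(3, -2)``.  ``max_shift`` bounds the search per axis;
    the default is 10% of the frame size (at least 10 px).
    """
    ref = np.asarray(reference, float)
    mov = np.asarray(moving, float)
    if ref.shape != mov.shape:
        raise DegenerateInputError(f"frame shapes differ: {ref.shape} vs {mov.shape}")
    if ref.std() == 0 or mov.std() == 0:
        raise DegenerateInputError("constant (zero-variance) frame: no structure to register")
    if max_shift is None:
        max_shift = (max(int(0.1 * ref.shape[0]), 10), max(int(0.1 * ref.shape[1]), 10))

    ref0 = ref - ref.mean()
    mov0 = mov - mov.mean()
    # circular cross-correlation: peak index = displacement of mov w.r.t. ref
    corr = np.fft.ifft2(np.conj(np.fft.fft2(ref0)) * np.fft.fft2(mov0)).real

    my, mx = max_shift
    ys = np.r_[0 : my + 1, corr.shape[0] - my : corr.shape[0]]
    xs = np.r_[0 : mx + 1, corr.shape[1] - mx : corr.shape[1]]
    window = corr[np.ix_(ys, xs)]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy, dx = int(ys[iy]), int(xs[ix])
    if dy > corr.shape[0] // 2:
        dy -= corr.shape[0]
    if dx > corr.shape[1] // 2:
        dx -= corr.shape[1]
    return (dy, dx)


def align_stack(
    stack: ImageStack,
    reference_index: int = 0,
    max_shift: tuple[int, int] | None = None,
) -> tuple[ImageStack, list[tuple[int, int]]]:
    """Register every frame to a reference frame; return stack and shifts.

    The reference defaults to the first frame; when the acquisition starts
    before the tracer arrives, pass the index of the first tracer-carrying
    frame instead (a pre-injection frame is uniform background and carries
    no registrable structure).  Out-of-field pixels exposed by the
    correction are filled with the frame's background median.  The per-frame
    shifts (estimated drift relative to the reference) are returned for
    audit; aligning an already-aligned stack yields all-zero shifts.
    Constant frames are left untouched with shift (0, 0) — a uniform frame
    is translation-invariant, so there is nothing to align.
    """
    frames = stack.frames
    if frames.shape[0] == 1:
        return stack, [(0, 0)]
    if not 0 <= reference_index < frames.shape[0]:
        raise DegenerateInputError(f"reference index {reference_index} outside stack")
    ref = frames[reference_index]
    if np.asarray(ref, float).std() == 0:
        raise DegenerateInputError(f"frame {reference_index}: constant reference frame")
    aligned = np.empty_like(frames)
    shifts: list[tuple[int, int]] = []
    for k in range(frames.shape[0]):
        if k == reference_index:
            aligned[k] = ref
            shifts.append((0, 0))
            continue
        if np.asarray(frames[k], float).std() == 0:
            aligned[k] = frames[k]
            shifts.append((0, 0))
            continue
        shift = estimate_translation(ref, frames[k], max_shift)
        fill = float(np.median(frames[k]))
        aligned[k] = translate_frame(frames[k], (-shift[0], -shift[1]), fill)
        shifts.append(shift)
    return ImageStack(aligned, stack.timestamps, stack.pixel_size), shifts
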