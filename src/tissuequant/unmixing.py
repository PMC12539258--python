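"""Spectral unmixing of multi-channel fluorescence images.

The acquired signal of each channel is modelled as a non-negative linear mix
of the fluorophore signals plus autofluorescence plus a constant per-channel
background::

    c = M @ a + b,      M >= 0, columns of M sum to 1, a >= 0

``M`` is estimated from a library of single-stain images (one image per
fluorophore plus one unstained image), and images are unmixed per pixel by
non-negative least squares, which keeps abundances physical (>= 0) and is
independent of pixel processing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .datatypes import Channel, FormatError, MarkerImageStack

AUTOFLUORESCENCE = "autofluorescence"


@dataclass
class MixingModel:
    """Column-normalized channels x sources mixing matrix plus background.

    One column per fluorophore, optionally one for autofluorescence; each
    column sums to 1 and all entries are non-negative.
    """

    matrix: np.ndarray
    sources: list[str]
    background: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n_chan, n_src = self.matrix.shape
        if n_src != len(self.sources):
            raise FormatError("one source name per matrix column required")
        if n_src > n_chan:
            raise FormatError("more sources than channels")
        if np.any(self.matrix < 0) or np.any(self.background < 0):
            raise FormatError("mixing matrix and background must be non-negative")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise FormatError("mixing-matrix columns must sum to 1")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n_chan)]

    @property
    def fluorophores(self) -> list[str]:
        return [s for s in self.sources if s != AUTOFLUORESCENCE]


def estimate_mixing_model(
    single_stain_stacks: dict[str, MarkerImageStack],
    unstained_stack: MarkerImageStack,
    top_fraction: float = 0.01,
) -> MixingModel:
    """Estimate the mixing matrix from a single-stain library.

    Parameters
    ----------
    single_stain_stacks
        Mapping fluorophore name -> stack stained with that fluorophore only.
        Each fluorophore name must match a manifest fluorophore, whose channel
        is taken as the stain's primary channel.
    unstained_stack
        Image with no stain: its per-channel median is the background offset,
        and its brightest pixels (total intensity) estimate the
        autofluorescence spectrum.
    top_fraction
        Fraction of brightest pixels (by primary-channel intensity) used per
        stain; the per-channel *median* over those pixels, background-
        subtracted and clipped at zero, becomes the normalized column.
    """
    ref = unstained_stack
    background = np.median(ref.pixels.reshape(-1, ref.n_channels), axis=0)
    fluor_names = [c.fluorophore for c in ref.channels]

    columns: list[np.ndarray] = []
    sources: list[str] = []
    for name, stack in single_stain_stacks.items():
        if stack.n_channels != ref.n_channels:
            raise FormatError(f"single-stain stack {name!r}: channel count mismatch")
        if name not in fluor_names:
            raise FormatError(f"fluorophore {name!r} not in channel manifest")
        primary = fluor_names.index(name)
        col = _top_pixel_spectrum(stack, primary, top_fraction, background)
        if not np.any(col > 0):
            raise FormatError(f"single-stain image for {name!r} has no signal")
        columns.append(col / col.sum())
        sources.append(name)

    # autofluorescence spectrum from the brightest unstained pixels
    flat = ref.pixels.reshape(-1, ref.n_channels)
    total = flat.sum(axis=1)
    af_col = _top_spectrum(flat, total, top_fraction, background)
    if np.any(af_col > 0):
        columns.append(af_col / af_col.sum())
        sources.append(AUTOFLUORESCENCE)
    # a flat unstained image carries no AF structure beyond background: the AF
    # source is dropped rather than kept as an unnormalizable zero column

    return MixingModel(
        matrix=np.column_stack(columns),
        sources=sources,
        background=background,
        channel_names=[c.channel_id for c in ref.channels],
    )


def _top_pixel_spectrum(
    stack: MarkerImageStack, primary: int, top_fraction: float, background: np.ndarray
) -> np.ndarray:
    flat = stack.pixels.reshape(-1, stack.n_channels)
    return _top_spectrum(flat, flat[:, primary], top_fraction, background)


def _top_spectrum(
    flat: np.ndarray, brightness: np.ndarray, top_fraction: float, background: np.ndarray
) -> np.ndarray:
    k = max(1, int(round(top_fraction * len(flat))))
    top = np.argpartition(brightness, -k)[-k:]
    spectrum = np.median(flat[top], axis=0) - background
    return np.clip(spectrum, 0.0, None)


def unmix(stack: MarkerImageStack, model: MixingModel) -> MarkerImageStack:
    """Unmix a stack into per-fluorophore abundances by per-pixel NNLS.

    Per pixel solves ``min_a>=0 || (c - b) - M a ||_2``; the output stack has
    one channel per non-autofluorescence source.  Deterministic, and pixels
    are independent so the result does not depend on processing order.
    """
    if stack.n_channels != model.matrix.shape[0]:
        raise FormatError(
            f"stack has {stack.n_channels} channels, model expects {model.matrix.shape[0]}"
        )
    M = model.matrix
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise FormatError(
            f"mixing matrix is rank deficient (cond={np.linalg.cond(M):.3g})"
        )
    h, w, _ = stack.pixels.shape
    flat = stack.pixels.reshape(-1, stack.n_channels) - model.background
    out = np.empty((flat.shape[0], M.shape[1]))
    # cache: many pixels repeat exactly in synthetic images
    cache: dict[bytes, np.ndarray] = {}
    for i, c in enumerate(flat):
        key = c.tobytes()
        hit = cache.get(key)
        if hit is None:
            hit, _ = nnls(M, c)
            cache[key] = hit
        out[i] = hit

    keep = [k for k, s in enumerate(model.sources) if s != AUTOFLUORESCENCE]
    fluor_to_marker = {c.fluorophore: c.marker for c in stack.channels}
    channels = [
        Channel(
            channel_id=f"unmixed_{model.sources[k]}",
            marker=fluor_to_marker.get(model.sources[k], model.sources[k]),
            fluorophore=model.sources[k],
        )
        for k in keep
    ]
    return MarkerImageStack(
        pixels=out[:, keep].reshape(h, w, len(keep)),
        channels=channels,
        pixel_size_um=stack.pixel_size_um,
        image_id=stack.image_id,
        modality=stack.modality,
    )
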