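"""±3σ intensity normalization of a region.

The mean μ and (population) standard deviation σ of the region are computed,
the window ``[μ - 3σ, μ + 3σ]`` is mapped linearly onto the gray range
``[0, L]`` with ``L = 2**bit_depth - 1``, and values falling outside are
clamped to 0 or L:

    N(x, y)      = L * (I(x, y) - min_norm) / (max_norm - min_norm)
    I_norm(x, y) = L     if N > L
                   0     if N < 0
                   round(N) otherwise

For a Gaussian-like histogram (typical of MR regions) this standardizes
location and scale before texture features are computed, so downstream
features respond to structure rather than to scanner gain or offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import Region


@dataclass(frozen=True)
class NormalizedRegion:
    """A region after ±3σ normalization, with the window that produced it."""

    pixels: np.ndarray  # integers in [0, gray_max]
    bit_depth: int
    gray_max: int
    mu: float
    sigma: float

    @property
    def min_norm(self) -> float:
        return self.mu - 3.0 * self.sigma

    @property
    def max_norm(self) -> float:
        return self.mu + 3.0 * self.sigma

    @property
    def shape(self):
        return self.pixels.shape


def normalize_3sigma(region: Region, ceiling: Optional[int] = None) -> NormalizedRegion:
    """Apply ±3σ normalization to a region.

    Parameters
    ----------
    region : Region
        Non-empty integer region.
    ceiling : int, optional
        Clamp ceiling L.  Defaults to the full dynamic range of the input
        (255 for 8-bit, 4095 for 12-bit); pass 255 to clamp deep data onto
        the 8-bit range instead.

    Notes
    -----
    σ is the population standard deviation.  A constant region (σ = 0) maps
    to the mid-gray constant ``round(L / 2)``; rounding everywhere is
    half-away-from-zero.
    """
    values = np.asarray(region.pixels, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot normalize an empty region")
    L = int(ceiling) if ceiling is not None else 2 ** region.bit_depth - 1
    mu = float(values.mean())
    sigma = float(values.std())  # population
    if sigma == 0.0:
        out = np.full_like(values, np.floor(L / 2.0 + 0.5))
    else:
        n = L * (values - (mu - 3.0 * sigma)) / (6.0 * sigma)
        # clamp first, then round: clamped values are exact integers already
        out = np.clip(n, 0.0, float(L))
        out = np.floor(out + 0.5)
        out = np.minimum(out, float(L))
    return NormalizedRegion(
        pixels=out.astype(np.int64),
        bit_depth=region.bit_depth,
        gray_max=L,
        mu=mu,
        sigma=sigma,
    )
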