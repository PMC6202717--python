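"""Legacy rank-difference indices, kept as descriptive baselines.

Neither index carries a significance criterion here: criterion-based
calls from raw difference indices are subjective, so these series are
reported alongside the resampling test for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_null import RankedCensus

__all__ = ["IndexSeries", "holling_index", "siemann_brown_index"]


@dataclass(frozen=True)
class IndexSeries:
    """A difference-index series aligned to interior ranks.

    ``values`` has length n-2 for the Holling index (each value needs
    both neighbours; endpoints are undefined and omitted) and n-1 for
    the Siemann-Brown index.
    """

    values: np.ndarray
    method: str
    gamma: float | None = None


def holling_index(
    census: RankedCensus, gamma: float = 1.3, transform: str = "exponent"
) -> IndexSeries:
    """Body-mass difference index HI = ((M[k+1] - M[k-1]) / M[k])**gamma.

    Computed on raw (gram-scale) masses at interior ranks.  The
    conventional transforms are 1.3 for birds and 1.1 for mammals;
    whether the constant acts as the exponent gamma or as a mass
    pre-transform is ambiguous in the source literature, so both
    readings are available:

    - transform="exponent" (default): gamma is the exponent.
    - transform="mass": masses are raised to the constant first and the
      index uses exponent 1.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if transform not in ("exponent", "mass"):
        raise ValueError("transform must be 'exponent' or 'mass'")
    m = census.mass
    if transform == "mass":
        m = m ** gamma
        exponent = 1.0
    else:
        exponent = gamma
    values = ((m[2:] - m[:-2]) / m[1:-1]) ** exponent
    return IndexSeries(values=values, method="HI", gamma=gamma)


def siemann_brown_index(census: RankedCensus) -> IndexSeries:
    """SB = log10(M[r+1] / M[r]): the successive log10 ratio.

    Algebraically identical to the observed log10 rank gaps.
    """
    return IndexSeries(values=np.diff(census.logmass), method="SB")
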