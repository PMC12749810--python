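"""Edge-safe binary morphology.

scipy's plain binary opening/closing treat everything outside the image as
background, which erodes a one-pixel frame off any structure touching the
border (a confluent field loses its whole rim).  These wrappers run the
erosion steps with the outside treated as foreground, matching the behavior
of interactive image-analysis tools.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["binary_opening", "binary_closing"]


def binary_opening(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    eroded = ndi.binary_erosion(mask, structure=structure, border_value=1)
    return ndi.binary_dilation(eroded, structure=structure)


def binary_closing(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    dilated = ndi.binary_dilation(mask, structure=structure)
    return ndi.binary_erosion(dilated, structure=structure, border_value=1)
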