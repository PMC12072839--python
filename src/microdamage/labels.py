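"""Label codes for cross-section masks.

A label mask partitions a slice into four classes; the codes below are
also the pixel values used when masks are written as label TIFFs.
"""

import numpy as np

BACKGROUND = 0  # outside the object support
SOLID = 1       # intact material, xi = 1
DAMAGE = 2      # crack interior, xi = 0
BOUNDARY = 3    # crack-boundary band, xi = 0.5

LABEL_NAMES = {BACKGROUND: "background", SOLID: "solid",
               DAMAGE: "damage", BOUNDARY: "boundary"}

#: xi value assigned to a point landing in each in-object label
XI_BY_LABEL = {SOLID: 1.0, DAMAGE: 0.0, BOUNDARY: 0.5}


def object_mask(mask: np.ndarray) -> np.ndarray:
    """Boolean support of the object (solid | damage | boundary)."""
    return mask != BACKGROUND


def tally(mask: np.ndarray) -> dict:
    """Exact pixel counts per label, as a plain dict keyed by label name."""
    m = np.asarray(mask)
    return {name: int(np.count_nonzero(m == code))
            for code, name in LABEL_NAMES.items()}
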