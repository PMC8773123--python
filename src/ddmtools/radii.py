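"""Van der Waals radii used for solvent-accessibility calculations.

A single element-level radii set in the Chothia/NACCESS tradition
(Chothia, J Mol Biol 1975; Hubbard & Thornton's NACCESS uses the same
family of values).  One fixed set is deliberate: buried-area comparisons
between two states are only meaningful when both states are measured
with identical radii.
"""

from __future__ import annotations

import warnings

#: Element symbol (upper case) -> van der Waals radius in Angstrom.
VDW_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "H": 1.00,
    "SE": 1.90,
    "FE": 1.47,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 1.97,  # calcium ion, not the alpha-carbon atom name
}

#: Fallback radius for elements absent from the table.
DEFAULT_RADIUS: float = 1.70

RADII_SET_NAME = "chothia-element"


def vdw_radius(element: str) -> float:
    """Return the van der Waals radius (Å) for an element symbol.

    Unknown elements fall back to 1.70 Å with a warning.
    """
    r = VDW_RADII.get(element.strip().upper())
    if r is None:
        warnings.warn(
            f"no van der Waals radius for element {element!r}; "
            f"using fallback {DEFAULT_RADIUS} Å",
            stacklevel=2,
        )
        return DEFAULT_RADIUS
    return r
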