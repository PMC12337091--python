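"""Shared vocabulary: pigment classes, spectral bands and spectrum roles."""

from __future__ import annotations

from enum import Enum


class PigmentClass(str, Enum):
    """Chemical classes of light-harvesting pigments handled by the model."""

    CHL_A = "chl_a"
    CHL_B = "chl_b"
    CHL_C1 = "chl_c1"
    CRT = "crt"

    @property
    def is_chlorophyll(self) -> bool:
        return self is not PigmentClass.CRT


#: canonical report order: carotenoids first, then chlorophylls a/b/c1
CLASS_ORDER = (PigmentClass.CRT, PigmentClass.CHL_A, PigmentClass.CHL_B, PigmentClass.CHL_C1)


class Band(str, Enum):
    """Electronic absorption band, treated as a single-state entity.

    Q is the low-energy band (550-700 nm); B (Soret) the high-energy band
    (350-500 nm).  Carotenoid bright-state (S2) absorption falls in the B
    window and is handled under Band.B.
    """

    Q = "Q"
    B = "B"


class SpectralRole(str, Enum):
    ABSORPTION = "absorption"
    EMISSION = "emission"
    EXTINCTION = "extinction"
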