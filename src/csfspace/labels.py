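"""Shared label conventions for tissue classes and CSF compartments."""

from enum import IntEnum

__all__ = ["Tissue", "Compartment"]


class Tissue(IntEnum):
    """Hard tissue classes, ordered by typical T1 intensity (CSF darkest)."""

    BACKGROUND = 0
    CSF = 1
    GM = 2
    WM = 3


class Compartment(IntEnum):
    """CSF compartments tracked in phantom ground truth."""

    NONE = 0
    LATERAL_VENTRICLE = 1
    HIGH_CONVEXITY_SAS = 2
    SYLVIAN = 3
    OTHER_CSF = 4
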