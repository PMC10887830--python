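"""Canonical names of the eight radiographic sagittal-alignment parameters.

The order is the one used throughout: cervical sagittal alignment (CSA, a
C2 plumb-line to C7 distance in mm), craniocervical angle (CCA), T1 slope
(T1S), C2-C7 cervical lordosis (CL), cranial tilt (CranT), cervical tilt
(CervT), C7 slope (C7S) and T4-T12 thoracic kyphosis (TK). All are angles
in degrees except CSA.
"""

PARAMETERS: tuple[str, ...] = (
    "CSA",
    "CCA",
    "T1S",
    "CL",
    "CranT",
    "CervT",
    "C7S",
    "TK",
)
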