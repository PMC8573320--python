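"""Centralized unit conventions and conversions.

Conventions used throughout the package:

* ring widths        -- millimetres (mm)
* stem diameters     -- centimetres (cm)
* tree heights       -- metres (m)
* cell dimensions    -- micrometres (um), areas in um^2
* temperature        -- degrees Celsius
* precipitation      -- millimetres (mm)

Tucson (.rwl) files store ring widths as integers in units of 0.01 mm.
"""

MM_PER_CM = 10.0
CM_PER_M = 100.0
RWL_SCALE = 100.0  # rwl integer units per mm


def mm_to_cm(x):
    return x / MM_PER_CM


def cm_to_mm(x):
    return x * MM_PER_CM


def cm_to_m(x):
    return x / CM_PER_M


def m_to_cm(x):
    return x * CM_PER_M
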