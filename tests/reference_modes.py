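"""Independent brute-force reference for the pattern-mode geometry.

Each mode's defining region is written as a self-contained membership test
with no shared control flow; a triple satisfying several regions is
resolved by the documented precedence (direction, neutral, dominant,
synergistic, additive, minor, non-assigned).  Used only as a test oracle
against stressmodes.pattern_classifier.classify_feature.
"""

import math


def in_antagonistic(x, y, z, sigma):
    if x == 0 or y == 0 or z == 0:
        return False
    return math.copysign(1, x) != math.copysign(1, z) and \
        math.copysign(1, y) != math.copysign(1, z)


def in_unilateral(x, y, z, sigma):
    if x == 0 or y == 0 or z == 0:
        return False
    st_flip = math.copysign(1, x) != math.copysign(1, z)
    wl_flip = math.copysign(1, y) != math.copysign(1, z)
    return (st_flip and not wl_flip) or (wl_flip and not st_flip)


def _all_one_direction(x, y, z):
    return (x > 0 and y > 0 and z > 0) or (x < 0 and y < 0 and z < 0)


def in_neutral(x, y, z, sigma):
    return _all_one_direction(x, y, z) and \
        abs(x - z) <= sigma and abs(y - z) <= sigma


def in_dominant(x, y, z, sigma):
    if not _all_one_direction(x, y, z):
        return False
    st_near = abs(x - z) <= sigma
    wl_near = abs(y - z) <= sigma
    return (st_near and not wl_near) or (wl_near and not st_near)


def in_synergistic(x, y, z, sigma):
    return _all_one_direction(x, y, z) and \
        abs(x - z) > sigma and abs(y - z) > sigma and \
        abs(z) - abs(x + y) > sigma


def in_additive(x, y, z, sigma):
    return _all_one_direction(x, y, z) and \
        abs(x - z) > sigma and abs(y - z) > sigma and \
        abs(abs(z) - abs(x + y)) <= sigma


def in_minor(x, y, z, sigma):
    return _all_one_direction(x, y, z) and \
        abs(x - z) > sigma and abs(y - z) > sigma and \
        abs(z) - abs(x + y) < -sigma and \
        abs(z) < max(abs(x), abs(y)) - sigma


PRECEDENCE = (
    ("antagonistic", in_antagonistic),
    ("unilateral", in_unilateral),
    ("neutral", in_neutral),
    ("dominant", in_dominant),
    ("synergistic", in_synergistic),
    ("additive", in_additive),
    ("minor", in_minor),
)


def reference_mode(x, y, z, sigma=0.5):
    """First matching region in precedence order, else non_assigned."""
    for name, member in PRECEDENCE:
        if member(x, y, z, sigma):
            return name
    return "non_assigned"
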