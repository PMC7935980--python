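"""Unit conversion constants.

All computation is SI internally; user-facing interfaces accept the units the
chip community works in (micrometres, nanometres, gauss, hertz).
"""

import math

MU0 = 4.0e-7 * math.pi  # vacuum permeability, T·m/A

UM = 1.0e-6  # metre per micrometre
NM = 1.0e-9  # metre per nanometre
GAUSS = 1.0e-4  # tesla per gauss


def gauss_to_tesla(b_gauss: float) -> float:
    return b_gauss * GAUSS


def tesla_to_gauss(b_tesla: float) -> float:
    return b_tesla / GAUSS
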