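"""Missing-value sentinel shared across feature modules.

A similarity that "cannot work" for a pair (unannotated protein, protein
absent from the network, no pathway membership on either side) returns
``MISSING`` (NaN) rather than 0; downstream code carries an explicit
missing mask and imputes at training time.
"""

import math

MISSING: float = math.nan


def is_missing(value: float) -> bool:
    return isinstance(value, float) and math.isnan(value)
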