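"""Default region-of-interest label sets.

The cortical parcellation used throughout is the 42 Brodmann areas resolved by
standard EEG source localisation (BAs 1-11, 13, 17-25 and 27-47), taken in both
hemispheres, for 84 regions in total.  Node order is fixed (ascending area
number, left before right) so that matrices, graphs and capacity vectors are
directly comparable across subjects.
"""

from __future__ import annotations

# Brodmann areas resolved by the source-localisation parcellation.
_BRODMANN_AREAS: tuple[int, ...] = tuple(
    list(range(1, 12)) + [13] + list(range(17, 26)) + list(range(27, 48))
)

#: The 84 default node labels: 42 Brodmann areas x {left, right}.
DEFAULT_ROI_LABELS: tuple[str, ...] = tuple(
    f"BA{area:02d}_{hemi}" for area in _BRODMANN_AREAS for hemi in ("L", "R")
)

assert len(DEFAULT_ROI_LABELS) == 84
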