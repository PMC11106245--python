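"""Screening-platform metadata.

The discovery screen draws on two immunoassay platforms: a proximity-
extension assay panel reporting relative NPX values, and an xMAP bead panel
reporting calibrated absolute concentrations.  Only the panel sizes matter
to the pipeline — they fix the size of the univariate/multivariate
screening pool — and the final custom panel reserves one slot for an
analyte added outside the computational selection.
"""

from __future__ import annotations

#: Proteins measured per screening platform.
PLATFORM_PANEL_SIZES: dict[str, int] = {
    "pea_npx": 1196,
    "xmap_rbm": 215,
}

#: Proteins selected computationally for the custom assay panel.
PANEL_BUDGET = 20

#: Panel slots reserved for analytes added outside the selection run.
RESERVED_SLOTS = 1


def screening_pool_size(panel_sizes: dict[str, int] | None = None) -> int:
    """Total number of proteins entering the univariate and multivariate
    screens (sum over platforms)."""
    sizes = PLATFORM_PANEL_SIZES if panel_sizes is None else panel_sizes
    return int(sum(sizes.values()))


def final_panel_size(budget: int = PANEL_BUDGET, reserved: int = RESERVED_SLOTS) -> int:
    """Manufactured panel size: computational selections plus reserved
    slots."""
    return int(budget + reserved)
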