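"""Small conversion helpers shared by the CLI and examples."""

from __future__ import annotations

import pandas as pd

from .loading import GaitLoading


def loading_to_frame(loading: GaitLoading) -> pd.DataFrame:
    """Long-format stance loading table for one knee."""
    return pd.DataFrame(
        {
            "stance_percent": loading.stance_percent,
            "flexion_deg": loading.flexion_deg,
            "force_medial_n": loading.force_medial,
            "force_lateral_n": loading.force_lateral,
        }
    )
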