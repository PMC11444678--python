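"""Bench-assay arithmetic: GRABS stiffness scores and replicate summaries.

The GRABS (general regulators affecting bacterial stiffness) score compares
how much a mutant's growth is penalized by being embedded in agarose
relative to a reference strain:

    score = OD_mut,agarose / OD_ref,agarose − OD_mut,liquid / OD_ref,liquid

Positive scores indicate stiffer cells than the reference, negative scores
softer cells.  Dye-release (RBB) measurements are summarized as mean ± SD
over technical replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def grabs_score(
    od_mut_agarose: float,
    od_ref_agarose: float,
    od_mut_liquid: float,
    od_ref_liquid: float,
) -> float:
    """GRABS stiffness score; requires all four ODs > 0."""
    ods = (od_mut_agarose, od_ref_agarose, od_mut_liquid, od_ref_liquid)
    if any(not (od > 0) for od in ods):
        raise ValueError(f"all ODs must be > 0, got {ods}")
    return od_mut_agarose / od_ref_agarose - od_mut_liquid / od_ref_liquid


def grabs_timecourse(
    curves: pd.DataFrame,
    mutant: str = "mutant",
    reference: str = "reference",
) -> pd.DataFrame:
    """GRABS score at every shared time point of a long-format curve table.

    ``curves`` needs columns strain, medium, time_h, od600 with media
    "liquid" and "agarose".  Returns (time_h, score); by convention the
    headline score is the last (24 h) time point.
    """
    def pick(strain, medium):
        sel = curves[(curves["strain"] == strain) & (curves["medium"] == medium)]
        return sel.set_index("time_h")["od600"]

    ma, ra = pick(mutant, "agarose"), pick(reference, "agarose")
    ml, rl = pick(mutant, "liquid"), pick(reference, "liquid")
    times = sorted(set(ma.index) & set(ra.index) & set(ml.index) & set(rl.index))
    rows = [
        (t, grabs_score(ma[t], ra[t], ml[t], rl[t]))
        for t in times
        if min(ma[t], ra[t], ml[t], rl[t]) > 0
    ]
    if not rows:
        raise ValueError("no shared time point with all four ODs > 0")
    return pd.DataFrame(rows, columns=["time_h", "score"])


def replicate_summary(values) -> tuple[float, float | None, int]:
    """(mean, sample SD, n) of replicate measurements.

    SD uses the n−1 denominator and is reported absent (None) at n = 1.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return mean, sd, int(arr.size)
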