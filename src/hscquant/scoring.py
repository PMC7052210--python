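"""Ordinal histology scores as pure functions of measured features.

Four semi-quantitative scales used in the CDAHFD mouse model and the human
biopsy cohort: stellate-cell hypertrophy in mouse fields and human biopsies
(both 0-3), steatosis grade (0-3, from fat-droplet area percentage) and
lobular inflammation grade (0-3, from inflammatory foci per lobule).
Fibrosis staging (0, 1a, 1b, 1c, 2, 3, 4 or METAVIR F0-F4) is expert
histopathology: it is carried through tables as a recorded label and never
computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ScorePanel",
    "mouse_hypertrophy_score",
    "human_hypertrophy_score",
    "steatosis_grade",
    "inflammation_grade",
    "score_table",
    "FIBROSIS_STAGES",
]

#: Valid recorded fibrosis-stage labels (never computed).
FIBROSIS_STAGES = frozenset(
    {"0", "1a", "1b", "1c", "2", "3", "4", "F0", "F1", "F2", "F3", "F4"}
)

#: Default surrogate threshold separating "small" from "bigger"
#: hypertrophied cells in the mouse score (µm²).
DEFAULT_CELL_SIZE_THRESHOLD_UM2 = 200.0


@dataclass
class ScorePanel:
    """One specimen's scores; fibrosis_stage is input metadata only."""

    mouse_hypertrophy: int | None = None
    human_hypertrophy: int | None = None
    steatosis: int | None = None
    inflammation: int | None = None
    fibrosis_stage: str | None = None

    def __post_init__(self) -> None:
        for name in ("mouse_hypertrophy", "human_hypertrophy", "steatosis",
                     "inflammation"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 3:
                raise ValueError(f"{name} must be in 0..3")
        if self.fibrosis_stage is not None and (
            str(self.fibrosis_stage) not in FIBROSIS_STAGES
        ):
            raise ValueError(f"unknown fibrosis stage {self.fibrosis_stage!r}")


def mouse_hypertrophy_score(
    n_hypertrophied_cells_per_field: float,
    mean_cell_area_um2: float = 0.0,
    size_threshold_um2: float = DEFAULT_CELL_SIZE_THRESHOLD_UM2,
) -> int:
    """Mouse HSC-hypertrophy score of one 200x microscopic field.

    0 = no visible hypertrophy; 1 = small and few hypertrophied cells;
    2 = bigger cells, fewer than 10 per field; 3 = more than 10 per field.

    The printed rule distinguishes 1 from 2 qualitatively ("small" vs
    "bigger"); here a configurable mean-cell-area threshold stands in as a
    surrogate.  A count of exactly 10 sits between the printed "less than
    10" and "more than 10"; it falls to the size-dependent branch (1 or 2),
    never to 3.
    """
    if n_hypertrophied_cells_per_field < 0 or mean_cell_area_um2 < 0:
        raise ValueError("inputs must be non-negative")
    if n_hypertrophied_cells_per_field == 0:
        return 0
    if n_hypertrophied_cells_per_field > 10:
        return 3
    return 2 if mean_cell_area_um2 >= size_threshold_um2 else 1


def human_hypertrophy_score(n_hypertrophied_areas_per_biopsy: int) -> int:
    """Human HSC-hypertrophy score of a whole biopsy at 200x.

    0 = none; 1 = one (a few cells) hypertrophied area; 2 = 2 to 5 areas;
    3 = more than 5 areas.
    """
    n = n_hypertrophied_areas_per_biopsy
    if n < 0:
        raise ValueError("count must be non-negative")
    if n == 0:
        return 0
    if n == 1:
        return 1
    if n <= 5:
        return 2
    return 3


def steatosis_grade(fat_area_pct: float) -> int:
    """Steatosis grade from average fat-droplet area percentage.

    0: 0 %; 1: 1-33 %; 2: 34-66 %; 3: 67-100 %.  Non-integer inputs are
    resolved by rounding to the nearest integer percent (half away from
    zero) before binning.
    """
    if not 0 <= fat_area_pct <= 100:
        raise ValueError("fat_area_pct must be in [0, 100]")
    pct = math.floor(fat_area_pct + 0.5)
    if pct == 0:
        return 0
    if pct <= 33:
        return 1
    if pct <= 66:
        return 2
    return 3


def inflammation_grade(foci_per_lobule: float) -> int:
    """Lobular-inflammation grade from inflammatory foci per lobule.

    0: none; 1: fewer than 2 foci per lobule; 2: between 2 and 4 (closed
    interval); 3: more than 4.
    """
    x = foci_per_lobule
    if x < 0:
        raise ValueError("foci count must be non-negative")
    if x == 0:
        return 0
    if x < 2:
        return 1
    if x <= 4:
        return 2
    return 3


_SCHEMES = {
    "mouse": (
        mouse_hypertrophy_score,
        ["n_hypertrophied_cells_per_field", "mean_cell_area_um2"],
        "mouse_hypertrophy_score",
    ),
    "human": (
        human_hypertrophy_score,
        ["n_hypertrophied_areas_per_biopsy"],
        "human_hypertrophy_score",
    ),
    "steatosis": (steatosis_grade, ["fat_area_pct"], "steatosis_grade"),
    "inflammation": (
        inflammation_grade,
        ["foci_per_lobule"],
        "inflammation_grade",
    ),
}


def score_table(df: pd.DataFrame, scheme: str, **kwargs) -> pd.DataFrame:
    """Apply one scoring scheme row-wise, appending the score column.

    ``df`` must contain the scheme's feature columns (e.g. ``fat_area_pct``
    for steatosis).  Extra keyword arguments (e.g. ``size_threshold_um2``)
    are forwarded to the scoring function.
    """
    if scheme not in _SCHEMES:
        raise ValueError(
            f"unknown scheme {scheme!r}; choose from {sorted(_SCHEMES)}"
        )
    fn, cols, out_col = _SCHEMES[scheme]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    out = df.copy()
    out[out_col] = [
        fn(*[row[c] for c in cols], **kwargs) for _, row in df.iterrows()
    ]
    return out
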