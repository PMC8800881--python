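"""Dataset access helpers.

The worked example in the documentation uses the SWMDK questionnaire
(Schaal Welbevinden met Docenten en Klasgenoten: well-being at school with
teachers and classmates): 13 five-point Likert items answered by 639
students from 30 school classes.  That table is distributed inside the R
package ``mokken`` and is not redistributed here; :data:`SWMDK_EXPORT_R`
is a ready-to-run R snippet that exports it to the CSV layout
:func:`load_swmdk` expects (13 item columns ``item1..item13`` plus a
``class`` column).

:func:`synthetic_swmdk` generates a synthetic stand-in with the same
shape (two correlated dimensions, 13 items, 30 classes) for examples and
tests that only need the structure, not the published numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core_data import GroupDesign, ItemScoreMatrix, read_item_scores
from .synthetic import MultilevelGrmSpec, simulate

__all__ = ["SWMDK_EXPORT_R", "load_swmdk", "synthetic_swmdk"]

SWMDK_EXPORT_R = """\
# Run once in R (requires install.packages("mokken")):
library(mokken)
data(SWMDK)
write.csv(
  setNames(SWMDK, c(paste0("item", 1:13), "class")),
  "swmdk.csv", row.names = FALSE
)
"""

SWMDK_ITEMS = tuple(f"item{k}" for k in range(1, 14))
SWMD_FINAL = tuple(f"item{k}" for k in (1, 2, 3, 4, 5, 6))  # teachers
SWMK_FINAL = tuple(f"item{k}" for k in (8, 9, 10, 11, 13))  # classmates


def load_swmdk(path: str | Path) -> tuple[ItemScoreMatrix, GroupDesign]:
    """Load a user-exported SWMDK CSV (see :data:`SWMDK_EXPORT_R`).

    Expects 13 integer item columns named ``item1..item13`` (scores 1-5)
    and a ``class`` group column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. The SWMDK data ship with the R package "
            "'mokken' and are not redistributed; export them once with:\n"
            + SWMDK_EXPORT_R
        )
    matrix, design = read_item_scores(path, group_column="class")
    missing = [c for c in SWMDK_ITEMS if c not in matrix.item_labels]
    if missing:
        raise ValueError(f"SWMDK export is missing columns {missing}")
    return matrix.subset(list(SWMDK_ITEMS)), design


def synthetic_swmdk(seed: int | None = 0,
                    icc: float = 0.17) -> tuple[ItemScoreMatrix,
                                                GroupDesign]:
    """SYNTHETIC stand-in for the SWMDK table (not the published data).

    Two latent dimensions (7 'teacher' and 6 'classmate' items,
    between-dimension correlation 0.5), 30 classes of about 21 students,
    five-point items; the latent ICC default matches the order of
    magnitude reported for classroom well-being scores.  Useful for
    demonstrating the workflow; its coefficient values are its own, not
    those of the real questionnaire.
    """
    rng = np.random.default_rng(seed)
    sizes = tuple(int(s) for s in
                  np.clip(rng.normal(21.3, 6.5, size=30), 8, 35).round())
    base = np.linspace(-1.8, 1.2, 4)
    thresholds = tuple(tuple(base + 0.25 * ((k % 4) - 1.5)) for k in range(13))
    disc = tuple(1.8 if k not in (6, 11) else 0.7 for k in range(13))
    spec = MultilevelGrmSpec(
        n_groups=30,
        group_sizes=sizes,
        icc=icc,
        discriminations=disc,
        thresholds=thresholds,
        item_dims=tuple(int(k >= 7) for k in range(13)),
        dim_correlation=0.5,
        item_labels=SWMDK_ITEMS,
    )
    matrix, design = simulate(spec, rng)
    # report on the 1-5 Likert scale like the questionnaire
    return ItemScoreMatrix(matrix.scores + 1, list(SWMDK_ITEMS)), design
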