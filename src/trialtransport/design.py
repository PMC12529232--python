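"""Design-matrix construction for the harmonized categorical schema.

All analysis variables are small categoricals with a fixed, reference-first
level order (see :mod:`trialtransport.harmonize`), so models share one
dummy-coding convention: full-level indicators with the first listed level
as reference.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .harmonize import CATEGORY_LEVELS

logger = logging.getLogger(__name__)


def design_matrix(
    df: pd.DataFrame,
    terms: list[str],
    add_intercept: bool = True,
    drop_constant: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Build a dense design matrix from categorical terms.

    Each term contributes one indicator per non-reference level.  Columns
    that are constant in ``df`` (e.g. a category level absent from a
    particular survey year) are dropped, otherwise the information matrix
    would be singular.

    Raises on missing values: imputation or complete-case filtering is an
    explicit upstream step, never an implicit drop here.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for term in terms:
        if term not in df.columns:
            raise KeyError(f"term {term!r} not in the record table")
        vals = df[term]
        if vals.isna().any():
            raise ValueError(
                f"{term!r} has {int(vals.isna().sum())} missing values; "
                "impute or restrict to complete cases first"
            )
        levels = CATEGORY_LEVELS.get(term)
        if levels is None:
            cols.append(vals.to_numpy(dtype=float))
            names.append(term)
            continue
        for level in levels[1:]:
            ind = (vals == level).to_numpy(dtype=float)
            if drop_constant and (ind.min() == ind.max()):
                logger.debug("dropping constant design column %s[%s]", term, level)
                continue
            cols.append(ind)
            names.append(f"{term}[{level}]")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names
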