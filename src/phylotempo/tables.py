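"""Reading and aligning species-level trait and covariate tables.

Trait tables are two-column CSV/TSV files with header ``species,value``;
covariate tables carry a ``species`` column plus one numeric column per
variable.  Matching against tree tips is exact-string after a documented
normalization (strip whitespace, unify spaces and underscores).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phylo import Phylogeny, normalize_label

__all__ = [
    "read_trait_table",
    "read_covariate_table",
    "align_trait",
    "align_covariates",
    "AlignmentError",
]


class AlignmentError(ValueError):
    """Species labels in a table do not match the tree tips."""


def _read_delimited(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_trait_table(path) -> pd.Series:
    """Read ``species,value`` CSV/TSV into a Series indexed by species."""
    df = _read_delimited(path)
    if "species" not in df.columns or "value" not in df.columns:
        raise AlignmentError(
            f"trait table must have columns 'species' and 'value', got {list(df.columns)}"
        )
    s = pd.Series(
        pd.to_numeric(df["value"]).to_numpy(),
        index=[str(x) for x in df["species"]],
        name="value",
    )
    dups = s.index[s.index.duplicated()].tolist()
    if dups:
        raise AlignmentError(f"duplicate species in trait table: {sorted(set(dups))}")
    return s


def read_covariate_table(path) -> pd.DataFrame:
    """Read a species × variables CSV into a DataFrame indexed by species."""
    df = _read_delimited(path)
    if "species" not in df.columns:
        raise AlignmentError("covariate table must have a 'species' column")
    df = df.set_index("species")
    df.index = [str(x) for x in df.index]
    dups = df.index[df.index.duplicated()].tolist()
    if dups:
        raise AlignmentError(f"duplicate species in covariate table: {sorted(set(dups))}")
    return df.apply(pd.to_numeric)


def _as_series(y) -> pd.Series:
    if isinstance(y, pd.Series):
        return y
    if isinstance(y, dict):
        return pd.Series(y)
    raise TypeError("trait values must be a pandas Series or a dict keyed by species")


def align_trait(tree: Phylogeny, y) -> np.ndarray:
    """Trait values ordered to match ``tree.tip_labels``.

    Every tip must have a value; extra species in the table are an error so
    silent mismatches cannot slip through (prune the tree or subset the
    table explicitly instead).
    """
    s = _as_series(y)
    lookup = {normalize_label(str(k)): float(v) for k, v in s.items()}
    if len(lookup) != len(s):
        raise AlignmentError("trait table has species that collide after label normalization")
    tips_norm = [normalize_label(t) for t in tree.tip_labels]
    missing = [t for t in tips_norm if t not in lookup]
    if missing:
        raise AlignmentError(f"tips without trait values: {missing}")
    extra = sorted(set(lookup) - set(tips_norm))
    if extra:
        raise AlignmentError(f"trait table species not in tree: {extra}")
    return np.array([lookup[t] for t in tips_norm], dtype=float)


def align_covariates(tree: Phylogeny, X: pd.DataFrame) -> pd.DataFrame:
    """Covariate rows reordered to match ``tree.tip_labels`` (all tips required)."""
    norm_index = {normalize_label(str(k)): k for k in X.index}
    if len(norm_index) != len(X.index):
        raise AlignmentError("covariate table has species that collide after label normalization")
    tips_norm = [normalize_label(t) for t in tree.tip_labels]
    missing = [t for t in tips_norm if t not in norm_index]
    if missing:
        raise AlignmentError(f"tips without covariate rows: {missing}")
    out = X.loc[[norm_index[t] for t in tips_norm]].copy()
    out.index = list(tree.tip_labels)
    return out
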