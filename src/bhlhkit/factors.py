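"""Numeric transformation of amino acids via physicochemical factor scores.

Each of the 20 canonical residues is summarized by five published factor
scores derived from factor analysis of 495 physicochemical property scales:

* ``pah`` - polarity, accessibility, hydrophobicity
* ``pss`` - propensity for secondary structure
* ``ms``  - molecular size / volume
* ``cc``  - codon composition
* ``ec``  - electrostatic charge

Transforming an enumerated alignment with one factor yields a 43-variable
dataset (one value per fixed site); the ``all`` set concatenates the five,
site-major, giving 215 variables.  Gaps become missing values (NaN) — factor
scores are defined only for the canonical residues.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .alignment import GAP, EnumeratedAlignment

FACTOR_NAMES: tuple[str, ...] = ("pah", "pss", "ms", "cc", "ec")
FACTOR_SETS: tuple[str, ...] = FACTOR_NAMES + ("all",)

_TABLE_CACHE: pd.DataFrame | None = None


def load_factor_table() -> pd.DataFrame:
    """The bundled 20x5 factor-score lookup table (rows = amino acids)."""
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        with resources.files("bhlhkit.data").joinpath("atchley_factors.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#", index_col="amino_acid")
        if df.shape != (20, 5) or df.isna().any().any():
            raise RuntimeError("packaged factor-score table is corrupt")
        _TABLE_CACHE = df[list(FACTOR_NAMES)]
    return _TABLE_CACHE


def factor_lookup(residue: str, factor: str) -> float:
    """Score for one residue; GAP (or anything non-canonical) -> NaN."""
    table = load_factor_table()
    if residue == GAP or residue not in table.index:
        return float("nan")
    return float(table.at[residue, factor])


class FactorScoreTransformer(TransformerMixin, BaseEstimator):
    """Map an :class:`EnumeratedAlignment` to a numeric site-by-factor dataset.

    Parameters
    ----------
    factor_set : str
        One of ``pah``, ``pss``, ``ms``, ``cc``, ``ec`` or ``all``.  Single
        factors yield 43 variables; ``all`` yields 215, ordered site-major
        with factors in the order pah, pss, ms, cc, ec within each site.

    Notes
    -----
    The transform is a pure lookup, so ``fit`` only validates parameters.
    Output is a DataFrame indexed like the alignment, with a two-level
    column index ``(site, factor)``.  Cells are NaN exactly where the
    residue is a gap.
    """

    def __init__(self, factor_set: str = "all"):
        self.factor_set = factor_set

    def _factors(self) -> tuple[str, ...]:
        if self.factor_set == "all":
            return FACTOR_NAMES
        if self.factor_set not in FACTOR_NAMES:
            raise ValueError(
                f"unknown factor_set {self.factor_set!r}; expected one of {FACTOR_SETS}"
            )
        return (self.factor_set,)

    def fit(self, X: EnumeratedAlignment, y=None) -> "FactorScoreTransformer":
        self._factors()
        self.n_features_in_ = len(X.coordinates.fixed_sites)
        return self

    def transform(self, X: EnumeratedAlignment) -> pd.DataFrame:
        factors = self._factors()
        table = load_factor_table()
        residues = X.fixed_residues()
        blocks = []
        for site in residues.columns:
            col = residues[site]
            for f in factors:
                mapped = col.map(table[f]).astype(float)
                blocks.append(mapped.rename((site, f)))
        out = pd.concat(blocks, axis=1)
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["site", "factor"])
        return out


def transform_alignment(
    alignment: EnumeratedAlignment, factor_set: str = "all"
) -> pd.DataFrame:
    """Functional wrapper over :class:`FactorScoreTransformer`."""
    return FactorScoreTransformer(factor_set=factor_set).fit(alignment).transform(alignment)


def write_numeric_tsv(X: pd.DataFrame, path) -> None:
    """Export a numeric dataset with ``site<k>:<factor>`` header descriptors."""
    out = X.copy()
    out.columns = [f"site{s}:{f}" for s, f in out.columns]
    out.index.name = "sequence_id"
    out.to_csv(path, sep="\t", na_rep="NA")
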