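"""Survey sampling weights and weighted descriptive tables.

The facility survey behind the analysis drew a stratified sample of
facilities from a national frame; the design weight of a responding
facility is the reciprocal of the product of the sampling fraction ps and
the response rate pr, sw = 1 / (ps * pr).  Raw weights are normalised to
mean one over the analysis sample (so weighted totals keep the sample
size) and applied to descriptive tabulations only: the hierarchical
posterior uses the unweighted likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurveyDesign",
    "compute_sampling_weight",
    "normalize_weights",
    "weighted_tabulate",
]


def compute_sampling_weight(ps: float, pr: float) -> float:
    """Design weight sw = 1 / (ps * pr).

    Parameters
    ----------
    ps : float
        Sampling fraction (sampled / frame), in (0, 1].
    pr : float
        Response rate (responded / sampled), in (0, 1].
    """
    for name, v in (("ps", ps), ("pr", pr)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    return 1.0 / (ps * pr)


@dataclass
class SurveyDesign:
    """Facility sampling design: frame size, sampled and responding counts.

    ``ps``, ``pr`` and ``sw`` are derived exactly from the counts unless
    given explicitly (the published figures round ps and pr before forming
    sw, so both pipelines are expressible).
    """

    n_frame: int
    n_sampled: int
    n_responded: int
    ps: float = None
    pr: float = None
    strata: list = None

    def __post_init__(self):
        if not (0 < self.n_sampled <= self.n_frame):
            raise ValueError("need 0 < n_sampled <= n_frame")
        if not (0 < self.n_responded <= self.n_sampled):
            raise ValueError("need 0 < n_responded <= n_sampled")
        if self.ps is None:
            self.ps = self.n_sampled / self.n_frame
        if self.pr is None:
            self.pr = self.n_responded / self.n_sampled

    @property
    def sw(self) -> float:
        return compute_sampling_weight(self.ps, self.pr)


def normalize_weights(weights, strata=None) -> np.ndarray:
    """Scale weights so they average one over the sample.

    The global rescale preserves all weight ratios (within and between
    strata); ``strata`` labels are accepted for interface symmetry and
    validated to cover every row.  Idempotent: normalising an already
    mean-one vector returns it unchanged.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty vector")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if strata is not None and len(strata) != len(w):
        raise ValueError("strata labels must cover all rows")
    return w * (len(w) / w.sum())


def weighted_tabulate(data, variable: str, by: str = None, weight: str = "weight",
                      levels=None) -> pd.DataFrame:
    """Weighted percentage table of ``variable``, optionally within ``by``.

    ``data`` is a DataFrame or an :class:`~ordcar.datasets.OrdinalDataset`
    (converted via ``to_frame``).  Percentages sum to 100 within each
    ``by`` cell; with unit weights they equal the raw frequency table.
    ``levels`` forces the set of reported levels (e.g. all outcome
    categories 1..K even when one is empty).

    Returns a DataFrame with columns
    ``variable, level, by_level, weighted_pct, unweighted_n``.
    """
    if hasattr(data, "to_frame") and not isinstance(data, pd.DataFrame):
        df = data.to_frame()
    else:
        df = data.copy()
    for col in (variable,) + ((by,) if by else ()):
        if col not in df.columns:
            raise KeyError(f"variable {col!r} not in dataset")
    w = df[weight] if weight in df.columns else pd.Series(1.0, index=df.index)
    df = df.assign(_w=w)
    if levels is None:
        levels = sorted(df[variable].unique())
    by_levels = sorted(df[by].unique()) if by else [None]
    rows = []
    for bl in by_levels:
        cell = df if bl is None else df[df[by] == bl]
        total = cell["_w"].sum()
        for lv in levels:
            sub = cell[cell[variable] == lv]
            rows.append({
                "variable": variable,
                "level": lv,
                "by_level": bl,
                "weighted_pct": 100.0 * sub["_w"].sum() / total if total > 0 else np.nan,
                "unweighted_n": int(len(sub)),
            })
    return pd.DataFrame(rows)
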