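"""Annual stereotype and medicalization scores, reliability, panel assembly.

The annual stereotype score (``sas``) is the mean rater sentiment (1-5) over
the year's retained collocates; the medicalization score (``med``) is the
mean per-word medical flag, a proportion in [0, 1].  ``type`` weighting
counts each retained collocate once; ``token`` weighting weights by its
co-occurrence count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .collocation import CollocateRecord
from .corpus_io import RatingLexicon, read_covariates

__all__ = [
    "AnnualPanel",
    "mean_sentiment",
    "cronbach_alpha",
    "annual_sas",
    "annual_medicalization",
    "build_panel",
    "support_ratio_decline",
    "packaged_support_ratio",
]

PANEL_COLUMNS = ["year", "sas", "med", "n_collocates", "policy", "support_ratio"]


@dataclass
class AnnualPanel:
    """One row per year: scores, policy indicator, support ratio.

    ``check_bounds=False`` relaxes the [1,5] / [0,1] score bounds so that
    synthetic panels generated from unbounded structural equations can reuse
    the same container.
    """

    data: pd.DataFrame
    check_bounds: bool = True

    def __post_init__(self) -> None:
        missing = set(PANEL_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        self.data = self.data[PANEL_COLUMNS].reset_index(drop=True)
        years = self.data["year"].to_numpy()
        if len(years) and not np.all(np.diff(years) > 0):
            raise ValueError("panel years must be strictly increasing with no duplicates")
        policy = self.data["policy"].to_numpy()
        if len(policy) and np.any(np.diff(policy) < 0):
            raise ValueError("policy indicator must be non-decreasing in year")
        if self.check_bounds:
            sas = self.data["sas"].to_numpy(dtype=float)
            med = self.data["med"].to_numpy(dtype=float)
            ok_sas = np.isnan(sas) | ((sas >= 1.0) & (sas <= 5.0))
            ok_med = np.isnan(med) | ((med >= 0.0) & (med <= 1.0))
            if not ok_sas.all():
                raise ValueError("sas scores must lie in [1, 5]")
            if not ok_med.all():
                raise ValueError("med scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def years(self) -> np.ndarray:
        return self.data["year"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, check_bounds: bool = True) -> "AnnualPanel":
        return cls(pd.read_csv(path, sep="\t"), check_bounds=check_bounds)


def mean_sentiment(entry) -> float:
    """Arithmetic mean of a lexicon entry's rater sentiments (1-5)."""
    if not entry.sentiment_ratings:
        raise ValueError(f"entry {entry.word!r} has no ratings")
    return sum(entry.sentiment_ratings) / len(entry.sentiment_ratings)


def cronbach_alpha(
    ratings: np.ndarray, ci: float = 0.95
) -> tuple[float, float, float]:
    """Cronbach's alpha over an item x rater matrix, with a Feldt
    F-distribution confidence interval.

    alpha = K/(K-1) * (1 - sum_j var_j / var_total), variances across items
    (ddof=1).  Returns ``(alpha, ci_low, ci_high)``; all NaN (with a warning)
    when the total variance is zero.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2-D item x rater matrix")
    n_items, k = ratings.shape
    if k < 2:
        raise ValueError("need >= 2 raters")
    if n_items < 3:
        raise ValueError("need >= 3 items")
    if np.isnan(ratings).any():
        raise ValueError("ratings matrix has missing cells")
    var_total = ratings.sum(axis=1).var(ddof=1)
    if var_total == 0:
        warnings.warn("total variance is zero; alpha undefined", stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    var_j = ratings.var(axis=0, ddof=1).sum()
    alpha = (k / (k - 1)) * (1 - var_j / var_total)
    df1 = n_items - 1
    df2 = df1 * (k - 1)
    tail = (1 - ci) / 2
    lo = 1 - (1 - alpha) * stats.f.isf(tail, df1, df2)
    hi = 1 - (1 - alpha) * stats.f.isf(1 - tail, df1, df2)
    return float(alpha), float(lo), float(hi)


def _annual_score(
    records: Iterable[CollocateRecord],
    per_word_value,
    weighting: Literal["type", "token"],
) -> pd.Series:
    by_year: dict[int, list[CollocateRecord]] = {}
    for rec in records:
        by_year.setdefault(rec.year, []).append(rec)
    out = {}
    for year in sorted(by_year):
        retained = [r for r in by_year[year] if r.retained]
        if not retained:
            warnings.warn(f"year {year}: no retained collocates; score is missing", stacklevel=3)
            out[year] = float("nan")
            continue
        values = np.array([per_word_value(r.word) for r in retained], dtype=float)
        if weighting == "type":
            out[year] = float(values.mean())
        elif weighting == "token":
            w = np.array([r.f_near for r in retained], dtype=float)
            if w.sum() == 0:
                out[year] = float(values.mean())
            else:
                out[year] = float(np.average(values, weights=w))
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
    return pd.Series(out, name="score")


def annual_sas(
    records: Iterable[CollocateRecord],
    lexicon: RatingLexicon,
    weighting: Literal["type", "token"] = "type",
) -> pd.Series:
    """Per-year mean sentiment over retained collocates (values in [1, 5])."""
    records = list(records)
    for r in records:
        if r.retained and r.word not in lexicon:
            raise ValueError(f"retained collocate {r.word!r} has no lexicon entry")
    return _annual_score(records, lambda w: lexicon[w].mean_sentiment, weighting)


def annual_medicalization(
    records: Iterable[CollocateRecord],
    lexicon: RatingLexicon,
    weighting: Literal["type", "token"] = "type",
) -> pd.Series:
    """Per-year mean medical-flag value over retained collocates ([0, 1]).

    A word whose raters disagree (flags 1 and 0) contributes 0.5.
    """
    records = list(records)
    for r in records:
        if r.retained and r.word not in lexicon:
            raise ValueError(f"retained collocate {r.word!r} has no lexicon entry")
    return _annual_score(records, lambda w: lexicon[w].mean_medical, weighting)


def n_retained_by_year(records: Iterable[CollocateRecord]) -> pd.Series:
    out: dict[int, int] = {}
    for r in records:
        if r.retained:
            out[r.year] = out.get(r.year, 0) + 1
    return pd.Series(out, dtype=int).sort_index()


def build_panel(
    sas: Mapping[int, float] | pd.Series,
    med: Mapping[int, float] | pd.Series,
    covariates: pd.DataFrame,
    policy_year: int,
    n_collocates: Mapping[int, int] | pd.Series | None = None,
    check_bounds: bool = True,
) -> AnnualPanel:
    """Assemble the year-level panel; policy = 1 iff year >= policy_year.

    Every scored year must appear in the covariate table (hard error
    otherwise).
    """
    sas = pd.Series(sas, dtype=float)
    med = pd.Series(med, dtype=float)
    years = sorted(set(sas.index) | set(med.index))
    cov = covariates.set_index("year")
    missing = [y for y in years if y not in cov.index]
    if missing:
        raise ValueError(f"covariate table missing years: {missing}")
    n_coll = pd.Series(n_collocates, dtype=float) if n_collocates is not None else None
    rows = []
    for y in years:
        rows.append(
            {
                "year": int(y),
                "sas": float(sas.get(y, np.nan)),
                "med": float(med.get(y, np.nan)),
                "n_collocates": int(n_coll.get(y, 0)) if n_coll is not None else 0,
                "policy": int(y >= policy_year),
                "support_ratio": float(cov.loc[y, "support_ratio"]),
            }
        )
    return AnnualPanel(pd.DataFrame(rows), check_bounds=check_bounds)


def support_ratio_decline(panel_or_covariates) -> float:
    """Percentage decline of the support ratio between the first and last
    year: 100 * (r_first - r_last) / r_first."""
    if isinstance(panel_or_covariates, AnnualPanel):
        df = panel_or_covariates.data
    else:
        df = panel_or_covariates
    df = df.sort_values("year")
    first = float(df["support_ratio"].iloc[0])
    last = float(df["support_ratio"].iloc[-1])
    return 100.0 * (first - last) / first


def packaged_support_ratio() -> pd.DataFrame:
    """The shipped old-age support-ratio fixture (2010-2017; endpoints 7.4
    and 5.1, intermediate years linearly interpolated)."""
    with resources.as_file(
        resources.files("agestereo.data").joinpath("support_ratio_2010_2017.tsv")
    ) as p:
        return read_covariates(p)
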