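"""Packaged aggregate tables from the published Haiti HIV-testing study.

These are the *printed* marginal tables of the source surveys — group
shares and group-specific prevalences per wave, per-wave tested /
not-tested totals, and the fitted-model variance ladder of the earliest
wave.  They let the trend and decomposition layers be exercised (and the
published headline numbers re-derived) without access to the
registration-gated microdata.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import GroupSummary

__all__ = [
    "haiti_group_margins",
    "haiti_totals",
    "haiti_variance_2006",
    "group_summaries_from_margins",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("prevdecomp.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def haiti_group_margins() -> pd.DataFrame:
    """Per-wave education and age-group shares (%) and group-specific
    outcome prevalences (%)."""
    return _read("haiti_group_margins.csv")


def haiti_totals() -> pd.DataFrame:
    """Per-wave tested / not-tested respondent counts."""
    return _read("haiti_totals.csv")


def haiti_variance_2006() -> pd.DataFrame:
    """Cluster variance and log-likelihood of the four-model ladder fitted
    to the earliest wave."""
    return _read("haiti_variance_2006.csv")


def group_summaries_from_margins(
    covariate: str, wave: str, margins: pd.DataFrame | None = None
) -> list[GroupSummary]:
    """Build :class:`GroupSummary` lists from the printed margins.

    Shares are renormalized to sum exactly to 1 (printed percentages carry
    rounding error); prevalences are used as printed.
    """
    df = haiti_group_margins() if margins is None else margins
    sub = df[(df["covariate"] == covariate) & (df["wave"].astype(str) == str(wave))]
    if sub.empty:
        raise KeyError(f"no margins for covariate {covariate!r}, wave {wave!r}")
    total = sub["share_pct"].sum()
    return [
        GroupSummary(
            group=row.category,
            share=row.share_pct / total,
            prevalence=row.prevalence_pct / 100.0,
            n_effective=float("nan"),
        )
        for row in sub.itertuples(index=False)
    ]
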