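"""Kitagawa decomposition of a between-wave change in prevalence.

The overall prevalence in one wave is a share-weighted average over
subgroups, ``Y_t = sum_j w_jt * y_jt`` with weighted shares ``w_jt`` and
subgroup prevalences ``y_jt``.  The change between two waves splits
exactly into

* a **compositional** component ``sum_j (dw_j) * ybar_j`` — shifts in
  subgroup sizes, holding subgroup rates at their two-wave midpoint — and
* a **behavioral** component ``sum_j wbar_j * (dy_j)`` — shifts in
  subgroup rates, holding shares at their midpoint.

Midpoint weighting is the unique symmetric variant with no interaction
remainder, so ``compositional + behavioral == delta_Y`` holds to machine
precision and is enforced as an invariant.

The behavioral component can be refined further: regress the subgroup
rates on a numeric score ``X_j`` of an auxiliary covariate within each
wave (``y_j = a + b X_j + e_j``), then each subgroup's rate change splits
exactly into an intercept shift, a covariate-level shift, a slope shift
and a residual via the midpoint product rule

    dy_j = da + bbar * dX_j + Xbar_j * db + de_j.

When the covariate scores do not move between waves the middle term
vanishes and the split reduces to intercept + slope + residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GroupSummary, SurveyRecord, as_frame

logger = logging.getLogger(__name__)

__all__ = [
    "DecompositionResult",
    "AdvancedDecompositionResult",
    "GroupContribution",
    "summarize_groups",
    "basic_decomposition",
    "decompose_summaries",
    "advanced_decomposition",
]


@dataclass(frozen=True)
class GroupContribution:
    """One subgroup's terms in the two-component split."""

    group: str | tuple[str, ...]
    d_share: float
    mid_share: float
    d_prevalence: float
    mid_prevalence: float
    compositional: float
    behavioral: float


@dataclass(frozen=True)
class DecompositionResult:
    delta_Y: float
    compositional: float
    behavioral: float
    per_group: tuple[GroupContribution, ...]
    compositional_share: float
    behavioral_share: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g.group,
                "d_share": g.d_share,
                "mid_share": g.mid_share,
                "d_prevalence": g.d_prevalence,
                "mid_prevalence": g.mid_prevalence,
                "compositional": g.compositional,
                "behavioral": g.behavioral,
            }
            for g in self.per_group
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BehavioralSplit:
    """Refinement of one subgroup's behavioral term."""

    group: str | tuple[str, ...]
    intercept_term: float  # wbar_j * da
    covariate_term: float  # wbar_j * bbar * dX_j
    slope_term: float  # wbar_j * Xbar_j * db
    residual_term: float  # wbar_j * de_j


@dataclass(frozen=True)
class AdvancedDecompositionResult:
    basic: DecompositionResult
    per_group_behavioral_split: tuple[BehavioralSplit, ...]
    alpha_change: float
    beta_change: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": s.group,
                "intercept_term": s.intercept_term,
                "covariate_term": s.covariate_term,
                "slope_term": s.slope_term,
                "residual_term": s.residual_term,
            }
            for s in self.per_group_behavioral_split
        ]
        return pd.DataFrame(rows)


def summarize_groups(
    data: pd.DataFrame | Iterable[SurveyRecord],
    wave: str,
    grouping: str | Sequence[str],
    all_groups: Sequence[str | tuple[str, ...]] | None = None,
) -> list[GroupSummary]:
    """Weighted share and prevalence of each subgroup within one wave.

    ``grouping`` may be one covariate name or several (cross-classified
    groups are labelled by tuples).  ``all_groups`` forces the output to
    cover a fixed group set; groups absent from the wave are included with
    share 0 and prevalence 0 (warned), so two waves can always be compared
    on a common group set.
    """
    frame = as_frame(data)
    sub = frame[frame["wave"].astype(str) == str(wave)]
    if sub.empty:
        raise ValueError(f"wave {wave!r} has no records")
    keys = [grouping] if isinstance(grouping, str) else list(grouping)
    W = sub["weight"].sum()
    agg = sub.groupby(keys, sort=False, observed=True).apply(
        lambda g: pd.Series(
            {
                "share": g["weight"].sum() / W,
                "prevalence": (g["weight"] * g["outcome"]).sum() / g["weight"].sum(),
                "n_effective": g["weight"].sum(),
            }
        ),
        include_groups=False,
    )
    summaries: dict[object, GroupSummary] = {}
    for key, row in agg.iterrows():
        label = key if isinstance(grouping, str) or len(keys) == 1 else tuple(key)
        if isinstance(label, tuple) and len(label) == 1:
            label = label[0]
        summaries[label] = GroupSummary(
            group=label,
            share=float(row["share"]),
            prevalence=float(row["prevalence"]),
            n_effective=float(row["n_effective"]),
        )
    if all_groups is not None:
        out = []
        for g in all_groups:
            if g in summaries:
                out.append(summaries[g])
            else:
                logger.warning(
                    "group %r absent in wave %r: share 0, prevalence defined as 0", g, wave
                )
                out.append(GroupSummary(group=g, share=0.0, prevalence=0.0, n_effective=0.0))
        return out
    return list(summaries.values())


def _check_pair(
    wave_t: Sequence[GroupSummary], wave_t1: Sequence[GroupSummary]
) -> None:
    gt = [s.group for s in wave_t]
    gt1 = [s.group for s in wave_t1]
    if gt != gt1:
        only_t = set(map(str, gt)) - set(map(str, gt1))
        only_t1 = set(map(str, gt1)) - set(map(str, gt))
        raise ValueError(
            "group sets differ between waves: "
            f"only in first {sorted(only_t)}, only in second {sorted(only_t1)}; "
            "use summarize_groups(..., all_groups=...) to align them"
        )


def decompose_summaries(
    wave_t: Sequence[GroupSummary], wave_t1: Sequence[GroupSummary]
) -> DecompositionResult:
    """Two-component split of the prevalence change between two waves.

    Both inputs must cover the identical ordered group set.  Shares of the
    change are percentages of the signed total change, so a component
    working against the total appears negative; the two shares always sum
    to 100.
    """
    _check_pair(wave_t, wave_t1)
    per_group = []
    comp = beh = 0.0
    for a, b in zip(wave_t, wave_t1):
        d_share = b.share - a.share
        mid_prev = 0.5 * (a.prevalence + b.prevalence)
        d_prev = b.prevalence - a.prevalence
        mid_share = 0.5 * (a.share + b.share)
        c = d_share * mid_prev
        h = mid_share * d_prev
        comp += c
        beh += h
        per_group.append(
            GroupContribution(
                group=a.group,
                d_share=d_share,
                mid_share=mid_share,
                d_prevalence=d_prev,
                mid_prevalence=mid_prev,
                compositional=c,
                behavioral=h,
            )
        )
    delta = comp + beh
    if delta != 0:
        comp_share = 100.0 * comp / delta
        beh_share = 100.0 - comp_share
    else:
        comp_share = beh_share = 0.0
    return DecompositionResult(
        delta_Y=delta,
        compositional=comp,
        behavioral=beh,
        per_group=tuple(per_group),
        compositional_share=comp_share,
        behavioral_share=beh_share,
    )


def basic_decomposition(
    data: pd.DataFrame | Iterable[SurveyRecord],
    wave_t: str,
    wave_t1: str,
    grouping: str | Sequence[str],
) -> DecompositionResult:
    """Convenience wrapper: summarize both waves on a common group set and
    decompose the change."""
    frame = as_frame(data)
    keys = [grouping] if isinstance(grouping, str) else list(grouping)
    groups = list(
        frame[frame["wave"].astype(str).isin([str(wave_t), str(wave_t1)])]
        .groupby(keys, sort=False, observed=True)
        .groups
    )
    if len(keys) == 1:
        groups = [g if not isinstance(g, tuple) else g[0] for g in groups]
    st = summarize_groups(frame, wave_t, grouping, all_groups=groups)
    st1 = summarize_groups(frame, wave_t1, grouping, all_groups=groups)
    return decompose_summaries(st, st1)


# ---------------------------------------------------------------------------
# regression-refined ("advanced") decomposition


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on x; returns (intercept, slope)."""
    w = np.asarray(w, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    sxx = np.average((x - xm) ** 2, weights=w)
    if sxx <= 0:
        raise ValueError("covariate score is constant: slope unidentified")
    sxy = np.average((x - xm) * (y - ym), weights=w)
    b = sxy / sxx
    return ym - b * xm, b


def advanced_decomposition(
    data: pd.DataFrame | Iterable[SurveyRecord],
    wave_t: str,
    wave_t1: str,
    grouping: str,
    within_covariate: str,
    scores: dict[str, float] | None = None,
) -> AdvancedDecompositionResult:
    """Refine the behavioral component through a within-group covariate.

    For each wave the subgroup prevalences ``y_j`` (groups defined by
    ``grouping``) are regressed on the group-level mean score ``X_j`` of
    ``within_covariate`` (ordinal ranks 0, 1, 2, ... by default, or
    user-supplied ``scores``), weighted by group share.  Writing the fit of
    wave ``t`` as ``y_j = a_t + b_t X_jt + e_jt``, each group's rate change
    splits exactly (midpoint product rule) into

        dy_j = da + bbar dX_j + Xbar_j db + de_j,

    and multiplying by the midpoint share gives an exact refinement of the
    group's behavioral term.
    """
    frame = as_frame(data)
    cats = list(pd.unique(frame[within_covariate]))
    if len(cats) < 2:
        raise ValueError(f"within covariate {within_covariate!r} needs >=2 categories")
    for wave in (wave_t, wave_t1):
        present = set(frame.loc[frame["wave"].astype(str) == str(wave), within_covariate])
        if present != set(cats):
            raise ValueError(
                f"within covariate {within_covariate!r} categories differ by wave"
            )
    if scores is None:
        scores = {c: float(i) for i, c in enumerate(sorted(cats))}
    basic = basic_decomposition(frame, wave_t, wave_t1, grouping)
    groups = [g.group for g in basic.per_group]

    def wave_stats(wave: str):
        sub = frame[frame["wave"].astype(str) == str(wave)].copy()
        sub["_x"] = sub[within_covariate].map(scores).astype(float)
        g = sub.groupby(grouping, sort=False, observed=True)
        share = g["weight"].sum() / sub["weight"].sum()
        prev = g.apply(
            lambda d: (d["weight"] * d["outcome"]).sum() / d["weight"].sum(),
            include_groups=False,
        )
        xbar = g.apply(
            lambda d: (d["weight"] * d["_x"]).sum() / d["weight"].sum(),
            include_groups=False,
        )
        share = share.reindex(groups).fillna(0.0)
        prev = prev.reindex(groups).fillna(0.0)
        xbar = xbar.reindex(groups).fillna(0.0)
        a, b = _wls_line(xbar.to_numpy(), prev.to_numpy(), share.to_numpy())
        resid = prev.to_numpy() - (a + b * xbar.to_numpy())
        return share.to_numpy(), prev.to_numpy(), xbar.to_numpy(), a, b, resid

    _, _, x_t, a_t, b_t, e_t = wave_stats(wave_t)
    _, _, x_t1, a_t1, b_t1, e_t1 = wave_stats(wave_t1)

    da, db = a_t1 - a_t, b_t1 - b_t
    bbar = 0.5 * (b_t + b_t1)
    xbar = 0.5 * (x_t + x_t1)
    dx = x_t1 - x_t
    de = e_t1 - e_t
    splits = []
    for j, g in enumerate(basic.per_group):
        splits.append(
            BehavioralSplit(
                group=groups[j],
                intercept_term=g.mid_share * da,
                covariate_term=g.mid_share * bbar * dx[j],
                slope_term=g.mid_share * xbar[j] * db,
                residual_term=g.mid_share * de[j],
            )
        )
    return AdvancedDecompositionResult(
        basic=basic,
        per_group_behavioral_split=tuple(splits),
        alpha_change=da,
        beta_change=db,
    )
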