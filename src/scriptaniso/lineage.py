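"""Cultural-transformation analyses over ancestor -> descendant branch events.

For each documented branching-out event the descendant's value on a measure
is compared with its ancestor's (descendant minus ancestor). Differentials
are grouped by ancestry (scripts sharing an ancestor nest together) and fed
to a random-intercept model whose intercept estimates the directional trend,
plus a default-prior Bayes factor for the no-trend null. Events with an
undefined endpoint are excluded pairwise per measure and logged, which is why
different measures can have different numbers of usable pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .inference import (
    BayesFactorResult,
    GroupedObservations,
    LmmFit,
    fit_intercept_model,
    jzs_bf01,
    product_moment_correlation,
    rank_correlation,
)
from .model import BranchEvent, ScriptCollection


@dataclass(frozen=True)
class DifferentialRecord:
    """One usable ancestor -> descendant differential for one feature."""

    event: BranchEvent
    feature: str
    delta: float
    ancestor_value: float
    descendant_value: float
    ancestry_group: str


@dataclass
class ExclusionLog:
    """Events excluded from a differential analysis, with reasons."""

    feature: str
    entries: list[tuple[BranchEvent, str]] = field(default_factory=list)

    def add(self, event: BranchEvent, reason: str) -> None:
        self.entries.append((event, reason))

    def __len__(self) -> int:
        return len(self.entries)


def _measure_lookup(measures: pd.DataFrame, feature: str) -> dict[str, float]:
    if feature not in measures.columns:
        raise KeyError(f"feature {feature!r} not among measure columns {list(measures.columns)}")
    out = {}
    for _, row in measures.iterrows():
        v = row[feature]
        if v is not None and pd.notna(v) and np.isfinite(float(v)):
            out[str(row["script"])] = float(v)
    return out


def branch_differentials(
    measures: pd.DataFrame,
    events: Sequence[BranchEvent],
    feature: str,
    collection: Optional[ScriptCollection] = None,
) -> tuple[list[DifferentialRecord], ExclusionLog]:
    """Descendant-minus-ancestor differentials for one feature.

    ``measures`` is a measures table (one row per script, feature columns).
    Events whose endpoints are missing from the table or undefined on the
    feature are excluded and logged; an event naming a script absent from the
    given collection raises.
    """
    if collection is not None:
        collection.resolve_events(events)
    values = _measure_lookup(measures, feature)
    known = set(str(s) for s in measures["script"])
    records: list[DifferentialRecord] = []
    log = ExclusionLog(feature=feature)
    for ev in events:
        missing = [c for c in (ev.ancestor, ev.descendant) if c not in known]
        if missing and collection is None:
            raise KeyError(f"event {ev.ancestor}->{ev.descendant}: unknown script(s) {missing}")
        undefined = [c for c in (ev.ancestor, ev.descendant) if c not in values]
        if undefined:
            log.add(ev, f"undefined {feature} for {', '.join(undefined)}")
            continue
        records.append(
            DifferentialRecord(
                event=ev,
                feature=feature,
                delta=values[ev.descendant] - values[ev.ancestor],
                ancestor_value=values[ev.ancestor],
                descendant_value=values[ev.descendant],
                ancestry_group=ev.ancestor,
            )
        )
    return records, log


@dataclass
class TransformationResult:
    feature: str
    fit: LmmFit
    bayes: BayesFactorResult
    n_pairs: int
    exclusions: ExclusionLog


def transformation_test(
    diffs: Sequence[DifferentialRecord],
    exclusions: Optional[ExclusionLog] = None,
    method: str = "REML",
    prior_scale: Optional[float] = None,
) -> TransformationResult:
    """Directional-trend test on differentials grouped by ancestry.

    The random-intercept model's fixed intercept is the average
    descendant-minus-ancestor change; the JZS Bayes factor quantifies support
    for the null of no directional change.
    """
    if not diffs:
        raise ValueError("no usable differentials")
    feature = diffs[0].feature
    deltas = np.array([d.delta for d in diffs])
    groups = np.array([d.ancestry_group for d in diffs])
    obs = GroupedObservations(y=deltas, group=groups)
    if obs.n_groups < 2:
        raise ValueError("need differentials from at least 2 ancestry groups")
    fit = fit_intercept_model(obs, method=method)
    kwargs = {} if prior_scale is None else {"prior_scale": prior_scale}
    if np.ptp(deltas) == 0.0:
        if deltas[0] != 0.0:
            raise ValueError("constant nonzero differentials: Bayes factor undefined")
        # every differential exactly zero: the point null is supported exactly
        bayes = BayesFactorResult(bf01=math.inf, t=0.0, n=len(deltas), prior_scale=kwargs.get("prior_scale", float(np.sqrt(2) / 2)))
    else:
        bayes = jzs_bf01(deltas, **kwargs)
    return TransformationResult(
        feature=feature,
        fit=fit,
        bayes=bayes,
        n_pairs=len(diffs),
        exclusions=exclusions or ExclusionLog(feature=feature),
    )


def heritability_correlation(
    diffs: Sequence[DifferentialRecord],
    kind: Literal["rank", "product_moment"] = "rank",
) -> tuple[float, float, int]:
    """Correlation between ancestor and descendant values over usable pairs."""
    if len(diffs) < 3:
        raise ValueError("need at least 3 usable pairs")
    anc = [d.ancestor_value for d in diffs]
    desc = [d.descendant_value for d in diffs]
    if kind == "rank":
        coef, p = rank_correlation(anc, desc)
    elif kind == "product_moment":
        coef, p = product_moment_correlation(anc, desc)
    else:
        raise ValueError(f"unknown correlation kind {kind!r}")
    return coef, p, len(diffs)


@dataclass
class FidelityResult:
    overall: float
    n_events: int
    by_ancestor_trait: dict[str, tuple[float, int]]


def inheritance_fidelity(
    collection: ScriptCollection,
    events: Sequence[BranchEvent],
    trait: str = "direction",
) -> FidelityResult:
    """Proportion of branch events in which the descendant keeps the trait.

    The per-ancestor-trait breakdown gives, for each trait value among
    ancestors (e.g. each direction of reading), the retention rate and the
    number of events starting from that value.
    """
    collection.resolve_events(events)
    matches: list[bool] = []
    by_trait: dict[str, list[bool]] = {}
    for ev in events:
        a = getattr(collection[ev.ancestor], trait)
        d = getattr(collection[ev.descendant], trait)
        same = a == d
        matches.append(same)
        by_trait.setdefault(str(a), []).append(same)
    if not matches:
        raise ValueError("no usable events")
    return FidelityResult(
        overall=float(np.mean(matches)),
        n_events=len(matches),
        by_ancestor_trait={k: (float(np.mean(v)), len(v)) for k, v in by_trait.items()},
    )
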