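"""Target-gene normalization and the effect of reference choice on circadian profiles.

A target gene's relative quantities are divided sample-wise by a normalization
factor (the geometric mean of a chosen reference-gene set). Comparing the same
target normalized under different reference strategies — a single habitual
reference versus the top-ranked stable pair — quantifies how much an unstable
reference distorts the apparent circadian profile and, in multi-strain designs,
the apparent between-strain fold change: a reference carrying a strain-specific
log2 offset delta inflates (or deflates) the target's strain ratio by exactly
2**delta.

Rhythm summaries come from a least-squares 24 h cosinor fit on log2 normalized
values: y = mesor + A cos(2*pi*(t - acrophase)/24). The peak time is the
acrophase and the peak/trough fold is 2**(2A). Strain fold changes are
geometric: mean log2 differences between strains over shared time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ValidationError
from .genorm import normalization_factor

__all__ = [
    "NormalizedProfile",
    "RhythmSummary",
    "normalize_target",
    "estimate_rhythm",
    "strain_fold_change",
    "compare_strategies",
]

PERIOD_H = 24.0


@dataclass
class NormalizedProfile:
    """A target gene normalized under one reference strategy.

    ``values`` holds one row per sample (``sample_id, strain, time_ct, value``);
    ``summary`` aggregates to mean, sd and n per (strain, time_ct) cell.
    """

    target: str
    strategy: str
    values: pd.DataFrame
    summary: pd.DataFrame


@dataclass(frozen=True)
class RhythmSummary:
    """Cosinor summary of one normalized profile."""

    peak_time: float | None  # hours CT; None when the profile is arrhythmic
    amplitude_fold: float  # peak mean / trough mean, >= 1
    mesor_log2: float
    amplitude_log2: float
    peak_defined: bool


def normalize_target(
    q_target: pd.Series,
    nf: pd.Series,
    meta: pd.DataFrame,
    target: str = "target",
    strategy: str = "custom",
) -> NormalizedProfile:
    """Divide a target's per-sample quantities by a per-sample normalization factor."""
    missing = sorted(set(q_target.index) ^ set(nf.index))
    if missing:
        raise ValidationError(
            f"target and normalization factor cover different samples; "
            f"difference: {missing[:10]}"
        )
    norm = q_target / nf.reindex(q_target.index)
    cols = [c for c in ("strain", "tissue", "time_ct") if c in meta.columns]
    values = (
        meta.set_index("sample_id")
        .loc[norm.index, cols]
        .assign(value=norm)
        .rename_axis("sample_id")
        .reset_index()
    )
    summary = (
        values.groupby(["strain", "time_ct"])["value"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    summary["sd"] = summary["sd"].fillna(0.0)
    return NormalizedProfile(
        target=target, strategy=strategy, values=values, summary=summary
    )


def estimate_rhythm(
    profile: NormalizedProfile | pd.DataFrame, amp_tol: float = 1e-9
) -> RhythmSummary:
    """Fit a 24 h cosinor to log2 normalized values and summarize the rhythm.

    Accepts a :class:`NormalizedProfile` or its ``values`` frame. Requires at
    least 4 distinct time points. A fitted amplitude below ``amp_tol`` (log2)
    marks the peak time undefined (``peak_defined`` False, amplitude_fold 1).
    """
    values = profile.values if isinstance(profile, NormalizedProfile) else profile
    t = values["time_ct"].to_numpy(float)
    if len(np.unique(t)) < 4:
        raise ValidationError(
            f"cosinor fit needs >= 4 distinct time points, got {len(np.unique(t))}"
        )
    y = np.log2(values["value"].to_numpy(float))
    omega = 2.0 * np.pi / PERIOD_H
    design = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    (mesor, a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    amplitude = float(np.hypot(a, b))
    if amplitude < amp_tol:
        return RhythmSummary(
            peak_time=None,
            amplitude_fold=1.0,
            mesor_log2=float(mesor),
            amplitude_log2=0.0,
            peak_defined=False,
        )
    acrophase = float(np.arctan2(b, a) / omega % PERIOD_H)
    return RhythmSummary(
        peak_time=acrophase,
        amplitude_fold=float(2.0 ** (2.0 * amplitude)),
        mesor_log2=float(mesor),
        amplitude_log2=amplitude,
        peak_defined=True,
    )


def strain_fold_change(
    profile: NormalizedProfile, strain_a: str, strain_b: str
) -> float:
    """Geometric fold change of strain_a over strain_b across shared time points.

    Within each (strain, time) cell the geometric mean of normalized values is
    taken; the fold change is the geometric mean over time points of the
    per-time cell ratios.
    """
    values = profile.values
    log_means = (
        values.assign(logv=np.log2(values["value"]))
        .groupby(["strain", "time_ct"])["logv"]
        .mean()
    )
    for s in (strain_a, strain_b):
        if s not in log_means.index.get_level_values("strain"):
            raise ValidationError(f"strain {s!r} absent from profile")
    la, lb = log_means.loc[strain_a], log_means.loc[strain_b]
    shared = la.index.intersection(lb.index)
    if len(shared) == 0:
        raise ValidationError(
            f"strains {strain_a!r} and {strain_b!r} share no time points"
        )
    return float(2.0 ** (la.loc[shared] - lb.loc[shared]).mean())


def compare_strategies(
    q: pd.DataFrame,
    meta: pd.DataFrame,
    target: str,
    strategies: Mapping[str, Sequence[str]],
    strain_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Normalize one target under several reference strategies and summarize each.

    ``strategies`` maps a label (e.g. ``"single:Actb"``, ``"genorm_top2"``) to
    the reference gene set that builds its normalization factor. Returns one
    row per strategy with the cosinor peak time, amplitude fold, and — when
    ``strain_pair`` is given or exactly two strains are present — the
    between-strain fold change of the normalized target.
    """
    if target not in q.index:
        raise ValidationError(f"target gene {target!r} not in quantity matrix")
    if strain_pair is None:
        strains = sorted(meta[meta["sample_id"].isin(q.columns)]["strain"].unique())
        strain_pair = (strains[0], strains[1]) if len(strains) == 2 else None
    rows = []
    profiles: dict[str, NormalizedProfile] = {}
    for label, genes in strategies.items():
        genes = list(genes)
        bad = [g for g in genes if g not in q.index]
        if bad:
            raise ValidationError(f"strategy {label!r} references unknown gene(s): {bad}")
        if target in genes:
            raise ValidationError(
                f"strategy {label!r} normalizes {target!r} to itself"
            )
        nf = normalization_factor(q, genes)
        prof = normalize_target(q.loc[target], nf, meta, target=target, strategy=label)
        profiles[label] = prof
        rhythm = estimate_rhythm(prof)
        row = {
            "strategy": label,
            "reference_genes": "+".join(genes),
            "peak_time": rhythm.peak_time,
            "amplitude_fold": rhythm.amplitude_fold,
            "peak_defined": rhythm.peak_defined,
        }
        if strain_pair is not None:
            row["strain_fold"] = strain_fold_change(prof, *strain_pair)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["profiles"] = profiles
    out.attrs["strain_pair"] = strain_pair
    return out
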