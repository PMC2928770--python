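"""Amplification-efficiency estimation and efficiency-corrected relative quantities.

The quantity transform is the efficiency-corrected delta-Cq method: for gene *g*
with amplification efficiency :math:`E_g` (fold product per PCR cycle),

.. math:: Q_{g,s} = E_g^{\\,\\min_{s'} Cq_{g,s'} - Cq_{g,s}}

so the most abundant sample of each gene (its lowest Cq) has Q = 1 and every
other sample a quantity in (0, 1]. Efficiencies are estimated from dilution
standard curves as :math:`E = 10^{-1/\\text{slope}}` of the regression of Cq on
log10 relative input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DatasetSpec, ValidationError

__all__ = [
    "EfficiencyFit",
    "estimate_efficiency",
    "relative_quantities",
    "read_quantities",
    "write_quantities",
]

DILUTION_COLUMNS = ("gene", "log10_relative_conc", "replicate", "cq")


@dataclass(frozen=True)
class EfficiencyFit:
    """Standard-curve fit: ``efficiency`` with its regression diagnostics."""

    gene: str
    efficiency: float
    slope: float  # cycles per decade of input, expected negative
    intercept: float
    r_squared: float


def estimate_efficiency(series: pd.DataFrame, gene: str | None = None) -> EfficiencyFit:
    """Fit a dilution standard curve and return the amplification efficiency.

    Parameters
    ----------
    series
        Dilution-series table with columns ``gene, log10_relative_conc,
        replicate, cq`` (or without ``gene`` if ``gene`` is given). At least
        three distinct concentrations are required.
    gene
        Gene symbol, if the table lacks a ``gene`` column or holds one gene.

    Raises
    ------
    ValidationError
        On fewer than 3 distinct concentrations, or on a degenerate fit
        (slope ≥ 0, i.e. Cq not decreasing with input, or |slope| < 0.5
        cycles/decade, implying an implausible efficiency above ~100-fold
        per cycle).
    """
    if "gene" in series.columns:
        genes = series["gene"].unique()
        if len(genes) != 1:
            raise ValidationError(
                f"estimate_efficiency expects one gene per series, got {sorted(genes)}"
            )
        gene = gene or str(genes[0])
    if gene is None:
        gene = "<unnamed>"
    x = series["log10_relative_conc"].to_numpy(float)
    y = series["cq"].to_numpy(float)
    if len(np.unique(x)) < 3:
        raise ValidationError(
            f"{gene}: dilution series needs >= 3 distinct concentrations, got {len(np.unique(x))}"
        )
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValidationError(
            f"{gene}: standard-curve slope {fit.slope:.3g} >= 0; Cq must fall with input"
        )
    if abs(fit.slope) < 0.5:
        raise ValidationError(
            f"{gene}: standard-curve slope {fit.slope:.3g} is degenerate (|slope| < 0.5)"
        )
    return EfficiencyFit(
        gene=gene,
        efficiency=float(10.0 ** (-1.0 / fit.slope)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def relative_quantities(
    agg: pd.DataFrame,
    efficiencies: Mapping[str, float],
    scope: DatasetSpec | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Efficiency-corrected relative quantities Q from aggregated Cq values.

    ``agg`` is an aggregated Cq table (``sample_id, gene, mean_cq, ...``).
    ``scope`` restricts the computation — and, crucially, the per-gene minimum
    Cq that anchors Q = 1 — to one analysis dataset; pass a
    :class:`~refstab.data_model.DatasetSpec`, an explicit sample-id sequence, or
    None for all samples. Returns a genes × samples DataFrame of quantities in
    (0, 1], with the scope label recorded in ``result.attrs["scope"]``.
    """
    if isinstance(scope, DatasetSpec):
        sample_ids, scope_label = list(scope.sample_ids), scope.label
    elif scope is None:
        sample_ids, scope_label = sorted(agg["sample_id"].unique()), "all"
    else:
        sample_ids, scope_label = list(scope), "custom"
    if not sample_ids:
        raise ValidationError("empty scope: no samples to quantify")

    sub = agg[agg["sample_id"].isin(sample_ids)]
    wide = sub.pivot(index="gene", columns="sample_id", values="mean_cq")
    wide = wide.reindex(columns=sample_ids)
    if wide.isna().to_numpy().any():
        missing = [
            (g, s)
            for g in wide.index
            for s in wide.columns
            if pd.isna(wide.loc[g, s])
        ]
        raise ValidationError(
            f"scope {scope_label!r} has {len(missing)} missing (gene, sample) "
            f"Cq cell(s), e.g. {missing[:5]}; run require_complete first"
        )
    absent = [g for g in wide.index if g not in efficiencies]
    if absent:
        raise ValidationError(f"no efficiency provided for gene(s): {absent}")

    eff = np.array([efficiencies[g] for g in wide.index], float)
    cq = wide.to_numpy(float)
    delta = cq.min(axis=1, keepdims=True) - cq  # lowest Cq (max abundance) minus sample
    q = pd.DataFrame(
        eff[:, None] ** delta, index=wide.index.copy(), columns=wide.columns.copy()
    )
    q.index.name = "gene"
    q.columns.name = "sample_id"
    q.attrs["scope"] = scope_label
    return q


def write_quantities(q: pd.DataFrame, path) -> None:
    """Write a genes × samples quantity matrix as wide CSV (first column ``gene``)."""
    q.sort_index().to_csv(path, index=True)


def read_quantities(path) -> pd.DataFrame:
    q = pd.read_csv(path, index_col=0)
    q.index.name = "gene"
    q.columns.name = "sample_id"
    if (q.to_numpy(float) <= 0).any():
        raise ValidationError(f"{path}: quantities must be > 0")
    return q
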