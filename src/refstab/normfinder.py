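"""Model-based reference-gene stability analysis (NormFinder).

The model decomposes log2 relative quantities y_igj (gene i, subgroup g,
sample j) into a gene level, a sample loading effect, a systematic
gene-by-group deviation d_ig and residual noise with gene-and-group-specific
variance sigma²_ig:

    y_igj = alpha_i + beta_gj + d_ig + eps_igj,   eps_igj ~ N(0, sigma²_ig)

Subgroups default to the circadian sacrifice time, so a gene whose level
drifts systematically across time points accrues intergroup deviation, and a
gene that fluctuates animal-to-animal accrues intragroup variance. The
stability value rho_i combines both (lower = more stable):

    rho_i = (1/G) * sum_g [ |d~_ig| + sqrt( w_ig * sigma^2_ig / n_g ) ]

where d~_ig is the intergroup deviation shrunk toward zero by the factor
w_ig = gamma² / (gamma² + sigma²_ig/n_g) and gamma² is the variance of the
deviations across all (gene, group) cells. With a single group the deviation
terms vanish and rho_i reduces to the residual standard deviation.

Estimators
----------
Per subgroup g with n_g samples over I genes:

* two-way residuals r_igj = y_igj − mean_i − mean_j + grand mean;
* raw variance v_ig = Σ_j r²_igj / (n_g − 1);
* bias-corrected sigma²_ig = [I/(I−2)] (v_ig − v̄_g/(I−1)), floored at 0 —
  the correction follows from E[v_ig] = sigma²_ig (1 − 2/I) + mean_i(sigma²_ig)/I
  and is pinned by a Monte-Carlo unbiasedness test in the suite;
* group levels z_ig = mean_j(y_igj) − mean over genes of the same, and
  deviations d̂_ig = z_ig − Σ_g n_g z_ig / Σ_g n_g (so Σ_i d̂_ig = 0 per group);
* gamma² = max(0, Σ_ig d̂²_ig / ((I−1)(G−1)) − mean_ig(sigma²_ig/n_g)), the
  (I−1)(G−1) denominator matching the free dimensions of the double-centred
  deviation array.

Negative variance estimates are floored at zero and counted in the result.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import ValidationError

__all__ = [
    "NormFinderInput",
    "NormFinderResult",
    "log_quantities",
    "fit_variance_model",
    "stability_values",
    "best_pair",
    "run_normfinder",
]


@dataclass
class NormFinderInput:
    """Log2 quantities plus the subgroup assignment of every sample."""

    y: pd.DataFrame  # genes x samples, log2 scale
    groups: pd.Series  # sample_id -> subgroup label

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.y.columns)
        if self.groups.isna().any():
            missing = list(self.y.columns[self.groups.isna()])
            raise ValidationError(f"samples without a subgroup label: {missing[:5]}")
        if self.y.shape[0] < 3:
            raise ValidationError(
                f"NormFinder needs >= 3 genes (intragroup correction divides by I-2), "
                f"got {self.y.shape[0]}"
            )
        sizes = self.groups.value_counts()
        small = sorted(sizes.index[sizes < 2])
        if small:
            raise ValidationError(f"subgroup(s) with < 2 samples: {small}")
        if self.y.isna().to_numpy().any():
            raise ValidationError("log-quantity matrix must be complete (no NaN)")

    @property
    def n_genes(self) -> int:
        return self.y.shape[0]

    @property
    def group_labels(self) -> list:
        return sorted(self.groups.unique())


@dataclass
class NormFinderResult:
    """Fitted variance components, stability values and the best two-gene pair."""

    sigma2: pd.DataFrame  # genes x groups, intragroup variance estimates
    d_hat: pd.DataFrame  # genes x groups, intergroup deviations
    d_tilde: pd.DataFrame  # shrunken deviations
    gamma2: float  # variance of deviations across (gene, group) cells
    group_sizes: pd.Series
    floored_sigma2: int  # count of variance cells clipped at 0
    stability: pd.Series | None = None  # rho per gene, ascending = more stable
    ranking: tuple[str, ...] | None = None
    best_pair: tuple[str, str] | None = None
    best_pair_stability: float | None = None
    combined_lt_single: bool | None = None

    @property
    def best_single(self) -> str:
        return self.ranking[0]


def log_quantities(
    q: pd.DataFrame,
    meta: pd.DataFrame | Mapping | pd.Series,
    group_by: str = "time_ct",
) -> NormFinderInput:
    """Log2-transform a quantity matrix and resolve the sample subgrouping.

    ``meta`` is a sample table with a ``sample_id`` column and the grouping
    factor named by ``group_by`` (default the circadian time), or directly a
    mapping/Series sample_id -> group label. Grouping by a constant factor
    yields single-group mode.
    """
    if (q.to_numpy(float) <= 0).any():
        raise ValidationError("all quantities must be > 0 to take logs")
    if isinstance(meta, pd.DataFrame):
        groups = meta.set_index("sample_id")[group_by]
    else:
        groups = pd.Series(dict(meta) if not isinstance(meta, pd.Series) else meta)
    return NormFinderInput(y=np.log2(q), groups=groups)


def _fit_arrays(y: np.ndarray, codes: np.ndarray, n_groups: int):
    """Core fit on a genes x samples array with integer group codes 0..G-1.

    Returns (sigma2, d_hat, d_tilde, gamma2, group_sizes, n_floored); all
    per-(gene, group) arrays have shape (I, G).
    """
    n_genes = y.shape[0]
    sigma2 = np.empty((n_genes, n_groups))
    z = np.empty((n_genes, n_groups))
    sizes = np.empty(n_groups, int)
    for g in range(n_groups):
        yg = y[:, codes == g]
        sizes[g] = yg.shape[1]
        resid = yg - yg.mean(1, keepdims=True) - yg.mean(0, keepdims=True) + yg.mean()
        v = (resid**2).sum(1) / (sizes[g] - 1)
        sigma2[:, g] = n_genes / (n_genes - 2) * (v - v.mean() / (n_genes - 1))
        gene_means = yg.mean(1)
        z[:, g] = gene_means - gene_means.mean()
    n_floored = int((sigma2 < 0).sum())
    sigma2 = np.clip(sigma2, 0.0, None)

    if n_groups == 1:
        d_hat = np.zeros_like(z)
        return sigma2, d_hat, d_hat.copy(), 0.0, sizes, n_floored

    d_hat = z - (z * sizes).sum(1, keepdims=True) / sizes.sum()
    var_of_mean = sigma2 / sizes  # sigma²_ig / n_g
    gamma2 = (d_hat**2).sum() / ((n_genes - 1) * (n_groups - 1)) - var_of_mean.mean()
    gamma2 = max(0.0, float(gamma2))
    with np.errstate(invalid="ignore"):
        shrink = np.where(
            gamma2 + var_of_mean > 0, gamma2 / (gamma2 + var_of_mean), 0.0
        )
    d_tilde = d_hat * shrink
    return sigma2, d_hat, d_tilde, gamma2, sizes, n_floored


def fit_variance_model(inp: NormFinderInput) -> NormFinderResult:
    """Estimate intragroup variances and (shrunken) intergroup deviations."""
    labels = inp.group_labels
    codes = inp.groups.map({lab: i for i, lab in enumerate(labels)}).to_numpy()
    sigma2, d_hat, d_tilde, gamma2, sizes, n_floored = _fit_arrays(
        inp.y.to_numpy(float), codes, len(labels)
    )
    if n_floored:
        warnings.warn(
            f"{n_floored} intragroup variance estimate(s) were negative and floored at 0",
            stacklevel=2,
        )
    genes = inp.y.index.copy()
    return NormFinderResult(
        sigma2=pd.DataFrame(sigma2, index=genes, columns=labels),
        d_hat=pd.DataFrame(d_hat, index=genes.copy(), columns=labels),
        d_tilde=pd.DataFrame(d_tilde, index=genes.copy(), columns=labels),
        gamma2=gamma2,
        group_sizes=pd.Series(sizes, index=labels, name="n"),
        floored_sigma2=n_floored,
    )


def _stability_from_arrays(sigma2, d_tilde, gamma2, sizes) -> np.ndarray:
    n_groups = sigma2.shape[1]
    var_of_mean = sigma2 / sizes
    if n_groups == 1:
        return np.sqrt(sigma2[:, 0])
    with np.errstate(invalid="ignore"):
        shrink = np.where(
            gamma2 + var_of_mean > 0, gamma2 / (gamma2 + var_of_mean), 0.0
        )
    return (np.abs(d_tilde) + np.sqrt(shrink * var_of_mean)).mean(axis=1)


def stability_values(result: NormFinderResult) -> NormFinderResult:
    """Attach per-gene stability values rho and the ascending ranking."""
    rho = _stability_from_arrays(
        result.sigma2.to_numpy(),
        result.d_tilde.to_numpy(),
        result.gamma2,
        result.group_sizes.to_numpy(),
    )
    result.stability = pd.Series(rho, index=result.sigma2.index.copy(), name="rho")
    result.ranking = tuple(result.stability.sort_values(kind="mergesort").index)
    return result


def _pair_stability(y: np.ndarray, codes: np.ndarray, n_groups: int, i: int, j: int) -> float:
    """Stability of the (i, j) pseudo-gene after replacing the pair by its mean."""
    keep = [k for k in range(y.shape[0]) if k not in (i, j)]
    pseudo = (y[i] + y[j]) / 2.0
    y_new = np.vstack([y[keep], pseudo[None, :]])
    sigma2, _, d_tilde, gamma2, sizes, _ = _fit_arrays(y_new, codes, n_groups)
    return float(_stability_from_arrays(sigma2, d_tilde, gamma2, sizes)[-1])


def best_pair(inp: NormFinderInput) -> tuple[str, str, float]:
    """Exhaustively search all unordered gene pairs for the most stable combination.

    Each pair is collapsed to a pseudo-gene — the log-scale average, i.e. the
    geometric mean on the raw scale — which replaces both members, the model is
    re-fitted, and the pseudo-gene's stability taken as the pair's combined
    value. Needs >= 4 genes so the re-fit still has >= 3.
    """
    if inp.n_genes < 4:
        raise ValidationError(
            f"best_pair needs >= 4 genes (the re-fit drops one), got {inp.n_genes}"
        )
    labels = inp.group_labels
    codes = inp.groups.map({lab: i for i, lab in enumerate(labels)}).to_numpy()
    y = inp.y.to_numpy(float)
    genes = list(inp.y.index)
    best: tuple[str, str] | None = None
    best_rho = np.inf
    for i, j in itertools.combinations(range(len(genes)), 2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = _pair_stability(y, codes, len(labels), i, j)
        if rho < best_rho:
            best_rho = rho
            best = (genes[i], genes[j])
    assert best is not None
    return best[0], best[1], best_rho


def run_normfinder(
    q: pd.DataFrame,
    meta: pd.DataFrame | Mapping | pd.Series,
    group_by: str = "time_ct",
    with_best_pair: bool = True,
) -> NormFinderResult:
    """Full NormFinder analysis on a quantity matrix: fit, rank, best pair."""
    inp = log_quantities(q, meta, group_by=group_by)
    result = stability_values(fit_variance_model(inp))
    if with_best_pair and inp.n_genes >= 4:
        a, b, rho = best_pair(inp)
        result.best_pair = (a, b)
        result.best_pair_stability = rho
        result.combined_lt_single = bool(rho < result.stability.min())
    return result
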