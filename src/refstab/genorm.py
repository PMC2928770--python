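"""The geNorm reference-gene stability algorithm.

geNorm scores each candidate reference gene by the *average expression
stability* M: the mean, over all other candidates, of the standard deviation of
the pairwise log2 expression ratio across samples. Genes whose ratios to every
other candidate are constant across samples have low M and are considered
stable. The least stable gene (highest M) is excluded and M is recomputed,
iteratively, until two genes remain; those two cannot be ranked against each
other and share the top rank.

The number of reference genes worth using is judged by the pairwise variation
V(n/n+1): the standard deviation across samples of the log2 ratio between
normalization factors built from the top n and top n+1 ranked genes. A V below
the conventional 0.15 guideline indicates the (n+1)-th gene adds nothing.

All statistics here are scale-invariant: multiplying a gene's quantities, or a
sample's quantities, by any positive constant shifts log ratios by a constant
and leaves every standard deviation unchanged. Log base 2 is used throughout;
a different base would rescale M and V jointly and with them the meaning of
the V threshold.

Standard deviations use the n−1 (sample) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ValidationError

__all__ = [
    "GeNormResult",
    "pairwise_variation_matrix",
    "m_values",
    "rank_genes_genorm",
    "normalization_factor",
    "pairwise_variation_v",
    "run_genorm",
]

DEFAULT_V_THRESHOLD = 0.15


@dataclass
class GeNormResult:
    """Full output of a geNorm run.

    ``ranking`` lists genes from most to least stable; its first two entries
    are the final, jointly ranked pair (stored in lexicographic order — geNorm
    cannot order them). ``m_by_round`` records the M values at each exclusion
    round, round 0 covering all genes. ``v_curve`` maps n to V(n/n+1);
    ``recommended_n`` is the smallest n below ``v_threshold`` or the total
    gene count when no n qualifies (then ``threshold_met`` is False).
    """

    pairwise_v: pd.DataFrame
    m_by_round: list[pd.Series]
    ranking: tuple[str, ...]
    ties: list[tuple[str, ...]] = field(default_factory=list)
    v_curve: dict[int, float] | None = None
    recommended_n: int | None = None
    v_threshold: float | None = None
    threshold_met: bool | None = None

    @property
    def final_pair(self) -> tuple[str, str]:
        return self.ranking[0], self.ranking[1]

    @property
    def m_values(self) -> pd.Series:
        """M of every gene over the full candidate set (round 0)."""
        return self.m_by_round[0]


def _check_matrix(q: pd.DataFrame, min_genes: int = 2, min_samples: int = 3) -> None:
    if q.shape[0] < min_genes:
        raise ValidationError(f"need >= {min_genes} genes, got {q.shape[0]}")
    if q.shape[1] < min_samples:
        raise ValidationError(
            f"need >= {min_samples} samples for a stable sd, got {q.shape[1]}"
        )
    if (q.to_numpy(float) <= 0).any():
        raise ValidationError("all quantities must be > 0")


def pairwise_variation_matrix(q: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix V_jk = sd over samples of log2(Q_j / Q_k).

    Diagonal entries are NaN (a gene has no variation against itself).
    """
    _check_matrix(q)
    logq = np.log2(q.to_numpy(float))
    # sd of (x_j - x_k) across samples for every pair, vectorised:
    diffs = logq[:, None, :] - logq[None, :, :]
    v = diffs.std(axis=2, ddof=1)
    np.fill_diagonal(v, np.nan)
    return pd.DataFrame(v, index=q.index.copy(), columns=q.index.copy())


def m_values(q: pd.DataFrame) -> pd.Series:
    """Average expression stability M_j = mean over k≠j of V_jk (lower = more stable)."""
    v = pairwise_variation_matrix(q)
    m = v.mean(axis=1, skipna=True)
    m.name = "M"
    return m


def rank_genes_genorm(q: pd.DataFrame) -> GeNormResult:
    """Iterative-exclusion stability ranking.

    Repeatedly removes the gene with the highest M among the remaining set
    until two genes are left. Ties on the maximal M are broken by excluding the
    lexicographically later gene; every tie is recorded in ``result.ties``.
    """
    _check_matrix(q, min_genes=3)
    remaining = list(q.index)
    m_by_round: list[pd.Series] = []
    excluded: list[str] = []
    ties: list[tuple[str, ...]] = []
    while len(remaining) > 2:
        m = m_values(q.loc[remaining])
        m_by_round.append(m)
        worst_m = m.max()
        candidates = sorted(m.index[np.isclose(m, worst_m, rtol=0.0, atol=0.0)])
        if len(candidates) > 1:
            ties.append(tuple(candidates))
        worst = candidates[-1]  # lexicographically last among exact ties
        excluded.append(worst)
        remaining.remove(worst)
    m_by_round.append(m_values(q.loc[remaining]))
    ranking = tuple(sorted(remaining)) + tuple(reversed(excluded))
    return GeNormResult(
        pairwise_v=pairwise_variation_matrix(q),
        m_by_round=m_by_round,
        ranking=ranking,
        ties=ties,
    )


def normalization_factor(q: pd.DataFrame, gene_set: Sequence[str]) -> pd.Series:
    """Per-sample normalization factor: geometric mean of the given genes' quantities."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValidationError("gene_set must be nonempty")
    missing = [g for g in gene_set if g not in q.index]
    if missing:
        raise ValidationError(f"gene(s) not in quantity matrix: {missing}")
    nf = pd.Series(
        2.0 ** np.log2(q.loc[gene_set].to_numpy(float)).mean(axis=0),
        index=q.columns.copy(),
        name="nf",
    )
    return nf


def pairwise_variation_v(
    q: pd.DataFrame,
    ranking: Sequence[str],
    threshold: float = DEFAULT_V_THRESHOLD,
) -> tuple[dict[int, float], int, bool]:
    """Pairwise variation curve V(n/n+1) and the recommended gene count.

    For n = 2..N−1, V(n/n+1) is the sd over samples of log2(NF_n / NF_{n+1}),
    NF_n being the geometric-mean factor of the n top-ranked genes. Returns
    ``(v_curve, recommended_n, threshold_met)`` where ``recommended_n`` is the
    smallest n with V below ``threshold``, or N when none qualifies
    (``threshold_met`` False).
    """
    _check_matrix(q, min_genes=3)
    ranking = list(ranking)
    if set(ranking) != set(q.index):
        raise ValidationError("ranking must be a permutation of the matrix's genes")
    n_genes = len(ranking)
    v_curve: dict[int, float] = {}
    for n in range(2, n_genes):
        nf_n = np.log2(normalization_factor(q, ranking[:n]).to_numpy())
        nf_n1 = np.log2(normalization_factor(q, ranking[: n + 1]).to_numpy())
        v_curve[n] = float(np.std(nf_n - nf_n1, ddof=1))
    below = [n for n, v in v_curve.items() if v < threshold]
    if below:
        return v_curve, min(below), True
    return v_curve, n_genes, False


def run_genorm(q: pd.DataFrame, v_threshold: float = DEFAULT_V_THRESHOLD) -> GeNormResult:
    """Complete geNorm analysis: ranking plus V curve, in one result object."""
    res = rank_genes_genorm(q)
    res.v_curve, res.recommended_n, res.threshold_met = pairwise_variation_v(
        q, res.ranking, threshold=v_threshold
    )
    res.v_threshold = v_threshold
    return res
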