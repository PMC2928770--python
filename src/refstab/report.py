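"""Result writers and human-readable report rendering.

Every analysis stage writes small deterministic CSV/JSON artifacts; the
report assembles them across datasets into text tables: a genes × datasets
stability table with a best-two footer, and a V-curve table per dataset.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genorm import GeNormResult, normalization_factor
from .normfinder import NormFinderResult

__all__ = [
    "write_genorm_outputs",
    "write_normfinder_outputs",
    "write_comparison_outputs",
    "write_manifest",
    "render_report",
]


def write_genorm_outputs(result: GeNormResult, q: pd.DataFrame, outdir: str | Path) -> None:
    """Write ``genorm_ranking.csv``, ``genorm_v.csv`` and ``nf.csv``.

    The ranking file lists every exclusion round with the M values of the genes
    still in play and flags the gene excluded that round; the final two genes
    carry the joint rank "1-2". ``nf.csv`` holds the per-sample normalization
    factor built from the recommended number of top-ranked genes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_genes = len(result.ranking)
    rank_of = {g: str(i + 1) for i, g in enumerate(result.ranking)}
    rank_of[result.ranking[0]] = rank_of[result.ranking[1]] = "1-2"
    rows = []
    remaining = set(result.ranking)
    for rnd, m in enumerate(result.m_by_round):
        excluded_gene = (
            result.ranking[n_genes - 1 - rnd] if rnd < len(result.m_by_round) - 1 else None
        )
        for gene in sorted(remaining):
            rows.append(
                {
                    "round": rnd,
                    "gene": gene,
                    "m_value": m[gene],
                    "excluded": gene == excluded_gene,
                    "rank": rank_of[gene],
                }
            )
        if excluded_gene is not None:
            remaining.remove(excluded_gene)
    pd.DataFrame(rows).to_csv(outdir / "genorm_ranking.csv", index=False)

    v_rows = [
        {
            "n": n,
            "v_value": v,
            "below_threshold": v < (result.v_threshold if result.v_threshold is not None else 0.15),
        }
        for n, v in sorted((result.v_curve or {}).items())
    ]
    pd.DataFrame(v_rows, columns=["n", "v_value", "below_threshold"]).to_csv(
        outdir / "genorm_v.csv", index=False
    )

    n_use = result.recommended_n or 2
    gene_set = list(result.ranking[:n_use])
    nf = normalization_factor(q, gene_set)
    pd.DataFrame(
        {"sample_id": nf.index, "nf": nf.to_numpy(), "gene_set": "+".join(gene_set)}
    ).to_csv(outdir / "nf.csv", index=False)


def write_normfinder_outputs(result: NormFinderResult, outdir: str | Path) -> None:
    """Write ``normfinder.csv``, ``normfinder_groups.csv`` and ``best_pair.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stab = result.stability.sort_values(kind="mergesort")
    pd.DataFrame(
        {
            "gene": stab.index,
            "stability": stab.to_numpy(),
            "rank": range(1, len(stab) + 1),
            "floored_cells": result.floored_sigma2,
        }
    ).to_csv(outdir / "normfinder.csv", index=False)

    long = (
        result.sigma2.stack()
        .rename("sigma2")
        .to_frame()
        .join(result.d_hat.stack().rename("d_hat"))
        .join(result.d_tilde.stack().rename("d_tilde"))
        .reset_index()
    )
    long.columns = ["gene", "group", "sigma2", "d_hat", "d_tilde"]
    long.to_csv(outdir / "normfinder_groups.csv", index=False)

    payload = {
        "gene_a": None if result.best_pair is None else result.best_pair[0],
        "gene_b": None if result.best_pair is None else result.best_pair[1],
        "combined_stability": result.best_pair_stability,
        "best_single": result.ranking[0],
        "best_single_stability": float(result.stability.min()),
        "combined_lt_single": result.combined_lt_single,
    }
    (outdir / "best_pair.json").write_text(json.dumps(payload, indent=2) + "\n")


def write_comparison_outputs(
    comparison: pd.DataFrame, outdir: str | Path
) -> None:
    """Write ``normalized.csv`` (per-sample values, all strategies stacked) and
    ``comparison.json`` (per-strategy rhythm and strain-fold summary)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = comparison.attrs.get("profiles", {})
    frames = []
    for label, prof in profiles.items():
        frame = prof.values.copy()
        frame.insert(len(frame.columns) - 1, "strategy", label)
        frames.append(frame)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "normalized.csv", index=False
        )
    payload = {
        row["strategy"]: {
            "reference_genes": row["reference_genes"],
            "peak_time": row["peak_time"] if row["peak_defined"] else None,
            "amplitude_fold": row["amplitude_fold"],
            "strain_fold": row.get("strain_fold"),
        }
        for _, row in comparison.iterrows()
    }
    (outdir / "comparison.json").write_text(json.dumps(payload, indent=2) + "\n")


def write_manifest(
    outdir: str | Path,
    command: str,
    params: Mapping,
    inputs: Sequence[str | Path] = (),
) -> None:
    """Record what produced a result directory: command, parameters, input hashes."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "params": {k: str(v) for k, v in dict(params).items()},
        "inputs": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for p in inputs
            if Path(p).exists()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def render_report(results_root: str | Path) -> str:
    """Assemble per-dataset outputs under ``results_root`` into a text report.

    Expects one subdirectory per dataset label, each holding the stage outputs.
    Renders a genes × datasets stability table with the best-two footer and a
    V(n/n+1) table per dataset. Raises FileNotFoundError when nothing usable
    is found.
    """
    root = Path(results_root)
    dataset_dirs = sorted(
        d for d in root.iterdir() if d.is_dir() and (
            (d / "normfinder.csv").exists() or (d / "genorm_v.csv").exists()
        )
    ) if root.exists() else []
    if not dataset_dirs:
        raise FileNotFoundError(f"no dataset result directories under {root}")

    lines = []
    stab_cols, pair_rows = {}, {}
    for d in dataset_dirs:
        nf_csv = d / "normfinder.csv"
        if nf_csv.exists():
            tab = pd.read_csv(nf_csv)
            stab_cols[d.name] = tab.set_index("gene")["stability"]
        bp = d / "best_pair.json"
        if bp.exists():
            pair_rows[d.name] = json.loads(bp.read_text())
    if stab_cols:
        wide = pd.DataFrame(stab_cols)
        lines.append("Stability values (lower = more stable), genes x datasets")
        lines.append(wide.to_string(float_format=lambda x: f"{x:.3f}"))
        if pair_rows:
            lines.append("")
            lines.append("Best two-gene combination per dataset")
            for label, p in sorted(pair_rows.items()):
                if p.get("gene_a") is None:
                    continue
                lines.append(
                    f"  {label}: {p['gene_a']} + {p['gene_b']} "
                    f"(combined {p['combined_stability']:.3f}, "
                    f"best single {p['best_single']} {p['best_single_stability']:.3f})"
                )
        lines.append("")

    for d in dataset_dirs:
        v_csv = d / "genorm_v.csv"
        if v_csv.exists():
            vtab = pd.read_csv(v_csv)
            lines.append(f"Pairwise variation V(n/n+1), dataset {d.name}")
            for _, row in vtab.iterrows():
                mark = "ok" if row["below_threshold"] else "above threshold"
                lines.append(f"  V({int(row['n'])}/{int(row['n']) + 1}) = {row['v_value']:.4f}  [{mark}]")
            lines.append("")
    return "\n".join(lines).rstrip() + "\n"
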