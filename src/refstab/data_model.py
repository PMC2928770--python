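"""Domain tables, CSV readers/writers, replicate aggregation and dataset partitioning.

The package works on three long-format tables, all plain CSV:

``cq_long.csv``
    Raw quantification cycles, one row per technical replicate:
    ``sample_id,gene,replicate,cq``.
``samples.csv``
    Per-sample annotations: ``sample_id,strain,tissue,time_ct,animal_id``.
``efficiency.csv``
    Per-gene amplification efficiencies: ``gene,efficiency``.

Tables are carried as :class:`pandas.DataFrame` with exactly these columns;
validation happens at the I/O boundary and in :func:`validate_cq_table` /
:func:`validate_sample_meta` so downstream modules can assume well-formed input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from string import ascii_uppercase
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CQ_COLUMNS",
    "META_COLUMNS",
    "DEFAULT_STRAINS",
    "DEFAULT_TISSUES",
    "DEFAULT_TIMEPOINTS",
    "DatasetSpec",
    "read_cq_table",
    "write_cq_table",
    "read_sample_meta",
    "write_sample_meta",
    "read_efficiencies",
    "write_efficiencies",
    "validate_cq_table",
    "validate_sample_meta",
    "validate_efficiencies",
    "aggregate_technical_replicates",
    "partition_datasets",
    "dataset_by_label",
    "require_complete",
]


class ValidationError(ValueError):
    """An input table violates a schema or domain invariant."""


CQ_COLUMNS = ("sample_id", "gene", "replicate", "cq")
META_COLUMNS = ("sample_id", "strain", "tissue", "time_ct", "animal_id")

#: Strains of the default study design, in dataset-label order
#: (inbred first, then the two mixed-background strains).
DEFAULT_STRAINS = ("C57BL/6JOlaHsd", "mixed-CremKO", "mixed-WT")
DEFAULT_TISSUES = ("liver", "adrenal")
#: Circadian sacrifice times in hours; CT0 and CT24 are distinct samplings
#: of the same phase, never merged at the data layer.
DEFAULT_TIMEPOINTS = (0, 4, 8, 12, 16, 20, 24)

# Efficiency sanity bounds: hard domain (1, 2.1], soft range seen in practice.
_EFF_HARD = (1.0, 2.1)
_EFF_SOFT = (1.6, 2.05)


@dataclass(frozen=True)
class DatasetSpec:
    """One analysis dataset: a (strain-filter, tissue) stratum with resolved members.

    Per-stratum datasets get single letters in strain-major order
    (A = first strain/first tissue, B = first strain/second tissue, ...);
    the pooled all-strain dataset of each tissue follows with the next letters.
    """

    label: str
    strain_filter: tuple[str, ...] | None  # None = all strains
    tissue_filter: str
    sample_ids: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __repr__(self) -> str:  # compact: membership can be large
        strains = "all" if self.strain_filter is None else "/".join(self.strain_filter)
        return (
            f"DatasetSpec(label={self.label!r}, strains={strains}, "
            f"tissue={self.tissue_filter!r}, n={self.n_samples})"
        )


# ---------------------------------------------------------------------------
# validation


def validate_cq_table(cq: pd.DataFrame) -> pd.DataFrame:
    if tuple(cq.columns) != CQ_COLUMNS:
        raise ValidationError(
            f"Cq table must have columns {','.join(CQ_COLUMNS)}, got {','.join(map(str, cq.columns))}"
        )
    vals = pd.to_numeric(cq["cq"], errors="coerce")
    bad = ~np.isfinite(vals) | (vals <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"cq must be finite and > 0; first offending row {row}: {cq.iloc[row].to_dict()}"
        )
    dup = cq.duplicated(subset=["sample_id", "gene", "replicate"])
    if dup.any():
        key = cq.loc[dup, ["sample_id", "gene", "replicate"]].iloc[0].tolist()
        raise ValidationError(f"duplicate (sample_id, gene, replicate) key: {key}")
    return cq


def validate_sample_meta(
    meta: pd.DataFrame,
    strains: Sequence[str] | None = None,
    tissues: Sequence[str] | None = None,
    timepoints: Sequence[float] | None = None,
) -> pd.DataFrame:
    if tuple(meta.columns) != META_COLUMNS:
        raise ValidationError(
            f"sample table must have columns {','.join(META_COLUMNS)}, got {','.join(map(str, meta.columns))}"
        )
    dup = meta.duplicated(subset=["sample_id"])
    if dup.any():
        raise ValidationError(f"duplicate sample_id: {meta.loc[dup, 'sample_id'].iloc[0]!r}")
    if strains is not None:
        unknown = set(meta["strain"]) - set(strains)
        if unknown:
            raise ValidationError(f"unknown strain label(s): {sorted(unknown)}")
    if tissues is not None:
        unknown = set(meta["tissue"]) - set(tissues)
        if unknown:
            raise ValidationError(f"unknown tissue label(s): {sorted(unknown)}")
    if timepoints is not None:
        unknown = set(meta["time_ct"]) - set(timepoints)
        if unknown:
            raise ValidationError(f"time_ct outside configured time points: {sorted(unknown)}")
    return meta


def validate_efficiencies(eff: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for gene, e in eff.items():
        e = float(e)
        if not (_EFF_HARD[0] < e <= _EFF_HARD[1]):
            raise ValidationError(
                f"efficiency for {gene!r} is {e}; must lie in ({_EFF_HARD[0]}, {_EFF_HARD[1]}]"
            )
        if not (_EFF_SOFT[0] <= e <= _EFF_SOFT[1]):
            warnings.warn(
                f"efficiency for {gene!r} ({e}) is outside the usual range "
                f"[{_EFF_SOFT[0]}, {_EFF_SOFT[1]}]",
                stacklevel=2,
            )
        out[str(gene)] = e
    return out


# ---------------------------------------------------------------------------
# readers / writers (deterministic row order: sample_id, gene, replicate)


def _read_csv(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if tuple(df.columns) != columns:
        raise ValidationError(
            f"{path}: expected header {','.join(columns)}, got {','.join(map(str, df.columns))}"
        )
    return df


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format Cq table (``sample_id,gene,replicate,cq``)."""
    df = _read_csv(path, CQ_COLUMNS)
    try:
        df["replicate"] = df["replicate"].astype(int)
        df["cq"] = df["cq"].astype(float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed numeric field: {exc}") from exc
    return validate_cq_table(df)


def write_cq_table(cq: pd.DataFrame, path: str | Path) -> None:
    validate_cq_table(cq)
    out = cq.sort_values(["sample_id", "gene", "replicate"], kind="mergesort")
    out.to_csv(path, index=False)


def read_sample_meta(path: str | Path, **domains) -> pd.DataFrame:
    df = _read_csv(path, META_COLUMNS)
    try:
        df["time_ct"] = df["time_ct"].astype(float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed time_ct: {exc}") from exc
    return validate_sample_meta(df, **domains)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    validate_sample_meta(meta)
    meta.sort_values("sample_id", kind="mergesort").to_csv(path, index=False)


def read_efficiencies(path: str | Path) -> dict[str, float]:
    df = _read_csv(path, ("gene", "efficiency"))
    return validate_efficiencies(dict(zip(df["gene"], df["efficiency"])))


def write_efficiencies(eff: Mapping[str, float], path: str | Path) -> None:
    validate_efficiencies(eff)
    pd.DataFrame(
        {"gene": sorted(eff), "efficiency": [eff[g] for g in sorted(eff)]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# replicate aggregation


def aggregate_technical_replicates(cq: pd.DataFrame, max_sd: float = 0.5) -> pd.DataFrame:
    """Collapse technical replicates to per-(sample, gene) mean Cq.

    Returns a frame with columns ``sample_id, gene, mean_cq, sd_cq, n_replicates,
    flag``. ``sd_cq`` is the sample standard deviation (ddof=1; 0.0 for a single
    replicate) and ``flag`` marks dispersions above ``max_sd`` cycles. Flagged
    rows are never dropped — outlier handling is the caller's decision.
    """
    validate_cq_table(cq)
    g = cq.groupby(["sample_id", "gene"], sort=True)["cq"]
    out = g.agg(mean_cq="mean", sd_cq="std", n_replicates="size").reset_index()
    out["sd_cq"] = out["sd_cq"].fillna(0.0)
    out["flag"] = out["sd_cq"] > max_sd
    return out


def require_complete(
    agg: pd.DataFrame, on_missing: str = "drop_gene"
) -> tuple[pd.DataFrame, dict]:
    """Enforce a complete (sample × gene) grid on an aggregated Cq table.

    Both stability algorithms need every sample measured for every gene.
    ``on_missing`` selects the repair policy: ``"drop_gene"`` removes genes not
    measured in every sample (the default; keeps sample counts intact),
    ``"drop_sample"`` removes samples missing any gene, ``"error"`` raises.
    Returns the filtered table and a report dict listing what was dropped.
    """
    if on_missing not in {"drop_gene", "drop_sample", "error"}:
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    wide = agg.pivot(index="gene", columns="sample_id", values="mean_cq")
    missing = wide.isna()
    report = {"dropped_genes": [], "dropped_samples": []}
    if not missing.to_numpy().any():
        return agg, report
    if on_missing == "error":
        cells = [
            (g, s) for g in wide.index for s in wide.columns if missing.loc[g, s]
        ]
        raise ValidationError(f"missing (gene, sample) cells: {cells[:10]}")
    if on_missing == "drop_gene":
        bad = sorted(wide.index[missing.any(axis=1)])
        report["dropped_genes"] = bad
        warnings.warn(
            f"dropping {len(bad)} gene(s) not measured in all samples: {bad}",
            stacklevel=2,
        )
        return agg[~agg["gene"].isin(bad)].reset_index(drop=True), report
    bad = sorted(wide.columns[missing.any(axis=0)])
    report["dropped_samples"] = bad
    warnings.warn(
        f"dropping {len(bad)} sample(s) missing one or more genes: {bad}",
        stacklevel=2,
    )
    return agg[~agg["sample_id"].isin(bad)].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# dataset partitioning


def partition_datasets(
    meta: pd.DataFrame,
    strains: Sequence[str] = DEFAULT_STRAINS,
    tissues: Sequence[str] = DEFAULT_TISSUES,
) -> list[DatasetSpec]:
    """Split samples into the study's analysis datasets.

    One dataset per (strain, tissue) stratum, labelled A, B, ... in strain-major
    order, followed by one pooled all-strain dataset per tissue. With the default
    three strains and two tissues this yields the familiar eight datasets A–H,
    where G pools all liver samples and H all adrenal samples. Per-stratum
    memberships are disjoint and each tissue's pooled dataset is exactly the
    union of that tissue's strata.
    """
    validate_sample_meta(meta, strains=strains, tissues=tissues)
    labels = iter(ascii_uppercase)
    specs: list[DatasetSpec] = []
    for strain in strains:
        for tissue in tissues:
            mask = (meta["strain"] == strain) & (meta["tissue"] == tissue)
            specs.append(
                DatasetSpec(
                    label=next(labels),
                    strain_filter=(strain,),
                    tissue_filter=tissue,
                    sample_ids=tuple(sorted(meta.loc[mask, "sample_id"])),
                )
            )
    for tissue in tissues:
        mask = meta["tissue"] == tissue
        specs.append(
            DatasetSpec(
                label=next(labels),
                strain_filter=None,
                tissue_filter=tissue,
                sample_ids=tuple(sorted(meta.loc[mask, "sample_id"])),
            )
        )
    return specs


def infer_domains(meta: pd.DataFrame) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Resolve (strains, tissues) orderings for partitioning.

    When the metadata uses only the default study labels, the default order is
    kept (so dataset letters match the published layout); otherwise labels are
    taken in order of first appearance.
    """
    strains = tuple(dict.fromkeys(meta["strain"]))
    tissues = tuple(dict.fromkeys(meta["tissue"]))
    if set(strains) <= set(DEFAULT_STRAINS):
        strains = tuple(s for s in DEFAULT_STRAINS if s in strains)
    if set(tissues) <= set(DEFAULT_TISSUES):
        tissues = tuple(t for t in DEFAULT_TISSUES if t in tissues)
    return strains, tissues


def dataset_by_label(specs: Iterable[DatasetSpec], label: str) -> DatasetSpec:
    for spec in specs:
        if spec.label == label:
            return spec
    raise KeyError(f"no dataset labelled {label!r}")
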