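"""Synthetic circadian qPCR studies with known ground truth.

The generator emulates a stratified circadian RT-qPCR experiment: three mouse
strains (one inbred, a mixed wild-type background and a knockout on the same
mixed background), two tissues (liver, adrenal gland), sacrifices every 4 h
from CT0 to CT24 with ragged biological replicate counts, ten candidate
reference genes plus one robustly rhythmic target gene, and three technical
qPCR replicates per sample.

Each biological sample's log2 abundance of a gene is

    a = loading_s + offset(gene, strain) + A * cos(2*pi*(t - acrophase)/24)
        + N(0, biological_sd)

where ``loading_s`` is a per-sample loading effect shared by every gene of the
sample (RNA input / RT yield). The abundance maps to a quantification cycle
through the gene's own amplification efficiency, Cq = base_cq − a / log2(E),
so that quantification with the true efficiencies inverts the simulation
exactly; technical replicates add Gaussian noise in cycles. CT24 is an
independent sampling at the CT0 phase, never a copy of CT0 animals.

The default configuration reproduces the study's printed design: replicate
counts per (strain, tissue, time) cell summing to 131 liver + 97 adrenal = 228
samples, a ribosomal-RNA analogue at mean Cq 8.8, the lowest-abundance
candidate at mean Cq 28.5, the remaining candidates between Cq 18 and 29,
gene-specific efficiencies from the published primer table, strain-specific
offsets and large biological scatter for the beta-actin and HMBS analogues
(the unstable references), and small scatter for the three microarray-selected
candidates. The target gene is Dbp-like: amplitude 2 log2 (16-fold peak to
trough), acrophase CT12.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_model import DEFAULT_TIMEPOINTS, ValidationError

__all__ = [
    "Rhythm",
    "GeneSim",
    "SimConfig",
    "SimTruth",
    "default_config",
    "default_design",
    "generate",
    "generate_dilution_series",
    "config_to_yaml",
    "config_from_yaml",
]

_STRAIN_CODES = {"C57BL/6JOlaHsd": "B6", "mixed-CremKO": "KO", "mixed-WT": "WT"}


@dataclass(frozen=True)
class Rhythm:
    """A 24 h cosine component: peak-to-mesor amplitude (log2) and acrophase (h)."""

    amplitude: float
    acrophase: float

    def __post_init__(self) -> None:
        if not (0 <= self.acrophase < 24):
            raise ValidationError(f"acrophase must lie in [0, 24), got {self.acrophase}")


@dataclass(frozen=True)
class GeneSim:
    """Simulation parameters of one gene.

    ``base_cq`` is the population-mean quantification cycle at zero effects;
    ``strain_offsets`` are constant log2 abundance shifts per strain (absent
    strains default to 0); ``biological_sd`` is animal-to-animal scatter in
    log2 units; ``tissues`` restricts where the gene is measured (None = all).
    """

    base_cq: float
    efficiency: float
    biological_sd: float = 0.3
    strain_offsets: Mapping[str, float] = field(default_factory=dict)
    rhythm: Rhythm | None = None
    tissues: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.biological_sd < 0:
            raise ValidationError("biological_sd must be >= 0")
        if not (1.0 < self.efficiency <= 2.1):
            raise ValidationError(
                f"efficiency must lie in (1, 2.1], got {self.efficiency}"
            )
        if self.base_cq <= 0:
            raise ValidationError("base_cq must be > 0")


@dataclass
class SimConfig:
    """Full study configuration: genes, design and noise layers.

    ``design`` maps (strain, tissue) to a mapping time -> biological replicate
    count, which may be ragged. Technical noise is in Cq cycles, loading noise
    in log2 abundance units.
    """

    genes: dict[str, GeneSim]
    design: dict[tuple[str, str], dict[float, int]]
    technical_replicates: int = 3
    technical_sd: float = 0.15
    loading_sd: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.technical_replicates < 1:
            raise ValidationError("technical_replicates must be >= 1")
        if self.technical_sd < 0 or self.loading_sd < 0:
            raise ValidationError("noise sds must be >= 0")
        for (strain, tissue), cells in self.design.items():
            for t, n in cells.items():
                if n < 1:
                    raise ValidationError(
                        f"replicate count must be >= 1 in cell ({strain}, {tissue}, {t})"
                    )

    @property
    def strains(self) -> tuple[str, ...]:
        seen = dict.fromkeys(s for s, _ in self.design)
        return tuple(seen)

    @property
    def tissues(self) -> tuple[str, ...]:
        seen = dict.fromkeys(t for _, t in self.design)
        return tuple(seen)

    def n_samples(self) -> int:
        return sum(n for cells in self.design.values() for n in cells.values())


@dataclass
class SimTruth:
    """Ground truth consumed by a generation run, for recovery tests."""

    base_cq: dict[str, float]
    efficiency: dict[str, float]
    biological_sd: dict[str, float]
    strain_offsets: dict[str, dict[str, float]]
    rhythm: dict[str, Rhythm | None]
    loading: pd.Series  # per-sample loading effect, log2


def default_design() -> dict[tuple[str, str], dict[float, int]]:
    """The published replicate structure: ragged counts per (strain, tissue, CT)."""
    times = DEFAULT_TIMEPOINTS
    counts = {
        ("C57BL/6JOlaHsd", "liver"): (5, 5, 5, 5, 5, 5, 5),  # dataset A, 35
        ("C57BL/6JOlaHsd", "adrenal"): (5, 4, 5, 5, 5, 5, 4),  # B, 33
        ("mixed-CremKO", "liver"): (6, 6, 7, 6, 6, 7, 7),  # C, 45
        ("mixed-CremKO", "adrenal"): (3, 4, 4, 5, 4, 5, 5),  # D, 30
        ("mixed-WT", "liver"): (8, 7, 7, 7, 7, 8, 7),  # E, 51
        ("mixed-WT", "adrenal"): (5, 5, 4, 5, 5, 5, 5),  # F, 34
    }
    return {
        key: {float(t): n for t, n in zip(times, reps)} for key, reps in counts.items()
    }


# Strain offsets are background-level: the two mixed-background strains share
# the same shift relative to the inbred strain.
_MIXED = {"mixed-CremKO", "mixed-WT"}


def _bg_offsets(mixed_shift: float) -> dict[str, float]:
    return {s: mixed_shift for s in _MIXED}


def default_config(seed: int | None = None) -> SimConfig:
    """The study-replica configuration.

    Base Cq levels and efficiencies follow the published summaries: the
    ribosomal-RNA analogue at Cq 8.8, the lowest-abundance candidate at 28.5,
    the rest spread over 18–29, efficiencies per the primer table. The
    beta-actin and HMBS analogues carry background-level strain offsets and
    large biological scatter (they span ~12 cycles over the full design and
    bias cross-strain normalization); the three microarray-selected candidates
    have small scatter (< 4-cycle range). The Dbp-like target peaks at CT12
    with a 2-log2 amplitude.

    Every reference candidate also carries a weak circadian modulation
    (0.05–0.4 log2 amplitude, smallest for the most stable genes): circadian
    time genuinely influences reference-gene expression — that is the point of
    subgrouping samples by sacrifice time — and a simulator with strictly
    time-flat references would make the between-time-point variance component
    identically zero, a degenerate case no circadian tissue exhibits.
    """
    genes = {
        "Actb": GeneSim(19.0, 1.98, 1.5, _bg_offsets(4.0), Rhythm(0.50, 21.0)),
        "Eif2a": GeneSim(24.0, 1.95, 0.25, rhythm=Rhythm(0.08, 5.0)),
        "Gapdh": GeneSim(18.5, 1.94, 0.55, _bg_offsets(0.6), Rhythm(0.40, 9.0)),
        "Hmbs": GeneSim(25.0, 1.64, 1.0, _bg_offsets(2.2), Rhythm(0.45, 15.0)),
        "Hprt1": GeneSim(23.0, 1.89, 0.45, rhythm=Rhythm(0.25, 3.0)),
        "Ppib": GeneSim(21.0, 1.93, 0.4, rhythm=Rhythm(0.20, 7.0)),
        "Rn18s": GeneSim(8.8, 1.79, 0.4, rhythm=Rhythm(0.15, 13.0)),
        "Rplp0": GeneSim(19.5, 1.98, 0.45, rhythm=Rhythm(0.20, 19.0)),
        "Tbcc": GeneSim(28.5, 1.90, 0.25, rhythm=Rhythm(0.06, 11.0)),
        "Utp6c": GeneSim(26.5, 1.82, 0.25, rhythm=Rhythm(0.07, 17.0)),
        "Dbp": GeneSim(22.0, 1.93, 0.3, rhythm=Rhythm(amplitude=2.0, acrophase=12.0)),
    }
    return SimConfig(genes=genes, design=default_design(), seed=seed)


def generate(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw one synthetic study: (Cq table, sample metadata, ground truth).

    Deterministic given the seed (argument overrides ``config.seed``). Sample
    ids encode strain, tissue, time and replicate index; each sample gets its
    own animal id (tissues are simulated as independent cohorts).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)

    meta_rows = []
    for (strain, tissue), cells in config.design.items():
        code = _STRAIN_CODES.get(strain, strain.replace("/", "").replace(" ", ""))
        for t, n in sorted(cells.items()):
            for k in range(1, n + 1):
                sid = f"{code}_{tissue}_ct{int(t):02d}_{k}"
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "strain": strain,
                        "tissue": tissue,
                        "time_ct": float(t),
                        "animal_id": f"{sid}_animal",
                    }
                )
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "strain", "tissue", "time_ct", "animal_id"])
    n_samples = len(meta)

    loading = rng.normal(0.0, config.loading_sd, n_samples)
    t = meta["time_ct"].to_numpy()
    strain_arr = meta["strain"].to_numpy()
    tissue_arr = meta["tissue"].to_numpy()

    cq_frames = []
    for gene, spec in config.genes.items():
        measured = (
            np.ones(n_samples, bool)
            if spec.tissues is None
            else np.isin(tissue_arr, list(spec.tissues))
        )
        a = loading.copy()
        for strain, off in spec.strain_offsets.items():
            a[strain_arr == strain] += off
        if spec.rhythm is not None:
            a += spec.rhythm.amplitude * np.cos(
                2.0 * np.pi * (t - spec.rhythm.acrophase) / 24.0
            )
        a += rng.normal(0.0, spec.biological_sd, n_samples)
        cq_mean = spec.base_cq - a / np.log2(spec.efficiency)
        reps = rng.normal(
            0.0, config.technical_sd, (n_samples, config.technical_replicates)
        )
        cq = cq_mean[:, None] + reps
        frame = pd.DataFrame(
            {
                "sample_id": np.repeat(meta["sample_id"].to_numpy(), config.technical_replicates),
                "gene": gene,
                "replicate": np.tile(
                    np.arange(1, config.technical_replicates + 1), n_samples
                ),
                "cq": cq.ravel(),
            }
        )
        cq_frames.append(frame[np.repeat(measured, config.technical_replicates)])
    cq_table = pd.concat(cq_frames, ignore_index=True)[
        ["sample_id", "gene", "replicate", "cq"]
    ]
    if (cq_table["cq"] <= 0).any():
        raise ValidationError(
            "simulated Cq <= 0; base_cq too low for the configured noise/effects"
        )

    truth = SimTruth(
        base_cq={g: s.base_cq for g, s in config.genes.items()},
        efficiency={g: s.efficiency for g, s in config.genes.items()},
        biological_sd={g: s.biological_sd for g, s in config.genes.items()},
        strain_offsets={g: dict(s.strain_offsets) for g, s in config.genes.items()},
        rhythm={g: s.rhythm for g, s in config.genes.items()},
        loading=pd.Series(loading, index=meta["sample_id"].to_numpy(), name="loading"),
    )
    return cq_table, meta, truth


def generate_dilution_series(
    base_cq: float,
    efficiency: float,
    dilution_factor: float = 5.0,
    n_points: int = 5,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
    gene: str = "gene",
) -> pd.DataFrame:
    """Simulate a serial-dilution standard curve for one primer pair.

    Concentrations fall by ``dilution_factor`` per step from the undiluted
    pool (relative concentration 1); Cq follows
    base_cq − log10(conc)/log10(E) plus Gaussian noise in cycles. Returns a
    frame with columns ``gene, log10_relative_conc, replicate, cq``.
    """
    if n_points < 3:
        raise ValidationError(f"need >= 3 dilution points, got {n_points}")
    if dilution_factor <= 1:
        raise ValidationError("dilution_factor must be > 1")
    if replicates < 1 or noise_sd < 0:
        raise ValidationError("replicates must be >= 1 and noise_sd >= 0")
    if not (1.0 < efficiency <= 2.1):
        raise ValidationError(f"efficiency must lie in (1, 2.1], got {efficiency}")
    rng = np.random.default_rng(seed)
    log10_conc = -np.log10(dilution_factor) * np.arange(n_points)
    slope = -1.0 / np.log10(efficiency)
    rows = []
    for x in log10_conc:
        for r in range(1, replicates + 1):
            rows.append(
                {
                    "gene": gene,
                    "log10_relative_conc": x,
                    "replicate": r,
                    "cq": base_cq + slope * x + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "log10_relative_conc", "replicate", "cq"])


# ---------------------------------------------------------------------------
# YAML round trip (sim.yaml)


def config_to_yaml(config: SimConfig, path: str | Path) -> None:
    doc = {
        "technical_replicates": config.technical_replicates,
        "technical_sd": config.technical_sd,
        "loading_sd": config.loading_sd,
        "seed": config.seed,
        "genes": {
            g: {
                "base_cq": s.base_cq,
                "efficiency": s.efficiency,
                "biological_sd": s.biological_sd,
                "strain_offsets": dict(s.strain_offsets),
                "rhythm": None if s.rhythm is None else asdict(s.rhythm),
                "tissues": None if s.tissues is None else list(s.tissues),
            }
            for g, s in config.genes.items()
        },
        "design": [
            {"strain": strain, "tissue": tissue, "replicates": {float(t): n for t, n in cells.items()}}
            for (strain, tissue), cells in config.design.items()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path) -> SimConfig:
    doc = yaml.safe_load(Path(path).read_text())
    genes = {}
    for g, s in doc["genes"].items():
        rhythm = s.get("rhythm")
        genes[g] = GeneSim(
            base_cq=float(s["base_cq"]),
            efficiency=float(s["efficiency"]),
            biological_sd=float(s.get("biological_sd", 0.3)),
            strain_offsets=dict(s.get("strain_offsets") or {}),
            rhythm=None if rhythm is None else Rhythm(**rhythm),
            tissues=None if s.get("tissues") is None else tuple(s["tissues"]),
        )
    design = {
        (entry["strain"], entry["tissue"]): {
            float(t): int(n) for t, n in entry["replicates"].items()
        }
        for entry in doc["design"]
    }
    return SimConfig(
        genes=genes,
        design=design,
        technical_replicates=int(doc.get("technical_replicates", 3)),
        technical_sd=float(doc.get("technical_sd", 0.15)),
        loading_sd=float(doc.get("loading_sd", 0.15)),
        seed=doc.get("seed"),
    )
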