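"""Synthetic iTRAQ 4-plex reporter-ion data with known ground truth.

The generator emulates a pooled-sample 4-plex experiment run in technical
duplicate: every peptide has a log-normal baseline abundance shared by the
four channels, each channel multiplies it by log-normal technical noise,
and a configurable fraction of proteins carries a true fold-change on one
designated channel contrast. Per-channel noise has standard deviation
``null_sigma / sqrt(2)`` so that the natural-log ratio of any two channels
has SD exactly ``null_sigma`` — the Gaussian structure the downstream null
model assumes.

Truth (which proteins changed, by how much, on which contrast) is drawn
from a stream derived from the master seed only, so duplicate experiments
share proteins, peptides and effects while their technical noise differs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quantio import PEPTIDE_COLUMNS, ChannelContrast, validate_peptide_table

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# fixed sub-stream tags hashed into the seed sequence
_TRUTH_STREAM = 0
_NOISE_STREAM = 1

_DEFAULT_AFFECTED = ChannelContrast(
    "s_after_vs_before", 116, 117, "young susceptible after/before smoking"
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one duplicate-pair simulation.

    Defaults describe a mid-size pooled epithelial-lining-fluid run: a few
    hundred proteins, a long-tailed peptide count per protein (shifted
    Poisson, minimum 1), 5% truly changed proteins at |ln FC| = 1, and
    technical ln-ratio noise of SD 0.15.
    """

    n_proteins: int = 300
    peptides_per_protein_mean: float = 4.0
    de_fraction: float = 0.05
    effect_ln_fc: float = 1.0
    null_sigma: float = 0.15
    base_area_ln_mean: float = 7.0
    base_area_ln_sd: float = 1.0
    confidence_range: tuple[float, float] = (95.0, 99.9)
    dropout_rate: float = 0.0
    affected_contrast: ChannelContrast = field(default=_DEFAULT_AFFECTED)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError(f"n_proteins must be >= 1, got {self.n_proteins}")
        if self.peptides_per_protein_mean < 1:
            raise ConfigurationError(
                f"peptides_per_protein_mean must be >= 1, got {self.peptides_per_protein_mean}"
            )
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError(f"de_fraction must be in [0, 1], got {self.de_fraction}")
        if self.effect_ln_fc <= 0:
            raise ConfigurationError(f"effect_ln_fc must be positive, got {self.effect_ln_fc}")
        if self.null_sigma <= 0:
            raise ConfigurationError(f"null_sigma must be positive, got {self.null_sigma}")
        if self.base_area_ln_sd < 0:
            raise ConfigurationError(
                f"base_area_ln_sd must be non-negative, got {self.base_area_ln_sd}"
            )
        lo, hi = self.confidence_range
        if not (0.0 < lo <= hi <= 100.0):
            raise ConfigurationError(
                f"confidence_range must satisfy 0 < lo <= hi <= 100, got {self.confidence_range}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth label for one simulated protein."""

    protein_accession: str
    is_changed: bool
    true_ln_fc: float  # 0 when unchanged; signed when changed
    contrast: str  # contrast the effect applies to
    n_peptides: int


def _truth_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng((config.seed, _TRUTH_STREAM))


def _noise_rng(config: SimulationConfig, experiment_id: str) -> np.random.Generator:
    tag = zlib.crc32(experiment_id.encode("utf-8"))
    return np.random.default_rng((config.seed, _NOISE_STREAM, tag))


def _draw_truth(config: SimulationConfig):
    """Draw proteins, peptide counts, sequences and effects (seed-only stream)."""
    rng = _truth_rng(config)
    n = config.n_proteins
    accessions = [f"SIM{i + 1:05d}" for i in range(n)]
    n_peptides = 1 + rng.poisson(config.peptides_per_protein_mean - 1.0, size=n)
    changed = rng.random(n) < config.de_fraction
    signs = rng.choice([-1.0, 1.0], size=n)
    ln_fc = np.where(changed, signs * config.effect_ln_fc, 0.0)

    sequences: list[list[str]] = []
    for k in n_peptides:
        seqs: set[str] = set()
        while len(seqs) < k:
            length = int(rng.integers(7, 16))
            seqs.add("".join(rng.choice(_AMINO_ACIDS, size=length)))
        sequences.append(sorted(seqs))

    truth = [
        SimulationTruth(
            protein_accession=acc,
            is_changed=bool(ch),
            true_ln_fc=float(fc),
            contrast=config.affected_contrast.name,
            n_peptides=int(k),
        )
        for acc, ch, fc, k in zip(accessions, changed, ln_fc, n_peptides)
    ]
    return truth, sequences


def generate_experiment(
    config: SimulationConfig, experiment_id: str = "exp1"
) -> tuple[pd.DataFrame, list[SimulationTruth]]:
    """Simulate one 4-plex experiment.

    Returns a validated peptide quantification table (one row per peptide)
    and the per-protein truth list. Identical (config, experiment_id)
    pairs yield bit-identical output.
    """
    truth, sequences = _draw_truth(config)
    rng = _noise_rng(config, experiment_id)

    acc_col: list[str] = []
    seq_col: list[str] = []
    effect_col: list[float] = []
    for rec, seqs in zip(truth, sequences):
        acc_col.extend([rec.protein_accession] * rec.n_peptides)
        seq_col.extend(seqs)
        effect_col.extend([rec.true_ln_fc] * rec.n_peptides)
    m = len(acc_col)

    channel_sd = config.null_sigma / np.sqrt(2.0)
    base_ln = rng.normal(config.base_area_ln_mean, config.base_area_ln_sd, size=m)
    ln_areas = base_ln[:, None] + rng.normal(0.0, channel_sd, size=(m, 4))
    num_idx = [114, 115, 116, 117].index(config.affected_contrast.numerator_channel)
    ln_areas[:, num_idx] += np.asarray(effect_col)
    areas = np.exp(ln_areas)

    lo, hi = config.confidence_range
    confidence = rng.uniform(lo, hi, size=m)

    if config.dropout_rate > 0:
        mask = rng.random(size=(m, 4)) < config.dropout_rate
        areas[mask] = 0.0

    table = pd.DataFrame(
        {
            "experiment_id": experiment_id,
            "protein_accession": acc_col,
            "peptide_sequence": seq_col,
            "confidence_pct": confidence,
            "area_114": areas[:, 0],
            "area_115": areas[:, 1],
            "area_116": areas[:, 2],
            "area_117": areas[:, 3],
        },
        columns=PEPTIDE_COLUMNS,
    )
    return validate_peptide_table(table, source=f"simulated:{experiment_id}"), truth


def generate_replicate_pair(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[SimulationTruth]]:
    """Simulate the duplicate design: two experiments sharing one truth.

    The replicates quantify the same proteins and peptides with the same
    true effects but independent technical noise.
    """
    table_a, truth = generate_experiment(config, "exp1")
    table_b, truth_b = generate_experiment(config, "exp2")
    assert truth == truth_b  # same seed-derived truth stream by construction
    return table_a, table_b, truth


def truth_frame(truth: list[SimulationTruth]) -> pd.DataFrame:
    """Tabulate a truth list for the sidecar TSV."""
    return pd.DataFrame(
        [
            {
                "protein_accession": t.protein_accession,
                "is_changed": t.is_changed,
                "true_ln_fc": t.true_ln_fc,
                "contrast": t.contrast,
                "n_peptides": t.n_peptides,
            }
            for t in truth
        ]
    )


def write_truth(truth: list[SimulationTruth], path) -> None:
    truth_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[SimulationTruth]:
    df = pd.read_csv(path, sep="\t")
    return [
        SimulationTruth(
            protein_accession=str(r.protein_accession),
            is_changed=bool(r.is_changed),
            true_ln_fc=float(r.true_ln_fc),
            contrast=str(r.contrast),
            n_peptides=int(r.n_peptides),
        )
        for r in df.itertuples()
    ]


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: the same study conditions under a different master seed."""
    return replace(config, seed=seed)
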