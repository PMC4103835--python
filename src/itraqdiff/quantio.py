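"""Reading, writing and filtering peptide-level quantification tables.

The on-disk format is a UTF-8, tab-separated table with a header row whose
columns are exactly the fields of a peptide quantification record:

``experiment_id  protein_accession  peptide_sequence  confidence_pct
area_114  area_115  area_116  area_117``

One row per identified peptide; the four ``area_*`` columns hold the
reporter-ion peak areas of the 4-plex channels (arbitrary units).
Identification filtering follows the conventional two-rule scheme: a
peptide-level confidence threshold (95% by default, equivalent to a
ProteinPilot ProtScore of 1.3) followed by a minimum number of unique
peptides per protein (2 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError, ValidationError

CHANNELS = (114, 115, 116, 117)

AREA_COLUMNS = [f"area_{c}" for c in CHANNELS]

PEPTIDE_COLUMNS = [
    "experiment_id",
    "protein_accession",
    "peptide_sequence",
    "confidence_pct",
    *AREA_COLUMNS,
]

_NUMERIC_COLUMNS = ["confidence_pct", *AREA_COLUMNS]


def confidence_to_protscore(confidence_pct: float) -> float:
    """Convert a peptide identification confidence (%) to a ProtScore.

    ProtScore = −log10(1 − confidence/100); 95% maps to 1.3 (to one
    decimal), 99% to 2.0. Strictly increasing on (0, 100).
    """
    if not 0.0 < confidence_pct < 100.0:
        raise ConfigurationError(
            f"confidence_pct must lie in (0, 100), got {confidence_pct!r} "
            "(the score is unbounded at 100)"
        )
    return -math.log10(1.0 - confidence_pct / 100.0)


def protscore_to_confidence(protscore: float) -> float:
    """Inverse of :func:`confidence_to_protscore`: 100·(1 − 10**(−score))."""
    if protscore <= 0.0:
        raise ConfigurationError(f"protscore must be positive, got {protscore!r}")
    return 100.0 * (1.0 - 10.0 ** (-protscore))


@dataclass(frozen=True)
class ChannelContrast:
    """A named ratio between two reporter-ion channels.

    ``name`` identifies the contrast in outputs; the ratio is
    numerator-channel area over denominator-channel area. ``meaning`` is a
    free-text label (e.g. "susceptible after/before smoking").
    """

    name: str
    numerator_channel: int
    denominator_channel: int
    meaning: str = ""

    def __post_init__(self) -> None:
        for side, ch in (
            ("numerator_channel", self.numerator_channel),
            ("denominator_channel", self.denominator_channel),
        ):
            if ch not in CHANNELS:
                raise ConfigurationError(f"{side} must be one of {CHANNELS}, got {ch}")
        if self.numerator_channel == self.denominator_channel:
            raise ConfigurationError(
                f"contrast {self.name!r}: numerator and denominator channels "
                f"are both {self.numerator_channel}"
            )


#: The study design of the 4-plex run: 114 = non-susceptible after smoking,
#: 115 = non-susceptible baseline, 116 = susceptible after smoking,
#: 117 = susceptible baseline.
DEFAULT_CONTRASTS = (
    ChannelContrast("ns_after_vs_before", 114, 115, "young non-susceptible after/before smoking"),
    ChannelContrast("s_after_vs_before", 116, 117, "young susceptible after/before smoking"),
    ChannelContrast("s_vs_ns_baseline", 117, 115, "susceptible vs non-susceptible at baseline"),
)


def resolve_contrast(name: str, contrasts) -> ChannelContrast:
    """Look a contrast up by name; unknown names are a configuration error."""
    for c in contrasts:
        if c.name == name:
            return c
    known = ", ".join(c.name for c in contrasts)
    raise ConfigurationError(f"unknown contrast {name!r} (known: {known})")


@dataclass(frozen=True)
class IdentificationFilterConfig:
    """Peptide/protein identification acceptance rules.

    Either ``min_protscore`` or ``min_confidence_pct`` may be given; the
    other is derived. When both are supplied they must agree through
    score = −log10(1 − confidence/100) within 0.005.
    """

    min_protscore: float = field(default=None)  # type: ignore[assignment]
    min_confidence_pct: float = field(default=None)  # type: ignore[assignment]
    min_unique_peptides: int = 2

    def __post_init__(self) -> None:
        score, conf = self.min_protscore, self.min_confidence_pct
        if score is None and conf is None:
            score, conf = 1.3, 95.0
        elif score is None:
            score = confidence_to_protscore(conf)
        elif conf is None:
            conf = protscore_to_confidence(score)
        else:
            implied = confidence_to_protscore(conf)
            if abs(score - implied) > 0.005:
                raise ConfigurationError(
                    f"min_protscore={score} inconsistent with "
                    f"min_confidence_pct={conf} (implies {implied:.4f})"
                )
        if self.min_unique_peptides < 1:
            raise ConfigurationError(
                f"min_unique_peptides must be >= 1, got {self.min_unique_peptides}"
            )
        object.__setattr__(self, "min_protscore", float(score))
        object.__setattr__(self, "min_confidence_pct", float(conf))


def read_peptide_table(path, dialect: str = "\t") -> pd.DataFrame:
    """Read and validate a peptide quantification table.

    Returns a DataFrame with the canonical column order, original row order
    preserved. Missing columns raise :class:`SchemaError`; malformed
    numerics or invariant violations raise :class:`ValidationError` naming
    the offending 1-based data rows.
    """
    raw = pd.read_csv(path, sep=dialect, dtype=str, keep_default_na=False)
    missing = [c for c in PEPTIDE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"peptide table {path} is missing column(s): {', '.join(missing)}")
    raw = raw[PEPTIDE_COLUMNS].reset_index(drop=True)
    return validate_peptide_table(raw, source=str(path))


def validate_peptide_table(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Coerce numeric columns and enforce record invariants.

    Accepts string or numeric dtypes; all problems are collected and
    reported together with 1-based data-row numbers.
    """
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s): {', '.join(missing)}")
    out = df[PEPTIDE_COLUMNS].reset_index(drop=True).copy()
    problems: list[str] = []
    for col in _NUMERIC_COLUMNS:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna()
        for i in out.index[bad]:
            problems.append(f"row {i + 1}: {col}={out.at[i, col]!r} is not numeric")
        out[col] = converted
    if not problems:
        for i in out.index[~((out["confidence_pct"] > 0) & (out["confidence_pct"] <= 100))]:
            problems.append(
                f"row {i + 1}: confidence_pct={out.at[i, 'confidence_pct']} outside (0, 100]"
            )
        for col in AREA_COLUMNS:
            for i in out.index[out[col] < 0]:
                problems.append(f"row {i + 1}: {col}={out.at[i, col]} is negative")
        for col in ("protein_accession", "peptide_sequence"):
            for i in out.index[out[col].astype(str).str.len() == 0]:
                problems.append(f"row {i + 1}: {col} is empty")
    if problems:
        raise ValidationError(f"{source}: " + "; ".join(problems))
    return out


def write_peptide_table(df: pd.DataFrame, path) -> None:
    """Write a peptide table as TSV with the canonical column order."""
    df[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)


def filter_identifications(
    records: pd.DataFrame, cfg: IdentificationFilterConfig = IdentificationFilterConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the two identification rules and return (retained, rejections).

    Rule 1 drops peptides below ``min_confidence_pct``; rule 2 then drops
    every peptide of a protein with fewer than ``min_unique_peptides``
    distinct retained sequences (per experiment, uppercased). The rejection
    log has one row per dropped peptide naming the failed rule. The
    operation is idempotent.
    """
    df = records.reset_index(drop=True)
    ok_conf = df["confidence_pct"] >= cfg.min_confidence_pct
    kept = df[ok_conf]
    uniq = (
        kept.assign(_seq=kept["peptide_sequence"].str.upper())
        .groupby(["experiment_id", "protein_accession"])["_seq"]
        .transform("nunique")
    )
    ok_count = uniq >= cfg.min_unique_peptides

    rejections = []
    for i in df.index[~ok_conf]:
        rejections.append((i, "confidence_below_minimum"))
    for i in kept.index[~ok_count]:
        rejections.append((i, "insufficient_unique_peptides"))
    rej_df = pd.DataFrame(
        [
            {
                "row": i,
                "experiment_id": df.at[i, "experiment_id"],
                "protein_accession": df.at[i, "protein_accession"],
                "peptide_sequence": df.at[i, "peptide_sequence"],
                "rule": rule,
            }
            for i, rule in sorted(rejections)
        ],
        columns=["row", "experiment_id", "protein_accession", "peptide_sequence", "rule"],
    )
    retained = kept[ok_count].reset_index(drop=True)
    return retained, rej_df


def read_contrasts(path) -> list[ChannelContrast]:
    """Read a channel-map/contrast configuration (YAML or JSON).

    Expected layout::

        contrasts:
          - name: s_after_vs_before
            numerator: 116
            denominator: 117
            meaning: susceptible after/before smoking
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "contrasts" not in doc:
        raise ConfigurationError(f"{path}: expected a mapping with a 'contrasts' list")
    out = []
    for entry in doc["contrasts"]:
        try:
            out.append(
                ChannelContrast(
                    name=str(entry["name"]),
                    numerator_channel=int(entry["numerator"]),
                    denominator_channel=int(entry["denominator"]),
                    meaning=str(entry.get("meaning", "")),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: contrast entry missing key {exc}") from exc
    if not out:
        raise ConfigurationError(f"{path}: 'contrasts' list is empty")
    return out


def write_contrasts(contrasts, path) -> None:
    doc = {
        "contrasts": [
            {
                "name": c.name,
                "numerator": c.numerator_channel,
                "denominator": c.denominator_channel,
                "meaning": c.meaning,
            }
            for c in contrasts
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
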