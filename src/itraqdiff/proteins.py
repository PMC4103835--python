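"""Peptide-to-protein rollup and duplicate-experiment candidate selection.

A protein's reported ratio for a contrast is the median ratio of its
*discriminatory* peptides — those called beyond k·σ of the fitted null —
computed on the ln scale and exponentiated (for an even peptide count this
is the geometric mean of the two central ratios). Proteins with no discriminatory peptide get no ratio (rendered as
"σ <2.5" in reports); single-peptide results are flagged rather than
dropped. Candidate selection requires concordant significance (same
direction) in both duplicate experiments and at least
``min_discriminatory_peptides`` peptides with p < ``max_peptide_p`` in each
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "ProteinResult",
    "SelectionCriteria",
    "aggregate_protein",
    "aggregate_proteins",
    "results_frame",
    "replicate_overlap",
    "select_candidates",
]


@dataclass(frozen=True)
class ProteinResult:
    """Per-protein aggregate for one contrast in one experiment."""

    protein_accession: str
    contrast: str
    median_ratio: float | None  # median of exp(ln_ratio) over discriminatory peptides
    n_peptides_total: int
    n_peptides_discriminatory: int
    min_peptide_p: float
    call: str  # 'up' | 'down' | 'none'
    single_peptide_flag: bool
    note: str = ""  # free-text annotation (e.g. 'direction conflict')


@dataclass(frozen=True)
class SelectionCriteria:
    """Candidate-selection rules across the duplicate experiments."""

    require_both_experiments: bool = True
    min_discriminatory_peptides: int = 2
    max_peptide_p: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.max_peptide_p < 1.0:
            raise ConfigurationError(f"max_peptide_p must be in (0, 1), got {self.max_peptide_p}")
        if self.min_discriminatory_peptides < 1:
            raise ConfigurationError(
                "min_discriminatory_peptides must be >= 1, "
                f"got {self.min_discriminatory_peptides}"
            )


def aggregate_protein(observations: pd.DataFrame) -> ProteinResult:
    """Roll one protein's scored peptides (one contrast) up to a result.

    ``observations`` needs columns ``protein_accession, contrast, ln_ratio,
    p_value, significant, direction`` and must contain a single accession
    and contrast. The call is the majority direction among discriminatory
    peptides; an exact tie yields call 'none' with a conflict note. The
    median ratio is exp(median ln_ratio) over the discriminatory peptides
    and exists exactly when at least one peptide is discriminatory.
    """
    if len(observations) == 0:
        raise ValidationError("aggregate_protein: empty observation set")
    accessions = observations["protein_accession"].unique()
    contrasts = observations["contrast"].unique()
    if len(accessions) != 1 or len(contrasts) != 1:
        raise ValidationError(
            f"aggregate_protein expects one protein and one contrast, got "
            f"{list(accessions)} x {list(contrasts)}"
        )

    disc = observations[observations["significant"].astype(bool)]
    n_disc = len(disc)
    n_up = int((disc["direction"] == "up").sum())
    n_down = int((disc["direction"] == "down").sum())

    note = ""
    if n_disc == 0:
        call, median_ratio = "none", None
    else:
        # median taken on the ln scale, then exponentiated: identical to the
        # median of ratios for odd counts, geometric mean of the two central
        # ratios for even counts
        median_ratio = float(np.exp(np.median(disc["ln_ratio"].to_numpy(float))))
        if n_up > n_down:
            call = "up"
        elif n_down > n_up:
            call = "down"
        else:
            call, note = "none", "direction conflict among discriminatory peptides"

    return ProteinResult(
        protein_accession=str(accessions[0]),
        contrast=str(contrasts[0]),
        median_ratio=median_ratio,
        n_peptides_total=len(observations),
        n_peptides_discriminatory=n_disc,
        min_peptide_p=float(observations["p_value"].min()),
        call=call,
        single_peptide_flag=n_disc == 1,
        note=note,
    )


def aggregate_proteins(observations: pd.DataFrame) -> list[ProteinResult]:
    """Aggregate every (protein, contrast) group in a scored observation table."""
    return [
        aggregate_protein(group)
        for _, group in observations.groupby(["protein_accession", "contrast"], sort=True)
    ]


def results_frame(results: list[ProteinResult]) -> pd.DataFrame:
    """Tabulate protein results for the results TSV."""
    return pd.DataFrame(
        [
            {
                "protein_accession": r.protein_accession,
                "contrast": r.contrast,
                "median_ratio": r.median_ratio if r.median_ratio is not None else np.nan,
                "n_peptides_total": r.n_peptides_total,
                "n_peptides_discriminatory": r.n_peptides_discriminatory,
                "min_peptide_p": r.min_peptide_p,
                "call": r.call,
                "single_peptide_flag": r.single_peptide_flag,
                "note": r.note,
            }
            for r in results
        ]
    )


def replicate_overlap(
    results_exp1: list[ProteinResult], results_exp2: list[ProteinResult]
) -> list[tuple[ProteinResult, ProteinResult]]:
    """Proteins significantly changed in the same direction in both runs.

    Both result sets must cover the same contrast names. The retained set
    is symmetric in argument order (pairs come back in the first
    argument's order, partner order swapped).
    """
    contrasts1 = {r.contrast for r in results_exp1}
    contrasts2 = {r.contrast for r in results_exp2}
    if contrasts1 != contrasts2:
        raise ConfigurationError(
            f"contrast mismatch between experiments: {sorted(contrasts1)} vs {sorted(contrasts2)}"
        )
    index2 = {(r.protein_accession, r.contrast): r for r in results_exp2}
    pairs = []
    for r1 in results_exp1:
        r2 = index2.get((r1.protein_accession, r1.contrast))
        if r2 is None:
            continue
        if r1.call != "none" and r1.call == r2.call:
            pairs.append((r1, r2))
    return pairs


def select_candidates(
    pairs: list[tuple[ProteinResult, ProteinResult]],
    criteria: SelectionCriteria,
    pvalues_exp1: pd.DataFrame,
    pvalues_exp2: pd.DataFrame,
) -> tuple[list[tuple[ProteinResult, ProteinResult]], list[str]]:
    """Apply the peptide-count criterion to concordant protein pairs.

    ``pvalues_exp*`` are scored observation tables (columns
    ``protein_accession, contrast, p_value``) for the two experiments. A
    protein is retained when it has at least
    ``min_discriminatory_peptides`` peptides with p < ``max_peptide_p``
    (strict) in each experiment (in at least one when
    ``require_both_experiments`` is off). Returns the retained pairs and a
    per-protein selection log naming the failed rule.
    """

    def counts(pvals: pd.DataFrame) -> pd.Series:
        hit = pvals[pvals["p_value"] < criteria.max_peptide_p]
        return hit.groupby(["protein_accession", "contrast"]).size()

    c1, c2 = counts(pvalues_exp1), counts(pvalues_exp2)
    retained, log = [], []
    for r1, r2 in pairs:
        key = (r1.protein_accession, r1.contrast)
        n1 = int(c1.get(key, 0))
        n2 = int(c2.get(key, 0))
        ok1 = n1 >= criteria.min_discriminatory_peptides
        ok2 = n2 >= criteria.min_discriminatory_peptides
        ok = (ok1 and ok2) if criteria.require_both_experiments else (ok1 or ok2)
        if ok:
            retained.append((r1, r2))
            log.append(f"{key[0]}/{key[1]}: retained ({n1} and {n2} peptides "
                       f"with p < {criteria.max_peptide_p})")
        else:
            failing = []
            if not ok1:
                failing.append(f"experiment 1 has {n1}")
            if not ok2:
                failing.append(f"experiment 2 has {n2}")
            log.append(
                f"{key[0]}/{key[1]}: excluded — needs >= "
                f"{criteria.min_discriminatory_peptides} peptides with p < "
                f"{criteria.max_peptide_p}; " + ", ".join(failing)
            )
    return retained, log


def candidates_frame(pairs: list[tuple[ProteinResult, ProteinResult]]) -> pd.DataFrame:
    """Tabulate candidate pairs with per-experiment concordance columns."""
    rows = []
    for r1, r2 in pairs:
        rows.append(
            {
                "protein_accession": r1.protein_accession,
                "contrast": r1.contrast,
                "call": r1.call,
                "median_ratio_exp1": r1.median_ratio,
                "median_ratio_exp2": r2.median_ratio,
                "n_discriminatory_exp1": r1.n_peptides_discriminatory,
                "n_discriminatory_exp2": r2.n_peptides_discriminatory,
                "min_peptide_p_exp1": r1.min_peptide_p,
                "min_peptide_p_exp2": r2.min_peptide_p,
                "single_peptide_flag": r1.single_peptide_flag or r2.single_peptide_flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_accession",
            "contrast",
            "call",
            "median_ratio_exp1",
            "median_ratio_exp2",
            "n_discriminatory_exp1",
            "n_discriminatory_exp2",
            "min_peptide_p_exp1",
            "min_peptide_p_exp2",
            "single_peptide_flag",
        ],
    )
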