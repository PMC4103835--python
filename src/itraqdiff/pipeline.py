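"""End-to-end quantification pipeline and report rendering.

Orchestrates: read/validate peptide tables → identification filtering →
per-experiment, per-contrast ln-ratio computation → null-model fit →
peptide calls and p-values → protein rollup → duplicate-experiment
concordance and candidate selection. Every dropped row appears in exactly
one log with a reason, and a machine-readable run manifest records the
configuration, package version and peptide bookkeeping so that
n_input = n_used + n_filtered + n_excluded holds per experiment and
contrast.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, ValidationError
from .nullmodel import (
    CallingConfig,
    GaussianNull,
    HistogramSpec,
    SmootherSpec,
    call_significant,
    compute_ln_ratios,
    fit_null,
    peptide_pvalue,
)
from .proteins import (
    ProteinResult,
    SelectionCriteria,
    aggregate_proteins,
    candidates_frame,
    replicate_overlap,
    results_frame,
    select_candidates,
)
from .quantio import (
    DEFAULT_CONTRASTS,
    ChannelContrast,
    IdentificationFilterConfig,
    filter_identifications,
    read_contrasts,
    read_peptide_table,
    validate_peptide_table,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one quantification run needs."""

    contrasts: tuple[ChannelContrast, ...] = tuple(DEFAULT_CONTRASTS)
    id_filter: IdentificationFilterConfig = field(default_factory=IdentificationFilterConfig)
    hist: HistogramSpec = field(default_factory=HistogramSpec)
    smoother: SmootherSpec = field(default_factory=SmootherSpec)
    calling: CallingConfig = field(default_factory=CallingConfig)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)

    @classmethod
    def from_files(cls, contrasts_path=None, **kwargs) -> "PipelineConfig":
        contrasts = (
            tuple(read_contrasts(contrasts_path)) if contrasts_path else tuple(DEFAULT_CONTRASTS)
        )
        return cls(contrasts=contrasts, **kwargs)


@dataclass
class QuantificationBundle:
    """All artifacts of one run, in memory."""

    null_fits: dict[tuple[str, str], GaussianNull]  # (experiment, contrast) -> fit
    observations: pd.DataFrame  # scored peptide observations
    protein_results: dict[str, list[ProteinResult]]  # experiment -> results
    candidates: pd.DataFrame
    logs: dict[str, pd.DataFrame]
    selection_log: list[str]
    manifest: dict


def _score_observations(obs: pd.DataFrame, null: GaussianNull, cfg: CallingConfig) -> pd.DataFrame:
    out = obs.copy()
    values = out["ln_ratio"].to_numpy(float)
    out["p_value"] = peptide_pvalue(values, null, cfg)
    sig, direction = call_significant(values, null, cfg)
    out["significant"] = sig
    out["direction"] = direction
    return out


def run_quantification(
    tables, config: PipelineConfig = PipelineConfig(), out_dir=None
) -> QuantificationBundle:
    """Run the full quantification on one or two peptide tables.

    ``tables`` is a list of paths or in-memory DataFrames (one per
    experiment, or a single table mixing experiment_ids). Deterministic
    given inputs and configuration. When ``out_dir`` is given, all result
    tables, logs and a JSON manifest are written there; partial outputs
    are removed if the run fails.
    """
    frames = []
    for t in tables:
        if isinstance(t, (str, Path)):
            frames.append(read_peptide_table(t))
        else:
            frames.append(validate_peptide_table(t))
    records = pd.concat(frames, ignore_index=True)
    experiments = list(dict.fromkeys(records["experiment_id"]))
    if not 1 <= len(experiments) <= 2:
        raise ConfigurationError(
            f"expected 1 or 2 experiments, found {len(experiments)}: {experiments}"
        )
    if len(experiments) == 1 and config.selection.require_both_experiments:
        raise ConfigurationError(
            "require_both_experiments is set but only one experiment is present"
        )

    retained, rejections = filter_identifications(records, config.id_filter)

    null_fits: dict[tuple[str, str], GaussianNull] = {}
    scored_parts: list[pd.DataFrame] = []
    exclusion_parts: list[pd.DataFrame] = []
    results_by_exp: dict[str, list[ProteinResult]] = {}
    for exp in experiments:
        exp_records = retained[retained["experiment_id"] == exp].reset_index(drop=True)
        exp_scored: list[pd.DataFrame] = []
        for contrast in config.contrasts:
            obs, excl = compute_ln_ratios(exp_records, contrast)
            exclusion_parts.append(excl)
            null = fit_null(obs["ln_ratio"].to_numpy(float), config.hist, config.smoother)
            null_fits[(exp, contrast.name)] = null
            exp_scored.append(_score_observations(obs, null, config.calling))
        exp_obs = pd.concat(exp_scored, ignore_index=True)
        scored_parts.append(exp_obs)
        results_by_exp[exp] = aggregate_proteins(exp_obs)

    observations = pd.concat(scored_parts, ignore_index=True)
    exclusions = (
        pd.concat(exclusion_parts, ignore_index=True)
        if exclusion_parts
        else pd.DataFrame()
    )

    if len(experiments) == 2:
        exp1, exp2 = experiments
        pairs = replicate_overlap(results_by_exp[exp1], results_by_exp[exp2])
        pv1 = observations[observations["experiment_id"] == exp1]
        pv2 = observations[observations["experiment_id"] == exp2]
        selected, selection_log = select_candidates(pairs, config.selection, pv1, pv2)
    else:
        (exp1,) = experiments
        singles = [(r, r) for r in results_by_exp[exp1] if r.call != "none"]
        pv1 = observations
        selected, selection_log = select_candidates(singles, config.selection, pv1, pv1)
    candidates = candidates_frame(selected)

    n_contrasts = len(config.contrasts)
    manifest = {
        "package": "itraqdiff",
        "version": __version__,
        "config": _config_echo(config),
        "experiments": experiments,
        "counts": {
            "n_input_peptides": int(len(records)),
            "n_filtered_peptides": int(len(rejections)),
            "n_retained_peptides": int(len(retained)),
            "n_excluded_ratio_rows": int(len(exclusions)),
            "n_used_ratio_rows": int(len(observations)),
            "n_contrasts": n_contrasts,
            "n_candidates": int(len(candidates)),
        },
        "null_fits": {
            f"{exp}:{name}": {
                "mu": fit.mu,
                "sigma": fit.sigma,
                "amplitude": fit.amplitude,
                "rss": fit.rss,
                "n_in_range": fit.n_in_range,
                "n_out_of_range": fit.n_out_of_range,
            }
            for (exp, name), fit in null_fits.items()
        },
    }

    bundle = QuantificationBundle(
        null_fits=null_fits,
        observations=observations,
        protein_results=results_by_exp,
        candidates=candidates,
        logs={"identification_rejections": rejections, "ratio_exclusions": exclusions},
        selection_log=selection_log,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return {
        "contrasts": [enc(c) for c in config.contrasts],
        "id_filter": enc(config.id_filter),
        "hist": enc(config.hist),
        "smoother": enc(config.smoother),
        "calling": enc(config.calling),
        "selection": enc(config.selection),
    }


def _write_bundle(bundle: QuantificationBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def write_tsv(df: pd.DataFrame, name: str):
            path = out_dir / name
            df.to_csv(path, sep="\t", index=False)
            written.append(path)

        all_results = []
        for exp, results in bundle.protein_results.items():
            frame = results_frame(results)
            frame.insert(0, "experiment_id", exp)
            all_results.append(frame)
        write_tsv(pd.concat(all_results, ignore_index=True), "protein_results.tsv")
        write_tsv(bundle.candidates, "candidates.tsv")
        write_tsv(bundle.observations, "peptide_observations.tsv")
        write_tsv(bundle.logs["identification_rejections"], "identification_rejections.tsv")
        write_tsv(bundle.logs["ratio_exclusions"], "ratio_exclusions.tsv")

        path = out_dir / "selection_log.txt"
        path.write_text("\n".join(bundle.selection_log) + "\n")
        written.append(path)

        path = out_dir / "manifest.json"
        path.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
        written.append(path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


_NONSIG_MARKER = "σ <2.5"


def run_report(bundle: QuantificationBundle) -> str:
    """Render a human-readable report of one quantification run.

    Per experiment, proteins with at least one non-'none' call are listed
    with their median discriminatory-peptide ratio per contrast; proteins
    that did not reach significance on a contrast show the non-significant
    marker, single-peptide values carry a ``*`` footnote. Null-fit
    diagnostics and the candidate list follow.
    """
    missing = [
        name
        for name, part in (
            ("null_fits", bundle.null_fits),
            ("protein_results", bundle.protein_results),
            ("manifest", bundle.manifest),
        )
        if not part
    ]
    if bundle.candidates is None or bundle.observations is None:
        missing.append("candidates/observations")
    if missing:
        raise ValidationError(f"incomplete results bundle, missing: {', '.join(missing)}")

    lines: list[str] = []
    lines.append("iTRAQ differential-protein report")
    lines.append("=" * 50)

    for exp, results in bundle.protein_results.items():
        contrasts = sorted({r.contrast for r in results})
        lines.append("")
        lines.append(f"Experiment {exp}")
        lines.append("-" * 50)
        by_protein: dict[str, dict[str, ProteinResult]] = {}
        for r in results:
            by_protein.setdefault(r.protein_accession, {})[r.contrast] = r
        shown = {
            acc
            for acc, per in by_protein.items()
            if any(r.call != "none" for r in per.values())
        }
        header = ["protein"] + contrasts
        lines.append("\t".join(header))
        for acc in sorted(shown):
            cells = [acc]
            for contrast in contrasts:
                r = by_protein[acc].get(contrast)
                if r is None or r.call == "none" or r.median_ratio is None:
                    cells.append(_NONSIG_MARKER)
                else:
                    cells.append(f"{r.median_ratio:.2f}" + ("*" if r.single_peptide_flag else ""))
            lines.append("\t".join(cells))
        if not shown:
            lines.append("(no significantly changed proteins)")

    lines.append("")
    lines.append("Null-model fits (per experiment × contrast)")
    lines.append("-" * 50)
    for (exp, name), fit in bundle.null_fits.items():
        lines.append(
            f"{exp} {name}: mu={fit.mu:+.4f} sigma={fit.sigma:.4f} "
            f"rss={fit.rss:.1f} n_in_range={fit.n_in_range} "
            f"n_out_of_range={fit.n_out_of_range}"
        )

    lines.append("")
    n_cand = len(bundle.candidates)
    if n_cand == 0:
        lines.append("Candidates meeting all selection criteria: zero candidates")
    else:
        lines.append(f"Candidates meeting all selection criteria: {n_cand}")
        for _, row in bundle.candidates.iterrows():
            flag = "*" if row["single_peptide_flag"] else ""
            lines.append(
                f"  {row['protein_accession']} [{row['contrast']}] {row['call']}{flag} "
                f"median ratio {row['median_ratio_exp1']:.2f} / {row['median_ratio_exp2']:.2f}"
            )
    lines.append("")
    lines.append("* based on one peptide; " + _NONSIG_MARKER +
                 ": peptides did not reach the k·σ significance threshold")
    return "\n".join(lines) + "\n"
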