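"""End-to-end orchestration: simulate -> DE -> signature -> cohort -> score.

A run is configured by a flat, namespaced key-value set with documented
defaults (see ``DEFAULTS``), driven by one global seed.  Per-stage seeds are
derived from the global seed by hashing the stage name, so an individual
stage rerun with its derived seed reproduces the full-run artifact exactly.
All artifacts are plain TSV/JSON files and a manifest records their SHA-256
checksums, which makes byte-level determinism checkable.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .io import ValidationError
from .sam import SamConfig, SamDE
from .scoring import TumorScoreModel
from .signature import build_signature, common_gene_fraction, sirolimus_correction
from .simulate import (
    CohortSimParams,
    FibroblastSimParams,
    simulate_fibroblast_experiment,
    simulate_tumor_cohort,
)

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, object] = {
    # global
    "seed": 0,
    # fibroblast simulation
    "fibroblast.n_genes": 2000,
    "fibroblast.n_lines": 3,
    "fibroblast.frac_up_in_ko": 0.10,
    "fibroblast.frac_down_in_ko": 0.05,
    "fibroblast.effect_size_logfc": 2.0,
    "fibroblast.frac_reversed_up": 0.92,
    "fibroblast.frac_reversed_down": 0.80,
    "fibroblast.frac_shared_sirolimus": 0.05,
    "fibroblast.shared_sirolimus_logfc": 1.5,
    "fibroblast.noise_sd": 0.5,
    "fibroblast.baseline_log_mean": 3.0,
    "fibroblast.baseline_log_sd": 1.5,
    # SAM
    "sam.fdr_target": 0.10,
    "sam.s0_mode": "auto",
    "sam.s0_percentile": 5.0,
    "sam.s0_fixed": 0.0,
    "sam.max_exhaustive_perms": 5000,
    "sam.n_sampled_perms": 1000,
    # cohort simulation
    "cohort.n_tumors": 391,
    "cohort.frac_mutant": 43 / 391,
    "cohort.mutant_shift_logfc": 1.0,
    "cohort.noise_sd": 1.0,
    "cohort.n_background_genes": 200,
    "cohort.frac_silent_in_wt": 0.10,
    "cohort.baseline_log_mean": 5.0,
    "cohort.baseline_log_sd": 1.5,
    # scoring
    "score.test": "mann_whitney",
}

_TYPES: dict[str, type] = {k: type(v) for k, v in DEFAULTS.items()}


@dataclass
class RunConfig:
    """Resolved flat configuration for a pipeline run."""

    params: dict[str, object] = field(default_factory=lambda: dict(DEFAULTS))

    def __getitem__(self, key: str):
        return self.params[key]

    def override(self, key: str, value) -> None:
        if key not in DEFAULTS:
            hint = difflib.get_close_matches(key, DEFAULTS, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValidationError(f"unknown config key {key!r}{suggestion}")
        want = _TYPES[key]
        if want in (int, float):
            try:
                value = want(value) if want is float else _as_int(value)
            except (TypeError, ValueError):
                raise ValidationError(f"config key {key!r} expects {want.__name__}, got {value!r}")
        elif not isinstance(value, want):
            raise ValidationError(f"config key {key!r} expects {want.__name__}, got {value!r}")
        self.params[key] = value


def _as_int(value) -> int:
    if isinstance(value, bool) or (isinstance(value, float) and not value.is_integer()):
        raise ValueError(value)
    return int(value)


def validate_config(path) -> RunConfig:
    """Load a YAML key-value config, fill defaults, check keys and types."""
    cfg = RunConfig()
    text = Path(path).read_text(encoding="utf-8") if path else ""
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping of key: value")
    for key, value in data.items():
        cfg.override(str(key), value)
    logger.info("resolved config: %s", json.dumps({k: cfg.params[k] for k in sorted(cfg.params)}, default=str))
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fibroblast_params(cfg: RunConfig, seed: int) -> FibroblastSimParams:
    p = cfg.params
    return FibroblastSimParams(
        n_genes=p["fibroblast.n_genes"],
        n_lines=p["fibroblast.n_lines"],
        frac_up_in_ko=p["fibroblast.frac_up_in_ko"],
        frac_down_in_ko=p["fibroblast.frac_down_in_ko"],
        effect_size_logfc=p["fibroblast.effect_size_logfc"],
        frac_reversed_up=p["fibroblast.frac_reversed_up"],
        frac_reversed_down=p["fibroblast.frac_reversed_down"],
        frac_shared_sirolimus=p["fibroblast.frac_shared_sirolimus"],
        shared_sirolimus_logfc=p["fibroblast.shared_sirolimus_logfc"],
        noise_sd=p["fibroblast.noise_sd"],
        baseline_log_mean=p["fibroblast.baseline_log_mean"],
        baseline_log_sd=p["fibroblast.baseline_log_sd"],
        seed=seed,
    )


def _cohort_params(cfg: RunConfig, seed: int) -> CohortSimParams:
    p = cfg.params
    return CohortSimParams(
        n_tumors=p["cohort.n_tumors"],
        frac_mutant=p["cohort.frac_mutant"],
        mutant_shift_logfc=p["cohort.mutant_shift_logfc"],
        noise_sd=p["cohort.noise_sd"],
        n_background_genes=p["cohort.n_background_genes"],
        frac_silent_in_wt=p["cohort.frac_silent_in_wt"],
        baseline_log_mean=p["cohort.baseline_log_mean"],
        baseline_log_sd=p["cohort.baseline_log_sd"],
        seed=seed,
    )


def sam_config(cfg: RunConfig, seed: int) -> SamConfig:
    p = cfg.params
    return SamConfig(
        s0_mode=p["sam.s0_mode"],
        s0_percentile=p["sam.s0_percentile"],
        s0_fixed=p["sam.s0_fixed"],
        max_exhaustive_perms=p["sam.max_exhaustive_perms"],
        n_sampled_perms=p["sam.n_sampled_perms"],
        fdr_target=p["sam.fdr_target"],
        seed=seed,
    )


def default_ortholog_map(mouse_genes: list[str]) -> pd.DataFrame:
    """Synthetic one-to-one mouse->human map: upper-case the symbol."""
    return pd.DataFrame({"mouse_gene": mouse_genes, "human_gene": [g.upper() for g in mouse_genes]})


def run_full_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the full chain and write every intermediate artifact.

    Stages: fibroblast simulation -> three SAM contrasts -> signature ->
    sirolimus-correction report -> common-gene fractions -> ortholog map ->
    cohort simulation -> tumor scoring -> group comparison.  A manifest JSON
    records parameters, the seed and artifact checksums; ``summary.txt`` is a
    human-readable digest.  Any stage error aborts with the stage name;
    partial artifacts are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    artifacts: dict[str, str] = {}
    summary_lines: list[str] = []
    stage = "init"

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)
        return path

    try:
        stage = "simulate_fibroblast"
        fib_params = _fibroblast_params(config, stage_seed(seed, stage))
        matrix, samples, truth = simulate_fibroblast_experiment(fib_params)
        save("fibroblast_expression.tsv", lambda p: tio.write_expression_matrix(matrix, p))
        save("fibroblast_samples.tsv", lambda p: tio.write_sample_table(samples, p))
        save("fibroblast_truth.tsv", lambda p: truth.to_frame().to_csv(p, sep="\t", index=False))

        stage = "differential_expression"
        de = {}
        for comparison in ("ko_vs_wt_vehicle", "sir_vs_veh_in_ko", "sir_vs_veh_in_wt"):
            cfg = sam_config(config, stage_seed(seed, f"sam:{comparison}"))
            res = SamDE(matrix, samples, comparison, cfg).fit()
            de[comparison] = res
            save(f"de_{comparison}.tsv", lambda p, r=res: r.table.to_csv(p, sep="\t", index=False))
            summary_lines.append(res.summary())
            summary_lines.append("")

        stage = "build_signature"
        sig = build_signature(de["ko_vs_wt_vehicle"])
        save("signature_mouse.tsv", lambda p: tio.write_signature(sig, p))

        stage = "sirolimus_correction"
        report = sirolimus_correction(sig, de["sir_vs_veh_in_ko"])
        save("correction_report.tsv", lambda p: report.to_frame().to_csv(p, sep="\t", index=False))
        summary_lines.append(report.summary())

        stage = "common_gene_fraction"
        common = {
            "pct_common_up": common_gene_fraction(de["sir_vs_veh_in_wt"], de["sir_vs_veh_in_ko"], 1),
            "pct_common_down": common_gene_fraction(de["sir_vs_veh_in_wt"], de["sir_vs_veh_in_ko"], -1),
        }
        save(
            "common_gene_fraction.json",
            lambda p: p.write_text(json.dumps(common, indent=2) + "\n"),
        )

        stage = "ortholog_map"
        omap = default_ortholog_map(list(sig.genes))
        save("ortholog_map.tsv", lambda p: tio.write_ortholog_map(omap, p))

        stage = "simulate_cohort"
        from .scoring import map_orthologs

        human_sig = map_orthologs(sig, omap)
        if len(human_sig) == 0:
            raise ValidationError("empty human signature; cannot simulate a cohort")
        cohort_params = _cohort_params(config, stage_seed(seed, stage))
        tumor_matrix, mutations, cohort_truth = simulate_tumor_cohort(cohort_params, human_sig)
        save("signature_human.tsv", lambda p: tio.write_signature(human_sig, p))
        save("tumor_expression.tsv", lambda p: tio.write_expression_matrix(tumor_matrix, p))
        save("tumor_mutations.maf.tsv", lambda p: tio.write_mutation_table(mutations, p))
        save(
            "cohort_truth.tsv",
            lambda p: cohort_truth.to_frame().to_csv(p, sep="\t", index=False),
        )

        stage = "score_tumors"
        model = TumorScoreModel(
            tumor_matrix, human_sig, mutations=mutations, test=str(config["score.test"])
        )
        results = model.fit()
        save("tumor_scores.tsv", lambda p: results.score_table.to_csv(p, sep="\t"))
        comparison_payload = (
            {
                "statistic_name": results.comparison.statistic_name,
                "statistic": results.comparison.statistic,
                "p_value": results.comparison.p_value,
                "n_mutant": results.comparison.n_group1,
                "n_wildtype": results.comparison.n_group2,
                "median_mutant": results.comparison.median_group1,
                "median_wildtype": results.comparison.median_group2,
            }
            if results.comparison
            else None
        )
        save(
            "score_comparison.json",
            lambda p: p.write_text(json.dumps(comparison_payload, indent=2) + "\n"),
        )
        summary_lines.append(results.summary())
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    manifest = {
        "seed": seed,
        "parameters": {k: config.params[k] for k in sorted(config.params)},
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return out
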