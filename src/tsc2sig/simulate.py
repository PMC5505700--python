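"""Synthetic data with the statistical structure the downstream analysis assumes.

Three generators cover the three data domains of the pipeline:

* :func:`simulate_fibroblast_experiment` — a mouse dermal-fibroblast design of
  ``n_lines`` wild-type and ``n_lines`` Tsc2-null (KO) cell lines, each with a
  vehicle and a sirolimus arm paired within line.  Differentially expressed
  genes are planted on the log2(x+1) scale, and a stated fraction of them is
  "reversed" by sirolimus (the mTORC1-dependent part of the KO effect).
* :func:`simulate_tumor_cohort` — a tumor cohort in which a small fraction of
  tumors carries a non-silent TSC1/TSC2 mutation and shows a shift along the
  signature directions.
* :func:`simulate_clinical_tables` — serum-marker/lung-function/BMI tables and
  a two-group survival table.

Noise is Gaussian on the log2(x+1) scale rather than negative-binomial on
counts: the analysis pipeline operates entirely on transformed abundance
values, so the generators target that scale directly.  Planted-set sizes use
round-half-up so expected counts are exact and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, Signature, RAW, ValidationError

NONSILENT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "In_Frame_Del",
    "In_Frame_Ins",
    "5'UTR",
)


def round_half_up(x: float) -> int:
    """Deterministic round-half-up used for all planted-set sizes."""
    return int(np.floor(x + 0.5))


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")


@dataclass
class FibroblastSimParams:
    """Parameters of the synthetic fibroblast experiment (log2 units throughout)."""

    n_genes: int = 2000
    n_lines: int = 3
    frac_up_in_ko: float = 0.10
    frac_down_in_ko: float = 0.05
    effect_size_logfc: float = 2.0
    frac_reversed_up: float = 0.92
    frac_reversed_down: float = 0.80
    frac_shared_sirolimus: float = 0.05
    shared_sirolimus_logfc: float = 1.5
    noise_sd: float = 0.5
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.n_lines < 2:
            raise ValidationError("n_lines must be >= 2 (the two-class statistic is undefined below)")
        for name in (
            "frac_up_in_ko",
            "frac_down_in_ko",
            "frac_reversed_up",
            "frac_reversed_down",
            "frac_shared_sirolimus",
        ):
            _check_proportion(name, getattr(self, name))
        if self.frac_up_in_ko + self.frac_down_in_ko > 1:
            raise ValidationError("frac_up_in_ko + frac_down_in_ko must be <= 1")
        if self.noise_sd <= 0 or self.effect_size_logfc < 0:
            raise ValidationError("noise_sd must be > 0 and effect_size_logfc >= 0")


@dataclass
class CohortSimParams:
    """Parameters of the synthetic tumor cohort."""

    n_tumors: int = 391
    frac_mutant: float = 43 / 391
    mutant_shift_logfc: float = 1.0
    noise_sd: float = 1.0
    n_background_genes: int = 200
    frac_silent_in_wt: float = 0.10
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 2:
            raise ValidationError("n_tumors must be >= 2")
        if not 0.0 < self.frac_mutant < 1.0:
            raise ValidationError("frac_mutant must be in (0, 1)")
        _check_proportion("frac_silent_in_wt", self.frac_silent_in_wt)
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset, echoed alongside the data."""

    up_in_ko: list[str] = field(default_factory=list)
    down_in_ko: list[str] = field(default_factory=list)
    reversed_up: list[str] = field(default_factory=list)
    reversed_down: list[str] = field(default_factory=list)
    shared_sirolimus: list[str] = field(default_factory=list)
    mutant_tumors: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up_in_ko) & set(self.down_in_ko):
            raise ValidationError("planted up and down gene sets must be disjoint")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.up_in_ko:
            rows.append((g, "up_in_ko", g in self.reversed_up))
        for g in self.down_in_ko:
            rows.append((g, "down_in_ko", g in self.reversed_down))
        for g in self.shared_sirolimus:
            rows.append((g, "shared_sirolimus", False))
        for t in self.mutant_tumors:
            rows.append((t, "mutant_tumor", False))
        return pd.DataFrame(rows, columns=["id", "role", "reversed"])


def _back_transform(log_values: np.ndarray) -> np.ndarray:
    # 2**y - 1, floored at 0 so the raw matrix satisfies the raw-scale invariant
    return np.maximum(np.power(2.0, log_values) - 1.0, 0.0)


def simulate_fibroblast_experiment(
    params: FibroblastSimParams,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate the paired WT/KO vehicle/sirolimus fibroblast design.

    Returns a raw-scale expression matrix (4 * n_lines samples), a sample
    table with line pairing, and the planted ground truth.  Reversed genes
    have the KO effect removed in KO + sirolimus samples; a small shared gene
    set responds to sirolimus in both genotypes, which makes the WT sirolimus
    response an approximate subset of the KO response.
    """
    rng = np.random.default_rng(params.seed)
    m = params.n_genes
    genes = [f"gene{i:05d}" for i in range(m)]

    n_up = round_half_up(params.frac_up_in_ko * m)
    n_down = round_half_up(params.frac_down_in_ko * m)
    perm = rng.permutation(m)
    up_idx = np.sort(perm[:n_up])
    down_idx = np.sort(perm[n_up : n_up + n_down])
    rest = perm[n_up + n_down :]
    n_shared = round_half_up(params.frac_shared_sirolimus * m)
    shared_idx = np.sort(rest[: min(n_shared, len(rest))])

    n_rev_up = round_half_up(params.frac_reversed_up * n_up)
    n_rev_down = round_half_up(params.frac_reversed_down * n_down)
    rev_up_idx = np.sort(rng.permutation(up_idx)[:n_rev_up])
    rev_down_idx = np.sort(rng.permutation(down_idx)[:n_rev_down])

    ko_effect = np.zeros(m)
    ko_effect[up_idx] = params.effect_size_logfc
    ko_effect[down_idx] = -params.effect_size_logfc
    reversed_mask = np.zeros(m, dtype=bool)
    reversed_mask[rev_up_idx] = True
    reversed_mask[rev_down_idx] = True
    shared_effect = np.zeros(m)
    shared_effect[shared_idx] = params.shared_sirolimus_logfc * rng.choice(
        [-1.0, 1.0], size=len(shared_idx)
    )

    baseline = rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=m)

    sample_rows = []
    columns = []
    for line in range(1, params.n_lines + 1):
        for genotype in ("WT", "KO"):
            for treatment in ("vehicle", "sirolimus"):
                sid = f"L{line}_{genotype}_{'veh' if treatment == 'vehicle' else 'sir'}"
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "genotype": genotype,
                        "treatment": treatment,
                        "pair_id": f"L{line}_{genotype}",
                    }
                )
                is_ko = genotype == "KO"
                is_sir = treatment == "sirolimus"
                mean = baseline.copy()
                if is_ko:
                    effect = ko_effect.copy()
                    if is_sir:
                        effect[reversed_mask] = 0.0  # sirolimus removes the KO effect
                    mean = mean + effect
                if is_sir:
                    mean = mean + shared_effect
                columns.append(mean + rng.normal(0.0, params.noise_sd, size=m))
    log_matrix = np.column_stack(columns)
    matrix = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=[r["sample_id"] for r in sample_rows],
        values=_back_transform(log_matrix),
        scale=RAW,
    )
    samples = pd.DataFrame(sample_rows)
    truth = GroundTruth(
        up_in_ko=[genes[i] for i in up_idx],
        down_in_ko=[genes[i] for i in down_idx],
        reversed_up=[genes[i] for i in rev_up_idx],
        reversed_down=[genes[i] for i in rev_down_idx],
        shared_sirolimus=[genes[i] for i in shared_idx],
        params=asdict(params),
    )
    return matrix, samples, truth


def simulate_tumor_cohort(
    params: CohortSimParams, signature: Signature
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a tumor cohort carrying the signature shift in mutant tumors.

    Mutant tumors receive one non-silent TSC1 or TSC2 mutation record and a
    shift of ``direction * mutant_shift_logfc`` on every signature gene in log
    space; a configurable fraction of wild-type tumors receives a silent
    TSC1/TSC2 record instead.
    """
    if len(signature) == 0:
        raise ValidationError("signature must be non-empty")
    rng = np.random.default_rng(params.seed)
    n = params.n_tumors
    n_mut = round_half_up(params.frac_mutant * n)
    if n_mut == 0:
        raise ValidationError(
            f"frac_mutant={params.frac_mutant} yields 0 mutant tumors at n={n}"
        )
    tumors = [f"TUMOR{i:04d}" for i in range(n)]
    mutant_idx = np.sort(rng.permutation(n)[:n_mut])
    is_mutant = np.zeros(n, dtype=bool)
    is_mutant[mutant_idx] = True

    sig_genes = list(signature.genes)
    directions = np.array([signature.genes[g] for g in sig_genes], dtype=float)
    bg_genes = [f"BG{i:04d}" for i in range(params.n_background_genes)]
    genes = sig_genes + bg_genes
    m = len(genes)

    baseline = rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=m)
    shift = np.zeros(m)
    shift[: len(sig_genes)] = directions * params.mutant_shift_logfc
    log_matrix = (
        baseline[:, None]
        + np.outer(shift, is_mutant.astype(float))
        + rng.normal(0.0, params.noise_sd, size=(m, n))
    )
    matrix = ExpressionMatrix(
        gene_ids=genes, sample_ids=tumors, values=_back_transform(log_matrix), scale=RAW
    )

    records = []
    for i in range(n):
        if is_mutant[i]:
            gene = rng.choice(["TSC1", "TSC2"])
            cls = rng.choice(NONSILENT_CLASSES)
            records.append((tumors[i], gene, cls))
        elif rng.random() < params.frac_silent_in_wt:
            records.append((tumors[i], rng.choice(["TSC1", "TSC2"]), "Silent"))
    mutations = pd.DataFrame(
        records, columns=["tumor_id", "gene_symbol", "variant_classification"]
    )
    truth = GroundTruth(
        mutant_tumors=[tumors[i] for i in mutant_idx], params=asdict(params)
    )
    return matrix, mutations, truth


def simulate_clinical_tables(
    n_patients: int = 64,
    corr_gal3_fev1: float = -0.32,
    aml_effect: float = 1500.0,
    bmi_confounding: float = 0.4,
    n_subjects_survival: int = 46,
    median_survival_weeks: tuple[float, float] = (24.0, 28.0),
    censor_rate: float = 0.35,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the clinical (serum marker / lung function) and survival tables.

    The serum marker (gal3, pg/mL) and %FEV1 are drawn from a bivariate
    Gaussian with the requested correlation; BMI is linearly confounded with
    gal3; AML status shifts gal3 by ``aml_effect`` within the mild (%FEV1 > 80)
    stratum.  Survival times are exponential per group (female/male medians
    set by ``median_survival_weeks``) with independent exponential censoring.
    """
    if not abs(corr_gal3_fev1) < 1:
        raise ValidationError("corr_gal3_fev1 must satisfy |r| < 1")
    rng = np.random.default_rng(seed)

    cov = np.array([[1.0, corr_gal3_fev1], [corr_gal3_fev1, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_patients)
    gal3 = 4650.0 + 1980.0 * z[:, 0]
    fev1 = 70.0 + 20.0 * z[:, 1]
    bmi = 26.0 + 4.0 * (bmi_confounding * z[:, 0] + np.sqrt(max(1 - bmi_confounding**2, 0.0)) * rng.standard_normal(n_patients))
    aml = rng.random(n_patients) < 0.5
    gal3 = gal3 + aml_effect * (aml & (fev1 > 80))
    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n_patients)],
            "gal3": gal3,
            "fev1": fev1,
            "aml_status": aml.astype(int),
            "bmi": bmi,
        }
    )

    rows = []
    for group, median in zip(("F", "M"), median_survival_weeks):
        lam = np.log(2.0) / median
        n_g = n_subjects_survival // 2
        t = rng.exponential(1.0 / lam, size=n_g)
        c = rng.exponential(1.0 / (lam * censor_rate), size=n_g)
        time = np.minimum(t, c)
        event = t <= c
        for j in range(n_g):
            rows.append(
                {
                    "subject_id": f"{group}{j:03d}",
                    "time_weeks": float(np.round(time[j], 3)),
                    "event_flag": int(event[j]),
                    "group": "Tsc2cKO",
                    "sex": group,
                }
            )
    survival = pd.DataFrame(rows)
    return clinical, survival
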