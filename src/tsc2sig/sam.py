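"""Significance Analysis of Microarrays (SAM) for two-class and paired designs.

SAM ranks genes by a moderated difference statistic

    d_g = (difference in means) / (s_g + s0)

where ``s_g`` is the gene-wise standard error and ``s0`` (the "fudge factor")
is a small constant that stabilises d for low-variance genes.  Significance is
assessed against a permutation null: class labels are permuted (unpaired
design) or pair-difference signs are flipped (paired design), the null d
values are sorted within each permutation, and observed order statistics are
compared with the mean null order statistics d̄(i).  A gene is called at
threshold Δ by SAM's asymmetric rule, and the false discovery rate at Δ is
estimated as π0 times the median over permutations of the number of null d
values beyond the data-derived cutoffs, divided by the number of calls.  The
null count carries an add-one guard (a finite permutation set should never
estimate an exactly-zero false-call count), which keeps the caller
calibrated at the 8-20 permutations these designs afford.

At the sample sizes this pipeline targets (3 vs 3 lines, 3 pairs), the
permutation set is enumerated exhaustively (C(6,3)=20 assignments, 2^3=8 sign
patterns), which makes every result deterministic; larger designs fall back
to seeded uniform sampling.  Note that with 20 permutations the attainable
FDR granularity is coarse; the estimate is reported exactly as computed, with
no interpolation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, ValidationError, RAW, LOG2P1

logger = logging.getLogger(__name__)

COMPARISONS = ("ko_vs_wt_vehicle", "sir_vs_veh_in_ko", "sir_vs_veh_in_wt")


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform of a raw-scale matrix; errors if already transformed."""
    if matrix.scale != RAW:
        raise ValidationError("matrix is already on the log2(x+1) scale")
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=np.log2(matrix.values + 1.0),
        scale=LOG2P1,
    )


@dataclass
class SamConfig:
    """Tuning knobs of the SAM procedure."""

    s0_mode: str = "auto"          # "auto", "percentile", or "fixed"
    s0_percentile: float = 5.0     # used when s0_mode == "percentile"
    s0_fixed: float = 0.0          # used when s0_mode == "fixed"
    max_exhaustive_perms: int = 5000
    n_sampled_perms: int = 1000
    fdr_target: float = 0.10
    fdr_percentile: float = 50.0   # percentile of null exceedance counts; 50 = median FDR
    fdr_add_one: bool = True       # never estimate a zero false-call count from finite permutations
    delta_grid: np.ndarray | None = None  # None -> derived from |d - d_expected|
    max_grid_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_target < 1.0:
            raise ValidationError("fdr_target must be in (0, 1)")
        if not 0.0 <= self.fdr_percentile <= 100.0:
            raise ValidationError("fdr_percentile must be in [0, 100]")
        if self.s0_mode not in ("auto", "percentile", "fixed"):
            raise ValidationError(f"unknown s0_mode {self.s0_mode!r}")
        if self.s0_mode == "fixed" and self.s0_fixed < 0:
            raise ValidationError("fixed s0 must be >= 0")


# ---------------------------------------------------------------------------
# Statistics

def sam_statistic_unpaired(
    values: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class SAM statistic per gene; class 2 is the test class (KO).

    Returns ``(d, s)`` where ``s`` is the pooled gene-wise standard error
    s_g = sqrt(a * (SS1 + SS2)), a = (1/n1 + 1/n2) / (n1 + n2 - 2).  With
    s0 = 0 this is exactly the pooled-variance two-sample t statistic.
    """
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"each class needs >= 2 samples (got {n1} and {n2})")
    x1, x2 = values[:, idx1], values[:, idx2]
    num = x2.mean(axis=1) - x1.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    s = np.sqrt(a * ss)
    return _safe_ratio(num, s, s0), s


def sam_statistic_paired(diffs: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Paired SAM statistic from a genes x pairs matrix of differences.

    d_g = mean(z) / (s_g + s0) with s_g = sqrt(sum (z - mean)^2 / (n (n-1))).
    """
    n = diffs.shape[1]
    if n < 2:
        raise ValidationError(f"need >= 2 complete pairs (got {n})")
    zbar = diffs.mean(axis=1)
    s = np.sqrt(((diffs - zbar[:, None]) ** 2).sum(axis=1) / (n * (n - 1)))
    return _safe_ratio(zbar, s, s0), s


def _safe_ratio(num: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    denom = s + s0
    d = np.zeros_like(num)
    ok = denom > 0
    d[ok] = num[ok] / denom[ok]
    degenerate = ~ok & (num != 0)
    if degenerate.any():
        logger.warning(
            "%d genes have zero standard error and nonzero difference with s0=0; "
            "their d is set to +/-inf",
            int(degenerate.sum()),
        )
        d[degenerate] = np.sign(num[degenerate]) * np.inf
    return d


# ---------------------------------------------------------------------------
# Fudge factor

def estimate_s0(num: np.ndarray, s: np.ndarray) -> float:
    """Automatic s0: the candidate minimising the CV of windowed MADs of d.

    Candidates are the percentiles {0, 5, ..., 100} of the s distribution.
    For each candidate the genes are partitioned into 100 s-quantile windows,
    the median absolute deviation of d is computed per window, and the s0
    minimising the coefficient of variation of these MADs is chosen.  Ties
    are broken toward the smallest candidate.  Inputs with fewer than 100
    genes fall back to the 5th percentile of s with a warning.
    """
    m = len(s)
    if m < 100:
        logger.warning("fewer than 100 genes; falling back to s0 = 5th percentile of s")
        return float(np.percentile(s, 5.0))
    candidates = np.percentile(s, np.arange(0, 101, 5))
    edges = np.quantile(s, np.linspace(0.0, 1.0, 101))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 99)
    best_cv, best_s0 = np.inf, float(candidates[0])
    for cand in candidates:
        d = _safe_ratio(num, s, float(cand))
        finite = np.isfinite(d)
        mads = []
        for w in range(100):
            mask = (window == w) & finite
            if mask.sum() >= 2:
                mads.append(sps.median_abs_deviation(d[mask], scale="normal"))
        mads = np.asarray(mads)
        if len(mads) == 0 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean() if len(mads) > 1 else 0.0
        if cv < best_cv - 1e-12:  # strict improvement; ties keep the smaller s0
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def resolve_s0(config: SamConfig, num: np.ndarray, s: np.ndarray) -> float:
    if config.s0_mode == "fixed":
        return float(config.s0_fixed)
    if config.s0_mode == "percentile":
        return float(np.percentile(s, config.s0_percentile))
    return estimate_s0(num, s)


# ---------------------------------------------------------------------------
# Permutation null

def unpaired_permutations(
    n1: int, n2: int, max_exhaustive: int, n_sampled: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Label assignments (index arrays for class 1) including the observed one."""
    total = math.comb(n1 + n2, n1)
    indices = np.arange(n1 + n2)
    if total <= max_exhaustive:
        return [np.array(c) for c in itertools.combinations(indices, n1)]
    perms = [indices[:n1]]
    for _ in range(n_sampled - 1):
        perms.append(np.sort(rng.permutation(indices)[:n1]))
    return perms


def paired_sign_patterns(
    n_pairs: int, max_exhaustive: int, n_sampled: int, rng: np.random.Generator
) -> np.ndarray:
    """Sign-flip patterns (rows of +/-1) including the identity pattern."""
    if 2**n_pairs <= max_exhaustive:
        return np.array(list(itertools.product((1.0, -1.0), repeat=n_pairs)))
    out = [np.ones(n_pairs)]
    for _ in range(n_sampled - 1):
        out.append(rng.choice([1.0, -1.0], size=n_pairs))
    return np.array(out)


def permutation_null_unpaired(
    values: np.ndarray, n1: int, n2: int, s0: float, config: SamConfig
) -> np.ndarray:
    """Sorted null d per permutation (permutations x genes) for an unpaired design.

    ``values`` must be ordered with the class-1 samples first.
    """
    rng = np.random.default_rng(config.seed)
    perms = unpaired_permutations(
        n1, n2, config.max_exhaustive_perms, config.n_sampled_perms, rng
    )
    all_idx = np.arange(n1 + n2)
    rows = []
    for idx1 in perms:
        idx2 = np.setdiff1d(all_idx, idx1)
        d, _ = sam_statistic_unpaired(values, idx1, idx2, s0)
        rows.append(np.sort(d))
    return np.array(rows)


def permutation_null_paired(diffs: np.ndarray, s0: float, config: SamConfig) -> np.ndarray:
    """Sorted null d per sign-flip pattern (permutations x genes)."""
    rng = np.random.default_rng(config.seed)
    patterns = paired_sign_patterns(
        diffs.shape[1], config.max_exhaustive_perms, config.n_sampled_perms, rng
    )
    rows = []
    for signs in patterns:
        d, _ = sam_statistic_paired(diffs * signs[None, :], s0)
        rows.append(np.sort(d))
    return np.array(rows)


# ---------------------------------------------------------------------------
# Calling and FDR

@dataclass
class SamDEResults:
    """Per-gene SAM output plus the global quantities behind the calls.

    Attributes
    ----------
    table : DataFrame with columns gene_id, d, d_expected, q, direction, called.
    s0_used, delta_used, pi0, n_permutations, fdr_target : global fields.
    """

    table: pd.DataFrame
    s0_used: float
    delta_used: float
    pi0: float
    n_permutations: int
    fdr_target: float
    comparison: str = ""
    fdr_curve: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def called_genes(self) -> list[str]:
        return self.table.loc[self.table["called"], "gene_id"].tolist()

    def called_by_direction(self, direction: int) -> list[str]:
        mask = self.table["called"] & (self.table["direction"] == direction)
        return self.table.loc[mask, "gene_id"].tolist()

    @property
    def n_called(self) -> int:
        return int(self.table["called"].sum())

    def summary(self) -> str:
        n_up = len(self.called_by_direction(1))
        n_down = len(self.called_by_direction(-1))
        lines = [
            "SAM differential expression results",
            "=" * 38,
            f"comparison:        {self.comparison or '(unspecified)'}",
            f"genes tested:      {len(self.table)}",
            f"permutations:      {self.n_permutations}",
            f"s0 (fudge factor): {self.s0_used:.6g}",
            f"pi0 estimate:      {self.pi0:.4f}",
            f"delta used:        {self.delta_used:.6g}",
            f"FDR target:        {self.fdr_target:.2%}",
            f"called genes:      {self.n_called} ({n_up} up, {n_down} down)",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def plot(self, ax=None):
        """Quantile-quantile plot of observed d against expected null order statistics."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table.sort_values("d")
        ax.scatter(t["d_expected"], t["d"], s=6, c=np.where(t["called"], "red", "grey"))
        lim = [t["d_expected"].min(), t["d_expected"].max()]
        ax.plot(lim, lim, "k--", lw=1)
        ax.plot(lim, [v + self.delta_used for v in lim], "b:", lw=1)
        ax.plot(lim, [v - self.delta_used for v in lim], "b:", lw=1)
        ax.set_xlabel("expected null order statistic")
        ax.set_ylabel("observed d")
        return ax


def _cutoffs(d_sorted: np.ndarray, dbar: np.ndarray, delta: float) -> tuple[float, float]:
    """SAM's asymmetric cutoffs for threshold delta.

    Moving up from the origin, the first positive order statistic whose
    excursion above d̄ exceeds delta sets the upper cutoff; symmetrically for
    negatives moving down.
    """
    diff = d_sorted - dbar
    cut_up = np.inf
    up = np.where((d_sorted > 0) & (diff > delta))[0]
    if len(up):
        cut_up = d_sorted[up[0]]
    cut_low = -np.inf
    down = np.where((d_sorted < 0) & (-diff > delta))[0]
    if len(down):
        cut_low = d_sorted[down[-1]]
    return cut_up, cut_low


def call_significant(
    d: np.ndarray,
    null_sorted: np.ndarray,
    gene_ids: list[str],
    config: SamConfig,
    s0_used: float,
    never_call: np.ndarray | None = None,
    comparison: str = "",
) -> SamDEResults:
    """Δ-threshold calling with SAM's permutation median FDR.

    ``null_sorted`` is the permutations x genes matrix of sorted null d.
    Genes flagged in ``never_call`` (zero variance in all groups) keep d = 0
    and are excluded from calling.
    """
    m = len(d)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    dbar = null_sorted.mean(axis=0)

    null_flat = null_sorted.ravel()
    q25, q75 = np.percentile(null_flat, [25, 75])
    pi0 = min(1.0, float(((d >= q25) & (d <= q75)).sum()) / (0.5 * m))

    diffs = np.abs(d_sorted - dbar)
    if config.delta_grid is not None:
        grid = np.sort(np.asarray(config.delta_grid, dtype=float))
    else:
        grid = np.unique(diffs[np.isfinite(diffs)])
        grid = grid[grid > 0]
        if len(grid) > config.max_grid_size:
            # deterministic thinning; keeps extremes
            pick = np.linspace(0, len(grid) - 1, config.max_grid_size).round().astype(int)
            grid = grid[np.unique(pick)]
    if len(grid) == 0:
        grid = np.array([0.0])

    never = np.zeros(m, dtype=bool) if never_call is None else never_call

    fdr_rows = []
    per_gene_q = np.ones(m)
    chosen = None
    for delta in grid:
        cut_up, cut_low = _cutoffs(d_sorted, dbar, float(delta))
        called = ((d >= cut_up) | (d <= cut_low)) & ~never
        n_called = int(called.sum())
        if n_called == 0:
            med_fdr = 0.0
        else:
            null_counts = (null_sorted >= cut_up).sum(axis=1) + (
                null_sorted <= cut_low
            ).sum(axis=1)
            # add-one guard: a finite permutation set can otherwise estimate
            # an exact zero false-call count for a lone extreme gene, which
            # makes the caller badly anti-conservative at 8-20 permutations
            count = float(np.percentile(null_counts, config.fdr_percentile))
            med_fdr = min(1.0, pi0 * (count + 1.0) / n_called) if config.fdr_add_one else min(
                1.0, pi0 * count / n_called
            )
        fdr_rows.append((float(delta), n_called, med_fdr))
        per_gene_q[called] = np.minimum(per_gene_q[called], med_fdr)
        if chosen is None and med_fdr <= config.fdr_target:
            chosen = (float(delta), cut_up, cut_low, called, med_fdr)

    if chosen is None:
        delta_used = float(grid[-1])
        logger.warning(
            "no delta on the grid achieves median FDR <= %.3f; using the largest "
            "delta with zero calls allowed",
            config.fdr_target,
        )
        cut_up, cut_low = _cutoffs(d_sorted, dbar, delta_used)
        called = ((d >= cut_up) | (d <= cut_low)) & ~never
        med_fdr_used = fdr_rows[-1][2] if fdr_rows else 1.0
    else:
        delta_used, cut_up, cut_low, called, med_fdr_used = chosen

    # monotonize q over the |d - d_expected| ranking: a gene with a larger
    # excursion never has a larger q than one with a smaller excursion; the
    # running minimum only ever lowers q, so calls keep q <= target
    rank_pos = np.empty(m, dtype=int)
    rank_pos[order] = np.arange(m)
    gene_absdiff = np.abs(d - dbar[rank_pos])
    asc = np.argsort(gene_absdiff, kind="stable")
    qa = np.minimum.accumulate(per_gene_q[asc])
    per_gene_q = np.empty(m)
    per_gene_q[asc] = qa
    per_gene_q[called] = np.minimum(per_gene_q[called], med_fdr_used)

    direction = np.sign(d).astype(int)
    d_expected = dbar[rank_pos]
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "d": d,
            "d_expected": d_expected,
            "q": per_gene_q,
            "direction": direction,
            "called": called,
        }
    )
    return SamDEResults(
        table=table,
        s0_used=s0_used,
        delta_used=float(delta_used),
        pi0=pi0,
        n_permutations=null_sorted.shape[0],
        fdr_target=config.fdr_target,
        comparison=comparison,
        fdr_curve=pd.DataFrame(fdr_rows, columns=["delta", "n_called", "median_fdr"]),
    )


# ---------------------------------------------------------------------------
# Model interface

class SamDE:
    """SAM differential-expression model for one of the pipeline's contrasts.

    Parameters
    ----------
    matrix : ExpressionMatrix (raw or log2p1 scale; raw is transformed on fit)
    samples : sample table with columns sample_id, genotype, treatment, pair_id
    comparison : "ko_vs_wt_vehicle" (two-class, vehicle samples only),
        "sir_vs_veh_in_ko" or "sir_vs_veh_in_wt" (paired within cell line).
    config : SamConfig

    ``fit()`` runs log transform -> s0 estimation -> statistic -> permutation
    null -> Δ/FDR calling and returns :class:`SamDEResults`.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        samples: pd.DataFrame,
        comparison: str,
        config: SamConfig | None = None,
    ):
        if comparison not in COMPARISONS:
            raise ValidationError(f"unknown comparison {comparison!r}; expected {COMPARISONS}")
        absent = set(samples["sample_id"]) - set(matrix.sample_ids)
        if absent:
            raise ValidationError(f"samples absent from matrix: {sorted(absent)}")
        self.matrix = matrix
        self.samples = samples.reset_index(drop=True)
        self.comparison = comparison
        self.config = config or SamConfig()

    def fit(self) -> SamDEResults:
        matrix = self.matrix if self.matrix.scale == LOG2P1 else log_transform(self.matrix)
        cfg = self.config
        if self.comparison == "ko_vs_wt_vehicle":
            veh = self.samples[self.samples["treatment"] == "vehicle"]
            wt = veh.loc[veh["genotype"] == "WT", "sample_id"].tolist()
            ko = veh.loc[veh["genotype"] == "KO", "sample_id"].tolist()
            if len(wt) < 2 or len(ko) < 2:
                raise ValidationError(
                    f"ko_vs_wt_vehicle needs >= 2 vehicle samples per genotype "
                    f"(got WT={len(wt)}, KO={len(ko)})"
                )
            sub = matrix.subset_samples(wt + ko)
            idx1 = np.arange(len(wt))
            idx2 = np.arange(len(wt), len(wt) + len(ko))
            num = sub.values[:, idx2].mean(axis=1) - sub.values[:, idx1].mean(axis=1)
            _, s = sam_statistic_unpaired(sub.values, idx1, idx2, 0.0)
            s0 = resolve_s0(cfg, num, s)
            d, s = sam_statistic_unpaired(sub.values, idx1, idx2, s0)
            null = permutation_null_unpaired(sub.values, len(wt), len(ko), s0, cfg)
            never = (s == 0) & (num == 0)
            d = np.where(never, 0.0, d)
        else:
            genotype = "KO" if self.comparison == "sir_vs_veh_in_ko" else "WT"
            diffs = self._pair_differences(matrix, genotype)
            num = diffs.mean(axis=1)
            _, s = sam_statistic_paired(diffs, 0.0)
            s0 = resolve_s0(cfg, num, s)
            d, s = sam_statistic_paired(diffs, s0)
            null = permutation_null_paired(diffs, s0, cfg)
            never = (s == 0) & (num == 0)
            d = np.where(never, 0.0, d)
        return call_significant(
            d, null, list(self.matrix.gene_ids), cfg, s0, never, self.comparison
        )

    def _pair_differences(self, matrix: ExpressionMatrix, genotype: str) -> np.ndarray:
        sub = self.samples[self.samples["genotype"] == genotype]
        diffs = []
        for pair_id, grp in sub.groupby("pair_id", dropna=False):
            trt = dict(zip(grp["treatment"], grp["sample_id"]))
            if set(trt) != {"vehicle", "sirolimus"}:
                raise ValidationError(
                    f"incomplete pair {pair_id!r}: has treatments {sorted(trt)}"
                )
            i_sir = matrix.sample_ids.index(trt["sirolimus"])
            i_veh = matrix.sample_ids.index(trt["vehicle"])
            diffs.append(matrix.values[:, i_sir] - matrix.values[:, i_veh])
        if len(diffs) < 2:
            raise ValidationError(f"need >= 2 complete pairs for genotype {genotype}")
        return np.column_stack(diffs)


def differential_expression(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    comparison: str,
    config: SamConfig | None = None,
) -> SamDEResults:
    """Functional wrapper: fit a :class:`SamDE` model and return its results."""
    return SamDE(matrix, samples, comparison, config).fit()
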