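"""Project a mouse signature onto a human tumor cohort and score each tumor.

The per-tumor score is the mean, over signature genes present in the cohort,
of the direction-aligned z-scored log2(x+1) expression:

    score_t = mean_g( direction_g * z_gt ),   z_gt = (y_gt - mean(y_g)) / sd(y_g)

with the sample (n-1) standard deviation taken across all tumors.  Genes
underexpressed in the knockout carry direction -1, so every gene contributes
in the same orientation and a high score means "looks like TSC2 loss".
Tumors are stratified by non-silent TSC1/TSC2 mutation status and the two
groups are compared with a two-sided Mann-Whitney U test by default (Welch's
t is available as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, Signature, ValidationError, RAW
from .sam import log_transform
from .simulate import NONSILENT_CLASSES

logger = logging.getLogger(__name__)

DEFAULT_TARGET_GENES = frozenset({"TSC1", "TSC2"})
# MAF-dialect rendering of the non-silent categories: missense, nonsense,
# frameshift, splice site, in-frame indel, 5'UTR (plus the remaining
# protein-altering MAF classes).
DEFAULT_NONSILENT = frozenset(
    set(NONSILENT_CLASSES) | {"Nonstop_Mutation", "Translation_Start_Site"}
)


def map_orthologs(signature: Signature, ortholog_map: pd.DataFrame) -> Signature:
    """Translate a mouse-symbol signature into human symbols.

    Unmapped mouse genes are dropped (count logged).  When two mouse genes map
    onto the same human gene with the same direction a single entry is kept;
    with conflicting directions the human gene is dropped with a warning.
    """
    lookup = dict(zip(ortholog_map["mouse_gene"], ortholog_map["human_gene"]))
    human: dict[str, int] = {}
    conflicts: set[str] = set()
    n_unmapped = 0
    for mouse_gene, direction in signature.genes.items():
        hg = lookup.get(mouse_gene)
        if hg is None:
            n_unmapped += 1
            continue
        if hg in human and human[hg] != direction:
            conflicts.add(hg)
        else:
            human[hg] = direction
    for hg in conflicts:
        logger.warning("human gene %s dropped: conflicting directions across mouse orthologs", hg)
        human.pop(hg, None)
    if n_unmapped:
        logger.info("%d signature genes had no human ortholog and were dropped", n_unmapped)
    meta = dict(signature.meta)
    meta["ortholog_mapped"] = "true"
    meta["n_unmapped"] = str(n_unmapped)
    return Signature(genes=human, meta=meta)


def classify_mutants(
    mutations: pd.DataFrame,
    cohort: list[str],
    target_genes: frozenset[str] = DEFAULT_TARGET_GENES,
    nonsilent_classes: frozenset[str] = DEFAULT_NONSILENT,
) -> pd.Series:
    """Per-tumor status: 'mutant' iff >= 1 non-silent record in a target gene.

    Every tumor in the cohort roster without such a record is 'wildtype'.
    Mutation records for tumors outside the roster are ignored with a warning.
    """
    if not nonsilent_classes:
        raise ValidationError("nonsilent_classes must be non-empty")
    roster = set(cohort)
    outside = set(mutations["tumor_id"]) - roster
    if outside:
        logger.warning(
            "%d tumors in the mutation table are absent from the cohort roster and ignored",
            len(outside),
        )
    hit = mutations[
        mutations["gene_symbol"].isin(target_genes)
        & mutations["variant_classification"].isin(nonsilent_classes)
        & mutations["tumor_id"].isin(roster)
    ]
    mutant = set(hit["tumor_id"])
    return pd.Series(
        ["mutant" if t in mutant else "wildtype" for t in cohort], index=cohort, name="mutation_status"
    )


def score_tumors(matrix: ExpressionMatrix, signature: Signature) -> pd.DataFrame:
    """Directional z-score signature score per tumor.

    Returns a DataFrame indexed by tumor with columns ``score`` and
    ``n_genes_used``.  Signature genes missing from the matrix or with zero
    standard deviation across tumors are dropped (logged), and the score is
    the mean over the genes actually used.
    """
    if len(matrix.sample_ids) < 2:
        raise ValidationError("need >= 2 tumors; z-scores are undefined for a single tumor")
    y = log_transform(matrix) if matrix.scale == RAW else matrix
    present = [g for g in signature.genes if g in y.gene_ids]
    if not present:
        raise ValidationError("no signature genes present in the cohort matrix")
    n_missing = len(signature) - len(present)
    if n_missing:
        logger.info("%d signature genes absent from the cohort matrix", n_missing)
    idx = [y.gene_ids.index(g) for g in present]
    sub = y.values[idx, :]
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    n_zero_sd = int((~keep).sum())
    if n_zero_sd:
        logger.info("%d signature genes dropped for zero variance across tumors", n_zero_sd)
    if not keep.any():
        raise ValidationError("all signature genes have zero variance across tumors")
    sub = sub[keep]
    sd = sd[keep]
    directions = np.array([signature.genes[g] for g, k in zip(present, keep) if k], dtype=float)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    scores = (directions[:, None] * z).mean(axis=0)
    return pd.DataFrame(
        {"score": scores, "n_genes_used": int(keep.sum())}, index=list(matrix.sample_ids)
    ).rename_axis("tumor_id")


@dataclass
class ComparisonResult:
    """Two-group comparison of per-tumor values."""

    statistic_name: str
    statistic: float
    p_value: float
    n_group1: int
    n_group2: int
    mean_group1: float
    mean_group2: float
    median_group1: float
    median_group2: float

    def summary(self) -> str:
        return (
            f"{self.statistic_name} = {self.statistic:.4g}, p = {self.p_value:.4g} "
            f"(group1 n={self.n_group1}, median={self.median_group1:.4g}; "
            f"group2 n={self.n_group2}, median={self.median_group2:.4g})"
        )


def compare_groups(
    values: np.ndarray | pd.Series,
    status: np.ndarray | pd.Series,
    test: str = "mann_whitney",
) -> ComparisonResult:
    """Two-sided comparison of values between two groups (mutant vs wildtype).

    ``mann_whitney`` uses the normal approximation with tie correction;
    ``welch_t`` is Welch's unequal-variance t test.
    """
    values = np.asarray(values, dtype=float)
    status = np.asarray(status)
    labels = pd.unique(status)
    if len(labels) != 2:
        raise ValidationError(f"expected exactly 2 group labels, got {list(labels)}")
    # mutant first when present, for stable reporting
    if "mutant" in labels:
        labels = np.array(["mutant", [l for l in labels if l != "mutant"][0]], dtype=object)
    g1 = values[status == labels[0]]
    g2 = values[status == labels[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValidationError("both groups must be non-empty")
    if test == "mann_whitney":
        res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
        name, stat = "Mann-Whitney U", float(res.statistic)
    elif test == "welch_t":
        res = sps.ttest_ind(g1, g2, equal_var=False)
        name, stat = "Welch t", float(res.statistic)
    else:
        raise ValidationError(f"unknown test {test!r}; expected mann_whitney or welch_t")
    return ComparisonResult(
        statistic_name=name,
        statistic=stat,
        p_value=float(res.pvalue),
        n_group1=len(g1),
        n_group2=len(g2),
        mean_group1=float(g1.mean()),
        mean_group2=float(g2.mean()),
        median_group1=float(np.median(g1)),
        median_group2=float(np.median(g2)),
    )


@dataclass
class TumorScoreResults:
    """Per-tumor scores, mutation stratification, and the group comparison."""

    score_table: pd.DataFrame
    comparison: ComparisonResult | None
    signature_size: int
    n_genes_used: int

    def summary(self) -> str:
        lines = [
            "Tumor signature-score results",
            "=" * 30,
            f"tumors scored:      {len(self.score_table)}",
            f"signature genes:    {self.signature_size} ({self.n_genes_used} used)",
        ]
        if "mutation_status" in self.score_table:
            counts = self.score_table["mutation_status"].value_counts()
            lines.append(f"mutant / wildtype:  {counts.get('mutant', 0)} / {counts.get('wildtype', 0)}")
        if self.comparison is not None:
            lines.append(f"group comparison:   {self.comparison.summary()}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.score_table.copy()

    def plot(self, ax=None):
        """Boxplot of the score by mutation status."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        groups = [
            self.score_table.loc[self.score_table["mutation_status"] == s, "score"]
            for s in ("mutant", "wildtype")
        ]
        ax.boxplot(groups, tick_labels=["mutant", "wildtype"])
        ax.set_ylabel("signature score")
        return ax


class TumorScoreModel:
    """Signature-projection model over a tumor cohort.

    Combines ortholog mapping (optional), per-tumor directional z-scoring and
    mutant/wild-type stratification; ``fit()`` returns
    :class:`TumorScoreResults`.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        signature: Signature,
        mutations: pd.DataFrame | None = None,
        ortholog_map: pd.DataFrame | None = None,
        target_genes: frozenset[str] = DEFAULT_TARGET_GENES,
        nonsilent_classes: frozenset[str] = DEFAULT_NONSILENT,
        test: str = "mann_whitney",
    ):
        self.matrix = matrix
        self.signature = (
            map_orthologs(signature, ortholog_map) if ortholog_map is not None else signature
        )
        self.mutations = mutations
        self.target_genes = target_genes
        self.nonsilent_classes = nonsilent_classes
        self.test = test

    def fit(self) -> TumorScoreResults:
        table = score_tumors(self.matrix, self.signature)
        comparison = None
        if self.mutations is not None:
            status = classify_mutants(
                self.mutations,
                list(self.matrix.sample_ids),
                self.target_genes,
                self.nonsilent_classes,
            )
            table = table.join(status)
            if status.nunique() == 2:
                comparison = compare_groups(table["score"], table["mutation_status"], self.test)
            else:
                logger.warning("only one mutation-status group present; comparison skipped")
        return TumorScoreResults(
            score_table=table,
            comparison=comparison,
            signature_size=len(self.signature),
            n_genes_used=int(table["n_genes_used"].iloc[0]) if len(table) else 0,
        )
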