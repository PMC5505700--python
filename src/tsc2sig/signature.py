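"""Build the Tsc2 loss-of-function signature and its sirolimus-reversal report.

The signature is simply the set of genes called differentially expressed
between KO and WT fibroblasts, each carrying the direction of its change
(+1 up in KO, -1 down in KO).  "Reversed by sirolimus" requires a significant
call in the opposite direction in the paired sirolimus-vs-vehicle contrast —
not merely an opposite-sign statistic — so the reversal report is an
intersection of two FDR-thresholded gene lists.  Percentages are rounded
half-up to integers, matching the conventional reporting style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import Signature, ValidationError
from .sam import SamDEResults
from .simulate import round_half_up

logger = logging.getLogger(__name__)


@dataclass
class CorrectionReport:
    """Counts and gene lists of the sirolimus-reversal overlap."""

    n_up_in_ko: int
    n_up_reversed: int
    n_down_in_ko: int
    n_down_reversed: int
    up_reversed_genes: list[str] = field(default_factory=list)
    down_reversed_genes: list[str] = field(default_factory=list)

    @property
    def pct_up_reversed(self) -> int:
        return round_half_up(100.0 * self.n_up_reversed / self.n_up_in_ko) if self.n_up_in_ko else 0

    @property
    def pct_down_reversed(self) -> int:
        return (
            round_half_up(100.0 * self.n_down_reversed / self.n_down_in_ko)
            if self.n_down_in_ko
            else 0
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("up_in_ko", self.n_up_in_ko, self.n_up_reversed, self.pct_up_reversed),
                ("down_in_ko", self.n_down_in_ko, self.n_down_reversed, self.pct_down_reversed),
            ],
            columns=["direction", "n_signature", "n_reversed", "pct_reversed"],
        )

    def summary(self) -> str:
        return (
            f"{self.pct_up_reversed}% ({self.n_up_reversed} of {self.n_up_in_ko}) of "
            f"KO-overexpressed genes reversed by sirolimus; "
            f"{self.pct_down_reversed}% ({self.n_down_reversed} of {self.n_down_in_ko}) of "
            f"KO-underexpressed genes reversed"
        )


def build_signature(de_ko_vs_wt: SamDEResults, fdr_target: float | None = None) -> Signature:
    """Signature = all called genes of the KO-vs-WT contrast with direction sign(d)."""
    t = de_ko_vs_wt.table
    called = t[t["called"]]
    if called.empty:
        logger.warning("no genes called; returning an empty signature")
    genes = {row.gene_id: int(row.direction) for row in called.itertuples()}
    meta = {
        "source_comparison": de_ko_vs_wt.comparison or "ko_vs_wt_vehicle",
        "fdr_target": str(fdr_target if fdr_target is not None else de_ko_vs_wt.fdr_target),
        "n_up": str(sum(1 for d in genes.values() if d == 1)),
        "n_down": str(sum(1 for d in genes.values() if d == -1)),
    }
    return Signature(genes=genes, meta=meta)


def sirolimus_correction(signature: Signature, de_sir_in_ko: SamDEResults) -> CorrectionReport:
    """Overlap of the signature with the opposite-direction sirolimus calls.

    Up-in-KO genes count as reversed when called *down* under sirolimus in KO;
    down-in-KO genes when called *up*.
    """
    universe = set(de_sir_in_ko.table["gene_id"])
    missing = [g for g in signature.genes if g not in universe]
    if missing:
        raise ValidationError(
            f"{len(missing)} signature genes absent from the sirolimus DE universe, "
            f"e.g. {missing[:5]}"
        )
    called_down = set(de_sir_in_ko.called_by_direction(-1))
    called_up = set(de_sir_in_ko.called_by_direction(1))
    up_rev = [g for g in signature.up_genes if g in called_down]
    down_rev = [g for g in signature.down_genes if g in called_up]
    return CorrectionReport(
        n_up_in_ko=len(signature.up_genes),
        n_up_reversed=len(up_rev),
        n_down_in_ko=len(signature.down_genes),
        n_down_reversed=len(down_rev),
        up_reversed_genes=up_rev,
        down_reversed_genes=down_rev,
    )


def common_gene_fraction(
    de_a: SamDEResults, de_b: SamDEResults, direction: int
) -> int | None:
    """Rounded percentage of de_a's called genes (given direction) also called
    with the same direction in de_b; de_a is the putative subset side.

    Returns None (flagged missing) when de_a calls no genes in that direction.
    """
    a = set(de_a.called_by_direction(direction))
    if not a:
        logger.warning("subset side calls no genes for direction %+d; fraction undefined", direction)
        return None
    b = set(de_b.called_by_direction(direction))
    return round_half_up(100.0 * len(a & b) / len(a))


def annotate_candidates(
    genes: list[str],
    annotations: dict[str, set[str]],
    required_categories: set[str],
) -> list[str]:
    """Genes whose annotation set contains every required category, in input order.

    Genes absent from the annotation table are treated as unannotated and
    dropped.  Used for the dual-category candidate screen (e.g. requiring
    both 'extracellular region' and 'signaling').
    """
    if not required_categories:
        raise ValidationError("required_categories must be non-empty")
    required = set(required_categories)
    return [g for g in genes if required <= annotations.get(g, set())]
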