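"""miRNA target nomination: k-of-5 prediction consensus intersected with pulldown hits.

Binding-site predictions from five algorithms (miRanda, PicTar, TargetScan,
RNA22, PITA) are combined by requiring a gene to be predicted by at least k
of the five (default all five, with a 4-of-5 relaxation), and the consensus
set is intersected with the experimentally pulled-down candidates to nominate
final targets.  Gene symbols are matched case-insensitively after whitespace
stripping; symbols that fail to match are reported, not silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["ALGORITHMS", "CandidateSet", "consensus_targets", "intersect_candidates",
           "TargetNominator"]

ALGORITHMS = frozenset({"miRanda", "PicTar", "TargetScan", "RNA22", "PITA"})


def _norm_symbol(g: str) -> str:
    return str(g).strip().upper()


@dataclass
class CandidateSet:
    """An ordered gene set attributed to one miRNA and one evidence source."""

    mirna_id: str
    source: str  # pulldown | consensus | intersection
    genes: tuple[str, ...]
    k_required: int | None = None
    support: dict[str, int] = field(default_factory=dict)

    def __contains__(self, gene: str) -> bool:
        return _norm_symbol(gene) in {_norm_symbol(g) for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)


def consensus_targets(predictions: pd.DataFrame, mirna_id: str, k: int = 5) -> CandidateSet:
    """Genes predicted as targets of ``mirna_id`` by at least ``k`` of the 5 algorithms.

    ``predictions`` needs columns ``gene_id``, ``mirna_id``, ``algorithm``.
    """
    if not 1 <= k <= 5:
        raise ValueError("k must be between 1 and 5")
    if missing := {"gene_id", "mirna_id", "algorithm"} - set(predictions.columns):
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    bad = set(predictions["algorithm"].unique()) - ALGORITHMS
    if bad:
        raise ValueError(f"unknown prediction algorithms: {sorted(bad)}")
    sub = predictions[predictions["mirna_id"] == mirna_id].copy()
    sub["gene_norm"] = sub["gene_id"].map(_norm_symbol)
    support = (
        sub.drop_duplicates(["gene_norm", "algorithm"]).groupby("gene_norm")["algorithm"].size()
    )
    genes = tuple(sorted(support.index[support >= k]))
    return CandidateSet(
        mirna_id=mirna_id,
        source="consensus",
        genes=genes,
        k_required=k,
        support={g: int(support[g]) for g in genes},
    )


def intersect_candidates(consensus: CandidateSet, pulldown: CandidateSet) -> CandidateSet:
    """Nominated targets: genes in both the consensus and the pulldown set."""
    if consensus.mirna_id != pulldown.mirna_id:
        raise ValueError(
            f"miRNA mismatch: {consensus.mirna_id!r} vs {pulldown.mirna_id!r}"
        )
    pd_norm = {_norm_symbol(g): g for g in pulldown.genes}
    genes = tuple(sorted(_norm_symbol(g) for g in consensus.genes if _norm_symbol(g) in pd_norm))
    return CandidateSet(
        mirna_id=consensus.mirna_id,
        source="intersection",
        genes=genes,
        k_required=consensus.k_required,
        support={g: consensus.support.get(g, 0) for g in genes},
    )


def candidate_set_from_genes(mirna_id: str, genes, source: str = "pulldown") -> CandidateSet:
    """Wrap a plain gene iterable (e.g. pulldown hits) as a CandidateSet."""
    return CandidateSet(mirna_id=mirna_id, source=source, genes=tuple(genes))


class TargetNominator(BaseEstimator):
    """Nominates miRNA targets by intersecting prediction consensus with pulldown hits.

    Parameters
    ----------
    k : int, default 5
        Minimum number of supporting prediction algorithms.

    Attributes
    ----------
    consensus_ : dict miRNA -> CandidateSet from the prediction table.
    pulldown_ : dict miRNA -> CandidateSet of pulldown candidates.
    nominated_ : dict miRNA -> intersection CandidateSet.
    unmatched_ : dict miRNA -> pulldown symbols not present in the prediction table.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X: pd.DataFrame, y=None, pulldown_candidates: dict[str, list[str]] | None = None):
        if pulldown_candidates is None:
            raise ValueError("pulldown_candidates mapping (miRNA -> genes) is required")
        self.consensus_ = {}
        self.pulldown_ = {}
        self.nominated_ = {}
        self.unmatched_ = {}
        known = {_norm_symbol(g) for g in X["gene_id"]}
        for mirna, genes in pulldown_candidates.items():
            cons = consensus_targets(X, mirna, self.k)
            pull = candidate_set_from_genes(mirna, genes)
            self.consensus_[mirna] = cons
            self.pulldown_[mirna] = pull
            self.nominated_[mirna] = intersect_candidates(cons, pull)
            self.unmatched_[mirna] = sorted(
                {_norm_symbol(g) for g in genes} - known
            )
        return self
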