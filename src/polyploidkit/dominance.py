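"""FPKM normalisation and subgenome expression dominance.

For each homoeologous chromosome quartet and each expression library, the
copy with the highest summed FPKM is called "highest". A quartet whose
highest calls concentrate on one copy across libraries shows expression
dominance; concentration is tested with a chi-square goodness-of-fit of the
four per-copy highest-call counts against the uniform 25% expectation
(df = 3, no continuity correction). Fruit-stage reversals ask whether the
copy that dominates vegetative (non-fruit) libraries drops to the lowest
(or bottom-two) position in fruit libraries, tested against null
proportions 1/4 and 1/2 respectively.

Ties in the per-library argmax (relative tolerance 1e-9) are flagged and
excluded from the counts. The procedure assumes a single biological
replicate per library; the summary carries that caveat as a warning field.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .model import ExpressionMatrix, GenomeLayout

__all__ = [
    "fpkm",
    "chromosome_expression",
    "call_dominance",
    "fruit_reversal",
    "DominanceCall",
    "DominanceSummary",
]

TIE_RTOL = 1e-9
SINGLE_REPLICATE_WARNING = (
    "per-library expression values are single biological replicates; "
    "dominance calls are descriptive, not inferential about the population"
)


def fpkm(matrix: ExpressionMatrix,
         mapped_totals: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM[g, l] = (count[g, l] / (total[l] / 1e6)) / (length_bp[g] / 1000),
    with total[l] the library column sum unless an explicit mapped-read
    total vector is supplied.
    """
    totals = matrix.counts.sum(axis=0) if mapped_totals is None \
        else mapped_totals.reindex(matrix.library_ids)
    if totals.isna().any() or (totals <= 0).any():
        bad = totals.index[(totals.isna()) | (totals <= 0)][0]
        raise ValidationError(f"library {bad!r}: zero or missing mapped-read total")
    per_million = totals / 1e6
    kb = matrix.gene_length_bp / 1000.0
    return matrix.counts.div(per_million, axis=1).div(kb, axis=0)


def chromosome_expression(fpkm_matrix: pd.DataFrame, layout: GenomeLayout,
                          quartets=None,
                          restrict_to_quartets: bool = True) -> pd.DataFrame:
    """Summed FPKM per (quartet, copy) and library.

    With ``restrict_to_quartets`` (default) only genes that occupy complete
    collinear quartets are summed, so gene-content differences between
    copies do not masquerade as expression differences. Returns a DataFrame
    indexed by (quartet_id, copy_index) with one column per library.
    """
    chrom_info = {c.chrom_id: c for c in layout.chromosomes}
    if restrict_to_quartets:
        if quartets is None:
            raise ValidationError("restrict_to_quartets=True requires quartets")
        allowed = {g for q in quartets if q.complete
                   for g in q.copies.values() if g is not None}
    else:
        allowed = None

    rows = {}
    for g in layout.genes:
        if allowed is not None and g.gene_id not in allowed:
            continue
        if g.gene_id not in fpkm_matrix.index:
            continue
        c = chrom_info[g.chrom_id]
        key = (c.quartet_id, c.copy_index)
        if key not in rows:
            rows[key] = np.zeros(fpkm_matrix.shape[1])
        rows[key] += fpkm_matrix.loc[g.gene_id].to_numpy()
    if not rows:
        raise ValidationError("no genes available for chromosome expression totals")
    idx = pd.MultiIndex.from_tuples(sorted(rows), names=["quartet_id", "copy_index"])
    data = np.vstack([rows[k] for k in sorted(rows)])
    return pd.DataFrame(data, index=idx, columns=fpkm_matrix.columns)


@dataclass(frozen=True)
class DominanceCall:
    quartet_id: int
    library_id: str
    highest_copy: int | None  # None when tied
    tie: bool


@dataclass
class DominanceSummary:
    per_set: pd.DataFrame  # quartet_id, modal_copy, agreement, counts, chi2, p
    total_agreement: int
    total_comparisons: int
    mean_agreement: float
    n_libraries: int
    warnings: list[str] = field(default_factory=list)


def _argmax_with_tie(values: np.ndarray) -> tuple[int | None, bool]:
    top = values.max()
    if top == 0:  # all-zero library for this set: no information
        return None, True
    winners = np.flatnonzero(values >= top * (1 - TIE_RTOL))
    if len(winners) > 1:
        return None, True
    return int(winners[0]) + 1, False


def call_dominance(totals: pd.DataFrame,
                   alpha: float = 0.001) -> tuple[list[DominanceCall], DominanceSummary]:
    """Per-set, per-library highest-copy calls and the dominance summary.

    ``totals`` is the output of :func:`chromosome_expression`. Per set the
    modal copy is the most frequent argmax (ties broken toward the smaller
    copy index); agreement a_s counts the libraries where the modal copy is
    highest; the chi-square statistic tests the four per-copy counts
    against uniform.
    """
    quartet_ids = sorted(totals.index.get_level_values("quartet_id").unique())
    libraries = list(totals.columns)
    if len(libraries) < 2:
        raise ValidationError("need at least two libraries")
    if not quartet_ids:
        raise ValidationError("need at least one quartet set")

    calls: list[DominanceCall] = []
    rows = []
    warnings = [SINGLE_REPLICATE_WARNING]
    for qid in quartet_ids:
        block = totals.loc[qid]  # copy_index x library
        copies = list(block.index)
        if len(copies) < 2:
            continue
        counts = {c: 0 for c in (1, 2, 3, 4)}
        n_ties = 0
        for lib in libraries:
            vals = np.zeros(4)
            for i, c in enumerate(copies):
                vals[c - 1] = block.loc[c, lib]
            winner, tie = _argmax_with_tie(vals)
            calls.append(DominanceCall(qid, lib, winner, tie))
            if tie:
                n_ties += 1
            else:
                counts[winner] += 1
        n_informative = len(libraries) - n_ties
        if n_informative == 0:
            warnings.append(f"quartet {qid}: all libraries tied; excluded")
            continue
        obs = np.array([counts[c] for c in (1, 2, 3, 4)], dtype=float)
        chi2, p = stats.chisquare(obs)  # uniform expectation, df=3
        modal = int(np.argmax(obs)) + 1  # ties -> smaller copy index
        agreement = counts[modal]
        rows.append({"quartet_id": qid, "modal_copy": modal,
                     "agreement": agreement, "n_informative": n_informative,
                     "n_ties": n_ties,
                     "count_copy1": counts[1], "count_copy2": counts[2],
                     "count_copy3": counts[3], "count_copy4": counts[4],
                     "chi2": float(chi2), "p_value": float(p),
                     "significant": bool(p < alpha)})
    per_set = pd.DataFrame(rows)
    total_agreement = int(per_set["agreement"].sum()) if len(per_set) else 0
    total_comparisons = len(per_set) * len(libraries)
    mean_agreement = float(per_set["agreement"].mean()) if len(per_set) else float("nan")
    summary = DominanceSummary(per_set=per_set,
                               total_agreement=total_agreement,
                               total_comparisons=total_comparisons,
                               mean_agreement=mean_agreement,
                               n_libraries=len(libraries),
                               warnings=warnings)
    return calls, summary


def fruit_reversal(totals: pd.DataFrame, fruit_libraries: list[str]) -> dict:
    """Fruit-stage dominance reversal counts.

    The modal (dominant) copy of each set is computed from non-fruit
    libraries only; then over set x fruit-library comparisons we count how
    often that copy ranks lowest of the four, and how often it falls in the
    bottom two. Chi-square tests compare the counts against the null
    proportions 1/4 (lowest) and 1/2 (bottom two).
    """
    fruit = [l for l in totals.columns if l in set(fruit_libraries)]
    if not fruit:
        raise ValidationError("no fruit libraries present")
    nonfruit = [l for l in totals.columns if l not in set(fruit_libraries)]
    if not nonfruit:
        raise ValidationError("no non-fruit libraries to define the dominant copy")

    _, summary = call_dominance(totals[nonfruit])
    modal = dict(zip(summary.per_set["quartet_id"], summary.per_set["modal_copy"]))

    n_comparisons = 0
    n_lowest = 0
    n_bottom_two = 0
    for qid, m in modal.items():
        block = totals.loc[qid]
        for lib in fruit:
            vals = block[lib]
            # rank of modal copy, 1 = highest FPKM, 4 = lowest
            order = vals.rank(ascending=False, method="min")
            r = float(order.loc[m])
            n_comparisons += 1
            if r >= 4:
                n_lowest += 1
            if r >= 3:
                n_bottom_two += 1

    def gof(k, n, p_null):
        obs = np.array([k, n - k], dtype=float)
        exp = np.array([n * p_null, n * (1 - p_null)])
        chi2, p = stats.chisquare(obs, exp)
        return float(chi2), float(p)

    chi2_low, p_low = gof(n_lowest, n_comparisons, 0.25)
    chi2_b2, p_b2 = gof(n_bottom_two, n_comparisons, 0.5)
    return {
        "n_comparisons": n_comparisons,
        "lowest": n_lowest,
        "bottom_two": n_bottom_two,
        "chi2_lowest": chi2_low, "p_lowest": p_low,
        "chi2_bottom_two": chi2_b2, "p_bottom_two": p_b2,
        "modal_copy": modal,
    }
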