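"""Sequence divergence and molecular dating.

The dating chain is: observed per-site difference *d* between an aligned
sequence pair (gap and N columns excluded pairwise), Jukes-Cantor corrected
substitutions per site ``K = -(3/4) ln(1 - 4d/3)``, and divergence time
``T = K / (2 mu)`` for a substitution rate *mu* in substitutions/site/year.
Applied to the two LTRs of a retrotransposon the time dates the insertion;
applied to LTR pairs sampled between haplotypes or subgenomes it dates the
polyploid event or the progenitor split.

Synonymous/nonsynonymous rates between codon-aligned coding sequences use
the Nei-Gojobori (1986) fractional site-counting method with the same
Jukes-Cantor correction applied to the proportions ps and pn.

The LTR Assembly Index (LAI), a repeat-space assembly quality metric, is
``100 * intact LTR-RT bp / total LTR-RT bp``, genome wide and in sliding
windows.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .errors import SaturationError, UndefinedDistanceError, ValidationError
from .model import AlignedPair

__all__ = [
    "DatingResult",
    "pairwise_difference",
    "jc_correct",
    "date_divergence",
    "date_pairs",
    "CodonAlignment",
    "ng86_ks",
    "summarize_homoeolog_ks",
    "LtrAnnotation",
    "lai",
]

JC_SATURATION = 0.75
DEFAULT_MU = 1.3e-8  # synonymous substitutions / site / year

_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_BASES = "ACGT"


@dataclass(frozen=True)
class DatingResult:
    """Per-pair molecular dating record: d, K, mu and T (years)."""

    label: str
    d: float
    K: float
    mu: float
    T: float  # years

    @property
    def T_myr(self) -> float:
        """T in million years, rounded to 2 decimals (display convention)."""
        return round(self.T / 1e6, 2)

    @property
    def T_kyr(self) -> int:
        """T in thousand years, rounded to the nearest integer."""
        return round(self.T / 1e3)


def pairwise_difference(pair: AlignedPair) -> float:
    """Observed per-site difference d = mismatches / comparable sites.

    A site is comparable when both sequences carry an unambiguous base
    (A, C, G or T); columns with a gap or N in either sequence contribute
    to neither numerator nor denominator.
    """
    a = pair.seq_a.upper()
    b = pair.seq_b.upper()
    comparable = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        raise UndefinedDistanceError(
            f"pair {pair.label!r}: no comparable sites (all gaps/ambiguous)"
        )
    return mismatches / comparable


def jc_correct(d: float) -> float:
    """Jukes-Cantor corrected distance K = -(3/4) ln(1 - 4d/3).

    Valid for 0 <= d < 0.75; beyond that the correction is saturated
    (undefined).
    """
    if d < 0:
        raise ValidationError(f"negative difference d={d}")
    if d >= JC_SATURATION:
        raise SaturationError(f"d={d} >= {JC_SATURATION}: Jukes-Cantor correction saturated")
    return -0.75 * math.log1p(-4.0 * d / 3.0)


def date_divergence(d: float, mu: float = DEFAULT_MU, label: str = "") -> DatingResult:
    """Date a divergence from observed difference d at substitution rate mu.

    T = K / (2 mu) years, with K the Jukes-Cantor corrected distance.
    """
    if mu <= 0:
        raise ValidationError(f"substitution rate mu must be positive, got {mu}")
    K = jc_correct(d)
    return DatingResult(label=label, d=d, K=K, mu=mu, T=K / (2.0 * mu))


def date_pairs(pairs, mu: float = DEFAULT_MU) -> pd.DataFrame:
    """Date a collection of :class:`AlignedPair`; one row per pair.

    Saturated pairs (d >= 0.75) get NaN K/T and are flagged rather than
    dropped.
    """
    rows = []
    for i, pair in enumerate(pairs):
        d = pairwise_difference(pair)
        label = pair.label or f"pair{i}"
        try:
            res = date_divergence(d, mu=mu, label=label)
            rows.append((label, d, res.K, res.T, False))
        except SaturationError:
            rows.append((label, d, np.nan, np.nan, True))
    return pd.DataFrame(rows, columns=["label", "d", "K", "T", "saturated"])


# ---------------------------------------------------------------------------
# NG86 synonymous / nonsynonymous rates


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Each position contributes s_i = (synonymous single changes)/3; a change
    producing a stop codon counts as nonsynonymous.
    """
    aa = _STANDARD_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if _STANDARD_CODE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _codon_path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Multi-difference codons are averaged over all orderings of single-step
    mutational paths; paths passing through a stop codon are excluded when
    any stop-free path exists.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if _STANDARD_CODE[current] == _STANDARD_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            if _STANDARD_CODE[nxt] == "*":
                through_stop = True
            current = nxt
        paths.append((sd, nd, through_stop))
    clean = [(s, n) for s, n, stop in paths if not stop]
    if not clean:  # both endpoints near stops: fall back to all paths
        clean = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in clean) / len(clean)
    nd = sum(n for _, n in clean) / len(clean)
    return sd, nd


@dataclass
class CodonAlignment:
    """A codon-aligned coding sequence pair with NG86-derived quantities."""

    seq_a: str
    seq_b: str
    label: str = ""

    def __post_init__(self):
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValidationError(f"{self.label!r}: unequal sequence lengths")
        if len(self.seq_a) % 3 != 0 or not self.seq_a:
            raise ValidationError(f"{self.label!r}: length not a positive multiple of 3")
        for seq, name in ((self.seq_a, "seq_a"), (self.seq_b, "seq_b")):
            for i in range(0, len(seq), 3):
                codon = seq[i:i + 3]
                if codon not in _STANDARD_CODE:
                    raise ValidationError(f"{self.label!r}: invalid codon {codon!r} in {name}")
                if _STANDARD_CODE[codon] == "*":
                    raise ValidationError(
                        f"{self.label!r}: internal stop codon {codon!r} at nt {i + 1} in {name}"
                    )

    def codons(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]


@dataclass(frozen=True)
class KsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float


def ng86_ks(aln: CodonAlignment) -> KsResult:
    """Nei-Gojobori synonymous (Ks) and nonsynonymous (Ka) distances.

    Site counts are fractional and averaged over the two sequences; observed
    differences average all single-step mutational orderings; the
    Jukes-Cantor correction converts ps = Sd/S and pn = Nd/N into rates.
    """
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    for ca, cb in aln.codons():
        sa, _ = _codon_site_counts(ca)
        sb, _ = _codon_site_counts(cb)
        S_a += sa
        S_b += sb
        sd, nd = _codon_path_differences(ca, cb)
        Sd += sd
        Nd += nd
    L = len(aln.seq_a)
    S = (S_a + S_b) / 2.0
    N = L - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    if ps >= JC_SATURATION or pn >= JC_SATURATION:
        raise SaturationError(
            f"{aln.label!r}: ps={ps:.4f}, pn={pn:.4f} beyond Jukes-Cantor domain"
        )
    return KsResult(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
                    Ks=jc_correct(ps), Ka=jc_correct(pn))


def summarize_homoeolog_ks(alignments) -> dict:
    """Ks summary over homoeologous gene pairs.

    Saturated pairs are counted and excluded from the mean/median.
    """
    ks_values = []
    n_saturated = 0
    for aln in alignments:
        try:
            ks_values.append(ng86_ks(aln).Ks)
        except SaturationError:
            n_saturated += 1
    if not ks_values and n_saturated == 0:
        raise ValidationError("no datable pairs supplied")
    arr = np.asarray(ks_values, dtype=float)
    return {
        "n_pairs": len(ks_values) + n_saturated,
        "n_saturated": n_saturated,
        "mean_ks": float(arr.mean()) if arr.size else np.nan,
        "median_ks": float(np.median(arr)) if arr.size else np.nan,
        "ks_values": ks_values,
    }


# ---------------------------------------------------------------------------
# LTR Assembly Index


@dataclass
class LtrAnnotation:
    """Per-chromosome LTR-RT intervals: (chrom, start, end, intact flag).

    Coordinates are 1-based inclusive; intact intervals must also be covered
    by the total LTR-RT space (each intact interval is counted in both
    tallies).
    """

    intervals: pd.DataFrame  # columns: chrom, start, end, intact(bool)
    chrom_lengths: dict[str, int]

    def __post_init__(self):
        required = {"chrom", "start", "end", "intact"}
        if not required.issubset(self.intervals.columns):
            raise ValidationError(f"LTR interval table needs columns {sorted(required)}")
        if (self.intervals["start"] > self.intervals["end"]).any():
            raise ValidationError("LTR interval with start > end")


def _overlap_bp(starts, ends, lo, hi):
    """Total bp of 1-based inclusive intervals clipped to window [lo, hi]."""
    s = np.maximum(starts, lo)
    e = np.minimum(ends, hi)
    return int(np.maximum(e - s + 1, 0).sum())


def lai(annotation: LtrAnnotation, window: int = 3_000_000,
        step: int = 300_000) -> tuple[float, pd.DataFrame]:
    """LTR Assembly Index, genome wide and per sliding window.

    LAI = 100 * intact LTR-RT bp / total LTR-RT bp. Windows with zero total
    LTR bp are reported with NaN (undefined). Returns (genome_lai, windows).
    """
    iv = annotation.intervals
    intact_bp = int((iv.loc[iv["intact"], "end"] - iv.loc[iv["intact"], "start"] + 1).sum())
    total_bp = int((iv["end"] - iv["start"] + 1).sum())
    if intact_bp > total_bp:
        raise ValidationError("intact LTR bp exceeds total LTR bp")
    genome_lai = 100.0 * intact_bp / total_bp if total_bp > 0 else float("nan")

    rows = []
    for chrom, length in annotation.chrom_lengths.items():
        sub = iv[iv["chrom"] == chrom]
        st = sub["start"].to_numpy()
        en = sub["end"].to_numpy()
        mask = sub["intact"].to_numpy(dtype=bool)
        pos = 1
        while pos <= length:
            hi = min(pos + window - 1, length)
            tot = _overlap_bp(st, en, pos, hi)
            ina = _overlap_bp(st[mask], en[mask], pos, hi)
            rows.append((chrom, pos, hi, ina, tot,
                         100.0 * ina / tot if tot > 0 else np.nan))
            if hi == length:
                break
            pos += step
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "intact_bp", "total_bp", "lai"]
    )
    return genome_lai, windows
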