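"""Per-gene codon-usage-bias indices: RSCU, Wright's ENC, PR2 bias.

RSCU
    Relative synonymous codon usage: the observed count of a codon divided
    by the count expected if its amino acid used all synonyms equally,
    ``rscu[c] = x_c * k / X_aa``. 1 means no bias; >1 a preferred codon.

ENC
    Wright's effective number of codons. For each synonymous family the
    small-sample codon homozygosity is estimated as
    ``F = (n * sum(p^2) - 1) / (n - 1)``, families are averaged within their
    degeneracy class, and

        ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

    (2 single-codon amino acids enter as the constant). A missing three-fold
    mean (Ile absent or unusable) is replaced by ``(F2 + F4)/2``; values
    above the theoretical maximum of 61 are capped; if a two-, four- or
    six-fold class mean cannot be computed the result is undefined, with the
    reason recorded. ENC ranges from 20 (one codon per amino acid) to 61
    (fully uniform usage).

PR2
    Parity-rule-2 coordinates over fourfold-degenerate codon boxes:
    AU bias = A3/(A3+U3) (y-axis) and GC bias = G3/(G3+C3) (x-axis).
    (0.5, 0.5) indicates no strand/selection asymmetry at silent sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .genetic_code import GeneticCode
from .ingest_qc import CodonCounts

#: ENC degeneracy-class structure: class size -> number of families (table 11
#: and the standard code alike); the 2 is Met + Trp.
_CLASS_FAMILY_COUNTS = {2: 9, 3: 1, 4: 5, 6: 3}

ENC_MIN = 20.0
ENC_MAX = 61.0


@dataclass(frozen=True)
class RSCUTable:
    """RSCU values over sense codons of degeneracy >= 2 amino acids.

    Codons of amino acids absent from the counts table are NaN (undefined),
    never silently zero.
    """

    values: dict
    labels: Union[tuple, str, None] = None

    def get(self, codon: str) -> float:
        return self.values[codon]


@dataclass(frozen=True)
class ENCResult:
    enc: Optional[float]
    f_class: dict
    n_families_used: dict
    capped: bool
    undefined_reason: Optional[str] = None
    labels: Union[tuple, str, None] = None


@dataclass(frozen=True)
class PR2Point:
    au_bias: float
    gc_bias: float
    n_fourfold_codons: int
    labels: Union[tuple, str, None] = None


def rscu(counts: CodonCounts, code: GeneticCode) -> RSCUTable:
    """RSCU for every sense codon of a degeneracy >= 2 amino acid."""
    if counts.n_codons == 0:
        raise ValueError("RSCU undefined for an empty counts table")
    values: dict = {}
    for aa, family in code.families.items():
        k = len(family)
        if k < 2:
            continue
        total = sum(counts.get(c) for c in family)
        for c in family:
            values[c] = counts.get(c) * k / total if total > 0 else math.nan
    return RSCUTable(values=values, labels=counts.labels)


def family_homozygosity(family_counts: Sequence[int]) -> Optional[float]:
    """Small-sample codon homozygosity of one synonymous family.

    ``F = (n * sum(p^2) - 1) / (n - 1)`` with p the within-family codon
    frequencies; undefined (None) when fewer than two codons were observed.
    """
    n = sum(family_counts)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in family_counts)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCounts, code: GeneticCode) -> ENCResult:
    """Wright's effective number of codons for one counts table."""
    if counts.n_codons == 0:
        raise ValueError("ENC undefined for an empty counts table")
    per_class: dict = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.families.items():
        k = len(family)
        if k < 2:
            continue
        f_hat = family_homozygosity([counts.get(c) for c in family])
        if f_hat is not None and f_hat > 0:
            per_class[k].append(f_hat)

    f_class = {k: (sum(v) / len(v) if v else None) for k, v in per_class.items()}
    n_used = {k: len(v) for k, v in per_class.items()}

    missing = [k for k in (2, 4, 6) if f_class[k] is None]
    if missing:
        reason = "no usable family in degeneracy class(es) " + \
            ", ".join(str(k) for k in missing)
        return ENCResult(enc=None, f_class=f_class, n_families_used=n_used,
                         capped=False, undefined_reason=reason,
                         labels=counts.labels)
    if f_class[3] is None:
        f_class = dict(f_class)
        f_class[3] = (f_class[2] + f_class[4]) / 2.0

    raw = 2.0
    for k, n_fam in _CLASS_FAMILY_COUNTS.items():
        raw += n_fam / f_class[k]
    capped = raw > ENC_MAX
    return ENCResult(enc=min(raw, ENC_MAX), f_class=f_class,
                     n_families_used=n_used, capped=capped,
                     labels=counts.labels)


def pr2_bias(counts: CodonCounts, code: GeneticCode,
             boxes: str = "eight") -> PR2Point:
    """PR2 coordinates from third bases of fourfold-degenerate boxes.

    ``boxes`` is ``"eight"`` (every fully third-position-degenerate box,
    the inclusive default) or ``"five"`` (strictly four-fold amino acids
    only). A coordinate whose denominator is zero is NaN.
    """
    prefixes = code.fourfold_boxes(boxes)
    third = {b: 0 for b in "ACGT"}
    for prefix in prefixes:
        for b in "ACGT":
            third[b] += counts.get(prefix + b)
    n_total = sum(third.values())
    if n_total == 0:
        raise ValueError("PR2 undefined: no codons in fourfold boxes")
    at = third["A"] + third["T"]
    gc = third["G"] + third["C"]
    au_bias = third["A"] / at if at > 0 else math.nan
    gc_bias = third["G"] / gc if gc > 0 else math.nan
    return PR2Point(au_bias=au_bias, gc_bias=gc_bias,
                    n_fourfold_codons=n_total, labels=counts.labels)
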