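"""Positional GC composition of codon-count tables.

GC1/GC2/GC3 are the G+C fractions at the three codon positions; GC12 is the
arithmetic mean of GC1 and GC2 (the quantity the neutrality plot regresses
on GC3) and total GC the mean over all three positions. GC3s restricts the
third position to codons of amino acids with at least two synonyms, i.e. the
positions where usage can vary without changing the protein; single-codon
amino acids (Met, Trp under table 11) and stop codons contribute nothing.

All fractions are kept in [0, 1]; rendering as percentages is left to the
report layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genetic_code import GeneticCode
from .ingest_qc import CodonCounts

_GC = frozenset("GC")


@dataclass(frozen=True)
class CompositionStats:
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc_total: float
    gc3s: Optional[float]
    n_codons: int
    n_syn_codons: int


def positional_gc(counts: CodonCounts) -> CompositionStats:
    """GC fraction per codon position (gc3s left unset)."""
    n = counts.n_codons
    if n == 0:
        raise ValueError("positional GC undefined for an empty counts table")
    gc_at = [0, 0, 0]
    for codon, x in counts.counts.items():
        for k in range(3):
            if codon[k] in _GC:
                gc_at[k] += x
    gc1, gc2, gc3 = (g / n for g in gc_at)
    return CompositionStats(gc1=gc1, gc2=gc2, gc3=gc3,
                            gc12=(gc1 + gc2) / 2,
                            gc_total=(gc1 + gc2 + gc3) / 3,
                            gc3s=None, n_codons=n, n_syn_codons=0)


def gc3s(counts: CodonCounts, code: GeneticCode) -> float:
    """G+C fraction at third positions of synonymous codons only."""
    n_syn = 0
    gc = 0
    for codon in code.synonymous_codons():
        x = counts.get(codon)
        n_syn += x
        if codon[2] in _GC:
            gc += x
    if n_syn == 0:
        raise ValueError("gc3s undefined: no synonymous codons in table")
    return gc / n_syn


def composition_stats(counts: CodonCounts, code: GeneticCode) -> CompositionStats:
    """Positional GC plus GC3s in one record."""
    base = positional_gc(counts)
    n_syn = sum(counts.get(c) for c in code.synonymous_codons())
    value = gc3s(counts, code) if n_syn > 0 else None
    return CompositionStats(gc1=base.gc1, gc2=base.gc2, gc3=base.gc3,
                            gc12=base.gc12, gc_total=base.gc_total,
                            gc3s=value, n_codons=base.n_codons,
                            n_syn_codons=n_syn)
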