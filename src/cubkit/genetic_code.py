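"""Genetic-code tables and synonymous-family structure.

Plastid protein-coding genes are translated with NCBI translation table 11
(bacterial/plastid), whose amino-acid assignments — and therefore whose
synonymous-family degeneracy structure — are identical to the standard code:
2 single-codon amino acids (Met, Trp), 9 two-fold families, 1 three-fold
family (Ile), 5 four-fold families and 3 six-fold families (Leu, Ser, Arg).
The codon-usage indices in :mod:`cubkit.indices` consume this structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping

from Bio.Data import CodonTable

#: Canonical base order used for codon enumeration (TCAG, the codon-table order).
BASES = "TCAG"

#: All 64 codons in TCAG-nested order.
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

STOP_SYMBOL = "*"


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI genetic code plus the derived synonymous-family structure.

    Parameters
    ----------
    table_id : int
        NCBI translation-table identifier.
    codon_to_aa : mapping
        All 64 codons mapped to one-letter amino acids; stops map to ``"*"``.
    stops : frozenset of str
        Stop codons.
    accepted_starts : frozenset of str
        Initiation codons the QC layer accepts. Defaults to a strict
        ``{"ATG"}``; table-11 alternates (GTG, TTG ...) can be admitted
        explicitly.
    degeneracy : mapping
        Amino acid -> number of sense codons (1, 2, 3, 4 or 6).
    families : mapping
        Amino acid -> tuple of its sense codons (sorted).
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    stops: frozenset
    accepted_starts: frozenset
    degeneracy: Mapping[str, int]
    families: Mapping[str, tuple]

    @classmethod
    def from_ncbi(cls, table_id: int = 11,
                  accepted_starts: Iterable[str] = ("ATG",)) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = {c: STOP_SYMBOL for c in table.stop_codons}
        codon_to_aa.update(table.forward_table)
        if len(codon_to_aa) != 64:  # pragma: no cover - guards exotic tables
            raise ValueError(f"table {table_id} does not map all 64 codons")
        fams: dict = {}
        for codon, aa in sorted(table.forward_table.items()):
            fams.setdefault(aa, []).append(codon)
        families = {aa: tuple(codons) for aa, codons in fams.items()}
        degeneracy = {aa: len(codons) for aa, codons in families.items()}
        return cls(
            table_id=table_id,
            codon_to_aa=MappingProxyType(dict(codon_to_aa)),
            stops=frozenset(table.stop_codons),
            accepted_starts=frozenset(s.upper().replace("U", "T")
                                      for s in accepted_starts),
            degeneracy=MappingProxyType(degeneracy),
            families=MappingProxyType(families),
        )

    # -- convenience views -------------------------------------------------

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def sense_codons(self) -> tuple:
        """All codons that encode an amino acid, in TCAG-nested order."""
        return tuple(c for c in ALL_CODONS if c not in self.stops)

    def synonymous_codons(self) -> tuple:
        """Sense codons of amino acids with >= 2 synonyms (Met/Trp excluded)."""
        return tuple(c for c in self.sense_codons()
                     if self.degeneracy[self.codon_to_aa[c]] >= 2)

    def fourfold_boxes(self, mode: str = "eight") -> tuple:
        """Codon-box prefixes whose third position is fully degenerate.

        ``mode="eight"`` returns every NN prefix for which all four NNx
        codons are sense codons of the same amino acid (for table 11: Ala,
        Gly, Pro, Thr, Val plus the CTN, TCN, CGN boxes of Leu, Ser, Arg).
        ``mode="five"`` keeps only the boxes of amino acids whose whole
        family has degeneracy exactly 4.
        """
        if mode not in ("eight", "five"):
            raise ValueError(f"unknown fourfold box mode: {mode!r}")
        boxes = []
        for p1 in BASES:
            for p2 in BASES:
                prefix = p1 + p2
                codons = [prefix + b for b in BASES]
                if any(c in self.stops for c in codons):
                    continue
                aas = {self.codon_to_aa[c] for c in codons}
                if len(aas) != 1:
                    continue
                aa = aas.pop()
                if mode == "five" and self.degeneracy[aa] != 4:
                    continue
                boxes.append(prefix)
        return tuple(boxes)
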