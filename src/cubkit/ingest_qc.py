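"""Reading, QC-filtering and codon-counting of protein-coding sequences.

The filtering principles are the usual ones for plastid CDS cohorts: a
sequence is retained iff it starts with an accepted initiation codon, ends
with a stop codon, contains no internal stop, has a length that is a
multiple of three and strictly greater than a minimum (default 300 nt), and
carries no excess of ambiguous (N) codons. Terminal stop codons are removed
before any index is computed, so downstream codon-count tables contain sense
codons only.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .genetic_code import ALL_CODONS, GeneticCode

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

# QC failure codes, in report order.
NO_START = "NO_START"
NO_TERMINAL_STOP = "NO_TERMINAL_STOP"
INTERNAL_STOP = "INTERNAL_STOP"
NOT_MULTIPLE_OF_3 = "NOT_MULTIPLE_OF_3"
TOO_SHORT = "TOO_SHORT"
AMBIGUOUS_EXCESS = "AMBIGUOUS_EXCESS"


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T. Raises on characters outside {A,C,G,T,N}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class CodingSequence:
    """One protein-coding nucleotide sequence with its labels."""

    id: str
    gene: str
    taxon: str
    family: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize_sequence(self.seq))

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    def codons(self) -> list:
        """Frame-0 triplets over the complete-codon prefix of the sequence."""
        n = len(self.seq) - len(self.seq) % 3
        return [self.seq[i:i + 3] for i in range(0, n, 3)]


@dataclass(frozen=True)
class QCReport:
    id: str
    passed: bool
    reasons: tuple

    def __post_init__(self):
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be true iff reasons is empty")


@dataclass
class CodonCounts:
    """A 64-entry codon occurrence table, the unit every index consumes.

    ``labels`` is either a ``(gene, taxon, family)`` tuple for a single
    record or a free-form group label for concatenations.
    """

    counts: dict
    labels: Union[tuple, str, None] = None

    def __post_init__(self):
        bad = set(self.counts) - set(ALL_CODONS)
        if bad:
            raise ValueError(f"non-canonical codons in counts: {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon counts")

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _load_metadata(metadata) -> pd.DataFrame:
    if isinstance(metadata, pd.DataFrame):
        meta = metadata
    else:
        meta = pd.read_csv(metadata, sep="\t", dtype=str)
    required = {"id", "gene", "taxon", "family"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns: {sorted(missing)}")
    return meta.set_index("id")


def read_cds_fasta(path, metadata=None) -> list:
    """Read one CodingSequence per FASTA record.

    Without a sidecar ``metadata`` table (TSV path or DataFrame with columns
    id/gene/taxon/family), headers must follow the ``gene|taxon|family``
    convention. With metadata, records are joined by their FASTA id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _load_metadata(metadata) if metadata is not None else None

    with _open_maybe_gzip(path) as handle:
        # cheap structural check so malformed input names a line
        first = None
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            logger.warning("empty FASTA file: %s", path)
            return []
        if not first[1].startswith(">"):
            raise ValueError(
                f"{path}: malformed FASTA, line {first[0]} does not start with '>'")

    seqs = []
    missing_meta = []
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            header = record.description.strip()
            if meta is not None:
                if record.id not in meta.index:
                    missing_meta.append(record.id)
                    continue
                row = meta.loc[record.id]
                seqs.append(CodingSequence(id=record.id, gene=row["gene"],
                                           taxon=row["taxon"],
                                           family=row["family"],
                                           seq=str(record.seq)))
            else:
                parts = header.split("|")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}: header {header!r} does not follow "
                        "'gene|taxon|family' and no metadata table was given")
                gene, taxon, family = (p.strip() for p in parts[:3])
                seqs.append(CodingSequence(id=header, gene=gene, taxon=taxon,
                                           family=family, seq=str(record.seq)))
    if missing_meta:
        raise KeyError(
            f"records missing from metadata table: {sorted(missing_meta)}")
    return seqs


def extract_cds_from_genbank(path, family_map: Optional[Mapping] = None) -> list:
    """Extract CDS features from a GenBank flat file.

    Compound (``join``) locations are spliced in order and minus-strand
    features reverse-complemented, both via Biopython's feature extraction.
    Features lacking a ``gene`` qualifier are skipped with a warning. The
    taxon comes from the record's ORGANISM; the family from ``family_map``
    (taxon -> family), defaulting to ``"NA"``.
    """
    family_map = dict(family_map or {})
    seqs = []
    for record in SeqIO.parse(str(path), "genbank"):
        taxon = record.annotations.get("organism", record.id)
        for feature in record.features:
            if feature.type != "CDS":
                continue
            gene = feature.qualifiers.get("gene", [None])[0]
            if gene is None:
                logger.warning("%s: CDS feature at %s lacks a gene qualifier; "
                               "skipped", record.id, feature.location)
                continue
            nt = str(feature.extract(record.seq))
            seqs.append(CodingSequence(
                id=f"{record.id}:{gene}", gene=gene, taxon=taxon,
                family=family_map.get(taxon, "NA"), seq=nt))
    return seqs


# ---------------------------------------------------------------------------
# QC and counting
# ---------------------------------------------------------------------------

def qc_check(seq: CodingSequence, code: GeneticCode,
             min_len_nt: int = 300, max_n_codon_frac: float = 0.05) -> QCReport:
    """Apply the CDS retention rules to a single sequence."""
    reasons = []
    codons = seq.codons()
    if not codons or codons[0] not in code.accepted_starts:
        reasons.append(NO_START)
    if not codons or codons[-1] not in code.stops:
        reasons.append(NO_TERMINAL_STOP)
    if any(c in code.stops for c in codons[:-1]):
        reasons.append(INTERNAL_STOP)
    if seq.length_nt % 3 != 0:
        reasons.append(NOT_MULTIPLE_OF_3)
    if seq.length_nt <= min_len_nt:
        reasons.append(TOO_SHORT)
    if codons:
        n_frac = sum("N" in c for c in codons) / len(codons)
        if n_frac > max_n_codon_frac:
            reasons.append(AMBIGUOUS_EXCESS)
    return QCReport(id=seq.id, passed=not reasons, reasons=tuple(reasons))


def qc_filter(seqs: Iterable[CodingSequence], code: GeneticCode,
              min_len_nt: int = 300,
              max_n_codon_frac: float = 0.05):
    """Split sequences into (passed, reports-for-all).

    Failures are reported, never raised.
    """
    passed, reports = [], []
    for seq in seqs:
        report = qc_check(seq, code, min_len_nt=min_len_nt,
                          max_n_codon_frac=max_n_codon_frac)
        reports.append(report)
        if report.passed:
            passed.append(seq)
    return passed, reports


def strip_terminal_stop(seq: CodingSequence, code: GeneticCode) -> CodingSequence:
    """Drop the final (stop) codon; errors if the last codon is not a stop."""
    if seq.length_nt % 3 != 0:
        raise ValueError(f"{seq.id}: length not a multiple of 3")
    last = seq.seq[-3:]
    if last not in code.stops:
        raise ValueError(f"{seq.id}: terminal codon {last} is not a stop "
                         f"codon of table {code.table_id}")
    return replace(seq, seq=seq.seq[:-3])


def count_codons(seq: CodingSequence) -> CodonCounts:
    """Tally frame-0 codons; codons containing N are excluded entirely."""
    if seq.length_nt % 3 != 0:
        raise ValueError(f"{seq.id}: length not a multiple of 3")
    counts: dict = {}
    for codon in seq.codons():
        if "N" in codon:
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts=counts, labels=(seq.gene, seq.taxon, seq.family))


def concatenate_counts(tables: Sequence[CodonCounts], label) -> CodonCounts:
    """Element-wise sum of codon-count tables under a new group label."""
    tables = list(tables)
    if not tables:
        raise ValueError("cannot concatenate an empty collection of counts")
    total: dict = {}
    for t in tables:
        for codon, x in t.counts.items():
            total[codon] = total.get(codon, 0) + x
    return CodonCounts(counts=total, labels=label)


# ---------------------------------------------------------------------------
# tabular views
# ---------------------------------------------------------------------------

def qc_report_frame(reports: Iterable[QCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": r.id, "passed": r.passed, "reasons": ";".join(r.reasons)}
         for r in reports])


def counts_frame(tables: Iterable[CodonCounts]) -> pd.DataFrame:
    """Codon-count matrix: one row per table, 64 codon columns."""
    rows = []
    for t in tables:
        if isinstance(t.labels, tuple):
            gene, taxon, family = t.labels
        else:
            gene, taxon, family = (t.labels, "", "")
        row = {"gene": gene, "taxon": taxon, "family": family}
        row.update({c: t.get(c) for c in ALL_CODONS})
        rows.append(row)
    return pd.DataFrame(rows)
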