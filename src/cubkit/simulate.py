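"""Synthetic plastid-like codon-sequence generator.

The generator emits family-structured sets of coding sequences whose codon
usage is driven by two knobs that mirror the forces the analysis is designed
to separate:

``theta_gc`` — mutational GC pressure. Each gene draws its own equilibrium
    GC value uniformly from ``theta_gc +- theta_gc_spread``; under the
    *mutation* regime every base of every codon is an independent draw with
    that G+C probability (stop codons excluded by renormalizing over sense
    codons, the exact equivalent of rejection sampling). Because all three
    positions track the same pressure, GC12 follows GC3 across genes and the
    neutrality slope is close to 1.

``s_sel`` — third-position selection. Under the *selection* regime the
    amino-acid content of each gene is fixed by a usage profile (uniform by
    default) with deterministic largest-remainder allocation — the strong
    protein-level-constraint limit — and only the codon chosen *within* each
    synonymous family is random: its odds are the codon's mutational weight
    times ``exp(s)`` for the family's preferred codon (AT-ending by
    default). First/second positions are then nearly invariant across genes
    while third positions still feel the gene's mutational pressure, damped
    by selection: the neutrality slope is close to 0 (slightly positive,
    because the six-fold families Leu/Ser/Arg leak a little first/second
    position variation). Stronger ``s_sel`` concentrates usage on preferred
    codons and drives ENC down toward 20.

The *mixed* regime splits each gene's codons evenly between the two
mechanisms, landing the slope strictly between the pure regimes.

Defaults (11 families x 50 genes x 400 codons, theta in [0.2, 0.5],
s_sel = 1) emulate an AT-rich plastid gene cohort: realized GC3 falls
roughly in the 0.14-0.35 window and selection-regime ENC in the low-40s.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .composition import positional_gc
from .genetic_code import GeneticCode
from .ingest_qc import CodingSequence, CodonCounts

_GC = frozenset("GC")


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for one synthetic dataset."""

    n_families: int = 11
    genes_per_family: int = 50
    codons_per_gene: int = 400
    regime: str = "selection"
    theta_gc: float = 0.35
    theta_gc_spread: float = 0.15
    s_sel: float = 1.0
    preferred_end: str = "AT"
    aa_profile: Optional[dict] = None
    code_table: int = 11
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("mutation", "selection", "mixed"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not (0.0 < self.theta_gc < 1.0):
            raise ValueError("theta_gc must lie in (0, 1)")
        if self.theta_gc_spread < 0 or self.s_sel < 0:
            raise ValueError("theta_gc_spread and s_sel must be >= 0")
        lo = self.theta_gc - self.theta_gc_spread
        hi = self.theta_gc + self.theta_gc_spread
        if lo <= 0.0 or hi >= 1.0:
            raise ValueError("theta_gc +- spread must stay inside (0, 1)")
        if self.preferred_end not in ("AT", "GC"):
            raise ValueError("preferred_end must be 'AT' or 'GC'")
        if self.n_families < 1 or self.genes_per_family < 1 \
                or self.codons_per_gene < 1:
            raise ValueError("counts must be positive")


@dataclass
class TruthRecord:
    """Regenerable record of what the generator actually drew."""

    params: dict
    regime: str
    genes: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"params": self.params, "regime": self.regime,
                           "genes": self.genes}, indent=1)


# ---------------------------------------------------------------------------
# codon distributions
# ---------------------------------------------------------------------------

def _codon_weight(codon: str, theta: float) -> float:
    w = 1.0
    for b in codon:
        w *= theta / 2.0 if b in _GC else (1.0 - theta) / 2.0
    return w


def preferred_codon(family, preferred_end: str = "AT") -> str:
    """The family's preferred codon: first (sorted) codon ending in A, else
    T, for ``"AT"``; G then C for ``"GC"``."""
    order = "AT" if preferred_end == "AT" else "GC"
    for end in order:
        ending = [c for c in sorted(family) if c[2] == end]
        if ending:
            return ending[0]
    return sorted(family)[0]


def _mutation_probs(code: GeneticCode, theta: float):
    codons = code.sense_codons()
    w = np.array([_codon_weight(c, theta) for c in codons])
    return codons, w / w.sum()


def _family_probs(family, theta: float, s: float, pref: str):
    w = np.array([_codon_weight(c, theta) * (math.exp(s) if c == pref else 1.0)
                  for c in family])
    return w / w.sum()


def _allocate(profile: dict, n: int) -> dict:
    """Largest-remainder allocation of n codons to amino acids."""
    aas = sorted(profile)
    total = sum(profile[a] for a in aas)
    quotas = {a: n * profile[a] / total for a in aas}
    counts = {a: int(math.floor(quotas[a])) for a in aas}
    remainder = n - sum(counts.values())
    by_frac = sorted(aas, key=lambda a: (-(quotas[a] - counts[a]), a))
    for a in by_frac[:remainder]:
        counts[a] += 1
    return counts


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_codon_counts(params: GeneratorParams, code: GeneticCode,
                       rng: np.random.Generator, theta: float, s: float,
                       n: int) -> dict:
    """One gene's body codon counts under the given regime."""
    regime = params.regime
    counts: dict = {}

    def add(codon, x):
        if x:
            counts[codon] = counts.get(codon, 0) + int(x)

    def mutation_part(m):
        codons, p = _mutation_probs(code, theta)
        for codon, x in zip(codons, rng.multinomial(m, p)):
            add(codon, x)

    def selection_part(m):
        profile = params.aa_profile or {aa: 1.0 for aa in code.families}
        for aa, x in _allocate(profile, m).items():
            family = code.families[aa]
            if len(family) == 1:
                add(family[0], x)
                continue
            pref = preferred_codon(family, params.preferred_end)
            p = _family_probs(family, theta, s, pref)
            for codon, xc in zip(family, rng.multinomial(x, p)):
                add(codon, xc)

    if regime == "mutation":
        mutation_part(n)
    elif regime == "selection":
        selection_part(n)
    else:  # mixed
        mutation_part(n // 2)
        selection_part(n - n // 2)
    return counts


def _draw_gene_conditions(params: GeneratorParams, rng: np.random.Generator):
    theta = params.theta_gc + params.theta_gc_spread * rng.uniform(-1.0, 1.0)
    if params.regime == "mutation":
        s = 0.0
    else:
        s = params.s_sel * rng.uniform(0.7, 1.3)
    return theta, s


def generate_gene(params: GeneratorParams, rng: np.random.Generator,
                  gene: str = "g001", taxon: str = "taxon_1",
                  family: str = "fam01",
                  theta: Optional[float] = None,
                  s: Optional[float] = None) -> CodingSequence:
    """Emit start codon + ``codons_per_gene`` sense codons + stop codon.

    Generated genes pass QC by construction for ``codons_per_gene >= 100``.
    """
    code = GeneticCode.from_ncbi(params.code_table)
    if theta is None or s is None:
        drawn_theta, drawn_s = _draw_gene_conditions(params, rng)
        theta = drawn_theta if theta is None else theta
        s = drawn_s if s is None else s
    counts = _draw_codon_counts(params, code, rng, theta, s,
                                params.codons_per_gene)
    body = np.repeat([c for c in sorted(counts)],
                     [counts[c] for c in sorted(counts)])
    rng.shuffle(body)
    stops = sorted(code.stops)
    stop_w = np.array([_codon_weight(c, theta) for c in stops])
    stop = stops[rng.choice(len(stops), p=stop_w / stop_w.sum())]
    seq = "ATG" + "".join(body) + stop
    return CodingSequence(id=f"{gene}|{taxon}|{family}", gene=gene,
                          taxon=taxon, family=family, seq=seq)


def generate_dataset(params: GeneratorParams):
    """All families x genes; deterministic under ``params.seed``.

    Returns ``(sequences, truth)`` where the truth record echoes the
    parameters and the per-gene realized GC12/GC3 (computed over the start
    codon plus body, i.e. the same codons the pipeline will count).
    """
    rng = np.random.default_rng(params.seed)
    truth = TruthRecord(params=asdict(params), regime=params.regime)
    seqs = []
    for i in range(1, params.n_families + 1):
        family = f"fam{i:02d}"
        taxon = f"taxon_{family}"
        for j in range(1, params.genes_per_family + 1):
            gene = f"g{j:03d}"
            theta, s = _draw_gene_conditions(params, rng)
            seq = generate_gene(params, rng, gene=gene, taxon=taxon,
                                family=family, theta=theta, s=s)
            body = seq.seq[:-3]  # drop the stop, keep the start
            tallied: dict = {}
            for k in range(0, len(body), 3):
                c = body[k:k + 3]
                tallied[c] = tallied.get(c, 0) + 1
            comp = positional_gc(CodonCounts(counts=tallied))
            truth.genes.append({"family": family, "gene": gene,
                                "taxon": taxon, "theta": theta, "s": s,
                                "gc12": comp.gc12, "gc3": comp.gc3})
            seqs.append(seq)
    return seqs, truth


def write_dataset(seqs, truth: TruthRecord, out_dir,
                  basename: str = "synthetic") -> dict:
    """Write FASTA + metadata TSV + truth JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{basename}.fasta"
    meta = out_dir / f"{basename}_meta.tsv"
    truth_path = out_dir / f"{basename}_truth.json"
    with open(fasta, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for k in range(0, len(seq.seq), 70):
                fh.write(seq.seq[k:k + 70] + "\n")
    with open(meta, "w") as fh:
        fh.write("id\tgene\ttaxon\tfamily\n")
        for seq in seqs:
            fh.write(f"{seq.id}\t{seq.gene}\t{seq.taxon}\t{seq.family}\n")
    truth_path.write_text(truth.to_json())
    return {"fasta": fasta, "metadata": meta, "truth": truth_path}
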