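"""Independent brute-force transcriptions of the index formulas.

These are deliberately written from the definitions, against Biopython's
codon table directly, sharing no code with cubkit. They exist only to
cross-check the package implementations.
"""

from Bio.Data import CodonTable

BASES = "ACGT"


def families_and_stops(table_id=11):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fams = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return fams, set(table.stop_codons)


def rscu_oracle(counts, table_id=11):
    fams, _ = families_and_stops(table_id)
    out = {}
    for aa, codons in fams.items():
        k = len(codons)
        if k < 2:
            continue
        total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = counts.get(c, 0) * k / total if total else None
    return out


def gc3s_oracle(counts, table_id=11):
    fams, _ = families_and_stops(table_id)
    num = den = 0
    for aa, codons in fams.items():
        if len(codons) < 2:
            continue
        for c in codons:
            x = counts.get(c, 0)
            den += x
            if c[2] in "GC":
                num += x
    return num / den if den else None


def enc_oracle(counts, table_id=11):
    fams, _ = families_and_stops(table_id)
    class_f = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in fams.items():
        k = len(codons)
        if k < 2:
            continue
        xs = [counts.get(c, 0) for c in codons]
        n = sum(xs)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in xs) - 1) / (n - 1)
        if f > 0:
            class_f[k].append(f)
    means = {k: sum(v) / len(v) if v else None for k, v in class_f.items()}
    if means[2] is None or means[4] is None or means[6] is None:
        return None
    if means[3] is None:
        means[3] = (means[2] + means[4]) / 2
    raw = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(raw, 61.0)


def pr2_oracle(counts, table_id=11, mode="eight"):
    """(au_bias, gc_bias) over fully third-position-degenerate boxes."""
    fams, stops = families_and_stops(table_id)
    aa_of = {}
    for aa, codons in fams.items():
        for c in codons:
            aa_of[c] = aa
    third = dict.fromkeys(BASES, 0)
    for p1 in BASES:
        for p2 in BASES:
            codons = [p1 + p2 + b for b in BASES]
            if any(c in stops for c in codons):
                continue
            aas = {aa_of[c] for c in codons}
            if len(aas) != 1:
                continue
            if mode == "five" and len(fams[aas.pop()]) != 4:
                continue
            for b in BASES:
                third[b] += counts.get(p1 + p2 + b, 0)
    at = third["A"] + third["T"]
    gc = third["G"] + third["C"]
    return (third["A"] / at if at else None,
            third["G"] / gc if gc else None)


def enc_expected_curve_oracle(s):
    return 2 + s + 29 / (s * s + (1 - s) * (1 - s))
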