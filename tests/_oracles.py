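"""Independent brute-force oracles for primer matching and coverage.

Deliberately written from the IUPAC definitions alone, with plain Python
loops and its own complement table, so results can be compared against the
vectorized engine without sharing any code path.
"""

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def bf_revcomp(seq):
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def bf_match(primer_base, template_base):
    return bool(IUPAC[primer_base] & IUPAC[template_base])


def bf_mismatches(primer_seq, window):
    return sum(0 if bf_match(p, t) else 1 for p, t in zip(primer_seq, window))


def bf_scan(primer_seq, orientation, template, max_mm):
    """All footprints with <= max_mm mismatches as (start, end, mm), 1-based."""
    L = len(primer_seq)
    hits = []
    for s in range(len(template) - L + 1):
        window = template[s : s + L]
        if orientation == "reverse":
            window = bf_revcomp(window)
        mm = bf_mismatches(primer_seq, window)
        if mm <= max_mm:
            hits.append((s + 1, s + L, mm))
    return hits


def bf_min_mismatches(primer_seq, orientation, template, cap):
    """Minimum mismatch count over all footprints, or None; early exit past cap."""
    L = len(primer_seq)
    if len(template) < L:
        return None
    best = None
    for s in range(len(template) - L + 1):
        window = template[s : s + L]
        if orientation == "reverse":
            window = bf_revcomp(window)
        mm = 0
        for p, t in zip(primer_seq, window):
            if not bf_match(p, t):
                mm += 1
                if best is not None and mm > best:
                    break
                if mm > cap:
                    break
        else:
            best = mm if best is None else min(best, mm)
            if best == 0:
                return 0
    return best if (best is not None and best <= cap) else None


def bf_coverage(primer_seq, orientation, records, groups, in_group, max_mm=3):
    """(intra_group_percent, out_group_hits) tuples for m = 0..max_mm."""
    in_minima, out_minima = [], []
    for rec in records:
        mm = bf_min_mismatches(primer_seq, orientation, rec.seq, max_mm)
        (in_minima if groups[rec.id] == in_group else out_minima).append(mm)
    intra = tuple(
        100.0 * sum(1 for v in in_minima if v is not None and v <= m) / len(in_minima)
        for m in range(max_mm + 1)
    )
    hits = tuple(
        sum(1 for v in out_minima if v is not None and v <= m)
        for m in range(max_mm + 1)
    )
    return intra, hits
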