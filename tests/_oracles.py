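"""Independent brute-force oracles used to cross-check the kmer engine."""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq))


def oracle_coverage(query: str, reference: str, k: int, masked=frozenset()) -> float:
    """Base coverage of the reference by shared k-mers, by direct window scan.

    Every reference window of clean A/C/G/T bases is substring-searched in
    the query and in the query's reverse complement; matched windows mark
    their k bases covered.  Independent of the canonical-kmer index path.
    """
    query = query.upper()
    reference = reference.upper()
    rc_query = oracle_revcomp(query)
    covered = [False] * len(reference)
    for p in range(len(reference) - k + 1):
        window = reference[p : p + k]
        if any(c not in "ACGT" for c in window):
            continue
        canon = min(window, oracle_revcomp(window))
        if canon in masked:
            continue
        if window in query or window in rc_query:
            for i in range(p, p + k):
                covered[i] = True
    return sum(covered) / len(reference) if reference else 0.0
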