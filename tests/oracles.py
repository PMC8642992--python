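"""Independent brute-force oracles used to check the implementation.

These deliberately avoid circorf's own code paths: the ORF oracle walks every
start position character by character with modular indexing and translates
codon by codon through Biopython, and the AUC oracle enumerates all
positive/negative pairs.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Seq import Seq

# standard-code lookup built directly from Biopython, independent of circorf
_CODON_AA = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
}


def oracle_orfs(seq: str, max_cycles: int = 3) -> list[tuple]:
    """Exhaustive modular-walk ORF enumeration on a circular sequence.

    Returns sorted tuples (start, nt_length, aa_length, spans_junction,
    rolling, protein, stop_pos), deduplicated to the longest ORF per stop
    position (rolling walks per frame class), matching the documented
    contract of the ORF finder.
    """
    L = len(seq)
    seq = seq.upper()
    out: dict[tuple, tuple] = {}
    for start in range(L):
        first = "".join(seq[(start + i) % L] for i in range(3))
        if first != "ATG":
            continue
        aas: list[str] = []
        pos = start
        stop = None
        rolling = False
        for _ in range(math.ceil(max_cycles * L / 3)):
            codon = "".join(seq[(pos + i) % L] for i in range(3))
            aa = _CODON_AA[codon]
            if aa == "*":
                stop = pos % L
                break
            aas.append(aa)
            pos += 3
        else:
            rolling = True
        nt = 3 * (len(aas) + 1) if stop is not None else 3 * len(aas)
        spans = nt > 0 and (start + nt - 1) // L >= 1
        key = ("stop", stop) if stop is not None else ("rolling", start)
        rec = (start, nt, len(aas), spans, rolling, "".join(aas), stop)
        prev = out.get(key)
        if prev is None or len(aas) > prev[2] or (len(aas) == prev[2] and start < prev[0]):
            out[key] = rec
    return sorted(out.values())


def orfs_as_tuples(orfs) -> list[tuple]:
    """Project circorf CircORF objects onto the oracle tuple shape."""
    return sorted(
        (o.start, o.nt_length, o.aa_length, o.spans_junction, o.rolling_circle,
         o.protein, o.stop_pos)
        for o in orfs
    )


def oracle_auc(values, labels) -> float:
    """AUC by exhaustive comparison over all positive/negative value pairs."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = v[y == 1]
    neg = v[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_circle(rng: np.random.Generator, min_len: int = 3, max_len: int = 30) -> str:
    L = int(rng.integers(min_len, max_len + 1))
    return "".join("ACGT"[i] for i in rng.integers(0, 4, L))
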