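"""Category-overlap enrichment and a simple degenerate-motif scanner.

The two-sided Fisher exact test is computed by direct enumeration of the
conditional hypergeometric distribution — exact rational arithmetic for
small tables, log-space floating point for large ones — summing the
probabilities of all tables (fixed margins) no more probable than the
observed one.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.special import gammaln

#: grand totals up to this size use exact rational arithmetic
_EXACT_LIMIT = 2000

#: relative tolerance when comparing table probabilities
_REL_TOL = 1e-12

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

#: canonical Pumilio response element consensus (configurable everywhere)
DEFAULT_PRE = "UGUANAUA"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (in-set & in-category, in-set only, category only, neither)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table entries must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        """ad/bc; inf when bc == 0 and ad > 0, nan when both products are 0."""
        ad, bc = self.a * self.d, self.b * self.c
        if bc == 0:
            return math.inf if ad > 0 else math.nan
        return ad / bc


def _fisher_exact_rational(t: ContingencyTable) -> float:
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = t.total
    denom = math.comb(n, c1)

    def weight(a: int) -> int:
        return math.comb(r1, a) * math.comb(r2, c1 - a)

    w_obs = weight(t.a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    cutoff = Fraction(w_obs) * (1 + Fraction(1, 10**12))
    num = sum(weight(a) for a in range(lo, hi + 1) if Fraction(weight(a)) <= cutoff)
    return float(Fraction(num, denom))


def _fisher_exact_float(t: ContingencyTable) -> float:
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = t.total
    lo, hi = max(0, c1 - r2), min(r1, c1)
    a_vals = np.arange(lo, hi + 1)

    def logcomb(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    logp = logcomb(r1, a_vals) + logcomb(r2, c1 - a_vals) - logcomb(n, c1)
    logp_obs = float(logp[a_vals == t.a][0])
    keep = logp <= logp_obs + math.log1p(1e-7)
    return float(min(1.0, np.exp(logp[keep]).sum()))


def fisher_exact_two_sided(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (odds ratio, p).

    p is the sum of hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's (within a relative tolerance). Exact rational arithmetic is
    used for grand totals <= 2000.
    """
    if table.total == 0:
        return math.nan, 1.0
    if table.total <= _EXACT_LIMIT:
        p = _fisher_exact_rational(table)
    else:
        p = _fisher_exact_float(table)
    return table.odds_ratio(), min(p, 1.0)


def overlap_enrichment(
    query: set, category: set, background: set
) -> tuple[float, ContingencyTable, float]:
    """Enrichment of ``query`` genes in ``category`` over ``background``.

    ratio = (|query & category| / |category|) / (|query| / |background|);
    the attached Fisher p is computed on the 2x2 table over the
    background. Both sets must be subsets of the background.
    """
    if not query <= background or not category <= background:
        raise ValueError("query and category must be subsets of the background")
    if not category:
        raise ValueError("empty category: enrichment ratio undefined")
    if not query:
        raise ValueError("empty query: enrichment ratio undefined")
    a = len(query & category)
    b = len(query - category)
    c = len(category - query)
    d = len(background) - a - b - c
    table = ContingencyTable(a, b, c, d)
    ratio = (a / len(category)) / (len(query) / len(background))
    _, p = fisher_exact_two_sided(table)
    return ratio, table, p


# ---------------------------------------------------------------------------
# motif scanning


def _compile_iupac(pattern: str) -> re.Pattern:
    if not pattern:
        raise ValueError("empty motif pattern")
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r} in motif {pattern!r}")
        parts.append(IUPAC[ch])
    return re.compile("".join(parts))


def scan_motif(sequence: str, pattern: str) -> list[int]:
    """0-based offsets of non-overlapping matches of an IUPAC pattern.

    U and T are equivalent; N matches any base. The sequence must be in
    transcript orientation.
    """
    rx = _compile_iupac(pattern)
    seq = sequence.upper().replace("U", "T")
    return [m.start() for m in rx.finditer(seq)]


def scan_motif_set(sequences: dict[str, str], pattern: str) -> dict[str, list[int]]:
    """Per-sequence hit offsets for a labeled sequence set."""
    return {name: scan_motif(seq, pattern) for name, seq in sequences.items()}


def motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pattern: str = DEFAULT_PRE,
) -> tuple[ContingencyTable, float]:
    """Fisher test of motif presence (>= 1 hit) in targets vs background."""
    if not target_seqs or not background_seqs:
        raise ValueError("both sequence sets must be non-empty")
    t_pos = sum(bool(scan_motif(s, pattern)) for s in target_seqs.values())
    b_pos = sum(bool(scan_motif(s, pattern)) for s in background_seqs.values())
    table = ContingencyTable(
        a=t_pos,
        b=len(target_seqs) - t_pos,
        c=b_pos,
        d=len(background_seqs) - b_pos,
    )
    _, p = fisher_exact_two_sided(table)
    return table, p
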