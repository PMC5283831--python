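"""Consensus-motif scanning of peak sequences and a binomial
over-representation test.

Motifs are IUPAC consensus strings (e.g. the SOX motif ``AACAAT``, or the
TPA-response element ``TGASTCA`` commonly used for AP-1/c-JUN).  Scanning is
exact consensus matching on both strands; ``N`` in a sequence never matches.
Enrichment of the fraction of peaks carrying at least one hit is tested
against a background rate estimated from dinucleotide-shuffled copies of the
same sequences with a one-sided binomial tail, reported in log10 to survive
extreme significance without underflow.

Position-weight-matrix scanning and de novo discovery are out of scope:
the claims covered here are consensus-level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Motif",
    "ScanSummary",
    "IUPAC",
    "reverse_complement",
    "scan_sequence",
    "peak_hit_fraction",
    "dinucleotide_shuffle",
    "estimate_background_rate",
    "binomial_enrichment",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide or IUPAC consensus string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """An IUPAC consensus motif."""

    consensus: str
    name: str = ""

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        if not cons:
            raise ValueError("empty consensus")
        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters in consensus: {sorted(bad)}")
        object.__setattr__(self, "consensus", cons)

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def match_table(self) -> np.ndarray:
        """(motif_len, 5) boolean table; column 4 is 'N' and never matches."""
        tab = np.zeros((len(self.consensus), 5), dtype=bool)
        for j, letter in enumerate(self.consensus):
            for b in IUPAC[letter]:
                tab[j, _BASE_CODE[b]] = True
        return tab

    def degeneracy(self) -> int:
        """Number of concrete sequences matching the consensus."""
        n = 1
        for letter in self.consensus:
            n *= len(IUPAC[letter])
        return n

    def match_probability(self, gc: float = 0.5) -> float:
        """Per-window single-strand match probability under an i.i.d.
        background with the given GC content."""
        p_base = {"A": (1 - gc) / 2, "T": (1 - gc) / 2,
                  "C": gc / 2, "G": gc / 2}
        p = 1.0
        for letter in self.consensus:
            p *= sum(p_base[b] for b in IUPAC[letter])
        return p


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_CODE.items():
        code[ord(b)] = i
    enc = code[arr]
    if np.any(enc < 0):
        bad = sorted({chr(c) for c in arr[enc < 0]})
        raise ValueError(f"invalid characters in sequence: {bad}")
    return enc


def _scan_encoded(enc: np.ndarray, tab: np.ndarray) -> np.ndarray:
    m = tab.shape[0]
    n_win = enc.size - m + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n_win, dtype=bool)
    for j in range(m):
        ok &= tab[j][enc[j:j + n_win]]
        if not ok.any():
            break
    return np.flatnonzero(ok)


def scan_sequence(seq: str, motif: Motif | str) -> list[tuple[int, str]]:
    """All consensus matches in `seq` on both strands.

    Returns ``(offset, strand)`` pairs, offsets 0-based on the forward
    sequence, overlapping hits allowed.  A reverse-strand hit at offset ``i``
    means the reverse complement of ``seq[i:i+len(motif)]`` matches the
    consensus.  When the motif is its own reverse complement (e.g.
    ``TGASTCA``), every site matches on both strands and is reported once,
    on the forward strand.
    """
    if isinstance(motif, str):
        motif = Motif(motif)
    enc = _encode(seq)
    fwd = _scan_encoded(enc, motif.match_table)
    hits = [(int(i), "+") for i in fwd]
    rc = Motif(reverse_complement(motif.consensus))
    if rc.consensus != motif.consensus:
        fwd_set = set(fwd.tolist())
        rev = _scan_encoded(enc, rc.match_table)
        hits += [(int(i), "-") for i in rev if int(i) not in fwd_set]
    return sorted(hits)


def peak_hit_fraction(sequences, motif: Motif | str) -> tuple[int, int, float]:
    """Fraction of sequences carrying at least one hit on either strand.

    Returns ``(n_with_hit, n_seqs, fraction)``; `fraction` is in [0, 1].
    """
    if isinstance(motif, str):
        motif = Motif(motif)
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    tab_f = motif.match_table
    tab_r = Motif(reverse_complement(motif.consensus)).match_table
    n_hit = 0
    for s in seqs:
        enc = _encode(s)
        if _scan_encoded(enc, tab_f).size or _scan_encoded(enc, tab_r).size:
            n_hit += 1
    return n_hit, len(seqs), n_hit / len(seqs)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts
    (Altschul-Erickson Eulerian-path shuffle).

    The shuffled sequence starts and ends with the same letters as the
    input, and every adjacent-pair count is conserved.
    """
    s = seq.upper()
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    nodes = list(edges)
    # draw random terminal edges forming in-tree to the final letter
    for _ in range(1000):
        last_edge = {v: edges[v][rng.integers(len(edges[v]))]
                     for v in nodes if v != last}
        if all(_reaches(v, last, last_edge) for v in last_edge):
            break
    else:  # pragma: no cover - probability ~0 for DNA alphabets
        raise RuntimeError("failed to sample an Eulerian ordering")
    order: dict[str, list[str]] = {}
    for v in nodes:
        lst = list(edges[v])
        if v != last:
            lst.remove(last_edge[v])
        perm = rng.permutation(len(lst))
        lst = [lst[i] for i in perm]
        if v != last:
            lst.append(last_edge[v])
        order[v] = lst
    out = [s[0]]
    ptr = {v: 0 for v in nodes}
    cur = s[0]
    while cur in order and ptr[cur] < len(order[cur]):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _reaches(v: str, last: str, last_edge: dict[str, str]) -> bool:
    seen = set()
    while v != last:
        if v in seen or v not in last_edge:
            return False
        seen.add(v)
        v = last_edge[v]
    return True


def estimate_background_rate(sequences, motif: Motif | str,
                             n_shuffles: int = 10,
                             seed: int | np.random.Generator = 0) -> float:
    """Background per-sequence hit rate from dinucleotide-shuffled copies.

    Each input sequence is shuffled `n_shuffles` times (dinucleotide counts
    preserved) and the fraction of shuffled copies with >= 1 hit is returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled = [dinucleotide_shuffle(s, rng)
                for s in sequences for _ in range(n_shuffles)]
    _, _, frac = peak_hit_fraction(shuffled, motif)
    return frac


@dataclass
class ScanSummary:
    """Per-peak-set motif scan summary with enrichment statistics."""

    motif: str
    n_peaks: int
    n_with_hit: int
    hit_fraction: float  # percent
    background_rate: float  # percent
    log10_p_binomial: float

    @property
    def p_binomial(self) -> float:
        return 10.0 ** self.log10_p_binomial

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "n_peaks": self.n_peaks,
            "n_with_hit": self.n_with_hit,
            "hit_fraction_pct": self.hit_fraction,
            "background_rate_pct": self.background_rate,
            "log10_p_binomial": self.log10_p_binomial,
        }


def binomial_enrichment(n_with_hit: int, n_peaks: int,
                        background_rate: float) -> float:
    """One-sided binomial tail ``log10 P[X >= n_with_hit]`` with
    ``X ~ Binomial(n_peaks, background_rate)``.

    `background_rate` is a fraction in [0, 1] (estimate it with
    :func:`estimate_background_rate`).  Returned in log10; ``-inf`` (with a
    warning) when the background rate is 0 but hits were observed.
    """
    if not 0 <= background_rate <= 1:
        raise ValueError("background_rate must be a fraction in [0, 1]")
    if n_with_hit > n_peaks:
        raise ValueError("n_with_hit cannot exceed n_peaks")
    if n_with_hit == 0:
        return 0.0  # p = 1
    if background_rate == 0:
        import warnings

        warnings.warn("background rate is 0 with observed hits; p underflows to 0",
                      RuntimeWarning, stacklevel=2)
        return float("-inf")
    logp = stats.binom.logsf(n_with_hit - 1, n_peaks, background_rate)
    return float(logp / np.log(10))


def scan_summary(sequences, motif: Motif | str, n_shuffles: int = 10,
                 seed: int = 0) -> ScanSummary:
    """Full scan of a peak-sequence set: hit fraction, shuffled background,
    binomial enrichment."""
    if isinstance(motif, str):
        motif = Motif(motif)
    n_hit, n, frac = peak_hit_fraction(sequences, motif)
    bg = estimate_background_rate(sequences, motif, n_shuffles=n_shuffles, seed=seed)
    log10p = binomial_enrichment(n_hit, n, bg)
    return ScanSummary(
        motif=motif.consensus,
        n_peaks=n,
        n_with_hit=n_hit,
        hit_fraction=100.0 * frac,
        background_rate=100.0 * bg,
        log10_p_binomial=log10p,
    )
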