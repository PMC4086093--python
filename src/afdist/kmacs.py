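"""k-mismatch average common substring (kmacs) distances.

For each position i of a query sequence x, the k-mismatch matching
statistic is the length of the longest substring of x starting at i that
matches some substring of a subject y with at most k Hamming mismatches.
The average L(x,y) of these lengths is a similarity measure; it is turned
into a distance by a log-length normalization,

    d(x,y) = ln|y| / L(x,y) − ln|x| / L(x,x),    L(x,x) = (|x|+1)/2,

symmetrized as (d(x,y) + d(y,x)) / 2. With k = 0 this is the classical
average common substring (ACS) approach.

Two computation modes are provided: ``exact`` evaluates the definition by
an exhaustive quadratic scan (vectorized over anti-diagonal offsets), and
``heuristic`` finds the longest exact match per position through a suffix
array of the subject and then greedily chains longest-common-extension
steps across up to k mismatches. The heuristic never exceeds the exact
statistic and coincides with it for k = 0.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass

import numpy as np

from ._types import Alphabet, DistanceMatrix, Sequence
from .errors import ContractError
from .seqio import detect_alphabet

logger = logging.getLogger(__name__)

K_MAX = 100
DEFAULT_K = 5

#: Above this total input size the automatic mode switches from the exact
#: quadratic scan to the suffix-array heuristic.
AUTO_EXACT_LIMIT = 1_000_000

#: How many subject positions attaining the maximal exact match length the
#: heuristic extends from (a cap keeps the worst case near-linearithmic).
MAX_CANDIDATES = 50


@dataclass
class MatchingStatistics:
    """Per-position k-mismatch longest-match lengths of a query vs a subject."""

    query: str
    subject: str
    k: int
    lengths: np.ndarray

    def mean(self) -> float:
        return float(self.lengths.mean())


def _check_args(x: Sequence, y: Sequence, k: int) -> None:
    if len(x) < 1 or len(y) < 1:
        raise ContractError("sequences must be non-empty")
    if not (0 <= k <= K_MAX):
        raise ContractError(f"k must be in [0, {K_MAX}], got {k}")


def _encode_pair(x: Sequence, y: Sequence, alphabet: Alphabet):
    """Encode both sequences as integer arrays.

    Characters outside the alphabet (ambiguity codes such as N or X) get a
    different sentinel in each sequence so that they never compare equal —
    an ambiguous residue always counts as a mismatch.
    """
    symbols = sorted(alphabet.symbols)
    code = {c: i for i, c in enumerate(symbols)}
    nx = len(symbols)
    xa = np.array([code.get(c, nx) for c in x.residues], dtype=np.int64)
    ya = np.array([code.get(c, nx + 1) for c in y.residues], dtype=np.int64)
    return xa, ya


def _exact_pair_lengths(xa: np.ndarray, ya: np.ndarray, k: int):
    """Exhaustive k-mismatch matching statistics in both directions.

    Scans every anti-diagonal of the |x| x |y| comparison grid once: along a
    diagonal the window x[i..i+L) vs y[j..j+L) accumulates mismatches, and
    the statistic at a start offset is the distance to the (k+1)-th mismatch
    at or after it. The per-diagonal run lengths serve both directions,
    since Hamming distance is symmetric in the two windows.
    """
    n, m = len(xa), len(ya)
    best_x = np.zeros(n, dtype=np.int64)
    best_y = np.zeros(m, dtype=np.int64)
    for d in range(-(n - 1), m):
        i0 = max(0, -d)
        ln = min(n, m - d) - i0
        if ln <= 0:
            continue
        mm = xa[i0 : i0 + ln] != ya[i0 + d : i0 + d + ln]
        mpos = np.flatnonzero(mm)
        t = np.arange(ln)
        if len(mpos) == 0:
            runs = ln - t
        else:
            idx = np.searchsorted(mpos, t) + k
            stop = np.where(
                idx < len(mpos), mpos[np.minimum(idx, len(mpos) - 1)], ln
            )
            runs = stop - t
        np.maximum(best_x[i0 : i0 + ln], runs, out=best_x[i0 : i0 + ln])
        np.maximum(best_y[i0 + d : i0 + d + ln], runs, out=best_y[i0 + d : i0 + d + ln])
    return best_x, best_y


def exact_kmismatch_lengths(
    x: Sequence, y: Sequence, k: int, alphabet: Alphabet = None
) -> MatchingStatistics:
    """Exact k-mismatch matching statistics of ``x`` against ``y``."""
    _check_args(x, y, k)
    if alphabet is None:
        alphabet = detect_alphabet([x, y])
    xa, ya = _encode_pair(x, y, alphabet)
    best_x, _ = _exact_pair_lengths(xa, ya, k)
    return MatchingStatistics(x.name, y.name, k, best_x)


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy lexsort)."""
    n = len(codes)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    step = 1
    idx = np.arange(n)
    while True:
        second = np.where(idx + step < n, rank[np.minimum(idx + step, n - 1)] + 1, 0)
        order = np.lexsort((second, rank))
        r1, r2 = rank[order], second[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        if n > 1:
            changed[1:] = np.cumsum((r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1]))
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = changed
        rank = new_rank
        if changed[-1] == n - 1 or step >= n:
            return order
        step *= 2


_SENT_X = "\x01"  # out-of-alphabet character in the query
_SENT_Y = "\x02"  # out-of-alphabet character in the subject


def _sentinelize(residues: str, alphabet: Alphabet, sentinel: str) -> str:
    if all(c in alphabet.symbols for c in residues):
        return residues
    return "".join(c if c in alphabet.symbols else sentinel for c in residues)


def _chain_extend(xs: str, i: int, ys: str, j: int, k: int) -> int:
    """Greedy match length from (i, j), consuming at most k mismatches."""
    n, m = len(xs), len(ys)
    ln = 0
    mism = 0
    while i + ln < n and j + ln < m:
        if xs[i + ln] == ys[j + ln]:
            ln += 1
        else:
            mism += 1
            if mism > k:
                break
            ln += 1
    return ln


def heuristic_kmismatch_lengths(
    x: Sequence,
    y: Sequence,
    k: int,
    alphabet: Alphabet = None,
    max_candidates: int = MAX_CANDIDATES,
) -> MatchingStatistics:
    """Suffix-array heuristic for the k-mismatch matching statistics.

    For each query position the longest *exact* match in the subject is
    located by binary search in the subject's suffix array; the match is
    then extended past mismatches by chaining up to k greedy
    longest-common-extension steps, trying every subject position that
    attains the maximal exact match length (capped at ``max_candidates``)
    and keeping the best extension. Lower-bounds the exact statistic;
    equals it when k = 0.
    """
    _check_args(x, y, k)
    if alphabet is None:
        alphabet = detect_alphabet([x, y])
    xs = _sentinelize(x.residues, alphabet, _SENT_X)
    ys = _sentinelize(y.residues, alphabet, _SENT_Y)
    n, m = len(xs), len(ys)
    ycodes = np.frombuffer(ys.encode("latin-1"), dtype=np.uint8)
    sa = _suffix_array(ycodes)
    sa_list = [int(j) for j in sa]
    suffix_of = lambda j: ys[j:]

    def lcp(j: int, i: int) -> int:
        ln = 0
        while i + ln < n and j + ln < m and xs[i + ln] == ys[j + ln]:
            ln += 1
        return ln

    out = np.zeros(n, dtype=np.int64)
    for i in range(n):
        xsuf = xs[i:]
        pos = bisect.bisect_left(sa_list, xsuf, key=suffix_of)
        # Longest exact match length = max LCP with the two SA neighbours.
        maxlen = 0
        for t in (pos - 1, pos):
            if 0 <= t < m:
                l = lcp(sa_list[t], i)
                if l > maxlen:
                    maxlen = l
        # All suffixes sharing that prefix are contiguous around pos.
        candidates = []
        t = pos
        while t < m and len(candidates) < max_candidates:
            j = sa_list[t]
            if ys[j : j + maxlen] != xsuf[:maxlen]:
                break
            candidates.append(j)
            t += 1
        t = pos - 1
        while t >= 0 and len(candidates) < max_candidates:
            j = sa_list[t]
            if ys[j : j + maxlen] != xsuf[:maxlen]:
                break
            candidates.append(j)
            t -= 1
        if k == 0 or maxlen >= len(xsuf):
            out[i] = maxlen
            continue
        best = maxlen
        for j in candidates:
            best = max(best, _chain_extend(xs, i, ys, j, k))
        out[i] = best
    return MatchingStatistics(x.name, y.name, k, out)


_MODES = ("exact", "heuristic", "auto")


def _resolve_mode(mode: str, total_len: int) -> str:
    if mode not in _MODES:
        raise ContractError(f"unknown mode {mode!r}; choose from {_MODES}")
    if mode == "auto":
        return "exact" if total_len <= AUTO_EXACT_LIMIT else "heuristic"
    return mode


def _matching_fn(mode: str):
    return exact_kmismatch_lengths if mode == "exact" else heuristic_kmismatch_lengths


def kmacs_distance(
    x: Sequence,
    y: Sequence,
    k: int = DEFAULT_K,
    mode: str = "auto",
    alphabet: Alphabet = None,
) -> float:
    """Symmetrized kmacs distance between two sequences."""
    _check_args(x, y, k)
    if len(x) < 2 or len(y) < 2:
        raise ContractError("kmacs distance needs sequences of length >= 2")
    if alphabet is None:
        alphabet = detect_alphabet([x, y])
    resolved = _resolve_mode(mode, len(x) + len(y))
    if resolved == "exact":
        xa, ya = _encode_pair(x, y, alphabet)
        lx, ly = _exact_pair_lengths(xa, ya, k)
    else:
        lx = heuristic_kmismatch_lengths(x, y, k, alphabet).lengths
        ly = heuristic_kmismatch_lengths(y, x, k, alphabet).lengths
    return _distance_from_lengths(x, y, lx, ly)


def _distance_from_lengths(x, y, lx, ly) -> float:
    n, m = len(x), len(y)
    l_xy = float(lx.sum() / n)
    l_yx = float(ly.sum() / m)
    if l_xy == 0.0 or l_yx == 0.0:
        cap = 2.0 * math.log(max(n, m))
        logger.warning(
            "no common substrings between %s and %s; distance capped at %.6f",
            x.name,
            y.name,
            cap,
        )
        return cap
    d_xy = math.log(m) / l_xy - math.log(n) / ((n + 1) / 2)
    d_yx = math.log(n) / l_yx - math.log(m) / ((m + 1) / 2)
    return (d_xy + d_yx) / 2.0


def kmacs_distance_matrix(
    seqs, k: int = DEFAULT_K, mode: str = "auto", alphabet: Alphabet = None
) -> DistanceMatrix:
    """Pairwise kmacs distance matrix over a sequence set."""
    if len(seqs) < 2:
        raise ContractError("need at least two sequences for a distance matrix")
    if alphabet is None:
        alphabet = detect_alphabet(seqs)
    total = sum(len(s) for s in seqs)
    resolved = _resolve_mode(mode, total)
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = kmacs_distance(
                seqs[i], seqs[j], k, resolved, alphabet
            )
    return DistanceMatrix([s.name for s in seqs], values)
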