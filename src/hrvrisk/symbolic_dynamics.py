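"""Symbolic-dynamics HRV index families.

Four coarse-graining schemes of the NN interval series are implemented:

* **Classical symbolic dynamics (SD)** — each interval is mapped onto the
  alphabet {0,1,2,3} relative to the segment mean mu with scaling
  parameter alpha = 0.1 (0: mu < NN <= (1+alpha)mu; 1: NN > (1+alpha)mu;
  2: (1-alpha)mu < NN <= mu; 3: NN <= (1-alpha)mu).  Overlapping
  3-symbol words give 4^3 = 64 word types, from which wpsum02 (words of
  only "0"/"2", depressed variability), wpsum13 (only "1"/"3", elevated
  variability), the 64 single-word probabilities pW000..pW333 and the
  threshold counts pTH1..pTH20 (number of word types with probability
  strictly above k%) are derived.
* **Binary variability patterns** — successive differences are coded 1
  when |dNN| >= 5 ms else 0; among the 2^6 = 64 overlapping 6-symbol
  words, plvar5 is the probability of "000000" (low variability) and
  phvar5 of "111111" (high variability).
* **Segmented short-term SD (SSD)** — classical SD evaluated in 30-min
  windows shifted by 1 min over a 24-h record, summarized by the mean
  (m_) and standard deviation (s_) of each per-window index and by the
  Shannon entropy of each word type's probability distribution across
  windows (Sturges bin count nob = round(1 + 3.32 log10 S)).
* **Short-term SD (STSD)** — 6-level uniform quantization in 300-beat
  windows, 6^3 = 216 patterns grouped into the families 0V / 1V / 2V and
  the ramp/peak/valley/plateau refinements.
* **SD-coded SD (SDSD)** — in each sliding window of M = 5 intervals the
  symbol is the number of successive differences that are decreases
  larger in magnitude than the window standard deviation (a = 1);
  tau1_p001 counts symbol values occurring with probability above 1%.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ContractError, InsufficientDataError
from .io_preprocess import NNSeries

__all__ = [
    "SymbolSequence",
    "WordHistogram",
    "PatternFamilyProfile",
    "encode_classical",
    "word_histogram",
    "classical_sd_indices",
    "binary_variability_patterns",
    "ssd_24h",
    "stsd",
    "sdsd",
    "STSD_FAMILIES",
]

STSD_FAMILIES = (
    "ST_0V",
    "ST_1V",
    "ST_2V",
    "ST_ASC",
    "ST_DESC",
    "ST_PEAK",
    "ST_VAL",
    "ST_PLATEAU",
)


@dataclass
class SymbolSequence:
    symbols: np.ndarray
    alphabet_size: int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.size and self.symbols.max() >= self.alphabet_size:
            raise ContractError("symbol outside declared alphabet")


@dataclass
class WordHistogram:
    word_length: int
    alphabet_size: int
    counts: dict
    probabilities: dict


@dataclass
class PatternFamilyProfile:
    """Per-300-beat-window STSD family fractions and their aggregates."""

    per_window: dict  # family name -> np.ndarray over windows
    aggregates: dict  # m_<family> / s_<family> -> float
    n_windows: int


def encode_classical(nn: NNSeries, alpha: float = 0.1) -> SymbolSequence:
    """Four-symbol coding of NN intervals relative to the segment mean."""
    x = np.asarray(nn.nn, dtype=float)
    if x.size < 1:
        raise InsufficientDataError("empty series")
    mu = x.mean()
    sym = np.empty(x.size, dtype=np.int64)
    sym[(x > mu) & (x <= (1 + alpha) * mu)] = 0
    sym[x > (1 + alpha) * mu] = 1
    sym[(x > (1 - alpha) * mu) & (x <= mu)] = 2
    sym[x <= (1 - alpha) * mu] = 3
    return SymbolSequence(sym, alphabet_size=4, provenance=f"classical(alpha={alpha})")


def _word_codes(symbols: np.ndarray, word_length: int, alphabet_size: int) -> np.ndarray:
    """Integer code of each overlapping word (most significant symbol first)."""
    codes = symbols[: len(symbols) - word_length + 1].copy()
    for k in range(1, word_length):
        codes = codes * alphabet_size + symbols[k : len(symbols) - word_length + 1 + k]
    return codes


def _word_probs(symbols: np.ndarray, word_length: int, alphabet_size: int) -> np.ndarray:
    codes = _word_codes(symbols, word_length, alphabet_size)
    counts = np.bincount(codes, minlength=alphabet_size**word_length)
    return counts / len(codes)


def _word_names(word_length: int, alphabet_size: int) -> list[str]:
    return ["".join(map(str, w)) for w in product(range(alphabet_size), repeat=word_length)]


def word_histogram(sym: SymbolSequence, word_length: int = 3) -> WordHistogram:
    """Overlapping-word histogram with every possible word type present."""
    if len(sym.symbols) < word_length:
        raise InsufficientDataError(
            f"need at least {word_length} symbols, have {len(sym.symbols)}"
        )
    codes = _word_codes(sym.symbols, word_length, sym.alphabet_size)
    counts = np.bincount(codes, minlength=sym.alphabet_size**word_length)
    names = _word_names(word_length, sym.alphabet_size)
    total = len(codes)
    return WordHistogram(
        word_length=word_length,
        alphabet_size=sym.alphabet_size,
        counts=dict(zip(names, counts.tolist())),
        probabilities=dict(zip(names, (counts / total).tolist())),
    )


def _pth_counts(probs: np.ndarray, kmax: int = 20) -> np.ndarray:
    """pTHk = number of word types with probability strictly above k%."""
    return np.array([(probs > k / 100.0).sum() for k in range(1, kmax + 1)])


def classical_sd_indices(h: WordHistogram) -> dict:
    """wpsum02 / wpsum13, pW000..pW333 and pTH1..pTH20 from a 64-word histogram."""
    if h.alphabet_size != 4 or h.word_length != 3:
        raise ContractError("classical SD indices require alphabet 4, word length 3")
    names = _word_names(3, 4)
    probs = np.array([h.probabilities[w] for w in names])
    only02 = np.array([set(w) <= {"0", "2"} for w in names])
    only13 = np.array([set(w) <= {"1", "3"} for w in names])
    out = {
        "wpsum02": float(probs[only02].sum()),
        "wpsum13": float(probs[only13].sum()),
    }
    out.update({f"pW{w}": float(p) for w, p in zip(names, probs)})
    out.update({f"pTH{k}": int(c) for k, c in enumerate(_pth_counts(probs), start=1)})
    return out


def binary_variability_patterns(nn: NNSeries, limit_ms: float = 5.0) -> dict:
    """plvar / phvar: probabilities of all-quiet and all-active 6-words.

    Successive differences are coded 1 when ``|dNN| >= limit_ms`` else 0;
    plvar is the probability of the word "000000" among overlapping
    6-symbol words and phvar that of "111111".
    """
    if len(nn) < 7:
        raise InsufficientDataError("binary patterns need >= 7 intervals")
    b = (np.abs(np.diff(nn.nn)) >= limit_ms).astype(np.int64)
    run = sliding_window_view(b, 6).sum(axis=1)
    tag = f"{limit_ms:g}"
    return {
        f"plvar{tag}": float(np.mean(run == 0)),
        f"phvar{tag}": float(np.mean(run == 6)),
    }


def _shannon_over_windows(values: np.ndarray, nob: int) -> float:
    """Shannon entropy (bits) of the binned distribution of per-window values."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(values, bins=nob, range=(lo, hi))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def ssd_24h(
    nn24h: NNSeries,
    window_s: int = 1800,
    shift_s: int = 60,
    alpha: float = 0.1,
) -> dict:
    """Segmented short-term SD over a long (24-h) record.

    Classical SD is evaluated per 30-min window (1-min shift, mean mu
    local to the window); the per-window pW and pTH indices are
    summarized by their mean (m_) and standard deviation (s_) across
    windows, and each word type additionally by the Shannon entropy of
    its probability distribution over windows, binned into
    ``nob = round(1 + 3.32 log10 S)`` bins spanning that word type's
    [min, max].
    """
    if nn24h.duration_s < window_s + shift_s:
        raise InsufficientDataError("segmented SD needs at least two 30-min windows")
    starts = np.arange(0.0, nn24h.duration_s - window_s + 1e-9, shift_s)
    names = _word_names(3, 4)
    pw_rows, pth_rows = [], []
    for s0 in starts:
        i0, i1 = np.searchsorted(nn24h.t, [s0, s0 + window_s])
        seg = nn24h.nn[i0:i1]
        if len(seg) < 3:
            continue
        mu = seg.mean()
        sym = np.empty(len(seg), dtype=np.int64)
        sym[(seg > mu) & (seg <= (1 + alpha) * mu)] = 0
        sym[seg > (1 + alpha) * mu] = 1
        sym[(seg > (1 - alpha) * mu) & (seg <= mu)] = 2
        sym[seg <= (1 - alpha) * mu] = 3
        probs = _word_probs(sym, 3, 4)
        pw_rows.append(probs)
        pth_rows.append(_pth_counts(probs))
    S = len(pw_rows)
    if S < 2:
        raise InsufficientDataError("segmented SD needs at least two usable windows")
    pw = np.array(pw_rows)  # S x 64
    pth = np.array(pth_rows, dtype=float)  # S x 20
    nob = int(round(1 + 3.32 * np.log10(S)))
    out: dict = {"S_windows": S}
    for j, w in enumerate(names):
        out[f"m_pW{w}"] = float(pw[:, j].mean())
        out[f"s_pW{w}"] = float(pw[:, j].std(ddof=1))
        out[f"Shannon_pW{w}"] = _shannon_over_windows(pw[:, j], nob)
    for k in range(20):
        out[f"m_pTH{k + 1}"] = float(pth[:, k].mean())
        out[f"s_pTH{k + 1}"] = float(pth[:, k].std(ddof=1))
    return out


def _stsd_quantize(seg: np.ndarray, levels: int = 6) -> np.ndarray:
    lo, hi = seg.min(), seg.max()
    if hi <= lo:
        return np.zeros(len(seg), dtype=np.int64)
    q = np.floor((seg - lo) / (hi - lo) * levels).astype(np.int64)
    return np.minimum(q, levels - 1)


def _stsd_window_fractions(sym: np.ndarray) -> dict:
    a, b, c = sym[:-2], sym[1:-1], sym[2:]
    eq1 = a == b
    eq2 = b == c
    v0 = eq1 & eq2
    v1 = eq1 ^ eq2
    v2 = ~eq1 & ~eq2
    asc = v2 & (a < b) & (b < c)
    desc = v2 & (a > b) & (b > c)
    peak = v2 & (b > a) & (b > c)
    val = v2 & (b < a) & (b < c)
    n = len(a)
    return {
        "ST_0V": v0.mean(),
        "ST_1V": v1.mean(),
        "ST_2V": v2.mean(),
        "ST_ASC": asc.mean(),
        "ST_DESC": desc.mean(),
        "ST_PEAK": peak.mean(),
        "ST_VAL": val.mean(),
        "ST_PLATEAU": v1.mean(),  # one equal successive pair == plateau
    } if n else {}


def stsd(nn: NNSeries, window_beats: int = 300) -> PatternFamilyProfile:
    """Short-term SD pattern-family fractions per 300-beat window.

    Each non-overlapping window is quantized onto 6 equal-width levels
    over its own [min, max] (window maximum on level 5; internal edge
    ties go to the upper level); the 216 overlapping 3-symbol patterns
    are grouped into families: 0V (all equal), 1V (exactly one equal
    successive pair, identical to PLATEAU), and 2V (no equal successive
    pair) subdivided into strictly ascending/descending ramps, peaks and
    valleys.
    """
    if len(nn) < window_beats:
        raise InsufficientDataError(f"STSD needs >= {window_beats} intervals")
    n_win = len(nn) // window_beats
    rows = {f: [] for f in STSD_FAMILIES}
    for w in range(n_win):
        seg = nn.nn[w * window_beats : (w + 1) * window_beats]
        fr = _stsd_window_fractions(_stsd_quantize(seg))
        for f in STSD_FAMILIES:
            rows[f].append(fr[f])
    per_window = {f: np.array(v) for f, v in rows.items()}
    aggregates = {}
    for f in STSD_FAMILIES:
        v = per_window[f]
        aggregates[f"m_{f}"] = float(v.mean())
        aggregates[f"s_{f}"] = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    return PatternFamilyProfile(per_window=per_window, aggregates=aggregates, n_windows=n_win)


def sdsd(nn: NNSeries, a: float = 1.0, tau: int = 1, M: int = 5) -> dict:
    """Standard-deviation-coded SD.

    For each sliding window of M intervals (shift tau) the symbol is the
    number of the M-1 successive differences that are decreases whose
    magnitude strictly exceeds ``a`` times the window's (n-1) standard
    deviation, i.e. dNN < -a*SD_j.  ``tau1_p001`` is the number of
    symbol values with occurrence probability strictly above 1%.
    """
    if len(nn) < M + 1:
        raise InsufficientDataError(f"SDSD needs >= {M + 1} intervals")
    wins = sliding_window_view(nn.nn, M)[::tau]
    sd = wins.std(axis=1, ddof=1)
    d = np.diff(wins, axis=1)
    symbols = (d < -a * sd[:, None]).sum(axis=1)
    probs = np.bincount(symbols, minlength=M) / len(symbols)
    return {
        "tau1_p001": int((probs > 0.01).sum()),
        "symbol_probabilities": probs,
    }
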