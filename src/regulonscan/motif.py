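"""Information-theoretic motif models and genome scanning.

A binding-site model is built from an alignment of equal-length sites as a
positional base-frequency matrix.  Conservation is measured in bits:

* total information (``R_sequence``): per-column ``2 - H(l) - e(n)`` summed
  over columns, where ``H(l)`` is the Shannon entropy of the column and
  ``e(n)`` the small-sample correction for an alignment of ``n`` sites;
* individual information (``Ri``): per-site sum of the positional weights
  ``Riw(b, l) = 2 + log2 f(b, l) - e(n)``, so that the mean ``Ri`` over the
  alignment's own members equals the total information.

Scanning slides the weight matrix over both strands of a genome and reports
every window at or above a bit cutoff; ``localbest`` keeps only the best hit
within a fixed window, the standard treatment for tandemly overlapping
direct-repeat sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

__all__ = [
    "SiteAlignment",
    "InformationWeightMatrix",
    "BindingSiteCall",
    "small_sample_correction",
    "build_matrix",
    "total_information",
    "individual_information",
    "scan",
    "localbest",
    "sequence_walker_report",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string over {A,C,G,T} to integer codes 0..3."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


@dataclass(frozen=True)
class SiteAlignment:
    """Equal-length aligned binding sites.

    ``offset`` is the column index of the position labelled 0 in the motif
    coordinate frame, so an 18-bp box whose columns are labelled -3..+14
    has ``offset = 3``.
    """

    sequences: tuple[str, ...]
    offset: int = 0

    def __post_init__(self) -> None:
        seqs = tuple(s.upper() for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if len(seqs) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        L = len(seqs[0])
        if L < 1:
            raise ValueError("alignment sequences must be non-empty")
        for i, s in enumerate(seqs):
            if len(s) != L:
                raise ValueError(
                    f"sequence {i} has length {len(s)}, expected {L}"
                )
            for j, c in enumerate(s):
                if c not in _BASE_INDEX:
                    raise ValueError(
                        f"ambiguous base {c!r} in sequence {i}, column {j}"
                    )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def counts(self) -> np.ndarray:
        """L x 4 base counts."""
        codes = np.stack([encode(s) for s in self.sequences])
        out = np.zeros((self.length, 4), dtype=np.int64)
        for b in range(4):
            out[:, b] = (codes == b).sum(axis=0)
        return out

    def column_of(self, position: int) -> int:
        """Column index for a motif-frame position (e.g. -3..+14)."""
        col = position + self.offset
        if not 0 <= col < self.length:
            raise IndexError(f"position {position} outside alignment")
        return col

    def slice_positions(self, pos_from: int, pos_to: int) -> "SiteAlignment":
        """Sub-alignment over inclusive motif-frame positions."""
        a, b = self.column_of(pos_from), self.column_of(pos_to)
        if a > b:
            raise ValueError("empty position range")
        return SiteAlignment(
            tuple(s[a : b + 1] for s in self.sequences), offset=-pos_from
        )


def small_sample_correction(n: int, method: str = "approx") -> float:
    """Small-sample correction e(n), in bits per column.

    The plug-in entropy of a column estimated from ``n`` sampled bases
    underestimates the true entropy; for an equiprobable 4-letter genome the
    expected shortfall is ``e(n) = 2 - E[H_hat]``.  ``method='approx'`` uses
    the first-order approximation 3/(2 ln2 n); ``method='exact'`` enumerates
    all base-count compositions of ``n`` under the uniform multinomial,
    which is cheap for the small alignments where the approximation is
    poorest.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method == "approx":
        return 3.0 / (2.0 * math.log(2.0) * n)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    # E[H_hat] = sum over compositions (n1..n4) of P(composition) * H_hat
    expect_h = 0.0
    logp_base = gammaln(n + 1) - n * math.log(4.0)
    for n1 in range(n + 1):
        for n2 in range(n - n1 + 1):
            for n3 in range(n - n1 - n2 + 1):
                n4 = n - n1 - n2 - n3
                ns = (n1, n2, n3, n4)
                logp = logp_base - sum(gammaln(k + 1) for k in ns)
                h = -sum(
                    (k / n) * math.log2(k / n) for k in ns if k > 0
                )
                expect_h += math.exp(logp) * h
    return 2.0 - expect_h


@dataclass(frozen=True)
class InformationWeightMatrix:
    """Positional base frequencies and per-base bit weights.

    ``riw[l, b] = 2 + log2 freqs[l, b] - e_n`` by default (``corrected``
    True); with ``corrected`` False the correction is left out of the
    individual weights and applied only to the total information.  With
    ``pseudocount`` 0 an unseen base has weight ``-inf``, the theoretical
    "never observed" limit.
    """

    freqs: np.ndarray  # L x 4, rows sum to 1
    n: int
    e_n: float
    riw: np.ndarray  # L x 4, bits
    pseudocount: float
    offset: int = 0
    corrected: bool = True

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError("freqs must be L x 4")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each freqs column must sum to 1")
        if self.e_n < 0:
            raise ValueError("e_n must be >= 0")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def column_of(self, position: int) -> int:
        col = position + self.offset
        if not 0 <= col < self.length:
            raise IndexError(f"position {position} outside matrix")
        return col

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in np.argmax(self.riw, axis=1))

    @property
    def max_score(self) -> float:
        """Highest attainable Ri (the consensus score)."""
        return float(np.max(self.riw, axis=1).sum())


def build_matrix(
    alignment: SiteAlignment,
    pseudocount: float = 0.0,
    correction: str = "approx",
    corrected_riw: bool = True,
) -> InformationWeightMatrix:
    """Build an information weight matrix from an aligned site set.

    Frequencies are ``(count + pseudocount) / (n + 4 pseudocount)``;
    ``correction`` selects the e(n) estimator (see
    :func:`small_sample_correction`).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = alignment.counts()
    n = alignment.n
    freqs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    e_n = small_sample_correction(n, method=correction)
    with np.errstate(divide="ignore"):
        log_f = np.log2(freqs)
    riw = 2.0 + log_f - (e_n if corrected_riw else 0.0)
    return InformationWeightMatrix(
        freqs=freqs,
        n=n,
        e_n=e_n,
        riw=riw,
        pseudocount=pseudocount,
        offset=alignment.offset,
        corrected=corrected_riw,
    )


def total_information(
    matrix: InformationWeightMatrix,
    pos_from: int | None = None,
    pos_to: int | None = None,
) -> tuple[float, float]:
    """Total information R_sequence over an inclusive position range.

    Returns ``(bits, sd_bits)``.  Per column, ``2 - H(l) - e(n)``; the SD is
    the delta-method sampling standard deviation of the plug-in entropy sum,
    ``sqrt(sum_l var_l)`` with
    ``var_l = (sum_b f (log2 f)^2 - H_l^2) / n``.
    """
    if pos_from is None:
        a = 0
    else:
        a = matrix.column_of(pos_from)
    if pos_to is None:
        b = matrix.length - 1
    else:
        b = matrix.column_of(pos_to)
    if a > b:
        raise ValueError("empty column range")
    f = matrix.freqs[a : b + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
        plog2p = np.where(f > 0, f * np.log2(f) ** 2, 0.0)
    h = -plogp.sum(axis=1)
    bits = float(((2.0 - matrix.e_n) - h).sum())
    var = (plog2p.sum(axis=1) - h**2) / matrix.n
    sd = float(math.sqrt(max(var.sum(), 0.0)))
    return bits, sd


def individual_information(matrix: InformationWeightMatrix, seq: str) -> float:
    """Individual information Ri of one sequence, in bits."""
    codes = encode(seq)
    if codes.shape[0] != matrix.length:
        raise ValueError(
            f"sequence length {codes.shape[0]} != matrix length {matrix.length}"
        )
    if (codes < 0).any():
        bad = int(np.where(codes < 0)[0][0])
        raise ValueError(f"ambiguous base {seq[bad]!r} at offset {bad}")
    return float(matrix.riw[np.arange(matrix.length), codes].sum())


@dataclass(frozen=True, order=True)
class BindingSiteCall:
    """A scored motif occurrence on a genome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    ri_bits: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    def sequence(self, genome: Mapping[str, str]) -> str:
        s = genome[self.chrom][self.start : self.end]
        return s if self.strand == "+" else reverse_complement(s)


def _window_scores(riw: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score every length-L window of an encoded sequence."""
    L = riw.shape[0]
    n_win = codes.shape[0] - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    for l in range(L):
        scores += riw[l, codes[l : l + n_win]]
    return scores


def scan(
    matrix: InformationWeightMatrix,
    genome: Mapping[str, str],
    cutoff_bits: float,
    both_strands: bool = True,
) -> list[BindingSiteCall]:
    """Report every window with Ri >= cutoff on either strand.

    Reverse-strand windows are scored as their reverse complement; all
    coordinates are 0-based half-open on the forward strand.  When the same
    window passes on both strands, the higher-Ri strand is kept ('+' on a
    palindromic tie).
    """
    L = matrix.length
    # reverse-complement matrix scores a forward window as its rev-comp
    riw_rc = matrix.riw[::-1, ::-1]
    calls: list[BindingSiteCall] = []
    for chrom in genome:
        codes = encode(genome[chrom])
        if (codes < 0).any():
            raise ValueError(f"ambiguous bases in sequence {chrom!r}")
        fwd = _window_scores(matrix.riw, codes)
        if both_strands:
            rev = _window_scores(riw_rc, codes)
        else:
            rev = np.full_like(fwd, -np.inf)
        hits = np.nonzero((fwd >= cutoff_bits) | (rev >= cutoff_bits))[0]
        for i in hits:
            i = int(i)
            sf, sr = fwd[i], rev[i]
            if sf >= sr:
                calls.append(BindingSiteCall(chrom, i, i + L, "+", float(sf)))
            else:
                calls.append(BindingSiteCall(chrom, i, i + L, "-", float(sr)))
    calls.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return calls


def localbest(
    calls: Sequence[BindingSiteCall], window_bp: int = 200
) -> list[BindingSiteCall]:
    """Keep only the best-scoring call within any ``window_bp`` stretch.

    Greedy by descending Ri; ties broken leftmost, then forward strand.
    Two retained calls are always >= ``window_bp`` apart (start to start).
    """
    order = sorted(
        calls, key=lambda c: (c.chrom, -c.ri_bits, c.start, c.strand)
    )
    kept: list[BindingSiteCall] = []
    for c in order:
        if any(
            k.chrom == c.chrom and abs(k.start - c.start) < window_bp
            for k in kept
        ):
            continue
        kept.append(c)
    kept.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return kept


def sequence_walker_report(
    matrix: InformationWeightMatrix, seq: str, anchor: int = 0
) -> str:
    """Plain-text sequence walker: per-position Riw contributions.

    Each line gives the motif-frame position, the base, its weight in bits
    and a signed bar; the footer states the total Ri (the sum of the
    contributions).  ``anchor`` is added to the printed genomic coordinate.
    """
    codes = encode(seq)
    if codes.shape[0] != matrix.length:
        raise ValueError("sequence length does not match matrix")
    contribs = matrix.riw[np.arange(matrix.length), codes]
    lines = ["pos\tcoord\tbase\tbits\tbar"]
    for l in range(matrix.length):
        pos = l - matrix.offset
        c = contribs[l]
        nbar = min(int(round(abs(c) * 2)), 20)
        bar = ("+" if c >= 0 else "-") * nbar
        lines.append(f"{pos:+d}\t{anchor + l}\t{seq[l].upper()}\t{c:.3f}\t{bar}")
    total = float(contribs.sum())
    lines.append(f"Ri\t\t\t{total:.3f}\t")
    return "\n".join(lines)
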