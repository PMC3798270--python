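"""Strand-aware ChIP-seq point-source deconvolution.

Read 5' positions on the forward and reverse strands flank a protein
binding point at roughly half the sonicated fragment length on either side.
The caller models the observed per-bp strand counts as a Poisson process
whose rate is a depth-corrected input background plus a sum of point
sources convolved with a Gaussian kernel, each source shifted -d/2 on the
forward strand and +d/2 on the reverse, where d (the fragment offset) is
learned from the strand cross-correlation.  Sources are placed greedily at
single-bp resolution; each placement must improve the Poisson
log-likelihood by at least ``llr_threshold``.  The false-discovery rate of
a run is estimated by a sample swap: calls made with input over IP divided
by calls made with IP over input.

The depth correction factor is the ratio of input to IP read counts, so a
factor above 1 up-weights an IP library sequenced shallower than its input.
The fit is fully deterministic for a fixed input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "ReadProfile",
    "DeconvCall",
    "strand_kernel_density",
    "estimate_offset",
    "deconvolve",
    "sample_swap_fdr",
    "exclude_regions",
]

KERNEL_TAIL_SIGMAS = 8.0  # truncation radius; tail mass < 1e-14


@dataclass(frozen=True)
class ReadProfile:
    """Mapped read 5' positions for one reference sequence, per strand."""

    chrom: str
    fwd_positions: np.ndarray
    rev_positions: np.ndarray
    role: str = "IP"

    def __post_init__(self) -> None:
        for name in ("fwd_positions", "rev_positions"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.size and arr.min() < 0:
                raise ValueError("read positions must be non-negative")
            object.__setattr__(self, name, np.sort(arr))

    @property
    def n_reads(self) -> int:
        return int(self.fwd_positions.size + self.rev_positions.size)

    def max_position(self) -> int:
        mx = 0
        if self.fwd_positions.size:
            mx = max(mx, int(self.fwd_positions.max()))
        if self.rev_positions.size:
            mx = max(mx, int(self.rev_positions.max()))
        return mx

    def shifted(self, delta: int) -> "ReadProfile":
        return replace(
            self,
            fwd_positions=self.fwd_positions + delta,
            rev_positions=self.rev_positions + delta,
        )


@dataclass(frozen=True)
class DeconvCall:
    """A deconvolved point binding source."""

    chrom: str
    source_position: int
    llr: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


def _gaussian_kernel(bandwidth_bp: float) -> np.ndarray:
    """Unit-mass Gaussian kernel sampled per bp, truncated far in the tail."""
    radius = int(math.ceil(KERNEL_TAIL_SIGMAS * bandwidth_bp))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / bandwidth_bp) ** 2)
    return k / (bandwidth_bp * math.sqrt(2.0 * math.pi))


def _density(
    positions: np.ndarray, length: int, kernel: np.ndarray
) -> np.ndarray:
    counts = np.bincount(
        np.clip(positions, 0, length - 1), minlength=length
    ).astype(float)
    return fftconvolve(counts, kernel, mode="same")


def strand_kernel_density(
    profile: ReadProfile,
    bandwidth_bp: float = 30.0,
    depth_correction: float = 1.0,
    genome_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of read 5' ends, one track per strand.

    Each read contributes a unit-mass Gaussian of SD ``bandwidth_bp``; the
    result is scaled by ``depth_correction`` so its integral equals
    ``depth_correction x read count`` up to kernel mass lost off the ends.
    """
    if bandwidth_bp <= 0:
        raise ValueError("bandwidth_bp must be positive")
    if depth_correction <= 0:
        raise ValueError("depth_correction must be positive")
    length = genome_length or profile.max_position() + 1
    kernel = _gaussian_kernel(bandwidth_bp)
    fwd = depth_correction * _density(profile.fwd_positions, length, kernel)
    rev = depth_correction * _density(profile.rev_positions, length, kernel)
    return fwd, rev


def estimate_offset(
    profile: ReadProfile,
    bandwidth_bp: float = 30.0,
    max_offset: int = 1000,
    genome_length: int | None = None,
) -> int:
    """Fragment offset d: the lag maximizing fwd/rev density correlation.

    For reads whose 5' ends flank sources at +-F/2 the lag recovers the
    fragment length F.  Always >= 0; identical strand tracks give 0.
    """
    if profile.fwd_positions.size == 0 or profile.rev_positions.size == 0:
        raise ValueError("need reads on both strands to estimate the offset")
    fwd, rev = strand_kernel_density(
        profile, bandwidth_bp, genome_length=genome_length
    )
    # corr[d] = sum_x fwd[x] * rev[x + d] for d = 0..max_offset
    full = fftconvolve(rev, fwd[::-1], mode="full")
    zero_lag = fwd.size - 1
    lags = full[zero_lag : zero_lag + max_offset + 1]
    return int(np.argmax(lags))


def sample_swap_fdr(calls_fwd: int, calls_swap: int) -> float | None:
    """FDR estimate: swapped-orientation calls over forward calls.

    Returns ``None`` (undefined) when there are no forward calls.
    """
    if calls_fwd < 0 or calls_swap < 0:
        raise ValueError("call counts must be non-negative")
    if calls_fwd == 0:
        return None
    return calls_swap / calls_fwd


def exclude_regions(
    profile: ReadProfile, regions: Sequence[tuple[str, int, int]]
) -> ReadProfile:
    """Drop reads whose 5' position falls inside any listed interval.

    Intervals are (chrom, start, end), 0-based half-open; intervals on
    other reference sequences are ignored.
    """
    ivs = sorted(
        (s, e) for c, s, e in regions if c == profile.chrom and e > s
    )
    if not ivs:
        return profile
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    bounds = np.array([b for iv in merged for b in iv])

    def keep(pos: np.ndarray) -> np.ndarray:
        inside = np.searchsorted(bounds, pos, side="right") % 2 == 1
        return pos[~inside]

    return replace(
        profile,
        fwd_positions=keep(profile.fwd_positions),
        rev_positions=keep(profile.rev_positions),
    )


def deconvolve(
    ip: ReadProfile,
    input_profile: ReadProfile | None,
    bandwidth_bp: float = 30.0,
    llr_threshold: float = 21.75,
    max_sources: int = 50,
    depth_correction: float | None = None,
    offset: int | None = None,
    genome_length: int | None = None,
    background_floor: float = 1e-4,
) -> list[DeconvCall]:
    """Greedy Poisson point-source fit of strand-separated read counts.

    Sources are placed one at a time at the single-bp position maximizing
    the matched-filter excess over the current model; the source amplitude
    is fitted by Newton iteration on the local Poisson likelihood, and the
    placement is kept only if the exact log-likelihood-ratio gain is at
    least ``llr_threshold``.  The background is the input kernel density
    divided by ``depth_correction`` (input/IP read-count ratio, estimated
    from the libraries when not given), plus a small uniform floor.  Calls
    are returned sorted by position.
    """
    if llr_threshold <= 0:
        raise ValueError("llr_threshold must be positive")
    length = genome_length
    if length is None:
        length = ip.max_position() + 1
        if input_profile is not None and input_profile.n_reads:
            length = max(length, input_profile.max_position() + 1)
    if ip.n_reads == 0:
        return []
    n_fwd = np.bincount(
        np.clip(ip.fwd_positions, 0, length - 1), minlength=length
    ).astype(float)
    n_rev = np.bincount(
        np.clip(ip.rev_positions, 0, length - 1), minlength=length
    ).astype(float)

    # model kernel for the fit: truncated at 4 SD and renormalized to
    # unit mass, so local windows stay short; densities for export keep
    # the long-tailed kernel
    radius = int(math.ceil(4.0 * bandwidth_bp))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / bandwidth_bp) ** 2)
    kernel /= kernel.sum()

    if input_profile is not None and input_profile.n_reads > 0:
        if depth_correction is None:
            depth_correction = input_profile.n_reads / ip.n_reads
        in_fwd, in_rev = strand_kernel_density(
            input_profile, bandwidth_bp, genome_length=length
        )
        # multi-scale background in IP-count units: the sharp input
        # density, a broad local rate and the global rate — the sharp
        # density alone dips towards zero between sparse input reads and
        # would let a handful of IP reads score arbitrarily high
        broad = max(int(25 * bandwidth_bp), 500)
        box = np.ones(broad) / broad
        loc_f = fftconvolve(
            np.bincount(
                np.clip(input_profile.fwd_positions, 0, length - 1),
                minlength=length,
            ).astype(float),
            box,
            mode="same",
        )
        loc_r = fftconvolve(
            np.bincount(
                np.clip(input_profile.rev_positions, 0, length - 1),
                minlength=length,
            ).astype(float),
            box,
            mode="same",
        )
        glob_f = input_profile.fwd_positions.size / length
        glob_r = input_profile.rev_positions.size / length
        bg_fwd = np.maximum.reduce([in_fwd, loc_f, np.full(length, glob_f)])
        bg_fwd /= depth_correction
        bg_rev = np.maximum.reduce([in_rev, loc_r, np.full(length, glob_r)])
        bg_rev /= depth_correction
    else:
        rate_f = ip.fwd_positions.size / length
        rate_r = ip.rev_positions.size / length
        bg_fwd = np.full(length, rate_f)
        bg_rev = np.full(length, rate_r)
    floor = max(background_floor, 1e-12)
    bg_fwd = np.maximum(bg_fwd, floor)
    bg_rev = np.maximum(bg_rev, floor)

    if offset is None:
        try:
            offset = estimate_offset(
                ip, bandwidth_bp, genome_length=length
            )
        except ValueError:
            offset = 0
    sh_f = offset // 2  # fwd reads sit at source - sh_f
    sh_r = offset - sh_f

    # pad all tracks so every kernel window is full-length regardless of
    # source position; off-genome padding carries zero reads and a floor
    # rate, so edge sources pay for kernel mass falling off the genome
    pad = radius + max(sh_f, sh_r)
    K = kernel.size
    n_f = np.zeros(length + 2 * pad)
    n_r = np.zeros(length + 2 * pad)
    n_f[pad : pad + length] = n_fwd
    n_r[pad : pad + length] = n_rev
    lam_fwd = np.full(length + 2 * pad, floor)
    lam_rev = np.full(length + 2 * pad, floor)
    lam_fwd[pad : pad + length] = bg_fwd
    lam_rev[pad : pad + length] = bg_rev
    ksum = float(kernel.sum())
    from numpy.lib.stride_tricks import sliding_window_view

    win_nf = sliding_window_view(n_f, K)
    win_nr = sliding_window_view(n_r, K)

    def _win_lam(candidates: np.ndarray):
        # lam windows must be re-sliced each call (lam mutates in place)
        wf = sliding_window_view(lam_fwd, K)
        wr = sliding_window_view(lam_rev, K)
        idx_f = candidates - sh_f + pad - radius
        idx_r = candidates + sh_r + pad - radius
        return wf[idx_f], wr[idx_r], win_nf[idx_f], win_nr[idx_r]

    def _fit_candidates(candidates: np.ndarray):
        """Per-candidate optimal amplitude and exact LL gain (vectorized).

        Newton iteration on the local Poisson likelihood in the amplitude,
        jointly over both strand windows.
        """
        Lf, Lr, Nf, Nr = _win_lam(candidates)
        excess = (
            Nf.sum(axis=1) - Lf.sum(axis=1) + Nr.sum(axis=1) - Lr.sum(axis=1)
        )
        a = np.maximum(excess / 2.0, 0.5)
        k2 = kernel**2
        for _ in range(12):
            denf = Lf + a[:, None] * kernel
            denr = Lr + a[:, None] * kernel
            g = (
                (Nf * kernel / denf).sum(axis=1)
                + (Nr * kernel / denr).sum(axis=1)
                - 2.0 * ksum
            )
            h = -(
                (Nf * k2 / denf**2).sum(axis=1)
                + (Nr * k2 / denr**2).sum(axis=1)
            )
            step = np.divide(
                g, h, out=np.zeros_like(g), where=h < 0
            )
            a_new = a - step
            a_new = np.where(a_new <= 0, a / 2.0, a_new)
            if np.all(np.abs(a_new - a) < 1e-6 * np.maximum(a, 1.0)):
                a = a_new
                break
            a = a_new
        a = np.maximum(a, 1e-9)
        ak = a[:, None] * kernel
        gains = (
            (Nf * (np.log(Lf + ak) - np.log(Lf))).sum(axis=1)
            + (Nr * (np.log(Lr + ak) - np.log(Lr))).sum(axis=1)
            - 2.0 * a * ksum
        )
        return a, gains

    def fit_amplitude(s: int) -> float:
        a, _ = _fit_candidates(np.array([s]))
        return float(a[0])

    def local_gain(s: int, a: float) -> float:
        """Exact LL gain of adding a source of amplitude a at s."""
        Lf, Lr, Nf, Nr = _win_lam(np.array([s]))
        ak = a * kernel
        return float(
            (Nf[0] * (np.log(Lf[0] + ak) - np.log(Lf[0]))).sum()
            + (Nr[0] * (np.log(Lr[0] + ak) - np.log(Lr[0]))).sum()
            - 2.0 * a * ksum
        )

    def add_source(s: int, a: float, sign: float = 1.0) -> None:
        for lam, shift in ((lam_fwd, -sh_f), (lam_rev, sh_r)):
            c = s + shift + pad
            lam[c - radius : c + radius + 1] += sign * a * kernel

    def shifted_corr_genome() -> np.ndarray:
        """Matched-filter residual score at every genome position."""
        cf = fftconvolve(n_f - lam_fwd, kernel[::-1], mode="same")
        cr = fftconvolve(n_r - lam_rev, kernel[::-1], mode="same")
        pos = np.arange(length)
        return cf[pos - sh_f + pad] + cr[pos + sh_r + pad]

    def best_local(center: int, half_window: int) -> tuple[int, float, float]:
        """Best (position, gain, amplitude) within +-half_window.

        Coarse stride-3 sweep followed by a single-bp refinement around
        the coarse optimum.
        """
        lo = max(0, center - half_window)
        hi = min(length - 1, center + half_window)
        coarse = np.arange(lo, hi + 1, 3)
        a, gains = _fit_candidates(coarse)
        c = int(coarse[int(np.argmax(gains))])
        fine = np.arange(max(0, c - 2), min(length - 1, c + 2) + 1)
        a, gains = _fit_candidates(fine)
        i = int(np.argmax(gains))
        return int(fine[i]), float(gains[i]), float(a[i])

    sources: list[list[float]] = []  # [position, amplitude]
    ll = 0.0  # model log-likelihood relative to background-only

    def snapshot():
        return lam_fwd.copy(), lam_rev.copy(), [list(s) for s in sources], ll

    def restore(state) -> None:
        nonlocal sources, ll
        lam_fwd[:], lam_rev[:] = state[0], state[1]
        sources = [list(s) for s in state[2]]
        ll = state[3]

    def place(pos: int, a: float) -> float:
        """Add a source; returns the exact LL gain of the placement."""
        nonlocal ll
        gain = local_gain(pos, a)
        add_source(pos, a)
        sources.append([pos, a])
        ll += gain
        return gain

    def drop(i: int) -> float:
        """Remove source i; returns the LL loss its removal causes."""
        nonlocal ll
        pos, a = int(sources[i][0]), sources[i][1]
        add_source(pos, a, sign=-1.0)
        loss = local_gain(pos, a)
        del sources[i]
        ll -= loss
        return loss

    def refit_one(i: int, half_window: int) -> bool:
        """Refit source i's position and amplitude, others fixed."""
        nonlocal ll
        pos0, a0 = int(sources[i][0]), sources[i][1]
        add_source(pos0, a0, sign=-1.0)
        ll -= local_gain(pos0, a0)
        pos, gain, a = best_local(pos0, half_window)
        sources[i][0], sources[i][1] = pos, a
        add_source(pos, a)
        ll += gain
        return pos != pos0 or abs(a - a0) > 1e-6

    def refine(sweeps: int, half_window: int, indices=None) -> None:
        for _ in range(sweeps):
            moved = False
            idxs = range(len(sources)) if indices is None else indices
            for i in idxs:
                moved |= refit_one(i, half_window)
            if not moved:
                break

    # phase 1: greedy placement down to a low gain floor (final acceptance
    # is the removal test of phase 3, against llr_threshold)
    greedy_floor = min(llr_threshold, max(2.0, 0.1 * llr_threshold))
    while len(sources) < max_sources:
        corr = shifted_corr_genome()
        s = int(np.argmax(corr))
        if corr[s] <= 0:
            break
        pos, gain, a = best_local(s, int(bandwidth_bp))
        if gain < greedy_floor or a <= 0:
            break
        place(pos, a)

    refine_window = int(2 * bandwidth_bp)
    refine(3, refine_window)

    # phase 2: split moves — replace one source by a pair when the pair
    # improves the joint likelihood by at least llr_threshold, the same
    # price phase 3 demands of every retained source
    split_deltas = range(8, int(2.5 * bandwidth_bp) + 1, 5)
    splits_done = 0
    while splits_done < max_sources:
        accepted = False
        for i in range(len(sources)):
            if len(sources) >= max_sources:
                break
            base = snapshot()
            pos0 = int(sources[i][0])
            drop(i)
            removed = snapshot()
            best_state = None
            best_ll = -np.inf
            for delta in split_deltas:
                lo, hi = pos0 - delta, pos0 + delta
                if lo < 0 or hi >= length:
                    continue
                restore(removed)
                place(lo, fit_amplitude(lo))
                place(hi, fit_amplitude(hi))
                refine(
                    1,
                    refine_window,
                    indices=(len(sources) - 2, len(sources) - 1),
                )
                if ll > best_ll:
                    best_ll = ll
                    best_state = snapshot()
            if best_state is not None and best_ll - base[3] >= llr_threshold:
                restore(best_state)
                accepted = True
                splits_done += 1
                break
            restore(base)
        if not accepted:
            break

    # phase 3: removal test with refit — a source survives only if
    # removing it (letting the remaining sources re-settle) costs at
    # least llr_threshold in joint log-likelihood
    final_llr: list[float] = []
    while sources:
        base = snapshot()
        losses = []
        states = []
        for i in range(len(sources)):
            restore(base)
            drop(i)
            refine(1, refine_window)
            losses.append(base[3] - ll)
            states.append(snapshot())
        weakest = int(np.argmin(losses))
        if losses[weakest] >= llr_threshold:
            restore(base)
            final_llr = losses
            break
        restore(states[weakest])
    calls = [
        DeconvCall(ip.chrom, int(p), float(llr), float(a))
        for (p, a), llr in zip(sources, final_llr)
    ]
    calls.sort(key=lambda c: c.source_position)
    return calls
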