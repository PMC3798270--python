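"""Two-channel tiling-array (ChIP-chip) enrichment analysis.

Probe-level log-ratio tracks are quantile-normalized across channels and
replicate arrays, enriched regions are called as runs of probes above a
track-wide percentile threshold (the two stringencies used in practice are
the 95th and 98th percentiles), replicate calls are intersected, and two
false-positive filters annotate the surviving regions: overlap with regions
enriched in a regulator-deletion control strain, and the RNA-polymerase
crosslinking artifact at highly transcribed loci (regulator signal that
tracks RNAP occupancy and is condition-independent).

Filters only add flags; they never move region boundaries.  Downstream
steps drop flagged regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProbeTrack",
    "PeakRegion",
    "quantile_normalize",
    "median_smooth",
    "call_percentile_regions",
    "intersect_replicates",
    "delta_strain_filter",
    "rnap_crosslink_filter",
]


@dataclass
class ProbeTrack:
    """Per-probe values (chrom, start, end, value), sorted by coordinate."""

    probes: pd.DataFrame
    role: str = "log2ratio"

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "value"}
        if not req.issubset(self.probes.columns):
            raise ValueError(f"probe table needs columns {sorted(req)}")
        df = self.probes.sort_values(["chrom", "start"]).reset_index(drop=True)
        if (df["start"] < 0).any():
            raise ValueError("negative probe coordinates")
        self.probes = df

    @property
    def values(self) -> np.ndarray:
        return self.probes["value"].to_numpy(dtype=float)

    def with_values(self, values: np.ndarray) -> "ProbeTrack":
        df = self.probes.copy()
        df["value"] = np.asarray(values, dtype=float)
        return ProbeTrack(df, role=self.role)

    def centers(self) -> np.ndarray:
        return (
            self.probes["start"].to_numpy() + self.probes["end"].to_numpy()
        ) / 2.0


@dataclass
class PeakRegion:
    """An enriched region with provenance flags."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float
    support: set = field(default_factory=set)
    filters: set = field(default_factory=set)
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie within the region")

    def overlaps(self, other: "PeakRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _check_same_probes(tracks: Sequence[ProbeTrack]) -> None:
    ref = tracks[0].probes[["chrom", "start", "end"]]
    for i, t in enumerate(tracks[1:], start=2):
        cur = t.probes[["chrom", "start", "end"]]
        if len(cur) != len(ref) or not cur.reset_index(drop=True).equals(
            ref.reset_index(drop=True)
        ):
            merged = ref.merge(cur, how="outer", indicator=True)
            diff = merged[merged["_merge"] != "both"]
            raise ValueError(
                f"track {i} probe set differs from track 1; "
                f"{len(diff)} discrepant probes, first:\n{diff.head()}"
            )


def quantile_normalize(tracks: Sequence[ProbeTrack]) -> list[ProbeTrack]:
    """Force the same empirical distribution onto every track.

    Each track's sorted values are replaced by the rank-wise mean of the
    sorted values across tracks; tied values within a track receive the
    mean of the reference values they span.
    """
    if not tracks:
        return []
    _check_same_probes(tracks)
    mat = np.column_stack([t.values for t in tracks])
    sorted_mat = np.sort(mat, axis=0)
    reference = sorted_mat.mean(axis=1)
    out = []
    for j, t in enumerate(tracks):
        v = mat[:, j]
        order = np.argsort(v, kind="stable")
        new = np.empty_like(v)
        new[order] = reference
        # average the assigned values over ties
        df = pd.DataFrame({"v": v, "new": new})
        new = df.groupby("v")["new"].transform("mean").to_numpy()
        out.append(t.with_values(new))
    return out


def median_smooth(track: ProbeTrack, window_bp: int = 300) -> ProbeTrack:
    """Replace each probe by the median of probes within +-window_bp/2."""
    df = track.probes
    new = np.empty(len(df), dtype=float)
    half = window_bp / 2.0
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        centers = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
        vals = sub["value"].to_numpy(dtype=float)
        lo = np.searchsorted(centers, centers - half, side="left")
        hi = np.searchsorted(centers, centers + half, side="right")
        for k in range(len(idx)):
            new[idx[k]] = np.median(vals[lo[k] : hi[k]])
    return track.with_values(new)


def call_percentile_regions(
    track: ProbeTrack, percentile: float = 95.0, min_run_probes: int = 4
) -> list[PeakRegion]:
    """Runs of probes above a track-wide percentile become regions.

    A region is a maximal run of >= ``min_run_probes`` consecutive probes
    all strictly above the percentile threshold of the whole track.  The
    score is the maximum probe value, the summit the center of the maximal
    probe, and the p-value the binomial-null probability that a fixed run
    of that length lies wholly above the threshold.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    vals = track.values
    if vals.size == 0:
        return []
    threshold = float(np.percentile(vals, percentile))
    p0 = 1.0 - percentile / 100.0
    regions: list[PeakRegion] = []
    for chrom, sub in track.probes.groupby("chrom", sort=False):
        v = sub["value"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        above = v > threshold
        i = 0
        while i < len(v):
            if not above[i]:
                i += 1
                continue
            j = i
            while j < len(v) and above[j]:
                j += 1
            if j - i >= min_run_probes:
                seg = slice(i, j)
                k = i + int(np.argmax(v[seg]))
                summit = int((starts[k] + ends[k]) // 2)
                regions.append(
                    PeakRegion(
                        chrom=str(chrom),
                        start=int(starts[i]),
                        end=int(ends[j - 1]),
                        summit=summit,
                        score=float(v[k]),
                        support={"chipchip"},
                        pvalue=p0 ** (j - i),
                    )
                )
            i = j
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _coverage_intersection(
    regions_by_replicate: Sequence[Sequence[PeakRegion]],
) -> dict[str, list[tuple[int, int]]]:
    """Base intervals covered by at least one region in *every* replicate."""

    def union(regions: Sequence[PeakRegion], chrom: str):
        ivs = sorted(
            (r.start, r.end) for r in regions if r.chrom == chrom
        )
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return merged

    chroms = sorted(
        {r.chrom for reps in regions_by_replicate for r in reps}
    )
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in chroms:
        cur = union(regions_by_replicate[0], chrom)
        for reps in regions_by_replicate[1:]:
            other = union(reps, chrom)
            nxt: list[list[int]] = []
            i = j = 0
            while i < len(cur) and j < len(other):
                s = max(cur[i][0], other[j][0])
                e = min(cur[i][1], other[j][1])
                if s < e:
                    nxt.append([s, e])
                if cur[i][1] < other[j][1]:
                    i += 1
                else:
                    j += 1
            cur = nxt
        out[chrom] = [(s, e) for s, e in cur]
    return out


def intersect_replicates(
    regions_by_replicate: Sequence[Sequence[PeakRegion]],
) -> list[PeakRegion]:
    """Keep only signal present in every replicate.

    Each connected component of the cross-replicate coverage intersection
    is expanded to the union of the replicate regions overlapping it;
    support flags record the contributing replicates.
    """
    if not regions_by_replicate:
        return []
    inter = _coverage_intersection(regions_by_replicate)
    merged: list[PeakRegion] = []
    for chrom, cores in inter.items():
        for s, e in cores:
            contributing = [
                (i, r)
                for i, reps in enumerate(regions_by_replicate)
                for r in reps
                if r.chrom == chrom and r.start < e and s < r.end
            ]
            start = min(r.start for _, r in contributing)
            end = max(r.end for _, r in contributing)
            best = max(contributing, key=lambda t: t[1].score)[1]
            support = {f"rep{i + 1}" for i, _ in contributing}
            for _, r in contributing:
                support |= r.support
            merged.append(
                PeakRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=best.summit,
                    score=best.score,
                    support=support,
                    pvalue=best.pvalue,
                )
            )
    # components may expand into overlapping unions; merge those
    merged.sort(key=lambda r: (r.chrom, r.start))
    out: list[PeakRegion] = []
    for r in merged:
        if out and out[-1].overlaps(r):
            prev = out[-1]
            keep = prev if prev.score >= r.score else r
            out[-1] = PeakRegion(
                chrom=r.chrom,
                start=min(prev.start, r.start),
                end=max(prev.end, r.end),
                summit=keep.summit,
                score=keep.score,
                support=prev.support | r.support,
                pvalue=keep.pvalue,
            )
        else:
            out.append(r)
    return out


def delta_strain_filter(
    regions: Sequence[PeakRegion], control_regions: Sequence[PeakRegion]
) -> list[PeakRegion]:
    """Flag regions also enriched in the regulator-deletion control."""
    out = []
    for r in regions:
        flags = set(r.filters)
        if any(r.overlaps(c) for c in control_regions):
            flags.add("delta_control_fail")
        out.append(replace(r, filters=flags))
    return out


def _bin_max(
    track: ProbeTrack, chrom: str, n_bins: int, bin_bp: int
) -> np.ndarray:
    """Per-bin maximum probe value (probes assigned by center)."""
    sub = track.probes[track.probes["chrom"] == chrom]
    centers = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
    vals = sub["value"].to_numpy(dtype=float)
    out = np.full(n_bins, -np.inf)
    bins = np.clip(centers // bin_bp, 0, n_bins - 1).astype(int)
    np.maximum.at(out, bins, vals)
    return out


def rnap_crosslink_filter(
    regions: Sequence[PeakRegion],
    arca_track: ProbeTrack,
    rnap_track: ProbeTrack,
    bin_bp: int = 300,
    rnap_log2_cutoff: float = 1.75,
    aerobic_track: ProbeTrack | None = None,
    box_calls: Sequence | None = None,
    box_rescue_bits: float = 10.0,
    condition_ratio: float = 0.8,
) -> tuple[list[PeakRegion], dict]:
    """Flag regions whose regulator signal is an RNAP crosslinking artifact.

    The genome is divided into non-overlapping ``bin_bp`` bins and the
    maximum log2 ratio per bin extracted for each track.  Pearson r and a
    least-squares regression of regulator on RNAP signal are computed over
    bins with RNAP >= ``rnap_log2_cutoff``.  A region is flagged when it
    overlaps at least one such high-RNAP bin, every overlapping high-RNAP
    bin has condition-independent regulator signal (aerobic and anaerobic
    maxima within ``condition_ratio`` of each other), and no binding-site
    call of >= ``box_rescue_bits`` bits lies inside the region.  Returns
    the flagged regions and a report with the per-bin table, r and the
    regression line (``None`` when fewer than 3 bins qualify).
    """
    chroms = sorted(set(arca_track.probes["chrom"]))
    report: dict = {"bins": {}, "r": None, "slope": None, "intercept": None}
    flagged: dict[str, np.ndarray] = {}
    all_arca, all_rnap = [], []
    bin_tables: dict[str, pd.DataFrame] = {}
    for chrom in chroms:
        end = int(
            max(
                arca_track.probes.loc[
                    arca_track.probes["chrom"] == chrom, "end"
                ].max(),
                rnap_track.probes.loc[
                    rnap_track.probes["chrom"] == chrom, "end"
                ].max(),
            )
        )
        n_bins = int(np.ceil(end / bin_bp))
        arca = _bin_max(arca_track, chrom, n_bins, bin_bp)
        rnap = _bin_max(rnap_track, chrom, n_bins, bin_bp)
        aero = (
            _bin_max(aerobic_track, chrom, n_bins, bin_bp)
            if aerobic_track is not None
            else np.full(n_bins, np.nan)
        )
        tbl = pd.DataFrame(
            {
                "bin_start": np.arange(n_bins) * bin_bp,
                "arca_max": arca,
                "rnap_max": rnap,
                "aerobic_max": aero,
            }
        )
        bin_tables[chrom] = tbl
        usable = np.isfinite(arca) & np.isfinite(rnap)
        high = usable & (rnap >= rnap_log2_cutoff)
        all_arca.append(arca[high])
        all_rnap.append(rnap[high])
        flagged[chrom] = high
    report["bins"] = bin_tables
    arca_high = np.concatenate(all_arca) if all_arca else np.empty(0)
    rnap_high = np.concatenate(all_rnap) if all_rnap else np.empty(0)
    if arca_high.size >= 3 and np.ptp(rnap_high) > 0:
        fit = stats.linregress(rnap_high, arca_high)
        report.update(
            {"r": float(fit.rvalue), "slope": float(fit.slope),
             "intercept": float(fit.intercept), "n_bins": int(arca_high.size)}
        )
    enough_bins = arca_high.size >= 3
    out = []
    for r in regions:
        flags = set(r.filters)
        tbl = bin_tables.get(r.chrom)
        if tbl is not None and enough_bins:
            b0 = r.start // bin_bp
            b1 = (r.end - 1) // bin_bp
            high_mask = flagged[r.chrom][b0 : b1 + 1]
            if high_mask.any():
                sub = tbl.iloc[b0 : b1 + 1][high_mask]
                cond_indep = True
                if aerobic_track is not None:
                    a = sub["arca_max"].to_numpy()
                    o = sub["aerobic_max"].to_numpy()
                    with np.errstate(divide="ignore", invalid="ignore"):
                        lo = np.minimum(a, o)
                        hi = np.maximum(a, o)
                        ratio = np.where(hi > 0, lo / hi, 1.0)
                    cond_indep = bool(np.all(ratio >= condition_ratio))
                has_box = False
                if box_calls:
                    has_box = any(
                        c.chrom == r.chrom
                        and c.start >= r.start
                        and c.end <= r.end
                        and c.ri_bits >= box_rescue_bits
                        for c in box_calls
                    )
                if cond_indep and not has_box:
                    flags.add("rnap_crosslink_fail")
        out.append(replace(r, filters=flags))
    return out, report
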