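"""Direct-repeat (DR) architecture of response-regulator binding sites.

The 18-bp core box is two tandem 10-bp DR half-sites at 11-bp
center-to-center (ctc) spacing; many in-vivo sites carry additional DR
elements, either consecutively (every spacing 11 bp, one helical turn) or
with a distal element two helical turns (22 bp) away.  This module builds
the 10-bp single-DR weight matrix by pooling the two half-sites of every
aligned box, rescans the flanks of each box for extra elements at a 0-bit
cutoff (the theoretical lowest limit of binding), and classifies each site's
architecture from the chain of ctc spacings.

ctc spacing is operationalized as the start-to-start distance of the 10-bp
elements, which equals center-to-center for equal-length elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import (
    BindingSiteCall,
    InformationWeightMatrix,
    SiteAlignment,
    build_matrix,
    scan,
)

DR_LENGTH = 10
#: motif-frame spans of the two half-sites within the aligned box
HALF_SITE_1 = (-3, 6)
HALF_SITE_2 = (8, 17)

__all__ = [
    "DRElement",
    "DRArchitecture",
    "build_dr_matrix",
    "scan_flanks",
    "classify_architecture",
    "architecture_census",
]


@dataclass(frozen=True)
class DRElement:
    """One 10-bp direct-repeat half-site occurrence."""

    chrom: str
    start: int
    end: int
    strand: str
    ri_bits: float

    def __post_init__(self) -> None:
        if self.end - self.start != DR_LENGTH:
            raise ValueError("DR elements are exactly 10 bp")


@dataclass(frozen=True)
class DRArchitecture:
    """A classified binding site: ordered DR elements and ctc spacings."""

    anchor_box: BindingSiteCall
    elements: tuple[DRElement, ...]  # 5'->3' on the anchor strand
    spacings: tuple[int, ...]  # ctc between consecutive elements
    label: str
    n_dr: int

    def __post_init__(self) -> None:
        if self.elements and len(self.spacings) != len(self.elements) - 1:
            raise ValueError("need len(elements) - 1 spacings")


def build_dr_matrix(
    box_alignment: SiteAlignment, pseudocount: float = 0.0, **kwargs
) -> InformationWeightMatrix:
    """Pool both half-sites of every aligned box into a 10-bp DR matrix.

    The box alignment must cover motif positions -3..+17 (the second
    half-site extends 3 bp past the 18-bp core).  With n boxes the matrix is
    built from 2n half-sites.
    """
    last_needed = HALF_SITE_2[1] + box_alignment.offset
    if last_needed >= box_alignment.length:
        missing = last_needed - box_alignment.length + 1
        raise ValueError(
            f"box alignment must cover positions {HALF_SITE_1[0]}..{HALF_SITE_2[1]}; "
            f"missing the last {missing} column(s)"
        )
    a1 = box_alignment.column_of(HALF_SITE_1[0])
    a2 = box_alignment.column_of(HALF_SITE_2[0])
    half_sites = []
    for s in box_alignment.sequences:
        half_sites.append(s[a1 : a1 + DR_LENGTH])
        half_sites.append(s[a2 : a2 + DR_LENGTH])
    pooled = SiteAlignment(tuple(half_sites), offset=-HALF_SITE_1[0])
    return build_matrix(pooled, pseudocount=pseudocount, **kwargs)


def _dedupe_opposite_strands(elements: list[DRElement]) -> list[DRElement]:
    """Overlapping opposite-strand hits at one locus: keep the higher Ri."""
    kept: list[DRElement] = []
    for e in sorted(elements, key=lambda e: (-e.ri_bits, e.start, e.strand)):
        clash = any(
            k.strand != e.strand and k.start < e.end and e.start < k.end
            for k in kept
        )
        if not clash:
            kept.append(e)
    kept.sort(key=lambda e: e.start)
    return kept


def scan_flanks(
    dr_matrix: InformationWeightMatrix,
    genome: Mapping[str, str],
    anchor_boxes: Sequence[BindingSiteCall],
    window_bp: int = 100,
    cutoff_bits: float = 0.0,
) -> list[list[DRElement]]:
    """Scan a window centered on each anchor box for DR elements.

    Returns, per anchor, every hit >= ``cutoff_bits`` on both strands inside
    the ``window_bp`` window (this always includes the anchor box's own two
    half-sites when they pass the cutoff), sorted 5'->3' on the anchor
    strand.  Overlapping opposite-strand hits at the same locus are resolved
    to the higher-scoring strand.
    """
    out: list[list[DRElement]] = []
    for box in anchor_boxes:
        seq = genome.get(box.chrom)
        if seq is None:
            raise ValueError(f"anchor on unknown sequence {box.chrom!r}")
        if box.start < 0 or box.end > len(seq):
            raise ValueError("anchor outside genome bounds")
        center = (box.start + box.end) // 2
        w0 = max(0, center - window_bp // 2)
        w1 = min(len(seq), center + (window_bp + 1) // 2)
        sub = {box.chrom: seq[w0:w1]}
        calls = scan(dr_matrix, sub, cutoff_bits, both_strands=True)
        elems = [
            DRElement(box.chrom, w0 + c.start, w0 + c.end, c.strand, c.ri_bits)
            for c in calls
        ]
        elems = _dedupe_opposite_strands(elems)
        elems.sort(key=lambda e: e.start, reverse=(box.strand == "-"))
        out.append(elems)
    return out


def classify_architecture(
    anchor_box: BindingSiteCall,
    elements: Iterable[DRElement],
    allowed_spacings: frozenset[int] | set[int] = frozenset({11, 22}),
    tolerance_bp: int = 0,
    consecutive_spacing: int = 11,
    distal_spacing: int = 22,
    anchor_strand_only: bool = True,
) -> DRArchitecture:
    """Classify a binding site by its chain of DR spacings.

    The canonical chain is the maximal run of elements connected by allowed
    ctc spacings (11 bp = consecutive, 22 bp = distal) that contains the
    anchor box's own half-sites; an element at any other spacing is recorded
    but excluded from ``n_dr`` and flags the label ``+offspaced``.  Labels:
    ``2DR``, ``3DR-consecutive`` .., ``kDR+distal`` for a final two-turn
    spacing, ``degenerate`` when fewer than two canonical elements remain.
    """

    def ok(spacing: int) -> bool:
        return any(abs(spacing - a) <= tolerance_bp for a in allowed_spacings)

    elems = list(elements)
    if anchor_strand_only:
        elems = [e for e in elems if e.strand == anchor_box.strand]
    # genomic 5'->3' order along the anchor strand
    elems.sort(key=lambda e: e.start, reverse=(anchor_box.strand == "-"))
    sign = -1 if anchor_box.strand == "-" else 1
    spacings = [
        sign * (b.start - a.start) for a, b in zip(elems, elems[1:])
    ]

    # maximal allowed-spacing run containing the anchor's first half-site
    runs: list[tuple[int, int]] = []  # [first_idx, last_idx] inclusive
    i = 0
    while i < len(elems):
        j = i
        while j < len(spacings) and ok(spacings[j]):
            j += 1
        runs.append((i, j))
        i = j + 1 if j == i else j
    anchor_idx = next(
        (k for k, e in enumerate(elems) if e.start == anchor_box.start), None
    )
    chain = None
    for a, b in runs:
        if anchor_idx is not None and a <= anchor_idx <= b:
            chain = (a, b)
            break
    if chain is None and runs:
        chain = max(runs, key=lambda r: r[1] - r[0])
    a, b = chain if chain else (0, 0)
    chain_elems = elems[a : b + 1]
    chain_spacings = spacings[a:b]
    n_dr = len(chain_elems)

    if n_dr < 2:
        label = "degenerate"
    else:
        n_consec = 1
        for s in chain_spacings:
            if abs(s - consecutive_spacing) <= tolerance_bp:
                n_consec += 1
            else:
                break
        distal = bool(chain_spacings) and abs(
            chain_spacings[-1] - distal_spacing
        ) <= tolerance_bp
        if distal and n_consec == n_dr - 1:
            label = f"{n_consec}DR+distal"
        elif n_consec == n_dr:
            label = "2DR" if n_dr == 2 else f"{n_dr}DR-consecutive"
        else:
            label = f"{n_consec}DR-mixed"
    if len(chain_elems) < len(elems):
        label += "+offspaced"

    return DRArchitecture(
        anchor_box=anchor_box,
        elements=tuple(elems),
        spacings=tuple(spacings),
        label=label,
        n_dr=n_dr,
    )


def architecture_census(
    architectures: Sequence[DRArchitecture],
) -> pd.DataFrame:
    """Counts per architecture label, with per-class DR conservation.

    One row per label: number of sites, the canonical DR count, and the
    mean per-element Ri in bits (averaged over canonical-chain elements of
    all sites in the class) — the per-class conservation that decreases
    with increasing repeat number in the in-vivo site set.
    """
    if not architectures:
        return pd.DataFrame(
            columns=["label", "n_sites", "n_dr", "mean_dr_ri_bits"]
        )
    rows = []
    by_label: dict[str, list[DRArchitecture]] = {}
    for arch in architectures:
        by_label.setdefault(arch.label, []).append(arch)
    for label in sorted(by_label):
        group = by_label[label]
        ris = [e.ri_bits for arch in group for e in arch.elements]
        rows.append(
            {
                "label": label,
                "n_sites": len(group),
                "n_dr": int(np.median([a.n_dr for a in group])),
                "mean_dr_ri_bits": float(np.mean(ris)) if ris else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["label", "n_sites", "n_dr", "mean_dr_ri_bits"])


def census_by_ndr(architectures: Sequence[DRArchitecture]) -> pd.DataFrame:
    """Site counts grouped by canonical DR count."""
    counts: dict[int, int] = {}
    for arch in architectures:
        counts[arch.n_dr] = counts.get(arch.n_dr, 0) + 1
    return pd.DataFrame(
        [{"n_dr": k, "n_sites": counts[k]} for k in sorted(counts)],
        columns=["n_dr", "n_sites"],
    )
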