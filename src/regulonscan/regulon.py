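"""Regulon reconstruction: merge binding regions, call differentially
expressed operons, and classify direct versus indirect regulation.

An operon is *directly* regulated when it is both differentially expressed
upon deletion of the regulator and carries an in-vivo binding region in its
upstream/promoter window; the sign convention throughout is expression in
the deletion strain over wild type, so a transcript that goes *up* when the
regulator is removed is *repressed* by it.  Differentially expressed
operons without binding are attributed to indirect regulation unless a
high-scoring binding site is still found upstream by a motif scan (a site
the ChIP experiments may have missed), and a bookkeeping report traces
indirect targets through directly regulated transcription factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chipchip import PeakRegion
from .motif import (
    BindingSiteCall,
    InformationWeightMatrix,
    individual_information,
    localbest,
    scan,
)

__all__ = [
    "OperonRecord",
    "RegulonAssignment",
    "merge_region_sets",
    "call_de_operons",
    "assign_regions_to_operons",
    "classify_regulon",
    "indirect_site_search",
    "promoter_overlap",
    "site_position_table",
    "hierarchy_report",
]


@dataclass(frozen=True)
class OperonRecord:
    """An operon: ordered genes, strand, and optional promoter anatomy."""

    operon_id: str
    genes: tuple[str, ...]
    strand: str
    start: int  # first-gene start coordinate (5' end on the operon strand)
    chrom: str = "genome"
    tss: int | None = None
    minus10: int | None = None  # start of the -10 element
    minus35: int | None = None  # start of the -35 element

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("operon needs at least one gene")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def anchor(self) -> int:
        """Promoter anchor: the TSS when known, else the first-gene start."""
        return self.tss if self.tss is not None else self.start


@dataclass(frozen=True)
class RegulonAssignment:
    operon_id: str
    de_verdict: str  # up | down | none
    regions: tuple[int, ...]  # indices into the merged region list
    classification: str
    promoter_overlap: str = "unknown"


def _region_has_box(
    region: PeakRegion,
    genome: Mapping[str, str],
    box_matrix: InformationWeightMatrix,
    cutoff_bits: float,
) -> bool:
    seq = genome.get(region.chrom)
    if seq is None:
        return False
    sub = seq[max(0, region.start) : region.end]
    if len(sub) < box_matrix.length:
        return False
    return bool(scan(box_matrix, {"_": sub}, cutoff_bits))


def merge_region_sets(
    seq_both_reps: Sequence[PeakRegion],
    seq_single_rep: Sequence[PeakRegion],
    chip_only: Sequence[PeakRegion],
    genome: Mapping[str, str],
    box_matrix: InformationWeightMatrix,
    rescue_cutoff_bits: float = 10.0,
) -> list[PeakRegion]:
    """Build the final binding-region list with the box rescue rule.

    Regions supported by both sequencing replicates are always kept.
    Regions seen in only one replicate, or only on the array platform, are
    kept only when they contain a binding-site call of at least
    ``rescue_cutoff_bits`` (flagged ``rescued_by_box``).  Overlapping
    duplicates are merged into their union.
    """
    final: list[PeakRegion] = [
        replace(r, support=set(r.support), filters=set(r.filters))
        for r in seq_both_reps
    ]
    for r in list(seq_single_rep) + list(chip_only):
        if _region_has_box(r, genome, box_matrix, rescue_cutoff_bits):
            final.append(
                replace(
                    r,
                    support=set(r.support),
                    filters=set(r.filters) | {"rescued_by_box"},
                )
            )
    final.sort(key=lambda r: (r.chrom, r.start))
    merged: list[PeakRegion] = []
    for r in final:
        if merged and merged[-1].overlaps(r):
            prev = merged[-1]
            keep = prev if prev.score >= r.score else r
            merged[-1] = PeakRegion(
                chrom=r.chrom,
                start=min(prev.start, r.start),
                end=max(prev.end, r.end),
                summit=keep.summit,
                score=keep.score,
                support=prev.support | r.support,
                filters=prev.filters | r.filters,
                pvalue=keep.pvalue,
            )
        else:
            merged.append(r)
    return merged


def call_de_operons(
    expression: pd.DataFrame,
    operons: Sequence[OperonRecord],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    min_genes: int = 2,
    single_gene_passes: bool = True,
) -> tuple[dict[str, str], list[str]]:
    """Differential-expression verdict per operon.

    A gene passes at ``|log2FC| >= log2(fc_threshold)`` and
    ``p < p_threshold``.  A multi-gene operon is differentially expressed
    when at least ``min_genes`` member genes pass with a consistent sign; a
    single-gene operon when its gene passes (configurable).  Genes with
    mixed passing signs veto the operon.  Returns (verdicts, genes not in
    any operon); verdicts are 'up'/'down' (in the deletion strain) or
    'none'.
    """
    req = {"gene", "log2fc", "pvalue"}
    if not req.issubset(expression.columns):
        raise ValueError(f"expression table needs columns {sorted(req)}")
    cutoff = math.log2(fc_threshold)
    by_gene = {
        str(r.gene): (float(r.log2fc), float(r.pvalue))
        for r in expression.itertuples()
    }
    assigned: set[str] = set()
    verdicts: dict[str, str] = {}
    for op in operons:
        assigned.update(op.genes)
        signs = []
        for g in op.genes:
            if g not in by_gene:
                continue
            fc, p = by_gene[g]
            if abs(fc) >= cutoff and p < p_threshold:
                signs.append(1 if fc > 0 else -1)
        needed = 1 if (len(op.genes) == 1 and single_gene_passes) else min_genes
        if len(signs) >= needed and len(set(signs)) == 1:
            verdicts[op.operon_id] = "up" if signs[0] > 0 else "down"
        else:
            verdicts[op.operon_id] = "none"
    unassigned = sorted(set(by_gene) - assigned)
    return verdicts, unassigned


def assign_regions_to_operons(
    regions: Sequence[PeakRegion],
    operons: Sequence[OperonRecord],
    max_upstream_bp: int = 500,
) -> dict[int, list[str]]:
    """Map binding regions to the operons they may regulate.

    A region maps to an operon when it overlaps the strand-aware upstream
    window of ``max_upstream_bp`` ending at the promoter anchor (TSS when
    annotated, else first-gene start).  One region between divergent
    operons maps to both; a region overlapping no window maps to none
    (intragenic regions drop out here).
    """
    out: dict[int, list[str]] = {i: [] for i in range(len(regions))}
    for i, r in enumerate(regions):
        if r.filters & {"delta_control_fail", "rnap_crosslink_fail"}:
            continue
        for op in operons:
            if op.chrom != r.chrom:
                continue
            if op.strand == "+":
                w0, w1 = op.anchor - max_upstream_bp, op.anchor + 1
            else:
                w0, w1 = op.anchor, op.anchor + max_upstream_bp + 1
            if r.start < w1 and w0 < r.end:
                out[i].append(op.operon_id)
    return out


def classify_regulon(
    de_verdicts: Mapping[str, str],
    region_map: Mapping[int, list[str]],
    predicted_site_operons: Iterable[str] = (),
) -> tuple[list[RegulonAssignment], dict[str, int]]:
    """Cross binding with expression into the direct/indirect regulon.

    direct = differentially expressed and bound upstream (repressed when up
    in the deletion strain, activated when down); indirect = differentially
    expressed, unbound, and with no predicted upstream site either
    (``predicted_site_operons`` comes from :func:`indirect_site_search`);
    bound-but-unchanged operons and the Venn counts are also reported.
    """
    operon_regions: dict[str, list[int]] = {}
    for idx, ops in region_map.items():
        for op in ops:
            operon_regions.setdefault(op, []).append(idx)
    predicted = set(predicted_site_operons)
    assignments: list[RegulonAssignment] = []
    venn = {
        "direct": 0,
        "de_not_bound": 0,
        "bound_not_de": 0,
        "total_de": 0,
        "direct_repressed": 0,
        "direct_activated": 0,
        "indirect": 0,
    }
    for operon_id in sorted(set(de_verdicts) | set(operon_regions)):
        verdict = de_verdicts.get(operon_id, "none")
        regions = tuple(sorted(operon_regions.get(operon_id, [])))
        if verdict != "none":
            venn["total_de"] += 1
            if regions:
                venn["direct"] += 1
                if verdict == "up":
                    cls = "direct-repressed"
                    venn["direct_repressed"] += 1
                else:
                    cls = "direct-activated"
                    venn["direct_activated"] += 1
            else:
                venn["de_not_bound"] += 1
                if operon_id in predicted:
                    cls = "DE-not-bound"
                else:
                    cls = "indirect"
                    venn["indirect"] += 1
        elif regions:
            cls = "bound-not-DE"
            venn["bound_not_de"] += 1
        else:
            cls = "none"
        assignments.append(
            RegulonAssignment(operon_id, verdict, regions, cls)
        )
    return assignments, venn


def indirect_site_search(
    operons: Sequence[OperonRecord],
    genome: Mapping[str, str],
    box_matrix: InformationWeightMatrix,
    cutoff_bits: float = 15.0,
    upstream_bp: int = 500,
    localbest_window: int = 200,
) -> dict[str, list[BindingSiteCall]]:
    """Scan upstream windows of unbound DE operons for missed sites.

    Each operon's strand-aware upstream window is scanned at
    ``cutoff_bits`` (default the average conservation of the box model)
    and reduced with localbest; operons with at least one hit are returned
    with their calls in genome coordinates.
    """
    out: dict[str, list[BindingSiteCall]] = {}
    for op in operons:
        seq = genome.get(op.chrom)
        if seq is None:
            continue
        if op.strand == "+":
            w0, w1 = max(0, op.anchor - upstream_bp), op.anchor
        else:
            w0, w1 = op.anchor + 1, min(len(seq), op.anchor + 1 + upstream_bp)
        if w1 - w0 < box_matrix.length:
            continue
        calls = scan(box_matrix, {op.chrom: seq[w0:w1]}, cutoff_bits)
        calls = localbest(calls, localbest_window)
        if calls:
            out[op.operon_id] = [
                BindingSiteCall(
                    op.chrom, w0 + c.start, w0 + c.end, c.strand, c.ri_bits
                )
                for c in calls
            ]
    return out


def promoter_overlap(
    site: BindingSiteCall, operon: OperonRecord
) -> str:
    """Position of a binding site relative to the RNAP-bound promoter.

    'overlap' when the site intersects the span from the -35 element to the
    TSS (strand-aware; the region occupied by sigma70-RNAP), else
    'upstream' or 'downstream' of it along the operon; 'unknown' without a
    TSS annotation.
    """
    if operon.tss is None:
        return "unknown"
    ends = [operon.tss]
    for el in (operon.minus35, operon.minus10):
        if el is not None:
            ends.extend([el, el + 6])
    lo, hi = min(ends), max(ends) + 1
    if site.start < hi and lo < site.end:
        return "overlap"
    if operon.strand == "+":
        return "upstream" if site.end <= lo else "downstream"
    return "upstream" if site.start >= hi else "downstream"


def site_position_table(
    sites_by_operon: Mapping[str, Sequence[BindingSiteCall]],
    operons: Sequence[OperonRecord],
) -> pd.DataFrame:
    """Signed site-to-TSS distances (negative = upstream of the TSS).

    The distance is measured from the site midpoint to the TSS along the
    operon strand; the overlap category is included per site.
    """
    by_id = {op.operon_id: op for op in operons}
    rows = []
    for operon_id, sites in sites_by_operon.items():
        op = by_id.get(operon_id)
        if op is None or op.tss is None:
            continue
        for s in sites:
            mid = (s.start + s.end) // 2
            dist = mid - op.tss if op.strand == "+" else op.tss - mid
            rows.append(
                {
                    "operon": operon_id,
                    "site_start": s.start,
                    "site_end": s.end,
                    "ri_bits": s.ri_bits,
                    "distance_to_tss": int(dist),
                    "category": promoter_overlap(s, op),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "operon",
            "site_start",
            "site_end",
            "ri_bits",
            "distance_to_tss",
            "category",
        ],
    )


def hierarchy_report(
    direct_assignments: Sequence[RegulonAssignment],
    tf_annotation: pd.DataFrame,
    indirect_operons: Iterable[str],
    gene_to_operon: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Attribute indirect targets to directly regulated transcription factors.

    ``tf_annotation`` lists (tf_gene, target_operon) pairs from an external
    regulatory-network annotation; rows are emitted for every annotated
    target that is in the indirect set and whose TF gene belongs to a
    directly regulated operon.  Self-regulation (a TF attributed to its own
    operon) is excluded.  Pure bookkeeping: no inference.
    """
    req = {"tf_gene", "target_operon"}
    if not req.issubset(tf_annotation.columns):
        raise ValueError(f"TF annotation needs columns {sorted(req)}")
    direct = {
        a.operon_id: a
        for a in direct_assignments
        if a.classification.startswith("direct")
    }
    indirect = set(indirect_operons)
    rows = []
    for r in tf_annotation.itertuples():
        tf, target = str(r.tf_gene), str(r.target_operon)
        tf_operon = (
            gene_to_operon.get(tf) if gene_to_operon is not None else tf
        )
        if tf_operon not in direct:
            continue
        if target == tf_operon:
            continue
        if target not in indirect:
            continue
        rows.append(
            {
                "tf_gene": tf,
                "tf_operon": tf_operon,
                "tf_classification": direct[tf_operon].classification,
                "target_operon": target,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tf_gene", "tf_operon", "tf_classification", "target_operon"],
    )
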