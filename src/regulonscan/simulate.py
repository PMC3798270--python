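"""Synthetic inputs with known ground truth for every pipeline stage.

Each simulator emits the plain-text formats the pipeline consumes together
with a :class:`PlantingRecord` that fully determines the expected output of
every downstream oracle test: planted site coordinates, strands,
architectures and spacings; per-operon regulation truth; and all simulation
parameters including the seed.

The generators model only the structure the analysis assumes — an i.i.d.
background genome with sites sampled from a positional base-frequency
model, strand-separated read 5' ends flanking sources at half a
Normal-distributed fragment length, probe log-ratios with a plateau over
each bound footprint plus Gaussian noise, and operon-structured expression
effects — not mappability, GC bias or probe cross-hybridization.

Randomness: one global integer seed per run; each simulator draws from a
deterministic sub-stream so the outputs are byte-identical given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chipseq import ReadProfile
from .chipchip import ProbeTrack
from .motif import BASES, InformationWeightMatrix, reverse_complement
from .regulon import OperonRecord

__all__ = [
    "PlantingRecord",
    "DEFAULT_DR_CONSENSUS",
    "spacings_for_label",
    "simulate_genome",
    "simulate_reads",
    "simulate_array",
    "simulate_expression",
]

#: canonical 10-bp direct-repeat half-site used when no matrix is supplied
DEFAULT_DR_CONSENSUS = "TGTTAATTAA"

DR_LEN = 10
_STREAMS = {"genome": 1, "reads": 2, "array": 3, "expression": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class PlantingRecord:
    """Ground truth of a simulation run (JSON-serializable)."""

    sites: list = field(default_factory=list)
    operons: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"sites": self.sites, "operons": self.operons, "params": self.params},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "PlantingRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["sites"], d["operons"], d["params"])


def spacings_for_label(label: str) -> list[int]:
    """ctc spacing chain for an architecture label.

    '2DR' -> [11]; '4DR' / '4DR-consecutive' -> [11, 11, 11];
    'kDR+distal' -> k-1 consecutive spacings then 22;
    '2DR+offspaced' -> [11, 12] (the extra element one bp out of register).
    """
    base, _, suffix = label.partition("+")
    k = int(base.split("DR")[0])
    spacings = [11] * (k - 1)
    if suffix == "distal":
        spacings.append(22)
    elif suffix == "offspaced":
        spacings.append(12)
    elif suffix:
        raise ValueError(f"unknown architecture label {label!r}")
    return spacings


def _sample_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _dr_sequence(
    dr_matrix: InformationWeightMatrix | None,
    sample_from_matrix: bool,
    rng: np.random.Generator,
) -> str:
    if dr_matrix is None:
        return DEFAULT_DR_CONSENSUS
    if not sample_from_matrix:
        return dr_matrix.consensus
    idx = [rng.choice(4, p=dr_matrix.freqs[l]) for l in range(dr_matrix.length)]
    return "".join(BASES[i] for i in idx)


def _site_sequence(
    spacings: Sequence[int],
    dr_matrix: InformationWeightMatrix | None,
    sample_from_matrix: bool,
    gc: float,
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Build one site on its own strand; returns (sequence, DR offsets)."""
    offsets = [0]
    for s in spacings:
        offsets.append(offsets[-1] + s)
    length = offsets[-1] + DR_LEN
    codes = _sample_background(length, gc, rng)
    seq = list("".join(BASES[c] for c in codes))
    for o in offsets:
        dr = _dr_sequence(dr_matrix, sample_from_matrix, rng)
        seq[o : o + DR_LEN] = dr
    return "".join(seq), offsets


def simulate_genome(
    length_bp: int,
    gc: float = 0.5,
    architecture_mix: Mapping[str, int] | None = None,
    dr_matrix: InformationWeightMatrix | None = None,
    seed: int = 0,
    min_distance: int = 300,
    sample_from_matrix: bool = False,
    strand_choice: str = "+",
    chrom: str = "chr",
) -> tuple[dict[str, str], PlantingRecord]:
    """Background genome with planted multi-DR binding sites.

    ``architecture_mix`` maps architecture labels (see
    :func:`spacings_for_label`) to site counts.  Sites are placed uniformly
    with at least ``min_distance`` bp between site starts; each site is a
    chain of 10-bp DR elements (consensus by default, or sampled from
    ``dr_matrix``'s base frequencies).  ``strand_choice`` is '+', '-' or
    'random'.
    """
    rng = _rng(seed, "genome")
    codes = _sample_background(length_bp, gc, rng)
    genome = list("".join(BASES[c] for c in codes))
    record = PlantingRecord(
        params={
            "length_bp": length_bp,
            "gc": gc,
            "seed": seed,
            "min_distance": min_distance,
            "sample_from_matrix": sample_from_matrix,
            "strand_choice": strand_choice,
        }
    )
    labels = [
        lab
        for lab, cnt in sorted((architecture_mix or {}).items())
        for _ in range(cnt)
    ]
    max_len = max(
        (sum(spacings_for_label(l)) + DR_LEN for l in labels), default=0
    )
    taken: list[int] = []  # site start positions
    for label in labels:
        spacings = spacings_for_label(label)
        site_seq, offsets = _site_sequence(
            spacings, dr_matrix, sample_from_matrix, gc, rng
        )
        M = len(site_seq)
        for _ in range(10_000):
            g = int(rng.integers(0, length_bp - max_len))
            if all(abs(g - t) >= min_distance for t in taken):
                break
        else:
            raise ValueError(
                "could not place all sites; genome too short for the mix"
            )
        taken.append(g)
        strand = strand_choice
        if strand_choice == "random":
            strand = "+" if rng.integers(2) == 0 else "-"
        planted = site_seq if strand == "+" else reverse_complement(site_seq)
        genome[g : g + M] = planted
        if strand == "+":
            dr_starts = [g + o for o in offsets]
            box_start = g
        else:
            dr_starts = [g + M - o - DR_LEN for o in offsets]
            box_start = g + M - 18
        record.sites.append(
            {
                "chrom": chrom,
                "site_start": g,
                "site_end": g + M,
                "strand": strand,
                "label": label,
                "n_dr": len(offsets),
                "spacings": list(spacings),
                "dr_starts": dr_starts,
                "box_start": box_start,
                "sequence": site_seq,
            }
        )
    return {chrom: "".join(genome)}, record


def simulate_reads(
    genome: Mapping[str, str] | int,
    sources: Sequence[int],
    coverage: float = 100.0,
    fragment_mu: float = 150.0,
    fragment_sd: float = 20.0,
    background_rate: float = 0.0,
    input_rate: float | None = None,
    seed: int = 0,
    chrom: str | None = None,
) -> tuple[ReadProfile, ReadProfile, PlantingRecord]:
    """Strand-separated ChIP read 5' ends around point sources.

    Per source the read count is Poisson(``coverage``); each read's
    fragment length F ~ Normal(mu, sd) and, with equal probability, the
    read is the forward 5' end at ``source - F/2`` or the reverse 5' end at
    ``source + F/2``.  Background reads land uniformly on both strands at
    ``background_rate`` per bp; the input library is uniform at
    ``input_rate`` per bp (defaults to matching the IP's mean depth).
    """
    if isinstance(genome, int):
        length = genome
        name = chrom or "chr"
    else:
        name = chrom or next(iter(genome))
        length = len(genome[name])
    rng = _rng(seed, "reads")
    fwd: list[np.ndarray] = []
    rev: list[np.ndarray] = []
    for s in sources:
        n = int(rng.poisson(coverage))
        frags = rng.normal(fragment_mu, fragment_sd, size=n)
        is_fwd = rng.integers(0, 2, size=n) == 0
        pos_f = np.rint(s - frags[is_fwd] / 2).astype(np.int64)
        pos_r = np.rint(s + frags[~is_fwd] / 2).astype(np.int64)
        fwd.append(np.clip(pos_f, 0, length - 1))
        rev.append(np.clip(pos_r, 0, length - 1))
    n_bg = int(rng.poisson(background_rate * length))
    bg_pos = rng.integers(0, length, size=n_bg)
    bg_fwd = rng.integers(0, 2, size=n_bg) == 0
    fwd.append(bg_pos[bg_fwd])
    rev.append(bg_pos[~bg_fwd])
    ip = ReadProfile(
        name,
        np.concatenate(fwd) if fwd else np.empty(0, dtype=np.int64),
        np.concatenate(rev) if rev else np.empty(0, dtype=np.int64),
        role="IP",
    )
    if input_rate is None:
        input_rate = max(background_rate, ip.n_reads / (2.0 * length))
    n_in = int(rng.poisson(input_rate * length))
    in_pos = rng.integers(0, length, size=n_in)
    in_fwd = rng.integers(0, 2, size=n_in) == 0
    inp = ReadProfile(name, in_pos[in_fwd], in_pos[~in_fwd], role="input")
    record = PlantingRecord(
        sites=[{"chrom": name, "source": int(s)} for s in sources],
        params={
            "coverage": coverage,
            "fragment_mu": fragment_mu,
            "fragment_sd": fragment_sd,
            "background_rate": background_rate,
            "input_rate": input_rate,
            "seed": seed,
            "length_bp": length,
        },
    )
    return ip, inp, record


def simulate_array(
    genome: Mapping[str, str] | int,
    site_centers: Sequence[int],
    probe_spacing: int = 50,
    probe_length: int = 50,
    effect_log2: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    aerobic_factor: float = 0.1,
    footprint_bp: int = 300,
    rnap_regions: Sequence[tuple[int, int]] = (),
    rnap_effect: float = 3.0,
    chrom: str | None = None,
) -> tuple[dict[str, ProbeTrack], PlantingRecord]:
    """Probe-level log2-ratio tracks with planted enrichment plateaus.

    Probes within ``footprint_bp`` of a site center carry ``effect_log2``
    in the anaerobic track; the aerobic track scales the effect by
    ``aerobic_factor`` (the occupancy drop without the activating signal);
    the deletion-strain control has no site effect.  ``rnap_regions``
    plant condition-independent RNAP-crosslinking artifacts: full effect in
    both anaerobic and aerobic tracks, matching signal in the RNAP track,
    and nothing in the control.  Gaussian noise of SD ``noise_sd`` is added
    everywhere.  Returns tracks keyed anaerobic/aerobic/delta/rnap.
    """
    if isinstance(genome, int):
        length = genome
        name = chrom or "chr"
    else:
        name = chrom or next(iter(genome))
        length = len(genome[name])
    rng = _rng(seed, "array")
    starts = np.arange(0, length - probe_length + 1, probe_spacing)
    centers = starts + probe_length / 2.0
    in_site = np.zeros(centers.size, dtype=bool)
    for c in site_centers:
        in_site |= np.abs(centers - c) <= footprint_bp / 2.0
    in_rnap = np.zeros(centers.size, dtype=bool)
    for s, e in rnap_regions:
        in_rnap |= (centers >= s) & (centers < e)

    def track(base: np.ndarray, role: str) -> ProbeTrack:
        vals = base + rng.normal(0.0, noise_sd, size=centers.size)
        return ProbeTrack(
            pd.DataFrame(
                {
                    "chrom": name,
                    "start": starts,
                    "end": starts + probe_length,
                    "value": vals,
                }
            ),
            role=role,
        )

    anaerobic = track(
        effect_log2 * in_site + rnap_effect * in_rnap, "log2ratio"
    )
    aerobic = track(
        effect_log2 * aerobic_factor * in_site + rnap_effect * in_rnap,
        "log2ratio",
    )
    delta = track(np.zeros(centers.size), "log2ratio")
    rnap = track(rnap_effect * in_rnap, "log2ratio")
    record = PlantingRecord(
        sites=[
            {
                "chrom": name,
                "center": int(c),
                "footprint_start": int(c - footprint_bp // 2),
                "footprint_end": int(c + footprint_bp // 2),
            }
            for c in site_centers
        ],
        params={
            "probe_spacing": probe_spacing,
            "probe_length": probe_length,
            "effect_log2": effect_log2,
            "noise_sd": noise_sd,
            "aerobic_factor": aerobic_factor,
            "footprint_bp": footprint_bp,
            "rnap_regions": [list(r) for r in rnap_regions],
            "rnap_effect": rnap_effect,
            "seed": seed,
        },
    )
    return (
        {"anaerobic": anaerobic, "aerobic": aerobic, "delta": delta, "rnap": rnap},
        record,
    )


def simulate_expression(
    operons: Sequence[OperonRecord],
    regulated: Mapping[str, int],
    effect_log2: float = 2.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantingRecord]:
    """Gene-level expression statistics with planted operon effects.

    ``regulated`` maps operon id to the sign of its log2 fold change in
    the deletion strain (+1 = up when the regulator is removed, i.e.
    repressed by it).  Genes of regulated operons get
    ``sign x effect_log2`` plus noise and a small p-value; all other genes
    are null (log2FC ~ Normal(0, noise_sd), p ~ Uniform(0, 1)).
    """
    rng = _rng(seed, "expression")
    rows = []
    for op in operons:
        sign = regulated.get(op.operon_id, 0)
        for g in op.genes:
            if sign:
                fc = sign * effect_log2 + rng.normal(0.0, noise_sd)
                p = 10.0 ** rng.uniform(-8.0, -3.0)
            else:
                fc = rng.normal(0.0, noise_sd)
                p = rng.uniform()
            rows.append({"gene": g, "log2fc": fc, "pvalue": p})
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue"])
    record = PlantingRecord(
        operons=[
            {"operon": op.operon_id, "sign": regulated.get(op.operon_id, 0)}
            for op in operons
        ],
        params={
            "effect_log2": effect_log2,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    return df, record
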