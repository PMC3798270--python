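"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython; the tabular formats (site tables, probe
tracks, read positions, operon/expression/TSS tables) are TSV handled with
pandas.  Weight matrices serialize to a small versioned TSV with header
comment lines so a scan is reproducible from the file alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import BASES, BindingSiteCall, InformationWeightMatrix

MATRIX_FORMAT_VERSION = 1


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_matrix(matrix: InformationWeightMatrix, path: str | Path) -> None:
    """Versioned TSV: header comments carry n, e_n, pseudocount, offset."""
    with open(path, "w") as fh:
        fh.write(f"# regulonscan-matrix\tv{MATRIX_FORMAT_VERSION}\n")
        fh.write(f"# n\t{matrix.n}\n")
        fh.write(f"# e_n\t{matrix.e_n!r}\n")
        fh.write(f"# pseudocount\t{matrix.pseudocount!r}\n")
        fh.write(f"# offset\t{matrix.offset}\n")
        fh.write(f"# corrected\t{int(matrix.corrected)}\n")
        fh.write("col\t" + "\t".join(f"f_{b}" for b in BASES) + "\n")
        for l in range(matrix.length):
            row = "\t".join(repr(float(v)) for v in matrix.freqs[l])
            fh.write(f"{l}\t{row}\n")


def read_matrix(path: str | Path) -> InformationWeightMatrix:
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    header[parts[0]] = parts[1]
                continue
            if line.startswith("col"):
                continue
            fields = line.split("\t")
            rows.append([float(x) for x in fields[1:5]])
    freqs = np.array(rows)
    e_n = float(header["e_n"])
    corrected = bool(int(header.get("corrected", "1")))
    with np.errstate(divide="ignore"):
        riw = 2.0 + np.log2(freqs) - (e_n if corrected else 0.0)
    return InformationWeightMatrix(
        freqs=freqs,
        n=int(header["n"]),
        e_n=e_n,
        riw=riw,
        pseudocount=float(header["pseudocount"]),
        offset=int(header.get("offset", "0")),
        corrected=corrected,
    )


def calls_to_frame(calls: Sequence[BindingSiteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "ri_bits": c.ri_bits,
            }
            for c in calls
        ],
        columns=["chrom", "start", "end", "strand", "ri_bits"],
    )


def write_calls_tsv(
    calls: Sequence[BindingSiteCall],
    path: str | Path,
    genome: Mapping[str, str] | None = None,
) -> None:
    df = calls_to_frame(calls)
    if genome is not None:
        df["seq"] = [c.sequence(genome) for c in calls]
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[BindingSiteCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        BindingSiteCall(
            str(r.chrom), int(r.start), int(r.end), str(r.strand), float(r.ri_bits)
        )
        for r in df.itertuples()
    ]


def write_calls_bed(calls: Sequence[BindingSiteCall], path: str | Path) -> None:
    """BED6; the score column holds Ri in bits."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tsite_{i}\t"
                f"{c.ri_bits:.4f}\t{c.strand}\n"
            )


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bedgraph(
    chrom: str, values: np.ndarray, path: str | Path, start: int = 0
) -> None:
    """Dense per-bp values -> run-length-merged bedGraph."""
    vals = np.asarray(values)
    with open(path, "w") as fh:
        if vals.size == 0:
            return
        boundaries = np.nonzero(np.diff(vals))[0] + 1
        edges = np.concatenate([[0], boundaries, [vals.size]])
        for a, b in zip(edges[:-1], edges[1:]):
            fh.write(f"{chrom}\t{start + a}\t{start + b}\t{vals[a]:g}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_site_alignment_tsv(
    path: str | Path, seq_column: str = "seq", offset: int = 0
):
    """Aligned-site TSV (one site sequence per row) -> SiteAlignment.

    The file needs a ``seq`` column; an optional single-column file without
    a header is also accepted.
    """
    from .motif import SiteAlignment

    df = pd.read_csv(path, sep="\t")
    if seq_column not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None, names=[seq_column])
    seqs = tuple(str(s).strip().upper() for s in df[seq_column])
    return SiteAlignment(seqs, offset=offset)
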