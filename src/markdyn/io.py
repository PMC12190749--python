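"""Readers and writers for the plain-text formats the pipeline consumes.

Everything tabular is TSV with a header; nested reports are JSON.  All
genomic formats are 0-based half-open on disk (BED conventions); the
GTF-subset reader converts from GTF's 1-based inclusive coordinates.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .consensus import ReplicatePeak
from .genes import GeneModel
from .intervals import GenomicInterval

PathLike = Union[str, Path]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- narrowPeak

_NARROWPEAK_COLS = 10


def read_narrowpeak(path: PathLike) -> list[ReplicatePeak]:
    """ENCODE narrowPeak: 10 columns, col 7 signalValue, col 9 qValue (-log10)."""
    peaks: list[ReplicatePeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != _NARROWPEAK_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_NARROWPEAK_COLS} columns, "
                    f"got {len(parts)}"
                )
            try:
                chrom, start, end, name, _score, strand = parts[:6]
                signal = float(parts[6])
                neglog10_q = float(parts[8])
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(
                ReplicatePeak(iv, neglog10_q=neglog10_q, signal=signal, name=name)
            )
    return peaks


def write_narrowpeak(path: PathLike, peaks: Iterable[ReplicatePeak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        p.name or ".",
                        "0",
                        iv.strand,
                        f"{p.signal:g}",
                        "-1",
                        f"{p.neglog10_q:g}",
                        "-1",
                    ]
                )
                + "\n"
            )


# --------------------------------------------------------------------- BED6


def read_bed6(path: PathLike) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            try:
                out.append(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed6(
    path: PathLike,
    intervals: Iterable[GenomicInterval],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = f"{scores[i]:g}" if scores is not None else "0"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# -------------------------------------------------------------- gene models

_GENE_COLS = ["gene_id", "symbol", "chrom", "strand", "tx_start", "tx_end", "biotype"]


def read_gene_table(path: PathLike) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing gene table columns {missing}")
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            symbol=None if pd.isna(r.symbol) else str(r.symbol),
            chrom=str(r.chrom),
            strand=str(r.strand),
            tx_start=int(r.tx_start),
            tx_end=int(r.tx_end),
            biotype=str(r.biotype),
        )
        for r in df.itertuples()
    ]


def write_gene_table(path: PathLike, genes: Iterable[GeneModel]) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "symbol": g.symbol or g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tx_start": g.tx_start,
            "tx_end": g.tx_end,
            "biotype": g.biotype,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_COLS).to_csv(path, sep="\t", index=False)


def read_gtf_genes(path: PathLike) -> list[GeneModel]:
    """Read 'gene' feature lines of a GTF subset (1-based inclusive -> 0-based half-open)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            if feature != "gene":
                continue
            attr = {}
            for item in attrs.strip().strip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attr[key] = val.strip().strip('"')
            if "gene_id" not in attr:
                raise ParseError(f"{path}:{lineno}: gene line without gene_id")
            genes.append(
                GeneModel(
                    gene_id=attr["gene_id"],
                    symbol=attr.get("gene_name"),
                    chrom=chrom,
                    strand=strand,
                    tx_start=int(start) - 1,
                    tx_end=int(end),
                    biotype=attr.get("gene_biotype", "protein_coding"),
                )
            )
    return genes


# -------------------------------------------------------------------- FASTA


def write_fasta(path: PathLike, genome: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: PathLike) -> dict[str, str]:
    """Whole-genome dict via pyfaidx (suitable for the miniature genomes here)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


# --------------------------------------------------------------- expression


def read_expression(path: PathLike) -> pd.DataFrame:
    """TSV gene_id x timepoint abundance matrix (first column = gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative abundance values")
    return df


def write_expression(path: PathLike, expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


# ---------------------------------------------------------------------- GMT


def read_gmt(path: PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs set, description, >=1 gene"
                )
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path: PathLike, sets: Mapping[str, Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# --------------------------------------------------------------- MEME motifs


def read_meme_motifs(path: PathLike):
    """Parse MEME minimal format into PWMs.

    Only the pieces the scanner needs: the alphabet (must be ACGT),
    optional background frequencies, and per-MOTIF letter-probability
    matrices.
    """
    from .motifs import PWM

    background = np.full(4, 0.25)
    pwms = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
            background /= background.sum()
        elif line.startswith("MOTIF"):
            fields = line.split()
            motif_id = fields[1] if len(fields) > 1 else f"motif{len(pwms) + 1}"
            # find the letter-probability header before the next MOTIF
            j = i + 1
            header = None
            while j < len(lines):
                s = lines[j].strip()
                if s.startswith("letter-probability matrix"):
                    header = s
                    break
                if s.startswith("MOTIF"):
                    break
                j += 1
            if header is None:
                raise ParseError(f"{path}: motif {motif_id} lacks a letter-probability matrix")
            tokens = header.replace("=", " = ").split()
            width = None
            for k, tok in enumerate(tokens):
                if tok == "w" and k + 2 < len(tokens):
                    width = int(tokens[k + 2])
            rows = []
            j += 1
            while j < len(lines) and len(rows) < (width or 10**9):
                s = lines[j].strip()
                if not s:
                    if width is None:
                        break
                    j += 1
                    continue
                vals = s.split()
                if len(vals) != 4:
                    break
                rows.append([float(v) for v in vals])
                j += 1
            if width is not None and len(rows) != width:
                raise ParseError(
                    f"{path}: motif {motif_id}: expected {width} matrix rows, got {len(rows)}"
                )
            mat = np.array(rows).T  # 4 x w, rows A,C,G,T
            sums = mat.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 0.05):
                warnings.warn(
                    f"motif {motif_id}: probability rows deviate from sum 1; renormalizing"
                )
            pwms.append(PWM(motif_id=motif_id, matrix=mat, background=background))
            i = j - 1
        i += 1
    if not pwms:
        warnings.warn(f"{path}: no MOTIF blocks found")
    return pwms


def write_meme_motifs(path: PathLike, pwms, background: np.ndarray | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = background if background is not None else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip("ACGT", bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.matrix.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


# ------------------------------------------------------------- count matrix


def write_counts(path: PathLike, counts: "pd.DataFrame", library_sizes, norm_factors) -> None:
    counts.to_csv(path, sep="\t", index_label="peak_id")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "library_sizes": {k: int(v) for k, v in dict(library_sizes).items()},
                "norm_factors": {k: float(v) for k, v in dict(norm_factors).items()},
            },
            indent=2,
            sort_keys=True,
        )
    )


def read_counts(path: PathLike):
    counts = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    lib = pd.Series(sidecar["library_sizes"], dtype=float)[counts.columns]
    nf = pd.Series(sidecar["norm_factors"], dtype=float)[counts.columns]
    return counts, lib, nf
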