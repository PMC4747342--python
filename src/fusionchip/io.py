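"""Readers and writers for the pipeline's file formats.

All tabular outputs are TSV with ``#``-prefixed metadata headers.  BED is
0-based half-open natively; the refFlat-like gene table is 0-based
half-open too, with an ``one_based`` flag for tables using 1-based starts.
Peak BED files carry the mode in the thickStart column (column 7); on read
a missing mode defaults to the interval midpoint.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .de import HomologMap
from .enrich import GeneSet
from .intervals import GeneModel, GenomicInterval, Peak
from .motifs import PWM

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_refflat",
    "write_refflat",
    "read_gtf",
    "read_meme",
    "write_meme",
    "read_gmt",
    "write_gmt",
    "read_de_table",
    "write_de_table",
    "read_homolog_map",
    "write_homolog_map",
    "read_gene_list",
    "write_tsv",
    "write_manifest",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------- BED peaks

def read_peaks_bed(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 and f[3] != "." else f"peak_{ln}"
                score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
                mode = int(f[6]) if len(f) > 6 else (start + end) // 2
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: malformed BED line: {e}") from None
            peaks.append(Peak(name, GenomicInterval(chrom, start, end), mode, score))
    return peaks


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}\t.\t{p.mode}\n"
            )


# ---------------------------------------------------------------- gene models

REFFLAT_COLUMNS = (
    "gene_id chrom strand txStart txEnd exonStarts exonEnds cdsStart cdsEnd".split()
)


def read_refflat(path, one_based: bool = False) -> list[GeneModel]:
    off = 1 if one_based else 0
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{ln}: expected 9 columns")
            try:
                estarts = [int(x) - off for x in f[5].rstrip(",").split(",")]
                eends = [int(x) for x in f[6].rstrip(",").split(",")]
                genes.append(
                    GeneModel(
                        gene_id=f[0],
                        chrom=f[1],
                        strand=f[2],
                        start=int(f[3]) - off,
                        end=int(f[4]),
                        exons=tuple(zip(estarts, eends)),
                        cds_start=int(f[7]) - off,
                        cds_end=int(f[8]),
                    )
                )
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: malformed gene line: {e}") from None
    return genes


def write_refflat(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(REFFLAT_COLUMNS) + "\n")
        for g in genes:
            estarts = ",".join(str(s) for s, _ in g.exons)
            eends = ",".join(str(e) for _, e in g.exons)
            cs = g.cds_start if g.cds_start is not None else g.start
            ce = g.cds_end if g.cds_end is not None else g.start
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}"
                f"\t{estarts}\t{eends}\t{cs}\t{ce}\n"
            )


def read_gtf(path) -> list[GeneModel]:
    """Build gene models from a GTF (exon and CDS features, 1-based closed)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        rec = by_gene.setdefault(
            gid, {"chrom": feat.seqid, "strand": feat.strand, "exons": [], "cds": []}
        )
        seg = (feat.start - 1, feat.end)  # to 0-based half-open
        rec["exons" if feat.featuretype == "exon" else "cds"].append(seg)
    genes = []
    for gid, rec in by_gene.items():
        exons = sorted(rec["exons"])
        if not exons:
            continue
        cds = sorted(rec["cds"])
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=exons[0][0],
                end=exons[-1][1],
                exons=tuple(exons),
                cds_start=cds[0][0] if cds else exons[0][0],
                cds_end=cds[-1][1] if cds else exons[0][0],
            )
        )
    return genes


# ---------------------------------------------------------------- MEME minimal

def read_meme(path) -> list[PWM]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        counts = np.array(
            [[m.counts[base][i] for base in "ACGT"] for i in range(m.counts.length)],
            dtype=float,
        )
        probs = counts / counts.sum(axis=1, keepdims=True)
        bg = np.array([m.background[b] for b in "ACGT"], dtype=float)
        out.append(PWM(m.name, probs, bg / bg.sum()))
    return out


def write_meme(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg)
        )
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in p.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------- GMT

def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: GMT needs id, description, genes")
            sets.append(GeneSet(f[0], f[1], frozenset(g for g in f[2:] if g)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------- tables

def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "log2fc", "pvalue", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    return df


def write_de_table(df: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    write_tsv(df, path, meta)


def read_homolog_map(path) -> HomologMap:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene_a", "gene_b"])
    return HomologMap(zip(df["gene_a"].astype(str), df["gene_b"].astype(str)))


def write_homolog_map(hmap: HomologMap, path) -> None:
    with open(path, "w") as fh:
        for a in sorted(hmap.a_to_b):
            for b in sorted(hmap.a_to_b[a]):
                fh.write(f"{a}\t{b}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_tsv(df: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    """Write a TSV with '#key=value' metadata lines before the header."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_manifest(path, **fields) -> None:
    """JSON run manifest: inputs, thresholds, seed, package version."""
    from . import __version__

    payload = {"package": "fusionchip", "version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
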