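"""Readers and writers for the standard formats at the package boundary.

Internally everything is 0-based half-open; conversion to/from the
1-based closed conventions of GTF and SAM happens here and only here.
SAM I/O goes through pysam (spot barcode in the ``CB`` tag, simulated
origin locus in a custom ``XT`` tag, no sequence), GTF reading through
pyranges, matrices through scipy's MatrixMarket support in the 10x-style
triplet layout (matrix.mtx + features.tsv + barcodes.tsv + positions
TSV).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import scipy.io as sio
import scipy.sparse as sp

from .coverage import BinnedCoverage
from .quantify import SpotMatrix, FEATURE_COLUMNS
from .segment import TAR
from .simulate import GenomeSpec, READ_COLUMNS

__all__ = [
    "write_chrom_sizes", "read_chrom_sizes",
    "write_gtf_genes", "read_gtf_genes",
    "write_bed6", "read_bed6", "tars_to_bed", "write_tar_table",
    "write_sam", "read_sam",
    "write_spot_layout", "read_spot_layout",
    "write_truth_loci", "read_truth_loci",
    "write_spot_matrix", "read_spot_matrix",
    "write_bedgraph",
]


# -- genome -----------------------------------------------------------------

def write_chrom_sizes(genome: GenomeSpec, path) -> None:
    """Two-column chrom.sizes stub (name, length); no sequence needed."""
    with open(path, "w") as fh:
        for name, length in genome.contigs:
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path) -> GenomeSpec:
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "length"])
    return GenomeSpec([(r.name, int(r.length)) for r in
                       df.itertuples(index=False)])


# -- GTF --------------------------------------------------------------------

def write_gtf_genes(loci: pd.DataFrame, path, source: str = "utarscan") -> None:
    """Write annotated loci as GTF ``gene`` features (1-based, closed)."""
    genes = loci[loci["annotated"]] if "annotated" in loci.columns else loci
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            attrs = f'gene_id "{g.id}"; gene_name "{g.id}";'
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gtf_genes(path) -> pd.DataFrame:
    """Read ``gene`` features from a GTF into 0-based half-open intervals."""
    import pyranges as pr

    gr = pr.read_gtf(str(path))
    df = gr.df
    df = df[df["Feature"] == "gene"]
    return pd.DataFrame(
        {
            "id": df["gene_id"].to_numpy(),
            "contig": df["Chromosome"].astype(str).to_numpy(),
            "start": df["Start"].to_numpy(dtype=np.int64),
            "end": df["End"].to_numpy(dtype=np.int64),
            "strand": df["Strand"].astype(str).to_numpy(),
        }
    ).reset_index(drop=True)


# -- BED --------------------------------------------------------------------

def write_bed6(df: pd.DataFrame, path) -> None:
    """Write a BED6-shaped frame (contig, start, end, name, score, strand)."""
    df[["contig", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
    )


def tars_to_bed(tars: list[TAR]) -> pd.DataFrame:
    """BED6 frame for TARs: name = sample:index, score = round(mean_cov)."""
    return pd.DataFrame(
        {
            "contig": [t.contig for t in tars],
            "start": [t.start for t in tars],
            "end": [t.end for t in tars],
            "name": [t.name or f"tar:{i}" for i, t in enumerate(tars)],
            "score": [int(round(t.mean_cov)) for t in tars],
            "strand": [t.strand for t in tars],
        }
    )


def write_tar_table(tars: list[TAR], path) -> None:
    """Full TAR table as TSV (coordinates plus class and database label)."""
    pd.DataFrame(
        {
            "name": [t.name for t in tars],
            "contig": [t.contig for t in tars],
            "start": [t.start for t in tars],
            "end": [t.end for t in tars],
            "strand": [t.strand for t in tars],
            "n_bins": [t.n_bins for t in tars],
            "mean_cov": [t.mean_cov for t in tars],
            "class": [t.tar_class for t in tars],
            "db_label": [t.db_label for t in tars],
        }
    ).to_csv(path, sep="\t", index=False)


# -- SAM --------------------------------------------------------------------

def write_sam(
    reads: pd.DataFrame, genome: GenomeSpec, path, sort: bool = False
) -> None:
    """Write simulated reads as minimal SAM.

    Mandatory 11 fields with ``SEQ``/``QUAL`` omitted (``*``), CIGAR
    ``<len>M``, barcode in ``CB``, origin locus id in ``XT``.  With
    ``sort=True`` records are written coordinate-sorted (``SO`` header
    set accordingly).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unsorted"},
        "SQ": [{"SN": n, "LN": int(ln)} for n, ln in genome.contigs],
    }
    order = {n: i for i, (n, _) in enumerate(genome.contigs)}
    df = reads
    if sort:
        key = df["contig"].map(order)
        df = df.assign(_k=key).sort_values(
            ["_k", "start"], kind="mergesort"
        ).drop(columns="_k")
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, r in enumerate(df.itertuples(index=False)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i:07d}"
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = order[r.contig]
            a.reference_start = int(r.start)
            a.mapping_quality = 60
            a.cigarstring = f"{int(r.length)}M"
            a.set_tag("CB", str(r.barcode))
            a.set_tag("XT", str(r.origin))
            a.set_tag("FL", int(r.fragment_length))
            out.write(a)


def read_sam(path) -> pd.DataFrame:
    """Read a SAM file into the internal reads table.

    Mapped records only; the 5'-relevant interval is the aligned
    reference span.  Barcodes come from ``CB`` (reads without one get an
    empty barcode, which downstream counts as off-tissue).
    """
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            rows.append(
                (
                    a.reference_name,
                    a.reference_start,
                    a.reference_end - a.reference_start,
                    "-" if a.is_reverse else "+",
                    a.get_tag("CB") if a.has_tag("CB") else "",
                    a.get_tag("XT") if a.has_tag("XT") else "",
                    a.get_tag("FL") if a.has_tag("FL") else 0,
                )
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


# -- spots / truth ----------------------------------------------------------

def write_spot_layout(spots: pd.DataFrame, path) -> None:
    spots[["barcode", "x", "y", "domain"]].to_csv(path, sep="\t", index=False)


def read_spot_layout(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_loci(loci: pd.DataFrame, path) -> None:
    loci.to_csv(path, sep="\t", index=False)


def read_truth_loci(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- matrix triplet ---------------------------------------------------------

def write_spot_matrix(matrix: SpotMatrix, outdir) -> None:
    """10x-style triplet: matrix.mtx, features.tsv, barcodes.tsv, positions.

    Integer matrices round-trip bit-exactly through the MatrixMarket
    writer; normalised (float) matrices are written in real format.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = matrix.counts.tocoo()
    if matrix.meta.get("normalized"):
        sio.mmwrite(str(outdir / "matrix.mtx"), counts)
    else:
        sio.mmwrite(str(outdir / "matrix.mtx"), counts.astype(np.int64),
                    field="integer")
    matrix.features[FEATURE_COLUMNS].to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(matrix.barcodes).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if matrix.coords is not None:
        matrix.coords.to_csv(outdir / "positions.tsv", sep="\t", index=False)


def read_spot_matrix(outdir) -> SpotMatrix:
    outdir = Path(outdir)
    counts = sp.csr_matrix(sio.mmread(str(outdir / "matrix.mtx")))
    features = pd.read_csv(
        outdir / "features.tsv", sep="\t", header=None, names=FEATURE_COLUMNS
    )
    barcodes = pd.read_csv(
        outdir / "barcodes.tsv", sep="\t", header=None
    )[0].astype(str).tolist()
    coords = None
    if (outdir / "positions.tsv").exists():
        coords = pd.read_csv(outdir / "positions.tsv", sep="\t")
    return SpotMatrix(
        features=features, barcodes=barcodes, counts=counts, coords=coords
    )


# -- coverage ---------------------------------------------------------------

def write_bedgraph(tracks: dict, path, strand: str) -> None:
    """One bedGraph (0-based half-open) per strand, nonzero bins only."""
    with open(path, "w") as fh:
        for (contig, s), track in sorted(tracks.items()):
            if s != strand:
                continue
            assert isinstance(track, BinnedCoverage)
            nz = np.flatnonzero(track.counts)
            bs = track.bin_size
            for b in nz:
                end = min((b + 1) * bs, track.contig_length)
                fh.write(f"{contig}\t{b * bs}\t{end}\t{track.counts[b]}\n")
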