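"""Classify TARs against gene annotation and lncRNA databases.

A TAR overlapping a reference gene by at least one base is an aTAR
(annotated); a TAR falling outside gene boundaries is a uTAR
(unannotated).  Gene overlap is strand-specific by default (matching the
strand-specific database overlap downstream), with an ``ignore`` mode
for unstranded annotation sets.  uTARs are then labelled by
strand-matched >=1-base overlap against two curated lncRNA reference
sets (FANTOM-like "db1" and LncExpDB-like "db2"): ``novel`` / ``db1`` /
``db2`` / ``both``.  Cross-sample sharing of uTARs is computed as
connected components of the strand-matched overlap graph, so "shared by
k samples" is well defined under chained overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd
from intervaltree import IntervalTree

from .segment import TAR

__all__ = [
    "AnnotationSet",
    "SharingTable",
    "classify_tars",
    "overlap_databases",
    "classification_report",
    "share_across_samples",
]


def _build_trees(df: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in df.itertuples(index=False):
        key = (row.contig, row.strand)
        trees.setdefault(key, IntervalTree()).addi(
            int(row.start), int(row.end), getattr(row, "name", None) or
            getattr(row, "id", None)
        )
    return trees


@dataclass
class AnnotationSet:
    """Reference genes with per-(contig, strand) interval indexes."""

    genes: pd.DataFrame  # columns: id, contig, start, end, strand (0-based ho)
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"id", "contig", "start", "end", "strand"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"annotation is missing columns: {missing}")
        self._trees = {}
        for row in self.genes.itertuples(index=False):
            key = (row.contig, row.strand)
            self._trees.setdefault(key, IntervalTree()).addi(
                int(row.start), int(row.end), row.id
            )

    @classmethod
    def from_gtf(cls, path) -> "AnnotationSet":
        from .io import read_gtf_genes

        return cls(read_gtf_genes(path))

    @classmethod
    def from_loci(cls, loci: pd.DataFrame) -> "AnnotationSet":
        """Annotation from a simulation truth table (annotated rows only)."""
        genes = loci.loc[
            loci["annotated"], ["id", "contig", "start", "end", "strand"]
        ].reset_index(drop=True)
        return cls(genes)

    def overlapping(
        self, contig: str, start: int, end: int, strand: str | None = None
    ) -> list[str]:
        """Gene ids overlapping [start, end); all strands if strand None."""
        strands = ("+", "-") if strand is None else (strand,)
        hits = []
        for s in strands:
            tree = self._trees.get((contig, s))
            if tree is not None:
                hits.extend(iv.data for iv in tree.overlap(start, end))
        return hits


def classify_tars(
    tars: list[TAR],
    annotation: AnnotationSet,
    strand_mode: str = "specific",
    min_overlap: int = 1,
) -> list[TAR]:
    """Label every TAR as aTAR or uTAR by gene overlap.

    ``strand_mode='specific'`` (default) requires the overlapping gene to
    share the TAR's strand; ``'ignore'`` accepts either strand.  A TAR is
    an aTAR iff its overlap with some gene is at least ``min_overlap``
    bases (default 1).  Returns new TAR objects; every TAR is labelled
    exactly once.
    """
    if strand_mode not in ("specific", "ignore"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    out = []
    for t in tars:
        strand = t.strand if strand_mode == "specific" else None
        strands = ("+", "-") if strand is None else (strand,)
        hit = False
        for s in strands:
            tree = annotation._trees.get((t.contig, s))
            if tree is None:
                continue
            for iv in tree.overlap(t.start, t.end):
                if min(t.end, iv.end) - max(t.start, iv.begin) >= min_overlap:
                    hit = True
                    break
            if hit:
                break
        out.append(replace(t, tar_class="aTAR" if hit else "uTAR"))
    return out


def overlap_databases(
    utars: list[TAR],
    db1: pd.DataFrame,
    db2: pd.DataFrame,
    min_overlap: int = 1,
) -> list[TAR]:
    """Label uTARs by strand-specific overlap with two lncRNA databases.

    ``db1`` / ``db2`` are BED6-shaped frames (contig, start, end, name,
    score, strand).  A uTAR overlapping (>= ``min_overlap`` bases, same
    strand) only db1 is labelled ``db1``, only db2 ``db2``, both
    ``both``, neither ``novel``.  Inputs must all be uTARs.
    """
    bad = [t for t in utars if t.tar_class != "uTAR"]
    if bad:
        raise ValueError(
            f"overlap_databases expects uTARs only; got class "
            f"{bad[0].tar_class!r}"
        )
    trees = [_build_trees(db1), _build_trees(db2)]
    out = []
    for t in utars:
        hits = []
        for tr in trees:
            tree = tr.get((t.contig, t.strand))
            hit = False
            if tree is not None:
                for iv in tree.overlap(t.start, t.end):
                    if min(t.end, iv.end) - max(t.start, iv.begin) >= min_overlap:
                        hit = True
                        break
            hits.append(hit)
        label = {
            (False, False): "novel",
            (True, False): "db1",
            (False, True): "db2",
            (True, True): "both",
        }[tuple(hits)]
        out.append(replace(t, db_label=label))
    return out


def classification_report(tars: list[TAR]) -> dict:
    """Tallies per class and per database label.

    Returns ``n_total``, ``n_atar``, ``n_utar``, per-db_label counts and
    ``frac_utar_in_db`` (fraction of uTARs found in at least one
    database).
    """
    n_atar = sum(t.tar_class == "aTAR" for t in tars)
    n_utar = sum(t.tar_class == "uTAR" for t in tars)
    db_counts = {k: 0 for k in ("novel", "db1", "db2", "both")}
    for t in tars:
        if t.tar_class == "uTAR" and t.db_label in db_counts:
            db_counts[t.db_label] += 1
    in_db = db_counts["db1"] + db_counts["db2"] + db_counts["both"]
    return {
        "n_total": len(tars),
        "n_atar": int(n_atar),
        "n_utar": int(n_utar),
        "db_counts": db_counts,
        "frac_utar_in_db": (in_db / n_utar) if n_utar else 0.0,
    }


@dataclass
class SharingTable:
    """uTAR sharing across samples via overlap connected components."""

    components: list[dict]      # {"members": [(sample, TAR), ...],
                                #  "samples": sorted list of sample names}
    counts: dict[int, int]      # cardinality -> number of components

    @property
    def n_components(self) -> int:
        return len(self.components)

    def to_frame(self) -> pd.DataFrame:
        """One row per shared unit: interval hull, samples, cardinality."""
        rows = []
        for c in self.components:
            tars = [t for _, t in c["members"]]
            rows.append(
                {
                    "contig": tars[0].contig,
                    "start": min(t.start for t in tars),
                    "end": max(t.end for t in tars),
                    "strand": tars[0].strand,
                    "n_samples": len(c["samples"]),
                    "samples": ",".join(c["samples"]),
                    "n_utars": len(tars),
                }
            )
        return pd.DataFrame(
            rows, columns=["contig", "start", "end", "strand", "n_samples",
                           "samples", "n_utars"]
        )


def share_across_samples(utar_sets: dict[str, list[TAR]]) -> SharingTable:
    """Group uTARs from multiple samples into shared units.

    Nodes are uTARs; edges join strand-matched, >=1-base-overlapping
    uTARs from *different* samples; connected components are the shared
    units.  ``counts[k]`` is the number of components spanning exactly
    ``k`` distinct samples.  Requires at least two samples.  The result
    is invariant to sample input order.
    """
    if len(utar_sets) < 2:
        raise ValueError("sharing requires at least two samples")
    graph = nx.Graph()
    trees: dict[tuple[str, str], IntervalTree] = {}
    for sample in sorted(utar_sets):
        for i, t in enumerate(utar_sets[sample]):
            node = (sample, i)
            graph.add_node(node)
            key = (t.contig, t.strand)
            tree = trees.setdefault(key, IntervalTree())
            for iv in tree.overlap(t.start, t.end):
                other_sample, _ = iv.data
                if other_sample != sample:
                    graph.add_edge(node, iv.data)
            tree.addi(t.start, t.end, node)

    components = []
    counts: dict[int, int] = {}
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        samples = sorted({s for s, _ in members})
        components.append(
            {
                "members": [(s, utar_sets[s][i]) for s, i in members],
                "samples": samples,
            }
        )
    components.sort(
        key=lambda c: (c["members"][0][1].contig,
                       c["members"][0][1].start,
                       c["members"][0][1].strand)
    )
    for c in components:
        k = len(c["samples"])
        counts[k] = counts.get(k, 0) + 1
    return SharingTable(components=components, counts=counts)
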