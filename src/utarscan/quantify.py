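"""Feature x spot count matrices and per-spot QC metrics.

Reads are assigned to features (genes + uTARs) by the position of their
5' end, consistent with the coverage binning: a read belongs to the
strand-matched feature whose interval contains its 5' end.  If that
position hits several features, the read goes to the feature with the
longest overlap with the *full* read interval; exact ties are discarded
as ambiguous.  Reads whose barcode is not in the spot layout are counted
as off-tissue and excluded from the matrix.  The identity

    assigned + unassigned + ambiguous + off_tissue == total reads

is returned with every quantification and asserted by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

__all__ = [
    "SpotMatrix",
    "AssignmentStats",
    "QCSummary",
    "features_from_annotation",
    "count_features_per_spot",
    "qc_metrics",
    "lognormalize",
]

FEATURE_COLUMNS = ["id", "kind", "contig", "start", "end", "strand"]


class AssignmentStats(NamedTuple):
    assigned: int
    unassigned: int
    ambiguous: int
    off_tissue: int

    @property
    def total(self) -> int:
        return sum(self)


@dataclass
class SpotMatrix:
    """Sparse features x spot-barcodes count matrix with coordinates."""

    features: pd.DataFrame          # FEATURE_COLUMNS
    barcodes: list[str]
    counts: sp.csr_matrix           # features x barcodes
    coords: pd.DataFrame | None = None  # barcode, x, y
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.barcodes) != len(set(self.barcodes)):
            raise ValueError("barcodes must be unique")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.features), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.features)} features x {len(self.barcodes)} barcodes"
            )
        # raw count matrices must be nonnegative; float matrices may hold
        # derived values (normalised expression, residuals)
        if (self.counts.nnz and self.counts.dtype.kind in "iu"
                and self.counts.data.min() < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def feature_index(self, feature_id: str) -> int:
        idx = np.flatnonzero((self.features["id"] == feature_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"feature {feature_id!r} not present in the matrix")
        return int(idx[0])

    def row(self, feature_id: str) -> np.ndarray:
        """Dense per-spot vector of one feature."""
        return np.asarray(
            self.counts[self.feature_index(feature_id)].todense()
        ).ravel()

    def to_anndata(self):
        """Spots x features AnnData (optional dependency)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=self.features.set_index("id"),
        )
        if self.coords is not None:
            xy = self.coords.set_index("barcode").loc[self.barcodes, ["x", "y"]]
            adata.obsm["spatial"] = xy.to_numpy()
        return adata


def features_from_annotation(genes: pd.DataFrame, utars) -> pd.DataFrame:
    """Combine genes and uTARs into one feature table.

    ``genes`` has columns id/contig/start/end/strand; ``utars`` is a list
    of TARs (their names become feature ids of kind ``uTAR``).
    """
    rows = [
        (g.id, "gene", g.contig, int(g.start), int(g.end), g.strand)
        for g in genes.itertuples(index=False)
    ]
    for i, t in enumerate(utars):
        fid = t.name or f"uTAR:{t.contig}:{t.start}-{t.end}:{t.strand}"
        rows.append((fid, "uTAR", t.contig, t.start, t.end, t.strand))
    feats = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if feats["id"].duplicated().any():
        raise ValueError("feature ids must be unique")
    return feats


def _disjoint_within_groups(feats: pd.DataFrame) -> bool:
    for _, grp in feats.groupby(["contig", "strand"], sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            return False
    return True


def count_features_per_spot(
    reads: pd.DataFrame,
    features: pd.DataFrame,
    layout: pd.DataFrame,
) -> tuple[SpotMatrix, AssignmentStats]:
    """Assign barcoded reads to features and build the count matrix.

    ``layout`` is the spot table (barcode, x, y[, domain]); barcodes not
    listed there are tallied as off-tissue.  See the module docstring for
    the assignment rule.  When the features are pairwise disjoint within
    each (contig, strand) — the usual case, since merged uTARs never
    overlap strand-matched genes — a vectorised interval lookup is used;
    otherwise a general interval-tree path with the longest-overlap tie
    rule takes over.  Both paths implement the same rule.
    """
    barcodes = list(layout["barcode"])
    bc_index = {b: i for i, b in enumerate(barcodes)}
    n_feat = len(features)

    contig = reads["contig"].to_numpy()
    start = reads["start"].to_numpy(dtype=np.int64)
    length = reads["length"].to_numpy(dtype=np.int64)
    strand = reads["strand"].to_numpy()
    five_prime = np.where(strand == "+", start, start + length - 1)
    read_bc = reads["barcode"].to_numpy()

    on_tissue = np.array([b in bc_index for b in read_bc])
    off_tissue = int((~on_tissue).sum())

    assign = np.full(len(reads), -1, dtype=np.int64)  # feature row or -1
    ambiguous = np.zeros(len(reads), dtype=bool)

    if _disjoint_within_groups(features):
        for (c, s), grp in features.groupby(["contig", "strand"], sort=False):
            g = grp.sort_values("start")
            fstart = g["start"].to_numpy()
            fend = g["end"].to_numpy()
            frows = g.index.to_numpy()
            mask = (contig == c) & (strand == s)
            if not mask.any():
                continue
            pos = five_prime[mask]
            j = np.searchsorted(fstart, pos, side="right") - 1
            ok = (j >= 0) & (pos < fend[np.clip(j, 0, None)])
            rows = np.flatnonzero(mask)[ok]
            assign[rows] = frows[j[ok]]
    else:
        trees: dict[tuple[str, str], IntervalTree] = {}
        for row in features.itertuples():
            trees.setdefault((row.contig, row.strand), IntervalTree()).addi(
                int(row.start), int(row.end), row.Index
            )
        for i in range(len(reads)):
            tree = trees.get((contig[i], strand[i]))
            if tree is None:
                continue
            hits = tree.at(int(five_prime[i]))
            if not hits:
                continue
            if len(hits) == 1:
                assign[i] = next(iter(hits)).data
                continue
            r0, r1 = int(start[i]), int(start[i] + length[i])
            best, best_ov, tie = -1, -1, False
            for iv in hits:
                ov = min(iv.end, r1) - max(iv.begin, r0)
                if ov > best_ov:
                    best, best_ov, tie = iv.data, ov, False
                elif ov == best_ov:
                    tie = True
            if tie:
                ambiguous[i] = True
            else:
                assign[i] = best

    countable = on_tissue & (assign >= 0) & ~ambiguous
    unassigned = int((on_tissue & (assign < 0) & ~ambiguous).sum())
    n_amb = int((on_tissue & ambiguous).sum())

    cols = np.array([bc_index[b] for b in read_bc[countable]], dtype=np.int64) \
        if countable.any() else np.array([], dtype=np.int64)
    mat = sp.coo_matrix(
        (
            np.ones(countable.sum(), dtype=np.int64),
            (assign[countable], cols),
        ),
        shape=(n_feat, len(barcodes)),
    ).tocsr()
    mat.sum_duplicates()

    coords = layout[["barcode", "x", "y"]].copy() if {"x", "y"} <= set(
        layout.columns
    ) else None
    sm = SpotMatrix(
        features=features.reset_index(drop=True),
        barcodes=barcodes,
        counts=mat,
        coords=coords,
        meta={"normalized": False},
    )
    stats = AssignmentStats(
        assigned=int(countable.sum()),
        unassigned=unassigned,
        ambiguous=n_amb,
        off_tissue=off_tissue,
    )
    assert stats.total == len(reads)
    return sm, stats


@dataclass
class QCSummary:
    """Per-spot and per-sample QC, as shown in standard ST QC panels."""

    per_spot: pd.DataFrame          # barcode, reads, features_detected
    total_features_detected: int    # features with >=1 count in >=1 spot
    median_features_per_spot: float
    median_reads_per_spot: float
    total_reads: int


def qc_metrics(matrix: SpotMatrix) -> QCSummary:
    """Reads and unique features detected per spot, plus sample totals."""
    counts = matrix.counts
    reads_per_spot = np.asarray(counts.sum(axis=0)).ravel()
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    per_spot = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "reads": reads_per_spot.astype(int),
            "features_detected": detected.astype(int),
        }
    )
    total_features = int(((counts > 0).sum(axis=1) > 0).sum())
    return QCSummary(
        per_spot=per_spot,
        total_features_detected=total_features,
        median_features_per_spot=float(np.median(detected)) if len(detected)
        else 0.0,
        median_reads_per_spot=float(np.median(reads_per_spot))
        if len(reads_per_spot) else 0.0,
        total_reads=int(reads_per_spot.sum()),
    )


def lognormalize(matrix: SpotMatrix) -> SpotMatrix:
    """Median-scaling log1p normalisation.

    ``value = log(1 + count * scale / spot_total)`` with ``scale`` the
    median spot total over spots with nonzero totals.  Zero-total spots
    are excluded from the result with a warning listing their barcodes
    (they carry no information and would divide by zero).  This is a
    deliberately simple stand-in for heavier spatial normalisations; the
    result is marked ``normalized`` in the matrix metadata.
    """
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    keep = totals > 0
    if not keep.any():
        raise ValueError("all spots have zero total counts; cannot normalise")
    if not keep.all():
        dropped = [b for b, k in zip(matrix.barcodes, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} zero-total spot(s): "
            + ", ".join(dropped),
            UserWarning,
        )
    scale = float(np.median(totals[keep]))
    sub = matrix.counts[:, keep].tocsc().astype(float)
    kept_totals = totals[keep]
    sub = sub.multiply(scale / kept_totals[None, :]).tocsr()
    sub.data = np.log1p(sub.data)
    coords = None
    kept_barcodes = [b for b, k in zip(matrix.barcodes, keep) if k]
    if matrix.coords is not None:
        coords = matrix.coords[matrix.coords["barcode"].isin(kept_barcodes)]
        coords = coords.reset_index(drop=True)
    return SpotMatrix(
        features=matrix.features,
        barcodes=kept_barcodes,
        counts=sub,
        coords=coords,
        meta={**matrix.meta, "normalized": True,
              "normalization": "median-scaling log1p", "scale": scale},
    )
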