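"""End-to-end orchestration: simulate -> bin -> segment -> classify ->
quantify -> QC -> DE -> concordance, plus evaluation against the
simulation ground truth.

A single master seed fans out into per-stage seeds (stage-name CRC-32
mixed with the master seed, see :func:`utarscan.simulate.derive_seed`),
so each stage is independently reproducible and the whole bundle is
byte-identical across runs with the same configuration.  Conservation
checks (reads in = binned counts; assigned + unassigned + ambiguous +
off-tissue = reads in) are asserted on every run and recorded in the
structured log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as tc
from . import coverage as cov
from . import de as de_mod
from . import io as uio
from . import quantify as qt
from . import segment as seg
from .simulate import (
    DOMAIN_KERATINOCYTE,
    KERATINOCYTE_MARKERS,
    SimConfig,
    fragment_and_place_reads,
    make_databases,
    make_genome,
    simulate_counts,
    simulate_spots,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "RecoveryReport",
    "run_pipeline",
    "recovery_eval",
    "truth_db_label",
]


@dataclass
class PipelineConfig:
    """Simulation settings plus every analysis knob of the pipeline."""

    sim: SimConfig = field(default_factory=SimConfig)
    bin_size: int = 50
    merge_gap: int = 500
    seg_mode: str = "hmm"          # {"hmm", "presence"}
    strand_mode: str = "specific"  # gene-overlap strandedness
    quantile: float = 0.75         # marker-signature labelling threshold
    alpha: float = 0.05            # significance level on BH-adjusted q
    min_detect_frac: float = 0.05
    markers: tuple[str, ...] = KERATINOCYTE_MARKERS
    outdir: str | None = None
    make_plots: bool = True

    def validate(self) -> None:
        self.sim.validate()
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be nonnegative")
        if self.seg_mode not in ("hmm", "presence"):
            raise ValueError(f"unknown seg_mode {self.seg_mode!r}")
        if self.strand_mode not in ("specific", "ignore"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["markers"] = list(self.markers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "markers" in d:
            d["markers"] = tuple(d["markers"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Digest of the scientific configuration (output location and
        plotting toggles excluded, so reruns elsewhere hash identically)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("make_plots", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RecoveryReport:
    """How well the run recovered the planted ground truth."""

    per_locus: pd.DataFrame        # planted lnc loci with match info
    precision: float
    recall: float
    precision_defined: bool        # False when no uTAR was called
    db_confusion: pd.DataFrame     # truth label x called label counts
    db_agreement: float            # fraction of matched pairs agreeing
    de_confusion: dict             # tp/fn/fp/tn on uTAR DE at q < alpha
    n_called_utars: int


@dataclass
class PipelineResult:
    config: PipelineConfig
    genome: object
    loci: pd.DataFrame
    db1: pd.DataFrame
    db2: pd.DataFrame
    spots: pd.DataFrame
    true_counts: pd.DataFrame
    reads: pd.DataFrame
    tracks: dict
    hmm_params: object | None
    tars: list
    utars: list
    report: dict                   # classification report
    matrix: qt.SpotMatrix
    norm_matrix: qt.SpotMatrix
    assignment: qt.AssignmentStats
    qc: qt.QCSummary
    scores: pd.Series
    labels: pd.Series
    de_table: pd.DataFrame
    concordance: pd.DataFrame
    recovery: RecoveryReport
    log: list[dict]


def truth_db_label(row) -> str:
    """Expected database label of a planted unannotated locus."""
    return {
        (False, False): "novel",
        (True, False): "db1",
        (False, True): "db2",
        (True, True): "both",
    }[(bool(row.in_db1), bool(row.in_db2))]


def recovery_eval(
    utars: list,
    de_table: pd.DataFrame,
    loci: pd.DataFrame,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Match called uTARs to planted unannotated loci and score the run.

    A called uTAR matches a planted locus iff they share the strand and
    their overlap covers at least 50 % of the planted length.  Precision
    is the fraction of called uTARs with a match, recall the fraction of
    planted loci matched; with no called uTARs recall is 0 and precision
    is reported as 0 with ``precision_defined=False``.  The database
    confusion table compares called ``db_label`` with the planted flags,
    and the DE confusion compares planted cell-type effects with uTARs
    significant at ``q < alpha``.
    """
    truth = loci[~loci["annotated"]].reset_index(drop=True)
    sig = set()
    if len(de_table):
        sig = set(de_table.loc[de_table["q"] < alpha, "feature"])

    matched_of_utar: dict[int, list[int]] = {i: [] for i in range(len(utars))}
    rows = []
    for li, locus in truth.iterrows():
        plen = locus.end - locus.start
        best_u, best_ov = None, 0
        for ui, t in enumerate(utars):
            if t.contig != locus.contig or t.strand != locus.strand:
                continue
            ov = t.overlap(int(locus.start), int(locus.end))
            if ov * 2 >= plen and ov > best_ov:
                best_u, best_ov = ui, ov
        if best_u is not None:
            matched_of_utar[best_u].append(li)
        rows.append(
            {
                "id": locus.id,
                "contig": locus.contig,
                "start": int(locus.start),
                "end": int(locus.end),
                "strand": locus.strand,
                "matched": best_u is not None,
                "utar": utars[best_u].name if best_u is not None else "",
                "truth_db": truth_db_label(locus),
                "called_db": utars[best_u].db_label
                if best_u is not None else "",
                "planted_de": bool(locus.celltype_effect != 1.0),
                "called_de": (utars[best_u].name in sig)
                if best_u is not None else False,
            }
        )
    per_locus = pd.DataFrame(rows)

    n_matched_utars = sum(bool(v) for v in matched_of_utar.values())
    precision_defined = len(utars) > 0
    precision = n_matched_utars / len(utars) if utars else 0.0
    recall = per_locus["matched"].mean() if len(per_locus) else 0.0

    matched = per_locus[per_locus["matched"]]
    labels = ["novel", "db1", "db2", "both"]
    db_confusion = pd.crosstab(
        matched["truth_db"], matched["called_db"]
    ).reindex(index=labels, columns=labels, fill_value=0) if len(matched) \
        else pd.DataFrame(0, index=labels, columns=labels)
    db_agreement = (
        float((matched["truth_db"] == matched["called_db"]).mean())
        if len(matched) else 0.0
    )

    tp = int((per_locus["planted_de"] & per_locus["called_de"]).sum())
    fn = int((per_locus["planted_de"] & ~per_locus["called_de"]).sum())
    # false DE: significant uTARs not matching any planted DE locus
    de_truth_names = set(
        per_locus.loc[per_locus["planted_de"] & per_locus["matched"], "utar"]
    )
    sig_utars = {t.name for t in utars if t.name in sig}
    fp = len(sig_utars - de_truth_names)
    tn = sum(
        1 for t in utars
        if t.name not in sig_utars and t.name not in de_truth_names
    )
    de_confusion = {"tp": tp, "fn": fn, "fp": fp, "tn": tn}

    return RecoveryReport(
        per_locus=per_locus,
        precision=float(precision),
        recall=float(recall),
        precision_defined=precision_defined,
        db_confusion=db_confusion,
        db_agreement=db_agreement,
        de_confusion=de_confusion,
        n_called_utars=len(utars),
    )


def _plot_spatial(spots: pd.DataFrame, values: pd.Series, title: str, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    merged = spots.set_index("barcode").join(values.rename("v"), how="left")
    fig, ax = plt.subplots(figsize=(6, 3.2))
    sc = ax.scatter(merged["x"], merged["y"], c=merged["v"], s=36,
                    cmap="viridis")
    fig.colorbar(sc, ax=ax, label=title)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on one simulated sample and evaluate recovery.

    With ``config.outdir`` set, all stage outputs (chrom.sizes, GTF,
    BED, SAM, layout and truth TSVs, MTX triplet, TAR/DE/QC tables,
    spatial maps, JSON-lines log, config + hash) are written there.
    Identical configurations produce byte-identical tables.
    """
    config.validate()
    log: list[dict] = []
    t0 = time.perf_counter()

    def stage(name, **extra):
        log.append(
            {"stage": name, "elapsed_s": round(time.perf_counter() - t0, 4),
             **extra}
        )

    # 1. simulation
    genome, loci = make_genome(config.sim)
    db1, db2 = make_databases(loci, config.sim)
    spots = simulate_spots(config.sim)
    true_counts = simulate_counts(loci, spots, config.sim)
    reads = fragment_and_place_reads(true_counts, loci, config.sim)
    expected_reads = int(true_counts.to_numpy().sum()) * \
        config.sim.reads_per_count
    if len(reads) != expected_reads:
        raise AssertionError("read-count conservation violated in simulation")
    stage("simulate", n_reads=len(reads), n_loci=len(loci),
          n_spots=len(spots), reads_conserved=True)

    # 2. binning
    tracks = cov.bin_reads(reads, genome, bin_size=config.bin_size)
    binned_total = int(sum(t.counts.sum() for t in tracks.values()))
    if binned_total != len(reads):
        raise AssertionError("binned counts do not equal the input reads")
    stage("bin", total_binned=binned_total, binned_conserved=True)

    # 3. segmentation
    tars, hmm_params = seg.segment_tracks(
        tracks, mode=config.seg_mode, max_gap=config.merge_gap,
        sample=f"sim{config.sim.seed}",
    )
    stage("call-tars", n_tars=len(tars), mode=config.seg_mode,
          hmm_iterations=getattr(hmm_params, "n_iter", None))

    # 4. classification
    ann = tc.AnnotationSet.from_loci(loci)
    tars = tc.classify_tars(tars, ann, strand_mode=config.strand_mode)
    utars = [t for t in tars if t.tar_class == "uTAR"]
    utars = tc.overlap_databases(utars, db1, db2)
    by_name = {t.name: t for t in utars}
    tars = [by_name.get(t.name, t) for t in tars]
    report = tc.classification_report(tars)
    stage("classify", **{k: v for k, v in report.items() if k != "db_counts"})

    # 5. quantification + QC
    genes = loci.loc[loci["annotated"],
                     ["id", "contig", "start", "end", "strand"]]
    features = qt.features_from_annotation(genes, utars)
    matrix, assignment = qt.count_features_per_spot(reads, features, spots)
    qc = qt.qc_metrics(matrix)
    stage("quantify", **assignment._asdict(),
          assignment_conserved=assignment.total == len(reads))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        norm = qt.lognormalize(matrix)
    stage("normalize", n_spots_kept=len(norm.barcodes))

    # 6. marker labelling + DE on uTAR features
    scores = de_mod.signature_score(norm, list(config.markers))
    labels = de_mod.label_spots(scores, quantile=config.quantile)
    utar_rows = np.flatnonzero((norm.features["kind"] == "uTAR").to_numpy())
    utar_matrix = qt.SpotMatrix(
        features=norm.features.iloc[utar_rows].reset_index(drop=True),
        barcodes=norm.barcodes,
        counts=norm.counts[utar_rows, :],
        coords=norm.coords,
        meta=norm.meta,
    )
    if len(utar_rows):
        de_table = de_mod.wilcoxon_de(
            utar_matrix, labels, min_detect_frac=config.min_detect_frac,
            alpha=config.alpha,
        )
    else:
        de_table = pd.DataFrame(
            columns=["feature", "kind", "n1", "n2", "U", "p", "q", "log2fc",
                     "direction", "significant"]
        )
    stage("de", n_tested=len(de_table),
          n_significant=int(de_table["significant"].sum())
          if len(de_table) else 0)

    # 7. spatial concordance of significant uTARs with the signature
    conc_rows = []
    for f in de_table.loc[de_table["significant"], "feature"]:
        res = de_mod.spatial_concordance(scores, utar_matrix.row(f))
        conc_rows.append((f, res.rho, res.p, res.n, res.defined))
    concordance = pd.DataFrame(
        conc_rows, columns=["feature", "rho", "p", "n", "defined"]
    )
    stage("concordance", n_features=len(concordance))

    # 8. truth evaluation
    recovery = recovery_eval(utars, de_table, loci, alpha=config.alpha)
    stage("recovery", precision=recovery.precision, recall=recovery.recall,
          db_agreement=recovery.db_agreement, **recovery.de_confusion)

    result = PipelineResult(
        config=config, genome=genome, loci=loci, db1=db1, db2=db2,
        spots=spots, true_counts=true_counts, reads=reads, tracks=tracks,
        hmm_params=hmm_params, tars=tars, utars=utars, report=report,
        matrix=matrix, norm_matrix=norm, assignment=assignment, qc=qc,
        scores=scores, labels=labels, de_table=de_table,
        concordance=concordance, recovery=recovery, log=log,
    )
    if config.outdir is not None:
        _write_bundle(result, Path(config.outdir))
    return result


def _write_bundle(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    uio.write_chrom_sizes(res.genome, outdir / "genome.chrom.sizes")
    uio.write_gtf_genes(res.loci, outdir / "annotation.gtf")
    uio.write_bed6(res.db1, outdir / "db1.bed")
    uio.write_bed6(res.db2, outdir / "db2.bed")
    uio.write_spot_layout(res.spots, outdir / "spots.tsv")
    uio.write_truth_loci(res.loci, outdir / "truth_loci.tsv")
    res.true_counts.to_csv(outdir / "truth_counts.tsv", sep="\t")
    uio.write_sam(res.reads, res.genome, outdir / "reads.sam")
    uio.write_sam(res.reads, res.genome, outdir / "reads.sorted.sam",
                  sort=True)
    for s, fname in (("+", "coverage.plus.bedgraph"),
                     ("-", "coverage.minus.bedgraph")):
        uio.write_bedgraph(res.tracks, outdir / fname, strand=s)
    uio.write_bed6(uio.tars_to_bed(res.tars), outdir / "tars.bed")
    uio.write_tar_table(res.tars, outdir / "tars.tsv")
    uio.write_spot_matrix(res.matrix, outdir / "matrix")
    res.qc.per_spot.to_csv(outdir / "qc_per_spot.tsv", sep="\t", index=False)
    res.de_table.to_csv(outdir / "de_utars.tsv", sep="\t", index=False)
    res.labels.rename("label").to_frame().assign(
        score=res.scores
    ).to_csv(outdir / "spot_labels.tsv", sep="\t")
    res.concordance.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    res.recovery.per_locus.to_csv(
        outdir / "recovery_per_locus.tsv", sep="\t", index=False
    )
    summary = {
        "config_hash": cfg.config_hash,
        "seed": cfg.sim.seed,
        "classification": res.report,
        "assignment": res.assignment._asdict(),
        "qc": {
            "total_features_detected": res.qc.total_features_detected,
            "median_features_per_spot": res.qc.median_features_per_spot,
            "median_reads_per_spot": res.qc.median_reads_per_spot,
            "total_reads": res.qc.total_reads,
        },
        "recovery": {
            "precision": res.recovery.precision,
            "recall": res.recovery.recall,
            "precision_defined": res.recovery.precision_defined,
            "db_agreement": res.recovery.db_agreement,
            "de_confusion": res.recovery.de_confusion,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    cfg.to_yaml(outdir / "config.yaml")
    with open(outdir / "run_log.jsonl", "w") as fh:
        for rec in res.log:
            fh.write(json.dumps(rec) + "\n")
    if cfg.make_plots:
        _plot_spatial(res.spots, res.scores, "marker signature score",
                      outdir / "signature_map.png")
        sig = res.de_table.loc[res.de_table["significant"], "feature"]
        if len(sig):
            f = sig.iloc[0]
            vals = pd.Series(res.norm_matrix.row(f),
                             index=res.norm_matrix.barcodes)
            _plot_spatial(res.spots, vals, f"uTAR {f} expression",
                          outdir / "utar_map.png")
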