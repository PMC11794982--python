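"""Synthetic spatial-transcriptomics data with full ground truth.

This module emulates the raw material of an FFPE spatial (Visium-style)
run at the level downstream analysis actually sees: a small multi-contig
genome carrying planted annotated genes and unannotated lncRNA-like loci,
curated lncRNA "databases" holding a known subset of the unannotated loci,
a rectangular spot array split into two cell-type domains (a
keratinocyte-like domain and background tissue), negative-binomial
expression with planted cell-type fold changes, and spot-barcoded reads
whose placement reflects the capture chemistry:

* ``polyA`` capture — cDNA is primed off the poly(A) tail, so read 3' ends
  pile up near the transcript 3' end, with an exponential fall-off whose
  scale is the mean surviving fragment length (degradation).
* ``probe`` capture — hybridisation probes tile the transcript, modelled
  as uniform read placement.

Degradation is parameterised as the mean RNA fragment length; the DV200
quality metric (percentage of fragments strictly longer than 200 bases)
is computable from the emitted fragment lengths and is implemented here
as a standalone operation.

All coordinates are 0-based half-open; conversion to 1-based formats
(GTF, SAM) happens only in :mod:`utarscan.io`.  Every operation is
deterministic given the configured seed.

Negative-binomial parameterisation: ``dispersion`` is the *size* (shape)
parameter of the mean/size convention, i.e. ``var = mu + mu**2 / size``.
Larger ``dispersion`` means *less* overdispersion.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GenomeSpec",
    "SimulationSizingError",
    "KERATINOCYTE_MARKERS",
    "derive_seed",
    "make_genome",
    "make_databases",
    "simulate_spots",
    "simulate_counts",
    "fragment_and_place_reads",
    "dv200",
]

#: Canonical keratinocyte marker panel used to name the marker-like genes
#: planted in the keratinocyte domain (KRT5, KRT1, KRT10, DSP, LOR).
KERATINOCYTE_MARKERS = ("KRT5", "KRT1", "KRT10", "DSP", "LOR")

#: Domain labels used by the spot layout.
DOMAIN_KERATINOCYTE = "keratinocyte"
DOMAIN_OTHER = "other"

#: Columns of the reads table produced by :func:`fragment_and_place_reads`.
READ_COLUMNS = [
    "contig",
    "start",
    "length",
    "strand",
    "barcode",
    "origin",
    "fragment_length",
]


class SimulationSizingError(ValueError):
    """Raised when loci cannot be placed on the configured genome."""


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stable 31-bit stage seed from a master seed.

    The stage name is hashed (CRC-32) and mixed with the master seed so
    each pipeline stage owns an independent, reproducible stream.
    """
    return (zlib.crc32(stage.encode("utf-8")) ^ int(master_seed)) % (2**31)


@dataclass
class SimConfig:
    """All knobs of the synthetic generator.

    Defaults define the reference study conditions used throughout the
    test-suite: 40 genes (five of them the keratinocyte marker panel),
    20 unannotated lncRNA-like loci all carrying an 8-fold keratinocyte
    effect, 200 spots on a 10 x 20 grid with the keratinocyte-like
    domain in the top 20 % of grid columns, and probe-mode (uniform)
    read placement.
    """

    seed: int = 0
    # genome
    n_contigs: int = 4
    contig_length: int = 250_000
    n_genes: int = 40
    n_lnc: int = 20
    min_gap: int = 2_000          # > merge gap (500) so truths stay separable
    locus_len_range: tuple[int, int] = (1_000, 10_000)
    # expression
    base_mean: float = 2.0        # expected counts per spot per locus
    dispersion: float = 5.0       # NB size; var = mu + mu^2/size
    n_marker_genes: int = 5
    de_frac_lnc: float = 1.0      # fraction of lnc loci carrying the effect
    de_fold: float = 8.0          # keratinocyte-domain fold change
    # databases
    db1_frac: float = 0.6         # FANTOM-like
    db2_frac: float = 0.5         # LncExpDB-like
    # spots
    n_spots: int = 200
    domain_frac: float = 0.2      # fraction of grid columns in the domain
    flip_rate: float = 0.05       # per-spot domain label-flip noise
    # reads
    capture_mode: str = "probe"   # {"polyA", "probe"}
    degradation: float = 1_000.0  # mean RNA fragment length (bases)
    reads_per_count: int = 1
    read_len_cap: int = 50
    min_fragment: int = 30

    def validate(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("genome must have >=1 contig of positive length")
        if self.min_gap <= 500:
            raise ValueError("min_gap must exceed the 500-bp merge gap")
        lo, hi = self.locus_len_range
        if not (0 < lo <= hi):
            raise ValueError("locus_len_range must satisfy 0 < lo <= hi")
        if self.capture_mode not in ("polyA", "probe"):
            raise ValueError(f"unknown capture_mode {self.capture_mode!r}")
        for name in ("db1_frac", "db2_frac", "de_frac_lnc", "flip_rate",
                     "domain_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_marker_genes > self.n_genes:
            raise ValueError("n_marker_genes cannot exceed n_genes")
        if self.degradation <= 0:
            raise ValueError("degradation (mean fragment length) must be > 0")
        if self.reads_per_count < 1:
            raise ValueError("reads_per_count must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["locus_len_range"] = list(d["locus_len_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "locus_len_range" in d:
            d["locus_len_range"] = tuple(d["locus_len_range"])
        return cls(**d)


@dataclass
class GenomeSpec:
    """Contig names and lengths (no sequence is ever needed)."""

    contigs: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        if any(length <= 0 for _, length in self.contigs):
            raise ValueError("contig lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.contigs)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


# ---------------------------------------------------------------------------
# genome + truth loci
# ---------------------------------------------------------------------------

def make_genome(config: SimConfig) -> tuple[GenomeSpec, pd.DataFrame]:
    """Place annotated genes and unannotated lncRNA-like loci on a genome.

    Returns the genome spec and a truth table with one row per planted
    locus.  Columns: ``id, contig, start, end, strand, annotated,
    base_mean, dispersion, celltype_effect, in_db1, in_db2``.
    Coordinates are 0-based half-open.  Loci are placed uniformly at
    random but kept at least ``min_gap`` bases from every other locus on
    the same contig (both strands — stricter than needed for merging,
    which only acts within a strand, but it keeps strand-ignore
    classification clean too).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "genome"))
    genome = GenomeSpec(
        [(f"chr{i + 1}", config.contig_length) for i in range(config.n_contigs)]
    )

    n_total = config.n_genes + config.n_lnc
    lo, hi = config.locus_len_range
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in genome.contigs}
    rows = []
    max_tries = 1_000
    contig_names = [c for c, _ in genome.contigs]
    for i in range(n_total):
        length = int(rng.integers(lo, hi + 1))
        for _ in range(max_tries):
            contig = contig_names[int(rng.integers(len(contig_names)))]
            clen = genome.lengths[contig]
            if clen < length:
                continue
            start = int(rng.integers(0, clen - length + 1))
            end = start + length
            ok = all(
                start - e >= config.min_gap or s - end >= config.min_gap
                for s, e in placed[contig]
            )
            if ok:
                break
        else:
            raise SimulationSizingError(
                f"could not place locus {i + 1}/{n_total} after {max_tries} "
                "attempts; enlarge the genome or reduce n_genes/n_lnc/min_gap"
            )
        placed[contig].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((contig, start, end, strand, length))

    annotated = np.zeros(n_total, dtype=bool)
    annotated[: config.n_genes] = True

    ids = []
    gene_i = lnc_i = 0
    markers = list(KERATINOCYTE_MARKERS)[: config.n_marker_genes]
    for k in range(n_total):
        if annotated[k]:
            gene_i += 1
            ids.append(markers[gene_i - 1] if gene_i <= len(markers)
                       else f"gene{gene_i:04d}")
        else:
            lnc_i += 1
            ids.append(f"lnc{lnc_i:04d}")

    effect = np.ones(n_total)
    effect[: config.n_marker_genes] = config.de_fold  # marker genes
    lnc_idx = np.flatnonzero(~annotated)
    n_de = int(round(config.de_frac_lnc * len(lnc_idx)))
    de_lnc = rng.choice(lnc_idx, size=n_de, replace=False) if n_de else []
    effect[np.asarray(de_lnc, dtype=int)] = config.de_fold

    loci = pd.DataFrame(
        {
            "id": ids,
            "contig": [r[0] for r in rows],
            "start": [r[1] for r in rows],
            "end": [r[2] for r in rows],
            "strand": [r[3] for r in rows],
            "annotated": annotated,
            "base_mean": config.base_mean,
            "dispersion": config.dispersion,
            "celltype_effect": effect,
            "in_db1": False,
            "in_db2": False,
        }
    )
    return genome, loci


def make_databases(
    loci: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw two curated lncRNA reference sets from the unannotated loci.

    A seed-chosen fraction ``db1_frac`` / ``db2_frac`` of the unannotated
    loci is placed (with its exact interval and strand) in each database;
    membership flags are written back into ``loci`` (columns ``in_db1``,
    ``in_db2``).  The returned frames are BED6-shaped
    (contig, start, end, name, score, strand).
    """
    rng = np.random.default_rng(derive_seed(config.seed, "databases"))
    lnc = loci.index[~loci["annotated"]].to_numpy()
    loci.loc[:, ["in_db1", "in_db2"]] = False

    out = []
    for frac, col in ((config.db1_frac, "in_db1"), (config.db2_frac, "in_db2")):
        n = int(round(frac * len(lnc)))
        chosen = rng.choice(lnc, size=n, replace=False) if n else np.array([], int)
        loci.loc[chosen, col] = True
        sub = loci.loc[np.sort(chosen)]
        out.append(
            pd.DataFrame(
                {
                    "contig": sub["contig"].to_numpy(),
                    "start": sub["start"].to_numpy(),
                    "end": sub["end"].to_numpy(),
                    "name": sub["id"].to_numpy(),
                    "score": 0,
                    "strand": sub["strand"].to_numpy(),
                }
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# spots + expression
# ---------------------------------------------------------------------------

def _grid_shape(n_spots: int) -> tuple[int, int]:
    """Rows x cols with rows the largest divisor of n not above sqrt(n)."""
    rows = 1
    for d in range(1, int(np.sqrt(n_spots)) + 1):
        if n_spots % d == 0:
            rows = d
    return rows, n_spots // rows


def simulate_spots(config: SimConfig) -> pd.DataFrame:
    """Lay spots on a rectangular grid with a two-domain split.

    The keratinocyte-like domain is the half-plane of grid columns with
    ``x >= (1 - domain_frac) * n_cols``; each spot's label then flips
    with probability ``flip_rate`` (emulating the ragged tissue margins a
    pathologist would draw around).  Returns columns
    ``barcode, x, y, domain``.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "spots"))
    rows, cols = _grid_shape(config.n_spots)
    ys, xs = np.divmod(np.arange(config.n_spots), cols)
    boundary = (1.0 - config.domain_frac) * cols
    domain = np.where(xs >= boundary, DOMAIN_KERATINOCYTE, DOMAIN_OTHER)
    flip = rng.random(config.n_spots) < config.flip_rate
    flipped = np.where(
        domain == DOMAIN_KERATINOCYTE, DOMAIN_OTHER, DOMAIN_KERATINOCYTE
    )
    domain = np.where(flip, flipped, domain)
    return pd.DataFrame(
        {
            "barcode": [f"spot{i:05d}" for i in range(config.n_spots)],
            "x": xs.astype(int),
            "y": ys.astype(int),
            "domain": domain,
        }
    )


def simulate_counts(
    loci: pd.DataFrame, spots: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Draw the true locus x spot count table.

    ``count(l, s) ~ NB(mean = base_mean_l * effect_l^[spot s in domain],
    size = dispersion_l)`` where the effect applies only in the
    keratinocyte-like domain.  Returns an integer DataFrame indexed by
    locus id with one column per barcode.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "counts"))
    in_domain = (spots["domain"] == DOMAIN_KERATINOCYTE).to_numpy()
    base = loci["base_mean"].to_numpy()[:, None]
    effect = np.where(
        in_domain[None, :], loci["celltype_effect"].to_numpy()[:, None], 1.0
    )
    mu = base * effect
    size = loci["dispersion"].to_numpy()[:, None] * np.ones_like(mu)
    counts = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    # NB(mean, size): numpy draws with p = size / (size + mean)
    p = size[pos] / (size[pos] + mu[pos])
    counts[pos] = rng.negative_binomial(size[pos], p)
    return pd.DataFrame(
        counts, index=loci["id"].to_numpy(), columns=spots["barcode"].to_numpy()
    )


# ---------------------------------------------------------------------------
# fragmentation + read placement
# ---------------------------------------------------------------------------

def _truncated_exponential(
    rng: np.random.Generator, mean: float, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Inverse-CDF draws from Exp(mean) truncated to [lo, hi] elementwise."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    u = rng.random(lo.shape)
    a = np.exp(-lo / mean)
    b = np.exp(-hi / mean)
    return -mean * np.log(a - u * (a - b))


def fragment_and_place_reads(
    counts: pd.DataFrame, loci: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Turn the true count table into spot-barcoded reads.

    Each count unit yields ``reads_per_count`` reads.  The surviving RNA
    fragment length is exponential with mean ``degradation``, truncated
    to ``[min_fragment, locus length]``; the read covers
    ``min(fragment_length, read_len_cap)`` bases of its locus.  In
    ``polyA`` mode the read's 3' end sits an Exp(degradation)-distributed
    distance (truncated to fit) from the locus 3' end — the geometry of
    oligo-dT capture on degraded RNA.  In ``probe`` mode the read start
    is uniform within the locus.  Reads never leave their origin locus
    and inherit its strand.

    Returns a DataFrame with :data:`READ_COLUMNS`.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "reads"))
    mat = counts.to_numpy() * config.reads_per_count
    li, si = np.nonzero(mat)
    reps = mat[li, si]
    li = np.repeat(li, reps)
    si = np.repeat(si, reps)
    n = li.size

    locus = loci.iloc[li]
    lstart = locus["start"].to_numpy()
    lend = locus["end"].to_numpy()
    llen = (lend - lstart).astype(float)
    strand = locus["strand"].to_numpy()

    frag = _truncated_exponential(
        rng, config.degradation,
        np.full(n, float(config.min_fragment)), llen,
    )
    frag = np.ceil(frag).astype(np.int64)
    read_len = np.minimum(frag, config.read_len_cap)
    slack = (lend - lstart - read_len).astype(float)

    if config.capture_mode == "polyA":
        d = _truncated_exponential(rng, config.degradation, np.zeros(n), slack)
        d = np.floor(d).astype(np.int64)
        start = np.where(strand == "+", lend - d - read_len, lstart + d)
    else:  # probe: uniform placement
        offset = np.floor(rng.random(n) * (slack + 1)).astype(np.int64)
        start = lstart + offset

    return pd.DataFrame(
        {
            "contig": locus["contig"].to_numpy(),
            "start": start.astype(np.int64),
            "length": read_len.astype(np.int64),
            "strand": strand,
            "barcode": counts.columns.to_numpy()[si],
            "origin": locus["id"].to_numpy(),
            "fragment_length": frag,
        }
    )


def dv200(fragment_lengths) -> float:
    """Percentage of fragments strictly longer than 200 bases.

    The standard FFPE RNA-quality metric (DV200); values of at least
    30 % are conventionally considered acceptable for sequencing.
    """
    lengths = np.asarray(fragment_lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("dv200 requires a nonempty list of fragment lengths")
    if np.any(lengths <= 0):
        raise ValueError("fragment lengths must be positive")
    return float(100.0 * np.mean(lengths > 200.0))
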