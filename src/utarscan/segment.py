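"""Segment binned coverage into transcriptionally active regions (TARs).

Two segmentation modes are offered:

* ``hmm`` (default) — a two-state hidden Markov model on
  ``log(count + 1)``-transformed bin counts, fitted by Baum-Welch across
  all tracks of a sample (pooled fit, one parameter set per sample) and
  decoded per track with Viterbi (:mod:`utarscan.hmm`).
* ``presence`` — the literal rule: a bin is transcriptionally active iff
  any read was detected in it.

Maximal runs of active bins become TARs with bin-aligned genomic
coordinates; same-strand TARs no more than ``max_gap`` (default 500)
bases apart are then merged transitively into one unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .coverage import BinnedCoverage
from .hmm import HMMParams, TwoStateGaussianHMM, DegenerateDataError

__all__ = [
    "TAR",
    "DEFAULT_MERGE_GAP",
    "call_active_bins_presence",
    "fit_hmm",
    "decode_states",
    "states_to_tars",
    "merge_tars",
    "segment_tracks",
]

DEFAULT_MERGE_GAP = 500

CLASS_UNSET = "unset"


@dataclass
class TAR:
    """A contiguous transcribed interval (0-based half-open, bin-aligned)."""

    contig: str
    start: int
    end: int
    strand: str
    n_bins: int = 0
    mean_cov: float = 0.0
    tar_class: str = CLASS_UNSET   # {aTAR, uTAR, unset}
    db_label: str = CLASS_UNSET    # {novel, db1, db2, both, unset}
    sample: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"TAR must have start < end, got {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TAR strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        """Number of overlapping bases with [start, end)."""
        return max(0, min(self.end, end) - max(self.start, start))


def call_active_bins_presence(track: BinnedCoverage) -> np.ndarray:
    """State 1 iff reads were detected in the bin (the literal rule)."""
    return (track.counts > 0).astype(np.int8)


def fit_hmm(
    tracks,
    tol: float = 1e-6,
    max_iter: int = 1000,
    var_floor: float = 1e-3,
) -> HMMParams:
    """Baum-Welch fit of the two-state HMM, pooled across tracks.

    ``tracks`` is an iterable (or dict) of :class:`BinnedCoverage`; the
    observation for each bin is ``log(count + 1)``.  Raises
    :class:`~utarscan.hmm.DegenerateDataError` if all bin counts are
    identical (use presence mode then).  The returned params carry the
    iteration count, final log-likelihood and the per-iteration trace.
    """
    if isinstance(tracks, dict):
        tracks = list(tracks.values())
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one coverage track")
    seqs = [np.log1p(t.counts.astype(float)) for t in tracks]
    est = TwoStateGaussianHMM(tol=tol, max_iter=max_iter, var_floor=var_floor)
    est.fit(seqs)
    return est.params_


def decode_states(track: BinnedCoverage, params: HMMParams) -> np.ndarray:
    """Viterbi path for one track (ties resolved to untranscribed)."""
    obs = np.log1p(track.counts.astype(float))
    return TwoStateGaussianHMM().predict(obs, params=params)


def states_to_tars(
    states: np.ndarray, track: BinnedCoverage, sample: str | None = None
) -> list[TAR]:
    """Turn maximal runs of state 1 into bin-aligned TARs.

    The last TAR on a contig is closed at the contig length (the final
    bin may be partial).
    """
    states = np.asarray(states)
    if len(states) != track.n_bins:
        raise ValueError(
            f"states length {len(states)} != track bins {track.n_bins}"
        )
    active = states.astype(bool)
    if not active.any():
        return []
    edges = np.diff(np.concatenate(([0], active.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # exclusive bin index
    bs = track.bin_size
    tars = []
    for b0, b1 in zip(starts, ends):
        seg = track.counts[b0:b1]
        tars.append(
            TAR(
                contig=track.contig,
                start=int(b0 * bs),
                end=int(min(b1 * bs, track.contig_length)),
                strand=track.strand,
                n_bins=int(b1 - b0),
                mean_cov=float(seg.mean()),
                sample=sample,
            )
        )
    return tars


def merge_tars(tars: list[TAR], max_gap: int = DEFAULT_MERGE_GAP) -> list[TAR]:
    """Merge same-contig, same-strand TARs no more than ``max_gap`` apart.

    Merging is transitive (a chain of TARs each within the gap becomes a
    single unit); the merged ``mean_cov`` is the bin-count-weighted mean
    of the members and ``n_bins`` their sum (gap bins are not counted).
    Output is sorted by (contig, strand, start) with all remaining
    same-strand gaps strictly greater than ``max_gap``.  Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be nonnegative")
    groups: dict[tuple[str, str], list[TAR]] = {}
    for t in tars:
        groups.setdefault((t.contig, t.strand), []).append(t)

    out: list[TAR] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda t: (t.start, t.end))
        cur = replace(members[0])
        cur_w = cur.n_bins * cur.mean_cov
        for nxt in members[1:]:
            if nxt.start - cur.end <= max_gap:
                cur.end = max(cur.end, nxt.end)
                cur.n_bins += nxt.n_bins
                cur_w += nxt.n_bins * nxt.mean_cov
            else:
                cur.mean_cov = cur_w / cur.n_bins if cur.n_bins else 0.0
                out.append(cur)
                cur = replace(nxt)
                cur_w = cur.n_bins * cur.mean_cov
        cur.mean_cov = cur_w / cur.n_bins if cur.n_bins else 0.0
        out.append(cur)
    for t in out:
        t.tar_class = CLASS_UNSET
        t.db_label = CLASS_UNSET
    return out


def segment_tracks(
    tracks: dict,
    mode: str = "hmm",
    max_gap: int = DEFAULT_MERGE_GAP,
    sample: str | None = None,
    params: HMMParams | None = None,
) -> tuple[list[TAR], HMMParams | None]:
    """Segment every track of a sample and merge the resulting TARs.

    In ``hmm`` mode a single parameter set is fitted across all tracks
    (unless ``params`` is supplied) and each track is decoded with it;
    in ``presence`` mode the literal bin-occupancy rule is used.
    Returns the merged TAR list and the HMM params (None for presence).
    """
    if mode not in ("hmm", "presence"):
        raise ValueError(f"unknown segmentation mode {mode!r}")
    fitted = None
    if mode == "hmm":
        fitted = params if params is not None else fit_hmm(tracks)
    tars: list[TAR] = []
    for key in sorted(tracks):
        track = tracks[key]
        if mode == "hmm":
            states = decode_states(track, fitted)
        else:
            states = call_active_bins_presence(track)
        tars.extend(states_to_tars(states, track, sample=sample))
    merged = merge_tars(tars, max_gap=max_gap)
    for i, t in enumerate(merged):
        t.name = f"{sample or 'sample'}:{i}"
    return merged, fitted
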