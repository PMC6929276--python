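"""ROSE-style super-enhancer calling.

Enhancers within ``max_gap`` (default 12.5 kb, end-to-start) of each other are
stitched into single entities; entities are ranked by total background-
normalized coactivator signal over their span, and everything above the
elbow of the scaled rank/signal curve — the first point where the discrete
slope exceeds 1 — is labelled a super-enhancer.

Negatives here are simply the stitched entities below the cutoff ("typical
enhancers"); no further filtering of the negative class is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomicRegion, ReadSet
from .signal_quant import DEFAULT_EXT_LEN, background_normalize, region_density

DEFAULT_MAX_GAP = 12_500


@dataclass
class StitchedEntity:
    """A maximal run of enhancers whose successive gaps are <= max_gap."""

    region: GenomicRegion
    constituents: list[GenomicRegion]
    total_signal: float = 0.0

    def __post_init__(self):
        if not self.constituents:
            raise ValueError("entity must have at least one constituent")


@dataclass
class SECallResult:
    """Entities ranked ascending by signal, the cutoff, and binary labels."""

    ranked: list[StitchedEntity]
    cutoff: float
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_super(self) -> int:
        return int(self.labels.sum())


def stitch(regions: list[GenomicRegion],
           max_gap: int = DEFAULT_MAX_GAP) -> list[StitchedEntity]:
    """Merge regions whose end-to-start gap is <= max_gap, transitively.

    Chromosomes are handled independently; overlapping inputs (gap <= 0)
    always merge. Output is sorted by (chrom, start).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    entities: list[StitchedEntity] = []
    for chrom in sorted(by_chrom):
        chrom_regions = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cluster: list[GenomicRegion] = []
        cluster_end = None
        for r in chrom_regions:
            if cluster and r.start - cluster_end <= max_gap:
                cluster.append(r)
                cluster_end = max(cluster_end, r.end)
            else:
                if cluster:
                    entities.append(_make_entity(chrom, cluster))
                cluster = [r]
                cluster_end = r.end
        if cluster:
            entities.append(_make_entity(chrom, cluster))
    return entities


def _make_entity(chrom: str, cluster: list[GenomicRegion]) -> StitchedEntity:
    start = min(r.start for r in cluster)
    end = max(r.end for r in cluster)
    return StitchedEntity(region=GenomicRegion(chrom, start, end),
                          constituents=list(cluster))


def total_signal(entity: StitchedEntity, signal_reads: ReadSet,
                 control_reads: ReadSet | None = None,
                 ext_len: int = DEFAULT_EXT_LEN) -> float:
    """Background-normalized density over the entity span, times span length."""
    dens = region_density(signal_reads, entity.region, ext_len)
    ctrl = (region_density(control_reads, entity.region, ext_len)
            if control_reads is not None else None)
    return background_normalize(dens, ctrl) * entity.region.length


def find_cutoff(signals: np.ndarray | list[float]) -> float:
    """Elbow cutoff on the ranked-signal curve.

    Signals are sorted ascending; ranks and signals are min-max scaled to
    [0, 1]; the cutoff is the signal at the start of the first segment whose
    discrete slope exceeds 1. A flat curve (or one that never steepens past
    the diagonal) returns the maximum signal, labelling nothing.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.size < 2:
        raise ValueError("need at least 2 entities to locate a cutoff")
    s = np.sort(signals)
    span = s[-1] - s[0]
    if span == 0:
        return float(s[-1])
    y = (s - s[0]) / span
    # uniform rank spacing: slope of segment i is dy * (n - 1)
    slopes = np.diff(y) * (signals.size - 1)
    steep = np.nonzero(slopes > 1.0)[0]
    if steep.size == 0:
        return float(s[-1])
    return float(s[steep[0]])


def call_super_enhancers(regions: list[GenomicRegion],
                         signal_reads: ReadSet,
                         control_reads: ReadSet | None = None,
                         max_gap: int = DEFAULT_MAX_GAP,
                         ext_len: int = DEFAULT_EXT_LEN) -> SECallResult:
    """Full pipeline: stitch -> total signal -> elbow cutoff -> labels.

    With a single stitched entity no elbow exists; the entity is labelled 0
    and the cutoff degenerates to its own signal.
    """
    if not regions:
        raise ValueError("region set is empty")
    entities = stitch(regions, max_gap)
    for e in entities:
        e.total_signal = total_signal(e, signal_reads, control_reads, ext_len)
    entities.sort(key=lambda e: e.total_signal)
    signals = np.array([e.total_signal for e in entities])
    if signals.size < 2:
        cutoff = float(signals[0])
    else:
        cutoff = find_cutoff(signals)
    labels = (signals > cutoff).astype(int)
    return SECallResult(ranked=entities, cutoff=cutoff, labels=labels)


def write_se_calls(result: SECallResult, path) -> None:
    """BED output: score = total signal, name suffixed _SE or _TE."""
    with open(path, "w") as fh:
        for e, lab in zip(result.ranked, result.labels):
            base = e.region.name or f"{e.region.chrom}_{e.region.start}"
            suffix = "_SE" if lab else "_TE"
            fh.write(f"{e.region.chrom}\t{e.region.start}\t{e.region.end}\t"
                     f"{base}{suffix}\t{e.total_signal:.6g}\n")


def write_ranked_signals(result: SECallResult, path) -> None:
    """Rank/signal TSV for plotting the hockey-stick curve."""
    with open(path, "w") as fh:
        fh.write("rank\ttotal_signal\tis_super\n")
        for rank, (e, lab) in enumerate(zip(result.ranked, result.labels)):
            fh.write(f"{rank}\t{e.total_signal:.6g}\t{int(lab)}\n")
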