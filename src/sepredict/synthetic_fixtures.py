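"""Seeded synthetic-data generators for every stage of the pipeline.

Two families:

* read simulators — uniform background with planted fold-enriched peaks,
  feeding the quantification and SE-calling path;
* feature-table simulators — class-conditional Gaussian columns with
  planted per-feature mean shifts, feeding the model and ranking path.
  The default preset mirrors the published cohort: 1119 positives and
  9981 negatives (11100 samples, a 9:1 negative:positive ratio), with the
  six informative columns Med12 > Cdk8 > Brd4 > Cdk9 > p300 > H3K27ac.

All generators are pure functions of their config (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import FEATURE_NAMES, FeatureMatrix
from .io_formats import GenomicRegion, Read, ReadSet, write_bed, write_sam

#: published cohort sizes
PRESET_N_POS = 1119
PRESET_N_NEG = 9981

#: class-mean shifts (within-class sd units) for the informative columns,
#: in decreasing order of planted effect
DEFAULT_EFFECTS: dict[str, float] = {
    "Med12": 3.0,
    "Cdk8": 2.5,
    "Brd4": 2.0,
    "Cdk9": 1.5,
    "p300": 1.0,
    "H3K27ac": 0.5,
}


@dataclass
class ReadSimConfig:
    """Planted-peak read simulation over a toy genome."""

    genome_layout: dict[str, int]                    # chrom -> length
    background_rate: float = 0.01                    # expected reads per bp
    peaks: list[tuple[GenomicRegion, float]] = field(default_factory=list)
    n_reads: int | None = None                       # None: Poisson from rates
    read_len: int = 36
    seed: int = 0

    def __post_init__(self):
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for region, fold in self.peaks:
            if fold < 1:
                raise ValueError("peak fold-enrichment must be >= 1")
            if region.chrom not in self.genome_layout:
                raise ValueError(f"peak on unknown chromosome {region.chrom!r}")


@dataclass
class TableSimConfig:
    """Class-conditional Gaussian feature table with planted effects."""

    n_pos: int = PRESET_N_POS
    n_neg: int = PRESET_N_NEG
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.effect_sizes) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"effect sizes for unknown features: {sorted(unknown)}")


def simulate_reads(config: ReadSimConfig) -> ReadSet:
    """Draw reads from a piecewise-uniform genome intensity.

    Background intensity is 1 per bp, multiplied by the fold inside each
    peak; read count is ``n_reads`` if given, else Poisson with mean
    background_rate x fold-weighted genome length. Strands are uniform.
    """
    total_len = sum(config.genome_layout.values())
    if total_len <= 0:
        raise ValueError("genome has zero length")
    rng = np.random.default_rng(config.seed)

    # build weighted segments: (chrom, start, end, weight)
    segments: list[tuple[str, int, int, float]] = []
    for chrom, length in config.genome_layout.items():
        chrom_peaks = sorted(
            [(r.start, r.end, fold) for r, fold in config.peaks if r.chrom == chrom])
        cursor = 0
        for start, end, fold in chrom_peaks:
            if start > cursor:
                segments.append((chrom, cursor, start, 1.0))
            segments.append((chrom, start, end, fold))
            cursor = max(cursor, end)
        if cursor < length:
            segments.append((chrom, cursor, length, 1.0))

    weights = np.array([(e - s) * w for _, s, e, w in segments], dtype=float)
    weighted_len = weights.sum()
    if config.n_reads is not None:
        n_reads = config.n_reads
    else:
        n_reads = int(rng.poisson(config.background_rate * weighted_len))
    if weighted_len == 0 or n_reads == 0:
        return ReadSet(reads=[], total_mapped=0)

    seg_idx = rng.choice(len(segments), size=n_reads, p=weights / weighted_len)
    offsets = rng.random(n_reads)
    strands = rng.random(n_reads) < 0.5
    reads: list[Read] = []
    for i in range(n_reads):
        chrom, s, e, _ = segments[seg_idx[i]]
        start = s + int(offsets[i] * (e - s))
        chrom_len = config.genome_layout[chrom]
        end = min(start + config.read_len, chrom_len)
        start = max(0, end - config.read_len)
        reads.append(Read(chrom, start, end, "+" if strands[i] else "-"))
    return ReadSet(reads=reads, total_mapped=n_reads)


def simulate_feature_table(config: TableSimConfig) -> FeatureMatrix:
    """Gaussian feature table: negatives ~ N(0, sd), positives ~ N(d_j, sd)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    d = np.array([config.effect_sizes.get(name, 0.0) for name in FEATURE_NAMES])
    labels = np.concatenate([np.ones(config.n_pos, dtype=int),
                             np.zeros(config.n_neg, dtype=int)])
    X = rng.normal(0.0, config.noise_sd, size=(n, len(FEATURE_NAMES)))
    X[:config.n_pos] += d
    # deterministic shuffle so folds don't see label-sorted blocks
    order = rng.permutation(n)
    values = pd.DataFrame(X[order], columns=list(FEATURE_NAMES))
    return FeatureMatrix(sample_ids=[f"s{i}" for i in range(n)],
                         values=values, labels=labels[order])


def make_se_fixture(seed: int, out_dir: str | Path | None = None,
                    n_weak: int = 95, n_strong: int = 5,
                    fold: float = 60.0,
                    ) -> tuple[list[GenomicRegion], ReadSet, np.ndarray]:
    """Enhancer BED + coactivator reads with planted super-enhancer clusters.

    Plants ``n_strong`` three-constituent clusters (stitchable: constituent
    gaps < 12.5 kb) with strong fold-enrichment among ``n_weak`` isolated
    background-level enhancers, spaced > 12.5 kb apart so stitching yields
    exactly n_weak + n_strong entities. Returns (regions, reads, expected
    entity labels in ascending-signal order). With ``out_dir`` set, writes
    ``enhancers.bed`` and ``signal.sam``.
    """
    rng = np.random.default_rng(seed)
    spacing = 20_000  # > max_gap so separate entities never stitch together
    regions: list[GenomicRegion] = []
    peaks: list[tuple[GenomicRegion, float]] = []
    strong_spans: list[tuple[int, int]] = []
    cursor = 10_000
    slots = ["strong"] * n_strong + ["weak"] * n_weak
    rng.shuffle(slots)
    for i, kind in enumerate(slots):
        if kind == "weak":
            length = 1_000
            regions.append(GenomicRegion("chr1", cursor, cursor + length, f"e{i}"))
            cursor += length + spacing
        else:
            # three constituents, 2 kb apart (< 12.5 kb, so they stitch)
            span_start = cursor
            for j in range(3):
                regions.append(GenomicRegion("chr1", cursor, cursor + 1_000,
                                             f"e{i}c{j}"))
                cursor += 1_000 + 2_000
            span_end = cursor - 2_000
            peaks.append((GenomicRegion("chr1", span_start, span_end), fold))
            strong_spans.append((span_start, span_end))
            cursor += spacing
    genome_len = cursor + 10_000
    if n_strong == 0:
        # Degenerate flat-curve case: Poisson background noise would always
        # push some slope of the scaled rank curve above 1 (the mean slope is
        # exactly 1), so tile reads deterministically at a 50 bp period that
        # is phase-aligned with every enhancer, making all signals equal.
        reads = [Read("chr1", s, min(s + 36, genome_len), "+")
                 for s in range(0, genome_len - 36, 50)]
        read_set = ReadSet(reads=reads, total_mapped=len(reads))
    else:
        read_config = ReadSimConfig(genome_layout={"chr1": genome_len},
                                    background_rate=0.02, peaks=peaks,
                                    read_len=36, seed=seed)
        read_set = simulate_reads(read_config)

    # expected labels in ascending-total-signal order: weak entities first
    expected = np.concatenate([np.zeros(n_weak, dtype=int),
                               np.ones(n_strong, dtype=int)])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_bed(regions, out_dir / "enhancers.bed")
        write_sam(read_set, out_dir / "signal.sam", {"chr1": genome_len})
    return regions, read_set, expected
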