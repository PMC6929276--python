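"""Assembly of the 36-column feature matrix.

The canonical registry holds 31 signal/TF columns plus five sequence-derived
ones (AT content, GC content, phastCons, phastConsP, repeat fraction). The
coactivator track that defines the labels (Med1) is deliberately absent from
the registry — it would leak the label — while the distinct Mediator subunit
Med12 is a feature. HDAC and HDAC2 are kept in the registry even though no
public track is listed for them; synthetic and user-supplied tables must
still provide those columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PWM, GenomicRegion, ScoreTrack

#: canonical feature order; exactly 36 names
FEATURE_NAMES: tuple[str, ...] = (
    "H3K27ac", "H3K4me1", "H3K4me3", "H3K9me3", "Brd4", "Cdk8", "Cdk9",
    "Med12", "p300", "CBP", "Pol2", "Lsd1", "Brg1", "Smc1", "Nipbl", "Mi2b",
    "CHD7", "HDAC2", "HDAC", "DNaseI", "Oct4", "Sox2", "Nanog", "Smad3",
    "Stat3", "Tcf3", "Esrrb", "Klf4", "Prdm14", "Tcfcp2l1", "Nr5a2",
    "AT content", "GC content", "phastCons", "phastConsP", "repeat fraction",
)
SEQUENCE_FEATURES: tuple[str, ...] = FEATURE_NAMES[31:]
SIGNAL_FEATURES: tuple[str, ...] = FEATURE_NAMES[:31]

assert len(FEATURE_NAMES) == 36, "feature registry must have exactly 36 names"

#: per-base conservation score counted as "conserved" for phastConsP
CONSERVED_THRESHOLD = 0.5

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class FeatureMatrix:
    """n_samples x 36 feature values with a parallel binary label vector."""

    sample_ids: list[str]
    values: pd.DataFrame
    labels: np.ndarray
    column_sources: dict[str, str] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if list(self.values.columns) != list(FEATURE_NAMES):
            raise ValueError(
                f"feature matrix must have the canonical 36 columns, got "
                f"{len(self.values.columns)}")
        if len(self.values) != len(self.labels) or len(self.values) != len(self.sample_ids):
            raise ValueError("sample_ids, values and labels must align")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.values.size and self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing values in columns {bad}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels


def sequence_composition(seq: str) -> tuple[float, float, float]:
    """(AT content, GC content, repeat fraction) of a sequence.

    AT/GC ignore N bases; repeat fraction is the share of soft-masked
    (lowercase) bases over the whole sequence.
    """
    if not seq:
        raise ValueError("empty sequence")
    n_lower = sum(1 for c in seq if c.islower())
    up = seq.upper()
    counts = {b: up.count(b) for b in "ACGT"}
    acgt = sum(counts.values())
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    at = (counts["A"] + counts["T"]) / acgt
    gc = (counts["G"] + counts["C"]) / acgt
    return at, gc, n_lower / len(seq)


def conservation_features(region: GenomicRegion, track: ScoreTrack,
                          threshold: float = CONSERVED_THRESHOLD
                          ) -> tuple[float, float]:
    """(mean per-base score, fraction of bases scoring >= threshold).

    Bases missing from the track count as 0.
    """
    if region.length <= 0:
        raise ValueError("zero-length region")
    scores = track.region_scores(region)
    return float(scores.mean()), float((scores >= threshold).mean())


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _log_odds(pwm: PWM) -> np.ndarray:
    return np.log2(pwm.matrix / pwm.background[:, None])


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3; anything else (N) to 4."""
    return np.array([_BASE_INDEX.get(c, 4) for c in seq.upper()], dtype=np.intp)


def _best_window_score(codes: np.ndarray, lom: np.ndarray) -> float:
    w = lom.shape[1]
    # row 4 scores 0: N contributes log2(bg/bg) for an uninformative base
    lom5 = np.vstack([lom, np.zeros((1, w))])
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    scores = lom5[windows, np.arange(w)].sum(axis=1)
    return float(scores.max())


def motif_affinity(seq: str, pwm: PWM, mode: str = "best",
                   threshold: float = 0.0) -> float:
    """Binding-affinity score of a sequence against one motif.

    Scans every window on both strands with log2-odds scoring against the
    PWM background. ``mode="best"`` (default) returns the maximum window
    score; ``mode="sum"`` returns the sum of window scores exceeding
    ``threshold`` — an alternative aggregate for dense motif fields.
    """
    if len(seq) < pwm.width:
        raise ValueError(
            f"sequence length {len(seq)} shorter than motif width {pwm.width}")
    if mode not in ("best", "sum"):
        raise ValueError(f"unknown mode {mode!r}")
    lom = _log_odds(pwm)
    lom5 = np.vstack([lom, np.zeros((1, pwm.width))])
    all_scores = []
    for s in (seq, reverse_complement(seq)):
        codes = _encode(s)
        windows = np.lib.stride_tricks.sliding_window_view(codes, pwm.width)
        all_scores.append(lom5[windows, np.arange(pwm.width)].sum(axis=1))
    scores = np.concatenate(all_scores)
    if mode == "best":
        return float(scores.max())
    return float(scores[scores > threshold].sum())


def assemble(signal_densities: pd.DataFrame,
             sequence_features: pd.DataFrame,
             labels: Sequence[int],
             sample_ids: Sequence[str] | None = None,
             zscore: bool = False,
             column_sources: Mapping[str, str] | None = None) -> FeatureMatrix:
    """Combine signal densities and sequence-derived columns into the matrix.

    ``signal_densities`` must provide exactly the 31 signal columns and
    ``sequence_features`` the 5 sequence-derived ones; both must cover the
    same samples in the same order. Columns are reordered to the canonical
    registry. With ``zscore=True`` every column is standardized to mean 0,
    sd 1 (constant columns are left centered only).
    """
    if len(signal_densities) != len(sequence_features):
        raise ValueError(
            f"sample-set mismatch: {len(signal_densities)} signal rows vs "
            f"{len(sequence_features)} sequence rows")
    missing_sig = set(SIGNAL_FEATURES) - set(signal_densities.columns)
    if missing_sig:
        raise ValueError(f"missing signal columns: {sorted(missing_sig)}")
    extra_sig = set(signal_densities.columns) - set(SIGNAL_FEATURES)
    if extra_sig:
        raise ValueError(
            f"unexpected signal columns (labels may be leaking): {sorted(extra_sig)}")
    missing_seq = set(SEQUENCE_FEATURES) - set(sequence_features.columns)
    if missing_seq:
        raise ValueError(f"missing sequence columns: {sorted(missing_seq)}")

    n = len(signal_densities)
    values = pd.concat(
        [signal_densities.reset_index(drop=True)[list(SIGNAL_FEATURES)],
         sequence_features.reset_index(drop=True)[list(SEQUENCE_FEATURES)]],
        axis=1)[list(FEATURE_NAMES)]
    if zscore and n:
        values = zscore_columns(values)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return FeatureMatrix(sample_ids=list(map(str, sample_ids)),
                         values=values,
                         labels=np.asarray(labels, dtype=int),
                         column_sources=dict(column_sources) if column_sources else None)


def zscore_columns(values: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column; constant columns are centered, not scaled."""
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame((arr - mean) / sd_safe, columns=values.columns,
                        index=values.index)


def zscore_matrix(fm: FeatureMatrix) -> FeatureMatrix:
    return FeatureMatrix(sample_ids=list(fm.sample_ids),
                         values=zscore_columns(fm.values),
                         labels=fm.labels.copy(),
                         column_sources=fm.column_sources)
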