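"""Rehabilitation assessment: similarity of synergy factors to a reference.

Progress is quantified by pairing a subject's CP synergy components with a
reference (typically healthy-subject) model via optimal assignment on the
spatial muscle-weight correlations, then reporting per-pair Pearson r in the
spatial, frequency and temporal domains under that single pairing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .decomposition import SynergyModel3D

__all__ = ["SimilarityReport", "pearson_r", "match_components", "compare_synergies"]


@dataclass
class SimilarityReport:
    """Per-pair similarity of a subject model to a reference model."""

    pairing: list[tuple[int, int]]  # (subject component, reference component)
    spatial_r: np.ndarray
    frequency_r: np.ndarray
    temporal_r: np.ndarray
    n_subject_synergies: int
    n_reference_synergies: int
    unpaired_subject: list[int] = field(default_factory=list)
    unpaired_reference: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "pairing": self.pairing,
            "spatial_r": self.spatial_r.tolist(),
            "frequency_r": self.frequency_r.tolist(),
            "temporal_r": self.temporal_r.tolist(),
            "n_subject_synergies": self.n_subject_synergies,
            "n_reference_synergies": self.n_reference_synergies,
            "unpaired_subject": self.unpaired_subject,
            "unpaired_reference": self.unpaired_reference,
        }))

    def to_rows(self) -> list[tuple]:
        """Flat (pair, domain, r) rows for CSV export."""
        rows = []
        for k, (si, ri) in enumerate(self.pairing):
            rows.append((f"S{si + 1}-R{ri + 1}", "spatial", self.spatial_r[k]))
            rows.append((f"S{si + 1}-R{ri + 1}", "frequency", self.frequency_r[k]))
            rows.append((f"S{si + 1}-R{ri + 1}", "temporal", self.temporal_r[k]))
        return rows


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("sequences must be 1-D, equal length, n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant sequence")
    return float(pearsonr(x, y).statistic)


def _safe_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, 0.0 for degenerate (constant) inputs."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(pearsonr(x, y).statistic)


def match_components(
    subject: SynergyModel3D, reference: SynergyModel3D
) -> list[tuple[int, int]]:
    """Injective pairing of components maximizing summed spatial Pearson r.

    Solved as an optimal assignment over the smaller rank; tie-breaks are
    deterministic (lowest index first).  Returns (subject, reference) index
    pairs sorted by subject index.
    """
    rs, rr = subject.S.shape[1], reference.S.shape[1]
    if rs == 0 or rr == 0:
        raise ValueError("both models must have at least one component")
    corr = np.empty((rs, rr))
    for i in range(rs):
        for j in range(rr):
            corr[i, j] = _safe_r(subject.S[:, i], reference.S[:, j])
    row, col = linear_sum_assignment(-corr)
    return sorted(zip(row.tolist(), col.tolist()))


def _resample(col: np.ndarray, n: int) -> np.ndarray:
    if col.size == n:
        return col
    return np.interp(np.linspace(0, 1, n), np.linspace(0, 1, col.size), col)


def compare_synergies(
    subject: SynergyModel3D, reference: SynergyModel3D
) -> SimilarityReport:
    """Per-pair Pearson similarity in the spatial, frequency and temporal domains.

    Pairs are fixed once by spatial matching and reused for the other two
    domains; temporal factors are linearly resampled to the reference length.
    Both models must be built over the same channel and scale sets.
    """
    if subject.S.shape[0] != reference.S.shape[0]:
        raise ValueError("models built over different channel sets")
    if (subject.channel_names and reference.channel_names
            and subject.channel_names != reference.channel_names):
        raise ValueError("channel-name mismatch between models")
    if subject.F.shape[0] != reference.F.shape[0]:
        raise ValueError("models built over different scale sets")
    pairing = match_components(subject, reference)
    sp, fr, te = [], [], []
    for si, ri in pairing:
        sp.append(_safe_r(subject.S[:, si], reference.S[:, ri]))
        fr.append(_safe_r(subject.F[:, si], reference.F[:, ri]))
        t_sub = _resample(subject.T[:, si], reference.T.shape[0])
        te.append(_safe_r(t_sub, reference.T[:, ri]))
    paired_s = {p[0] for p in pairing}
    paired_r = {p[1] for p in pairing}
    return SimilarityReport(
        pairing=pairing,
        spatial_r=np.array(sp),
        frequency_r=np.array(fr),
        temporal_r=np.array(te),
        n_subject_synergies=subject.S.shape[1],
        n_reference_synergies=reference.S.shape[1],
        unpaired_subject=[i for i in range(subject.S.shape[1]) if i not in paired_s],
        unpaired_reference=[j for j in range(reference.S.shape[1]) if j not in paired_r],
    )
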