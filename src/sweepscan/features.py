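"""Feature matrices for the window classifier.

A classification frame (default 1.05 Mb) is divided into 21 equal subwindows;
the 11 summary statistics (per-population ones computed for both populations,
18 rows in total) are evaluated per subwindow and each row is normalized by
its sum across subwindows, so the classifier sees the spatial *shape* of each
statistic along the frame rather than its absolute level.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .popdata import HaplotypeMatrix, PopulationPair, SiteMask
from .sumstats import STAT_NAMES, summary_stat_set

__all__ = ["FeatureMatrix", "build_features", "normalize_features", "feature_layout_hash"]

NORM_EPS = 1e-8


@dataclass
class FeatureMatrix:
    """Statistics x subwindows matrix for one classification frame.

    ``values`` holds the row-normalized matrix (each row sums to 1 unless the
    raw row-sum guard replaced it by the uniform row); ``raw`` the
    un-normalized statistics with NaN where undefined.  ``n_imputed`` counts
    raw NaN cells replaced by their row mean before normalization.
    """

    values: np.ndarray
    raw: np.ndarray
    stat_names: tuple[str, ...]
    window_meta: dict = field(default_factory=dict)
    n_imputed: int = 0

    @property
    def n_subwindows(self) -> int:
        return self.values.shape[1]

    def nan_fraction(self) -> float:
        return float(np.isnan(self.raw).mean())


def feature_layout_hash(stat_names: tuple[str, ...], n_subwindows: int, extra: dict | None = None) -> str:
    payload = json.dumps(
        {"stats": list(stat_names), "subwindows": n_subwindows, "extra": extra or {}},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def normalize_raw(raw: np.ndarray, eps: float = NORM_EPS) -> tuple[np.ndarray, int]:
    """Row-normalize a statistics x subwindows matrix.

    NaN cells are imputed to the row mean of the finite cells first; rows
    whose (post-imputation) sum has magnitude < ``eps`` — or that are all
    NaN — fall back to the uniform row 1/n.  Returns the normalized matrix
    and the number of imputed cells."""
    raw = np.asarray(raw, dtype=float)
    n_stats, n_sub = raw.shape
    out = raw.copy()
    n_imputed = 0
    for i in range(n_stats):
        row = out[i]
        bad = np.isnan(row)
        if bad.all():
            out[i] = 1.0 / n_sub
            n_imputed += int(bad.sum())
            continue
        if bad.any():
            row[bad] = row[~bad].mean()
            n_imputed += int(bad.sum())
        total = row.sum()
        if abs(total) < eps:
            out[i] = 1.0 / n_sub
        else:
            out[i] = row / total
    return out, n_imputed


def normalize_features(raw: "FeatureMatrix") -> "FeatureMatrix":
    """Normalized copy of a feature matrix (divide each statistic by its sum
    across subwindows; uniform fallback for near-zero row sums)."""
    values, n_imputed = normalize_raw(raw.raw)
    return FeatureMatrix(values, raw.raw, raw.stat_names, dict(raw.window_meta), n_imputed)


def build_features(
    hap: HaplotypeMatrix,
    mask: SiteMask | None,
    locus_interval: tuple[int, int],
    pair: PopulationPair,
    subwindows: int = 21,
    max_missing_frac: float = 0.2,
    pi_per_site: bool = True,
) -> FeatureMatrix:
    """Compute and normalize the statistics x subwindows matrix for one frame.

    The frame ``locus_interval`` must divide evenly into ``subwindows``.
    Subwindows with no accessible sequence get NaN statistics, flagged for
    imputation by the normalization step.
    """
    start, end = locus_interval
    if (end - start) % subwindows:
        raise ValueError("locus interval must divide evenly into subwindows")
    width = (end - start) // subwindows
    raw = np.empty((len(STAT_NAMES), subwindows))
    unmasked_frac = np.empty(subwindows)
    for w in range(subwindows):
        ws, we = start + w * width, start + (w + 1) * width
        acc = mask.accessible_bp(ws, we) if mask is not None else width
        unmasked_frac[w] = acc / width
        if acc == 0:
            raw[:, w] = np.nan
            continue
        stats = summary_stat_set(
            hap, (ws, we), pair, acc, max_missing_frac, pi_per_site
        )
        raw[:, w] = stats.as_vector()
    meta = {
        "chrom": hap.chrom,
        "start": start,
        "end": end,
        "central_start": start + (subwindows // 2) * width,
        "central_end": start + (subwindows // 2 + 1) * width,
        "unmasked_frac": unmasked_frac,
    }
    values, n_imputed = normalize_raw(raw)
    return FeatureMatrix(values, raw, STAT_NAMES, meta, n_imputed)
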