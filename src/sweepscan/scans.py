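"""Genome-wide empirical analyses.

Windowed Hudson-FST tracks (ratio of averages in non-overlapping 10-kb
windows, valid-site threshold), loess smoothing for plotting, outgroup-
polarized 2D site-frequency spectra with per-site allele downsampling, the
sliding-frame selection scan driven by the trained window classifier, window
intersection across pairwise comparisons, and the drift-null comparison of
empirical against simulated windowed-FST distributions.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classifier import ClassCall, WindowClassifier, predict_windows
from .features import FeatureMatrix, normalize_raw
from .popdata import (
    GenotypeDepthMatrix,
    HaplotypeMatrix,
    PopulationPair,
    SiteMask,
    apply_mask,
    coverage_filter,
)
from .simulate import DemographicModel, ne_swap_experiment, simulate_genome
from .sumstats import STAT_NAMES, hudson_fst_components, summary_stat_set

__all__ = [
    "FstTrack",
    "Sfs2D",
    "window_fst_scan",
    "loess_smooth",
    "build_2dsfs",
    "downsampled_sfs1d",
    "selection_scan",
    "scan_chromosome",
    "intersect_calls",
    "drift_null_compare",
]


# ---------------------------------------------------------------------------
# windowed FST


@dataclass
class FstTrack:
    """Non-overlapping fixed-width Hudson-FST windows for one chromosome.

    ``windows`` has columns chrom, start, end, n_valid_sites, fst; windows
    below the valid-site threshold are absent, not NaN rows.
    """

    windows: pd.DataFrame
    window_bp: int
    min_valid: int
    smoothed: np.ndarray | None = None

    def to_tsv(self, path) -> None:
        df = self.windows.copy()
        if self.smoothed is not None:
            df["fst_loess"] = self.smoothed
        df.to_csv(path, sep="\t", index=False, na_rep="NA")


def window_fst_scan(
    hap: HaplotypeMatrix,
    mask: SiteMask | None,
    depth: GenotypeDepthMatrix | None,
    pair: PopulationPair,
    window_bp: int = 10_000,
    min_valid: int = 2_000,
    chrom_length: int | None = None,
) -> FstTrack:
    """Hudson FST (ratio of averages) in non-overlapping windows.

    Valid sites per window are the unmasked positions minus any SNPs removed
    by the coverage filter (>= 5x in >= 80% of individuals when ``depth`` is
    given).  Windows with fewer than ``min_valid`` valid sites are excluded.
    """
    if chrom_length is None:
        if mask is not None:
            chrom_length = mask.length
        else:
            # round the span of the data up to whole windows
            top = int(hap.positions[-1]) + 1 if hap.n_sites else window_bp
            chrom_length = -(-top // window_bp) * window_bp
    work = hap
    dropped_pos = np.empty(0, dtype=np.int64)
    if depth is not None:
        before = work.positions
        work = coverage_filter(work, depth)
        dropped_pos = np.setdiff1d(before, work.positions)
    if mask is not None:
        work = apply_mask(work, mask)
        dropped_pos = dropped_pos[~mask.is_masked(dropped_pos)]

    num, den, pos = hudson_fst_components(work, pair)
    n_windows = chrom_length // window_bp
    edges = np.arange(n_windows + 1) * window_bp
    num_w = np.zeros(n_windows)
    den_w = np.zeros(n_windows)
    if pos.size:
        idx = np.searchsorted(edges, pos, side="right") - 1
        ok = (idx >= 0) & (idx < n_windows)
        np.add.at(num_w, idx[ok], num[ok])
        np.add.at(den_w, idx[ok], den[ok])
    rows = []
    for w in range(n_windows):
        ws, we = int(edges[w]), int(edges[w + 1])
        acc = mask.accessible_bp(ws, we) if mask is not None else window_bp
        n_valid = acc - int(((dropped_pos >= ws) & (dropped_pos < we)).sum())
        if n_valid < min_valid:
            continue
        fst = num_w[w] / den_w[w] if den_w[w] != 0 else np.nan
        rows.append((hap.chrom, ws, we, n_valid, fst))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_valid_sites", "fst"])
    return FstTrack(df, window_bp, min_valid)


def loess_smooth(
    track: "FstTrack | np.ndarray",
    span: float = 0.01,
    degree: int = 1,
    x: np.ndarray | None = None,
) -> np.ndarray:
    """Loess smoothing (tricube weights, local least-squares polynomial fit,
    gaussian family) evaluated at the window midpoints.

    Presentation-layer only: smoothed values never feed statistics.  Accepts
    an :class:`FstTrack` (midpoints as x, fst as y) or a plain y array with
    explicit ``x``.  With fewer than 10 points the raw values are returned
    with a warning.
    """
    if isinstance(track, FstTrack):
        y = track.windows["fst"].to_numpy(dtype=float)
        xs = (track.windows["start"].to_numpy() + track.windows["end"].to_numpy()) / 2.0
    else:
        y = np.asarray(track, dtype=float)
        xs = np.asarray(x, dtype=float) if x is not None else np.arange(y.size, dtype=float)
    n = y.size
    if n < 10:
        warnings.warn("fewer than 10 points; returning raw values", stacklevel=2)
        out = y.copy()
        if isinstance(track, FstTrack):
            track.smoothed = out
        return out
    q = int(np.ceil(span * n))
    q = min(max(q, degree + 1), n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(xs - xs[i])
        nearest = np.argpartition(d, q - 1)[:q]
        dmax = d[nearest].max()
        if dmax == 0:
            out[i] = y[nearest].mean()
            continue
        u = d[nearest] / dmax
        w = np.clip(1 - u**3, 0, None) ** 3
        if w.sum() == 0 or np.count_nonzero(w) <= degree:
            out[i] = np.average(y[nearest], weights=None)
            continue
        t = xs[nearest] - xs[i]
        design = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[nearest] * sw, rcond=None)
        out[i] = coef[0]
    if isinstance(track, FstTrack):
        track.smoothed = out
    return out


# ---------------------------------------------------------------------------
# 2D site-frequency spectra


@dataclass
class Sfs2D:
    """Unfolded joint site-frequency spectrum at downsampled allele counts."""

    counts: np.ndarray  # (n_down_a + 1) x (n_down_b + 1)
    n_down_a: int
    n_down_b: int
    pop_a: str
    pop_b: str
    site_indices: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def marginal(self, which: str) -> np.ndarray:
        if which == "a":
            return self.counts.sum(axis=1)
        if which == "b":
            return self.counts.sum(axis=0)
        raise ValueError("which must be 'a' or 'b'")


def _site_rng(master_seed: int, chrom: str, pos: int, pop: str) -> np.random.Generator:
    """Per-(site, population) random substream: downsampling draws depend only
    on the site, the population label and the master seed, so swapping the
    populations transposes the spectrum exactly."""
    key = (master_seed & 0x7FFFFFFF, zlib.crc32(chrom.encode()), int(pos), zlib.crc32(pop.encode()))
    return np.random.default_rng(np.random.SeedSequence(key))


def _downsampled_counts(
    hap: HaplotypeMatrix, pop: str, n_down: int, master_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per polarized site: derived count among ``n_down`` alleles drawn
    without replacement from the population's non-missing alleles; -1 where
    fewer than ``n_down`` alleles are available."""
    rows = hap.rows_for_pop(pop)
    sub = hap.alleles[rows]
    nonmiss = sub != -1
    m = nonmiss.sum(axis=0)
    d = ((sub == 1) & nonmiss).sum(axis=0)
    out = np.full(hap.n_sites, -1, dtype=np.int64)
    for j in range(hap.n_sites):
        if not hap.polarized[j] or m[j] < n_down:
            continue
        rng = _site_rng(master_seed, hap.chrom, int(hap.positions[j]), pop)
        out[j] = rng.hypergeometric(int(d[j]), int(m[j] - d[j]), n_down)
    return out, m


def build_2dsfs(
    hap: HaplotypeMatrix,
    pair: PopulationPair,
    n_down_a: int = 40,
    n_down_b: int = 40,
    seed: int = 0,
) -> Sfs2D:
    """Unfolded 2D SFS over polarized biallelic sites.

    Each site is downsampled to ``n_down`` alleles per population without
    replacement; sites with fewer valid allele calls than the downsampling
    size in either population are excluded.
    """
    if n_down_a < 2 or n_down_b < 2:
        raise ValueError("downsampling sizes must be >= 2")
    da, _ = _downsampled_counts(hap, pair.pop_a, n_down_a, seed)
    db, _ = _downsampled_counts(hap, pair.pop_b, n_down_b, seed)
    ok = (da >= 0) & (db >= 0)
    counts = np.zeros((n_down_a + 1, n_down_b + 1), dtype=np.int64)
    np.add.at(counts, (da[ok], db[ok]), 1)
    return Sfs2D(counts, n_down_a, n_down_b, pair.pop_a, pair.pop_b, np.flatnonzero(ok))


def downsampled_sfs1d(
    hap: HaplotypeMatrix,
    pop: str,
    n_down: int,
    seed: int = 0,
    site_indices: np.ndarray | None = None,
) -> np.ndarray:
    """1D downsampled unfolded SFS (same per-site substreams as the 2D
    builder), optionally restricted to a given site set."""
    d, _ = _downsampled_counts(hap, pop, n_down, seed)
    if site_indices is not None:
        sel = np.zeros(hap.n_sites, dtype=bool)
        sel[site_indices] = True
        d = np.where(sel, d, -1)
    out = np.zeros(n_down + 1, dtype=np.int64)
    ok = d >= 0
    np.add.at(out, d[ok], 1)
    return out


# ---------------------------------------------------------------------------
# the selection scan


def scan_chromosome(
    hap: HaplotypeMatrix,
    mask: SiteMask | None,
    pair: PopulationPair,
    clf: WindowClassifier,
    subwindow_bp: int,
    n_subwindows: int = 21,
    support_threshold: float = 0.99,
    min_unmasked_frac: float = 0.2,
    chrom_length: int | None = None,
    pi_per_site: bool = True,
) -> list[ClassCall]:
    """Classify sliding frames along one chromosome.

    The chromosome is tiled into subwindows; a frame of ``n_subwindows``
    consecutive tiles steps one tile at a time and its call is assigned to
    the central tile.  Central tiles with fewer than ``min_unmasked_frac``
    unmasked sites are skipped.  Per-tile statistics are computed once and
    reused across overlapping frames.
    """
    if chrom_length is None:
        chrom_length = mask.length if mask is not None else (int(hap.positions[-1]) + 1 if hap.n_sites else 0)
    n_tiles = chrom_length // subwindow_bp
    if n_tiles < n_subwindows:
        return []
    raw = np.empty((len(STAT_NAMES), n_tiles))
    acc_frac = np.empty(n_tiles)
    for t in range(n_tiles):
        ws, we = t * subwindow_bp, (t + 1) * subwindow_bp
        acc = mask.accessible_bp(ws, we) if mask is not None else subwindow_bp
        acc_frac[t] = acc / subwindow_bp
        if acc == 0:
            raw[:, t] = np.nan
            continue
        raw[:, t] = summary_stat_set(hap, (ws, we), pair, acc, pi_per_site=pi_per_site).as_vector()

    feats = []
    for k in range(n_tiles - n_subwindows + 1):
        c = k + n_subwindows // 2
        if acc_frac[c] < min_unmasked_frac:
            continue
        sub_raw = raw[:, k : k + n_subwindows]
        if np.isnan(sub_raw).mean() > 0.5:
            continue
        values, n_imp = normalize_raw(sub_raw)
        meta = {
            "chrom": hap.chrom,
            "start": k * subwindow_bp,
            "end": (k + n_subwindows) * subwindow_bp,
            "central_start": c * subwindow_bp,
            "central_end": (c + 1) * subwindow_bp,
            "unmasked_frac": acc_frac[k : k + n_subwindows].copy(),
        }
        feats.append(FeatureMatrix(values, sub_raw.copy(), STAT_NAMES, meta, n_imp))
    return predict_windows(clf, feats, support_threshold)


def selection_scan(
    haps: dict[str, HaplotypeMatrix],
    masks: dict[str, SiteMask] | None,
    pair: PopulationPair,
    clf: WindowClassifier,
    subwindow_bp: int,
    n_subwindows: int = 21,
    support_threshold: float = 0.99,
    min_unmasked_frac: float = 0.2,
    pi_per_site: bool = True,
) -> tuple[list[ClassCall], dict]:
    """Scan a multi-chromosome cohort; summary reports the fraction of
    classified windows with supported divergent calls, genome-wide and per
    chromosome."""
    calls: list[ClassCall] = []
    per_chrom: dict[str, dict] = {}
    for chrom in sorted(haps):
        mask = masks.get(chrom) if masks else None
        cc = scan_chromosome(
            haps[chrom], mask, pair, clf, subwindow_bp, n_subwindows,
            support_threshold, min_unmasked_frac, pi_per_site=pi_per_site,
        )
        n_div = sum(c.supported and c.call == "divergent" for c in cc)
        per_chrom[chrom] = {
            "n_classified": len(cc),
            "n_divergent_supported": n_div,
            "fraction_divergent_supported": n_div / len(cc) if cc else np.nan,
        }
        calls.extend(cc)
    n_div = sum(c.supported and c.call == "divergent" for c in calls)
    summary = {
        "n_classified": len(calls),
        "n_divergent_supported": n_div,
        "fraction_divergent_supported": n_div / len(calls) if calls else np.nan,
        "support_threshold": support_threshold,
        "per_chrom": per_chrom,
    }
    return calls, summary


def _central_window(call: ClassCall) -> tuple[str, int, int]:
    m = call.window_meta
    return (m["chrom"], int(m["central_start"]), int(m["central_end"]))


def intersect_calls(
    calls_by_comparison: list[list[ClassCall]],
    mode: str = "shared_divergent",
) -> tuple[set, list[int]]:
    """Window-set intersection across pairwise comparisons.

    ``all_pairs_common_windows`` returns the classified-window universe
    present in every comparison (the harmonized denominator for
    percent-of-genome summaries); ``shared_divergent`` returns the windows
    with a supported divergent call in every comparison.  All comparisons
    must use the same window grid.
    """
    if mode not in ("all_pairs_common_windows", "shared_divergent"):
        raise ValueError(f"unknown mode {mode!r}")
    widths = set()
    sets = []
    for calls in calls_by_comparison:
        wins = set()
        for c in calls:
            chrom, s, e = _central_window(c)
            widths.add(e - s)
            if mode == "all_pairs_common_windows" or (c.supported and c.call == "divergent"):
                wins.add((chrom, s, e))
        sets.append(wins)
    if len(widths) > 1:
        raise ValueError("comparisons use different window grids")
    if not sets:
        return set(), []
    common = set.intersection(*sets)
    return common, [len(s) for s in sets]


# ---------------------------------------------------------------------------
# drift-null genome simulations


def drift_null_compare(
    empirical_track: FstTrack | None,
    model: DemographicModel,
    chrom_lengths: dict[str, int],
    n_replicates: int,
    n_a: int,
    n_b: int,
    rng: np.random.Generator,
    swap_with: DemographicModel | None = None,
    mutation_scale: float = 1.0,
    recombination_scale: float = 1.0,
    window_bp: int = 10_000,
    min_valid: int = 2_000,
    pair_labels: tuple[str, str] = ("A", "B"),
) -> dict:
    """Distribution report of simulated windowed FST under the neutral model.

    Simulates ``n_replicates`` genomes (optionally after exchanging past and
    present effective sizes with ``swap_with``), computes windowed Hudson FST
    exactly like the empirical pipeline and reports quantiles plus a KS
    comparison against the empirical track when one is supplied.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    used = model
    if swap_with is not None:
        used, _ = ne_swap_experiment(model, swap_with)
    pair = PopulationPair(pair_labels[0], pair_labels[1], n_a, n_b)
    reps = simulate_genome(
        used, chrom_lengths, n_replicates, n_a, n_b, rng,
        mutation_scale, recombination_scale, pair_labels,
    )
    sim_fst: list[float] = []
    per_rep_medians = []
    for rep in reps:
        vals = []
        for chrom, hap in rep.items():
            track = window_fst_scan(
                hap, None, None, pair, window_bp, min_valid,
                chrom_length=chrom_lengths[chrom],
            )
            vals.extend(track.windows["fst"].dropna().tolist())
        sim_fst.extend(vals)
        per_rep_medians.append(float(np.median(vals)) if vals else np.nan)
    sim_fst_arr = np.asarray(sim_fst)
    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    report = {
        "n_replicates": n_replicates,
        "n_windows": int(sim_fst_arr.size),
        "sim_quantiles": {str(q): float(np.quantile(sim_fst_arr, q)) for q in qs}
        if sim_fst_arr.size
        else {},
        "sim_median": float(np.median(sim_fst_arr)) if sim_fst_arr.size else np.nan,
        "per_replicate_medians": per_rep_medians,
        "swapped": swap_with is not None,
    }
    if empirical_track is not None:
        emp = empirical_track.windows["fst"].dropna().to_numpy()
        report["empirical_quantiles"] = {str(q): float(np.quantile(emp, q)) for q in qs}
        report["empirical_median"] = float(np.median(emp))
        ks = sps.ks_2samp(emp, sim_fst_arr)
        report["ks_statistic"] = float(ks.statistic)
        report["ks_pvalue"] = float(ks.pvalue)
    return report
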