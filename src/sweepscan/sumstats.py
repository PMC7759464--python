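"""Population-genetic summary statistics on haplotype matrices.

The selection scan describes each subwindow by 11 statistics: within each
population pi, Tajima's D, Fay & Wu's H, Garud's H1, H12 and H2/H1 and the
1-HAF score; between populations Hudson's FST (ratio of averages), DXY, Gmin
and SS-H12.  Watterson's theta is included for simulator calibration.

Missing-data policy (see docs/methods.md): frequency-based statistics use
observed non-missing allele counts per site; haplotype-identity statistics
(H1/H12/H2-H1, 1-HAF, Gmin, SS-H12) first drop sites with more than
``max_missing_frac`` missing calls in the analysis panel and impute the rest
to the major allele of the haplotype's own population.  Undefined values are
returned as NaN, never silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np

from .popdata import MISSING, HaplotypeMatrix, PopulationPair

__all__ = [
    "SummaryStatSet",
    "STAT_NAMES",
    "nucleotide_diversity",
    "tajimas_d",
    "fay_wu_h",
    "garud_h",
    "haf_score",
    "hudson_fst",
    "hudson_fst_components",
    "dxy",
    "gmin",
    "ss_h12",
    "watterson_theta",
    "summary_stat_set",
]

DEFAULT_MAX_MISSING_FRAC = 0.2


# ---------------------------------------------------------------------------
# helpers


def _window(hap: HaplotypeMatrix, interval: tuple[int, int] | None) -> HaplotypeMatrix:
    if interval is None:
        return hap
    return hap.restrict(*interval)


def _counts(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (derived/alt count, non-missing count)."""
    nonmiss = alleles != MISSING
    d = ((alleles == 1) & nonmiss).sum(axis=0)
    return d, nonmiss.sum(axis=0)


def _pairwise_het(d: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference 2*d*(m-d)/(m*(m-1)); 0 where m < 2."""
    out = np.zeros(d.shape, dtype=float)
    ok = m >= 2
    out[ok] = 2.0 * d[ok] * (m[ok] - d[ok]) / (m[ok] * (m[ok] - 1.0))
    return out


def _imputed_panel(
    alleles: np.ndarray, max_missing_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Drop sites with too much missingness, impute the rest to the major
    allele (ties to 0).  Returns (imputed 0/1 matrix, kept-site indices)."""
    n = alleles.shape[0]
    miss = alleles == MISSING
    keep = np.flatnonzero(miss.sum(axis=0) <= max_missing_frac * n)
    sub = alleles[:, keep].copy()
    d, m = _counts(sub)
    major = np.where(2 * d > m, 1, 0).astype(np.int8)
    mm = sub == MISSING
    sub[mm] = np.broadcast_to(major, sub.shape)[mm]
    return sub, keep


def _imputed_by_pop(hap: HaplotypeMatrix, pair: PopulationPair, max_missing_frac: float):
    """Common kept-site set (pooled missingness rule), imputation within each
    population.  Returns (matrix_a, matrix_b) of 0/1 alleles."""
    rows_a = hap.rows_for_pop(pair.pop_a)
    rows_b = hap.rows_for_pop(pair.pop_b)
    pooled = hap.alleles[np.concatenate([rows_a, rows_b])]
    miss = pooled == MISSING
    keep = np.flatnonzero(miss.sum(axis=0) <= max_missing_frac * pooled.shape[0])

    out = []
    for rows in (rows_a, rows_b):
        sub = hap.alleles[rows][:, keep].copy()
        d, m = _counts(sub)
        major = np.where(2 * d > m, 1, 0).astype(np.int8)
        mm = sub == MISSING
        sub[mm] = np.broadcast_to(major, sub.shape)[mm]
        out.append(sub)
    return out[0], out[1]


def _hap_classes(panel: np.ndarray) -> np.ndarray:
    """Descending haplotype-class frequencies; ties broken lexicographically
    (np.unique returns classes in lexicographic order and the sort is stable)."""
    if panel.shape[1] == 0:
        return np.array([1.0])
    _, counts = np.unique(panel, axis=0, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    return counts[order] / panel.shape[0]


def _tajima_constants(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def _a1(n: int) -> float:
    return float((1.0 / np.arange(1, n)).sum()) if n > 1 else np.nan


# ---------------------------------------------------------------------------
# within-population statistics


def nucleotide_diversity(
    hap: HaplotypeMatrix, interval: tuple[int, int] | None, accessible_bp: int
) -> float:
    """Per-site pi: mean pairwise difference summed over sites, divided by
    the accessible base pairs of the interval."""
    if accessible_bp <= 0:
        warnings.warn("accessible_bp is 0; pi undefined", stacklevel=2)
        return np.nan
    w = _window(hap, interval)
    d, m = _counts(w.alleles)
    return float(_pairwise_het(d, m).sum() / accessible_bp)


def watterson_theta(
    hap: HaplotypeMatrix, interval: tuple[int, int] | None, accessible_bp: int
) -> float:
    """Watterson's theta per site: S / (a1(n) * accessible_bp)."""
    if accessible_bp <= 0:
        warnings.warn("accessible_bp is 0; theta_W undefined", stacklevel=2)
        return np.nan
    w = _window(hap, interval)
    if w.n_haplotypes < 2:
        return np.nan
    d, m = _counts(w.alleles)
    s = int(((d > 0) & (d < m)).sum())
    return s / (_a1(w.n_haplotypes) * accessible_bp)


def tajimas_d(hap: HaplotypeMatrix, interval: tuple[int, int] | None = None) -> float:
    """Tajima's D: (pi_total - S/a1) / sqrt(e1*S + e2*S*(S-1))."""
    w = _window(hap, interval)
    n = w.n_haplotypes
    if n < 3:
        return np.nan
    d, m = _counts(w.alleles)
    seg = (d > 0) & (d < m)
    s = int(seg.sum())
    if s == 0:
        return np.nan
    pi_total = _pairwise_het(d, m).sum()
    a1 = _a1(n)
    e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    return float((pi_total - s / a1) / np.sqrt(var))


def fay_wu_h(hap: HaplotypeMatrix, interval: tuple[int, int] | None = None) -> float:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H over polarized
    segregating sites (theta_H weights high-frequency derived alleles)."""
    w = _window(hap, interval)
    pol = w.take_sites(np.flatnonzero(w.polarized))
    d, m = _counts(pol.alleles)
    seg = (d > 0) & (d < m) & (m >= 2)
    if not seg.any():
        return np.nan
    d, m = d[seg], m[seg]
    theta_pi = 2.0 * d * (m - d) / (m * (m - 1.0))
    theta_h = 2.0 * d**2 / (m * (m - 1.0))
    return float((theta_pi - theta_h).sum())


def garud_h(
    hap: HaplotypeMatrix,
    interval: tuple[int, int] | None = None,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
) -> tuple[float, float, float]:
    """Garud's haplotype homozygosity statistics (H1, H12, H2/H1).

    H1 = sum p_i^2; H12 = (p1+p2)^2 + sum_{i>=3} p_i^2; H2 = H1 - p1^2,
    with p_i the descending haplotype-class frequencies.  A window with no
    segregating sites gives (1, 1, 0).
    """
    w = _window(hap, interval)
    if w.n_haplotypes == 0:
        return np.nan, np.nan, np.nan
    panel, _ = _imputed_panel(w.alleles, max_missing_frac)
    p = _hap_classes(panel)
    h1 = float((p**2).sum())
    h12 = float((p[:2].sum()) ** 2 + (p[2:] ** 2).sum())
    h2h1 = float((h1 - p[0] ** 2) / h1)
    return h1, h12, h2h1


def haf_score(
    hap: HaplotypeMatrix,
    interval: tuple[int, int] | None = None,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
) -> float:
    """1-HAF summary: each haplotype scores the sum of the derived-allele
    counts at the sites where it carries the derived allele; the window value
    is the mean score over haplotypes (sample-size comparable)."""
    w = _window(hap, interval)
    pol = w.take_sites(np.flatnonzero(w.polarized))
    if pol.n_sites == 0 or pol.n_haplotypes == 0:
        return np.nan
    panel, _ = _imputed_panel(pol.alleles, max_missing_frac)
    counts = panel.sum(axis=0)
    scores = panel.astype(np.int64) @ counts
    return float(scores.mean())


# ---------------------------------------------------------------------------
# between-population statistics


def hudson_fst_components(
    hap: HaplotypeMatrix, pair: PopulationPair, interval: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Hudson FST numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    Sites where either population has < 2 non-missing haplotypes are skipped.
    Returns (num, den, positions) for the contributing sites.
    """
    w = _window(hap, interval)
    da, ma = _counts(w.alleles[w.rows_for_pop(pair.pop_a)])
    db, mb = _counts(w.alleles[w.rows_for_pop(pair.pop_b)])
    ok = (ma >= 2) & (mb >= 2)
    da, ma, db, mb = da[ok], ma[ok], db[ok], mb[ok]
    p1 = da / ma
    p2 = db / mb
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (ma - 1) - p2 * (1 - p2) / (mb - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den, w.positions[ok]


def hudson_fst(
    hap: HaplotypeMatrix, interval: tuple[int, int] | None, pair: PopulationPair
) -> float:
    """Hudson's FST over the interval as a ratio of averages: sum(num)/sum(den)
    across sites (never an average of per-site ratios).  Sites monomorphic
    across both populations have den = 0 and contribute nothing."""
    num, den, _ = hudson_fst_components(hap, pair, interval)
    total_den = den.sum()
    if total_den == 0:
        return np.nan
    return float(num.sum() / total_den)


def dxy(
    hap: HaplotypeMatrix,
    interval: tuple[int, int] | None,
    pair: PopulationPair,
    accessible_bp: int,
) -> float:
    """Per-site between-population divergence: mean pairwise difference over
    all cross-population haplotype pairs, divided by accessible bp."""
    if accessible_bp <= 0:
        warnings.warn("accessible_bp is 0; dxy undefined", stacklevel=2)
        return np.nan
    w = _window(hap, interval)
    da, ma = _counts(w.alleles[w.rows_for_pop(pair.pop_a)])
    db, mb = _counts(w.alleles[w.rows_for_pop(pair.pop_b)])
    ok = (ma >= 1) & (mb >= 1)
    da, ma, db, mb = da[ok], ma[ok], db[ok], mb[ok]
    per_site = (da * (mb - db) + db * (ma - da)) / (ma * mb)
    return float(per_site.sum() / accessible_bp)


def gmin(
    hap: HaplotypeMatrix,
    interval: tuple[int, int] | None,
    pair: PopulationPair,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
) -> float:
    """Gmin: minimum cross-population pairwise distance divided by the mean
    cross-population pairwise distance; small values flag shared haplotypes."""
    w = _window(hap, interval)
    a, b = _imputed_by_pop(w, pair, max_missing_frac)
    a16 = a.astype(np.int16)
    b16 = b.astype(np.int16)
    dist = a16 @ (1 - b16).T + (1 - a16) @ b16.T
    mean = dist.mean()
    if mean == 0:
        return np.nan
    return float(dist.min() / mean)


def ss_h12(
    hap: HaplotypeMatrix,
    interval: tuple[int, int] | None,
    pair: PopulationPair,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
) -> float:
    """Signed pooled haplotype homozygosity separating shared from divergent
    sweeps.

    Magnitude: H12 of the pooled two-population sample.  Sign: +1 when the
    modal pooled haplotype class occurs in both populations at at least half
    its pooled frequency (a shared sweep), else -1 (the modal class is
    effectively private, as under divergent sweeps).  Near zero under
    neutrality because pooled H12 is then small.
    """
    w = _window(hap, interval)
    if w.n_sites == 0:
        return np.nan
    a, b = _imputed_by_pop(w, pair, max_missing_frac)
    pooled = np.concatenate([a, b], axis=0)
    classes, counts = np.unique(pooled, axis=0, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    p = counts[order] / pooled.shape[0]
    h12 = float((p[:2].sum()) ** 2 + (p[2:] ** 2).sum())
    modal = classes[order[0]]
    freq_a = float((a == modal).all(axis=1).mean()) if a.shape[0] else 0.0
    freq_b = float((b == modal).all(axis=1).mean()) if b.shape[0] else 0.0
    pooled_freq = p[0]
    sign = 1.0 if min(freq_a, freq_b) >= 0.5 * pooled_freq else -1.0
    return sign * h12


# ---------------------------------------------------------------------------
# the full statistic set


@dataclass
class SummaryStatSet:
    """The 11 selection-scan statistics for one window (per-population ones
    carried for both populations), in the fixed feature-row order."""

    pi_a: float
    pi_b: float
    tajd_a: float
    tajd_b: float
    faywu_h_a: float
    faywu_h_b: float
    h1_a: float
    h1_b: float
    h12_a: float
    h12_b: float
    h2h1_a: float
    h2h1_b: float
    haf1_a: float
    haf1_b: float
    fst: float
    dxy: float
    gmin: float
    ssh12: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


STAT_NAMES: tuple[str, ...] = tuple(f.name for f in fields(SummaryStatSet))


def summary_stat_set(
    hap: HaplotypeMatrix,
    interval: tuple[int, int] | None,
    pair: PopulationPair,
    accessible_bp: int,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
    pi_per_site: bool = True,
) -> SummaryStatSet:
    """All statistics for one window.  ``pi_per_site`` divides pi and dxy by
    accessible bp (the default); otherwise window totals are reported."""
    w = _window(hap, interval)
    sub_a = w.subpop(pair.pop_a)
    sub_b = w.subpop(pair.pop_b)
    denom = accessible_bp if pi_per_site else 1
    if accessible_bp <= 0:
        pi_a = pi_b = d_xy = np.nan
    else:
        pi_a = nucleotide_diversity(sub_a, None, denom)
        pi_b = nucleotide_diversity(sub_b, None, denom)
        d_xy = dxy(w, None, pair, denom)
    h1_a, h12_a, h2h1_a = garud_h(sub_a, None, max_missing_frac)
    h1_b, h12_b, h2h1_b = garud_h(sub_b, None, max_missing_frac)
    return SummaryStatSet(
        pi_a=pi_a,
        pi_b=pi_b,
        tajd_a=tajimas_d(sub_a),
        tajd_b=tajimas_d(sub_b),
        faywu_h_a=fay_wu_h(sub_a),
        faywu_h_b=fay_wu_h(sub_b),
        h1_a=h1_a,
        h1_b=h1_b,
        h12_a=h12_a,
        h12_b=h12_b,
        h2h1_a=h2h1_a,
        h2h1_b=h2h1_b,
        haf1_a=haf_score(sub_a, None, max_missing_frac),
        haf1_b=haf_score(sub_b, None, max_missing_frac),
        fst=hudson_fst(w, None, pair),
        dxy=d_xy,
        gmin=gmin(w, None, pair, max_missing_frac),
        ssh12=ss_h12(w, None, pair, max_missing_frac),
    )
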