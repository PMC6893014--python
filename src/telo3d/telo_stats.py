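"""Condition-level telomere statistics.

Aggregates per-spot tables into the study's headline readouts:

* per-cell spot counts (mean ± sd) against the expected 92 of a diploid
  G1 karyotype;
* relative telomere length from intensity sums — the ratio of
  per-replicate intensity-sum means between two conditions;
* spot-volume statistics, coefficient of variation, and the
  volume-vs-intensity linear fit (R²);
* clustering inference from the count deficit: with E telomeres expected
  but O spots observed, (E−O)/E of the telomeres are hidden inside
  multi-telomere spots, and — if every merged spot is a pair — (E−O)/O
  of the observed spots contain more than one telomere;
* bimodality of the spot-volume distribution (single telomeres vs merged
  spots) via 1- vs 2-component Gaussian mixtures on log-volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.mixture import GaussianMixture

from .models import CellRecord, ExpectedKaryotype


@dataclass
class ConditionSummary:
    """Per-condition statistics over gated G1 cells."""

    label: str
    n_cells: int
    mean_count: float
    sd_count: float
    mean_volume: float
    volume_cv: float
    intensity_sum_mean: float
    intensity_sum_sd: float
    intensity_cv: float


@dataclass
class CorrelationSummary:
    """Ordinary least-squares fit of spot volume on intensity sum."""

    r_squared: float
    slope: float
    intercept: float
    n_spots: int


@dataclass
class ClusteringEstimate:
    """Count-deficit and volume-bimodality view of telomere clustering."""

    expected_count: float
    observed_mean_count: float
    unresolved_fraction: float  # (E - O) / E
    min_multispot_fraction_pairwise: float  # (E - O) / O
    volume_bimodality_threshold: float | None
    is_bimodal: bool


def condition_summary(spots: pd.DataFrame, cells: list[CellRecord],
                      label: str = "") -> ConditionSummary:
    """Summarise a per-spot table over the G1-gated cells.

    ``spots`` must carry ``nucleus_id``, ``volume_um3`` and
    ``intensity_sum``; cells gated out of G1 are ignored, and G1 cells
    with no detected spots count as zero.
    """
    g1_ids = [c.nucleus_id for c in cells if c.phase_gate in ("G1", "ungated")]
    if len(g1_ids) == 0:
        raise ValueError("no G1 cells to summarise")
    spots = spots[spots["nucleus_id"].isin(g1_ids)]
    counts = spots.groupby("nucleus_id").size().reindex(g1_ids, fill_value=0)
    vol = spots["volume_um3"].to_numpy(float)
    inten = spots["intensity_sum"].to_numpy(float)

    def cv(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.mean(x)) if len(x) > 1 and np.mean(x) != 0 else 0.0

    return ConditionSummary(
        label=label,
        n_cells=len(g1_ids),
        mean_count=float(counts.mean()),
        sd_count=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        mean_volume=float(vol.mean()) if len(vol) else float("nan"),
        volume_cv=cv(vol),
        intensity_sum_mean=float(inten.mean()) if len(inten) else float("nan"),
        intensity_sum_sd=float(inten.std(ddof=1)) if len(inten) > 1 else 0.0,
        intensity_cv=cv(inten),
    )


def length_ratio(summary_a: ConditionSummary, summary_b: ConditionSummary,
                 per_replicate_means: pd.DataFrame,
                 statistic: str = "mean") -> tuple[float, float]:
    """Relative telomere length of condition b vs a from intensity sums.

    ``per_replicate_means`` has columns ``condition, replicate,
    intensity_sum_mean`` (or ``intensity_sum_median`` with
    ``statistic='median'``).  Replicates are paired by index; the ratio
    b/a is computed per replicate and its mean ± sd returned — mirroring
    a design with independent biological replicates.
    """
    col = f"intensity_sum_{statistic}"
    tab = per_replicate_means
    a = tab.loc[tab["condition"] == summary_a.label].sort_values("replicate")[col].to_numpy(float)
    b = tab.loc[tab["condition"] == summary_b.label].sort_values("replicate")[col].to_numpy(float)
    if len(a) == 0 or len(b) == 0 or len(a) != len(b):
        raise ValueError("need the same, non-zero number of replicates per condition")
    if np.any(a == 0):
        raise ZeroDivisionError("zero intensity-sum mean in the denominator condition")
    ratios = b / a
    return float(ratios.mean()), float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0


def volume_intensity_correlation(spots: pd.DataFrame) -> CorrelationSummary:
    """OLS fit of spot volume on intensity sum; R² is the squared Pearson r."""
    if len(spots) < 3:
        raise ValueError("need at least 3 spots for a correlation")
    x = spots["intensity_sum"].to_numpy(float)
    y = spots["volume_um3"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("constant intensity sums; correlation undefined")
    fit = sstats.linregress(x, y)
    return CorrelationSummary(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_spots=len(spots),
    )


def volume_bimodality(volumes: np.ndarray, random_state: int = 0,
                      ) -> tuple[bool, float | None]:
    """1- vs 2-component Gaussian mixture on log-volume, chosen by BIC.

    Returns ``(is_bimodal, threshold)``; the threshold is the crossing
    point of the two weighted component densities between their means
    (the volume above which a spot more likely holds >1 telomere).
    Bimodality requires both that the two-component model wins on BIC
    and that the fitted mixture density itself has two local maxima — a
    two-component fit to a merely skewed distribution does not qualify.
    """
    v = np.asarray(volumes, float)
    v = v[v > 0]
    if len(v) < 10:
        return False, None
    logv = np.log(v).reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=random_state).fit(logv)
    g2 = GaussianMixture(2, n_init=5, random_state=random_state).fit(logv)
    if g2.bic(logv) >= g1.bic(logv):
        return False, None
    means = g2.means_.ravel()
    sds = np.sqrt(g2.covariances_.ravel())
    w = g2.weights_
    lo, hi = np.sort(means)
    if hi - lo < 1e-9:
        return False, None
    span = np.linspace(logv.min() - 0.5, logv.max() + 0.5, 2001)
    mix = (w[0] * sstats.norm.pdf(span, means[0], sds[0])
           + w[1] * sstats.norm.pdf(span, means[1], sds[1]))
    n_modes = int(np.sum((mix[1:-1] > mix[:-2]) & (mix[1:-1] > mix[2:])))
    if n_modes < 2:
        return False, None
    grid = np.linspace(lo, hi, 2001)
    order = np.argsort(means)
    d_low = w[order[0]] * sstats.norm.pdf(grid, means[order[0]], sds[order[0]])
    d_high = w[order[1]] * sstats.norm.pdf(grid, means[order[1]], sds[order[1]])
    diff = d_low - d_high
    sign_change = np.nonzero(np.diff(np.sign(diff)))[0]
    if len(sign_change) == 0:
        return False, None
    threshold = float(np.exp(grid[sign_change[0]]))
    return True, threshold


def clustering_estimate(expected: ExpectedKaryotype, summary: ConditionSummary,
                        spots: pd.DataFrame, random_state: int = 0,
                        ) -> ClusteringEstimate:
    """Infer telomere clustering from the count deficit and volume modes.

    ``unresolved_fraction`` = (E − O)/E is the fraction of telomeres not
    individually resolved; ``min_multispot_fraction_pairwise`` = (E − O)/O
    is the fraction of observed spots that must hold >1 telomere if each
    merged spot is a pair (each merged pair hides exactly one count).
    Negative values (O > E) are reported as-is.
    """
    e = float(expected.expected_telomeres)
    o = float(summary.mean_count)
    if e <= 0:
        raise ValueError("expected count must be positive")
    if o <= 0:
        raise ValueError("observed mean count must be positive")
    is_bim, thr = volume_bimodality(
        spots["volume_um3"].to_numpy(float), random_state=random_state)
    return ClusteringEstimate(
        expected_count=e,
        observed_mean_count=o,
        unresolved_fraction=(e - o) / e,
        min_multispot_fraction_pairwise=(e - o) / o,
        volume_bimodality_threshold=thr,
        is_bimodal=is_bim,
    )


def genomic_fraction(telomere_length_kb: float, n_chromosomes: int = 46,
                     genome_bp: float = 6e9) -> tuple[float, float]:
    """Telomeric fraction of the genome and its reciprocal.

    Two telomeres of ``telomere_length_kb`` per chromosome:
    fraction = 2 * n_chromosomes * length_bp / genome_bp.
    """
    if telomere_length_kb <= 0 or n_chromosomes <= 0 or genome_bp <= 0:
        raise ValueError("inputs must be positive")
    fraction = 2.0 * n_chromosomes * telomere_length_kb * 1e3 / genome_bp
    return fraction, 1.0 / fraction


def expected_count(karyotype: ExpectedKaryotype, phase: str = "G1") -> int:
    """Expected telomere count: 2 per chromosome in G1, doubled for G2."""
    if karyotype.n_chromosomes <= 0:
        raise ValueError("n_chromosomes must be positive")
    base = karyotype.expected_telomeres
    return 2 * base if phase == "G2" else base


def compare_conditions(values_a: np.ndarray, values_b: np.ndarray,
                       ) -> tuple[float, float]:
    """Two-tailed unpaired t-test on per-cell values; returns (t, p)."""
    t, p = sstats.ttest_ind(np.asarray(values_a, float),
                            np.asarray(values_b, float))
    return float(t), float(p)
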