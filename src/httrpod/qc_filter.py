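"""Sample QC, normalization, probe filtering and per-contrast statistics.

Sample-level quality control follows the rules used for TempO-Seq
count matrices: a mapped-read floor (10% of the target depth), a Gini
coefficient ceiling of 0.95 on the per-probe read distribution, a
nearest-neighbour 1 − Spearman-ρ distance cut-off of 0.1, and Tukey
outer fences (3 × IQR, inclusive) on the number of detected probes
(≥ 5 reads) and the number of probes capturing the top 80% of signal.

Probe relevance filtering applies the R-ODAF rules: a probe is kept
when at least 75% of the samples of at least one experimental group
exceed 0.5 counts per million, and removed as a spurious spike when,
in any group, max − median of its counts reaches
sum / (n_replicates + 1).

Contrast statistics use median-of-ratios size factors and a Welch
t-test on log2(normalized count + 0.5); this is a deliberately simple,
documented estimator standing in for a shrinkage-based differential
expression fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .experiment import CountExperiment

PSEUDOCOUNT = 0.5
DETECTED_MIN_READS = 5
TOP_SIGNAL_FRACTION = 0.80


@dataclass
class QCThresholds:
    """Sample-QC cut-offs; defaults are the study values."""

    target_reads: float | None = None
    min_reads_fraction: float = 0.10
    gini_max: float = 0.95
    spearman_distance_max: float = 0.1
    outer_fence_k: float = 3.0


@dataclass
class SampleQCReport:
    sample_id: str
    library_size: int
    n_detected_probes: int
    n_top80_probes: int
    gini: float
    min_pairwise_spearman_distance: float
    pass_: bool
    fail_reasons: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------
# QC metrics
# ----------------------------------------------------------------------
def gini(counts) -> float:
    """Gini coefficient of a non-negative vector.

    ``G = sum_i (2i - n - 1) x_(i) / (n sum(x))`` over ascending-sorted
    values: 0 for perfect equality, (n−1)/n when a single entry carries
    all mass.
    """
    x = np.sort(np.asarray(counts, dtype=float))
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("need a 1-D non-empty vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("Gini undefined for an all-zero vector")
    n = len(x)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * total))


def _n_top_signal_probes(col: np.ndarray, fraction: float = TOP_SIGNAL_FRACTION) -> int:
    desc = np.sort(col)[::-1]
    cum = np.cumsum(desc)
    total = cum[-1]
    if total == 0:
        return 0
    return int(np.searchsorted(cum, fraction * total) + 1)


def _tukey_fences(values: np.ndarray, k: float) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])  # linear-interpolation quartiles
    iqr = q3 - q1
    if iqr == 0:
        # degenerate spread (e.g. every probe detected in every sample):
        # no distribution to define extreme outliers from, rule is inert
        return -np.inf, np.inf
    return q1 - k * iqr, q3 + k * iqr


def sample_qc(
    experiment: CountExperiment, thresholds: QCThresholds
) -> list[SampleQCReport]:
    """Evaluate every sample against the four QC rules.

    A sample fails when (a) its library size is below
    ``min_reads_fraction × target_reads``, (b) its Gini coefficient
    exceeds ``gini_max``, (c) its minimum 1 − Spearman-ρ distance to
    every other sample exceeds ``spearman_distance_max``, or (d) its
    detected-probe or top-80%-signal probe count falls outside the
    study-wide Tukey outer fences (inclusive boundaries).
    ``fail_reasons`` enumerates each rule violated.  Verdicts do not
    depend on sample order.
    """
    if thresholds.target_reads is None:
        raise ValueError("target_reads must be set explicitly (no silent default)")
    counts = experiment.counts.to_numpy(dtype=float)
    n_probes, n_samples = counts.shape
    if n_samples < 4:
        raise ValueError("need at least 4 samples for outlier fences")

    lib = counts.sum(axis=0)
    n_detected = (counts >= DETECTED_MIN_READS).sum(axis=0)
    n_top80 = np.array([_n_top_signal_probes(counts[:, j]) for j in range(n_samples)])
    g = np.array([gini(counts[:, j]) for j in range(n_samples)])

    # Spearman is invariant under monotone transforms, so computing it on
    # raw counts equals computing it on log counts.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(counts, axis=0).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, np.inf)
    min_dist = np.nanmin(dist, axis=1)
    # identical profiles give rho=1 -> distance 0; degenerate constant
    # columns give nan, treated as maximal dissimilarity
    min_dist = np.where(np.isfinite(min_dist), min_dist, 2.0)

    det_lo, det_hi = _tukey_fences(n_detected.astype(float), thresholds.outer_fence_k)
    top_lo, top_hi = _tukey_fences(n_top80.astype(float), thresholds.outer_fence_k)

    reports = []
    for j, sid in enumerate(experiment.sample_ids):
        reasons = []
        if lib[j] < thresholds.min_reads_fraction * thresholds.target_reads:
            reasons.append("mapped_reads")
        if g[j] > thresholds.gini_max:
            reasons.append("gini")
        if min_dist[j] > thresholds.spearman_distance_max:
            reasons.append("spearman")
        if not (det_lo <= n_detected[j] <= det_hi) or not (top_lo <= n_top80[j] <= top_hi):
            reasons.append("outer_fence")
        reports.append(
            SampleQCReport(
                sample_id=sid,
                library_size=int(lib[j]),
                n_detected_probes=int(n_detected[j]),
                n_top80_probes=int(n_top80[j]),
                gini=float(g[j]),
                min_pairwise_spearman_distance=float(min_dist[j]),
                pass_=not reasons,
                fail_reasons=reasons,
            )
        )
    return reports


def qc_report_frame(reports: list[SampleQCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "library_size": [r.library_size for r in reports],
            "n_detected_probes": [r.n_detected_probes for r in reports],
            "n_top80_probes": [r.n_top80_probes for r in reports],
            "gini": [r.gini for r in reports],
            "min_pairwise_spearman_distance": [
                r.min_pairwise_spearman_distance for r in reports
            ],
            "pass": [r.pass_ for r in reports],
            "fail_reasons": [";".join(r.fail_reasons) for r in reports],
        }
    ).set_index("sample_id")


# ----------------------------------------------------------------------
# Normalization
# ----------------------------------------------------------------------
def size_factors_median_of_ratios(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (the DESeq estimator).

    ``factor_j = median_i(count_ij / geomean_i)`` over probes expressed
    in every sample.  Columns that are exact scalar multiples of one
    another recover those scalars up to a common constant.  When no
    probe is expressed in all samples, falls back to library-size
    ratios with a warning.
    """
    x = np.asarray(counts, dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        warnings.warn(
            "no probe expressed in all samples; falling back to library-size factors",
            stacklevel=2,
        )
        lib = x.sum(axis=0)
        return lib / np.exp(np.mean(np.log(np.where(lib > 0, lib, 1.0))))
    sub = x[all_pos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    return np.exp(np.median(np.log(sub) - log_geo, axis=0))


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, normalized by per-sample library size."""
    lib = counts.sum(axis=0)
    return counts * 1e6 / lib


# ----------------------------------------------------------------------
# Probe filters
# ----------------------------------------------------------------------
def relevance_filter(
    counts: pd.DataFrame,
    groups: pd.Series,
    cpm_min: float = 0.5,
    group_fraction: float = 0.75,
) -> pd.Index:
    """Probes where at least ``group_fraction`` of one group's samples
    exceed ``cpm_min`` counts per million."""
    if set(groups.index) != set(counts.columns):
        raise ValueError("group labels must cover all samples")
    c = cpm(counts)
    keep = pd.Series(False, index=counts.index)
    for _, members in groups.groupby(groups).groups.items():
        if len(members) == 0:
            raise ValueError("empty group")
        frac = (c[list(members)] > cpm_min).sum(axis=1) / len(members)
        keep |= frac >= group_fraction
    return counts.index[keep]


def spike_filter(
    counts: pd.DataFrame,
    groups: pd.Series,
    remove_when_spiked: bool = True,
) -> pd.Index:
    """Remove probes whose signal within any group is a spurious spike.

    A probe is a spike in a group when ``max − median >= sum / (n + 1)``
    for that group's replicate counts (n = replicates).  Kept probes
    satisfy ``max − median < sum / (n + 1)`` in every group.  The
    published rule's sentence admits the opposite polarity;
    ``remove_when_spiked=False`` flips it.
    """
    keep = pd.Series(True, index=counts.index)
    for _, members in groups.groupby(groups).groups.items():
        sub = counts[list(members)].to_numpy(dtype=float)
        n = sub.shape[1]
        if n < 2:
            raise ValueError("spike rule needs >= 2 replicates per group")
        spiked = sub.max(axis=1) - np.median(sub, axis=1) >= sub.sum(axis=1) / (n + 1)
        keep &= ~spiked if remove_when_spiked else spiked
    return counts.index[keep]


# ----------------------------------------------------------------------
# Contrast statistics
# ----------------------------------------------------------------------
@dataclass
class ContrastResult:
    probe_id: str
    log2_fold_change: float
    linear_fold_change: float
    unadjusted_p: float
    mean_cpm_treated: float
    mean_cpm_control: float
    passed_relevance: bool = True


def contrast_stats(
    experiment: CountExperiment,
    chemical: str,
    concentration: float,
    size_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-probe log2 fold change and unadjusted p for one
    treated-vs-plate-matched-control contrast.

    Counts are divided by median-of-ratios size factors (computed
    experiment-wide unless supplied), log2(x + 0.5)-transformed, and
    compared by a Welch t-test.  Linear fold change is ``2^|log2FC|``
    with the sign of the change.  Relevance and spike filters are
    assumed already applied to ``experiment``.
    """
    treated = experiment.treated_samples(chemical, concentration)
    if not treated:
        raise ValueError(f"no treated samples for {chemical} at {concentration} µM")
    plates = set(experiment.metadata.loc[treated, "plate"])
    controls = [s for p in sorted(plates) for s in experiment.control_samples(plate=p)]
    if not controls:
        raise ValueError("no plate-matched control samples")
    if len(treated) < 2 or len(controls) < 2:
        raise ValueError("each group needs >= 2 samples for a p-value")

    if size_factors is None:
        size_factors = size_factors_median_of_ratios(experiment.counts)
    sf = pd.Series(size_factors, index=experiment.sample_ids)
    norm = experiment.counts / sf
    log_t = np.log2(norm[treated].to_numpy() + PSEUDOCOUNT)
    log_c = np.log2(norm[controls].to_numpy() + PSEUDOCOUNT)

    lfc = log_t.mean(axis=1) - log_c.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(log_t, log_c, axis=1, equal_var=False).pvalue
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance ties -> uninformative

    c = cpm(experiment.counts)
    return pd.DataFrame(
        {
            "probe_id": experiment.probe_ids,
            "log2_fold_change": lfc,
            "linear_fold_change": np.where(lfc >= 0, 2.0**lfc, -(2.0**-lfc)),
            "unadjusted_p": p,
            "mean_cpm_treated": c[treated].mean(axis=1).to_numpy(),
            "mean_cpm_control": c[controls].mean(axis=1).to_numpy(),
        }
    ).set_index("probe_id")
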