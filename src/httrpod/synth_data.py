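"""Synthetic concentration-response count experiments with known ground truth.

Emulates a TempO-Seq-style design: an 8-point concentration series
(0.001–50 µM) with ≥4 replicates per concentration plus plate-matched
solvent controls, negative-binomial counts, and a minority of probes
responding monotonically through a saturating (Hill-type)
concentration-response curve with known parameters.  Because every
responsive probe's benchmark concentration is available in closed form,
every downstream stage (QC, trend testing, curve fitting, tPOD
derivation, mixture addition) can be tested for parameter recovery
without any external data.

The generative model: for probe *i* in sample *j* at concentration
:math:`c_j`,

.. math:: y_{ij} \\sim \\mathrm{NB}(\\mu = m_i(c_j)\\, s_j,\\ k_i)

where :math:`m_i(c)` is the Hill mean (:func:`hill_mean`), :math:`s_j`
a per-sample size factor, and :math:`k_i` the negative-binomial size
(dispersion) parameter.  Down-regulation divides by the fold-change
curve so fold changes are symmetric on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiment import CountExperiment

DEFAULT_CONCENTRATIONS = (0.001, 0.01, 0.1, 0.5, 1.0, 5.0, 10.0, 50.0)
LN2 = math.log(2.0)


# ----------------------------------------------------------------------
# Design and ground truth
# ----------------------------------------------------------------------
@dataclass
class SimDesign:
    """Layout of a simulated concentration series.

    ``concentrations`` must be strictly increasing and positive;
    replicates at least 2.  Samples are assigned round-robin to
    ``n_plates`` plates and every plate receives
    ``n_control_replicates`` solvent-control wells.
    ``plate_effect_sigma`` adds an optional multiplicative log-normal
    size factor per plate (default off); ``size_factor_sigma`` is the
    log-normal spread of per-sample library-size factors.
    """

    n_probes: int
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_replicates: int = 4
    n_control_replicates: int = 4
    n_plates: int = 1
    plate_effect_sigma: float = 0.0
    size_factor_sigma: float = 0.05

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.ndim != 1 or len(conc) < 2:
            raise ValueError("need at least two concentrations")
        if (conc <= 0).any() or (np.diff(conc) <= 0).any():
            raise ValueError("concentrations must be strictly increasing and positive")
        if self.n_replicates < 2 or self.n_control_replicates < 1:
            raise ValueError("replicates out of range")
        if self.n_probes < 1 or self.n_plates < 1:
            raise ValueError("n_probes and n_plates must be positive")


@dataclass
class GeneTruth:
    """Ground-truth generative parameters for one probe.

    ``dispersion`` is the negative-binomial size parameter *k* (may be
    ``inf`` for a Poisson surrogate).  Non-responsive probes must have
    ``max_fold_change == 1``.  ``biomarker_member`` optionally tags the
    probe as belonging to a named directional gene set.
    """

    probe_id: str
    baseline_mean: float
    dispersion: float
    responsive: bool
    direction: str = "up"
    max_fold_change: float = 1.0
    ac50: float = 1.0
    hill_coef: float = 1.0
    biomarker_member: str | None = None

    def __post_init__(self) -> None:
        for name in ("baseline_mean", "dispersion", "max_fold_change", "ac50", "hill_coef"):
            v = getattr(self, name)
            if not (v > 0) or (math.isnan(v)):
                raise ValueError(f"{name} must be positive and finite-or-inf, got {v!r}")
        if math.isinf(self.max_fold_change) or math.isinf(self.ac50) or math.isinf(self.hill_coef):
            raise ValueError("fold change, ac50 and hill coefficient must be finite")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not self.responsive and self.max_fold_change != 1.0:
            raise ValueError("non-responsive probes must have max_fold_change = 1")
        if self.max_fold_change < 1.0:
            raise ValueError("max_fold_change must be >= 1")


def hill_mean(conc: float | np.ndarray, truth: GeneTruth) -> float | np.ndarray:
    """Expected count at concentration ``conc`` (µM) under the Hill model.

    Up-regulated probes follow
    ``baseline * (1 + (F-1) * c^h / (ac50^h + c^h))``; down-regulated
    probes divide the baseline by the same saturating fold-change curve,
    so the response is monotone in ``conc`` and symmetric on the log
    scale.  At ``conc = 0`` the baseline is returned exactly.
    """
    c = np.asarray(conc, dtype=float)
    if (c < 0).any():
        raise ValueError("concentration must be non-negative")
    h, a = truth.hill_coef, truth.ac50
    with np.errstate(divide="ignore"):
        frac = np.where(c > 0, c**h / (a**h + c**h), 0.0)
    fold = 1.0 + (truth.max_fold_change - 1.0) * frac
    out = truth.baseline_mean * fold if truth.direction == "up" else truth.baseline_mean / fold
    return float(out) if np.isscalar(conc) else out


def analytic_bmc(truth: GeneTruth, bmr_log2: float) -> float | None:
    """Closed-form concentration at which |log2 response - log2 baseline|
    reaches ``bmr_log2``.

    Returns ``None`` for non-responsive probes and whenever the response
    saturates below the benchmark (``2^bmr >= max_fold_change``); the
    root is unique because the Hill curve is strictly monotone.
    """
    if not truth.responsive or truth.max_fold_change <= 1.0:
        return None
    r = 2.0**bmr_log2 - 1.0
    span = truth.max_fold_change - 1.0
    if r <= 0 or r >= span:
        return None
    return float(truth.ac50 * (r / (span - r)) ** (1.0 / truth.hill_coef))


def control_log2_sd(truth: GeneTruth) -> float:
    """Delta-method SD of log2 counts at the control concentration.

    ``Var(log2 Y) ≈ (1/µ + 1/k) / ln(2)^2`` for NB(µ, k); the ``1/k``
    term vanishes for the Poisson surrogate ``k = inf``.
    """
    mu, k = truth.baseline_mean, truth.dispersion
    extra = 0.0 if math.isinf(k) else 1.0 / k
    return math.sqrt(1.0 / mu + extra) / LN2


def make_truths(
    n_probes: int,
    n_responsive: int,
    seed: int,
    *,
    baseline_log_mean: float = math.log(100.0),
    baseline_log_sigma: float = 1.0,
    dispersion_log_mean: float = math.log(20.0),
    dispersion_log_sigma: float = 0.4,
    fold_change_range: tuple[float, float] = (2.5, 6.0),
    ac50_log10_range: tuple[float, float] = (-1.0, 1.0),
    hill_range: tuple[float, float] = (1.0, 2.0),
    frac_down: float = 0.3,
    biomarker_set: str | None = None,
    n_biomarker: int = 0,
) -> list[GeneTruth]:
    """Draw a realistic truth table: log-normal baselines and dispersions,
    the first ``n_responsive`` probes responsive with log-uniform AC50s.

    When ``biomarker_set`` is given, the first ``n_biomarker`` responsive
    probes are tagged as members of that directional gene set.
    """
    if n_responsive > n_probes:
        raise ValueError("n_responsive exceeds n_probes")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(baseline_log_mean, baseline_log_sigma, n_probes))
    base = np.clip(base, 5.0, None)  # keep detectable above the CPM floor
    disp = np.exp(rng.normal(dispersion_log_mean, dispersion_log_sigma, n_probes))
    fc = rng.uniform(*fold_change_range, n_probes)
    ac50 = 10.0 ** rng.uniform(*ac50_log10_range, n_probes)
    hill = rng.uniform(*hill_range, n_probes)
    down = rng.random(n_probes) < frac_down
    truths = []
    for i in range(n_probes):
        resp = i < n_responsive
        member = biomarker_set if (resp and i < n_biomarker) else None
        truths.append(
            GeneTruth(
                probe_id=f"P{i:05d}",
                baseline_mean=float(base[i]),
                dispersion=float(disp[i]),
                responsive=resp,
                direction="down" if (resp and down[i]) else "up",
                max_fold_change=float(fc[i]) if resp else 1.0,
                ac50=float(ac50[i]),
                hill_coef=float(hill[i]),
                biomarker_member=member,
            )
        )
    return truths


def mixture_truths(
    truths: list[GeneTruth],
    fractions: list[float],
    potency_ratios: list[float],
) -> list[GeneTruth]:
    """Ground truth for a mixture whose components share one mechanism.

    Component *i* is modeled as a dilution of the reference component
    with potency ratio ``rho_i`` (its AC50 is ``rho_i`` times the
    reference AC50).  Under concentration addition the mixture at total
    concentration *c* acts like the reference at
    ``c * sum(p_i / rho_i)``, which for a Hill curve is again a Hill
    curve with AC50 scaled by ``1 / sum(p_i / rho_i)``.
    """
    p = np.asarray(fractions, dtype=float)
    rho = np.asarray(potency_ratios, dtype=float)
    if len(p) != len(rho):
        raise ValueError("fractions and potency_ratios length mismatch")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    scale = 1.0 / float((p / rho).sum())
    out = []
    for t in truths:
        out.append(
            GeneTruth(
                probe_id=t.probe_id,
                baseline_mean=t.baseline_mean,
                dispersion=t.dispersion,
                responsive=t.responsive,
                direction=t.direction,
                max_fold_change=t.max_fold_change,
                ac50=t.ac50 * scale if t.responsive else t.ac50,
                hill_coef=t.hill_coef,
                biomarker_member=t.biomarker_member,
            )
        )
    return out


def truth_table(truths: list[GeneTruth]) -> pd.DataFrame:
    """Tabular mirror of the GeneTruth fields, indexed by probe id."""
    return pd.DataFrame(
        {
            "probe_id": [t.probe_id for t in truths],
            "baseline_mean": [t.baseline_mean for t in truths],
            "dispersion": [t.dispersion for t in truths],
            "responsive": [t.responsive for t in truths],
            "direction": [t.direction for t in truths],
            "max_fold_change": [t.max_fold_change for t in truths],
            "ac50": [t.ac50 for t in truths],
            "hill_coef": [t.hill_coef for t in truths],
            "biomarker_member": [t.biomarker_member or "" for t in truths],
        }
    ).set_index("probe_id")


# ----------------------------------------------------------------------
# Count generation
# ----------------------------------------------------------------------
def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    if math.isinf(size_param):
        return rng.poisson(mean)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_experiment(
    design: SimDesign,
    truths: list[GeneTruth],
    seed: int,
    chemical: str = "chemA",
) -> tuple[CountExperiment, pd.DataFrame]:
    """Simulate counts for one chemical's concentration series.

    Returns the experiment and its ground-truth table.  Identical seeds
    give bit-identical output.
    """
    if len(truths) != design.n_probes:
        raise ValueError("probe count does not match number of truths")
    rng = np.random.default_rng(seed)

    # sample layout: controls per plate first, then treated round-robin
    rows = []
    for plate in range(design.n_plates):
        for r in range(design.n_control_replicates):
            rows.append((f"{chemical}_ctrl_p{plate}_r{r}", chemical, 0.0, plate, r, "control"))
    for ci, conc in enumerate(design.concentrations):
        for r in range(design.n_replicates):
            plate = r % design.n_plates
            rows.append((f"{chemical}_c{ci}_r{r}", chemical, float(conc), plate, r, "treated"))
    meta = pd.DataFrame(
        rows,
        columns=["sample_id", "chemical", "concentration_uM", "plate", "replicate", "role"],
    ).set_index("sample_id")

    plate_factor = (
        np.exp(rng.normal(0.0, design.plate_effect_sigma, design.n_plates))
        if design.plate_effect_sigma > 0
        else np.ones(design.n_plates)
    )
    sf = np.exp(rng.normal(0.0, design.size_factor_sigma, len(meta)))
    sf *= plate_factor[meta["plate"].to_numpy()]

    conc_vec = meta["concentration_uM"].to_numpy(dtype=float)
    counts = np.empty((design.n_probes, len(meta)), dtype=np.int64)
    for i, t in enumerate(truths):
        mean = hill_mean(conc_vec, t) * sf
        counts[i] = _nb_draw(rng, mean, t.dispersion)
    counts_df = pd.DataFrame(counts, index=[t.probe_id for t in truths], columns=meta.index)
    return CountExperiment(counts_df, meta), truth_table(truths)


# ----------------------------------------------------------------------
# QC-failure injection
# ----------------------------------------------------------------------
def inject_qc_failures(
    experiment: CountExperiment,
    spec: dict[str, list[str]],
    seed: int,
    low_depth_reads: int = 50_000,
) -> CountExperiment:
    """Corrupt named samples so they must fail specific QC rules.

    ``spec`` keys: ``low_depth`` (samples binomially thinned to about
    ``low_depth_reads`` total reads), ``spiked`` (the sample's whole
    library moved onto its single most-expressed probe, so the Gini
    coefficient reaches its degenerate bound (n−1)/n), and
    ``decorrelated`` (counts permuted across probes, destroying rank
    correlation with every other sample while preserving depth and
    inequality metrics).  An empty spec returns an identical copy.
    """
    known = {"low_depth", "spiked", "decorrelated"}
    unknown_keys = set(spec) - known
    if unknown_keys:
        raise ValueError(f"unknown corruption kinds: {sorted(unknown_keys)}")
    all_named = [s for ids in spec.values() for s in ids]
    missing = set(all_named) - set(experiment.sample_ids)
    if missing:
        raise KeyError(f"unknown sample ids: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    counts = experiment.counts.copy()
    for sid in spec.get("low_depth", []):
        col = counts[sid].to_numpy()
        total = col.sum()
        if total > low_depth_reads:
            counts[sid] = rng.binomial(col, low_depth_reads / total)
    for sid in spec.get("spiked", []):
        col = counts[sid].to_numpy()
        total = col.sum()
        new = np.zeros_like(col)
        new[int(np.argmax(col))] = total
        counts[sid] = new
    for sid in spec.get("decorrelated", []):
        counts[sid] = rng.permutation(counts[sid].to_numpy())
    return CountExperiment(counts, experiment.metadata.copy())
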