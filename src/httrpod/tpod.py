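"""Transcriptomic points of departure (tPODs) and their bootstrap CIs.

Five tPOD methods over the surviving gene-level BMC table:

- ``gene25`` — the 25th lowest gene BMC (bounds from that gene's
  BMCL/BMCU), marking where concerted transcriptomic change begins
  above the platform's noise floor;
- ``pathway5pct`` — the minimum over eligible gene sets of the 5th
  percentile of member-gene BMCs (a set is eligible with ≥ 3 fitted
  genes, ≥ 5% of its annotated members fitted, and ≥ 40 annotated
  genes);
- ``lcrd`` — lowest consistent response dose: the first gene on the
  ascending BMC curve that starts a run of genes with small
  consecutive log10 gaps, skipping isolated early responders;
- ``er_5pct`` / ``er_median`` — 5th percentile / median BMC of the
  genes of a directional ERα biomarker set (≥ 3 members fitted;
  optionally requiring the biomarker to have been called activated at
  some concentration).

Confidence intervals for set-based tPODs come from a parametric
bootstrap: per member gene, residuals are resampled as
Normal(0, σ̂), the gene's selected model is refit and a BMC recorded
when one results; the fraction of resamples yielding a BMC is the
gene's inclusion probability.  Each simulated experiment includes gene
*g* when an independent uniform draw falls below that probability,
samples one of its bootstrap BMCs, and computes the tPOD statistic;
the point estimate is the median over simulated experiments and the
CI its 2.5th/97.5th percentiles.

Percentiles use linear interpolation between order statistics
throughout (the type-7 convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .dose_response import (
    CurveFit,
    _first_crossing,
    _fit_lstsq,
    _make_fit,
    POWER_MAX,
    predict_model,
)

TPOD_METHODS = ("gene25", "pathway5pct", "lcrd", "er_5pct", "er_median")


@dataclass
class TPOD:
    method: str
    value: float | None
    lower: float | None = None
    upper: float | None = None
    n_genes: int = 0
    source_set: str | None = None
    status: str = "ok"

    @property
    def defined(self) -> bool:
        return self.value is not None


# ----------------------------------------------------------------------
# Gene sets (GMT)
# ----------------------------------------------------------------------
def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    lines = [
        "\t".join([name, description or name] + list(genes))
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# tPOD derivations
# ----------------------------------------------------------------------
def _sorted_bmc(bmc_table: pd.DataFrame) -> pd.DataFrame:
    t = bmc_table.copy()
    t["_gene"] = t.index.astype(str)
    return t.sort_values(["bmc", "bmcl", "_gene"], kind="mergesort")


def tpod_gene25(bmc_table: pd.DataFrame, rank: int = 25) -> TPOD:
    """BMC of the ``rank``-th gene on the ascending BMC curve.

    The CI borrows the selected gene's own BMCL/BMCU.  Ties are broken
    by (BMC, BMCL, gene id) so the choice is deterministic.
    """
    if len(bmc_table) < rank:
        return TPOD("gene25", None, n_genes=len(bmc_table),
                    status=f"undefined: fewer than {rank} surviving genes")
    row = _sorted_bmc(bmc_table).iloc[rank - 1]
    return TPOD(
        "gene25",
        float(row["bmc"]),
        float(row["bmcl"]) if pd.notna(row.get("bmcl")) else None,
        float(row["bmcu"]) if pd.notna(row.get("bmcu")) else None,
        n_genes=len(bmc_table),
    )


def tpod_pathway(
    bmc_table: pd.DataFrame,
    catalog: dict[str, list[str]],
    min_fit: int = 3,
    min_fraction: float = 0.05,
    min_set_size: int = 40,
) -> TPOD:
    """Lowest 5th-percentile member BMC over eligible gene sets."""
    if not catalog:
        raise ValueError("empty gene-set catalog")
    best: TPOD | None = None
    genes = set(bmc_table.index.astype(str))
    for name, members in catalog.items():
        if len(members) < min_set_size:
            continue
        fit = [g for g in members if g in genes]
        if len(fit) < min_fit or len(fit) / len(members) < min_fraction:
            continue
        p5 = float(np.percentile(bmc_table.loc[fit, "bmc"].to_numpy(dtype=float), 5))
        if best is None or p5 < best.value:
            best = TPOD("pathway5pct", p5, n_genes=len(fit), source_set=name)
    if best is None:
        return TPOD("pathway5pct", None, status="undefined: no eligible gene set")
    return best


def tpod_lcrd(
    bmc_table: pd.DataFrame, run_length: int = 5, max_log10_gap: float = 0.5
) -> TPOD:
    """Lowest consistent response dose.

    On the ascending BMC sequence, the LCRD is the BMC of the first
    gene that starts a run of ``run_length`` genes whose consecutive
    log10-BMC gaps are each ≤ ``max_log10_gap``; genes before the run
    are isolated early responders.
    """
    if len(bmc_table) < run_length:
        return TPOD("lcrd", None, n_genes=len(bmc_table),
                    status=f"undefined: fewer than {run_length} surviving genes")
    b = np.sort(bmc_table["bmc"].to_numpy(dtype=float))
    gaps = np.diff(np.log10(b))
    ok = gaps <= max_log10_gap
    for i in range(len(b) - run_length + 1):
        if ok[i : i + run_length - 1].all():
            return TPOD("lcrd", float(b[i]), n_genes=len(bmc_table))
    return TPOD("lcrd", None, n_genes=len(bmc_table),
                status="undefined: no qualifying run")


def tpod_biomarker(
    bmc_table: pd.DataFrame,
    er_set: list[str],
    mode: str = "fifth",
    min_fit: int = 3,
    activation_required: bool = False,
    activated: bool | None = None,
) -> TPOD:
    """5th-percentile or median BMC of a biomarker's member genes.

    Undefined when fewer than ``min_fit`` members have BMCs, or when
    ``activation_required`` and the biomarker was never called
    activated (mirroring the exclusion of compounds that do not engage
    the receptor).
    """
    if not er_set:
        raise ValueError("empty biomarker gene set")
    if mode not in ("fifth", "median"):
        raise ValueError("mode must be 'fifth' or 'median'")
    method = "er_5pct" if mode == "fifth" else "er_median"
    if activation_required and not activated:
        return TPOD(method, None, status="undefined: biomarker not activated")
    genes = set(bmc_table.index.astype(str))
    fit = [g for g in er_set if g in genes]
    if len(fit) < min_fit:
        return TPOD(method, None, n_genes=len(fit),
                    status=f"undefined: fewer than {min_fit} member genes with BMCs")
    b = bmc_table.loc[fit, "bmc"].to_numpy(dtype=float)
    value = float(np.percentile(b, 5)) if mode == "fifth" else float(np.median(b))
    return TPOD(method, value, n_genes=len(fit))


# ----------------------------------------------------------------------
# Parametric bootstrap CI
# ----------------------------------------------------------------------
def _refit_same_family(fit: CurveFit, y: np.ndarray) -> CurveFit | None:
    """Refit ``fit``'s model family to new responses, warm-started at the
    original parameters (no per-resample model reselection)."""
    c, name, sign = fit.conc, fit.model_name, fit.sign
    if name == "linear":
        X = np.column_stack([np.ones_like(c), c])
        return _make_fit(name, _fit_lstsq(X, y), c, y)
    if name == "poly2":
        X = np.column_stack([np.ones_like(c), c, c * c])
        return _make_fit(name, _fit_lstsq(X, y), c, y)
    if name == "power":
        def ss_of_p(p):
            X = np.column_stack([np.ones_like(c), np.power(c, p)])
            th = _fit_lstsq(X, y)
            r = y - X @ th
            return float(r @ r), th
        res = optimize.minimize_scalar(
            lambda p: ss_of_p(p)[0], bounds=(1.0, POWER_MAX), method="bounded"
        )
        _, (a, b) = ss_of_p(float(res.x))
        return _make_fit(name, (a, b, float(res.x)), c, y)
    # exponential families: single warm-started nonlinear refit
    if name == "exp3":
        bounds = ([1e-8, 0.0, 1.0], [np.inf, np.inf, POWER_MAX])
    else:
        r_hat = fit.params[3]
        bounds = (
            [1e-8, 0.0, 1.0, 1.0 + 1e-6 if r_hat > 1 else 1e-6],
            [np.inf, np.inf, POWER_MAX, np.inf if r_hat > 1 else 1.0 - 1e-6],
        )
    x0 = np.clip(fit.params, bounds[0], bounds[1])
    try:
        sol = optimize.least_squares(
            lambda th: predict_model(name, th, c, sign) - y,
            x0, bounds=bounds, max_nfev=200,
        )
    except Exception:
        return None
    return _make_fit(name, sol.x, c, y, sign=sign, converged=sol.status > 0)


def bootstrap_gene_bmcs(
    fit: CurveFit,
    control_sd: float,
    max_conc: float,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
    resample_bmr: bool = True,
) -> np.ndarray:
    """Bootstrap BMC sample for one gene.

    Residuals are resampled as Normal(0, σ̂) around the fitted curve
    (σ̂² = SS/n) and the full BMC analysis is repeated on each
    resample: the gene's selected model family is refit and, with
    ``resample_bmr``, the benchmark response is recomputed from the
    resampled control replicates (scaled so the original data would
    reproduce ``control_sd``), which propagates the sampling noise of
    the control SD into the interval.  A BMC is recorded when one
    results within (0, max_conc].  Returns the (possibly shorter than
    ``n_boot``) array of bootstrap BMCs; the inclusion probability is
    ``len(result) / n_boot``.  At zero residual noise every resample
    reproduces the original BMC exactly.
    """
    rng = rng or np.random.default_rng(0)
    fitted = fit.predict(fit.conc)
    sigma = math.sqrt(fit.ss / len(fit.y))
    ctrl = np.asarray(fit.conc, float) == 0.0
    sd_orig = float(np.std(fit.y[ctrl], ddof=1)) if ctrl.sum() >= 2 else 0.0
    bmr_ratio = control_sd / sd_orig if (resample_bmr and sd_orig > 0 and sigma > 0) else None
    out = []
    for _ in range(n_boot):
        y_star = fitted + rng.normal(0.0, sigma, len(fitted)) if sigma > 0 else fitted.copy()
        refit = _refit_same_family(fit, y_star)
        if refit is None:
            continue
        if bmr_ratio is not None:
            bmr = float(np.std(y_star[ctrl], ddof=1)) * bmr_ratio
            if not bmr > 0:
                continue
        else:
            bmr = control_sd
        bmc = _first_crossing(refit.predict, bmr, max_conc)
        if bmc is not None and 0.0 < bmc <= max_conc:
            out.append(bmc)
    return np.asarray(out, dtype=float)


def _statistic(name: str):
    if name == "median":
        return np.median
    if name == "fifth":
        return lambda b: np.percentile(b, 5)
    if callable(name):
        return name
    raise ValueError(f"unknown tPOD statistic {name!r}")


def bootstrap_ci(
    member_fits: dict[str, tuple[CurveFit, float]],
    max_conc: float,
    statistic: str = "median",
    n_boot_per_gene: int = 100,
    n_experiments: int = 10_000,
    min_genes: int = 1,
    seed: int = 0,
) -> tuple[float | None, float | None, float | None]:
    """Parametric-bootstrap point estimate and 95% CI for a set tPOD.

    ``member_fits`` maps gene id to (selected CurveFit, benchmark
    response in modeling units).  Returns (median estimate, 2.5th,
    97.5th percentile); all None when every inclusion probability is 0.
    Fully deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    stat = _statistic(statistic)
    gene_bmcs, probs = [], []
    for gene in sorted(member_fits):
        fit, bmr = member_fits[gene]
        bmcs = bootstrap_gene_bmcs(fit, bmr, max_conc, n_boot_per_gene, rng)
        gene_bmcs.append(bmcs)
        probs.append(len(bmcs) / n_boot_per_gene)
    probs = np.asarray(probs)
    if (probs == 0).all():
        return None, None, None

    n_genes = len(probs)
    include = rng.random((n_experiments, n_genes)) < probs
    draws = np.full((n_experiments, n_genes), np.nan)
    for g, bmcs in enumerate(gene_bmcs):
        if len(bmcs):
            draws[:, g] = bmcs[rng.integers(0, len(bmcs), n_experiments)]
    values = []
    for e in range(n_experiments):
        b = draws[e, include[e]]
        b = b[np.isfinite(b)]
        if len(b) >= min_genes:
            values.append(stat(b))
    if not values:
        return None, None, None
    values = np.asarray(values)
    return (
        float(np.median(values)),
        float(np.percentile(values, 2.5)),
        float(np.percentile(values, 97.5)),
    )


def tpod_report(tpods: list[TPOD]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": [t.method for t in tpods],
            "value": [t.value for t in tpods],
            "lower": [t.lower for t in tpods],
            "upper": [t.upper for t in tpods],
            "n_genes": [t.n_genes for t in tpods],
            "source_set": [t.source_set or "" for t in tpods],
            "status": [t.status for t in tpods],
        }
    ).set_index("method")
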