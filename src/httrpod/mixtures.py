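"""Concentration-addition mixture predictions.

Under concentration addition the components of a mixture act as
dilutions of one another, so the predicted mixture benchmark
concentration is the fraction-weighted harmonic combination of the
component BMCs:

    BMC_pred = ( sum_i  p_i / BMC_i )^-1

with molar fractions ``p_i`` summing to 1.  The prediction is bounded
by the smallest and largest component BMC, strictly increasing in any
component BMC, invariant to component order, and reduces to the common
value when all components are equipotent.

Components lacking a defined BMC for a given tPOD method (e.g. no
ERα-biomarker BMC because the compound never activates the receptor)
are by default excluded from the sum while the remaining fractions are
kept as-is — equivalent to assigning them infinite BMC, i.e. zero
contribution to potency; set ``renormalize=True`` to rescale the
remaining fractions to 1 instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FRACTION_TOL = 1e-9


def molar_fractions(proportions) -> np.ndarray:
    """Normalize positive molar proportions to fractions summing to 1."""
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need at least one component")
    if (p <= 0).any() or not np.isfinite(p).all():
        raise ValueError("proportions must be positive and finite")
    return p / p.sum()


@dataclass
class MixtureSpec:
    """Named mixture: ordered components with molar proportions."""

    name: str
    components: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        self.fractions = molar_fractions([p for _, p in self.components])
        assert abs(self.fractions.sum() - 1.0) < FRACTION_TOL

    @property
    def chemicals(self) -> list[str]:
        return [c for c, _ in self.components]


def predict_bmc(
    components: list[tuple[float, float | None]],
    renormalize: bool = False,
) -> float | None:
    """Concentration-addition prediction from (fraction, BMC) pairs.

    Fractions must sum to 1; ``None`` BMCs mark components without a
    defined potency for this endpoint and contribute nothing (or, with
    ``renormalize``, are dropped and the rest rescaled).  Returns None
    when no component has a BMC.
    """
    fracs = np.asarray([p for p, _ in components], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    defined = [(p, b) for p, b in components if b is not None]
    if not defined:
        return None
    for _, b in defined:
        if not b > 0:
            raise ValueError("BMCs must be positive")
    p = np.asarray([p for p, _ in defined], dtype=float)
    b = np.asarray([b for _, b in defined], dtype=float)
    if renormalize:
        p = p / p.sum()
    return float(1.0 / (p / b).sum())


@dataclass
class AdditionResult:
    mixture: str
    tpod_method: str
    bmc_pred: float | None
    empirical_bmc: float | None = None
    empirical_bmcl: float | None = None
    empirical_bmcu: float | None = None
    within_interval: bool | None = None
    fold_difference: float | None = None
    components_used: list[str] | None = None
    excluded: list[str] | None = None


def additivity_check(
    mixture: str,
    tpod_method: str,
    bmc_pred: float | None,
    empirical_bmc: float | None,
    empirical_bmcl: float | None = None,
    empirical_bmcu: float | None = None,
) -> AdditionResult:
    """Compare a predicted mixture BMC with its empirical counterpart.

    ``within_interval`` is True when bmcl ≤ bmc_pred ≤ bmcu (inclusive
    bounds); undefined (None) when the empirical CI is missing.  The
    fold difference pred/empirical is reported whenever both exist.
    """
    fold = None
    if bmc_pred is not None and empirical_bmc is not None:
        if empirical_bmc <= 0 or bmc_pred <= 0:
            raise ValueError("BMCs must be positive")
        fold = bmc_pred / empirical_bmc
    within = None
    if bmc_pred is not None and empirical_bmcl is not None and empirical_bmcu is not None:
        within = empirical_bmcl <= bmc_pred <= empirical_bmcu
    return AdditionResult(
        mixture, tpod_method, bmc_pred, empirical_bmc,
        empirical_bmcl, empirical_bmcu, within, fold,
    )


# ----------------------------------------------------------------------
# TSV interfaces
# ----------------------------------------------------------------------
def read_mixtures(path: str | Path) -> list[MixtureSpec]:
    """Mixture definitions from a TSV with columns
    ``mixture``, ``component``, ``proportion``."""
    df = pd.read_csv(path, sep="\t")
    required = {"mixture", "component", "proportion"}
    if not required <= set(df.columns):
        raise ValueError(f"mixtures TSV needs columns {sorted(required)}")
    out = []
    for name, grp in df.groupby("mixture", sort=False):
        out.append(
            MixtureSpec(str(name), list(zip(grp["component"].astype(str),
                                            grp["proportion"].astype(float))))
        )
    return out


def predict_for_mixtures(
    mixtures: list[MixtureSpec],
    component_bmcs: dict[str, float | None],
    tpod_method: str = "gene25",
    renormalize: bool = False,
) -> list[AdditionResult]:
    """Eq.-style predictions for a batch of mixtures given per-chemical
    component BMCs (``None`` marks an undefined component BMC)."""
    out = []
    for mix in mixtures:
        comps = [
            (float(f), component_bmcs.get(chem))
            for chem, f in zip(mix.chemicals, mix.fractions)
        ]
        used = [c for c, (_, b) in zip(mix.chemicals, comps) if b is not None]
        excluded = [c for c in mix.chemicals if c not in used]
        pred = predict_bmc(comps, renormalize=renormalize)
        out.append(
            AdditionResult(
                mix.name, tpod_method, pred,
                components_used=used, excluded=excluded,
            )
        )
    return out


def addition_frame(results: list[AdditionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mixture": [r.mixture for r in results],
            "method": [r.tpod_method for r in results],
            "bmc_pred": [r.bmc_pred for r in results],
            "empirical": [r.empirical_bmc for r in results],
            "bmcl": [r.empirical_bmcl for r in results],
            "bmcu": [r.empirical_bmcu for r in results],
            "within_interval": [r.within_interval for r in results],
            "fold_difference": [r.fold_difference for r in results],
        }
    )
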