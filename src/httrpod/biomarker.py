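"""Directional gene-set biomarker scoring and overt-stress flagging.

Each chemical-concentration contrast is reduced to a signed
differentially-expressed-gene (DEG) list (unadjusted p < 0.05 and
absolute linear fold change ≥ 1.2) and compared with directional
biomarkers: the 50-gene ERα signature and a panel of stress-response
signatures (NRF2, HSF1, MTF1, AhR, TGx-DDI, TGx-HDACi, NF-κB, HIF1,
XBP1) plus cell proliferation (CP).

The score is a directional hypergeometric correlation: the concordant
overlap (DEG-up ∩ marker-up plus DEG-down ∩ marker-down) and the
discordant overlap each get an upper-tail hypergeometric p-value
against the tested gene universe, and

    signed_score = −log10(p_concordant) + log10(p_discordant),

positive when concordance dominates.  Calls use the ±4 threshold:
``activated`` at ≥ +4, ``suppressed`` at ≤ −4, else ``inactive``.

A condition showing activation of at least two stress biomarkers
(CP excluded by default, since widespread proliferation signaling is
not by itself cytotoxic) is flagged as overtly stressed and its
concentration removed from downstream BMC modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

STRESS_BIOMARKERS = (
    "NRF2", "HSF1", "MTF1", "AhR", "TGx-DDI", "TGx-HDACi", "NF-kB", "HIF1", "XBP1", "CP",
)
CALL_THRESHOLD = 4.0


@dataclass
class Biomarker:
    """A directional gene set: member genes with expected direction."""

    name: str
    up: frozenset[str] = field(default_factory=frozenset)
    down: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.up and not self.down:
            raise ValueError(f"biomarker {self.name!r} has no member genes")
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def inverted(self) -> "Biomarker":
        return Biomarker(self.name, self.down, self.up)


@dataclass
class BiomarkerScore:
    biomarker: str
    chemical: str
    concentration_uM: float
    signed_score: float
    call: str  # activated / suppressed / inactive


def read_directional_sets(path: str | Path) -> dict[str, Biomarker]:
    """Read biomarkers from a sectioned two-column file.

    Lines starting with ``>`` open a named set; following lines are
    ``gene<TAB>direction`` with direction ``up`` or ``down``.
    """
    sets: dict[str, Biomarker] = {}
    name, up, down = None, set(), set()

    def flush():
        if name is not None:
            sets[name] = Biomarker(name, frozenset(up), frozenset(down))

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name, up, down = line[1:].strip(), set(), set()
            if name in sets:
                raise ValueError(f"duplicate biomarker name {name!r}")
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("up", "down"):
            raise ValueError(f"malformed biomarker line: {line!r}")
        (up if parts[1] == "up" else down).add(parts[0])
    flush()
    return sets


def write_directional_sets(sets: dict[str, Biomarker], path: str | Path) -> None:
    lines = []
    for name, bm in sets.items():
        lines.append(f">{name}")
        lines += [f"{g}\tup" for g in sorted(bm.up)]
        lines += [f"{g}\tdown" for g in sorted(bm.down)]
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# DEG list and scoring
# ----------------------------------------------------------------------
def deg_list(
    contrasts: pd.DataFrame, p_max: float = 0.05, fc_min: float = 1.2
) -> tuple[set[str], set[str]]:
    """Signed DEG partition from a contrast-statistics table.

    Requires columns ``unadjusted_p`` and ``linear_fold_change``
    (signed); returns (up genes, down genes).  Empty sets are allowed.
    """
    sig = (contrasts["unadjusted_p"] < p_max) & (
        contrasts["linear_fold_change"].abs() >= fc_min
    )
    up = set(contrasts.index[sig & (contrasts["linear_fold_change"] > 0)].astype(str))
    down = set(contrasts.index[sig & (contrasts["linear_fold_change"] < 0)].astype(str))
    return up, down


def directional_set_score(
    deg_up: set[str],
    deg_down: set[str],
    biomarker: Biomarker,
    universe_size: int,
) -> tuple[float, str]:
    """Signed −log10 hypergeometric score and activity call.

    Upper-tail hypergeometric p-values are computed for the concordant
    and discordant overlaps between the signed DEG list and the
    directional biomarker, against a universe of ``universe_size``
    tested genes.  Genes unrelated to the biomarker change neither
    overlap, only the DEG list size.
    """
    if len(biomarker) == 0:
        raise ValueError("empty biomarker")
    n_deg = len(deg_up) + len(deg_down)
    n_marker = len(biomarker)
    if universe_size < n_deg or universe_size < n_marker:
        raise ValueError("universe smaller than the gene lists")
    concordant = len(deg_up & biomarker.up) + len(deg_down & biomarker.down)
    discordant = len(deg_up & biomarker.down) + len(deg_down & biomarker.up)
    p_con = float(stats.hypergeom.sf(concordant - 1, universe_size, n_marker, n_deg))
    p_dis = float(stats.hypergeom.sf(discordant - 1, universe_size, n_marker, n_deg))
    score = -np.log10(max(p_con, 1e-300)) + np.log10(max(p_dis, 1e-300))
    if score >= CALL_THRESHOLD:
        call = "activated"
    elif score <= -CALL_THRESHOLD:
        call = "suppressed"
    else:
        call = "inactive"
    return float(score), call


def score_contrast(
    contrasts: pd.DataFrame,
    biomarkers: dict[str, Biomarker],
    chemical: str,
    concentration: float,
    universe_size: int | None = None,
    p_max: float = 0.05,
    fc_min: float = 1.2,
) -> list[BiomarkerScore]:
    """Score every biomarker against one contrast's DEG list.

    The universe defaults to the number of probes in the contrast table
    (those passing the relevance filter).
    """
    up, down = deg_list(contrasts, p_max=p_max, fc_min=fc_min)
    if universe_size is None:
        universe_size = len(contrasts)
    out = []
    for name, bm in biomarkers.items():
        score, call = directional_set_score(up, down, bm, universe_size)
        out.append(BiomarkerScore(name, chemical, float(concentration), score, call))
    return out


def scores_frame(scores: list[BiomarkerScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "biomarker": [s.biomarker for s in scores],
            "chemical": [s.chemical for s in scores],
            "concentration_uM": [s.concentration_uM for s in scores],
            "signed_score": [s.signed_score for s in scores],
            "call": [s.call for s in scores],
        }
    )


def stress_flag(
    scores: pd.DataFrame,
    min_active: int = 2,
    exclude: tuple[str, ...] = ("CP",),
    stress_names: tuple[str, ...] = STRESS_BIOMARKERS,
) -> pd.DataFrame:
    """Flag (chemical, concentration) conditions with overt stress.

    A condition is flagged when at least ``min_active`` stress
    biomarkers are called ``activated`` there; suppression does not
    count, and biomarkers in ``exclude`` (cell proliferation by
    default) are ignored.
    """
    counted = [b for b in stress_names if b not in exclude]
    sub = scores[scores["biomarker"].isin(counted)]
    flags = (
        sub.assign(active=sub["call"] == "activated")
        .groupby(["chemical", "concentration_uM"])["active"]
        .sum()
        .reset_index()
    )
    flags["flagged"] = flags["active"] >= min_active
    return flags.rename(columns={"active": "n_activated"})


def max_unflagged_conc(
    flags: pd.DataFrame, chemical: str, concentrations: list[float]
) -> float:
    """Highest analyzable concentration for ``chemical`` once flagged
    (overtly stressed) concentrations are excluded."""
    sub = flags[(flags["chemical"] == chemical) & flags["flagged"]]
    bad = set(sub["concentration_uM"])
    ok = [c for c in concentrations if c not in bad]
    if not ok:
        raise ValueError(f"every concentration of {chemical} is stress-flagged")
    return max(ok)
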