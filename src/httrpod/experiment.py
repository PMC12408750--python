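"""Shared container for probe-by-sample count experiments.

A :class:`CountExperiment` couples a non-negative integer count matrix
(probes as rows, samples as columns) with per-sample metadata describing
the exposure design: which chemical, at which concentration (µM), on
which plate, and whether the sample is a treated well or a plate-matched
solvent control.  Every pipeline stage consumes and produces this
container or plain TSV files written from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

METADATA_COLUMNS = ["sample_id", "chemical", "concentration_uM", "plate", "replicate", "role"]
ROLES = ("treated", "control")


@dataclass
class CountExperiment:
    """Probe × sample counts plus per-sample design metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; index = probe ids,
        columns = sample ids.
    metadata
        DataFrame indexed by sample id with columns ``chemical``,
        ``concentration_uM``, ``plate``, ``replicate`` and ``role``
        (``treated`` or ``control``).  Extra columns (e.g. QC
        provenance such as ``mapped_read_fraction``) are preserved.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.metadata.index):
            # allow same set, different order: align metadata to counts
            if set(self.counts.columns) != set(self.metadata.index):
                raise ValueError("counts columns and metadata sample ids do not match")
            self.metadata = self.metadata.loc[self.counts.columns]
        missing = {"chemical", "concentration_uM", "plate", "replicate", "role"} - set(
            self.metadata.columns
        )
        if missing:
            raise ValueError(f"metadata missing required columns: {sorted(missing)}")
        bad = set(self.metadata["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")

    # ------------------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def control_samples(self, plate: object | None = None) -> list[str]:
        m = self.metadata
        mask = m["role"] == "control"
        if plate is not None:
            mask &= m["plate"] == plate
        return list(m.index[mask])

    def treated_samples(self, chemical: str, concentration: float) -> list[str]:
        m = self.metadata
        mask = (
            (m["role"] == "treated")
            & (m["chemical"] == chemical)
            & np.isclose(m["concentration_uM"].astype(float), concentration)
        )
        return list(m.index[mask])

    def subset_samples(self, sample_ids: list[str]) -> "CountExperiment":
        return CountExperiment(
            self.counts[sample_ids].copy(), self.metadata.loc[sample_ids].copy()
        )

    def subset_probes(self, probe_ids) -> "CountExperiment":
        return CountExperiment(self.counts.loc[list(probe_ids)].copy(), self.metadata.copy())

    # ------------------------------------------------------------------
    def to_tsv(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        """Write counts (probes × samples) and metadata as TSV."""
        self.counts.rename_axis("probe_id").to_csv(counts_path, sep="\t")
        self.metadata.rename_axis("sample_id").reset_index().to_csv(
            metadata_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, counts_path: str | Path, metadata_path: str | Path) -> "CountExperiment":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str}).set_index(
            "sample_id"
        )
        return cls(counts, meta)
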