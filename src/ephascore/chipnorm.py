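"""Reference-cell-line chip normalization and the chip quality gate.

Each 9-well chip carries triplicate wells of a reference line (MDA MB231 in
the original assay).  Day-to-day fluctuations of the detection system shift
all scores on a chip proportionally, so:

* **QC gate** — a chip is usable only if its reference triplicates are
  statistically indistinguishable (Kruskal–Wallis omnibus p > alpha; Dunn's
  pairwise p-values are logged as diagnostics).  Failing chips are excluded
  outright.
* **Normalization** — the triplicates of an accepted chip are pooled into a
  single distribution and every score on the chip is divided by its mean:
  s_hat = s / mean(pooled reference scores).  This cancels any multiplicative
  chip effect exactly and puts all chips on a common scale where the pooled
  reference mean is 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .popstats import kw_dunn
from .scoring import CellScore

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_POPULATION = "MDA_MB231"
MIN_REFERENCE_CELLS = 150
MIN_CELLS_PER_REFERENCE_WELL = 10


class ChipConfigurationError(ValueError):
    """Raised for manifests that violate the chip layout contract."""


@dataclass
class Well:
    well_id: str
    population_id: str
    cells: list[CellScore] = field(default_factory=list)

    def raw_scores(self) -> np.ndarray:
        return np.array([c.s_epha for c in self.cells], dtype=float)


@dataclass
class ChipRecord:
    """One chip's wells, reference designation, and QC/normalization state."""

    chip_id: str
    wells: list[Well]
    reference_wells: list[str]
    reference_population: str = DEFAULT_REFERENCE_POPULATION
    qc_passed: bool | None = None
    qc_pvalue: float | None = None
    qc_dunn_pvalues: np.ndarray | None = None
    reference_mean: float | None = None

    def __post_init__(self) -> None:
        well_ids = [w.well_id for w in self.wells]
        if len(set(well_ids)) != len(well_ids):
            raise ChipConfigurationError("duplicate well ids")
        if len(set(self.reference_wells)) != 3:
            raise ChipConfigurationError("exactly 3 distinct reference wells required")
        by_id = {w.well_id: w for w in self.wells}
        for rid in self.reference_wells:
            if rid not in by_id:
                raise ChipConfigurationError(f"reference well {rid} not on chip")
            if by_id[rid].population_id != self.reference_population:
                raise ChipConfigurationError(
                    f"reference well {rid} carries {by_id[rid].population_id}, "
                    f"expected {self.reference_population}"
                )

    def well(self, well_id: str) -> Well:
        return next(w for w in self.wells if w.well_id == well_id)

    def reference_samples(self) -> list[np.ndarray]:
        return [self.well(r).raw_scores() for r in self.reference_wells]

    def pooled_reference(self) -> np.ndarray:
        return np.concatenate(self.reference_samples())

    def to_frame(self) -> pd.DataFrame:
        """Long-format score table (one row per cell)."""
        rows = [
            {
                "chip_id": self.chip_id,
                "well_id": w.well_id,
                "population_id": w.population_id,
                "cell_id": c.cell_id,
                "is_reference": w.well_id in self.reference_wells,
                "s_epha": c.s_epha,
                "s_epha_hat": c.s_epha_hat,
                "n_pixels": c.n_pixels,
            }
            for w in self.wells
            for c in w.cells
        ]
        return pd.DataFrame(rows)


def chip_qc(chip: ChipRecord, alpha: float = 0.05) -> tuple[bool, float]:
    """Gate a chip on the indistinguishability of its reference triplicates.

    Kruskal–Wallis across the three reference wells; the chip passes when the
    omnibus p > alpha.  Dunn's Bonferroni-adjusted pairwise p-values are
    stored on the record for diagnostics only — the decision is the omnibus
    p, which is the single criterion the assay prescribes.
    """
    samples = chip.reference_samples()
    if any(s.size < MIN_CELLS_PER_REFERENCE_WELL for s in samples):
        raise ChipConfigurationError(
            f"each reference well needs >= {MIN_CELLS_PER_REFERENCE_WELL} cells"
        )
    omnibus_p, dunn, _ = kw_dunn(samples, alpha=alpha)
    passed = omnibus_p > alpha
    chip.qc_passed = passed
    chip.qc_pvalue = omnibus_p
    chip.qc_dunn_pvalues = dunn
    if not passed:
        logger.warning(
            "chip %s failed reference QC (KW p=%.3g <= %.3g); chip excluded",
            chip.chip_id, omnibus_p, alpha,
        )
    else:
        logger.info("chip %s passed reference QC (KW p=%.3g)", chip.chip_id, omnibus_p)
    return passed, omnibus_p


def normalize_chip(chip: ChipRecord, force: bool = False) -> ChipRecord:
    """Divide every score on the chip by the pooled-reference mean.

    Requires a passed QC (override with ``force=True``, which warns).  The
    pooled reference mean afterwards equals 1 by construction; the reference
    cells themselves are normalized too.
    """
    if chip.qc_passed is None and not force:
        raise ChipConfigurationError("run chip_qc before normalize_chip (or force=True)")
    if chip.qc_passed is False and not force:
        raise ChipConfigurationError(f"chip {chip.chip_id} failed QC; not normalizing")
    if force and not chip.qc_passed:
        warnings.warn(f"normalizing chip {chip.chip_id} despite QC state", stacklevel=2)
    pooled = chip.pooled_reference()
    if pooled.size < MIN_REFERENCE_CELLS:
        logger.warning(
            "chip %s: only %d pooled reference cells (< %d recommended)",
            chip.chip_id, pooled.size, MIN_REFERENCE_CELLS,
        )
    ref_mean = float(pooled.mean())
    if ref_mean <= 0:
        raise ValueError("non-positive reference mean; cannot normalize")
    chip.reference_mean = ref_mean
    for w in chip.wells:
        w.cells = [replace(c, s_epha_hat=c.s_epha / ref_mean) for c in w.cells]
    return chip


def batch_normalize(
    chips: list[ChipRecord],
    alpha: float = 0.05,
) -> tuple[list[ChipRecord], list[str], float]:
    """QC-gate and normalize a batch of chips.

    Returns (accepted normalized chips, excluded chip ids, exclusion rate).
    In the original assay fewer than 20% of chips failed the gate; a higher
    rate flags a device-preparation problem rather than a statistical fluke.
    """
    if not chips:
        raise ValueError("no chips given")
    accepted: list[ChipRecord] = []
    excluded: list[str] = []
    for chip in chips:
        passed, _ = chip_qc(chip, alpha=alpha)
        if passed:
            accepted.append(normalize_chip(chip))
        else:
            excluded.append(chip.chip_id)
    rate = len(excluded) / len(chips)
    logger.info("batch exclusion rate: %.3f (%d/%d)", rate, len(excluded), len(chips))
    if not accepted:
        raise ValueError("all chips failed reference QC; nothing to normalize")
    return accepted, excluded, rate


def qc_report(chips: list[ChipRecord]) -> pd.DataFrame:
    """QC summary, one row per chip."""
    rows = [
        {
            "chip_id": c.chip_id,
            "qc_passed": c.qc_passed,
            "qc_pvalue": c.qc_pvalue,
            "reference_mean": c.reference_mean,
            "n_reference_cells": int(c.pooled_reference().size),
        }
        for c in chips
    ]
    return pd.DataFrame(rows)
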