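"""Synthetic data carrying the statistical structure the analysis assumes.

Generators for the four kinds of input the pipeline consumes, so every
downstream stage is testable without microscope or sequencing data:

* single-cell fluorescence fields — one disk-shaped cell whose foreground
  signal is split over puncta; an ``aggregation`` knob in [0, 1] moves the
  signal from many scattered small puncta to at most three large merged
  aggregates near the cell interior, at conserved total signal (the signal
  is redistributed, never added), so the entropy score rises with it;
* 9-well chips with reference triplicates and a single multiplicative
  ``chip_gain`` on every per-cell score, emulating day-to-day detection
  fluctuations that the reference normalization must cancel;
* clonal colony score series that start narrow around their founder's score
  at day 10 and mix back toward the unsorted baseline at day 20;
* genes x cells log2(TPM+1) expression matrices whose pathway-gene mean is
  line specific, with dropout.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .chipnorm import ChipRecord, Well
from .imaging import FluorescenceField, LabelMask, extract_cells
from .popstats import ColonySeries, ScoreDistribution
from .scoring import CellScore, score_cells
from .transcriptomics import ExpressionMatrix

_SEED_MAX = 2**31 - 1


@dataclass
class CellSynthParams:
    """Single synthetic cell: puncta in a disk mask, tunable aggregation.

    ``aggregation`` is the probability that a punctum's signal is deposited
    into one of at most 3 aggregate blobs (width ``aggregate_sigma_px``,
    centers within the inner 50% radius) instead of a scattered small
    punctum (width ``punctum_sigma_px``, center uniform over the cell).
    Each punctum carries ``total_signal / n_puncta`` regardless of its
    assignment, so the expected integrated foreground is independent of
    aggregation.
    """

    cell_radius_px: float = 60.0
    n_puncta: int = 30
    aggregation: float = 0.5
    total_signal: float = 3.0e5
    punctum_sigma_px: float = 2.5
    aggregate_sigma_px: float = 5.0
    background_level: float = 100.0
    noise_model: str = "poisson"
    noise_scale: float = 1.0
    image_size: int = 256

    def validate(self) -> None:
        if not 0.0 <= self.aggregation <= 1.0:
            raise ValueError("aggregation must be in [0, 1]")
        if self.total_signal <= 0:
            raise ValueError("total_signal must be positive")
        if self.n_puncta < 1:
            raise ValueError("n_puncta must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.cell_radius_px < 2 * self.punctum_sigma_px:
            raise ValueError("cell too small to place puncta (radius < 2*punctum_sigma)")
        if 2 * self.cell_radius_px >= self.image_size:
            raise ValueError("cell does not fit in the field")


def _uniform_in_disk(rng: np.random.Generator, radius: float, n: int = 1) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = 2 * np.pi * rng.random(n)
    return np.column_stack([r * np.sin(theta), r * np.cos(theta)])


def _deposit_punctum(fg, mask, center, sigma, signal) -> None:
    """Add one Gaussian punctum, renormalized so its in-mask sum is `signal`."""
    size = fg.shape[0]
    cy, cx = center
    if sigma < 0.25:  # delta-like: all signal in the nearest in-mask pixel
        iy, ix = int(round(cy)), int(round(cx))
        iy, ix = np.clip(iy, 0, size - 1), np.clip(ix, 0, size - 1)
        if not mask[iy, ix]:
            ys, xs = np.nonzero(mask)
            j = np.argmin((ys - cy) ** 2 + (xs - cx) ** 2)
            iy, ix = ys[j], xs[j]
        fg[iy, ix] += signal
        return
    half = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(cy) - half), min(size, int(cy) + half + 1)
    x0, x1 = max(0, int(cx) - half), min(size, int(cx) + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    kernel = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    kernel *= mask[y0:y1, x0:x1]
    total = kernel.sum()
    if total <= 0:
        ys, xs = np.nonzero(mask)
        j = np.argmin((ys - cy) ** 2 + (xs - cx) ** 2)
        fg[ys[j], xs[j]] += signal
        return
    fg[y0:y1, x0:x1] += kernel * (signal / total)


def generate_cell_image(
    params: CellSynthParams, seed: int
) -> tuple[FluorescenceField, LabelMask]:
    """Render one synthetic cell as a 16-bit field plus its label mask.

    Deterministic for a fixed seed.  The single cell is labeled 1.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    size = params.image_size
    center = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - center) ** 2 + (xx - center) ** 2 <= params.cell_radius_px**2

    n_aggregates = int(rng.integers(1, 4))
    agg_centers = center + _uniform_in_disk(rng, params.cell_radius_px / 2.0, n_aggregates)

    signal_per_punctum = params.total_signal / params.n_puncta
    fg = np.zeros((size, size), dtype=float)
    for _ in range(params.n_puncta):
        aggregated = rng.random() < params.aggregation
        if aggregated:
            c = agg_centers[int(rng.integers(n_aggregates))]
            _deposit_punctum(fg, mask, c, params.aggregate_sigma_px, signal_per_punctum)
        else:
            c = center + _uniform_in_disk(rng, params.cell_radius_px)[0]
            _deposit_punctum(fg, mask, c, params.punctum_sigma_px, signal_per_punctum)

    img = fg + params.background_level
    if params.noise_model == "gaussian" and params.noise_scale > 0:
        img = img + rng.normal(0.0, params.noise_scale, img.shape)
    elif params.noise_model == "poisson":
        gain = params.noise_scale if params.noise_scale > 0 else 1.0
        img = rng.poisson(np.maximum(img, 0.0) * gain).astype(float) / gain
    pixels = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return (
        FluorescenceField(pixels=pixels, bit_depth=16),
        LabelMask(labels=mask.astype(np.int32)),
    )


def simulate_score_pool(
    profile: CellSynthParams,
    n_cells: int,
    seed: int,
    background_subtract: bool = True,
) -> np.ndarray:
    """Raw entropy scores of ``n_cells`` rendered and scored cells.

    This is the image-level path; chip generation can resample from the
    returned pool (the fast score-level path, which agrees with it in
    distribution by construction).
    """
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_cells):
        fieldobj, mask = generate_cell_image(profile, int(rng.integers(_SEED_MAX)))
        records = extract_cells(fieldobj, mask, min_area=1)
        scores.extend(c.s_epha for c in score_cells(records, background_subtract))
    return np.array(scores)


@dataclass
class ChipSynthParams:
    """Layout and acquisition parameters of one synthetic 9-well chip."""

    wells_per_population: dict[str, list[int]]
    reference_population: str
    reference_wells: list[int]
    n_wells: int = 9
    cells_per_well: int = 100
    chip_gain: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.chip_gain <= 0:
            raise ValueError("chip_gain must be positive")
        if len(set(self.reference_wells)) != 3:
            raise ValueError("exactly 3 distinct reference wells required")
        all_wells = [w for ws in self.wells_per_population.values() for w in ws]
        if len(set(all_wells)) != len(all_wells):
            raise ValueError("a well is assigned to more than one population")
        if any(w < 0 or w >= self.n_wells for w in all_wells):
            raise ValueError("well index out of range")
        if self.reference_population not in self.wells_per_population:
            raise ValueError("reference population has no wells")
        ref_ws = set(self.wells_per_population[self.reference_population])
        if not set(self.reference_wells) <= ref_ws:
            raise ValueError("reference wells must carry the reference population")


def default_chip_layout(
    test_population: str,
    reference_population: str = "MDA_MB231",
    cells_per_well: int = 100,
    chip_gain: float = 1.0,
    seed: int = 0,
) -> ChipSynthParams:
    """A 9-well chip: reference triplicate in wells 0-2, test line in wells 3-8."""
    return ChipSynthParams(
        wells_per_population={
            reference_population: [0, 1, 2],
            test_population: [3, 4, 5, 6, 7, 8],
        },
        reference_population=reference_population,
        reference_wells=[0, 1, 2],
        cells_per_well=cells_per_well,
        chip_gain=chip_gain,
        seed=seed,
    )


def generate_chip(
    params: ChipSynthParams,
    population_profiles: dict[str, CellSynthParams],
    mode: str = "score",
    score_pools: dict[str, np.ndarray] | None = None,
    n_calibration_cells: int = 120,
) -> ChipRecord:
    """Simulate one chip's per-cell raw scores, multiplied by its gain.

    ``mode="image"`` renders and scores every cell; ``mode="score"`` (the
    fast path) resamples per-cell scores from an image-calibrated pool per
    population — pass precomputed pools via ``score_pools`` to share one
    calibration across a batch of chips.  The same multiplicative
    ``chip_gain`` applies to every well, after all sampling, so two chips
    generated with the same seed and different gains differ exactly by the
    gain ratio.
    """
    params.validate()
    for pop in params.wells_per_population:
        if pop not in population_profiles and not (score_pools and pop in score_pools):
            raise ValueError(f"no profile (or score pool) for population {pop!r}")
    if mode not in ("score", "image"):
        raise ValueError("mode must be 'score' or 'image'")
    rng = np.random.default_rng(params.seed)

    pools: dict[str, np.ndarray] = {}
    if mode == "score":
        for pop in sorted(params.wells_per_population):
            if score_pools and pop in score_pools:
                pools[pop] = np.asarray(score_pools[pop], dtype=float)
            else:
                pools[pop] = simulate_score_pool(
                    population_profiles[pop],
                    n_calibration_cells,
                    int(rng.integers(_SEED_MAX)),
                )

    wells: list[Well] = []
    well_pop = {
        w: pop for pop, ws in params.wells_per_population.items() for w in ws
    }
    for idx in sorted(well_pop):
        pop = well_pop[idx]
        if mode == "score":
            raw = rng.choice(pools[pop], size=params.cells_per_well, replace=True)
        else:
            raw = simulate_score_pool(
                population_profiles[pop],
                params.cells_per_well,
                int(rng.integers(_SEED_MAX)),
            )
        cells = [
            CellScore(
                cell_id=i + 1,
                well_id=f"W{idx}",
                chip_id=f"chip{params.seed}",
                population_id=pop,
                s_epha=float(s * params.chip_gain),
                n_pixels=0,
            )
            for i, s in enumerate(raw)
        ]
        wells.append(Well(well_id=f"W{idx}", population_id=pop, cells=cells))

    return ChipRecord(
        chip_id=f"chip{params.seed}",
        wells=wells,
        reference_wells=[f"W{i}" for i in params.reference_wells],
        reference_population=params.reference_population,
    )


def simulate_chip_batch(
    n_chips: int,
    population_profiles: dict[str, CellSynthParams],
    test_population: str,
    reference_population: str = "MDA_MB231",
    cells_per_well: int = 100,
    gain_sigma: float = 0.15,
    seed: int = 0,
    calibration_cells: int = 150,
) -> list[ChipRecord]:
    """A batch of chips with lognormal chip gains and one shared calibration.

    Gains are drawn log-normally (log-sd ``gain_sigma``), emulating
    proportional day-to-day detection fluctuations; score pools are
    calibrated once from the image-level path and shared across chips.
    """
    rng = np.random.default_rng(seed)
    pools = {
        pop: simulate_score_pool(profile, calibration_cells, int(rng.integers(_SEED_MAX)))
        for pop, profile in sorted(population_profiles.items())
    }
    chips = []
    for _ in range(n_chips):
        gain = float(np.exp(rng.normal(0.0, gain_sigma)))
        layout = default_chip_layout(
            test_population,
            reference_population,
            cells_per_well=cells_per_well,
            chip_gain=gain,
            seed=int(rng.integers(_SEED_MAX)),
        )
        chips.append(generate_chip(layout, population_profiles, score_pools=pools))
    return chips


@dataclass
class ColonySynthParams:
    """Clonal colony score series: narrow at day 10, drifting back by day 20.

    ``convergence_weight_day20`` (w) mixes colony-centered draws with fresh
    baseline draws at day 20: 0 = perfect inheritance with no drift, 1 =
    fully reverted to the unsorted population distribution.
    """

    population_scores: np.ndarray
    n_colonies: int = 9
    founders: np.ndarray | None = None
    intra_colony_sd_day10: float = 0.08
    convergence_weight_day20: float = 0.5
    cells_per_colony_per_day: int = 40
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.convergence_weight_day20 <= 1.0:
            raise ValueError("convergence_weight_day20 must be in [0, 1]")
        if np.asarray(self.population_scores).size == 0:
            raise ValueError("population_scores must be non-empty")
        if self.n_colonies < 2:
            raise ValueError("need at least 2 colonies")
        if self.intra_colony_sd_day10 < 0:
            raise ValueError("intra_colony_sd_day10 must be >= 0")


def generate_colony_series(params: ColonySynthParams) -> list[ColonySeries]:
    """One :class:`ColonySeries` per colony, all sharing the unsorted baseline."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    baseline_scores = np.asarray(params.population_scores, dtype=float).ravel()
    baseline = ScoreDistribution("baseline", baseline_scores)
    if params.founders is not None:
        founders = np.asarray(params.founders, dtype=float)
        if founders.size != params.n_colonies:
            raise ValueError("one founder score per colony required")
    else:
        founders = rng.choice(baseline_scores, size=params.n_colonies, replace=False)

    m = params.cells_per_colony_per_day
    w = params.convergence_weight_day20
    sd = params.intra_colony_sd_day10
    colonies: list[ColonySeries] = []
    for i, founder in enumerate(founders):
        day10 = np.clip(founder + rng.normal(0.0, sd, m), 0.0, None)
        colony_like = np.clip(founder + rng.normal(0.0, sd, m), 0.0, None)
        from_baseline = rng.choice(baseline_scores, size=m, replace=True)
        take_baseline = rng.random(m) < w
        day20 = np.where(take_baseline, from_baseline, colony_like)
        colonies.append(
            ColonySeries(
                colony_id=f"colony{i + 1}",
                day10=ScoreDistribution(f"colony{i + 1}_d10", day10),
                day20=ScoreDistribution(f"colony{i + 1}_d20", day20),
                baseline=baseline,
                founder_score=float(founder),
            )
        )
    return colonies


@dataclass
class ExpressionSynthParams:
    """Synthetic genes x cells log2(TPM+1) matrix with a shifted pathway set."""

    line_pathway_means: dict[str, float]
    n_genes: int = 200
    pathway_gene_ids: list[str] = dc_field(default_factory=list)
    n_cells_per_line: int = 50
    dispersion: float = 0.5
    dropout_rate: float = 0.1
    background_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pathway_gene_ids:
            self.pathway_gene_ids = [f"PW{i:04d}" for i in range(1, 31)]

    def validate(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if len(self.pathway_gene_ids) > self.n_genes:
            raise ValueError("pathway larger than gene universe")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not self.line_pathway_means:
            raise ValueError("need at least one line")


def generate_expression_matrix(params: ExpressionSynthParams) -> ExpressionMatrix:
    """Pathway genes get line-specific means, other genes a shared mean; dropout zeroes entries."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_filler = params.n_genes - len(params.pathway_gene_ids)
    genes = list(params.pathway_gene_ids) + [f"GENE{i:04d}" for i in range(1, n_filler + 1)]
    is_pathway = np.array([g in set(params.pathway_gene_ids) for g in genes])

    blocks, cells, lines = [], [], []
    for line in sorted(params.line_pathway_means):
        mu = params.line_pathway_means[line]
        means = np.where(is_pathway, mu, params.background_mean)
        block = rng.normal(
            means[:, None], params.dispersion, (len(genes), params.n_cells_per_line)
        )
        blocks.append(np.clip(block, 0.0, None))
        cells.extend(f"{line}_c{i:03d}" for i in range(params.n_cells_per_line))
        lines.extend([line] * params.n_cells_per_line)

    values = np.concatenate(blocks, axis=1)
    if params.dropout_rate > 0:
        values[rng.random(values.shape) < params.dropout_rate] = 0.0
    df = pd.DataFrame(values, index=genes, columns=cells)
    return ExpressionMatrix(values=df, cell_line=pd.Series(lines, index=cells))


def write_score_table(chips: list[ChipRecord], path) -> None:
    """Long-format per-cell score table (TSV), one row per cell across chips."""
    pd.concat([c.to_frame() for c in chips], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def write_chip_manifest(chip: ChipRecord, path) -> None:
    rows = [
        {
            "chip_id": chip.chip_id,
            "well_id": w.well_id,
            "population_id": w.population_id,
            "is_reference": w.well_id in chip.reference_wells,
        }
        for w in chip.wells
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_expression_tsv(matrix: ExpressionMatrix, values_path, annotation_path) -> None:
    """Write the E matrix and a cell annotation table as TSV."""
    matrix.values.to_csv(values_path, sep="\t")
    ann = pd.DataFrame(
        {
            "cell_id": matrix.cell_line.index,
            "line_id": matrix.cell_line.values,
            "line_class": [matrix.line_class[ln] for ln in matrix.cell_line],
        }
    )
    ann.to_csv(annotation_path, sep="\t", index=False)
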