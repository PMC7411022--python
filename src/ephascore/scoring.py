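"""Per-cell receptor-clustering score and the morphological descriptor bank.

The central quantity is the intensity-entropy score

    S = (1/N) * sum_i  rho_i * ln(rho_i),    rho_i = I_i / mean(I)

computed over the N pixels of one cell's ROI.  S depends only on the
*multiset* of pixel intensities — it deliberately ignores where the signal
sits inside the cell — and is invariant under any multiplicative gain.
Uniform signal gives S = 0; concentrating all signal in one pixel gives the
maximum ln(N).  Cells whose ligand clusters aggregate into a few large
puncta therefore score high, cells with scattered small puncta score low.

The 1/N factor makes the score intensive (independent of cell area), which
is what lets cells of different sizes and lines share one scale.

Around the score sits a documented descriptor bank (intensity moments,
punctum statistics, radial signal distribution, shape) and a Random-Forest /
t-SNE feature-ranking utility used to check that the entropy score is the
discriminative descriptor among them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from skimage import measure
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.preprocessing import StandardScaler

from .imaging import CellRecord, FluorescenceField, LabelMask, estimate_background

logger = logging.getLogger(__name__)

DEFAULT_RELATIVE_THRESHOLD = 0.5
MIN_PUNCTUM_AREA_PX = 4


class ScoreUndefinedError(ValueError):
    """Raised when the score is undefined (all-zero or degenerate intensities)."""


@dataclass
class CellScore:
    """A scored cell: raw entropy score plus the chip-normalized value once set."""

    cell_id: int
    well_id: str
    chip_id: str
    population_id: str
    s_epha: float
    n_pixels: int
    s_epha_hat: float | None = None


@dataclass
class DescriptorVector:
    cell_id: int
    values: dict[str, float]


@dataclass
class FeatureRanking:
    """Normalized Random-Forest importances, 2-D embedding, and OOB accuracy."""

    importances: dict[str, float]
    embedding: np.ndarray
    classifier_oob_accuracy: float
    excluded_descriptors: list[str]


def sepha(intensities) -> float:
    """Intensity-entropy clustering score of one cell's pixel multiset.

    Parameters
    ----------
    intensities : array-like of non-negative reals, length >= 2.

    Returns
    -------
    float in [0, ln N], 0 iff the intensities are constant.  Uses the
    continuity convention 0*ln(0) = 0, so zero pixels (e.g. after background
    subtraction) are legal as long as the mean stays positive.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("score requires at least 2 pixels")
    if np.any(x < 0):
        raise ValueError("negative intensities are not allowed")
    mean = x.mean()
    if mean <= 0:
        raise ScoreUndefinedError("all-zero intensities: score undefined")
    if np.ptp(x) == 0:  # constant intensities: exactly 0 regardless of rounding
        return 0.0
    rho = x / mean
    pos = rho > 0
    return float(np.sum(rho[pos] * np.log(rho[pos])) / x.size)


def score_cells(
    records: list[CellRecord],
    background_subtract: bool = True,
) -> list[CellScore]:
    """Score every cell record; background is subtracted (floored at 0) by default.

    Cells whose intensities become all-zero (or otherwise fail the score
    preconditions) are dropped with a logged reason rather than raising.
    """
    if not records:
        warnings.warn("score_cells called with no records", stacklevel=2)
        return []
    out: list[CellScore] = []
    for rec in records:
        vals = rec.intensities
        if background_subtract:
            vals = np.maximum(vals - rec.background_estimate, 0.0)
        try:
            s = sepha(vals)
        except (ScoreUndefinedError, ValueError) as exc:
            logger.info("dropping cell %s/%s/%d: %s", rec.chip_id, rec.well_id, rec.cell_id, exc)
            continue
        out.append(
            CellScore(
                cell_id=rec.cell_id,
                well_id=rec.well_id,
                chip_id=rec.chip_id,
                population_id=rec.population_id,
                s_epha=s,
                n_pixels=rec.area_px,
            )
        )
    return out


def detect_puncta(
    fieldobj: FluorescenceField,
    cell_mask: np.ndarray,
    relative_threshold: float = DEFAULT_RELATIVE_THRESHOLD,
    background: float | None = None,
):
    """Label bright puncta inside one cell.

    Pixels above ``background + relative_threshold * (max - background)``
    within the cell are connected-component labeled (8-connectivity);
    components under 4 px are discarded.  Returns the labeled int array.
    """
    if not 0 < relative_threshold < 1:
        raise ValueError("relative_threshold must be in (0, 1)")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    px = fieldobj.pixels.astype(float)
    if background is None:
        background = float(np.median(px[~cell_mask])) if (~cell_mask).any() else 0.0
    inside = px[cell_mask]
    peak = inside.max() if inside.size else 0.0
    # no in-cell contrast (uniform signal) or nothing above background: no puncta
    if peak <= background or (inside.size and np.ptp(inside) == 0):
        return np.zeros(fieldobj.shape, dtype=np.int32)
    cut = background + relative_threshold * (peak - background)
    bright = (px > cut) & cell_mask
    labels = measure.label(bright, connectivity=2)
    for region in measure.regionprops(labels):
        if region.area < MIN_PUNCTUM_AREA_PX:
            labels[labels == region.label] = 0
    out = measure.label(labels > 0, connectivity=2)
    return out.astype(np.int32)


#: descriptor names produced by :func:`descriptor_bank`, in output order
DESCRIPTOR_NAMES = (
    "s_epha",
    "mean_intensity",
    "sd_intensity",
    "cv_intensity",
    "skewness",
    "kurtosis",
    "top_decile_signal_fraction",
    "punctum_count",
    "punctum_mean_area",
    "punctum_max_area",
    "punctum_area_fraction",
    "punctum_nn_mean_distance",
    "punctum_nn_min_distance",
    "radial_signal_frac_25",
    "radial_signal_frac_50",
    "radial_signal_frac_75",
    "cell_area_px",
    "cell_eccentricity",
)


def descriptor_bank(
    fieldobj: FluorescenceField,
    mask: LabelMask,
    cell_id: int,
    relative_threshold: float = DEFAULT_RELATIVE_THRESHOLD,
    background: float | None = None,
) -> DescriptorVector:
    """Compute the documented morphological descriptor set for one cell.

    Intensity descriptors use background-subtracted values (floored at 0).
    Radial fractions measure what share of total signal lies within 25/50/75 %
    of the cell's normalized radius from its centroid.  Spot-detection failure
    yields zeroed punctum statistics, never an exception.
    """
    sel = mask.labels == cell_id
    if not sel.any():
        raise ValueError(f"cell {cell_id} not present in mask")
    if background is None:
        background = estimate_background(fieldobj, mask) if (mask.labels == 0).any() else 0.0
    vals = np.maximum(fieldobj.pixels[sel].astype(float) - background, 0.0)
    n = vals.size
    total = vals.sum()
    mean = vals.mean()
    sd = vals.std()
    d: dict[str, float] = {
        "s_epha": sepha(vals) if mean > 0 else 0.0,
        "mean_intensity": mean,
        "sd_intensity": sd,
        "cv_intensity": sd / mean if mean > 0 else 0.0,
        "skewness": float(sps.skew(vals)) if sd > 0 else 0.0,
        "kurtosis": float(sps.kurtosis(vals)) if sd > 0 else 0.0,
    }
    k = max(1, int(np.ceil(0.1 * n)))
    d["top_decile_signal_fraction"] = (
        float(np.sort(vals)[-k:].sum() / total) if total > 0 else 0.0
    )

    labels = detect_puncta(fieldobj, sel, relative_threshold, background=background)
    regions = measure.regionprops(labels)
    areas = np.array([r.area for r in regions], dtype=float)
    d["punctum_count"] = float(len(regions))
    d["punctum_mean_area"] = float(areas.mean()) if areas.size else 0.0
    d["punctum_max_area"] = float(areas.max()) if areas.size else 0.0
    d["punctum_area_fraction"] = float(areas.sum() / n) if areas.size else 0.0
    if len(regions) >= 2:
        cents = np.array([r.centroid for r in regions])
        dist = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=-1)
        np.fill_diagonal(dist, np.inf)
        nn = dist.min(axis=1)
        d["punctum_nn_mean_distance"] = float(nn.mean())
        d["punctum_nn_min_distance"] = float(nn.min())
    else:
        d["punctum_nn_mean_distance"] = 0.0
        d["punctum_nn_min_distance"] = 0.0

    rows, cols = np.nonzero(sel)
    cy, cx = rows.mean(), cols.mean()
    r = np.hypot(rows - cy, cols - cx)
    rmax = r.max() if r.max() > 0 else 1.0
    rn = r / rmax
    for frac in (0.25, 0.50, 0.75):
        key = f"radial_signal_frac_{int(frac * 100)}"
        d[key] = float(vals[rn <= frac].sum() / total) if total > 0 else 0.0

    props = measure.regionprops(sel.astype(np.uint8))[0]
    d["cell_area_px"] = float(n)
    d["cell_eccentricity"] = float(props.eccentricity)

    ordered = {name: float(d[name]) for name in DESCRIPTOR_NAMES}
    if not all(np.isfinite(v) for v in ordered.values()):
        bad = [k for k, v in ordered.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite descriptors: {bad}")
    return DescriptorVector(cell_id=cell_id, values=ordered)


def rank_descriptors(
    vectors: list[DescriptorVector],
    labels: list[str],
    seed: int = 0,
    n_estimators: int = 300,
) -> FeatureRanking:
    """Rank descriptors by Random-Forest importance for separating populations.

    Descriptors are standardized; constant descriptors are excluded and
    logged.  A 2-D t-SNE embedding of the standardized matrix is returned for
    visualization.  Deterministic under a fixed seed.
    """
    if len(vectors) != len(labels):
        raise ValueError("one label per descriptor vector required")
    pops, counts = np.unique(labels, return_counts=True)
    if len(pops) < 2 or counts.min() < 20:
        raise ValueError("need >= 2 populations with >= 20 cells each")
    names = list(vectors[0].values)
    for v in vectors:
        if list(v.values) != names:
            raise ValueError("descriptor name sets differ across cells")
    X = np.array([[v.values[n] for n in names] for v in vectors], dtype=float)
    keep = X.std(axis=0) > 0
    excluded = [n for n, k in zip(names, keep) if not k]
    if excluded:
        logger.info("excluding constant descriptors: %s", excluded)
    names = [n for n, k in zip(names, keep) if k]
    Xs = StandardScaler().fit_transform(X[:, keep])
    y = np.asarray(labels)

    clf = RandomForestClassifier(
        n_estimators=n_estimators, oob_score=True, random_state=seed, n_jobs=1
    )
    clf.fit(Xs, y)
    imp = clf.feature_importances_
    imp = imp / imp.sum() if imp.sum() > 0 else np.full_like(imp, 1 / len(imp))

    perplexity = min(30.0, (len(vectors) - 1) / 3.0)
    emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca").fit_transform(
        Xs
    )
    return FeatureRanking(
        importances=dict(zip(names, imp.tolist())),
        embedding=emb,
        classifier_oob_accuracy=float(clf.oob_score_),
        excluded_descriptors=excluded,
    )
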