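"""Scale scoring: interpersonal circumplex dimensions, depression subscale,
and two-way imputation of item-level missingness.

The IIP-C (32 items) is scored into eight octant scales (4 items each),
standardized against a norm table, and projected onto the circumplex
dimensions:

    elevation = mean(z_1..z_8)
    agency    = (1/4) * sum_i z_i * sin(angle_i)
    communion = (1/4) * sum_i z_i * cos(angle_i)

with the warm/communal pole (LM) at 0 degrees and the dominant pole (PA) at
90 degrees, octants every 45 degrees counterclockwise.  The 1/4 scaling makes
a unit-amplitude cosine profile score amplitude 1 on the projected dimension.

Item-level missing responses are singly imputed by two-way imputation
(person mean + item mean - overall mean, computed over observed cells), with
an optional stochastic variant for the multiple-imputation stability
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

#: Octant order and angular positions (degrees).  PA = dominant (90), LM = warm (0).
OCTANT_ORDER = ("PA", "BC", "DE", "FG", "HI", "JK", "LM", "NO")
OCTANT_ANGLES_DEG = (90.0, 135.0, 180.0, 225.0, 270.0, 315.0, 0.0, 45.0)

#: Default item -> octant map: fixed blocks of 4 in the 32-item order.
DEFAULT_ITEM_OCTANT_MAP: dict[int, str] = {
    i: OCTANT_ORDER[i // 4] for i in range(32)
}


@dataclass(frozen=True)
class OctantProfile:
    """Eight octant scale scores in the fixed order PA..NO."""

    octant_scores: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.octant_scores, dtype=float)
        if z.shape != (8,):
            raise ValueError("an octant profile has exactly 8 scores")
        object.__setattr__(self, "octant_scores", z)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.asarray(OCTANT_ANGLES_DEG)


@dataclass(frozen=True)
class NormTable:
    """Per-octant normative means and standard deviations (PA..NO order)."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if m.shape != (8,) or s.shape != (8,):
            raise ValueError("norm table needs 8 means and 8 SDs")
        if np.any(s <= 0):
            raise ValueError("norm SDs must be positive")
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)


@dataclass(frozen=True)
class CircumplexScores:
    agency: float
    communion: float
    elevation: float


def score_octants(
    iipc_items: Sequence[float],
    item_octant_map: Mapping[int, str] = DEFAULT_ITEM_OCTANT_MAP,
) -> OctantProfile:
    """Mean the four items of each octant into its scale score.

    Items must be complete; impute item-level missingness first.
    """
    items = np.asarray(iipc_items, dtype=float)
    if items.shape != (32,):
        raise ValueError("IIP-C has 32 items")
    if np.any(np.isnan(items)):
        raise ValueError("missing items present; run two-way imputation first")
    counts = {o: 0 for o in OCTANT_ORDER}
    sums = {o: 0.0 for o in OCTANT_ORDER}
    for idx in range(32):
        octant = item_octant_map.get(idx)
        if octant not in counts:
            raise ValueError(f"item {idx} maps to unknown octant {octant!r}")
        counts[octant] += 1
        sums[octant] += items[idx]
    if any(c != 4 for c in counts.values()):
        raise ValueError("item-octant map must assign exactly 4 items per octant")
    return OctantProfile(np.array([sums[o] / 4.0 for o in OCTANT_ORDER]))


def standardize_octants(profile: OctantProfile, norms: NormTable) -> OctantProfile:
    """z-score each octant against its normative mean and SD."""
    return OctantProfile((profile.octant_scores - norms.means) / norms.sds)


def dimensional_scores(z_profile: OctantProfile) -> CircumplexScores:
    """Project a z-scored octant profile onto (agency, communion, elevation)."""
    z = z_profile.octant_scores
    ang = np.deg2rad(z_profile.angles_deg)
    return CircumplexScores(
        agency=float(np.sum(z * np.sin(ang)) / 4.0),
        communion=float(np.sum(z * np.cos(ang)) / 4.0),
        elevation=float(np.mean(z)),
    )


def score_depression(scl_items: Sequence[float]) -> float:
    """Mean item score of the 17-item revised SCL-90-R depression subscale."""
    items = np.asarray(scl_items, dtype=float)
    if items.shape != (17,):
        raise ValueError("the revised depression subscale has 17 items")
    if np.any(np.isnan(items)):
        raise ValueError("missing items present; run two-way imputation first")
    if np.any((items < 1) | (items > 5)):
        raise ValueError("SCL items are rated 1-5")
    return float(np.mean(items))


def _twoway_fit(matrix: np.ndarray):
    obs = ~np.isnan(matrix)
    if np.any(obs.sum(axis=1) == 0):
        raise ValueError("a person (row) has no observed items")
    if np.any(obs.sum(axis=0) == 0):
        raise ValueError("an item (column) has no observed responses")
    person_means = np.nanmean(matrix, axis=1)
    item_means = np.nanmean(matrix, axis=0)
    grand_mean = float(np.nanmean(matrix))
    fitted = person_means[:, None] + item_means[None, :] - grand_mean
    resid = matrix - fitted
    n_obs = int(obs.sum())
    residual_sd = float(np.sqrt(np.nansum(resid**2) / n_obs)) if n_obs else 0.0
    return person_means, item_means, grand_mean, fitted, residual_sd


@dataclass(frozen=True)
class ImputationModel:
    """Two-way additive fit PM_i + IM_j - OM over the observed cells."""

    person_means: np.ndarray
    item_means: np.ndarray
    grand_mean: float
    residual_sd: float


def fit_imputation_model(matrix) -> ImputationModel:
    m = np.asarray(matrix, dtype=float)
    pm, im, om, _, rsd = _twoway_fit(m)
    return ImputationModel(pm, im, om, rsd)


def twoway_impute(
    matrix,
    stochastic: bool = False,
    round_to_scale: bool = False,
    scale_points: Sequence[float] | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Fill missing cells with PM_i + IM_j - OM (two-way imputation).

    Parameters
    ----------
    matrix
        persons x items array; missing cells are NaN.
    stochastic
        Add Normal(0, residual_sd) noise to each imputed value, where
        residual_sd is the SD of observed-cell residuals under the two-way fit.
    round_to_scale
        Round imputed values to the nearest legal scale point and clip to the
        scale range.  ``scale_points`` defaults to the sorted unique observed
        values.
    """
    m = np.asarray(matrix, dtype=float).copy()
    pm, im, om, fitted, rsd = _twoway_fit(m)
    miss = np.isnan(m)
    if not np.any(miss):
        return m
    values = fitted[miss]
    if stochastic:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, rsd, size=values.shape)
    if round_to_scale:
        if scale_points is None:
            pts = np.unique(m[~miss])
        else:
            pts = np.sort(np.asarray(scale_points, dtype=float))
        idx = np.argmin(np.abs(values[:, None] - pts[None, :]), axis=1)
        values = pts[idx]
    m[miss] = values
    return m


def imputation_stability(
    matrix,
    score_fn: Callable[[np.ndarray], float],
    n_imputations: int = 1000,
    round_to_scale: bool = False,
    scale_points: Sequence[float] | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Per-person SD of a summary score across stochastic two-way imputations.

    Persons with no missing items have SD exactly 0.  This is the stability
    diagnostic used to justify single imputation: small SDs mean the summary
    scores barely vary across plausible completions.
    """
    if n_imputations < 2:
        raise ValueError("need at least 2 imputations to estimate an SD")
    m = np.asarray(matrix, dtype=float)
    miss_rows = np.any(np.isnan(m), axis=1)
    rng = np.random.default_rng(seed)
    scores = np.zeros((n_imputations, m.shape[0]))
    for k in range(n_imputations):
        completed = twoway_impute(
            m,
            stochastic=True,
            round_to_scale=round_to_scale,
            scale_points=scale_points,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scores[k] = np.apply_along_axis(score_fn, 1, completed)
    sds = scores.std(axis=0, ddof=1)
    sds[~miss_rows] = 0.0
    return sds


def score_parents(
    dataset,
    norms: NormTable,
    item_octant_map: Mapping[int, str] = DEFAULT_ITEM_OCTANT_MAP,
    seed: int | None = None,
):
    """Score every parent of a dataset: circumplex dimensions + depression mean.

    Item-level missingness is singly imputed by deterministic two-way
    imputation with rounding to the scale (computed jointly over all parents
    with at least one observed item per scale); parents with a whole scale
    missing keep NaN on that scale's summary scores, flagged in the output.

    Returns a DataFrame indexed by parent_id with columns agency, communion,
    elevation, depression, n_imputed_iipc, n_imputed_scl, iipc_missing,
    scl_missing.
    """
    import pandas as pd

    parents = dataset.parents
    iip = np.vstack([p.iipc_items for p in parents])
    scl = np.vstack([p.scl_items for p in parents])
    ids = [p.parent_id for p in parents]

    def _impute_partial(matrix: np.ndarray, points: Sequence[float]) -> np.ndarray:
        out = matrix.copy()
        rows = ~np.all(np.isnan(matrix), axis=1)
        if rows.any() and np.any(np.isnan(matrix[rows])):
            out[rows] = twoway_impute(
                matrix[rows], stochastic=False, round_to_scale=True,
                scale_points=points, seed=seed,
            )
        return out

    iip_f = _impute_partial(iip, points=range(5))
    scl_f = _impute_partial(scl, points=range(1, 6))

    records = []
    for i, pid in enumerate(ids):
        iip_missing = bool(np.all(np.isnan(iip[i])))
        scl_missing = bool(np.all(np.isnan(scl[i])))
        if iip_missing:
            ag = co = el = np.nan
        else:
            prof = score_octants(iip_f[i], item_octant_map)
            dims = dimensional_scores(standardize_octants(prof, norms))
            ag, co, el = dims.agency, dims.communion, dims.elevation
        dep = np.nan if scl_missing else score_depression(scl_f[i])
        records.append(
            {
                "parent_id": pid,
                "agency": ag,
                "communion": co,
                "elevation": el,
                "depression": dep,
                "n_imputed_iipc": int(np.isnan(iip[i]).sum()) if not iip_missing else 32,
                "n_imputed_scl": int(np.isnan(scl[i]).sum()) if not scl_missing else 17,
                "iipc_missing": iip_missing,
                "scl_missing": scl_missing,
            }
        )
    return pd.DataFrame(records).set_index("parent_id")
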