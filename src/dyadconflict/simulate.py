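"""Synthetic dyadic study generator with known ground truth.

Emulates the study design this package analyses: ~60 depressed adolescents
(13-17), each with one or two participating parents (expected composition 43
fathers / 57 mothers), adolescent-reported conflict on 16 dichotomous items
per dyad, parent-reported interpersonal problems (32 ordinal items on the
circumplex) and depressive symptoms (17 ordinal items), realistic predictor
correlations, and the study's missingness pattern (sparse item-level MCAR
plus a handful of whole-scale dropouts).

The generative model mirrors the fitted one: per-parent true scores
(agency, communion, elevation, depression) from a correlated multivariate
normal; per-dyad latent conflict

    theta = x'b + u_family + eps,   u ~ Normal(0, tau),  eps ~ t_nu(0, sigma);

conflict items Bernoulli from a 2PL item bank; questionnaire items built from
noisy linear propensities around the true scores and discretized to their
ordinal ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datamodel import AdolescentRecord, DyadRecord, ParentRecord, StudyDataset
from .irt import ItemParameters, item_prob
from .scoring import NormTable, OCTANT_ANGLES_DEG

#: Default predictor correlations, order (agency, communion, elevation, depression).
DEFAULT_PREDICTOR_CORRELATION = np.array(
    [
        [1.00, -0.22, -0.54, -0.42],
        [-0.22, 1.00, -0.18, -0.06],
        [-0.54, -0.18, 1.00, 0.58],
        [-0.42, -0.06, 0.58, 1.00],
    ]
)

PREDICTOR_NAMES = ("agency", "communion", "elevation", "depression")


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator.

    Defaults emulate the modelled study: 60 families whose two-parent share
    implies 43 expected fathers and 57 expected mothers; standardized effects
    near the reported posterior means; residual/random-intercept scales near
    the reported variance posteriors; heavy-but-mild t tails (nu ~ 20).
    """

    n_families: int = 60
    prob_two_parents: float = 40 / 60
    prob_mother_only: float = 17 / 60
    prob_female_adolescent: float = 55 / 60
    true_coefficients: dict = field(
        default_factory=lambda: {
            "agency": 0.2,
            "communion": 0.0,
            "elevation": 0.1,
            "depression": -0.16,
            "depression_x_mother": 0.16,
        }
    )
    random_intercept_sd: float = 0.46  # tau
    residual_sd: float = 0.52  # sigma
    t_df: float = 20.0  # nu
    predictor_correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_PREDICTOR_CORRELATION.copy()
    )
    # ordinal item machinery (artifact choices, see docs/methods.md)
    iip_item_intercept: float = 1.2
    iip_item_slope: float = 0.7
    iip_item_noise_sd: float = 0.6
    scl_item_intercept: float = 1.9
    scl_item_slope: float = 0.8
    scl_item_noise_sd: float = 0.7
    item_missing_rates: dict = field(
        default_factory=lambda: {"cbq": 0.007, "iipc": 0.004, "scl": 0.001}
    )
    whole_scale_missing_counts: dict = field(
        default_factory=lambda: {"cbq": 2, "scl": 3, "iipc": 1}
    )
    n_items_cbq: int = 16
    seed: int = 0

    def validate(self) -> None:
        probs = [self.prob_two_parents, self.prob_mother_only, self.prob_female_adolescent]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.prob_two_parents + self.prob_mother_only > 1:
            raise ValueError("infeasible family-composition probabilities")
        R = np.asarray(self.predictor_correlation, dtype=float)
        if R.shape != (4, 4) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
            raise ValueError("predictor_correlation must be symmetric 4x4 with unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) <= 0:
            raise ValueError("predictor_correlation must be positive-definite")
        if self.t_df < 1:
            raise ValueError("t_df must be >= 1")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("scales must be non-negative")
        for r in self.item_missing_rates.values():
            if not 0 <= r <= 1:
                raise ValueError("missing rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Latent quantities behind a generated dataset, for recovery tests."""

    theta: dict  # (family_id, parent_id) -> latent conflict level
    true_scores: dict  # parent_id -> {agency, communion, elevation, depression}
    random_intercepts: dict  # family_id -> u
    item_bank: ItemParameters
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta": {f"{f}|{p}": v for (f, p), v in self.theta.items()},
            "true_scores": self.true_scores,
            "random_intercepts": self.random_intercepts,
            "item_discrimination": self.item_bank.discrimination.tolist(),
            "item_difficulty": self.item_bank.difficulty.tolist(),
            "config": _config_to_jsonable(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["predictor_correlation"] = np.asarray(config.predictor_correlation).tolist()
    return d


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed) & 0x7FFFFFFF, tag]))


def generate_item_bank(n_items: int, seed: int) -> ItemParameters:
    """Draw a 2PL item bank from the model's own priors.

    Discriminations ~ Gamma(shape 2, rate 0.5) truncated to (0, 10];
    difficulties ~ Normal(0, s) with the spread s itself drawn half-t(3, 0, 1),
    mirroring the hierarchical difficulty prior.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = _rng(seed, 101)
    disc = np.empty(n_items)
    filled = 0
    while filled < n_items:
        draw = rng.gamma(shape=2.0, scale=2.0, size=n_items)
        keep = draw[(draw > 0) & (draw <= 10.0)]
        take = min(n_items - filled, keep.size)
        disc[filled : filled + take] = keep[:take]
        filled += take
    spread = abs(rng.standard_t(df=3))
    diff = rng.normal(0.0, spread, size=n_items)
    return ItemParameters(disc, diff)


def _discretize(latent: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Round latent propensities to the nearest scale point (equally spaced cuts)."""
    return np.clip(np.rint(latent), lo, hi)


def generate_study(config: SimulationConfig) -> tuple[StudyDataset, GroundTruth]:
    """Generate a complete (no missingness) StudyDataset plus its ground truth."""
    config.validate()
    rng = _rng(config.seed, 202)
    bank = generate_item_bank(config.n_items_cbq, config.seed)
    L = np.linalg.cholesky(np.asarray(config.predictor_correlation, dtype=float))
    coefs = dict(config.true_coefficients)

    adolescents, parents, dyads = [], [], []
    theta_truth, score_truth, u_truth = {}, {}, {}
    angles = np.deg2rad(np.asarray(OCTANT_ANGLES_DEG))

    p_both = config.prob_two_parents
    p_mother = config.prob_mother_only
    parent_counter = 0
    for i in range(config.n_families):
        fam = f"F{i + 1:03d}"
        age = int(rng.integers(13, 18))
        gender = "female" if rng.random() < config.prob_female_adolescent else "male"
        adolescents.append(AdolescentRecord(fam, age, gender))
        u = rng.normal(0.0, config.random_intercept_sd)
        u_truth[fam] = float(u)

        comp = rng.random()
        if comp < p_both:
            members = ["father", "mother"]
        elif comp < p_both + p_mother:
            members = ["mother"]
        else:
            members = ["father"]

        for pg in members:
            parent_counter += 1
            pid = f"P{parent_counter:03d}"
            x = L @ rng.standard_normal(4)  # (agency, communion, elevation, depression)
            score_truth[pid] = dict(zip(PREDICTOR_NAMES, map(float, x)))
            mother = 1.0 if pg == "mother" else 0.0
            mean = (
                coefs.get("agency", 0.0) * x[0]
                + coefs.get("communion", 0.0) * x[1]
                + coefs.get("elevation", 0.0) * x[2]
                + coefs.get("depression", 0.0) * x[3]
                + coefs.get("depression_x_mother", 0.0) * x[3] * mother
                + coefs.get("mother", 0.0) * mother
                + coefs.get("age", 0.0) * (age - 15)
                + u
            )
            eps = config.residual_sd * rng.standard_t(config.t_df) if config.residual_sd > 0 else 0.0
            theta = float(mean + eps)
            theta_truth[(fam, pid)] = theta

            # IIP-C items: octant propensity = elevation + agency*sin + communion*cos
            octant_prop = x[2] + x[0] * np.sin(angles) + x[1] * np.cos(angles)
            item_prop = np.repeat(octant_prop, 4)  # blocks of 4 per octant
            latent = (
                config.iip_item_intercept
                + config.iip_item_slope * (item_prop + rng.normal(0, config.iip_item_noise_sd, 32))
            )
            iip = _discretize(latent, 0, 4)

            scl_latent = (
                config.scl_item_intercept
                + config.scl_item_slope * (x[3] + rng.normal(0, config.scl_item_noise_sd, 17))
            )
            scl = _discretize(scl_latent, 1, 5)
            parents.append(ParentRecord(pid, fam, pg, iip, scl))

            p = item_prob(theta, bank.discrimination, bank.difficulty)
            cbq = (rng.random(config.n_items_cbq) < p).astype(float)
            dyads.append(DyadRecord(fam, pid, cbq))

    dataset = StudyDataset(adolescents, parents, dyads)
    truth = GroundTruth(theta_truth, score_truth, u_truth, bank, config)
    return dataset, truth


def inject_missingness(dataset: StudyDataset, config: SimulationConfig) -> StudyDataset:
    """Apply MCAR item-level deletion plus whole-scale dropouts (in place on a copy).

    Item cells are deleted independently at the configured per-scale rates.
    Whole scales are then deleted for randomly chosen respondents: CBQ for
    whole dyads, SCL and IIP-C for whole parents.  At most one whole scale is
    forced per respondent, except that when both SCL and IIP-C counts are
    requested, one SCL-missing parent also loses the IIP-C (the study observed
    exactly that overlap).
    """
    rng = _rng(config.seed, 303)
    rates = config.item_missing_rates
    counts = config.whole_scale_missing_counts

    import copy

    ds = copy.deepcopy(dataset)
    for p in ds.parents:
        p.iipc_items[rng.random(32) < rates.get("iipc", 0.0)] = np.nan
        p.scl_items[rng.random(17) < rates.get("scl", 0.0)] = np.nan
    for d in ds.dyads:
        d.cbq_items[rng.random(d.cbq_items.size) < rates.get("cbq", 0.0)] = np.nan

    n_cbq = int(counts.get("cbq", 0))
    n_scl = int(counts.get("scl", 0))
    n_iip = int(counts.get("iipc", 0))
    if n_cbq > len(ds.dyads) or max(n_scl, n_iip) > len(ds.parents):
        raise ValueError("whole-scale missing counts exceed respondent counts")

    if n_cbq:
        for j in rng.choice(len(ds.dyads), size=n_cbq, replace=False):
            ds.dyads[j].cbq_items[:] = np.nan

    scl_idx = rng.choice(len(ds.parents), size=n_scl, replace=False) if n_scl else np.array([], int)
    for j in scl_idx:
        ds.parents[j].scl_items[:] = np.nan
    if n_iip:
        # one overlap with the SCL-missing parents when possible; remaining
        # IIP-C dropouts come from parents not already scale-missing
        overlap = 1 if (n_scl > 0 and n_iip >= 1) else 0
        chosen = list(scl_idx[:overlap])
        remaining = [k for k in range(len(ds.parents)) if k not in set(scl_idx)]
        extra = n_iip - overlap
        if extra > len(remaining):
            raise ValueError("whole-scale missing counts exceed respondent counts")
        if extra:
            chosen += list(rng.choice(remaining, size=extra, replace=False))
        for j in chosen:
            ds.parents[j].iipc_items[:] = np.nan
    return ds


def generate_dataset(config: SimulationConfig) -> tuple[StudyDataset, GroundTruth]:
    """generate_study followed by inject_missingness (the full study emulation)."""
    complete, truth = generate_study(config)
    return inject_missingness(complete, config), truth


def synthetic_norms(config: SimulationConfig | None = None, n: int = 20000, seed: int = 12345) -> NormTable:
    """Octant norm table from the generator's own marginals (Monte Carlo).

    Stands in for population norms, which are an external input on real data;
    the stand-in is synthetic and is labelled as such.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(np.asarray(config.predictor_correlation, dtype=float))
    x = rng.standard_normal((n, 4)) @ L.T
    angles = np.deg2rad(np.asarray(OCTANT_ANGLES_DEG))
    octant_prop = x[:, 2:3] + x[:, 0:1] * np.sin(angles) + x[:, 1:2] * np.cos(angles)
    item_prop = np.repeat(octant_prop, 4, axis=1)
    latent = config.iip_item_intercept + config.iip_item_slope * (
        item_prop + rng.normal(0, config.iip_item_noise_sd, (n, 32))
    )
    items = _discretize(latent, 0, 4)
    octants = items.reshape(n, 8, 4).mean(axis=2)
    return NormTable(octants.mean(axis=0), octants.std(axis=0, ddof=1))
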