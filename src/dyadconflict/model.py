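"""Joint Bayesian model: 2PL measurement of latent conflict + multilevel
robust regression with Student-t errors, estimated by NUTS.

Model (for dyad d in family f(d), conflict items j):

    y_dj ~ Bernoulli( logit^{-1}( alpha_j (theta_d - beta_j) ) )
    theta_d ~ Student-t( nu, x_d' b [+ intercept] + u_{f(d)}, sigma )
    u_f ~ Normal(0, tau)

with priors: b ~ N(0,1); alpha_j ~ Gamma(2, 0.5) truncated to (0, 10];
beta_j ~ N(mu_beta, sigma_beta) with mu_beta ~ N(0, 3) and sigma_beta ~
half-t(3,0,1); sigma, tau ~ half-t(3,0,1); nu - 1 ~ Gamma(2, 0.1).  Whole
-scale-missing continuous predictors are treated as unknowns under a joint
multivariate normal over (agency, communion, elevation, depression).

The log posterior and its gradient are computed analytically on an
unconstrained parameter vector (log/logit transforms with Jacobians), which
is what makes NUTS practical here.  Four pre-registered regression
specifications are provided (M1-M4): depressive symptoms with and without a
parent-gender interaction, and interpersonal-circumplex problems with and
without the interaction; all include adolescent age centred at 15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln

from .datamodel import StudyDataset
from .nuts import sample_nuts

PREDICTOR_BLOCK = ("agency", "communion", "elevation", "depression")

# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the prior distributions (see module docstring)."""

    coef_sd: float = 1.0
    theta_anchor_sd: float = 1.0
    item_difficulty_loc_sd: float = 3.0
    scale_half_t_df: float = 3.0
    scale_half_t_scale: float = 1.0
    discrimination_shape: float = 2.0
    discrimination_rate: float = 0.5
    discrimination_cap: float = 10.0
    t_df_shape: float = 2.0
    t_df_rate: float = 0.1


_MODEL_TERMS = {
    "M1_depression": (
        False,
        [("x", 3, "depression"), ("age", None, "age")],
    ),
    "M2_depression_gender": (
        True,
        [
            ("x", 3, "depression"),
            ("mother", None, "mother"),
            ("x_mother", 3, "depression_x_mother"),
            ("age", None, "age"),
        ],
    ),
    "M3_interpersonal": (
        False,
        [
            ("x", 0, "agency"),
            ("x", 1, "communion"),
            ("x", 2, "elevation"),
            ("age", None, "age"),
        ],
    ),
    "M4_interpersonal_gender": (
        True,
        [
            ("x", 0, "agency"),
            ("x", 1, "communion"),
            ("x", 2, "elevation"),
            ("mother", None, "mother"),
            ("x_mother", 0, "agency_x_mother"),
            ("x_mother", 1, "communion_x_mother"),
            ("x_mother", 2, "elevation_x_mother"),
            ("age", None, "age"),
        ],
    ),
}

MODEL_IDS = tuple(_MODEL_TERMS)


@dataclass(frozen=True)
class ModelSpec:
    """One of the four pre-registered regression specifications."""

    model_id: str

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_TERMS:
            raise ValueError(f"unknown model id {self.model_id!r}; choose from {MODEL_IDS}")

    @property
    def includes_intercept(self) -> bool:
        return _MODEL_TERMS[self.model_id][0]

    @property
    def terms(self):
        return _MODEL_TERMS[self.model_id][1]

    @property
    def coef_names(self) -> list[str]:
        names = ["intercept"] if self.includes_intercept else []
        return names + [t[2] for t in self.terms]


@dataclass(frozen=True)
class ModelOptions:
    """Structural switches (likelihood family, fixed scales, toy modes)."""

    likelihood: str = "t"  # "t" | "normal"
    fix_nu: float | None = None
    fix_sigma: float | None = None
    random_intercept: bool = True
    fix_tau: float | None = None
    predictor_model: bool = True
    theta_anchor: bool = False
    latent_outcome: bool = True  # False: theta observed directly (toy/oracle mode)


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup_iterations: int = 1000
    sampling_iterations: int = 3500
    seed: int = 0
    target_acceptance: float = 0.9
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.sampling_iterations < 1 or self.warmup_iterations < 0:
            raise ValueError("iteration counts must be positive")


#: Reduced profile used by the test-suite and scaled-down pipelines.
TEST_SAMPLER = SamplerConfig(chains=2, warmup_iterations=500, sampling_iterations=500)


# ---------------------------------------------------------------------------
# predictor matrix


@dataclass
class PredictorMatrix:
    """Per-dyad design inputs aligned with the dyad list of a dataset.

    ``x`` holds the four standardized continuous predictors (agency,
    communion, elevation, depression) with NaN marking whole-scale-missing
    entries; gender and age are always observed.
    """

    x: np.ndarray  # (D, 4), NaN = missing
    mother: np.ndarray  # (D,)
    age_centered: np.ndarray  # (D,)
    family_ids: list[str]  # per dyad
    parent_ids: list[str]  # per dyad
    families: list[str]  # unique family order
    family_index: np.ndarray  # (D,) into families


def build_predictor_matrix(dataset: StudyDataset, scores: pd.DataFrame) -> PredictorMatrix:
    """Assemble the regression design from a scored-parents table.

    ``scores`` is indexed by parent_id with columns agency, communion,
    elevation, depression (NaN where the whole scale was missing).  The four
    continuous predictors are z-scored within sample; age is centred at 15;
    the mother dummy codes father as the reference category.
    """
    adol = dataset.adolescent_by_family()
    cols = list(PREDICTOR_BLOCK)
    missing_parents = [p.parent_id for p in dataset.parents if p.parent_id not in scores.index]
    if missing_parents:
        raise ValueError(f"no scores for parents {missing_parents}")

    x_rows, mother, age_c, fam_ids, par_ids = [], [], [], [], []
    parent_by_id = dataset.parent_by_id()
    for d in dataset.dyads:
        row = scores.loc[d.parent_id, cols].to_numpy(dtype=float)
        x_rows.append(row)
        mother.append(1.0 if parent_by_id[d.parent_id].gender == "mother" else 0.0)
        age_c.append(float(adol[d.family_id].age_years - 15))
        fam_ids.append(d.family_id)
        par_ids.append(d.parent_id)

    x = np.asarray(x_rows, dtype=float)
    # standardize within sample over observed entries
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd

    families = sorted(set(fam_ids), key=fam_ids.index)
    fam_lookup = {f: i for i, f in enumerate(families)}
    return PredictorMatrix(
        x=x,
        mother=np.asarray(mother),
        age_centered=np.asarray(age_c),
        family_ids=fam_ids,
        parent_ids=par_ids,
        families=families,
        family_index=np.asarray([fam_lookup[f] for f in fam_ids], dtype=int),
    )


def _design_and_grad_map(spec: ModelSpec, x: np.ndarray, mother: np.ndarray, age: np.ndarray):
    """Design matrix W (D, K) and, per continuous column j, the design columns
    through which x[:, j] enters (base and mother-interaction)."""
    D = x.shape[0]
    cols = []
    if spec.includes_intercept:
        cols.append(np.ones(D))
    base_col = {}  # predictor-block col j -> design index
    inter_col = {}
    offset = 1 if spec.includes_intercept else 0
    for k, (kind, j, _name) in enumerate(spec.terms):
        if kind == "x":
            cols.append(x[:, j])
            base_col[j] = offset + k
        elif kind == "x_mother":
            cols.append(x[:, j] * mother)
            inter_col[j] = offset + k
        elif kind == "mother":
            cols.append(mother)
        elif kind == "age":
            cols.append(age)
        else:  # pragma: no cover
            raise AssertionError(kind)
    return np.column_stack(cols), base_col, inter_col


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """Named posterior draws indexed (chain, iteration, ...) plus diagnostics."""

    draws: dict
    coef_names: list[str]
    spec: ModelSpec
    options: ModelOptions
    diagnostics: dict

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def coefficient(self, coef_name: str) -> np.ndarray:
        k = self.coef_names.index(coef_name)
        return self.pooled("b")[:, k]

    def to_inference_data(self):
        import arviz as az

        return az.from_dict({k: v for k, v in self.draws.items()})


# ---------------------------------------------------------------------------
# the joint model


_TRIL_R, _TRIL_C = np.tril_indices(4)
_IS_DIAG = _TRIL_R == _TRIL_C


def _solve_lower4(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Forward substitution L Z = B for 4x4 lower-triangular L, B (4, n)."""
    Z = np.empty_like(B)
    Z[0] = B[0] / L[0, 0]
    Z[1] = (B[1] - L[1, 0] * Z[0]) / L[1, 1]
    Z[2] = (B[2] - L[2, 0] * Z[0] - L[2, 1] * Z[1]) / L[2, 2]
    Z[3] = (B[3] - L[3, 0] * Z[0] - L[3, 1] * Z[1] - L[3, 2] * Z[2]) / L[3, 3]
    return Z


def _solve_upper4(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Back substitution L' A = B (L lower-triangular), B (4, n)."""
    A = np.empty_like(B)
    A[3] = B[3] / L[3, 3]
    A[2] = (B[2] - L[3, 2] * A[3]) / L[2, 2]
    A[1] = (B[1] - L[2, 1] * A[2] - L[3, 1] * A[3]) / L[1, 1]
    A[0] = (B[0] - L[1, 0] * A[1] - L[2, 0] * A[2] - L[3, 0] * A[3]) / L[0, 0]
    return A


class JointModel:
    """Log posterior + gradient of the joint model on an unconstrained vector."""

    def __init__(
        self,
        spec: ModelSpec,
        matrix: PredictorMatrix,
        y_items: np.ndarray | None,
        y_cont: np.ndarray | None = None,
        priors: PriorSpec = PriorSpec(),
        options: ModelOptions = ModelOptions(),
    ) -> None:
        self.spec, self.priors, self.options = spec, priors, options
        self.mother = matrix.mother
        self.age = matrix.age_centered
        self.fam_idx = matrix.family_index
        self.n_fam = len(matrix.families)
        self.D = matrix.x.shape[0]

        if options.latent_outcome:
            if y_items is None:
                raise ValueError("latent-outcome model needs item responses")
            y = np.asarray(y_items, dtype=float)
            self.obs_mask = ~np.isnan(y)
            if np.any(self.obs_mask.sum(axis=0) == 0):
                warnings.warn("an item has no observed responses", stacklevel=2)
            self.obs_f = self.obs_mask.astype(float)
            self.y = np.where(self.obs_mask, y, 0.0)
            self.J = y.shape[1]
        else:
            if y_cont is None:
                raise ValueError("observed-outcome model needs a continuous outcome")
            self.y_cont = np.asarray(y_cont, dtype=float)
            self.J = 0

        self.x_obs = matrix.x.copy()
        self.x_miss_idx = np.argwhere(np.isnan(matrix.x))
        if self.x_miss_idx.size and not options.predictor_model:
            raise ValueError(
                "whole-scale-missing predictors present; enable the multivariate "
                "normal predictor model"
            )
        self.x_obs[np.isnan(self.x_obs)] = 0.0  # placeholder, overwritten per eval
        # design cache: only the missing-x entries change between evaluations
        self.W0, self.base_col, self.inter_col = _design_and_grad_map(
            spec, self.x_obs, self.mother, self.age
        )

        self.use_u = options.random_intercept and options.fix_tau != 0.0
        self.free_tau = self.use_u and options.fix_tau is None
        self.free_sigma = options.fix_sigma is None
        self.t_like = options.likelihood == "t"
        self.free_nu = self.t_like and options.fix_nu is None

        # --- parameter layout ------------------------------------------------
        slices = {}
        pos = 0

        def _add(name: str, size: int):
            nonlocal pos
            slices[name] = slice(pos, pos + size)
            pos += size

        if options.latent_outcome:
            _add("theta", self.D)
        if self.use_u:
            _add("u_raw", self.n_fam)
        if self.free_tau:
            _add("log_tau", 1)
        self.K = len(spec.coef_names)
        _add("b", self.K)
        if self.free_sigma:
            _add("log_sigma", 1)
        if self.free_nu:
            _add("nu_raw", 1)
        if options.latent_outcome:
            _add("alpha_raw", self.J)
            _add("beta_raw", self.J)
            _add("mu_beta", 1)
            _add("log_sigma_beta", 1)
        if options.predictor_model:
            _add("mu_x", 4)
            _add("lchol", 10)
            if len(self.x_miss_idx):
                _add("x_miss", len(self.x_miss_idx))
        self.slices = slices
        self.dim = pos

    # -- transforms ---------------------------------------------------------

    def _unpack(self, v: np.ndarray) -> dict:
        return {k: v[s] for k, s in self.slices.items()}

    # -- log posterior and gradient ------------------------------------------

    def _build_fast_args(self):
        from ._fast import NUMBA_AVAILABLE

        if not NUMBA_AVAILABLE:  # pragma: no cover - numba is a hard runtime dep
            return None
        opt = self.options
        base_arr = np.full(4, -1, dtype=np.int64)
        inter_arr = np.full(4, -1, dtype=np.int64)
        for j, k in self.base_col.items():
            base_arr[j] = k
        for j, k in self.inter_col.items():
            inter_arr[j] = k
        order = [
            "theta", "u_raw", "log_tau", "b", "log_sigma", "nu_raw", "alpha_raw",
            "beta_raw", "mu_beta", "log_sigma_beta", "mu_x", "lchol", "x_miss",
        ]
        idx = np.array(
            [self.slices[n].start if n in self.slices else -1 for n in order],
            dtype=np.int64,
        )
        flags = np.array(
            [
                opt.latent_outcome, self.use_u, self.free_tau, self.free_sigma,
                self.t_like, self.free_nu, opt.theta_anchor, opt.predictor_model,
            ],
            dtype=np.bool_,
        )
        pr = self.priors
        consts = np.array(
            [
                float(opt.fix_sigma or 0.0), float(opt.fix_tau or 0.0),
                float(opt.fix_nu or 0.0), pr.coef_sd, pr.theta_anchor_sd,
                pr.item_difficulty_loc_sd, pr.discrimination_shape,
                pr.discrimination_rate, pr.discrimination_cap, pr.t_df_rate,
            ]
        )
        if opt.latent_outcome:
            y, obs = self.y, self.obs_f
            y_cont = np.zeros(0)
        else:
            y = np.zeros((self.D, 0))
            obs = np.zeros((self.D, 0))
            y_cont = self.y_cont
        miss = self.x_miss_idx if len(self.x_miss_idx) else np.zeros((0, 2), dtype=np.int64)
        return (
            y, obs, y_cont, self.W0, self.mother, self.fam_idx.astype(np.int64),
            self.x_obs, miss[:, 0].astype(np.int64), miss[:, 1].astype(np.int64),
            base_arr, inter_arr, idx, flags, consts,
        )

    def logp_grad(self, v: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint log posterior density and gradient (compiled fast path)."""
        if not hasattr(self, "_fast_args"):
            self._fast_args = self._build_fast_args()
        if self._fast_args is not None:
            from ._fast import joint_logp_grad

            lp, grad = joint_logp_grad(v, *self._fast_args)
            return float(lp), grad
        return self.logp_grad_reference(v)

    def logp_grad_reference(self, v: np.ndarray) -> tuple[float, np.ndarray]:
        pr = self.priors
        opt = self.options
        p = self._unpack(v)
        grad = np.zeros_like(v)
        g = {k: grad[s] for k, s in self.slices.items()}  # views
        lp = 0.0

        # constrained quantities
        if self.free_sigma:
            sigma = float(np.exp(p["log_sigma"][0]))
        else:
            sigma = float(opt.fix_sigma)
        if self.free_tau:
            tau = float(np.exp(p["log_tau"][0]))
        elif self.use_u:
            tau = float(opt.fix_tau)
        else:
            tau = 0.0
        if self.t_like:
            if self.free_nu:
                gshift = float(np.exp(p["nu_raw"][0]))
                nu = 1.0 + gshift
            else:
                nu = float(opt.fix_nu)

        base_col, inter_col = self.base_col, self.inter_col
        if "x_miss" in p and len(self.x_miss_idx):
            x = self.x_obs.copy()
            x[self.x_miss_idx[:, 0], self.x_miss_idx[:, 1]] = p["x_miss"]
            W = self.W0.copy()
            for (d, j), val in zip(self.x_miss_idx, p["x_miss"]):
                if j in base_col:
                    W[d, base_col[j]] = val
                if j in inter_col:
                    W[d, inter_col[j]] = val * self.mother[d]
        else:
            x, W = self.x_obs, self.W0
        b = p["b"]
        m = W @ b
        if self.use_u:
            u = tau * p["u_raw"]
            m = m + u[self.fam_idx]

        # outcome value
        if opt.latent_outcome:
            theta = p["theta"]
        else:
            theta = self.y_cont

        # ---- structural likelihood theta ~ t/normal(m, sigma) --------------
        z = (theta - m) / sigma
        if self.t_like:
            z2 = z * z
            w = (nu + 1.0) / (nu + z2)
            lp += self.D * (
                gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(nu * np.pi) - np.log(sigma)
            )
            lp += float(np.sum(-(nu + 1) / 2 * np.log1p(z2 / nu)))
            dtheta = -w * z / sigma
            dsigma = float(np.sum(w * z2 - 1.0)) / sigma
            if self.free_nu:
                dnu = float(
                    np.sum(
                        0.5
                        * (
                            digamma((nu + 1) / 2)
                            - digamma(nu / 2)
                            - 1.0 / nu
                            - np.log1p(z2 / nu)
                            + w * z2 / nu
                        )
                    )
                )
        else:
            lp += float(np.sum(-0.5 * z * z)) - self.D * np.log(sigma)
            dtheta = -z / sigma
            dsigma = float(np.sum(z * z - 1.0)) / sigma

        dm = -dtheta  # gradient w.r.t. the linear predictor
        g["b"] += W.T @ dm

        # x-entry gradients through the design (missing entries only need it)
        if "x_miss" in p and len(self.x_miss_idx):
            dX = np.zeros_like(x)
            for j, k in base_col.items():
                dX[:, j] += dm * b[k]
            for j, k in inter_col.items():
                dX[:, j] += dm * b[k] * self.mother
            g["x_miss"] += dX[self.x_miss_idx[:, 0], self.x_miss_idx[:, 1]]

        if self.use_u:
            du = np.bincount(self.fam_idx, weights=dm, minlength=self.n_fam)
            g["u_raw"] += tau * du
            if self.free_tau:
                dtau = float(np.dot(du, p["u_raw"]))
                g["log_tau"] += tau * (dtau - 4 * tau / (3 + tau * tau)) + 1.0
                lp += -2.0 * np.log1p(tau * tau / 3.0) + float(p["log_tau"][0])
            # u_raw ~ N(0,1)
            lp += float(np.sum(-0.5 * p["u_raw"] ** 2))
            g["u_raw"] += -p["u_raw"]

        if self.free_sigma:
            g["log_sigma"] += sigma * (dsigma - 4 * sigma / (3 + sigma * sigma)) + 1.0
            lp += -2.0 * np.log1p(sigma * sigma / 3.0) + float(p["log_sigma"][0])

        if self.t_like and self.free_nu:
            # nu = 1 + gshift, gshift ~ Gamma(2, 0.1), log-Jacobian log(gshift)
            lp += 2.0 * np.log(gshift) - pr.t_df_rate * gshift
            g["nu_raw"] += gshift * (dnu - pr.t_df_rate) + 2.0

        # ---- coefficients ---------------------------------------------------
        lp += float(np.sum(-0.5 * (b / pr.coef_sd) ** 2))
        g["b"] += -b / pr.coef_sd**2

        # ---- measurement layer ----------------------------------------------
        if opt.latent_outcome:
            g["theta"] += dtheta
            if opt.theta_anchor:
                lp += float(np.sum(-0.5 * (theta / pr.theta_anchor_sd) ** 2))
                g["theta"] += -theta / pr.theta_anchor_sd**2

            cap = pr.discrimination_cap
            s = expit(p["alpha_raw"])
            alpha = cap * s
            sigma_beta = float(np.exp(p["log_sigma_beta"][0]))
            mu_beta = float(p["mu_beta"][0])
            beta = mu_beta + sigma_beta * p["beta_raw"]

            dev = theta[:, None] - beta[None, :]
            eta = alpha[None, :] * dev
            # Bernoulli-logit mass over observed cells
            sp = np.logaddexp(0.0, eta)
            lp += float(np.sum(self.y * eta - sp * self.obs_f))
            r = self.y - expit(eta) * self.obs_f
            g["theta"] += r @ alpha
            dalpha = np.einsum("dj,dj->j", r, dev)
            dbeta = -alpha * r.sum(axis=0)

            # alpha prior Gamma(shape, rate) on (0, cap] + logit-cap Jacobian
            dalpha_draw = alpha * (1.0 - alpha / cap)
            lp += float(
                np.sum((pr.discrimination_shape - 1) * np.log(alpha) - pr.discrimination_rate * alpha)
            )
            lp += float(np.sum(np.log(alpha) + np.log1p(-alpha / cap)))
            g["alpha_raw"] += (
                dalpha + (pr.discrimination_shape - 1) / alpha - pr.discrimination_rate
            ) * dalpha_draw + (1.0 - 2.0 * alpha / cap)

            # hierarchical difficulty
            lp += float(np.sum(-0.5 * p["beta_raw"] ** 2))
            g["beta_raw"] += sigma_beta * dbeta - p["beta_raw"]
            lp += -0.5 * (mu_beta / pr.item_difficulty_loc_sd) ** 2
            g["mu_beta"] += float(np.sum(dbeta)) - mu_beta / pr.item_difficulty_loc_sd**2
            dsb = float(np.dot(dbeta, p["beta_raw"]))
            lp += -2.0 * np.log1p(sigma_beta**2 / 3.0) + float(p["log_sigma_beta"][0])
            g["log_sigma_beta"] += (
                sigma_beta * (dsb - 4 * sigma_beta / (3 + sigma_beta**2)) + 1.0
            )

        # ---- multivariate-normal predictor block ----------------------------
        if opt.predictor_model:
            mu_x = p["mu_x"]
            lvals = p["lchol"]
            L = np.zeros((4, 4))
            L[_TRIL_R, _TRIL_C] = np.where(_IS_DIAG, np.exp(lvals), lvals)
            diagL = np.diag(L)
            R = (x - mu_x[None, :]).T  # (4, D)
            Z = _solve_lower4(L, R)
            A = _solve_upper4(L, Z)  # (4, D) = Sigma^{-1} r_d columns
            lp += -self.D * float(np.sum(np.log(diagL))) - 0.5 * float(np.sum(Z * Z))
            g["mu_x"] += A.sum(axis=1)
            if "x_miss" in p and len(self.x_miss_idx):
                g["x_miss"] += -A[self.x_miss_idx[:, 1], self.x_miss_idx[:, 0]]
            GL = (A @ A.T) @ L
            GL[np.diag_indices(4)] -= self.D / diagL
            # priors: diag half-t(3,0,1) (+Jacobian), off-diag N(0,1)
            lp += float(np.sum(-2.0 * np.log1p(diagL**2 / 3.0) + np.log(diagL)))
            lp += float(np.sum(-0.5 * L[_TRIL_R[~_IS_DIAG], _TRIL_C[~_IS_DIAG]] ** 2))
            gl = GL[_TRIL_R, _TRIL_C]
            dprior = np.zeros(10)
            dprior[_IS_DIAG] = -4.0 * diagL / (3.0 + diagL**2)
            gl_out = np.where(
                _IS_DIAG,
                (gl + dprior) * np.where(_IS_DIAG, np.exp(lvals), 1.0) + 1.0,
                gl - lvals,
            )
            g["lchol"] += gl_out
            lp += float(np.sum(-0.5 * mu_x**2))
            g["mu_x"] += -mu_x

        return lp, grad

    # -- initialization -------------------------------------------------------

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        v = np.zeros(self.dim)
        jitter = rng.normal(0.0, 0.05, size=self.dim)
        p = {k: v[s] for k, s in self.slices.items()}
        if self.options.latent_outcome:
            frac = np.where(
                self.obs_mask.sum(axis=1) > 0,
                self.y.sum(axis=1) / np.maximum(self.obs_mask.sum(axis=1), 1),
                0.5,
            )
            p["theta"][:] = 2.0 * (frac - 0.5)
            p["alpha_raw"][:] = -1.0  # alpha ~ 2.7 of cap 10
            p["log_sigma_beta"][:] = np.log(0.7)
        if self.free_sigma:
            p["log_sigma"][:] = np.log(0.7)
        if self.free_tau:
            p["log_tau"][:] = np.log(0.5)
        if self.free_nu:
            p["nu_raw"][:] = np.log(19.0)  # nu ~ 20
        if self.options.predictor_model:
            p["lchol"][:] = 0.0  # identity Cholesky (log-diag 0)
        return v + jitter

    # -- constrained draws ----------------------------------------------------

    def constrain(self, raw: np.ndarray) -> dict:
        """Map (n, dim) unconstrained draws to named constrained arrays."""
        out = {}
        sl = self.slices
        opt = self.options
        if opt.latent_outcome:
            out["theta"] = raw[:, sl["theta"]]
        if self.use_u:
            tau = (
                np.exp(raw[:, sl["log_tau"]])[:, 0]
                if self.free_tau
                else np.full(raw.shape[0], float(opt.fix_tau))
            )
            out["tau"] = tau
            out["u"] = raw[:, sl["u_raw"]] * tau[:, None]
        out["b"] = raw[:, sl["b"]]
        out["sigma"] = (
            np.exp(raw[:, sl["log_sigma"]])[:, 0]
            if self.free_sigma
            else np.full(raw.shape[0], float(opt.fix_sigma))
        )
        if self.t_like:
            out["nu"] = (
                1.0 + np.exp(raw[:, sl["nu_raw"]])[:, 0]
                if self.free_nu
                else np.full(raw.shape[0], float(opt.fix_nu))
            )
        if opt.latent_outcome:
            cap = self.priors.discrimination_cap
            out["alpha"] = cap * expit(raw[:, sl["alpha_raw"]])
            sigma_beta = np.exp(raw[:, sl["log_sigma_beta"]])[:, 0]
            mu_beta = raw[:, sl["mu_beta"]][:, 0]
            out["beta"] = mu_beta[:, None] + sigma_beta[:, None] * raw[:, sl["beta_raw"]]
            out["mu_beta"], out["sigma_beta"] = mu_beta, sigma_beta
        if opt.predictor_model:
            out["mu_x"] = raw[:, sl["mu_x"]]
            lv = raw[:, sl["lchol"]]
            n = raw.shape[0]
            Ls = np.zeros((n, 4, 4))
            Ls[:, _TRIL_R, _TRIL_C] = np.where(_IS_DIAG[None, :], np.exp(lv), lv)
            out["Sigma_x"] = np.einsum("nij,nkj->nik", Ls, Ls)
            if "x_miss" in sl:
                out["x_miss"] = raw[:, sl["x_miss"]]
        return out


# ---------------------------------------------------------------------------
# fitting


def dyad_item_matrix(dataset: StudyDataset) -> np.ndarray:
    """CBQ responses as a (n_dyads, 16) float matrix with NaN missing."""
    return np.vstack([d.cbq_items for d in dataset.dyads])


def fit_joint(
    spec: ModelSpec,
    matrix: PredictorMatrix,
    y_items: np.ndarray | None = None,
    y_cont: np.ndarray | None = None,
    priors: PriorSpec = PriorSpec(),
    options: ModelOptions = ModelOptions(),
    sampler: SamplerConfig = SamplerConfig(),
    check_convergence: bool = True,
    rhat_threshold: float = 1.01,
    ess_threshold: float = 400.0,
) -> PosteriorSamples:
    """Sample the joint posterior with NUTS; returns per-chain named draws.

    Reproducible under ``sampler.seed``; warns (never silently passes) when
    split R-hat or bulk ESS of the regression parameters fail their
    thresholds, and reports divergent transitions in the diagnostics.
    """
    model = JointModel(
        spec, matrix, y_items=y_items, y_cont=y_cont, priors=priors, options=options
    )
    chains_raw = []
    diagnostics = {"divergences": [], "step_size": [], "mean_accept": [], "treedepth_hits": []}
    for c in range(sampler.chains):
        ss = np.random.SeedSequence(entropy=[int(sampler.seed) & 0x7FFFFFFF, c])
        child = ss.generate_state(1)[0] % (2**31 - 1)
        rng = np.random.default_rng(child)
        x0 = model.initial_point(rng)
        res = sample_nuts(
            model.logp_grad,
            x0,
            n_warmup=sampler.warmup_iterations,
            n_draws=sampler.sampling_iterations,
            seed=int(child),
            target_accept=sampler.target_acceptance,
            max_treedepth=sampler.max_treedepth,
        )
        chains_raw.append(res.draws)
        diagnostics["divergences"].append(res.n_divergent)
        diagnostics["step_size"].append(res.step_size)
        diagnostics["mean_accept"].append(res.mean_accept)
        diagnostics["treedepth_hits"].append(res.max_treedepth_hits)

    raw = np.stack(chains_raw)  # (chains, draws, dim)
    flat = raw.reshape(-1, raw.shape[-1])
    named_flat = model.constrain(flat)
    draws = {
        k: v.reshape(raw.shape[0], raw.shape[1], *v.shape[1:]) for k, v in named_flat.items()
    }
    post = PosteriorSamples(
        draws=draws,
        coef_names=spec.coef_names,
        spec=spec,
        options=options,
        diagnostics=diagnostics,
    )

    if check_convergence and sampler.chains >= 2:
        import arviz as az

        issues = []
        bd = draws["b"]
        for k, name in enumerate(spec.coef_names):
            r = float(az.rhat(bd[:, :, k]))
            e = float(az.ess(bd[:, :, k]))
            if r > rhat_threshold:
                issues.append(f"{name}: R-hat {r:.3f}")
            if e < ess_threshold:
                issues.append(f"{name}: ESS {e:.0f}")
        if issues:
            warnings.warn(
                "convergence criteria unmet for: " + "; ".join(issues), stacklevel=2
            )
        post.diagnostics["convergence_issues"] = issues
    return post


# ---------------------------------------------------------------------------
# held-out family likelihood and predictor correlations


def conditional_mean_impute(x_row: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Fill NaN entries of a 4-vector with E[x_miss | x_obs] under N(mu, Sigma)."""
    miss = np.isnan(x_row)
    if not miss.any():
        return x_row
    if miss.all():
        return mu.copy()
    out = x_row.copy()
    So = Sigma[np.ix_(~miss, ~miss)]
    Smo = Sigma[np.ix_(miss, ~miss)]
    out[miss] = mu[miss] + Smo @ np.linalg.solve(So, x_row[~miss] - mu[~miss])
    return out


def loglik_family(
    posterior: PosteriorSamples,
    spec: ModelSpec,
    family_x: np.ndarray,
    family_mother: np.ndarray,
    family_age: np.ndarray,
    family_items: np.ndarray,
    integrate_intercept_draws: int = 0,
    plugin_posterior_mean: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Per-draw log likelihood of one held-out family's observed conflict items.

    The dyad's latent level is set to the regression expected value x'b
    (+ intercept), with the new family's random intercept at its prior mean 0;
    the summed log probability mass of the observed items is returned per
    pooled posterior draw.  Missing continuous predictors of the held-out
    family are plugged in as their conditional mean under the fitted
    multivariate normal, per draw.

    ``integrate_intercept_draws > 0`` instead integrates the unseen family's
    intercept over Normal(0, tau) by Monte Carlo (that many samples per
    posterior draw).  ``plugin_posterior_mean=True`` evaluates a single
    plug-in likelihood at the posterior means of all parameters and returns a
    length-1 array.
    """
    y = np.asarray(family_items, dtype=float)
    observed_outcome = not posterior.options.latent_outcome
    if observed_outcome:
        if y.ndim != 1:
            raise ValueError("observed-outcome model expects a (n_dyads,) outcome")
    else:
        if y.ndim != 2:
            raise ValueError("family_items must be (n_dyads, n_items)")
        obs = ~np.isnan(y)
        if not obs.any():
            raise ValueError("family has no observed items")
    b = posterior.pooled("b")  # (S, K)
    if plugin_posterior_mean:
        b = b.mean(axis=0, keepdims=True)
    S = b.shape[0]
    x = np.asarray(family_x, dtype=float)

    def _pooled(name: str) -> np.ndarray:
        arr = posterior.pooled(name)
        return arr.mean(axis=0, keepdims=True) if plugin_posterior_mean else arr

    if np.isnan(x).any():
        if "mu_x" not in posterior.draws:
            raise ValueError("held-out family has missing predictors but the fit "
                             "had no predictor model")
        mu_x = _pooled("mu_x")
        Sig = _pooled("Sigma_x")
        m_list = np.empty((S, x.shape[0]))
        for s in range(S):
            xs = np.vstack([conditional_mean_impute(row, mu_x[s], Sig[s]) for row in x])
            W, _, _ = _design_and_grad_map(spec, xs, family_mother, family_age)
            m_list[s] = W @ b[s]
        m = m_list  # (S, n_dyads)
    else:
        W, _, _ = _design_and_grad_map(spec, x, family_mother, family_age)
        m = b @ W.T  # (S, n_dyads)

    if observed_outcome:
        sigma = _pooled("sigma")[:, None]  # (S, 1)
        nu = _pooled("nu")[:, None] if "nu" in posterior.draws else None

        def _ll_given_m(m_eval: np.ndarray) -> np.ndarray:
            z = (y[None, :] - m_eval) / sigma
            if nu is not None:
                from scipy.special import gammaln as _gl

                ll = (
                    _gl((nu + 1) / 2)
                    - _gl(nu / 2)
                    - 0.5 * np.log(nu * np.pi)
                    - np.log(sigma)
                    - (nu + 1) / 2 * np.log1p(z**2 / nu)
                )
            else:
                ll = -0.5 * z**2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
            return ll.sum(axis=1)

    else:
        alpha = _pooled("alpha")  # (S, J)
        beta = _pooled("beta")
        yb = np.where(obs, y, 0.0)

        def _ll_given_m(m_eval: np.ndarray) -> np.ndarray:
            # eta: (S, n_dyads, J)
            eta = alpha[:, None, :] * (m_eval[:, :, None] - beta[:, None, :])
            sp = np.logaddexp(0.0, eta)
            ll = np.where(obs[None, :, :], yb[None, :, :] * eta - sp, 0.0)
            return ll.sum(axis=(1, 2))

    if integrate_intercept_draws <= 0 or "tau" not in posterior.draws:
        return _ll_given_m(m)

    # Monte Carlo over the unseen family's intercept u ~ Normal(0, tau)
    tau = _pooled("tau")
    rng = np.random.default_rng(seed)
    acc = np.full(S, -np.inf)
    for _ in range(integrate_intercept_draws):
        u = rng.standard_normal(S) * tau
        acc = np.logaddexp(acc, _ll_given_m(m + u[:, None]))
    return acc - np.log(integrate_intercept_draws)


def predictor_correlations(posterior: PosteriorSamples, ci: float = 0.93) -> pd.DataFrame:
    """Posterior mean and CI of each pairwise predictor correlation."""
    if "Sigma_x" not in posterior.draws:
        raise ValueError("fit did not include the multivariate normal predictor model")
    Sig = posterior.pooled("Sigma_x")
    d = np.sqrt(np.einsum("nii->ni", Sig))
    corr = Sig / (d[:, :, None] * d[:, None, :])
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for i in range(4):
        for j in range(i):
            c = corr[:, i, j]
            rows.append(
                {
                    "pair": f"{PREDICTOR_BLOCK[i]}-{PREDICTOR_BLOCK[j]}",
                    "mean": float(np.mean(c)),
                    "ci_low": float(np.quantile(c, lo_q)),
                    "ci_high": float(np.quantile(c, hi_q)),
                }
            )
    return pd.DataFrame(rows).set_index("pair")
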